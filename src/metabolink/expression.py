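"""Similarity between perturbation transcriptional profiles.

Each compound carries a gene-level z-score signature describing how it
perturbs expression.  Two similarity statistics are provided:

* :func:`spearman_similarity` — rank correlation over the shared genes.
  Symmetric, parameter-free; the default.
* :func:`connectivity_similarity` — connectivity-map style: the query's
  most up- and down-regulated genes are scored against the reference's
  ranked profile with a two-sided Kolmogorov–Smirnov enrichment statistic.
  Directional; callers symmetrize by averaging the two directions.

Both live on [-1, 1]; :func:`to_unit_interval` maps onto [0, 1] so that the
expression half can be fused with the structural half of the score.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

MIN_SHARED_GENES = 3


@dataclass
class PerturbationSignature:
    """Per-compound gene-level z-score profile."""

    compound_id: str
    values: pd.Series  # index: gene ids, values: z-scores

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            raise ValueError(f"duplicate gene ids in signature {self.compound_id!r}")
        if not np.all(np.isfinite(self.values.to_numpy(dtype=float))):
            raise ValueError(f"non-finite z-score in signature {self.compound_id!r}")

    @property
    def gene_space(self) -> list[str]:
        return list(self.values.index)

    def __len__(self) -> int:
        return len(self.values)


def spearman_similarity(
    a: PerturbationSignature, b: PerturbationSignature
) -> Optional[float]:
    """Spearman rank correlation over the genes shared by two signatures.

    Ties receive average ranks.  Returns ``None`` (missing-value marker)
    when fewer than three genes are shared or when either restricted vector
    is constant, so the caller can fall back to structure-only scoring.
    """
    shared = a.values.index.intersection(b.values.index).sort_values()
    if len(shared) < MIN_SHARED_GENES:
        log.info(
            "signatures %s/%s share %d genes (<%d); expression similarity missing",
            a.compound_id, b.compound_id, len(shared), MIN_SHARED_GENES,
        )
        return None
    x = a.values.loc[shared].to_numpy(dtype=float)
    y = b.values.loc[shared].to_numpy(dtype=float)
    with warnings.catch_warnings():
        # a constant restriction is handled below as a missing value
        warnings.simplefilter("ignore", stats.ConstantInputWarning)
        rho = stats.spearmanr(x, y).statistic
    if not math.isfinite(rho):
        log.info(
            "constant signature restriction for %s/%s; expression similarity missing",
            a.compound_id, b.compound_id,
        )
        return None
    return float(rho)


def _ks_enrichment(hit_ranks: Sequence[int], n: int) -> float:
    """Two-sided KS enrichment of a hit set within a ranked list of length n.

    ``hit_ranks`` are 1-based positions, sorted ascending; with t hits,
    a = max_j (j/t − V(j)/n), b = max_j (V(j)/n − (j−1)/t) and the statistic
    is a if a > b else −b.
    """
    t = len(hit_ranks)
    if t == 0:
        return 0.0
    a = max(j / t - v / n for j, v in enumerate(hit_ranks, start=1))
    b = max(v / n - (j - 1) / t for j, v in enumerate(hit_ranks, start=1))
    return a if a > b else -b


def rank_genes(sig: PerturbationSignature) -> list[str]:
    """Reference order: genes by z-score descending, ties by gene id."""
    items = sorted(zip(sig.values.index, sig.values.to_numpy(dtype=float)),
                   key=lambda kv: (-kv[1], kv[0]))
    return [g for g, _ in items]


def extreme_gene_sets(
    sig: PerturbationSignature, top_n: int
) -> tuple[list[str], list[str]]:
    """The query's top_n most up- and down-regulated genes (ties by gene id)."""
    genes = list(sig.values.index)
    z = sig.values.to_numpy(dtype=float)
    up = sorted(zip(genes, z), key=lambda kv: (-kv[1], kv[0]))[:top_n]
    down = sorted(zip(genes, z), key=lambda kv: (kv[1], kv[0]))[:top_n]
    return [g for g, _ in up], [g for g, _ in down]


def connectivity_similarity(
    a: PerturbationSignature, b: PerturbationSignature, top_n: int = 50
) -> float:
    """Connectivity score of query *a* against reference *b*.

    The query's ``top_n`` highest-z genes form the up set and its ``top_n``
    lowest the down set; each set is scored against the reference's z-ranked
    gene list with the two-sided KS enrichment statistic and the result is
    ``(ES_up − ES_down) / 2`` in [−1, 1].  Positive values mean the query's
    up genes sit high and its down genes sit low in the reference profile.

    Directional by construction: callers wanting a symmetric score average
    ``connectivity_similarity(a, b)`` with ``connectivity_similarity(b, a)``.
    """
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    shared = set(a.values.index) & set(b.values.index)
    if top_n > len(shared) / 2:
        raise ValueError(
            f"top_n={top_n} exceeds half the shared gene count ({len(shared)})"
        )
    ranked = rank_genes(b)
    pos = {g: i + 1 for i, g in enumerate(ranked)}
    n = len(ranked)
    up, down = extreme_gene_sets(a, top_n)
    up_ranks = sorted(pos[g] for g in up if g in pos)
    down_ranks = sorted(pos[g] for g in down if g in pos)
    es_up = _ks_enrichment(up_ranks, n)
    es_down = _ks_enrichment(down_ranks, n)
    return (es_up - es_down) / 2.0


def to_unit_interval(s: float) -> float:
    """Affine map of a similarity in [−1, 1] onto [0, 1]: ``(s + 1) / 2``."""
    if not -1.0 <= s <= 1.0:
        raise ValueError(f"similarity {s} outside [-1, 1]")
    return (s + 1.0) / 2.0
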