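"""Fused metabolite–drug similarity score and the ranked pair table.

The combined score is a convex combination of the structural Tanimoto
similarity and the expression similarity mapped onto [0, 1]:

    score = alpha * s_struct + (1 - alpha) * s_expr

with two overrides: a pair whose canonical SMILES are equal is *identical*
and scores exactly 1.0 regardless of expression (score 1.0 is reserved for
exact compounds — drugs a microbe makes verbatim), and a pair with no usable
expression similarity falls back to structure only (score = s_struct).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .chem import CompoundRecord, Fingerprint, canonicalize, fingerprint, tanimoto
from .expression import (
    PerturbationSignature,
    connectivity_similarity,
    spearman_similarity,
    to_unit_interval,
)

log = logging.getLogger(__name__)

PAIR_COLUMNS = [
    "metabolite_id", "drug_id", "s_struct", "s_expr",
    "score", "identical_structure", "rank",
]


def combine(
    s_struct: float,
    s_expr: Optional[float],
    alpha: float = 0.5,
    identical: bool = False,
) -> float:
    """Fuse structural and expression similarity into one [0, 1] score."""
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha={alpha} outside [0, 1]")
    if not 0.0 <= s_struct <= 1.0:
        raise ValueError(f"s_struct={s_struct} outside [0, 1]")
    if s_expr is not None and not 0.0 <= s_expr <= 1.0:
        raise ValueError(f"s_expr={s_expr} outside [0, 1]")
    if identical:
        return 1.0
    if s_expr is None:
        return s_struct
    return alpha * s_struct + (1.0 - alpha) * s_expr


@dataclass
class ScoreRunSummary:
    """Bookkeeping for one scoring run."""

    n_metabolites_in: int = 0
    n_drugs_in: int = 0
    excluded_metabolites: list[str] = field(default_factory=list)
    excluded_drugs: list[str] = field(default_factory=list)
    n_pairs: int = 0
    n_pairs_without_expression: int = 0
    n_identical: int = 0

    def as_dict(self) -> dict:
        return {
            "n_metabolites_in": self.n_metabolites_in,
            "n_drugs_in": self.n_drugs_in,
            "excluded_metabolites": sorted(self.excluded_metabolites),
            "excluded_drugs": sorted(self.excluded_drugs),
            "n_excluded_compounds": len(self.excluded_metabolites) + len(self.excluded_drugs),
            "n_pairs": self.n_pairs,
            "n_pairs_without_expression": self.n_pairs_without_expression,
            "n_identical": self.n_identical,
        }


def _prepare(
    records: Sequence[CompoundRecord],
    excluded: list[str],
    fp_kind: str,
    fp_radius: int,
    fp_bits: int,
) -> dict[str, tuple[str, Fingerprint]]:
    """Canonical SMILES + fingerprint per valid compound; invalid excluded."""
    out: dict[str, tuple[str, Fingerprint]] = {}
    for rec in records:
        canon = canonicalize(rec.smiles)
        if canon is None:
            log.warning("excluding compound %s: invalid SMILES", rec.compound_id)
            excluded.append(rec.compound_id)
            continue
        out[rec.compound_id] = (
            canon,
            fingerprint(canon, kind=fp_kind, radius=fp_radius, n_bits=fp_bits),
        )
    return out


def _expression_scores(
    met_ids: Sequence[str],
    drug_ids: Sequence[str],
    signatures: Mapping[str, PerturbationSignature],
    method: str,
    top_n: int,
) -> dict[tuple[str, str], Optional[float]]:
    """Raw [-1, 1] expression similarity per pair (None where unavailable).

    Spearman has a vectorized fast path when all signatures live on one gene
    space: Spearman is Pearson on ranks, so a single correlation of the rank
    matrix covers every pair.
    """
    out: dict[tuple[str, str], Optional[float]] = {}
    have = [cid for cid in (*met_ids, *drug_ids) if cid in signatures]
    if method == "spearman" and have:
        spaces = {tuple(signatures[c].gene_space) for c in have}
        if len(spaces) == 1 and len(next(iter(spaces))) >= 3:
            mat = np.vstack([
                pd.Series(signatures[c].values).rank(method="average").to_numpy()
                for c in have
            ])
            with np.errstate(invalid="ignore"):
                corr = np.corrcoef(mat)
            idx = {c: i for i, c in enumerate(have)}
            for m in met_ids:
                for d in drug_ids:
                    if m in idx and d in idx:
                        rho = corr[idx[m], idx[d]]
                        out[(m, d)] = float(rho) if np.isfinite(rho) else None
                    else:
                        out[(m, d)] = None
            return out
    for m in met_ids:
        for d in drug_ids:
            sm, sd = signatures.get(m), signatures.get(d)
            if sm is None or sd is None:
                out[(m, d)] = None
            elif method == "spearman":
                out[(m, d)] = spearman_similarity(sm, sd)
            elif method == "connectivity":
                # directional statistic, symmetrized by direction averaging
                try:
                    out[(m, d)] = 0.5 * (
                        connectivity_similarity(sm, sd, top_n=top_n)
                        + connectivity_similarity(sd, sm, top_n=top_n)
                    )
                except ValueError:
                    out[(m, d)] = None
            else:
                raise ValueError(f"unknown expression method {method!r}")
    return out


def score_all_pairs(
    metabolites: Sequence[CompoundRecord],
    drugs: Sequence[CompoundRecord],
    signatures: Mapping[str, PerturbationSignature],
    alpha: float = 0.5,
    expression_method: str = "spearman",
    top_n: int = 50,
    fp_kind: str = "morgan",
    fp_radius: int = 2,
    fp_bits: int = 2048,
) -> tuple[pd.DataFrame, ScoreRunSummary]:
    """Score every valid metabolite × drug pair and rank the table.

    Returns the pair table (columns :data:`PAIR_COLUMNS`, sorted by score
    descending with ties broken by ``(metabolite_id, drug_id)``; ``s_expr``
    is NaN where no expression similarity was available) and a run summary
    counting exclusions and expression fallbacks.
    """
    summary = ScoreRunSummary(
        n_metabolites_in=len(metabolites), n_drugs_in=len(drugs)
    )
    mets = _prepare(metabolites, summary.excluded_metabolites, fp_kind, fp_radius, fp_bits)
    drgs = _prepare(drugs, summary.excluded_drugs, fp_kind, fp_radius, fp_bits)
    if not mets or not drgs:
        raise ValueError("no valid metabolites or no valid drugs to score")

    met_ids = sorted(mets)
    drug_ids = sorted(drgs)
    expr = _expression_scores(met_ids, drug_ids, signatures, expression_method, top_n)

    rows = []
    for m in met_ids:
        canon_m, fp_m = mets[m]
        for d in drug_ids:
            canon_d, fp_d = drgs[d]
            identical = canon_m == canon_d
            s_struct = tanimoto(fp_m, fp_d)
            raw = expr[(m, d)]
            s_expr = to_unit_interval(raw) if raw is not None else None
            if s_expr is None:
                summary.n_pairs_without_expression += 1
            if identical:
                summary.n_identical += 1
            rows.append(
                (m, d, s_struct, np.nan if s_expr is None else s_expr,
                 combine(s_struct, s_expr, alpha=alpha, identical=identical),
                 identical)
            )
    table = pd.DataFrame(
        rows,
        columns=["metabolite_id", "drug_id", "s_struct", "s_expr", "score",
                 "identical_structure"],
    )
    table = table.sort_values(
        ["score", "metabolite_id", "drug_id"], ascending=[False, True, True]
    ).reset_index(drop=True)
    table["rank"] = np.arange(1, len(table) + 1)
    summary.n_pairs = len(table)
    return table, summary
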