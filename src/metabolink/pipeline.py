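"""End-to-end pipeline: score → benchmark → bicluster → network → propagate.

Given a validated input bundle and a :class:`~metabolink.config.RunConfig`,
runs every stage in order and returns (optionally writing) the full artifact
bundle: ranked pair table, precision curve, biclusters, network exports,
linkage tables and a JSON run summary.  The pipeline proper is deterministic
for fixed inputs and config; randomness exists only in fixture generation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import networkx as nx
import pandas as pd

from . import io as mio
from .benchmark import label_counts, label_pairs, precision_curve
from .biclustering import Bicluster, build_score_matrix, discretize, qubic
from .config import RunConfig
from .mapping import (
    MicrobeLinkage,
    build_network,
    hubs_and_islands,
    linkage_summary,
    phylum_atc_summary,
    propagate_annotations,
)
from .scoring import score_all_pairs

log = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    """All artifacts of one pipeline run."""

    pairs: pd.DataFrame
    labeled: pd.DataFrame
    curve: pd.DataFrame
    score_matrix: pd.DataFrame
    biclusters: list[Bicluster]
    graph: nx.Graph
    hubs: list[str]
    islands: list[str]
    phylum_atc: pd.DataFrame
    linkages: list[MicrobeLinkage]
    summary: dict


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            log.info("[%s] start", name)
            try:
                return fn(*args, **kwargs)
            except Exception as e:
                raise RuntimeError(f"pipeline stage {name!r} failed: {e}") from e
        return wrapped
    return deco


def run_pipeline(
    dataset: mio.Dataset,
    config: Optional[RunConfig] = None,
    outdir=None,
) -> PipelineResult:
    """Run every stage on a dataset; write the artifact bundle if outdir given."""
    cfg = config or RunConfig()

    pairs, score_summary = _stage("score")(score_all_pairs)(
        dataset.metabolites, dataset.drugs, dataset.signatures,
        alpha=cfg.alpha, expression_method=cfg.expression_method, top_n=cfg.top_n,
        fp_kind=cfg.fp_kind, fp_radius=cfg.fp_radius, fp_bits=cfg.fp_bits,
    )

    labeled = _stage("benchmark")(label_pairs)(pairs, dataset.pathway_annotations)
    curve = precision_curve(labeled, cfg.benchmark_thresholds,
                            inclusive=cfg.inclusive_threshold)

    matrix = _stage("bicluster")(build_score_matrix)(
        pairs, dataset.microbes, cutoff=cfg.bicluster_cutoff
    )
    # binarize at the cutoff before discretization: presence of a qualifying
    # link is the qualitative signal of interest (cells below the cutoff are
    # already zeroed by build_score_matrix)
    binary = (matrix > 0).astype(float)
    qm = discretize(binary, r=cfg.qubic_r, q=cfg.qubic_q)
    blocks = qubic(qm, c=cfg.qubic_c, o=cfg.qubic_o, f=cfg.qubic_f)

    graph = _stage("network")(build_network)(
        pairs, dataset.microbes, dataset.drug_annotations, cutoff=cfg.bicluster_cutoff
    )
    if graph.number_of_edges() > 0:
        hubs, islands = hubs_and_islands(graph, by=cfg.hub_ranking)
    else:
        hubs, islands = [], []
    phylum_atc = phylum_atc_summary(graph)

    linkages = _stage("propagate")(propagate_annotations)(
        pairs, dataset.microbes, dataset.drug_annotations,
        linkage_cutoff=cfg.linkage_cutoff,
    )

    summary = {
        "config": cfg.as_dict(),
        "scoring": score_summary.as_dict(),
        "benchmark": {
            "label_counts": label_counts(labeled),
            "curve": curve.where(pd.notna(curve), None).to_dict(orient="records"),
        },
        "biclustering": {
            "n_biclusters": len(blocks),
            "top_block_size": blocks[0].size if blocks else 0,
        },
        "network": {
            "n_microbe_nodes": sum(
                1 for _, d in graph.nodes(data=True) if d.get("bipartite") == "microbe"
            ),
            "n_drug_nodes": sum(
                1 for _, d in graph.nodes(data=True) if d.get("bipartite") == "drug"
            ),
            "n_edges": graph.number_of_edges(),
            "total_edge_weight": int(
                sum(d["weight"] for _, _, d in graph.edges(data=True))
            ),
            "hubs": hubs,
            "islands": islands,
        },
        "linkages": linkage_summary(linkages),
        "input_warnings": list(dataset.warnings),
        "n_input_warnings": len(dataset.warnings),
    }

    result = PipelineResult(
        pairs=pairs, labeled=labeled, curve=curve, score_matrix=matrix,
        biclusters=blocks, graph=graph, hubs=hubs, islands=islands,
        phylum_atc=phylum_atc, linkages=linkages, summary=summary,
    )
    if outdir is not None:
        write_artifacts(result, outdir)
    return result


def write_artifacts(result: PipelineResult, outdir) -> dict[str, Path]:
    """Write the six output families of one run into a directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    mio.write_pairs(result.pairs, outdir / "pairs.tsv")
    mio.write_curve(result.curve, outdir / "precision_curve.tsv")
    mio.write_matrix(result.score_matrix, outdir / "score_matrix.tsv")
    mio.write_biclusters(result.biclusters, outdir / "biclusters.txt",
                         outdir / "biclusters.json")
    mio.write_edge_list(result.graph, outdir / "edges.tsv")
    if not result.phylum_atc.empty:
        result.phylum_atc.to_csv(outdir / "phylum_atc.tsv", sep="\t",
                                 index_label="phylum")
    pd.DataFrame(
        {"microbe_id": result.hubs + result.islands,
         "role": ["hub"] * len(result.hubs) + ["island"] * len(result.islands)}
    ).to_csv(outdir / "hubs_islands.tsv", sep="\t", index=False)
    mio.write_linkages(result.linkages, outdir)
    mio.write_summary(result.summary, outdir / "summary.json")
    return {"outdir": outdir}
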