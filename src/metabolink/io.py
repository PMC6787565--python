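"""Readers and writers for the interchange formats.

TSV is the dialect throughout (ids and annotation terms may contain commas);
in-cell lists are semicolon-separated and missing numerics serialize as
``NA``.  Every writer has a matching reader that recovers the fields
losslessly.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .benchmark import PathwayAnnotation
from .biclustering import Bicluster, format_blocks
from .chem import CompoundRecord, CompoundSource
from .expression import PerturbationSignature
from .mapping import DrugAnnotation, MicrobeLinkage, MicrobeRecord

log = logging.getLogger(__name__)

NA = "NA"


def _split(cell: str) -> frozenset[str]:
    return frozenset(x for x in str(cell).split(";") if x) if cell and str(cell) != NA else frozenset()


def _join(items: Iterable[str]) -> str:
    s = ";".join(sorted(items))
    return s if s else NA


def _require_columns(df: pd.DataFrame, cols: Sequence[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing mandatory column(s) {', '.join(missing)}")


# ---------------------------------------------------------------- compounds

def read_compounds(path) -> list[CompoundRecord]:
    """Compound table TSV with header ``compound_id name smiles source``."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    _require_columns(df, ["compound_id", "name", "smiles", "source"], path)
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            records.append(
                CompoundRecord(row.compound_id, row.name, row.smiles,
                               CompoundSource(row.source))
            )
        except ValueError as e:
            raise ValueError(f"{path}:{i}: {e}") from e
    ids = [r.compound_id for r in records]
    if len(set(ids)) != len(ids):
        dupes = sorted({x for x in ids if ids.count(x) > 1})
        raise ValueError(f"{path}: duplicate compound_id(s): {', '.join(dupes)}")
    return records


def write_compounds(records: Sequence[CompoundRecord], path) -> None:
    pd.DataFrame(
        [(r.compound_id, r.name, r.smiles, r.source.value) for r in records],
        columns=["compound_id", "name", "smiles", "source"],
    ).to_csv(path, sep="\t", index=False)


def read_compounds_sdf(path, source: CompoundSource) -> list[CompoundRecord]:
    """SDF reader: molecule title becomes the compound_id."""
    from rdkit import Chem

    records = []
    for mol in Chem.SDMolSupplier(str(path)):
        if mol is None:
            log.warning("%s: skipping unparseable SDF record", path)
            continue
        name = mol.GetProp("_Name") if mol.HasProp("_Name") else ""
        if not name:
            log.warning("%s: skipping SDF record without a title", path)
            continue
        records.append(CompoundRecord(name, name, Chem.MolToSmiles(mol), source))
    return records


# --------------------------------------------------------------- signatures

def read_signatures(path) -> dict[str, PerturbationSignature]:
    """Signature matrix TSV: first column gene_id, one column per compound."""
    df = pd.read_csv(path, sep="\t", index_col="gene_id", float_precision="round_trip")
    return {
        cid: PerturbationSignature(cid, df[cid].astype(float))
        for cid in df.columns
    }


def write_signatures(signatures: Mapping[str, PerturbationSignature], path) -> None:
    df = pd.DataFrame({cid: sig.values for cid, sig in sorted(signatures.items())})
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t")


# ----------------------------------------------------------------- pathways

def read_pathways_long(path) -> dict[str, PathwayAnnotation]:
    """Long-format membership TSV: ``entity_id pathway_id disease_related``."""
    df = pd.read_csv(path, sep="\t", dtype={"entity_id": str, "pathway_id": str})
    _require_columns(df, ["entity_id", "pathway_id", "disease_related"], path)
    memb: dict[str, set[str]] = {}
    dis: dict[str, set[str]] = {}
    for row in df.itertuples(index=False):
        memb.setdefault(row.entity_id, set()).add(row.pathway_id)
        if bool(row.disease_related):
            dis.setdefault(row.entity_id, set()).add(row.pathway_id)
    return {
        e: PathwayAnnotation(e, frozenset(memb[e]), frozenset(dis.get(e, ())))
        for e in memb
    }


def write_pathways_long(annotations: Mapping[str, PathwayAnnotation], path) -> None:
    rows = [
        (e, pw, pw in ann.disease_related)
        for e, ann in sorted(annotations.items())
        for pw in sorted(ann.pathways)
    ]
    pd.DataFrame(rows, columns=["entity_id", "pathway_id", "disease_related"]).to_csv(
        path, sep="\t", index=False
    )


def read_pathways_gmt(gmt_path, disease_ids_path=None) -> dict[str, PathwayAnnotation]:
    """GMT gene-set format: ``pathway_id<TAB>description<TAB>entity…`` per line,
    with an optional one-column file of disease-related pathway ids."""
    disease_ids: set[str] = set()
    if disease_ids_path is not None:
        disease_ids = {
            line.strip() for line in Path(disease_ids_path).read_text().splitlines()
            if line.strip()
        }
    memb: dict[str, set[str]] = {}
    for lineno, line in enumerate(Path(gmt_path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"{gmt_path}:{lineno}: malformed GMT line (<3 fields)")
        pw, _desc, *entities = parts
        for e in entities:
            if e:
                memb.setdefault(e, set()).add(pw)
    return {
        e: PathwayAnnotation(e, frozenset(pws), frozenset(pws & disease_ids))
        for e, pws in memb.items()
    }


# ----------------------------------------------------- microbes & drug ann.

def read_microbes(path) -> list[MicrobeRecord]:
    """Microbe table TSV: ``microbe_id taxon_name phylum habitat metabolite_ids``
    with semicolon-separated metabolite ids."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    _require_columns(
        df, ["microbe_id", "taxon_name", "phylum", "habitat", "metabolite_ids"], path
    )
    out = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            out.append(
                MicrobeRecord(row.microbe_id, row.taxon_name, row.phylum,
                              row.habitat, _split(row.metabolite_ids))
            )
        except ValueError as e:
            raise ValueError(f"{path}:{i}: {e}") from e
    return out


def write_microbes(microbes: Sequence[MicrobeRecord], path) -> None:
    pd.DataFrame(
        [(m.microbe_id, m.taxon_name, m.phylum, m.habitat, _join(m.metabolite_ids))
         for m in microbes],
        columns=["microbe_id", "taxon_name", "phylum", "habitat", "metabolite_ids"],
    ).to_csv(path, sep="\t", index=False)


def read_drug_annotations(path) -> dict[str, DrugAnnotation]:
    """Drug annotation TSV: semicolon-separated ATC codes and term lists."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    _require_columns(
        df,
        ["drug_id", "atc_codes", "indications", "side_effects", "immune_transitions"],
        path,
    )
    out = {}
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            out[row.drug_id] = DrugAnnotation(
                row.drug_id, _split(row.atc_codes), _split(row.indications),
                _split(row.side_effects), _split(row.immune_transitions),
            )
        except ValueError as e:
            raise ValueError(f"{path}:{i}: {e}") from e
    return out


def write_drug_annotations(annotations: Mapping[str, DrugAnnotation], path) -> None:
    pd.DataFrame(
        [(a.drug_id, _join(a.atc_codes), _join(a.indications),
          _join(a.side_effects), _join(a.immune_transitions))
         for _, a in sorted(annotations.items())],
        columns=["drug_id", "atc_codes", "indications", "side_effects",
                 "immune_transitions"],
    ).to_csv(path, sep="\t", index=False)


# ------------------------------------------------------------ pipeline outputs

def write_pairs(pairs: pd.DataFrame, path) -> None:
    out = pairs.copy()
    out["s_expr"] = out["s_expr"].map(lambda v: NA if pd.isna(v) else repr(float(v)))
    out["identical_structure"] = out["identical_structure"].map(lambda b: str(bool(b)))
    out.to_csv(path, sep="\t", index=False)


def read_pairs(path) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t",
        dtype={"metabolite_id": str, "drug_id": str, "identical_structure": str},
        na_values=[NA], keep_default_na=False, float_precision="round_trip",
    )
    df["identical_structure"] = df["identical_structure"] == "True"
    df["s_expr"] = df["s_expr"].astype(float)
    return df


def write_curve(curve: pd.DataFrame, path) -> None:
    curve.to_csv(path, sep="\t", index=False, na_rep=NA)


def read_curve(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=[NA], keep_default_na=False,
                       float_precision="round_trip")


def write_matrix(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t", index_label="row_id")


def read_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="row_id", float_precision="round_trip")


def write_biclusters(blocks: Sequence[Bicluster], text_path, json_path) -> None:
    Path(text_path).write_text(format_blocks(blocks))
    payload = [
        {"rows": list(b.rows), "cols": list(b.cols), "consistency": b.consistency}
        for b in blocks
    ]
    Path(json_path).write_text(json.dumps(payload, indent=2) + "\n")


def read_biclusters(json_path) -> list[Bicluster]:
    payload = json.loads(Path(json_path).read_text())
    return [
        Bicluster(rows=tuple(b["rows"]), cols=tuple(b["cols"]),
                  consistency=b["consistency"])
        for b in payload
    ]


def write_edge_list(graph, path) -> None:
    """Edge-list TSV: ``microbe_id drug_id weight phylum atc_letters``."""
    rows = []
    for u, v, data in graph.edges(data=True):
        if graph.nodes[u].get("bipartite") == "microbe":
            mic, drug = u, v
        else:
            mic, drug = v, u
        rows.append(
            (mic, drug, data["weight"], graph.nodes[mic]["phylum"],
             _join(graph.nodes[drug].get("atc_letters", ())))
        )
    rows.sort()
    pd.DataFrame(
        rows, columns=["microbe_id", "drug_id", "weight", "phylum", "atc_letters"]
    ).to_csv(path, sep="\t", index=False)


def read_edge_list(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"microbe_id": str, "drug_id": str},
                     na_values=[NA], keep_default_na=False,
                     float_precision="round_trip")
    df["atc_letters"] = df["atc_letters"].map(_split)
    return df


def linkage_tables(linkages: Sequence[MicrobeLinkage]) -> dict[str, pd.DataFrame]:
    """Flatten linkages into the four output tables.

    ``drugs`` mirrors the microbe–drug linkage list (one row per linked
    drug, identical vs analog classified); ``indications``, ``side_effects``
    and ``immune_transitions`` hold one row per propagated term with its
    (drug, score) provenance.
    """
    drug_rows = [
        (l.microbe_id, l.habitat, d, score, ident, via)
        for l in linkages
        for d, (score, ident, via) in sorted(l.linked_drugs.items())
    ]
    tables = {
        "drugs": pd.DataFrame(
            drug_rows,
            columns=["microbe_id", "habitat", "drug_id", "score",
                     "identical_structure", "via_metabolite"],
        )
    }
    for kind in ("indications", "side_effects", "immune_transitions"):
        rows = [
            (l.microbe_id, l.habitat, term, drug, score)
            for l in linkages
            for term, provs in sorted(getattr(l, kind).items())
            for drug, score in provs
        ]
        tables[kind] = pd.DataFrame(
            rows, columns=["microbe_id", "habitat", "term", "drug_id", "score"]
        )
    return tables


def write_linkages(linkages: Sequence[MicrobeLinkage], outdir) -> dict[str, Path]:
    outdir = Path(outdir)
    paths = {}
    for kind, df in linkage_tables(linkages).items():
        p = outdir / f"linkage_{kind}.tsv"
        if kind == "drugs":
            out = df.copy()
            out["identical_structure"] = out["identical_structure"].map(str)
            out.to_csv(p, sep="\t", index=False)
        else:
            df.to_csv(p, sep="\t", index=False)
        paths[kind] = p
    return paths


def read_linkage_table(path) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t",
        dtype={"microbe_id": str, "drug_id": str, "identical_structure": str},
        na_values=[NA], keep_default_na=False, float_precision="round_trip",
    )
    if "identical_structure" in df.columns:
        df["identical_structure"] = df["identical_structure"] == "True"
    return df


def write_summary(summary: dict, path) -> None:
    Path(path).write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")


def read_summary(path) -> dict:
    return json.loads(Path(path).read_text())


# --------------------------------------------------------------- input bundle

@dataclass
class Dataset:
    """Validated in-memory input bundle."""

    compounds: list[CompoundRecord]
    signatures: dict[str, PerturbationSignature]
    microbes: list[MicrobeRecord]
    pathway_annotations: dict[str, PathwayAnnotation]
    drug_annotations: dict[str, DrugAnnotation]
    warnings: list[str] = field(default_factory=list)

    @property
    def metabolites(self) -> list[CompoundRecord]:
        return [c for c in self.compounds if c.source is CompoundSource.METABOLITE]

    @property
    def drugs(self) -> list[CompoundRecord]:
        return [c for c in self.compounds if c.source is CompoundSource.DRUG]


def read_inputs(
    compounds_path,
    signatures_path=None,
    microbes_path=None,
    pathways_path=None,
    drug_annotations_path=None,
    strict: bool = False,
) -> Dataset:
    """Read and cross-validate the full input bundle.

    Dangling references (a microbe naming an unknown metabolite, a signature
    column without a compound record) are warned about and dropped; in
    strict mode a microbe with dangling metabolites is excluded entirely.
    """
    warnings: list[str] = []
    compounds = read_compounds(compounds_path)
    known = {c.compound_id for c in compounds}

    signatures: dict[str, PerturbationSignature] = {}
    if signatures_path is not None:
        for cid, sig in read_signatures(signatures_path).items():
            if cid not in known:
                warnings.append(f"signature column {cid!r} has no compound record; dropped")
            else:
                signatures[cid] = sig

    microbes: list[MicrobeRecord] = []
    if microbes_path is not None:
        for mic in read_microbes(microbes_path):
            dangling = sorted(mic.metabolite_ids - known)
            if dangling:
                warnings.append(
                    f"microbe {mic.microbe_id} references unknown metabolite(s): "
                    f"{', '.join(dangling)}"
                )
                if strict:
                    warnings.append(f"microbe {mic.microbe_id} excluded (strict mode)")
                    continue
                kept = mic.metabolite_ids & known
                if not kept:
                    warnings.append(
                        f"microbe {mic.microbe_id} excluded: no known metabolites"
                    )
                    continue
                mic = MicrobeRecord(mic.microbe_id, mic.taxon_name, mic.phylum,
                                    mic.habitat, frozenset(kept))
            microbes.append(mic)

    pathway_annotations = (
        read_pathways_long(pathways_path) if pathways_path is not None else {}
    )
    drug_annotations = (
        read_drug_annotations(drug_annotations_path)
        if drug_annotations_path is not None else {}
    )
    for w in warnings:
        log.warning("%s", w)
    return Dataset(compounds, signatures, microbes, pathway_annotations,
                   drug_annotations, warnings)


def write_bundle(bundle, outdir) -> dict[str, Path]:
    """Write a synthetic fixture bundle as the standard input files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "compounds": outdir / "compounds.tsv",
        "signatures": outdir / "signatures.tsv",
        "microbes": outdir / "microbes.tsv",
        "pathways": outdir / "pathways.tsv",
        "drug_annotations": outdir / "drug_annotations.tsv",
        "truth": outdir / "truth.tsv",
    }
    write_compounds([*bundle.drugs, *bundle.metabolites], paths["compounds"])
    write_signatures(bundle.signatures, paths["signatures"])
    write_microbes(bundle.microbes, paths["microbes"])
    write_pathways_long(bundle.pathway_annotations, paths["pathways"])
    write_drug_annotations(bundle.drug_annotations, paths["drug_annotations"])
    bundle.truth.to_csv(paths["truth"], sep="\t", index=False)
    return paths
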