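"""Deterministic synthetic universe for the whole pipeline.

Generates compounds (drugs and metabolites with planted structural
relations), perturbation signatures, pathway annotations, drug annotations
and microbe records, emulating the kinds of inputs that would normally be
extracted from compound, signature, pathway and side-effect databases.  The
planted ground truth ("truth table") makes every downstream stage testable:
a metabolite is either an *identical* copy of some drug, a single-substituent
*analog* of one, or structurally *unrelated*.

Chemistry is a small embedded library of ring scaffolds with one substituent
slot.  Drugs draw substituents from one set and analogs from a disjoint set,
so an analog is never canonical-equal to any drug; unrelated metabolites are
acyclic and therefore cannot coincide with the (all ring-bearing) drugs.

All randomness flows from one master seed through independent per-stage
streams, so adding a stage never shifts the output of another.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .benchmark import PathwayAnnotation
from .chem import CompoundRecord, CompoundSource, canonicalize
from .expression import PerturbationSignature
from .mapping import DrugAnnotation, MicrobeRecord

# Ring scaffolds with a single substituent slot. Every combination with the
# substituent sets below parses and canonicalizes to a unique molecule.
SCAFFOLDS = [
    "c1ccc({})cc1", "c1ccc2cc({})ccc2c1", "c1ccnc({})c1",
    "c1ccc(-c2ccc({})cc2)cc1", "c1cc({})oc1", "c1cc({})sc1",
    "c1cc({})[nH]c1", "Cc1ncc({})[nH]1", "c1ccc2[nH]cc({})c2c1",
    "C1CCC({})CC1", "C1CCC({})C1", "C1CCNC({})C1", "C1COC({})CN1",
    "c1cnc({})nc1", "c1ccc2ncc({})cc2c1", "c1cc({})[nH]n1",
    "c1oc({})nc1", "c1ccc2occ({})c2c1", "C1CCC({})O1", "CC1CCC({})CC1",
]
SUBSTITUENTS_DRUG = ["C", "CC", "O", "N", "Cl", "F", "C(C)C", "CO", "C(=O)O", "OC"]
SUBSTITUENTS_ANALOG = ["CCC", "Br", "I", "C(F)(F)F", "CCO", "C#N", "NC", "CN", "C(=O)N", "S"]
# Acyclic backbones for unrelated metabolites (extended with -C chains for variety)
UNRELATED_BACKBONES = [
    "CCCCCCCC", "CC(C)CC(C)O", "OCC(O)CO", "CCOC(=O)CC", "CC(N)C(=O)O",
    "OCCOCCO", "CC(C)(C)CO", "CCCC(=O)OC(C)C", "NCCCCN", "OC(=O)CCC(=O)O",
    "CC(O)C(O)CO", "CCCCN(CC)CC",
]

# Nine phyla, matching the granularity at which producer microbes are
# typically summarized.
DEFAULT_PHYLA = [
    "Actinobacteria", "Ascomycota", "Proteobacteria", "Firmicutes",
    "Bacteroidetes", "Cyanobacteria", "Basidiomycota", "Chloroflexi",
    "Deinococcus-Thermus",
]
INDICATION_VOCAB = [
    "hypertension", "irritable bowel syndrome", "type 2 diabetes", "melanoma",
    "pneumonia", "depression", "asthma", "rheumatoid arthritis",
]
SIDE_EFFECT_VOCAB = [
    "nausea", "diarrhea", "headache", "oily stools", "dyspepsia", "tinnitus",
    "rash", "fatigue",
]
IMMUNE_VOCAB = [
    "splenic CD4+ T cells increased", "Treg population increased",
    "NK cells decreased", "B cells increased", "CD8+ T cells increased",
]
ATC_LETTERS = sorted("ABCDGHJLMNPRSV")

REL_IDENTICAL = "identical"
REL_ANALOG = "analog"
REL_UNRELATED = "unrelated"
REL_PLANTED = "planted_identical"


@dataclass(frozen=True)
class FixtureConfig:
    """Knobs of the synthetic universe.

    ``frac_identical`` / ``frac_analog`` set the fraction of metabolites that
    are exact copies / close analogs of some drug; ``noise_sd`` is the
    standard deviation of Gaussian noise added to the latent z-score profile
    shared between a drug and its related metabolites;
    ``p_shared_pathway_for_related`` is the probability that a planted
    related pair is given a common disease-related pathway (making it a
    benchmark positive — unrelated pairs never share one).
    ``planted_bicluster=(phylum, atc_letter, (n_rows, n_cols))`` plants a
    block of microbes of one phylum whose metabolites copy drugs of one ATC
    class, for biclustering tests.
    """

    seed: int = 0
    n_drugs: int = 40
    n_metabolites: int = 60
    frac_identical: float = 0.15
    frac_analog: float = 0.35
    n_genes: int = 200
    noise_sd: float = 0.5
    n_pathways: int = 30
    p_shared_pathway_for_related: float = 0.9
    n_microbes: int = 20
    phylum_labels: tuple[str, ...] = tuple(DEFAULT_PHYLA)
    planted_bicluster: Optional[tuple[str, str, tuple[int, int]]] = None

    def __post_init__(self) -> None:
        if self.frac_identical + self.frac_analog > 1.0 + 1e-12:
            raise ValueError("frac_identical + frac_analog must be <= 1")
        if not (0.0 <= self.frac_identical <= 1.0 and 0.0 <= self.frac_analog <= 1.0):
            raise ValueError("fractions must lie in [0, 1]")
        for name in ("n_drugs", "n_metabolites", "n_genes", "n_pathways", "n_microbes"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0.0 <= self.p_shared_pathway_for_related <= 1.0:
            raise ValueError("p_shared_pathway_for_related must lie in [0, 1]")
        if self.n_metabolites < self.n_microbes:
            raise ValueError("need at least one metabolite per microbe")
        if self.n_drugs > len(SCAFFOLDS) * len(SUBSTITUENTS_DRUG):
            raise ValueError("n_drugs exceeds the embedded scaffold library")
        if self.planted_bicluster is not None:
            _, letter, (nr, nc) = self.planted_bicluster
            if letter not in ATC_LETTERS:
                raise ValueError(f"planted ATC letter {letter!r} not in the alphabet")
            if nr > self.n_microbes or nc > self.n_drugs:
                raise ValueError("planted block larger than the universe")


@dataclass
class FixtureBundle:
    """Everything one pipeline run needs, in memory."""

    config: FixtureConfig
    drugs: list[CompoundRecord]
    metabolites: list[CompoundRecord]
    truth: pd.DataFrame  # metabolite_id, relation, partner_drug_id, planted_row
    signatures: dict[str, PerturbationSignature]
    pathway_annotations: dict[str, PathwayAnnotation]
    drug_annotations: dict[str, DrugAnnotation]
    microbes: list[MicrobeRecord]


def _streams(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def generate_compounds(
    cfg: FixtureConfig, rng: Optional[np.random.Generator] = None
) -> tuple[list[CompoundRecord], list[CompoundRecord], pd.DataFrame]:
    """Drugs, metabolites and the planted-relation truth table.

    Metabolites are, in order: ``round(frac_identical * n)`` identical
    copies of randomly chosen drugs, ``round(frac_analog * n)`` analogs
    (same scaffold, substituent from the disjoint analog set), the rest
    unrelated acyclic molecules.  A planted bicluster adds one extra
    identical-copy metabolite per (planted microbe row, planted drug).
    """
    if rng is None:
        rng = _streams(cfg.seed, 4)[0]
    combos = [(t, s) for t in SCAFFOLDS for s in SUBSTITUENTS_DRUG]
    order = rng.permutation(len(combos))
    drug_combo: dict[str, tuple[str, str]] = {}
    drugs: list[CompoundRecord] = []
    for i in range(cfg.n_drugs):
        t, s = combos[order[i]]
        did = f"d{i:04d}"
        drugs.append(CompoundRecord(did, f"drug-{i}", t.format(s), CompoundSource.DRUG))
        drug_combo[did] = (t, s)
    drug_canon = {d.compound_id: canonicalize(d.smiles) for d in drugs}
    assert len(set(drug_canon.values())) == len(drugs), "drug library collision"

    n = cfg.n_metabolites
    n_id = round(cfg.frac_identical * n)
    n_an = min(round(cfg.frac_analog * n), n - n_id)
    metabolites: list[CompoundRecord] = []
    rows = []
    for i in range(n):
        mid = f"m{i:04d}"
        if i < n_id:
            partner = drugs[int(rng.integers(cfg.n_drugs))]
            smiles, rel, pid = partner.smiles, REL_IDENTICAL, partner.compound_id
        elif i < n_id + n_an:
            partner = drugs[int(rng.integers(cfg.n_drugs))]
            t, _ = drug_combo[partner.compound_id]
            sub = SUBSTITUENTS_ANALOG[int(rng.integers(len(SUBSTITUENTS_ANALOG)))]
            smiles, rel, pid = t.format(sub), REL_ANALOG, partner.compound_id
        else:
            j = i - n_id - n_an
            base = UNRELATED_BACKBONES[j % len(UNRELATED_BACKBONES)]
            smiles = base + "C" * (j // len(UNRELATED_BACKBONES))
            rel, pid = REL_UNRELATED, ""
        metabolites.append(CompoundRecord(mid, f"metab-{i}", smiles, CompoundSource.METABOLITE))
        rows.append((mid, rel, pid, -1))

    if cfg.planted_bicluster is not None:
        _, _, (nr, nc) = cfg.planted_bicluster
        for r in range(nr):
            for ci in range(nc):
                partner = drugs[ci]
                mid = f"pm{r:02d}x{ci:02d}"
                metabolites.append(
                    CompoundRecord(mid, f"planted-{r}-{ci}", partner.smiles,
                                   CompoundSource.METABOLITE)
                )
                rows.append((mid, REL_PLANTED, partner.compound_id, r))

    truth = pd.DataFrame(
        rows, columns=["metabolite_id", "relation", "partner_drug_id", "planted_row"]
    )
    # planted non-identity must hold: analogs and unrelated never equal a drug
    canon_drugs = set(drug_canon.values())
    for rec, rel in zip(metabolites, truth["relation"]):
        if rel in (REL_ANALOG, REL_UNRELATED):
            assert canonicalize(rec.smiles) not in canon_drugs, rec.compound_id
    return drugs, metabolites, truth


def generate_signatures(
    cfg: FixtureConfig,
    drugs: list[CompoundRecord],
    metabolites: list[CompoundRecord],
    truth: pd.DataFrame,
    rng: Optional[np.random.Generator] = None,
) -> dict[str, PerturbationSignature]:
    """Gene-level z-score profiles on a shared gene space.

    Each drug gets a latent effect vector; metabolites related to a drug
    (identical, analog, planted) share their partner's latent vector;
    unrelated metabolites get independent latents.  Observed profiles are
    latent + N(0, noise_sd²) noise, independently per compound.
    """
    if rng is None:
        rng = _streams(cfg.seed, 4)[1]
    genes = pd.Index([f"g{i:04d}" for i in range(cfg.n_genes)], name="gene_id")
    latent = {d.compound_id: rng.standard_normal(cfg.n_genes) for d in drugs}
    partner = dict(zip(truth["metabolite_id"], truth["partner_drug_id"]))
    sigs: dict[str, PerturbationSignature] = {}
    for d in drugs:
        obs = latent[d.compound_id] + cfg.noise_sd * rng.standard_normal(cfg.n_genes)
        sigs[d.compound_id] = PerturbationSignature(d.compound_id, pd.Series(obs, index=genes))
    for m in metabolites:
        pid = partner[m.compound_id]
        base = latent[pid] if pid else rng.standard_normal(cfg.n_genes)
        obs = base + cfg.noise_sd * rng.standard_normal(cfg.n_genes)
        sigs[m.compound_id] = PerturbationSignature(m.compound_id, pd.Series(obs, index=genes))
    return sigs


def generate_annotations(
    cfg: FixtureConfig,
    drugs: list[CompoundRecord],
    metabolites: list[CompoundRecord],
    truth: pd.DataFrame,
    rng: Optional[np.random.Generator] = None,
) -> tuple[dict[str, PathwayAnnotation], dict[str, DrugAnnotation], list[MicrobeRecord]]:
    """Pathway memberships, drug annotations and microbe records.

    Every planted related pair receives, with probability
    ``p_shared_pathway_for_related``, its own private disease-related
    pathway shared by exactly that metabolite and drug — so related pairs
    label positive at that rate and unrelated pairs never do.  Background
    (non-disease) pathways are assigned at random to all compounds so that
    everything is annotated.  Metabolites are partitioned among microbes;
    a planted bicluster pins the planted microbes' phylum and the planted
    drugs' ATC letter.
    """
    if rng is None:
        rng = _streams(cfg.seed, 4)[2]
    background = [f"pw{i:04d}" for i in range(cfg.n_pathways)]

    memb: dict[str, set[str]] = {}
    disease: dict[str, set[str]] = {}
    for rec in (*drugs, *metabolites):
        k = 1 + int(rng.integers(2))
        memb[rec.compound_id] = set(
            rng.choice(background, size=k, replace=False).tolist()
        )
        disease[rec.compound_id] = set()
    pair_idx = 0
    for mid, rel, pid in zip(
        truth["metabolite_id"], truth["relation"], truth["partner_drug_id"]
    ):
        if rel == REL_UNRELATED:
            continue
        if rng.random() < cfg.p_shared_pathway_for_related:
            pw = f"dpw{pair_idx:04d}"
            for ent in (mid, pid):
                memb[ent].add(pw)
                disease[ent].add(pw)
        pair_idx += 1
    pathway_annotations = {
        ent: PathwayAnnotation(ent, frozenset(memb[ent]), frozenset(disease[ent]))
        for ent in memb
    }

    planted = cfg.planted_bicluster
    drug_annotations: dict[str, DrugAnnotation] = {}
    for i, d in enumerate(drugs):
        letters = set(
            rng.choice(ATC_LETTERS, size=1 + int(rng.integers(2)), replace=False).tolist()
        )
        if planted is not None and i < planted[2][1]:
            letters.add(planted[1])
        ind = set(rng.choice(INDICATION_VOCAB, size=1 + int(rng.integers(2)),
                             replace=False).tolist())
        se = set(rng.choice(SIDE_EFFECT_VOCAB, size=int(rng.integers(3)),
                            replace=False).tolist())
        imm = set(rng.choice(IMMUNE_VOCAB, size=int(rng.integers(2)),
                             replace=False).tolist())
        drug_annotations[d.compound_id] = DrugAnnotation(
            d.compound_id,
            atc_codes=frozenset(f"{l}01AA{i:02d}" for l in letters),
            indications=frozenset(ind),
            side_effects=frozenset(se),
            immune_transitions=frozenset(imm),
        )

    regular = truth.loc[truth["planted_row"] < 0, "metabolite_id"].tolist()
    perm = rng.permutation(len(regular))
    chunks = np.array_split([regular[i] for i in perm], cfg.n_microbes)
    microbes: list[MicrobeRecord] = []
    for i, chunk in enumerate(chunks):
        mets = set(chunk.tolist())
        if planted is not None and i < planted[2][0]:
            phylum = planted[0]
            mets |= set(
                truth.loc[truth["planted_row"] == i, "metabolite_id"].tolist()
            )
        else:
            phylum = str(rng.choice(list(cfg.phylum_labels)))
        habitat = "gut" if rng.random() < 0.2 else "environmental"
        microbes.append(
            MicrobeRecord(
                microbe_id=f"mb{i:03d}",
                taxon_name=f"{phylum} sp. {i}",
                phylum=phylum,
                habitat=habitat,
                metabolite_ids=frozenset(mets),
            )
        )
    return pathway_annotations, drug_annotations, microbes


def generate_bundle(cfg: FixtureConfig) -> FixtureBundle:
    """Generate the full synthetic universe, reproducibly from cfg.seed."""
    s_comp, s_sig, s_ann, _ = _streams(cfg.seed, 4)
    drugs, metabolites, truth = generate_compounds(cfg, s_comp)
    signatures = generate_signatures(cfg, drugs, metabolites, truth, s_sig)
    pathway_annotations, drug_annotations, microbes = generate_annotations(
        cfg, drugs, metabolites, truth, s_ann
    )
    return FixtureBundle(
        config=cfg, drugs=drugs, metabolites=metabolites, truth=truth,
        signatures=signatures, pathway_annotations=pathway_annotations,
        drug_annotations=drug_annotations, microbes=microbes,
    )


def identical_fraction_from_pairs(pairs: pd.DataFrame, n_metabolites: int) -> float:
    """Estimate the identical-metabolite fraction from score-1.0 pairs.

    Score 1.0 is reserved for canonical-equal pairs, so the number of
    metabolites with at least one score-1.0 partner recovers the planted
    identical count.
    """
    hit = pairs.loc[pairs["score"] == 1.0, "metabolite_id"].nunique()
    return hit / n_metabolites
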