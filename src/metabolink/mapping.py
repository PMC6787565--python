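"""Bipartite microbe–drug network and drug-annotation propagation.

Above a score cutoff, each microbe is connected to the drugs its metabolites
resemble; edge weight counts the metabolite-level interactions behind the
edge.  Microbe *hubs* interact with the most distinct drug types (ATC
level-1 classes) and *islands* with the fewest.  Above a stricter linkage
cutoff, a drug's annotations — treatment indications, side effects, immune
transitions — are propagated to the microbe, each propagated term keeping
the provenance (drug, score) that justified it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import networkx as nx
import pandas as pd

log = logging.getLogger(__name__)

ATC_ALPHABET = frozenset("ABCDGHJLMNPRSV")


@dataclass(frozen=True)
class MicrobeRecord:
    """A microbe, its taxonomy, habitat and the metabolites it produces."""

    microbe_id: str
    taxon_name: str
    phylum: str
    habitat: str  # "gut" or "environmental"
    metabolite_ids: frozenset[str]

    def __post_init__(self) -> None:
        if not self.metabolite_ids:
            raise ValueError(f"microbe {self.microbe_id}: metabolite_ids empty")
        if not self.phylum:
            raise ValueError(f"microbe {self.microbe_id}: phylum empty")
        if self.habitat not in ("gut", "environmental"):
            raise ValueError(f"microbe {self.microbe_id}: bad habitat {self.habitat!r}")


@dataclass(frozen=True)
class DrugAnnotation:
    """ATC codes, indications, side effects and immune transitions of a drug."""

    drug_id: str
    atc_codes: frozenset[str] = frozenset()
    indications: frozenset[str] = frozenset()
    side_effects: frozenset[str] = frozenset()
    immune_transitions: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        bad = {c[0] for c in self.atc_codes if c} - ATC_ALPHABET
        if bad:
            raise ValueError(
                f"drug {self.drug_id}: ATC level-1 letters {sorted(bad)} outside "
                f"the ATC alphabet"
            )

    @property
    def atc_letters(self) -> frozenset[str]:
        """Level-1 (anatomical main group) letters of the ATC codes."""
        return frozenset(c[0] for c in self.atc_codes if c)


@dataclass
class MicrobeLinkage:
    """A microbe's propagated drugs and annotation terms, with provenance."""

    microbe_id: str
    habitat: str
    # drug_id -> (best score, identical flag, via metabolite_id)
    linked_drugs: dict[str, tuple[float, bool, str]] = field(default_factory=dict)
    # term -> list of (drug_id, score) supporting it
    indications: dict[str, list[tuple[str, float]]] = field(default_factory=dict)
    side_effects: dict[str, list[tuple[str, float]]] = field(default_factory=dict)
    immune_transitions: dict[str, list[tuple[str, float]]] = field(default_factory=dict)


def build_network(
    pairs: pd.DataFrame,
    microbes: Sequence[MicrobeRecord],
    annotations: Mapping[str, DrugAnnotation],
    cutoff: float = 0.6,
) -> nx.Graph:
    """Bipartite graph of microbes and drugs connected above a score cutoff.

    Edge (m, d) exists iff some metabolite of m scores >= cutoff against d;
    its weight is the number of such metabolite-level interactions.  Microbe
    nodes carry phylum and habitat, drug nodes their ATC level-1 letters
    (empty, with a warning, for unannotated drugs).
    """
    if not 0.0 <= cutoff <= 1.0:
        raise ValueError(f"cutoff {cutoff} outside [0, 1]")
    g = nx.Graph()
    for mic in microbes:
        g.add_node(mic.microbe_id, bipartite="microbe", phylum=mic.phylum,
                   habitat=mic.habitat)
    qualifying = pairs[pairs["score"] >= cutoff]
    met_to_microbes: dict[str, list[str]] = {}
    for mic in microbes:
        for met in mic.metabolite_ids:
            met_to_microbes.setdefault(met, []).append(mic.microbe_id)
    for met, d, score in zip(
        qualifying["metabolite_id"], qualifying["drug_id"], qualifying["score"]
    ):
        for mic_id in met_to_microbes.get(met, ()):
            if d not in g:
                ann = annotations.get(d)
                if ann is None:
                    log.warning("drug %s has no annotation record; ATC left empty", d)
                    letters: frozenset[str] = frozenset()
                else:
                    letters = ann.atc_letters
                g.add_node(d, bipartite="drug", atc_letters=letters)
            if g.has_edge(mic_id, d):
                g[mic_id][d]["weight"] += 1
            else:
                g.add_edge(mic_id, d, weight=1)
    return g


def hubs_and_islands(
    graph: nx.Graph, by: str = "atc_class"
) -> tuple[list[str], list[str]]:
    """Microbes interacting with the most / fewest drug types.

    The drug-type count of a microbe is the number of distinct ATC level-1
    letters among its drug neighbours (``by="atc_class"``, the default) or
    its raw drug degree (``by="degree"``).  Hubs are the argmax set and
    islands the argmin set among microbes with at least one edge; ties are
    reported in full, lexicographically sorted.
    """
    counts: dict[str, int] = {}
    for node, data in graph.nodes(data=True):
        if data.get("bipartite") != "microbe":
            continue
        neighbors = list(graph.neighbors(node))
        if not neighbors:
            continue
        if by == "atc_class":
            letters: set[str] = set()
            for d in neighbors:
                letters |= set(graph.nodes[d].get("atc_letters", ()))
            counts[node] = len(letters)
        elif by == "degree":
            counts[node] = len(neighbors)
        else:
            raise ValueError(f"unknown ranking {by!r}")
    if not counts:
        raise ValueError("graph has no microbe with an edge")
    hi, lo = max(counts.values()), min(counts.values())
    hubs = sorted(m for m, n in counts.items() if n == hi)
    islands = sorted(m for m, n in counts.items() if n == lo)
    return hubs, islands


def phylum_atc_summary(graph: nx.Graph) -> pd.DataFrame:
    """Contingency table of edge counts by microbe phylum × ATC level-1 class.

    A drug carrying several ATC letters contributes its edge to every one of
    them, so column marginals can exceed the raw edge count.
    """
    cells: dict[tuple[str, str], int] = {}
    for u, v in graph.edges():
        if graph.nodes[u].get("bipartite") == "microbe":
            mic, drug = u, v
        else:
            mic, drug = v, u
        phylum = graph.nodes[mic]["phylum"]
        for letter in sorted(graph.nodes[drug].get("atc_letters", ())):
            cells[(phylum, letter)] = cells.get((phylum, letter), 0) + 1
    if not cells:
        return pd.DataFrame()
    phyla = sorted({p for p, _ in cells})
    letters = sorted({t for _, t in cells})
    table = pd.DataFrame(0, index=phyla, columns=letters)
    for (p, t), n in cells.items():
        table.at[p, t] = n
    return table


def propagate_annotations(
    pairs: pd.DataFrame,
    microbes: Sequence[MicrobeRecord],
    annotations: Mapping[str, DrugAnnotation],
    linkage_cutoff: float = 0.9,
) -> list[MicrobeLinkage]:
    """Propagate drug annotations to microbes above the linkage cutoff.

    A pair qualifies at ``score >= linkage_cutoff`` (inclusive).  Per
    microbe, each linked drug keeps its best score, the metabolite that
    achieved it, and an identical-vs-analog classification (identical means
    the metabolite is the very same compound, score exactly 1.0).  The
    microbe's indications, side effects and immune transitions are the union
    over its linked drugs, each term recording (drug, score) provenance.
    Only microbes with at least one qualifying pair appear in the output.
    """
    met_to_microbes: dict[str, list[MicrobeRecord]] = {}
    for mic in microbes:
        for met in mic.metabolite_ids:
            met_to_microbes.setdefault(met, []).append(mic)
    qualifying = pairs[pairs["score"] >= linkage_cutoff]

    linkages: dict[str, MicrobeLinkage] = {}
    for row in qualifying.itertuples(index=False):
        for mic in met_to_microbes.get(row.metabolite_id, ()):
            link = linkages.setdefault(
                mic.microbe_id,
                MicrobeLinkage(microbe_id=mic.microbe_id, habitat=mic.habitat),
            )
            prev = link.linked_drugs.get(row.drug_id)
            if prev is None or row.score > prev[0]:
                link.linked_drugs[row.drug_id] = (
                    float(row.score), bool(row.identical_structure), row.metabolite_id
                )
    for link in linkages.values():
        for drug_id, (score, _, _) in sorted(link.linked_drugs.items()):
            ann = annotations.get(drug_id)
            if ann is None:
                continue
            for term in sorted(ann.indications):
                link.indications.setdefault(term, []).append((drug_id, score))
            for term in sorted(ann.side_effects):
                link.side_effects.setdefault(term, []).append((drug_id, score))
            for term in sorted(ann.immune_transitions):
                link.immune_transitions.setdefault(term, []).append((drug_id, score))
    return [linkages[m] for m in sorted(linkages)]


def linkage_summary(linkages: Sequence[MicrobeLinkage]) -> dict:
    """Headline counts over a set of microbe linkages.

    Linkage counts split identical (score 1.0) from analog
    (cutoff <= score < 1.0) pairs, and microbe counts split by habitat so
    gut-resident and environment-only producers can be reported separately.
    """
    n_linkages = sum(len(l.linked_drugs) for l in linkages)
    n_identical = sum(
        1 for l in linkages for (_, ident, _) in l.linked_drugs.values() if ident
    )
    return {
        "n_linkages": n_linkages,
        "n_identical_linkages": n_identical,
        "n_analog_linkages": n_linkages - n_identical,
        "n_microbes": len(linkages),
        "n_microbes_with_indications": sum(1 for l in linkages if l.indications),
        "n_microbes_with_side_effects": sum(1 for l in linkages if l.side_effects),
        "n_microbes_with_immune_transitions": sum(
            1 for l in linkages if l.immune_transitions
        ),
        "n_gut_microbes": sum(1 for l in linkages if l.habitat == "gut"),
        "n_environmental_microbes": sum(
            1 for l in linkages if l.habitat == "environmental"
        ),
    }
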