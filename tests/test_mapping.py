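"""Bipartite network, hubs/islands and annotation propagation."""

import numpy as np
import pandas as pd
import pytest

from metabolink import (
    DrugAnnotation,
    MicrobeRecord,
    build_network,
    hubs_and_islands,
    linkage_summary,
    phylum_atc_summary,
    propagate_annotations,
)


def microbe(mid, mets, phylum="Actinobacteria", habitat="environmental"):
    return MicrobeRecord(mid, f"{mid} taxon", phylum, habitat, frozenset(mets))


def drug_ann(did, letters, ind=(), se=(), imm=()):
    return DrugAnnotation(
        did, frozenset(f"{l}01AA01" for l in letters),
        frozenset(ind), frozenset(se), frozenset(imm),
    )


def pairs_df(rows):
    df = pd.DataFrame(rows, columns=["metabolite_id", "drug_id", "score"])
    df["identical_structure"] = df["score"] == 1.0
    return df


class TestBuildNetwork:
    def test_edge_weight_counts_metabolite_interactions(self):
        pairs = pairs_df([("x1", "d1", 0.7), ("x2", "d1", 0.8)])
        g = build_network(pairs, [microbe("mb1", {"x1", "x2"})],
                          {"d1": drug_ann("d1", "J")}, cutoff=0.6)
        assert g["mb1"]["d1"]["weight"] == 2

    def test_no_qualifying_pair_no_edges(self):
        pairs = pairs_df([("x1", "d1", 0.5)])
        g = build_network(pairs, [microbe("mb1", {"x1"})], {}, cutoff=0.6)
        assert g.number_of_edges() == 0

    def test_shared_metabolite_yields_edge_per_microbe(self):
        pairs = pairs_df([("x1", "d1", 0.7)])
        g = build_network(
            pairs, [microbe("mb1", {"x1"}), microbe("mb2", {"x1"})],
            {"d1": drug_ann("d1", "J")}, cutoff=0.6,
        )
        assert g.has_edge("mb1", "d1") and g.has_edge("mb2", "d1")

    def test_missing_drug_annotation_keeps_node_with_empty_atc(self):
        pairs = pairs_df([("x1", "dX", 0.7)])
        g = build_network(pairs, [microbe("mb1", {"x1"})], {}, cutoff=0.6)
        assert g.nodes["dX"]["atc_letters"] == frozenset()

    def test_weight_conservation(self, small_dataset, small_pairs):
        pairs, _ = small_pairs
        cutoff = 0.6
        g = build_network(pairs, small_dataset.microbes,
                          small_dataset.drug_annotations, cutoff=cutoff)
        total = sum(d["weight"] for _, _, d in g.edges(data=True))
        met_owner_count = {
            met: sum(1 for m in small_dataset.microbes if met in m.metabolite_ids)
            for met in pairs["metabolite_id"].unique()
        }
        expected = sum(
            met_owner_count[met]
            for met, score in zip(pairs["metabolite_id"], pairs["score"])
            if score >= cutoff
        )
        assert total == expected


class TestHubsAndIslands:
    def test_distinct_letter_counting(self):
        pairs = pairs_df([
            ("a1", "d1", 0.7), ("a1", "d2", 0.7), ("a1", "d3", 0.7),
            ("b1", "d1", 0.7), ("c1", "d1", 0.7), ("c1", "d2", 0.7),
        ])
        microbes = [microbe("A", {"a1"}), microbe("B", {"b1"}), microbe("C", {"c1"})]
        ann = {"d1": drug_ann("d1", "J"), "d2": drug_ann("d2", "L"),
               "d3": drug_ann("d3", "C")}
        g = build_network(pairs, microbes, ann, cutoff=0.6)
        hubs, islands = hubs_and_islands(g)
        assert hubs == ["A"] and islands == ["B"]

    def test_many_drugs_one_class_counts_once(self):
        pairs = pairs_df([(f"a1", f"d{i}", 0.7) for i in range(5)])
        ann = {f"d{i}": drug_ann(f"d{i}", "J") for i in range(5)}
        g = build_network(pairs, [microbe("A", {"a1"})], ann, cutoff=0.6)
        hubs, islands = hubs_and_islands(g)
        assert hubs == islands == ["A"]

    def test_degree_ranking_flag(self):
        pairs = pairs_df([("a1", "d1", 0.7), ("a1", "d2", 0.7), ("b1", "d1", 0.7)])
        ann = {"d1": drug_ann("d1", "J"), "d2": drug_ann("d2", "J")}
        g = build_network(pairs, [microbe("A", {"a1"}), microbe("B", {"b1"})], ann, 0.6)
        hubs_cls, _ = hubs_and_islands(g, by="atc_class")
        hubs_deg, _ = hubs_and_islands(g, by="degree")
        assert hubs_cls == ["A", "B"]  # both touch only class J
        assert hubs_deg == ["A"]

    def test_edgeless_graph_raises(self):
        g = build_network(pairs_df([("x1", "d1", 0.1)]),
                          [microbe("mb1", {"x1"})], {}, cutoff=0.6)
        with pytest.raises(ValueError):
            hubs_and_islands(g)

    def test_matches_bruteforce_on_random_graphs(self):
        rng = np.random.default_rng(21)
        letters = list("ABCDGHJLMNPRSV")
        for _ in range(100):
            n_mic, n_drug = int(rng.integers(2, 8)), int(rng.integers(2, 10))
            rows, ann = [], {}
            for j in range(n_drug):
                k = int(rng.integers(1, 3))
                ann[f"d{j}"] = drug_ann(f"d{j}", rng.choice(letters, size=k, replace=False))
            for i in range(n_mic):
                for j in range(n_drug):
                    if rng.random() < 0.4:
                        rows.append((f"x{i}", f"d{j}", 0.8))
            if not rows:
                continue
            microbes = [microbe(f"M{i}", {f"x{i}"}) for i in range(n_mic)]
            g = build_network(pairs_df(rows), microbes, ann, cutoff=0.6)
            hubs, islands = hubs_and_islands(g)
            counts = {}
            for i in range(n_mic):
                ls = set()
                touched = False
                for met, d, _ in rows:
                    if met == f"x{i}":
                        touched = True
                        ls |= {c[0] for c in ann[d].atc_codes}
                if touched:
                    counts[f"M{i}"] = len(ls)
            assert hubs == sorted(m for m, c in counts.items() if c == max(counts.values()))
            assert islands == sorted(m for m, c in counts.items() if c == min(counts.values()))


class TestPhylumAtcSummary:
    def test_single_edge_single_cell(self):
        g = build_network(pairs_df([("x1", "d1", 0.7)]),
                          [microbe("mb1", {"x1"}, phylum="Firmicutes")],
                          {"d1": drug_ann("d1", "J")}, 0.6)
        table = phylum_atc_summary(g)
        assert table.at["Firmicutes", "J"] == 1 and table.to_numpy().sum() == 1

    def test_multi_atc_drug_counts_in_every_class(self):
        g = build_network(pairs_df([("x1", "d1", 0.7)]),
                          [microbe("mb1", {"x1"}, phylum="Firmicutes")],
                          {"d1": drug_ann("d1", "JL")}, 0.6)
        table = phylum_atc_summary(g)
        assert table.at["Firmicutes", "J"] == 1 and table.at["Firmicutes", "L"] == 1

    def test_planted_enrichment_is_argmax(self):
        rows = [(f"p{i}", f"dL{j}", 0.8) for i in range(4) for j in range(3)]
        rows += [("q0", "dJ0", 0.8)]
        microbes = [microbe(f"P{i}", {f"p{i}"}, phylum="Ascomycota") for i in range(4)]
        microbes.append(microbe("Q", {"q0"}, phylum="Firmicutes"))
        ann = {f"dL{j}": drug_ann(f"dL{j}", "L") for j in range(3)}
        ann["dJ0"] = drug_ann("dJ0", "J")
        table = phylum_atc_summary(build_network(pairs_df(rows), microbes, ann, 0.6))
        flat = table.stack()
        assert flat.idxmax() == ("Ascomycota", "L")


class TestPropagation:
    def test_indication_propagates_with_provenance(self):
        pairs = pairs_df([("x1", "d1", 0.92)])
        ann = {"d1": drug_ann("d1", "A", ind=("irritable bowel syndrome",))}
        links = propagate_annotations(pairs, [microbe("X", {"x1"}, habitat="gut")],
                                      ann, linkage_cutoff=0.9)
        assert len(links) == 1
        assert links[0].indications["irritable bowel syndrome"] == [("d1", 0.92)]

    def test_score_one_classified_identical(self):
        pairs = pairs_df([("x1", "d1", 1.0), ("x2", "d2", 0.95)])
        microbes = [microbe("X", {"x1", "x2"})]
        ann = {"d1": drug_ann("d1", "A"), "d2": drug_ann("d2", "B")}
        links = propagate_annotations(pairs, microbes, ann)
        drugs = links[0].linked_drugs
        assert drugs["d1"][1] is True and drugs["d2"][1] is False

    def test_all_below_cutoff_yields_empty(self):
        pairs = pairs_df([("x1", "d1", 0.85)])
        assert propagate_annotations(pairs, [microbe("X", {"x1"})], {}) == []

    def test_cutoff_is_inclusive(self):
        pairs = pairs_df([("x1", "d1", 0.9)])
        links = propagate_annotations(pairs, [microbe("X", {"x1"})],
                                      {"d1": drug_ann("d1", "A")})
        assert len(links) == 1

    def test_every_term_traces_to_linked_drug_at_cutoff(self, small_dataset, small_pairs):
        pairs, _ = small_pairs
        links = propagate_annotations(pairs, small_dataset.microbes,
                                      small_dataset.drug_annotations, 0.9)
        for link in links:
            for kind in ("indications", "side_effects", "immune_transitions"):
                for term, provs in getattr(link, kind).items():
                    for drug_id, score in provs:
                        assert drug_id in link.linked_drugs
                        assert score >= 0.9
                        assert term in getattr(
                            small_dataset.drug_annotations[drug_id],
                            kind,
                        )

    def test_summary_counts_match_bruteforce(self, small_dataset, small_pairs):
        pairs, _ = small_pairs
        links = propagate_annotations(pairs, small_dataset.microbes,
                                      small_dataset.drug_annotations, 0.9)
        summary = linkage_summary(links)
        # brute-force recount from the pair table
        qualifying = pairs[pairs["score"] >= 0.9]
        expected_pairs = set()
        for met, d in zip(qualifying["metabolite_id"], qualifying["drug_id"]):
            for m in small_dataset.microbes:
                if met in m.metabolite_ids:
                    expected_pairs.add((m.microbe_id, d))
        assert summary["n_linkages"] == len(expected_pairs)
        assert summary["n_microbes"] == len({m for m, _ in expected_pairs})
        with_ind = {
            m for m, d in expected_pairs
            if small_dataset.drug_annotations[d].indications
        }
        assert summary["n_microbes_with_indications"] == len(with_ind)

    def test_atc_alphabet_enforced(self):
        with pytest.raises(ValueError):
            DrugAnnotation("d1", frozenset({"Z01AA01"}))
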