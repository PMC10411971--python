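"""LR database expansion, expressed-gene calls, edge enumeration, diffing."""

import numpy as np
import pandas as pd
import pytest

from cardiocomm.crosstalk import (build_lr_database, condition_specific_pairs,
                                  enumerate_interactions, expressed_genes,
                                  load_demo_database, read_sif,
                                  summarize_network, write_graphml, write_sif)
from cardiocomm.pseudobulk import PseudobulkTable


def _pb(columns: dict):
    """PseudobulkTable with a norm layer from {group: {gene: value}}."""
    norm = pd.DataFrame(columns).fillna(0.0)
    norm.columns = pd.MultiIndex.from_tuples(norm.columns)
    return PseudobulkTable(
        raw_sum=norm, raw_mean=norm, norm=norm,
        n_cells=pd.Series(1, index=norm.columns),
        total_counts=norm.sum(axis=0))


class TestDatabase:
    def test_one_to_many_expansion(self):
        pairs = pd.DataFrame({"ligand": ["L"], "receptor": ["R"]})
        db, report = build_lr_database(pairs, {"L": ["l1"], "R": ["r1a", "r1b"]})
        assert len(db) == 2
        assert set(zip(db.ligand, db.receptor)) == {("l1", "r1a"), ("l1", "r1b")}
        assert report["n_dropped_unmapped"] == 0

    def test_unmapped_side_dropped_and_counted(self):
        pairs = pd.DataFrame({"ligand": ["L", "M"], "receptor": ["R", "R"]})
        db, report = build_lr_database(pairs, {"L": ["l"], "R": ["r"]})
        assert len(db) == 1 and report["n_dropped_unmapped"] == 1

    def test_duplicate_human_pairs_deduplicated(self):
        pairs = pd.DataFrame({"ligand": ["L", "L2"], "receptor": ["R", "R2"]})
        orth = {"L": ["z"], "L2": ["z"], "R": ["w"], "R2": ["w"]}
        db, _ = build_lr_database(pairs, orth)
        assert len(db) == 1
        assert ";" in db["source_pair"].iloc[0]

    def test_demo_database_loads(self):
        db, report = load_demo_database()
        assert report["n_target_pairs"] > 20
        assert ("pltpa", "abca1a") in set(zip(db.ligand, db.receptor))
        # HMGB1->AGER has no ortholog row: exercised drop path
        assert report["n_dropped_unmapped"] >= 1

    def test_malformed_rows_rejected(self):
        pairs = pd.DataFrame({"ligand": ["L"], "receptor": [None]})
        with pytest.raises(ValueError):
            build_lr_database(pairs, {})


class TestExpressedGenes:
    def test_upper_quartile_cutoff(self):
        pb = _pb({("A", "PBS3d"): {"g0": 0, "g1": 1, "g2": 4, "g3": 10,
                                   "g4": 100}})
        # nonzero values {1,4,10,100}: UQ = 32.5, only g4 reaches it
        assert expressed_genes(pb, ("A", "PBS3d")) == {"g4"}

    def test_ties_at_cutoff_count_as_expressed(self):
        pb = _pb({("A", "PBS3d"): {"g0": 5.0, "g1": 5.0, "g2": 5.0}})
        assert expressed_genes(pb, ("A", "PBS3d")) == {"g0", "g1", "g2"}

    def test_all_zero_group_warns_empty(self):
        pb = _pb({("A", "PBS3d"): {"g0": 0.0, "g1": 0.0}})
        with pytest.warns(UserWarning):
            assert expressed_genes(pb, ("A", "PBS3d")) == set()

    def test_missing_group_raises(self):
        pb = _pb({("A", "PBS3d"): {"g0": 1.0}})
        with pytest.raises(KeyError):
            expressed_genes(pb, ("B", "PBS3d"))


DB = pd.DataFrame({"ligand": ["L1", "L2"], "receptor": ["R1", "R2"],
                   "source_pair": ["h1", "h2"]})


class TestEnumerate:
    def test_expression_gated_edges(self):
        expr = {"s": {"L1"}, "r": {"R1", "R2"}}
        edges = enumerate_interactions(DB, expr, ["s"], ["r"], "PBS3d")
        assert len(edges) == 1
        assert tuple(edges.iloc[0][["sender", "ligand", "receptor",
                                    "receiver"]]) == ("s", "L1", "R1", "r")

    def test_empty_expression_no_edges(self):
        edges = enumerate_interactions(DB, {"s": set(), "r": {"R1"}},
                                       ["s"], ["r"], "PBS3d")
        assert len(edges) == 0

    def test_autocrine_allowed(self):
        expr = {"s": {"L1", "R1"}}
        edges = enumerate_interactions(DB, expr, ["s"], ["s"], "PBS3d")
        assert len(edges) == 1 and edges.iloc[0]["receiver"] == "s"

    def test_missing_cluster_raises(self):
        with pytest.raises(KeyError):
            enumerate_interactions(DB, {"s": {"L1"}}, ["s"], ["r"], "PBS3d")

    def test_matches_triple_loop_oracle(self, rng):
        genes = [f"x{i}" for i in range(30)]
        db = pd.DataFrame({
            "ligand": rng.choice(genes, 40),
            "receptor": rng.choice(genes, 40),
        }).drop_duplicates()
        clusters = ["c1", "c2", "c3"]
        expr = {c: set(rng.choice(genes, rng.integers(0, 20)))
                for c in clusters}
        edges = enumerate_interactions(db, expr, clusters, clusters, "d")
        brute = set()
        for s in clusters:
            for r in clusters:
                for lig, rec in zip(db.ligand, db.receptor):
                    if lig in expr[s] and rec in expr[r]:
                        brute.add((s, lig, rec, r))
        got = set(zip(edges.sender, edges.ligand, edges.receptor,
                      edges.receiver))
        assert got == brute

    def test_monotone_in_expressed_sets(self, rng):
        expr_small = {"s": {"L1"}, "r": {"R1"}}
        expr_big = {"s": {"L1", "L2"}, "r": {"R1", "R2"}}
        small = enumerate_interactions(DB, expr_small, ["s"], ["r"], "d")
        big = enumerate_interactions(DB, expr_big, ["s"], ["r"], "d")
        assert len(big) >= len(small)


def _edges(keys, dataset="PBS3d"):
    return pd.DataFrame([k + (dataset,) for k in keys],
                        columns=["sender", "ligand", "receptor", "receiver",
                                 "dataset"])


class TestConditionSpecific:
    A = _edges([("s", "a", "ra", "r"), ("s", "b", "rb", "r"),
                ("s", "c", "rc", "r")])
    B = _edges([("s", "b", "rb", "r"), ("s", "d", "rd", "r")], "CL3d")

    def test_set_algebra_partition(self):
        out = condition_specific_pairs(self.A, self.B)
        by = out.groupby("specificity")["ligand"].apply(set)
        assert by["PBS-only"] == {"a", "c"}
        assert by["CL-only"] == {"d"}
        assert by["shared"] == {"b"}
        assert len(out) == 4  # exact partition of the union

    def test_identical_lists_all_shared(self):
        out = condition_specific_pairs(self.A, self.A.assign(dataset="CL3d"))
        assert (out["specificity"] == "shared").all()

    def test_disjoint_lists_nothing_shared(self):
        out = condition_specific_pairs(
            self.A, _edges([("s", "z", "rz", "r")], "CL3d"))
        assert "shared" not in set(out["specificity"])

    def test_mismatched_timepoints_rejected(self):
        with pytest.raises(ValueError, match="timepoint"):
            condition_specific_pairs(self.A, _edges([("s", "b", "rb", "r")],
                                                    "CL7d"))


class TestNetworkExport:
    def test_single_edge_count_matrix(self):
        counts = summarize_network(_edges([("s", "a", "ra", "r")]))
        assert counts.loc["s", "r"] == 1

    def test_counts_match_brute_tally(self, rng):
        keys = [(f"s{rng.integers(3)}", f"l{i}", f"r{i}",
                 f"r{rng.integers(2)}") for i in range(50)]
        edges = _edges(keys)
        counts = summarize_network(edges)
        for (s, r), grp in edges.groupby(["sender", "receiver"]):
            assert counts.loc[s, r] == len(grp)

    def test_sif_round_trip_preserves_edges(self, tmp_path):
        edges = _edges([("s", "a", "ra", "r"), ("t", "b", "rb", "r")])
        path = write_sif(edges, tmp_path / "n.sif")
        back = read_sif(path)
        assert set(map(tuple, back.itertuples(index=False))) == \
            set(map(tuple, edges[["sender", "ligand", "receptor",
                                  "receiver"]].itertuples(index=False)))

    def test_graphml_weights(self, tmp_path):
        import networkx as nx
        edges = _edges([("s", "a", "ra", "r"), ("s", "b", "rb", "r")])
        path = write_graphml(edges, tmp_path / "n.graphml")
        g = nx.read_graphml(path)
        assert g["s"]["r"]["weight"] == 2
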