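"""Shared-miRNA ceRNA pairing against a brute-force double-loop oracle."""

from itertools import combinations

import networkx as nx
import pandas as pd
import pytest

from camlnc.data_model import BindingTable, DataError
from camlnc.cerna import (
    cerna_network,
    cerna_network_export,
    focal_cerna,
    shared_mirna_pairs,
)


def table(records) -> BindingTable:
    return BindingTable(pd.DataFrame(records, columns=["mirna", "transcript", "mode"]))


def oracle_pairs(t: BindingTable, include_mimic_mimic=False):
    """Independent double loop over all transcript pairs x miRNAs."""
    tx = t.transcripts()
    out = {}
    for a, b in combinations(tx, 2):
        shared = {}
        for m in t.mirnas():
            rec = t.records
            ma = set(rec[(rec.mirna == m) & (rec.transcript == a)]["mode"])
            mb = set(rec[(rec.mirna == m) & (rec.transcript == b)]["mode"])
            if ma and mb:
                if "perfect" in ma and "perfect" in mb:
                    shared[m] = "pp"
                elif "perfect" in ma | mb:
                    shared[m] = "pm"
                else:
                    shared[m] = "mm"
        if not shared:
            continue
        kinds = set(shared.values())
        if "pp" in kinds:
            ptype = "target-target"
        elif "pm" in kinds:
            ptype = "target-mimic"
        elif include_mimic_mimic:
            ptype = "mimic-mimic"
        else:
            continue
        out[(a, b)] = (frozenset(shared), ptype)
    return out


PPCK_STYLE = table(
    [("miR1", "PPCK", "perfect"), ("miR2", "PPCK", "perfect")]
    + [("miR1", f"lnc{i}", "mimic") for i in (1, 2, 3)]
    + [("miR2", f"lnc{i}", "mimic") for i in (4, 5)]
)


class TestSharedPairs:
    def test_target_target_example(self):
        t = table([("m1", "A", "perfect"), ("m1", "B", "perfect"), ("m2", "C", "perfect")])
        (p,) = shared_mirna_pairs(t)
        assert p.key == ("A", "B")
        assert p.pair_type == "target-target"
        assert set(p.shared_mirnas) == {"m1"}

    def test_no_sharing_is_empty(self):
        t = table([("m1", "A", "perfect"), ("m2", "B", "mimic")])
        assert shared_mirna_pairs(t) == []
        assert shared_mirna_pairs(table([])) == []

    def test_mimic_mimic_excluded_by_default(self):
        t = table([("m1", "A", "mimic"), ("m1", "B", "mimic")])
        assert shared_mirna_pairs(t) == []
        (p,) = shared_mirna_pairs(t, include_mimic_mimic=True)
        assert p.pair_type == "mimic-mimic"

    def test_mixed_modes_typed_by_strongest_link(self):
        t = table(
            [("m1", "A", "perfect"), ("m1", "B", "mimic"),
             ("m2", "A", "perfect"), ("m2", "B", "perfect")]
        )
        (p,) = shared_mirna_pairs(t)
        assert p.pair_type == "target-target"
        assert set(p.shared_mirnas) == {"m1", "m2"}

    def test_matches_brute_force_on_random_table(self):
        import numpy as np

        rng = np.random.default_rng(21)
        records = set()
        while len(records) < 400:
            records.add(
                (f"m{rng.integers(30)}", f"t{rng.integers(60)}",
                 "perfect" if rng.integers(2) else "mimic")
            )
        t = table(sorted(records))
        for flag in (False, True):
            got = {
                p.key: (p.shared_mirnas, p.pair_type)
                for p in shared_mirna_pairs(t, include_mimic_mimic=flag)
            }
            assert got == oracle_pairs(t, include_mimic_mimic=flag)

    def test_monotone_under_added_binding(self):
        t = table([("m1", "A", "perfect"), ("m1", "B", "perfect")])
        before = {p.key for p in shared_mirna_pairs(t)}
        t2 = table(
            [("m1", "A", "perfect"), ("m1", "B", "perfect"), ("m9", "C", "mimic")]
        )
        assert before <= {p.key for p in shared_mirna_pairs(t2)}


class TestFocal:
    def test_ppck_style_triangle(self):
        """2 miRNAs perfectly bind the focal gene, 5 lncRNAs mimic-bind them:
        5 target-mimic partners competing for 2 miRNAs."""
        pairs, competed = focal_cerna(PPCK_STYLE, "PPCK")
        partners = {p.transcript_b if p.transcript_a == "PPCK" else p.transcript_a
                    for p in pairs}
        assert partners == {f"lnc{i}" for i in range(1, 6)}
        assert competed == {"miR1", "miR2"}
        assert all(p.pair_type == "target-mimic" for p in pairs)

    def test_focal_without_sharing(self):
        t = table([("m1", "A", "perfect"), ("m2", "B", "perfect")])
        pairs, competed = focal_cerna(t, "A")
        assert pairs == [] and competed == set()

    def test_absent_focal_rejected(self):
        with pytest.raises(DataError):
            focal_cerna(PPCK_STYLE, "nope")

    def test_matches_filtered_pair_list(self):
        import numpy as np

        rng = np.random.default_rng(2)
        records = {(f"m{rng.integers(10)}", f"t{rng.integers(20)}",
                    "perfect" if rng.integers(2) else "mimic") for _ in range(80)}
        t = table(sorted(records))
        focal = t.transcripts()[0]
        pairs, _ = focal_cerna(t, focal)
        expected = [p for p in shared_mirna_pairs(t) if focal in p.key]
        assert {p.key for p in pairs} == {p.key for p in expected}

    def test_planted_triangle_in_cohort(self, cohort):
        truth = cohort["cerna_truth"]
        for focal, info in truth["focal"].items():
            pairs, competed = focal_cerna(cohort["bindings"], focal)
            partners = sorted(
                p.transcript_b if p.transcript_a == focal else p.transcript_a
                for p in pairs
            )
            assert partners == info["decoys"]
            assert sorted(competed) == info["mirnas"]


class TestNetworkExport:
    def test_ppck_counts(self, tmp_path):
        pairs = shared_mirna_pairs(PPCK_STYLE)
        classes = {"PPCK": "mRNA", **{f"lnc{i}": "lincRNA" for i in range(1, 6)}}
        g = cerna_network_export(pairs, classes, str(tmp_path / "net.graphml"))
        # 1 focal + 5 lncRNAs + 2 miRNAs
        assert g.number_of_nodes() == 8
        # each miRNA joins focal + its own decoys: miR1 -> 4 edges, miR2 -> 3
        assert g.number_of_edges() == 7
        back = nx.read_graphml(str(tmp_path / "net.graphml"))
        assert back.number_of_nodes() == 8

    def test_empty_pairs_graph(self, tmp_path):
        g = cerna_network_export([], {}, str(tmp_path / "empty.graphml"))
        assert g.number_of_nodes() == 0

    def test_unclassified_node_rejected(self):
        pairs = shared_mirna_pairs(PPCK_STYLE)
        with pytest.raises(DataError, match="unclassified"):
            cerna_network(pairs, {"PPCK": "mRNA"})
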