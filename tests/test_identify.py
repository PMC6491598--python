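"""Class-code assignment and the five-criterion filter funnel."""

import numpy as np
import pandas as pd
import pytest

from camlnc.data_model import DataError, ExpressionMatrix
from camlnc.identify import (
    IdentificationConfig,
    assign_class_codes,
    classify_biotype,
    filter_lncrna,
)

from conftest import candidate, oracle_class_code, oracle_filter


def _code(tx, ref):
    return assign_class_codes([tx], ref)[0].class_code


class TestClassCodes:
    def test_far_from_genes_is_u(self, tiny_ref):
        tx = candidate("c", "chr1", "+", [(20000, 20500)])
        assert _code(tx, tiny_ref) == "u"

    def test_antisense_exonic_overlap_is_x(self, tiny_ref):
        tx = candidate("c", "chr1", "-", [(1200, 1700)])  # g1 is '+'
        assert _code(tx, tiny_ref) == "x"

    def test_sense_exonic_overlap_is_other(self, tiny_ref):
        tx = candidate("c", "chr1", "+", [(1200, 1700)])
        assert _code(tx, tiny_ref) == "other"

    def test_intron_containment_is_i(self, tiny_ref):
        tx = candidate("c", "chr1", "+", [(1800, 2400)])  # inside g1 intron
        assert _code(tx, tiny_ref) == "i"

    def test_unknown_chromosome_rejected(self, tiny_ref):
        tx = candidate("c", "chrX", "+", [(100, 400)])
        with pytest.raises(DataError, match="chrX"):
            assign_class_codes([tx], tiny_ref)

    def test_matches_all_pairs_oracle_on_synthetic_cohort(self, cohort):
        """Every planted candidate gets the oracle's code, and the planted
        truth agrees with both."""
        ann = cohort["ann"]
        coded = assign_class_codes(ann.candidates, ann.ref)
        assert len(coded) == len(ann.candidates)
        for tx in coded:
            assert tx.class_code == oracle_class_code(tx, ann.ref), tx.id
            assert tx.class_code == ann.truth[tx.id]["class_code"], tx.id


def _expr_for(ids, maxima):
    cols = ["s1", "s2"]
    vals = pd.DataFrame(
        {"s1": [m / 2 for m in maxima], "s2": list(maxima)}, index=ids
    )
    sdf = pd.DataFrame({"sample": cols, "tissue": cols,
                        "time_hour": np.nan, "replicate": pd.NA}).set_index("sample")
    sdf["replicate"] = sdf["replicate"].astype("Int64")
    return ExpressionMatrix(vals, sdf)


def _scores(ids, cpc=-1.2, pfam=0):
    return pd.DataFrame({"id": ids, "cpc_score": cpc, "pfam_hit": pfam})


class TestFilterFunnel:
    def test_single_examples(self):
        txs = [
            candidate("short", "chr1", "+", [(1, 150)], class_code="u"),
            candidate("good", "chr1", "+", [(1, 150), (300, 500)], class_code="u"),
            candidate("mono_mid", "chr1", "+", [(1, 400)], class_code="u"),
            candidate("cpc_zero", "chr1", "+", [(1, 400)], class_code="u"),
        ]
        scores = pd.DataFrame(
            {"id": ["short", "good", "mono_mid", "cpc_zero"],
             "cpc_score": [-1.0, -1.2, -1.0, 0.0],
             "pfam_hit": 0}
        )
        expr = _expr_for(["short", "good", "mono_mid", "cpc_zero"], [5.0, 0.7, 1.5, 5.0])
        accepted, low_conf, funnel = filter_lncrna(txs, scores, expr)
        ids = {t.id for t in accepted}
        # 150 nt fails length; 2-exon max FPKM 0.7 passes the 0.5 bar;
        # single-exon max 1.5 fails the 2.0 bar; CPC exactly 0 is excluded
        assert ids == {"good"}
        assert {t.id for t in low_conf} == {"mono_mid"}
        assert [s.name for s in funnel.steps] == [
            "class_code", "length", "cpc", "pfam", "strand", "expression"
        ]

    def test_funnel_monotone_and_partitions(self, cohort):
        ann = cohort["ann"]
        coded = assign_class_codes(ann.candidates, ann.ref)
        from camlnc.data_model import concat_samples

        expr = concat_samples(cohort["green"], cohort["white"])
        accepted, low_conf, funnel = filter_lncrna(
            coded, ann.scores, expr.subset([t.id for t in coded])
        )
        counts = [s.n_in for s in funnel.steps] + [funnel.steps[-1].n_out]
        assert counts == sorted(counts, reverse=True)
        rejected = [tid for s in funnel.steps for tid in s.rejected_ids]
        assert len(rejected) == len(set(rejected))  # no transcript in two bins
        assert set(rejected) | {t.id for t in accepted} == {t.id for t in coded}
        assert {t.id for t in low_conf} <= set(rejected)

    def test_accepted_equals_brute_force_oracle(self, cohort):
        ann = cohort["ann"]
        coded = assign_class_codes(ann.candidates, ann.ref)
        from camlnc.data_model import collapse_replicates, concat_samples

        expr = concat_samples(cohort["green"], cohort["white"]).subset(
            [t.id for t in coded]
        )
        accepted, _, _ = filter_lncrna(coded, ann.scores, expr)
        assert {t.id for t in accepted} == oracle_filter(
            coded, ann.scores, collapse_replicates(expr)
        )

    def test_missing_score_row_names_transcript(self):
        tx = candidate("lost", "chr1", "+", [(1, 400)], class_code="u")
        with pytest.raises(DataError, match="lost"):
            filter_lncrna([tx], _scores(["other"]), _expr_for(["lost"], [5.0]))

    def test_monoexon_threshold_must_dominate(self):
        with pytest.raises(DataError):
            IdentificationConfig(min_fpkm_multiexon=3.0, min_fpkm_monoexon=1.0)


class TestBiotype:
    def test_u_is_lincrna_and_x_is_lncnat(self):
        u = candidate("u1", "chr1", "+", [(1, 400)], class_code="u",
                      antisense_overlap=False)
        x = candidate("x1", "chr1", "+", [(1, 400)], class_code="x",
                      antisense_overlap=True)
        out = classify_biotype([u, x])
        assert [t.biotype for t in out] == ["lincRNA", "lncNAT"]

    def test_intronic_split_by_host_strand(self):
        sense = candidate("is", "chr1", "+", [(1, 400)], class_code="i",
                          antisense_overlap=False)
        anti = candidate("ia", "chr1", "+", [(1, 400)], class_code="i",
                         antisense_overlap=True)
        out = classify_biotype([sense, anti])
        assert [t.biotype for t in out] == ["lincRNA", "lncNAT"]

    def test_planted_counts_recovered(self):
        """7 planted antisense and 13 planted intergenic -> 7 lncNAT, 13 lincRNA."""
        txs = [
            candidate(f"a{i}", "chr1", "+", [(1, 400)], class_code="x",
                      antisense_overlap=True)
            for i in range(7)
        ] + [
            candidate(f"u{i}", "chr1", "+", [(1, 400)], class_code="u",
                      antisense_overlap=False)
            for i in range(13)
        ]
        out = classify_biotype(txs)
        assert sum(t.biotype == "lncNAT" for t in out) == 7
        assert sum(t.biotype == "lincRNA" for t in out) == 13

    def test_partition_is_total_on_cohort(self, cohort):
        ann = cohort["ann"]
        coded = assign_class_codes(ann.candidates, ann.ref)
        accepted = [t for t in coded if t.class_code in ("u", "x", "i") and t.strand in ("+", "-")]
        out = classify_biotype(accepted)
        assert all(t.biotype in ("lincRNA", "lncNAT") for t in out)
        planted = {"lincrna", "lncnat", "intronic"}
        for t in out:
            if ann.truth[t.id]["role"] in planted:
                assert t.biotype == ann.truth[t.id]["biotype"], t.id

    def test_unassigned_code_rejected(self):
        tx = candidate("c", "chr1", "+", [(1, 400)])
        with pytest.raises(DataError):
            classify_biotype([tx])
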