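"""Genomic-feature statistics against brute-force recomputation."""

import numpy as np
import pandas as pd
import pytest

from camlnc.data_model import DataError, ExpressionMatrix, GenomeAnnotation, GeneModel
from camlnc.characterize import (
    antisense_overlap_fraction,
    compare_expression_distributions,
    feature_summary,
    locus_distances,
)
from camlnc.identify import assign_class_codes, classify_biotype

from conftest import candidate, make_gene, oracle_ks_statistic


class TestFeatureSummary:
    def test_small_arithmetic(self):
        txs = [
            candidate("a", "chr1", "+", [(1, 100)], class_code="u", biotype="lincRNA"),
            candidate("b", "chr1", "+", [(1, 100), (200, 336), (500, 699)],
                      class_code="u", biotype="lincRNA"),
        ]
        s = feature_summary(txs).classes["lincRNA"]
        assert s.mean_exon_count == pytest.approx(2.0)
        assert s.fraction_spliced == pytest.approx(0.5)
        # exon lengths 100, 100, 137, 200 -> median 118.5; odd-count check below
        assert s.median_exon_length == pytest.approx(118.5)
        odd = feature_summary(
            [candidate("c", "chr1", "+", [(1, 100), (200, 336), (400, 599)],
                       biotype="lincRNA", class_code="u")]
        ).classes["lincRNA"]
        assert odd.median_exon_length == pytest.approx(137.0)

    def test_empty_class_absent_not_zero(self):
        txs = [candidate("a", "chr1", "+", [(1, 400)], class_code="u", biotype="lincRNA")]
        s = feature_summary(txs)
        assert "lncNAT" not in s.classes and "coding" not in s.classes

    def test_matches_brute_force_on_cohort(self, cohort):
        ann = cohort["ann"]
        classified = classify_biotype(
            [t for t in assign_class_codes(ann.candidates, ann.ref)
             if t.class_code in ("u", "x", "i") and t.strand in ("+", "-")]
        )
        all_tx = classified + ann.ref.transcripts
        s = feature_summary(all_tx)
        for cls in ("lincRNA", "lncNAT", "coding"):
            members = [t for t in all_tx if t.biotype == cls]
            got = s.classes[cls]
            assert got.n_transcripts == len(members)
            assert got.mean_exon_count == pytest.approx(
                np.mean([t.n_exons for t in members])
            )
            assert got.fraction_spliced == pytest.approx(
                np.mean([t.n_exons >= 2 for t in members])
            )
            lens = [e - s_ + 1 for t in members for s_, e in t.exons]
            assert got.median_exon_length == pytest.approx(np.median(lens))
            assert got.median_transcript_length == pytest.approx(
                np.median([t.length for t in members])
            )


class TestAntisenseOverlap:
    def test_full_containment_is_one(self, tiny_ref):
        nat = candidate("n", "chr1", "-", [(1100, 1400)], class_code="x",
                        biotype="lncNAT")
        assert antisense_overlap_fraction(nat, tiny_ref) == pytest.approx(1.0)

    def test_quarter_overlap(self, tiny_ref):
        # 400 nt exon, 100 bases inside g1's span [1000, 3500]
        nat = candidate("n", "chr1", "-", [(700, 1099)], class_code="x",
                        biotype="lncNAT")
        assert antisense_overlap_fraction(nat, tiny_ref) == pytest.approx(0.25)

    def test_requires_lncnat(self, tiny_ref):
        tx = candidate("n", "chr1", "-", [(1100, 1400)], class_code="x")
        with pytest.raises(DataError):
            antisense_overlap_fraction(tx, tiny_ref)

    def test_matches_per_base_oracle_on_cohort(self, cohort):
        ann = cohort["ann"]
        classified = classify_biotype(
            [t for t in assign_class_codes(ann.candidates, ann.ref)
             if t.class_code in ("u", "x", "i") and t.strand in ("+", "-")]
        )
        nats = [t for t in classified if t.biotype == "lncNAT"]
        assert nats
        spans = {g.id: (g.chrom, g.strand, g.span) for g in ann.ref.genes}
        for nat in nats:
            covered = set()
            for s, e in nat.exons:
                for chrom, strand, (gs, ge) in spans.values():
                    if chrom == nat.chrom and strand != nat.strand:
                        covered |= set(range(max(s, gs), min(e, ge) + 1))
            expected = len(covered) / nat.length
            assert antisense_overlap_fraction(nat, ann.ref) == pytest.approx(expected)
            assert 0 < expected <= 1


class TestLocusDistances:
    def test_gap_convention(self, tiny_ref):
        lnc = candidate("l", "chr1", "+", [(4000, 5000)], class_code="u",
                        biotype="lincRNA")
        d = locus_distances([lnc], tiny_ref)
        # g1 ends at 3500: gap 4000-3500-1 = 499 intervening bases
        assert d.lncrna_to_gene == [499]
        # adjacent genes [1000,3500] and [10000,11600] -> 6499 bases apart
        assert d.gene_to_gene == [6499]

    def test_overlap_gives_zero(self, tiny_ref):
        lnc = candidate("l", "chr1", "-", [(3400, 4200)], class_code="x",
                        biotype="lncNAT")
        assert locus_distances([lnc], tiny_ref).lncrna_to_gene == [0]

    def test_adjacent_interval_example(self):
        ref = GenomeAnnotation({"c": 10000}, [make_gene("g", "c", "+", [(3000, 4000)])])
        lnc = candidate("l", "c", "+", [(1000, 2000)], class_code="u", biotype="lincRNA")
        assert locus_distances([lnc], ref).lncrna_to_gene == [999]

    def test_single_gene_chromosome_contributes_no_interval(self):
        ref = GenomeAnnotation({"c": 10000}, [make_gene("g", "c", "+", [(3000, 4000)])])
        assert locus_distances([], ref).gene_to_gene == []

    def test_matches_all_pairs_oracle_on_cohort(self, cohort):
        ann = cohort["ann"]
        lncs = [t for t in assign_class_codes(ann.candidates, ann.ref)
                if t.class_code in ("u", "x", "i") and t.strand in ("+", "-")]
        d = locus_distances(lncs, ann.ref)
        spans = {}
        for g in ann.ref.genes:
            spans.setdefault(g.chrom, []).append(g.span)
        # lncRNA -> nearest gene, brute force
        expect = []
        for t in lncs:
            best = None
            ts, te = t.span
            for gs, ge in spans.get(t.chrom, []):
                gap = 0 if (gs <= te and ts <= ge) else (
                    ts - ge - 1 if ge < ts else gs - te - 1
                )
                best = gap if best is None else min(best, gap)
            expect.append(best)
        assert d.lncrna_to_gene == expect
        # gene-to-gene: consecutive sorted spans
        gg = []
        for chrom in spans:
            ordered = sorted(spans[chrom])
            gg.extend(max(0, b[0] - a[1] - 1) for a, b in zip(ordered, ordered[1:]))
        assert sorted(d.gene_to_gene) == sorted(gg)
        introns = [ie - is_ + 1 for g in ann.ref.genes
                   for t in g.transcripts for is_, ie in t.introns]
        assert sorted(d.intron_lengths) == sorted(introns)

    def test_strand_flip_invariance(self, cohort):
        ann = cohort["ann"]
        lncs = [t for t in assign_class_codes(ann.candidates, ann.ref)
                if t.class_code in ("u", "x", "i") and t.strand in ("+", "-")]
        flip = {"+": "-", "-": "+", ".": "."}
        flipped_genes = [
            GeneModel(g.id, g.chrom, flip[g.strand],
                      [t.copy(strand=flip[t.strand], biotype="coding")
                       for t in g.transcripts])
            for g in cohort["ann"].ref.genes
        ]
        flipped = GenomeAnnotation(ann.ref.chromosomes, flipped_genes)
        assert locus_distances(lncs, ann.ref).lncrna_to_gene == \
            locus_distances(lncs, flipped).lncrna_to_gene


class TestKS:
    def test_identical_samples_zero(self):
        a = [1.0, 2.0, 3.0, 4.0]
        stat, _ = compare_expression_distributions(a, a)
        assert stat == pytest.approx(0.0)

    def test_disjoint_supports_one(self):
        rng = np.random.default_rng(1)
        a = rng.uniform(0, 0.1, 50)
        b = rng.uniform(10, 10.1, 50)
        stat, p = compare_expression_distributions(a, b)
        assert stat == pytest.approx(1.0)
        assert p < 1e-20

    def test_statistic_matches_ecdf_oracle(self):
        rng = np.random.default_rng(42)
        a, b = rng.exponential(5, 100), rng.exponential(5, 100)
        stat, _ = compare_expression_distributions(a, b)
        assert stat == pytest.approx(oracle_ks_statistic(a, b))

    def test_empty_input_rejected(self):
        with pytest.raises(DataError):
            compare_expression_distributions([], [1.0])
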