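"""Shared fixtures: a tiny hand-built annotation, a noiseless simulated
cohort, and independent brute-force oracles used across test modules."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from camlnc.data_model import (
    ExpressionMatrix,
    GeneModel,
    GenomeAnnotation,
    TranscriptModel,
)
from camlnc.synthetic_data import (
    SimulationConfig,
    simulate_annotation,
    simulate_bindings,
    simulate_diel_expression,
    simulate_tissue_expression,
)


def make_gene(gid, chrom, strand, exons):
    tx = TranscriptModel(id=f"{gid}.1", gene_id=gid, chrom=chrom, strand=strand,
                         exons=exons, biotype="coding")
    return GeneModel(gid, chrom, strand, [tx])


@pytest.fixture
def tiny_ref() -> GenomeAnnotation:
    """Two genes on one chromosome: g1 (+) with two exons and a wide
    intron, g2 (-) downstream."""
    g1 = make_gene("g1", "chr1", "+", [(1000, 1500), (3000, 3500)])
    g2 = make_gene("g2", "chr1", "-", [(10000, 10400), (11000, 11600)])
    return GenomeAnnotation({"chr1": 50000}, [g1, g2])


def candidate(tid, chrom, strand, exons, **kw):
    return TranscriptModel(id=tid, gene_id=tid, chrom=chrom, strand=strand,
                           exons=exons, **kw)


@pytest.fixture(scope="session")
def noiseless_cfg() -> SimulationConfig:
    return SimulationConfig(seed=11, noise_sd=0.0)


@pytest.fixture(scope="session")
def cohort(noiseless_cfg):
    """One noiseless synthetic cohort shared across test modules."""
    ann = simulate_annotation(noiseless_cfg)
    green, white, diel_truth = simulate_diel_expression(noiseless_cfg, ann)
    tissue_m, tau_truth = simulate_tissue_expression(noiseless_cfg, ann)
    bindings, cerna_truth = simulate_bindings(noiseless_cfg, ann)
    return {
        "cfg": noiseless_cfg,
        "ann": ann,
        "green": green,
        "white": white,
        "diel_truth": diel_truth,
        "tissue": tissue_m,
        "tau_truth": tau_truth,
        "bindings": bindings,
        "cerna_truth": cerna_truth,
    }


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------


def _intervals_overlap(a, b) -> bool:
    return a[0] <= b[1] and b[0] <= a[1]


def oracle_class_code(tx: TranscriptModel, ref: GenomeAnnotation) -> str:
    """All-pairs interval-scan class code, written independently of the
    indexed implementation: 'u' no locus overlap; sense exonic -> 'other';
    antisense exonic -> 'x'; intron containment -> 'i'; else 'other'."""
    genes = [g for g in ref.genes if g.chrom == tx.chrom]
    touching = [
        g for g in genes
        if any(_intervals_overlap(ex, g.span) for ex in tx.exons)
    ]
    if not touching:
        return "u"
    sense = antisense = False
    for g in genes:
        for rtx in g.transcripts:
            for rex in rtx.exons:
                for ex in tx.exons:
                    if _intervals_overlap(ex, rex):
                        if g.strand == tx.strand:
                            sense = True
                        elif tx.strand != "." and g.strand != ".":
                            antisense = True
    if sense:
        return "other"
    if antisense:
        return "x"
    s, e = tx.span
    for g in touching:
        for rtx in g.transcripts:
            for intron in rtx.introns:
                if intron[0] <= s and e <= intron[1]:
                    return "i"
    return "other"


def oracle_filter(candidates, scores: pd.DataFrame, expr: ExpressionMatrix):
    """Literal re-application of the five written criteria (brute force)."""
    stab = scores.set_index("id")
    row_max = expr.values.max(axis=1)
    accepted = []
    for t in candidates:
        if t.class_code not in ("u", "x", "i"):
            continue
        if not t.length > 200:
            continue
        if not float(stab.loc[t.id, "cpc_score"]) < 0:
            continue
        if int(stab.loc[t.id, "pfam_hit"]) != 0:
            continue
        if t.strand not in ("+", "-"):
            continue
        bar = 0.5 if t.n_exons >= 2 else 2.0
        if float(row_max[t.id]) < bar:
            continue
        accepted.append(t.id)
    return set(accepted)


def oracle_tau(x) -> float:
    x = np.asarray(x, dtype=float)
    xhat = x / x.max()
    return sum(1.0 - v for v in xhat) / (len(x) - 1)


def oracle_ks_statistic(a, b) -> float:
    """sup_x |ECDF_a(x) - ECDF_b(x)| by direct evaluation at all points."""
    a = np.sort(np.asarray(a, dtype=float))
    b = np.sort(np.asarray(b, dtype=float))
    grid = np.concatenate([a, b])
    best = 0.0
    for x in grid:
        fa = np.searchsorted(a, x, side="right") / a.size
        fb = np.searchsorted(b, x, side="right") / b.size
        best = max(best, abs(fa - fb))
    return best
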