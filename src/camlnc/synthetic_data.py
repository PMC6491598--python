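"""Synthetic-data generator with planted ground truth.

Emulates every input of the analysis: a coding-gene reference annotation,
candidate transcripts planted as intergenic / antisense-exonic / intronic
(plus one planted failure set per filter criterion), coding-potential
scores, a four-tissue expression matrix with planted specific and
near-uniform rows, two diel time series (green leaf tip, white leaf base;
13 points, 3 replicates) with planted cycling transcripts and negatives,
and a miRNA binding table with planted ceRNA triangles.

Truth labels written to the manifest are *realized*: recomputed from the
numbers actually emitted (after noise and replicate averaging), so that
recovery tests on noiseless data are exact rather than approximate.
All randomness flows from one seed through named substreams; structure is
integer arithmetic, so output files are byte-identical across runs.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .data_model import (
    BindingTable,
    DataError,
    ExpressionMatrix,
    GeneModel,
    GenomeAnnotation,
    TranscriptModel,
    collapse_replicates,
    average_by_tissue,
    concat_samples,
    write_bindings,
    write_expression,
    write_gtf,
    write_tsv,
)
from .diel_cycling import MODEL_SHAPES, _shape_values
from .tissue_specificity import tau as tau_index

MARGIN = 500          # bp kept clear between genes and intergenic candidates
SPACING = 300         # bp between two candidates sharing a gap

# Planted cycling waveforms.  The spike model stays in the scoring library
# but is never planted: a one-point spike is invariant (in best-model r)
# under time-label permutation, so the permutation p-value has no power
# against it and a spike plant could never satisfy all four criteria.
PLANT_SHAPES = ("cosine", "box", "sawtooth")


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic cohort.

    Defaults mirror the real study's shape at desk scale: 13 diel time
    points x 2 leaf tissues x 3 replicates, four tissues with six fruit
    stages, FPKM-scale values, and mild measurement noise.
    """

    seed: int = 0
    # genome / annotation
    n_chromosomes: int = 2
    n_coding_genes: int = 60
    # planted candidate classes
    n_lincrna: int = 24
    n_lncnat: int = 12
    n_intronic: int = 8
    # planted single-criterion failures
    n_fail_class: int = 6
    n_fail_short: int = 6
    n_fail_cpc: int = 6
    n_fail_pfam: int = 6
    n_fail_unstranded: int = 6
    n_fail_lowexpr: int = 6
    # tissue panel
    tissues: tuple = ("flower", "leaf", "root", "fruit")
    n_fruit_stages: int = 6
    n_specific_lnc_per_tissue: int = 3
    n_specific_mrna_per_tissue: int = 5
    n_undetected_lnc: int = 4
    # diel series
    diel_grid: tuple = (18.0, 20.0, 22.0, 0.0, 2.0, 4.0, 6.0, 8.0, 10.0, 12.0, 13.0, 15.0, 16.0)
    n_replicates: int = 3
    n_cycling_both: int = 6
    n_cycling_green: int = 6
    n_cycling_white: int = 6
    n_flat: int = 6
    n_low_amplitude: int = 4
    n_low_fold: int = 4
    baseline_range: tuple = (2.0, 8.0)
    amplitude_range: tuple = (20.0, 40.0)
    low_amplitude: float = 5.0
    low_fold_baseline: float = 100.0
    low_fold_amplitude: float = 15.0
    noise_sd: float = 0.2
    negative_partner_every: int = 3
    # ceRNA triangles: (n shared miRNAs, n mimic decoys) per focal gene
    triangles: tuple = ((2, 5), (3, 8))
    n_target_target: int = 3
    n_background_bindings: int = 20

    def __post_init__(self) -> None:
        counts = [
            self.n_chromosomes, self.n_coding_genes, self.n_lincrna, self.n_lncnat,
            self.n_intronic, self.n_fail_class, self.n_fail_short, self.n_fail_cpc,
            self.n_fail_pfam, self.n_fail_unstranded, self.n_fail_lowexpr,
            self.n_replicates,
        ]
        if any(c < 0 for c in counts):
            raise DataError("simulation counts must be non-negative")
        if self.noise_sd < 0:
            raise DataError("noise_sd must be non-negative")
        host_needed = self.n_lncnat + self.n_intronic + self.n_fail_class
        if host_needed > self.n_coding_genes:
            raise DataError(
                f"need {host_needed} host genes but only {self.n_coding_genes} coding genes"
            )


@dataclass
class AnnotationSim:
    ref: GenomeAnnotation
    candidates: list[TranscriptModel]
    scores: pd.DataFrame
    truth: dict  # per candidate: class_code, biotype, failure role
    roles: dict = field(default_factory=dict)  # role -> list of candidate ids


def _rng(cfg: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(cfg.seed), stream])


def _norm_model(shape: str, grid: np.ndarray, phase: float) -> np.ndarray:
    v = _shape_values(shape, grid, phase)
    return (v - v.min()) / (v.max() - v.min())


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------


def _make_candidate_exons(rng, n_exons: int) -> list[int]:
    """Exon lengths for a candidate: first exon long enough that total > 200."""
    lens = [int(rng.integers(250, 501))]
    for _ in range(n_exons - 1):
        lens.append(int(rng.integers(80, 301)))
    return lens


def simulate_annotation(cfg: SimulationConfig) -> AnnotationSim:
    """Lay out coding genes and planted candidates on synthetic chromosomes.

    Intergenic candidates (class 'u') carry the per-criterion failure
    plants; antisense-exonic ('x'), intronic ('i', half sense half
    antisense) and sense-overlap ('other') candidates are hosted by
    distinct coding genes.
    """
    rng = _rng(cfg, 1)
    per_chrom = [cfg.n_coding_genes // cfg.n_chromosomes] * cfg.n_chromosomes
    for i in range(cfg.n_coding_genes % cfg.n_chromosomes):
        per_chrom[i] += 1

    genes: list[GeneModel] = []
    chromosomes: dict[str, int] = {}
    free: list[list] = []  # [chrom, lo, hi] usable intergenic intervals
    gidx = 0
    for ci in range(cfg.n_chromosomes):
        chrom = f"chr{ci + 1}"
        cursor = 1
        for _ in range(per_chrom[ci]):
            gap = int(rng.integers(4000, 9001))
            gstart = cursor + gap
            if gstart - MARGIN > cursor + MARGIN:
                free.append([chrom, cursor + MARGIN, gstart - MARGIN])
            n_ex = int(rng.integers(4, 9))
            pos = gstart
            exons = []
            for k in range(n_ex):
                elen = int(rng.integers(80, 301))
                exons.append((pos, pos + elen - 1))
                pos = exons[-1][1] + 1
                if k < n_ex - 1:
                    pos += int(rng.integers(200, 2501))
            strand = "+" if rng.integers(0, 2) == 0 else "-"
            gid = f"GENE{gidx:04d}"
            gidx += 1
            tx = TranscriptModel(
                id=f"{gid}.1", gene_id=gid, chrom=chrom, strand=strand,
                exons=exons, biotype="coding",
            )
            genes.append(GeneModel(gid, chrom, strand, [tx]))
            cursor = exons[-1][1]
        free.append([chrom, cursor + MARGIN, cursor + MARGIN + 15000])
        chromosomes[chrom] = cursor + MARGIN + 20000

    def alloc(span_len: int) -> tuple[str, int]:
        for iv in free:
            if iv[2] - iv[1] + 1 >= span_len:
                start = iv[1]
                iv[1] += span_len + SPACING
                return iv[0], start
        raise DataError(
            "chromosome capacity insufficient for the requested candidate count"
        )

    candidates: list[TranscriptModel] = []
    truth: dict[str, dict] = {}
    roles: dict[str, list[str]] = {}
    counter = [0]

    def next_id() -> str:
        counter[0] += 1
        return f"TCONS_{counter[0]:05d}"

    def add(tx: TranscriptModel, role: str, class_code: str, biotype: str) -> None:
        candidates.append(tx)
        truth[tx.id] = {"role": role, "class_code": class_code, "biotype": biotype}
        roles.setdefault(role, []).append(tx.id)

    def place_intergenic(role: str, n: int, exon_plan=None, strand_known=True) -> None:
        for k in range(n):
            if exon_plan is None:
                n_ex = int(rng.integers(1, 4))
                lens = _make_candidate_exons(rng, n_ex)
            else:
                lens = exon_plan(rng, k)
            introns = [int(rng.integers(150, 601)) for _ in range(len(lens) - 1)]
            span = sum(lens) + sum(introns)
            chrom, start = alloc(span)
            exons = []
            pos = start
            for i, ln in enumerate(lens):
                exons.append((pos, pos + ln - 1))
                pos = exons[-1][1] + 1
                if i < len(lens) - 1:
                    pos += introns[i]
            strand = ("+" if rng.integers(0, 2) == 0 else "-") if strand_known else "."
            tid = next_id()
            add(
                TranscriptModel(id=tid, gene_id=tid, chrom=chrom, strand=strand, exons=exons),
                role, "u", "lincRNA" if role == "lincrna" else "candidate",
            )

    place_intergenic("lincrna", cfg.n_lincrna)

    # host-gene-based candidates
    host_perm = rng.permutation(len(genes))
    hosts = iter(host_perm)

    def antisense_like(role: str, n: int, opposite: bool) -> None:
        for k in range(n):
            gene = genes[next(hosts)]
            gs, ge = gene.span
            L = int(rng.integers(300, 701))
            if opposite and k % 2 == 1:
                # edge-extended: starts upstream of the gene, fraction < 1,
                # but still reaches into the first exon
                ext = int(rng.integers(100, min(401, L - 150)))
                s = max(1, gs - ext)
                e = min(ge, s + L - 1)
            else:
                target = gene.transcripts[0].exons[min(1, gene.transcripts[0].n_exons - 1)]
                s = max(gs, target[0] - int(rng.integers(20, 101)))
                e = s + L - 1
                if e > ge:
                    e = ge
                    s = max(gs, e - L + 1)
            strand = gene.strand
            if opposite:
                strand = "-" if strand == "+" else "+"
            tid = next_id()
            add(
                TranscriptModel(id=tid, gene_id=tid, chrom=gene.chrom, strand=strand,
                                exons=[(s, e)]),
                role, "x" if opposite else "other",
                "lncNAT" if opposite else "rejected",
            )

    antisense_like("lncnat", cfg.n_lncnat, opposite=True)

    for k in range(cfg.n_intronic):
        gene = None
        intron = None
        while intron is None:
            try:
                gene = genes[next(hosts)]
            except StopIteration:
                raise DataError("no host gene with a long enough intron left") from None
            for iv in gene.transcripts[0].introns:
                if iv[1] - iv[0] + 1 >= 900:
                    intron = iv
                    break
        ilen = intron[1] - intron[0] + 1
        L = int(rng.integers(250, min(601, ilen - 120)))
        s = intron[0] + int(rng.integers(50, ilen - L - 50))
        antisense = k % 2 == 1
        strand = gene.strand
        if antisense:
            strand = "-" if strand == "+" else "+"
        tid = next_id()
        add(
            TranscriptModel(id=tid, gene_id=tid, chrom=gene.chrom, strand=strand,
                            exons=[(s, s + L - 1)]),
            "intronic", "i", "lncNAT" if antisense else "lincRNA",
        )

    antisense_like("fail_class", cfg.n_fail_class, opposite=False)

    def short_plan(rng, k):
        return [200 if k == 0 else int(rng.integers(120, 200))]

    place_intergenic("fail_short", cfg.n_fail_short, exon_plan=short_plan)
    place_intergenic("fail_cpc", cfg.n_fail_cpc)
    place_intergenic("fail_pfam", cfg.n_fail_pfam)
    place_intergenic("fail_unstranded", cfg.n_fail_unstranded, strand_known=False)

    def lowexpr_plan(rng, k):
        # alternate multi/single exon so both FPKM bars get exercised
        return _make_candidate_exons(rng, 2 if k % 2 == 0 else 1)

    place_intergenic("fail_lowexpr", cfg.n_fail_lowexpr, exon_plan=lowexpr_plan)

    # coding-potential scores consistent with the planted roles
    rows = []
    for tx in candidates:
        role = truth[tx.id]["role"]
        if role == "fail_cpc":
            cpc = 0.0 if roles["fail_cpc"][0] == tx.id else float(rng.uniform(0.0, 3.0))
        else:
            cpc = float(rng.uniform(-5.0, -0.5))
        pfam = 1 if role == "fail_pfam" else 0
        rows.append({"id": tx.id, "cpc_score": round(cpc, 4), "pfam_hit": pfam})
    scores = pd.DataFrame(rows)

    ref = GenomeAnnotation(chromosomes, genes)
    return AnnotationSim(ref=ref, candidates=candidates, scores=scores,
                         truth=truth, roles=roles)


# ---------------------------------------------------------------------------
# diel expression
# ---------------------------------------------------------------------------

_ACCEPT_ROLES = ("lincrna", "lncnat", "intronic")


def _lnc_accepted_ids(ann: AnnotationSim) -> list[str]:
    return [tid for role in _ACCEPT_ROLES for tid in ann.roles.get(role, [])]


def _assign_cycling_roles(cfg: SimulationConfig, ann: AnnotationSim, rng):
    """Assign diel roles to intended-accepted lncRNAs with unique (shape, phase)."""
    lnc_ids = _lnc_accepted_ids(ann)
    need = (cfg.n_cycling_both + cfg.n_cycling_green + cfg.n_cycling_white
            + cfg.n_flat + cfg.n_low_amplitude + cfg.n_low_fold)
    if need > len(lnc_ids):
        raise DataError(f"diel roles need {need} lncRNAs, only {len(lnc_ids)} planted")
    order = [lnc_ids[i] for i in rng.permutation(len(lnc_ids))]
    roles = {}
    combos = [(s, p) for s in PLANT_SHAPES for p in np.arange(0.0, 24.0, 2.0)]
    combo_idx = rng.permutation(len(combos))
    ci = 0

    def take_combo():
        nonlocal ci
        c = combos[combo_idx[ci % len(combos)]]
        ci += 1
        return c

    pos = 0
    for role, n in (
        ("cycling_both", cfg.n_cycling_both),
        ("cycling_green", cfg.n_cycling_green),
        ("cycling_white", cfg.n_cycling_white),
        ("flat", cfg.n_flat),
        ("low_amplitude", cfg.n_low_amplitude),
        ("low_fold", cfg.n_low_fold),
    ):
        for _ in range(n):
            tid = order[pos]
            pos += 1
            roles[tid] = {
                "role": role,
                "combo": take_combo() if role not in ("flat",) else None,
            }
    for tid in order[pos:]:
        roles[tid] = {"role": "steady", "combo": None}
    return roles


def _design_profiles(cfg: SimulationConfig, ann: AnnotationSim, rng):
    """Noiseless condition-level diel profiles for every transcript, both tissues.

    Returns (profiles, diel_roles, partners): profiles maps id ->
    {"green": vec, "white": vec}; partners lists (lnc, mrna, sign).
    """
    grid = np.asarray(cfg.diel_grid, dtype=float)
    lo_b, hi_b = cfg.baseline_range
    lo_a, hi_a = cfg.amplitude_range

    diel_roles = _assign_cycling_roles(cfg, ann, rng)
    n_exons_of = {tx.id: tx.n_exons for tx in ann.candidates}
    profiles: dict[str, dict[str, np.ndarray]] = {}

    def steady(lo=3.0, hi=40.0):
        # one baseline for both tissues: keeps concatenated 26-condition
        # profiles uncorrelated instead of block-structured
        b = float(rng.uniform(lo, hi))
        return (b * (1.0 + rng.uniform(-0.1, 0.1, size=grid.size)),
                b * (1.0 + rng.uniform(-0.1, 0.1, size=grid.size)))

    def waveform(combo, baseline, amplitude):
        shape, phase = combo
        return baseline + amplitude * _norm_model(shape, grid, phase)

    cycler_specs = {}
    for tid, info in diel_roles.items():
        role = info["role"]
        if role == "steady":
            g, w = steady()
            profiles[tid] = {"green": g, "white": w}
        elif role == "flat":
            b = float(rng.uniform(lo_b, hi_b + 20))
            profiles[tid] = {"green": np.full(grid.size, b),
                             "white": np.full(grid.size, b)}
        else:
            b = float(rng.uniform(lo_b, hi_b))
            if role == "low_amplitude":
                amp = cfg.low_amplitude
            elif role == "low_fold":
                b, amp = cfg.low_fold_baseline, cfg.low_fold_amplitude
            else:
                amp = float(rng.uniform(lo_a, hi_a))
            wav = waveform(info["combo"], b, amp)
            flatv = np.full(grid.size, float(rng.uniform(3.0, 20.0)))
            if role in ("cycling_both", "low_amplitude", "low_fold"):
                green, white = wav, wav.copy()
            elif role == "cycling_green":
                green, white = wav, flatv
            else:
                green, white = flatv, wav
            profiles[tid] = {"green": green, "white": white}
            cycler_specs[tid] = info

    # candidate plants that are not intended-accepted lncRNAs
    for role, ids in ann.roles.items():
        if role in _ACCEPT_ROLES:
            continue
        for i, tid in enumerate(ids):
            if role == "fail_lowexpr":
                if n_exons_of[tid] >= 2:  # multi-exon variant: below the 0.5 bar
                    g = rng.uniform(0.02, 0.3, size=grid.size)
                    w = rng.uniform(0.02, 0.3, size=grid.size)
                else:  # single-exon variant: above 0.5 but below the 2.0 bar
                    g = rng.uniform(0.6, 1.4, size=grid.size)
                    w = rng.uniform(0.6, 1.4, size=grid.size)
                profiles[tid] = {"green": g, "white": w}
            else:
                g, w = steady()
                profiles[tid] = {"green": g, "white": w}

    # coding genes: co-expression partners of cycling lncRNAs, rest steady
    coding_ids = [g.id for g in ann.ref.genes]
    pool = [coding_ids[i] for i in rng.permutation(len(coding_ids))]
    partners: list[tuple[str, str, str]] = []
    pi = 0
    for j, (tid, info) in enumerate(sorted(cycler_specs.items())):
        if info["role"] not in ("cycling_both", "cycling_green", "cycling_white"):
            continue
        if pi >= len(pool):
            break
        mid = pool[pi]
        pi += 1
        alpha = float(rng.uniform(0.7, 2.0))
        beta = float(rng.uniform(0.0, 5.0))
        profiles[mid] = {
            "green": alpha * profiles[tid]["green"] + beta,
            "white": alpha * profiles[tid]["white"] + beta,
        }
        partners.append((tid, mid, "positive"))
        if cfg.negative_partner_every and j % cfg.negative_partner_every == 0 and pi < len(pool):
            nid = pool[pi]
            pi += 1
            gamma = float(rng.uniform(0.7, 1.5))
            top = max(profiles[tid]["green"].max(), profiles[tid]["white"].max())
            delta = float(rng.uniform(1.0, 3.0))
            profiles[nid] = {
                "green": gamma * (top - profiles[tid]["green"]) + delta,
                "white": gamma * (top - profiles[tid]["white"]) + delta,
            }
            partners.append((tid, nid, "negative"))
    for mid in pool[pi:]:
        g, w = steady(5.0, 40.0)
        profiles[mid] = {"green": g, "white": w}

    return profiles, diel_roles, partners


def _emit_diel_matrix(cfg, profiles, tissue_key, tissue_label, ids, rng) -> ExpressionMatrix:
    grid = np.asarray(cfg.diel_grid, dtype=float)
    n_cols = grid.size * cfg.n_replicates
    design = np.vstack([profiles[t][tissue_key] for t in ids])
    values = np.repeat(design, cfg.n_replicates, axis=1)
    if cfg.noise_sd > 0:
        values = values + rng.normal(0.0, cfg.noise_sd, size=values.shape)
    values = np.clip(values, 0.0, None)
    cols, meta = [], []
    for t in grid:
        for rep in range(1, cfg.n_replicates + 1):
            name = f"{tissue_label}_t{t:g}_r{rep}"
            cols.append(name)
            meta.append({"sample": name, "tissue": tissue_label,
                         "time_hour": float(t), "replicate": rep})
    vdf = pd.DataFrame(values, index=ids, columns=cols)
    sdf = pd.DataFrame(meta).set_index("sample")
    sdf["replicate"] = sdf["replicate"].astype("Int64")
    assert vdf.shape[1] == n_cols
    return ExpressionMatrix(vdf, sdf)


def simulate_diel_expression(
    cfg: SimulationConfig, ann: AnnotationSim | None = None
):
    """Green-tip and white-base diel matrices plus realized cycling truth.

    Truth per transcript per tissue: best-model correlation, amplitude and
    fold change recomputed from the emitted replicate-averaged values; a
    transcript is truly cycling when r > 0.7, amplitude > 10 and fold
    change > 2 hold on those realized numbers.
    """
    ann = ann or simulate_annotation(cfg)
    rng = _rng(cfg, 3)
    profiles, diel_roles, partners = _design_profiles(cfg, ann, rng)
    ids = [t.id for t in ann.candidates] + [g.id for g in ann.ref.genes]
    green = _emit_diel_matrix(cfg, profiles, "green", "green_tip", ids, rng)
    white = _emit_diel_matrix(cfg, profiles, "white", "white_base", ids, rng)

    grid = np.asarray(cfg.diel_grid, dtype=float)
    lib_models = []
    for shape in MODEL_SHAPES:
        for phase in np.arange(0.0, 24.0, 2.0):
            v = _shape_values(shape, grid, float(phase))
            if v.std() > 0:
                lib_models.append(v)
    M = np.vstack(lib_models)
    Mz = (M - M.mean(axis=1, keepdims=True)) / M.std(axis=1, keepdims=True)

    def realized(m: ExpressionMatrix) -> dict[str, dict]:
        collapsed = collapse_replicates(m)
        out = {}
        for tid, row in collapsed.values.iterrows():
            x = row.to_numpy(dtype=float)
            amp = float(x.max() - x.min())
            fc = float((x.max() + 1.0) / (x.min() + 1.0))
            if x.std() == 0:
                r = 0.0
            else:
                xz = (x - x.mean()) / x.std()
                r = float((Mz @ xz / x.size).max())
            out[str(tid)] = {
                "r": r, "amplitude": amp, "fold_change": fc,
                "is_cycling": bool(r > 0.7 and amp > 10.0 and fc > 2.0),
            }
        return out

    truth = {
        "roles": {t: info["role"] for t, info in diel_roles.items()},
        "models": {
            t: {"shape": info["combo"][0], "phase": float(info["combo"][1])}
            for t, info in diel_roles.items() if info["combo"] is not None
        },
        "green_tip": realized(green),
        "white_base": realized(white),
        "partners": partners,
    }
    overlap = {}
    lnc_ids = _lnc_accepted_ids(ann)
    for tid in lnc_ids:
        g = truth["green_tip"][tid]["is_cycling"]
        w = truth["white_base"][tid]["is_cycling"]
        overlap[tid] = "both" if g and w else "green-only" if g else "white-only" if w else "none"
    truth["overlap_class"] = overlap
    return green, white, truth


# ---------------------------------------------------------------------------
# tissue expression
# ---------------------------------------------------------------------------


def simulate_tissue_expression(
    cfg: SimulationConfig, ann: AnnotationSim | None = None
):
    """Four-tissue matrix (fruit split into stages) with planted specific,
    near-uniform and undetected rows; truth tau is the realized value
    recomputed from the emitted numbers after fruit-stage averaging."""
    ann = ann or simulate_annotation(cfg)
    rng = _rng(cfg, 2)
    tissues = list(cfg.tissues)
    n_t = len(tissues)
    lnc_ids = _lnc_accepted_ids(ann)
    coding_ids = [g.id for g in ann.ref.genes]

    def assign(ids, n_specific_per_tissue, n_undetected):
        order = [ids[i] for i in rng.permutation(len(ids))]
        plan = {}
        pos = 0
        for tissue in tissues:
            for _ in range(n_specific_per_tissue):
                if pos < len(order):
                    plan[order[pos]] = ("specific", tissue)
                    pos += 1
        for _ in range(n_undetected):
            if pos < len(order):
                plan[order[pos]] = ("undetected", None)
                pos += 1
        for tid in order[pos:]:
            plan[tid] = ("uniform", None)
        return plan

    plan = assign(lnc_ids, cfg.n_specific_lnc_per_tissue, cfg.n_undetected_lnc)
    plan.update(assign(coding_ids, cfg.n_specific_mrna_per_tissue, 2))

    ids = lnc_ids + coding_ids
    base = np.zeros((len(ids), n_t))
    for i, tid in enumerate(ids):
        kind, tissue = plan[tid]
        if kind == "specific":
            dom = float(rng.uniform(20.0, 80.0))
            row = dom * rng.uniform(0.0, 0.05, size=n_t)
            row[tissues.index(tissue)] = dom
        elif kind == "undetected":
            row = rng.uniform(0.05, 0.9, size=n_t)
        else:
            b = float(rng.uniform(5.0, 15.0))
            row = b * (1.0 + rng.uniform(-0.05, 0.05, size=n_t))
        base[i] = row

    cols, meta = [], []
    values = []
    for j, tissue in enumerate(tissues):
        n_stage = cfg.n_fruit_stages if tissue == "fruit" else 1
        for s in range(1, n_stage + 1):
            name = tissue if n_stage == 1 else f"{tissue}_s{s}"
            cols.append(name)
            meta.append({"sample": name, "tissue": tissue,
                         "time_hour": np.nan, "replicate": pd.NA})
            col = base[:, j] * (1.0 + rng.uniform(-0.05, 0.05, size=len(ids)))
            values.append(col)
    values = np.vstack(values).T
    if cfg.noise_sd > 0:
        values = values + rng.normal(0.0, cfg.noise_sd * 0.2, size=values.shape)
    values = np.clip(values, 0.0, None)
    vdf = pd.DataFrame(values, index=ids, columns=cols)
    sdf = pd.DataFrame(meta).set_index("sample")
    sdf["replicate"] = sdf["replicate"].astype("Int64")
    m = ExpressionMatrix(vdf, sdf)

    averaged = average_by_tissue(m)
    truth = {}
    for tid, row in averaged.values.iterrows():
        x = row.to_numpy(dtype=float)
        kind, tissue = plan[str(tid)]
        if x.max() < 1.0:
            truth[str(tid)] = {"discarded": True, "tau": None,
                               "specific_tissue": None, "planted": kind}
            continue
        t = tau_index(x)
        top = x.max()
        winners = [averaged.values.columns[i] for i in range(x.size) if x[i] == top]
        truth[str(tid)] = {
            "discarded": False,
            "tau": t,
            "is_specific": bool(t > 0.8),
            "specific_tissue": winners[0] if len(winners) == 1 and t > 0.8 else None,
            "planted": kind,
        }
    return m, truth


# ---------------------------------------------------------------------------
# miRNA bindings
# ---------------------------------------------------------------------------


def simulate_bindings(cfg: SimulationConfig, ann: AnnotationSim | None = None):
    """Binding table with planted ceRNA triangles and non-sharing background.

    Each triangle: a focal coding transcript perfectly bound by m miRNAs;
    k decoy lncRNAs mimic-bound so the decoys jointly cover all m miRNAs.
    Additional planted target-target pairs share one perfect-mode miRNA
    between a coding transcript and a lncRNA.  Background miRNAs bind a
    single transcript each, creating no pairs.
    """
    ann = ann or simulate_annotation(cfg)
    rng = _rng(cfg, 4)
    lnc_ids = _lnc_accepted_ids(ann)
    coding_ids = [g.id for g in ann.ref.genes]
    lnc_pool = [lnc_ids[i] for i in rng.permutation(len(lnc_ids))]
    coding_pool = [coding_ids[i] for i in rng.permutation(len(coding_ids))]

    records = []
    mirna_n = [0]

    def new_mirna() -> str:
        mirna_n[0] += 1
        return f"miR{mirna_n[0]:04d}"

    truth_pairs = []
    focal_info = {}
    li = ci = 0
    for m, k in cfg.triangles:
        if li + k > len(lnc_pool) or ci >= len(coding_pool):
            raise DataError("not enough transcripts for the requested ceRNA triangles")
        focal = coding_pool[ci]
        ci += 1
        mirnas = [new_mirna() for _ in range(m)]
        for mi in mirnas:
            records.append((mi, focal, "perfect"))
        decoys = lnc_pool[li:li + k]
        li += k
        for j, decoy in enumerate(decoys):
            mi = mirnas[j % m]
            records.append((mi, decoy, "mimic"))
            truth_pairs.append(
                {"a": min(focal, decoy), "b": max(focal, decoy),
                 "pair_type": "target-mimic", "shared_mirnas": [mi]}
            )
        focal_info[focal] = {"decoys": sorted(decoys), "mirnas": sorted(mirnas)}

    for _ in range(cfg.n_target_target):
        if li >= len(lnc_pool) or ci >= len(coding_pool):
            break
        mi = new_mirna()
        a, b = coding_pool[ci], lnc_pool[li]
        ci += 1
        li += 1
        records.append((mi, a, "perfect"))
        records.append((mi, b, "perfect"))
        truth_pairs.append(
            {"a": min(a, b), "b": max(a, b),
             "pair_type": "target-target", "shared_mirnas": [mi]}
        )

    bound = {r[1] for r in records}
    spare = [t for t in lnc_pool[li:] + coding_pool[ci:] if t not in bound]
    for i in range(min(cfg.n_background_bindings, len(spare))):
        records.append((new_mirna(), spare[i], "perfect" if i % 2 == 0 else "mimic"))

    df = pd.DataFrame(records, columns=["mirna", "transcript", "mode"])
    table = BindingTable(df)
    # merge truth pairs sharing the same unordered transcript pair
    merged: dict[tuple, dict] = {}
    for p in truth_pairs:
        key = (p["a"], p["b"])
        if key not in merged:
            merged[key] = {"a": p["a"], "b": p["b"], "pair_type": p["pair_type"],
                           "shared_mirnas": set(p["shared_mirnas"])}
        else:
            merged[key]["shared_mirnas"] |= set(p["shared_mirnas"])
            if p["pair_type"] == "target-target":
                merged[key]["pair_type"] = "target-target"
    pairs = [
        {"a": v["a"], "b": v["b"], "pair_type": v["pair_type"],
         "shared_mirnas": sorted(v["shared_mirnas"])}
        for v in sorted(merged.values(), key=lambda v: (v["a"], v["b"]))
    ]
    truth = {"pairs": pairs, "focal": focal_info}
    return table, truth


# ---------------------------------------------------------------------------
# full cohort
# ---------------------------------------------------------------------------


def _realized_filter_fates(cfg, ann: AnnotationSim, green, white) -> dict[str, str]:
    """Apply the five written criteria directly to the emitted data."""
    merged = concat_samples(green, white)
    collapsed = collapse_replicates(merged)
    row_max = collapsed.values.max(axis=1)
    stab = ann.scores.set_index("id")
    fates = {}
    for tx in ann.candidates:
        code = ann.truth[tx.id]["class_code"]
        if code not in ("u", "x", "i"):
            fates[tx.id] = "rejected:class_code"
        elif not tx.length > 200:
            fates[tx.id] = "rejected:length"
        elif not float(stab.loc[tx.id, "cpc_score"]) < 0:
            fates[tx.id] = "rejected:cpc"
        elif int(stab.loc[tx.id, "pfam_hit"]):
            fates[tx.id] = "rejected:pfam"
        elif tx.strand == ".":
            fates[tx.id] = "low_confidence:strand"
        elif float(row_max[tx.id]) < (0.5 if tx.n_exons >= 2 else 2.0):
            fates[tx.id] = "low_confidence:expression"
        else:
            fates[tx.id] = "accepted"
    return fates


def _realized_coexpression(green, white, lnc_ids, coding_ids) -> list[list]:
    merged = collapse_replicates(concat_samples(green, white))
    lv = merged.values.loc[[t for t in lnc_ids if t in merged.values.index]]
    mv = merged.values.loc[[t for t in coding_ids if t in merged.values.index]]
    edges = []
    mvv = mv.to_numpy(dtype=float)
    for lid, row in lv.iterrows():
        x = row.to_numpy(dtype=float)
        if x.std() == 0:
            continue
        for mid, y in zip(mv.index, mvv):
            if y.std() == 0:
                continue
            r = float(np.corrcoef(x, y)[0, 1])
            if abs(r) > 0.95:
                edges.append([str(lid), str(mid), "positive" if r > 0 else "negative"])
    return edges


def simulate_all(cfg: SimulationConfig, out_dir: str) -> dict:
    """Generate the full synthetic cohort, write every input file plus
    ``truth.json``, and return the truth manifest."""
    import os

    os.makedirs(out_dir, exist_ok=True)
    ann = simulate_annotation(cfg)
    green, white, diel_truth = simulate_diel_expression(cfg, ann)
    tissue_m, tau_truth = simulate_tissue_expression(cfg, ann)
    bindings, cerna_truth = simulate_bindings(cfg, ann)
    fates = _realized_filter_fates(cfg, ann, green, white)
    accepted_lnc = [tx.id for tx in ann.candidates if fates[tx.id] == "accepted"]
    coding_ids = [g.id for g in ann.ref.genes]
    coexpr_edges = _realized_coexpression(green, white, accepted_lnc, coding_ids)

    write_gtf(ann.ref.transcripts, os.path.join(out_dir, "ref.gtf"))
    write_gtf(ann.candidates, os.path.join(out_dir, "candidates.gtf"))
    write_tsv(ann.scores, os.path.join(out_dir, "scores.tsv"))
    write_expression(green, os.path.join(out_dir, "diel_green.tsv"),
                     os.path.join(out_dir, "diel_green.samples.tsv"))
    write_expression(white, os.path.join(out_dir, "diel_white.tsv"),
                     os.path.join(out_dir, "diel_white.samples.tsv"))
    write_expression(tissue_m, os.path.join(out_dir, "tissues.tsv"),
                     os.path.join(out_dir, "tissues.samples.tsv"))
    write_bindings(bindings, os.path.join(out_dir, "bindings.tsv"))

    manifest = {
        "config": asdict(cfg),
        "transcripts": {
            tx.id: {**ann.truth[tx.id], "filter_fate": fates[tx.id],
                    "length": tx.length, "n_exons": tx.n_exons, "strand": tx.strand}
            for tx in ann.candidates
        },
        "accepted_lncrnas": accepted_lnc,
        "coding_genes": coding_ids,
        "tau": tau_truth,
        "cycling": diel_truth,
        "coexpression_edges": coexpr_edges,
        "cerna": cerna_truth,
    }
    with open(os.path.join(out_dir, "truth.json"), "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
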