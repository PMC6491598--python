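"""Diel (24-h) cycling detection by correlation to model waveforms.

Each diel expression profile is correlated against a library of
phase-shifted model shapes (cosine, spike, box, sawtooth) evaluated on
the actual sampling grid.  A transcript is called cycling when the best
model correlation r strictly exceeds 0.7 AND peak-to-trough fold change
exceeds 2 AND amplitude (max - min, FPKM) exceeds 10 AND a permutation
p-value (time labels shuffled, best-model r recomputed) falls below 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_model import DataError, ExpressionMatrix, collapse_replicates

MODEL_SHAPES = ("cosine", "spike", "box", "sawtooth")
PERIOD_HOURS = 24.0


@dataclass
class CyclingModelLibrary:
    """Model waveforms evaluated on one sampling grid.

    ``models`` maps "<shape>@<phase>h" to the value vector over
    ``time_grid``; constant vectors are dropped at construction.
    """

    time_grid: np.ndarray
    models: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def names(self) -> list[str]:
        return list(self.models)

    def matrix(self) -> np.ndarray:
        return np.vstack([self.models[n] for n in self.names])


def _shape_values(shape: str, t: np.ndarray, phase: float) -> np.ndarray:
    rel = np.mod(t - phase, PERIOD_HOURS)
    if shape == "cosine":
        return np.cos(2 * np.pi * rel / PERIOD_HOURS)
    if shape == "spike":
        circ = np.minimum(rel, PERIOD_HOURS - rel)  # circular distance to phase
        out = np.zeros_like(t, dtype=float)
        out[np.argmin(circ)] = 1.0
        return out
    if shape == "box":
        return (rel < PERIOD_HOURS / 2).astype(float)
    if shape == "sawtooth":
        return 1.0 - rel / PERIOD_HOURS
    raise DataError(f"unknown model shape {shape}")


def build_model_library(time_grid, phase_step_hours: float = 2.0) -> CyclingModelLibrary:
    """Model vectors for every shape and phase offset in [0, 24) at the
    given step, evaluated at the (possibly uneven) grid hours."""
    t = np.asarray(time_grid, dtype=float)
    if t.size < 6:
        raise DataError("time grid must have >= 6 points within one 24-h period")
    lib = CyclingModelLibrary(time_grid=t)
    phases = np.arange(0.0, PERIOD_HOURS, phase_step_hours)
    for shape in MODEL_SHAPES:
        for phase in phases:
            v = _shape_values(shape, t, float(phase))
            if v.std() == 0:
                continue
            lib.models[f"{shape}@{phase:g}h"] = v
    return lib


@dataclass
class CyclingConfig:
    r_threshold: float = 0.7        # strict lower bound on best-model r
    min_fold_change: float = 2.0    # strict; (max+pc)/(min+pc)
    min_amplitude: float = 10.0     # strict; max - min in FPKM
    p_threshold: float = 0.05
    n_permutations: int = 1000
    seed: int = 0
    pseudocount: float = 1.0

    def __post_init__(self) -> None:
        if self.n_permutations < 100:
            raise DataError("need >= 100 permutations for a stable p-value")
        if min(self.r_threshold, self.min_fold_change, self.min_amplitude,
               self.p_threshold, self.pseudocount) <= 0:
            raise DataError("cycling thresholds must be positive")


@dataclass
class CyclingCall:
    transcript_id: str
    tissue: str
    best_model: str | None
    r: float
    fold_change: float
    amplitude: float
    p: float
    is_cycling: bool
    reason: str = ""


def _standardize(x: np.ndarray) -> np.ndarray:
    return (x - x.mean(axis=-1, keepdims=True)) / x.std(axis=-1, keepdims=True)


def score_profile(
    profile,
    lib: CyclingModelLibrary,
    cfg: CyclingConfig | None = None,
    transcript_id: str = "",
    tissue: str = "",
    rng: np.random.Generator | None = None,
) -> CyclingCall:
    """Score one diel profile against the model library.

    p is a permutation p-value: the fraction (with +1/(n+1) continuity
    correction) of seeded time-label shuffles whose best-model correlation
    reaches the observed one.
    """
    cfg = cfg or CyclingConfig()
    x = np.asarray(profile, dtype=float)
    if x.shape != lib.time_grid.shape:
        raise DataError("profile length must match the model library grid")
    if (x < 0).any():
        raise DataError("diel profile has negative FPKM")

    mx, mn = float(x.max()), float(x.min())
    amplitude = mx - mn
    fold_change = (mx + cfg.pseudocount) / (mn + cfg.pseudocount)
    if x.std() == 0:
        return CyclingCall(transcript_id, tissue, None, float("nan"),
                           fold_change, amplitude, 1.0, False, "zero variance")

    models = lib.matrix()
    mz = _standardize(models)
    n = x.size
    xz = _standardize(x)
    rs = mz @ xz / n
    best = int(np.argmax(rs))
    r_obs = float(rs[best])

    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    perms = rng.permuted(np.tile(x, (cfg.n_permutations, 1)), axis=1)
    pz = _standardize(perms)
    perm_best = (pz @ mz.T / n).max(axis=1)
    p = (1 + int((perm_best >= r_obs - 1e-12).sum())) / (cfg.n_permutations + 1)

    is_cycling = (
        r_obs > cfg.r_threshold
        and fold_change > cfg.min_fold_change
        and amplitude > cfg.min_amplitude
        and p < cfg.p_threshold
    )
    return CyclingCall(
        transcript_id=transcript_id,
        tissue=tissue,
        best_model=lib.names[best],
        r=r_obs,
        fold_change=fold_change,
        amplitude=amplitude,
        p=p,
        is_cycling=is_cycling,
    )


def score_matrix(
    m: ExpressionMatrix,
    lib: CyclingModelLibrary | None = None,
    cfg: CyclingConfig | None = None,
    tissue: str = "",
) -> list[CyclingCall]:
    """Score every transcript of a diel matrix (replicates collapsed, columns
    ordered to match the sample-sheet time grid)."""
    cfg = cfg or CyclingConfig()
    if m.samples["replicate"].notna().any():
        m = collapse_replicates(m)
    if not m.has_time:
        raise DataError("diel scoring needs time_hour for every sample")
    hours = m.samples["time_hour"].to_numpy(dtype=float)
    if lib is None:
        lib = build_model_library(hours)
    elif not np.array_equal(lib.time_grid, hours):
        raise DataError("model library grid does not match the matrix time grid")
    if not tissue:
        tissues = set(m.samples["tissue"])
        tissue = tissues.pop() if len(tissues) == 1 else "mixed"
    calls = []
    for idx, (tid, row) in enumerate(m.values.iterrows()):
        rng = np.random.default_rng([cfg.seed, idx])
        calls.append(
            score_profile(row.to_numpy(dtype=float), lib, cfg,
                          transcript_id=str(tid), tissue=tissue, rng=rng)
        )
    return calls


def calls_table(calls: list[CyclingCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "transcript_id": c.transcript_id,
                "tissue": c.tissue,
                "best_model": c.best_model if c.best_model is not None else "",
                "r": c.r,
                "fold_change": c.fold_change,
                "amplitude": c.amplitude,
                "p": c.p,
                "is_cycling": c.is_cycling,
            }
            for c in calls
        ]
    )


def classify_overlap(
    green_calls: list[CyclingCall], white_calls: list[CyclingCall]
) -> dict[str, str]:
    """Two-tissue overlap classes: both / green-only / white-only / none.

    Both call lists must cover the same transcript universe; the four
    classes partition it.
    """
    green = {c.transcript_id: c.is_cycling for c in green_calls}
    white = {c.transcript_id: c.is_cycling for c in white_calls}
    if set(green) != set(white):
        raise DataError("green and white call sets cover different transcripts")
    out = {}
    for tid in green:
        g, w = green[tid], white[tid]
        if g and w:
            out[tid] = "both"
        elif g:
            out[tid] = "green-only"
        elif w:
            out[tid] = "white-only"
        else:
            out[tid] = "none"
    return out
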