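"""Seeded synthetic single-lead ECG and glucose timelines with
glycemic-state-modulated beat morphology.

Each heartbeat is a sum of five Gaussian bumps (P, Q, R, S, T) on an
isoelectric baseline — the classic parametric ECG morphology model. The
generator is *calibrated in feature space*: per-state targets for the
primitive intervals (R-R, P-Q, Q-R, R-S, S-T, in seconds) and for five
pairwise peak-amplitude differences (P-Q, Q-R, R-S, Q-S, S-T, in mV) are
mapped to wave centers and peak heights, so the designed fiducial
geometry reproduces the target feature means exactly (intervals) or in
the least-squares sense (amplitudes, whose pairwise targets are
over-determined: the five differences constrain only four degrees of
freedom and published per-state values need not be mutually consistent).

Dysglycemic morphology is the euglycemic target set plus per-feature
additive shifts scaled by ``effect_scale``; ``effect_scale = 0`` yields a
null cohort in which both states share one distribution. Within-subject
beat-to-beat variability is Gaussian jitter applied to the primitive
targets with SD = ``jitter_scale`` x |between-state shift| (a small floor
keeps uninformative primitives from degenerating); composite features
inherit their variability through the beat geometry.

All randomness flows from explicit seeds; per-subject seeds are derived
from the cohort master seed by fixed integer arithmetic.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .errors import CalibrationError, GenerationError
from .fiducials import FEATURE_NAMES, FEATURE_PAIRS, SLOPE_PAIRS, WAVES
from .signal_io import BGRecord, ECGRecord, GlycemicLabel, label_bg

EUGLYCEMIA = "euglycemia"
DYSGLYCEMIA = "dysglycemia"

#: per-state means of the primitive interval features (seconds) in an ICU
#: lead-II cohort: euglycemic vs dysglycemic state
STATE_INTERVALS = {
    EUGLYCEMIA: {"RR": 0.74, "PQ": 0.13, "QR": 0.08, "RS": 0.04, "ST": 0.25},
    DYSGLYCEMIA: {"RR": 0.66, "PQ": 0.16, "QR": 0.07, "RS": 0.05, "ST": 0.32},
}
#: per-state means of the five published pairwise amplitude features (mV)
STATE_AMPLITUDES = {
    EUGLYCEMIA: {"PQ": 0.13, "QR": 0.68, "RS": 0.75, "QS": 0.07, "ST": 0.64},
    DYSGLYCEMIA: {"PQ": 0.15, "QR": 0.56, "RS": 0.71, "QS": 0.05, "ST": 0.58},
}

INTERVAL_SHIFTS = {
    k: STATE_INTERVALS[DYSGLYCEMIA][k] - STATE_INTERVALS[EUGLYCEMIA][k]
    for k in STATE_INTERVALS[EUGLYCEMIA]
}
AMPLITUDE_SHIFTS = {
    k: STATE_AMPLITUDES[DYSGLYCEMIA][k] - STATE_AMPLITUDES[EUGLYCEMIA][k]
    for k in STATE_AMPLITUDES[EUGLYCEMIA]
}

#: fixed Gaussian widths (s); narrow QRS waves, broad P and T
DEFAULT_WIDTHS = {"P": 0.025, "Q": 0.010, "R": 0.010, "S": 0.010, "T": 0.050}
#: P-wave peak height anchor (mV) — pairwise amplitude targets fix only
#: differences between peaks, so one peak must be pinned
DEFAULT_P_ANCHOR_MV = 0.08

DEFAULT_JITTER_SCALE = 0.2
_JITTER_FLOOR_S = 0.004       # interval jitter floor (s)
_JITTER_FLOOR_MV = 0.004      # amplitude jitter floor (mV)
_MIN_INTERVAL_S = 0.012       # >= 1.5 samples at 125 Hz
_MIN_RR_S = 0.32              # just above the detector refractory
_MAX_T_OFFSET_S = 0.55        # keep the T peak inside the beat window
_CONSISTENCY_TOL_S = 0.005

# amplitude design system: unknowns (Q, R, S, T) with P anchored;
# rows: P-Q, R-Q, R-S, Q-S, T-S  (signed conventions of upright lead II)
_AMP_DESIGN = np.array(
    [
        [-1.0, 0.0, 0.0, 0.0],
        [-1.0, 1.0, 0.0, 0.0],
        [0.0, 1.0, -1.0, 0.0],
        [1.0, 0.0, -1.0, 0.0],
        [0.0, 0.0, -1.0, 1.0],
    ]
)
_AMP_PINV = np.linalg.pinv(_AMP_DESIGN)
_AMP_KEYS = ("PQ", "QR", "RS", "QS", "ST")


@dataclass(frozen=True)
class WaveParams:
    """Gaussian morphology of one beat state.

    ``centers_s`` are signed offsets relative to the R peak (P and Q
    negative), ``amplitudes_mv`` signed peak heights, ``widths_s`` the
    Gaussian standard deviations.
    """

    centers_s: dict
    amplitudes_mv: dict
    widths_s: dict
    heart_period_s: float
    baseline_wander_mv: float = 0.0
    noise_sd_mv: float = 0.01

    def __post_init__(self) -> None:
        c = self.centers_s
        if not (c["P"] < c["Q"] < c["R"] == 0.0 < c["S"] < c["T"]):
            raise CalibrationError(
                f"wave centers must be ordered P < Q < R(=0) < S < T, got {c}"
            )
        if any(w <= 0 for w in self.widths_s.values()):
            raise CalibrationError("wave widths must be positive")
        if not 0.3 <= self.heart_period_s <= 2.0:
            raise CalibrationError(
                f"heart period {self.heart_period_s} s outside [0.3, 2.0]"
            )

    def designed_fiducials(self, cfg: PipelineConfig | None = None) -> dict:
        """Designed sample indices (within a beat window, R pinned at
        ``pre_r_samples``) and the noise-free trace amplitudes there —
        the ground truth for delineation round-trip tests."""
        cfg = cfg or PipelineConfig()
        fs = cfg.sampling_rate_hz
        idx = {w: cfg.pre_r_samples + round(self.centers_s[w] * fs)
               for w in WAVES}
        t = (np.array([idx[w] for w in WAVES]) - cfg.pre_r_samples) / fs
        amps = gaussian_beat(self, t)
        return {"index": idx, "amplitude_mv": dict(zip(WAVES, amps))}


@dataclass(frozen=True)
class GlycemicEffect:
    """Additive per-feature shifts of the dysglycemic state means,
    multiplied by a global ``effect_scale`` (0 = null cohort)."""

    interval_shifts_s: dict = field(
        default_factory=lambda: dict(INTERVAL_SHIFTS))
    amplitude_shifts_mv: dict = field(
        default_factory=lambda: dict(AMPLITUDE_SHIFTS))
    effect_scale: float = 1.0


@dataclass(frozen=True)
class JitterSpec:
    """Per-primitive beat-to-beat jitter SDs (feature units)."""

    interval_sd_s: dict
    amplitude_sd_mv: dict

    @classmethod
    def from_scale(cls, jitter_scale: float = DEFAULT_JITTER_SCALE) -> "JitterSpec":
        """SD = jitter_scale x |between-state shift| per primitive, with a
        small floor; shift magnitudes come from the reference state table
        regardless of ``effect_scale`` so a null cohort keeps realistic
        variability."""
        return cls(
            interval_sd_s={
                k: max(jitter_scale * abs(v), _JITTER_FLOOR_S)
                for k, v in INTERVAL_SHIFTS.items()
            },
            amplitude_sd_mv={
                k: max(jitter_scale * abs(v), _JITTER_FLOOR_MV)
                for k, v in AMPLITUDE_SHIFTS.items()
            },
        )


@dataclass
class SyntheticSubject:
    """One simulated subject: glucose timeline, continuous ECG record and
    the per-beat designed ground truth."""

    subject_id: str
    base_targets: dict
    state_params: dict
    bg: list
    record: ECGRecord
    truth: pd.DataFrame
    seed: int
    af_or_pacemaker: bool = False


# ---------------------------------------------------------------------------
# morphology calibration
# ---------------------------------------------------------------------------

def gaussian_beat(params: WaveParams, t_grid: np.ndarray) -> np.ndarray:
    """Noise-free beat trace on ``t_grid`` (seconds relative to R)."""
    t = np.asarray(t_grid, dtype=float)
    out = np.zeros_like(t)
    for w in WAVES:
        width = params.widths_s[w]
        if width <= 0:
            raise CalibrationError(f"non-positive width for wave {w}")
        out += params.amplitudes_mv[w] * np.exp(
            -((t - params.centers_s[w]) ** 2) / (2.0 * width * width)
        )
    return out


def solve_wave_amplitudes(targets: dict, anchor_p_mv: float = DEFAULT_P_ANCHOR_MV) -> dict:
    """Peak heights from pairwise amplitude targets, least squares with
    the P peak anchored."""
    b = np.array([targets[k] for k in _AMP_KEYS], dtype=float)
    b[0] -= anchor_p_mv
    q, r, s, t = _AMP_PINV @ b
    return {"P": anchor_p_mv, "Q": q, "R": r, "S": s, "T": t}


def solve_wave_params(
    targets: dict,
    widths_s: dict | None = None,
    anchor_p_mv: float = DEFAULT_P_ANCHOR_MV,
    baseline_wander_mv: float = 0.0,
    noise_sd_mv: float = 0.01,
) -> WaveParams:
    """Map per-state feature-mean targets to Gaussian wave parameters.

    ``targets`` holds ``"intervals"`` (s) with keys RR, PQ, QR, RS, ST
    and optionally PR / QT (checked for additive consistency), and
    ``"amplitudes"`` (mV) with keys PQ, QR, RS, QS, ST. Intervals map
    exactly: Q sits QR before R, P sits PQ before Q, S sits RS after R
    and T sits ST after S.
    """
    iv = dict(targets["intervals"])
    for key in ("RR", "PQ", "QR", "RS", "ST"):
        if key not in iv:
            raise CalibrationError(f"interval target {key} missing")
        if key != "RR" and iv[key] <= 0:
            raise CalibrationError(
                f"interval target {key} = {iv[key]} s violates the wave "
                "ordering (all primitive intervals must be positive)"
            )
    conflicts = []
    if "PR" in iv and abs(iv["PR"] - (iv["PQ"] + iv["QR"])) > _CONSISTENCY_TOL_S:
        conflicts.append(
            f"PR = {iv['PR']} but PQ + QR = {iv['PQ'] + iv['QR']:.4f}")
    if "QT" in iv and abs(
            iv["QT"] - (iv["QR"] + iv["RS"] + iv["ST"])) > _CONSISTENCY_TOL_S:
        conflicts.append(
            f"QT = {iv['QT']} but QR + RS + ST = "
            f"{iv['QR'] + iv['RS'] + iv['ST']:.4f}")
    if conflicts:
        raise CalibrationError(
            "inconsistent interval system: " + "; ".join(conflicts))

    centers = {
        "P": -(iv["PQ"] + iv["QR"]),
        "Q": -iv["QR"],
        "R": 0.0,
        "S": iv["RS"],
        "T": iv["RS"] + iv["ST"],
    }
    return WaveParams(
        centers_s=centers,
        amplitudes_mv=solve_wave_amplitudes(targets["amplitudes"], anchor_p_mv),
        widths_s=dict(widths_s or DEFAULT_WIDTHS),
        heart_period_s=iv["RR"],
        baseline_wander_mv=baseline_wander_mv,
        noise_sd_mv=noise_sd_mv,
    )


def state_targets(
    state: str,
    effect: GlycemicEffect | None = None,
    base_targets: dict | None = None,
) -> dict:
    """Feature-mean targets for one glycemic state: the euglycemic base
    plus (for dysglycemia) the scaled effect shifts."""
    effect = effect or GlycemicEffect()
    base = base_targets or {
        "intervals": dict(STATE_INTERVALS[EUGLYCEMIA]),
        "amplitudes": dict(STATE_AMPLITUDES[EUGLYCEMIA]),
    }
    iv = dict(base["intervals"])
    am = dict(base["amplitudes"])
    if state == DYSGLYCEMIA:
        for k, v in effect.interval_shifts_s.items():
            iv[k] = iv[k] + effect.effect_scale * v
        for k, v in effect.amplitude_shifts_mv.items():
            am[k] = am[k] + effect.effect_scale * v
    elif state != EUGLYCEMIA:
        raise GenerationError(f"unknown glycemic state {state!r}")
    return {"intervals": iv, "amplitudes": am}


# ---------------------------------------------------------------------------
# beat-train rendering
# ---------------------------------------------------------------------------

def _draw_beat_primitives(
    targets: dict, jitter: JitterSpec, n: int, rng: np.random.Generator,
) -> dict:
    iv, am = targets["intervals"], targets["amplitudes"]
    draws = {}
    for k in ("RR", "PQ", "QR", "RS", "ST"):
        draws[k] = rng.normal(iv[k], jitter.interval_sd_s[k], n)
    draws["RR"] = np.clip(draws["RR"], _MIN_RR_S, 2.0)
    for k in ("PQ", "QR", "RS", "ST"):
        draws[k] = np.maximum(draws[k], _MIN_INTERVAL_S)
    # keep the T peak inside the one-second beat window
    over = draws["RS"] + draws["ST"] - _MAX_T_OFFSET_S
    draws["ST"] = np.where(over > 0, draws["ST"] - over, draws["ST"])
    for k in _AMP_KEYS:
        draws["amp_" + k] = np.maximum(
            rng.normal(am[k], jitter.amplitude_sd_mv[k], n), 0.01)
    return draws


def _render_beat_train(
    targets: dict,
    jitter: JitterSpec,
    n_beats: int,
    duration_s: float,
    rng: np.random.Generator,
    cfg: PipelineConfig,
    widths_s: dict,
    anchor_p_mv: float,
    start_offset_s: float = 0.5,
):
    """Render a continuous train of beats into a fresh signal buffer.

    Returns ``(signal, truth)``; ``truth`` holds one row per beat with
    the continuous designed R time, primitive draws and wave peak
    heights. Beats whose windows would cross the buffer edges are not
    emitted.
    """
    fs = float(cfg.sampling_rate_hz)
    n_samples = round(duration_s * fs)
    draws = _draw_beat_primitives(targets, jitter, n_beats, rng)
    r_times = start_offset_s + np.concatenate(
        ([0.0], np.cumsum(draws["RR"][:-1])))
    keep = r_times + 0.65 <= duration_s
    if not np.all(keep):
        n_beats = int(keep.sum())
        draws = {k: v[:n_beats] for k, v in draws.items()}
        r_times = r_times[:n_beats]

    amp_targets = np.column_stack([draws["amp_" + k] for k in _AMP_KEYS])
    b = amp_targets.copy()
    b[:, 0] -= anchor_p_mv
    qrst = b @ _AMP_PINV.T
    amps = {
        "P": np.full(n_beats, anchor_p_mv),
        "Q": qrst[:, 0], "R": qrst[:, 1], "S": qrst[:, 2], "T": qrst[:, 3],
    }
    centers = {
        "P": r_times - draws["PQ"] - draws["QR"],
        "Q": r_times - draws["QR"],
        "R": r_times,
        "S": r_times + draws["RS"],
        "T": r_times + draws["RS"] + draws["ST"],
    }

    sig = np.zeros(n_samples)
    for w in WAVES:
        width = widths_s[w]
        half = int(np.ceil(4.5 * width * fs))
        offs = np.arange(-half, half + 1)
        k0 = np.round(centers[w] * fs).astype(int)
        cols = k0[:, None] + offs[None, :]
        t = cols / fs
        vals = amps[w][:, None] * np.exp(
            -((t - centers[w][:, None]) ** 2) / (2.0 * width * width))
        inb = (cols >= 0) & (cols < n_samples)
        np.add.at(sig, cols[inb], vals[inb])

    truth = pd.DataFrame({
        "r_time_s": r_times,
        **{k: draws[k] for k in ("RR", "PQ", "QR", "RS", "ST")},
        **{"amp_" + w: amps[w] for w in WAVES},
    })
    return sig, truth


def _finalize_signal(
    sig: np.ndarray,
    rng: np.random.Generator,
    noise_sd_mv: float,
    baseline_wander_mv: float,
    fs: float,
    quantize_uv: bool = True,
) -> np.ndarray:
    if baseline_wander_mv > 0:
        t = np.arange(sig.size) / fs
        sig = sig + baseline_wander_mv * np.sin(2 * np.pi * 0.3 * t)
    if noise_sd_mv > 0:
        sig = sig + rng.normal(0.0, noise_sd_mv, sig.size)
    if quantize_uv:
        sig = np.round(sig, 3)  # microvolt amplitude quantization
    return sig


def simulate_state_run(
    state: str,
    n_beats: int,
    seed: int,
    cfg: PipelineConfig | None = None,
    effect: GlycemicEffect | None = None,
    jitter_scale: float = DEFAULT_JITTER_SCALE,
    base_targets: dict | None = None,
    noise_sd_mv: float = 0.01,
    baseline_wander_mv: float = 0.0,
    subject_id: str = "staterun",
):
    """One continuous single-state run of ``n_beats`` beats — the
    workhorse for calibration studies and round-trip tests.

    Returns ``(record, truth)``.
    """
    cfg = cfg or PipelineConfig()
    effect = effect or GlycemicEffect()
    targets = state_targets(state, effect, base_targets)
    jitter = JitterSpec.from_scale(jitter_scale)
    rng = np.random.default_rng(seed)
    duration = n_beats * (targets["intervals"]["RR"] + 0.05) + 2.0
    sig, truth = _render_beat_train(
        targets, jitter, n_beats, duration, rng, cfg,
        DEFAULT_WIDTHS, DEFAULT_P_ANCHOR_MV,
    )
    sig = _finalize_signal(sig, rng, noise_sd_mv, baseline_wander_mv,
                           cfg.sampling_rate_hz, quantize_uv=noise_sd_mv > 0)
    truth["state"] = state
    record = ECGRecord(subject_id=subject_id, samples=sig,
                       sampling_rate_hz=float(cfg.sampling_rate_hz))
    return record, truth


# ---------------------------------------------------------------------------
# subjects and cohorts
# ---------------------------------------------------------------------------

def _draw_bg_timeline(
    n_bg: int, rng: np.random.Generator, cfg: PipelineConfig,
) -> list:
    """Glucose values with guaranteed class counts.

    ``min_dys_records`` dysglycemic values (at least one hypo- and one
    hyperglycemic), up to two buffer-zone values when there is room, the
    rest euglycemic; order shuffled.
    """
    n_dys = cfg.min_dys_records
    n_eu_min = cfg.n_train_eu + cfg.n_val_eu
    if n_bg < n_dys + n_eu_min:
        raise GenerationError(
            f"n_bg = {n_bg} cannot satisfy {n_dys} dysglycemic + "
            f"{n_eu_min} euglycemic records"
        )
    n_buffer = min(2, n_bg - n_dys - n_eu_min)
    n_eu = n_bg - n_dys - n_buffer

    n_hypo = int(np.clip(rng.binomial(n_dys, 0.3), 1, n_dys - 1))
    values = []
    values += list(rng.uniform(cfg.bg_hypo_mgdl - 30.0,
                               cfg.bg_hypo_mgdl - 5.0, n_hypo))
    values += list(rng.uniform(cfg.bg_hyper_mgdl + 5.0,
                               cfg.bg_hyper_mgdl + 120.0, n_dys - n_hypo))
    values += list(rng.uniform(cfg.bg_eu_low_mgdl + 5.0,
                               cfg.bg_eu_high_mgdl - 5.0, n_eu))
    for j in range(n_buffer):  # alternate low/high buffer bands
        if j % 2 == 0:
            values.append(rng.uniform(cfg.bg_hypo_mgdl + 0.5,
                                      cfg.bg_eu_low_mgdl - 0.5))
        else:
            values.append(rng.uniform(cfg.bg_eu_high_mgdl + 0.5,
                                      cfg.bg_hyper_mgdl - 0.5))
    values = np.array(values)
    rng.shuffle(values)
    return [
        BGRecord(time_s=cfg.bg_corr_window_s * (k + 1), glucose_mgdl=float(v))
        for k, v in enumerate(values)
    ]


def simulate_subject(
    base: dict | WaveParams | None,
    effect: GlycemicEffect,
    n_bg: int,
    seed: int,
    cfg: PipelineConfig | None = None,
    jitter_scale: float = DEFAULT_JITTER_SCALE,
    noise_sd_mv: float = 0.01,
    baseline_wander_mv: float = 0.0,
    subject_id: str | None = None,
    anchor_p_mv: float = DEFAULT_P_ANCHOR_MV,
) -> SyntheticSubject:
    """Simulate one subject: ``n_bg`` glucose records, each preceded by a
    10-min ECG strip whose beats follow the state-appropriate morphology.

    Buffer-zone glucose values (excluded from training by labeling) are
    rendered with euglycemic morphology. Bit-identical for a fixed seed.
    """
    cfg = cfg or PipelineConfig()
    if n_bg < cfg.min_bg_records:
        raise GenerationError(
            f"n_bg = {n_bg} < min_bg_records = {cfg.min_bg_records}")
    if isinstance(base, WaveParams):
        base = targets_from_wave_params(base)
    rng = np.random.default_rng(seed)
    bg = _draw_bg_timeline(n_bg, rng, cfg)
    jitter = JitterSpec.from_scale(jitter_scale)
    fs = float(cfg.sampling_rate_hz)
    strip_n = round(cfg.bg_corr_window_s * fs)

    params = {
        st: solve_wave_params(
            state_targets(st, effect, base),
            anchor_p_mv=anchor_p_mv,
            noise_sd_mv=noise_sd_mv,
            baseline_wander_mv=baseline_wander_mv,
        )
        for st in (EUGLYCEMIA, DYSGLYCEMIA)
    }

    chunks, truths = [], []
    for k, rec in enumerate(bg):
        label = label_bg(rec.glucose_mgdl, cfg)
        st = DYSGLYCEMIA if label is GlycemicLabel.DYSGLYCEMIA else EUGLYCEMIA
        targets = state_targets(st, effect, base)
        max_beats = int(np.ceil(cfg.bg_corr_window_s / _MIN_RR_S)) + 2
        sig, truth = _render_beat_train(
            targets, jitter, max_beats, cfg.bg_corr_window_s, rng, cfg,
            DEFAULT_WIDTHS, anchor_p_mv,
        )
        sig = _finalize_signal(sig, rng, noise_sd_mv, baseline_wander_mv, fs)
        if sig.size != strip_n:
            raise GenerationError("strip rendering produced a short buffer")
        truth["r_time_s"] += k * cfg.bg_corr_window_s
        truth["strip_index"] = k
        truth["state"] = st
        truth["label"] = label.value
        chunks.append(sig)
        truths.append(truth)

    sid = subject_id or f"synth{seed:08d}"
    record = ECGRecord(subject_id=sid, samples=np.concatenate(chunks),
                       sampling_rate_hz=fs)
    return SyntheticSubject(
        subject_id=sid,
        base_targets=base or state_targets(EUGLYCEMIA),
        state_params=params,
        bg=bg,
        record=record,
        truth=pd.concat(truths, ignore_index=True),
        seed=seed,
    )


def targets_from_wave_params(params: WaveParams) -> dict:
    """Invert a morphology back to feature-space targets."""
    c, a = params.centers_s, params.amplitudes_mv
    return {
        "intervals": {
            "RR": params.heart_period_s,
            "PQ": c["Q"] - c["P"],
            "QR": -c["Q"],
            "RS": c["S"],
            "ST": c["T"] - c["S"],
        },
        "amplitudes": {
            "PQ": abs(a["Q"] - a["P"]),
            "QR": abs(a["R"] - a["Q"]),
            "RS": abs(a["S"] - a["R"]),
            "QS": abs(a["S"] - a["Q"]),
            "ST": abs(a["T"] - a["S"]),
        },
    }


def subject_seed(master_seed: int, index: int) -> int:
    return (master_seed * 1000003 + 10007 * index + 1) % (2 ** 31)


def make_cohort(
    n_subjects: int,
    effect_scale: float,
    seed: int,
    cfg: PipelineConfig | None = None,
    n_bg: int = 22,
    jitter_scale: float = DEFAULT_JITTER_SCALE,
    noise_sd_mv: float = 0.01,
    baseline_wander_mv: float = 0.0,
) -> list:
    """Simulate a cohort with per-subject morphology variation.

    Subject base parameters are drawn from simple population
    distributions (resting heart period offset SD 0.05 s; global
    amplitude scale SD 0.10) and per-subject seeds derive from the master
    seed by fixed arithmetic, so cohorts are reproducible end to end.
    """
    cfg = cfg or PipelineConfig()
    if n_subjects < 1:
        raise GenerationError("n_subjects must be >= 1")
    pop_rng = np.random.default_rng(seed)
    subjects = []
    for i in range(n_subjects):
        rr_off = float(np.clip(pop_rng.normal(0.0, 0.05), -0.12, 0.12))
        amp_scale = float(np.clip(pop_rng.normal(1.0, 0.10), 0.7, 1.3))
        base = state_targets(EUGLYCEMIA)
        base["intervals"]["RR"] += rr_off
        base["amplitudes"] = {
            k: v * amp_scale for k, v in base["amplitudes"].items()}
        effect = GlycemicEffect(
            interval_shifts_s=dict(INTERVAL_SHIFTS),
            amplitude_shifts_mv={
                k: v * amp_scale for k, v in AMPLITUDE_SHIFTS.items()},
            effect_scale=effect_scale,
        )
        subjects.append(
            simulate_subject(
                base, effect, n_bg, subject_seed(seed, i), cfg,
                jitter_scale=jitter_scale,
                noise_sd_mv=noise_sd_mv,
                baseline_wander_mv=baseline_wander_mv,
                subject_id=f"synth{i:03d}",
                anchor_p_mv=DEFAULT_P_ANCHOR_MV * amp_scale,
            )
        )
    return subjects


# ---------------------------------------------------------------------------
# designed-feature oracle
# ---------------------------------------------------------------------------

def designed_features(truth: pd.DataFrame) -> pd.DataFrame:
    """The 26 features computed directly from the designed (continuous,
    pre-rendering) beat parameters — the independent oracle against which
    the waveform -> delineation -> feature pipeline is validated.

    The final beat of each run has no next-beat R-R and is omitted.
    """
    t = truth.iloc[:-1] if len(truth) else truth
    offs = {
        "P": -(t["PQ"] + t["QR"]),
        "Q": -t["QR"],
        "R": 0.0 * t["QR"],
        "S": t["RS"],
        "T": t["RS"] + t["ST"],
    }
    amp = {w: t["amp_" + w] for w in WAVES}
    out = {}
    for p in FEATURE_PAIRS:
        out[f"{p}_interval"] = (offs[p[1]] - offs[p[0]]).to_numpy()
    out["RR_interval"] = t["RR"].to_numpy()
    for p in FEATURE_PAIRS:
        out[f"{p}_amplitude"] = np.abs(amp[p[1]] - amp[p[0]]).to_numpy()
    for p in SLOPE_PAIRS:
        out[f"{p}_slope"] = (
            (amp[p[1]] - amp[p[0]]) / (offs[p[1]] - offs[p[0]])
        ).to_numpy()
    return pd.DataFrame(out, columns=list(FEATURE_NAMES))
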