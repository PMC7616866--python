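"""Seeded synthetic 12-lead ECG cohorts with known generating structure.

The generator produces everything the downstream pipeline consumes: raw
multichannel ECG signals with six rhythm/conduction diagnosis labels
(first-degree AV block, RBBB, LBBB, sinus bradycardia, AF, sinus
tachycardia), a latent three-group risk structure expressed purely through
terminal-QRS and terminal-T-wave morphology, exponential survival times with
group-dependent hazards, and binary/continuous phenotype tables with
group-dependent effects.

The beat model is a per-beat sum of Gaussians (one bump per wave, P through
T) projected onto 12 leads by a fixed lead-scaling vector.  This is chosen
over biophysical dipole models because every generated quantity (peak
amplitudes, RR statistics, event-time distributions, odds ratios) has a
closed form that tests can check against.  It is not intended as
physiologically realistic ECG synthesis.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "LEAD_NAMES",
    "DIAGNOSES",
    "GROUP_MORPHOLOGY",
    "STRONG_GROUP_MORPHOLOGY",
    "BeatParams",
    "DiagnosisLabels",
    "LatentGroup",
    "ECGRecord",
    "SubjectSpec",
    "CohortConfig",
    "Cohort",
    "BinaryEffect",
    "ContinuousEffect",
    "default_phenotype_effects",
    "simulate_beat",
    "beat_waveform",
    "simulate_ecg",
    "simulate_survival",
    "simulate_phenotypes",
    "simulate_feature_clusters",
    "simulate_cohort",
    "terminal_window_mask",
]

LEAD_NAMES = ("I", "II", "III", "aVR", "aVL", "aVF",
              "V1", "V2", "V3", "V4", "V5", "V6")

DIAGNOSES = ("first_degree_avb", "rbbb", "lbbb",
             "sinus_brady", "afib", "sinus_tachy")

RHYTHMS = ("sinus", "sinus_brady", "sinus_tachy", "afib")

#: Relative projection of the common beat trace onto the 12 leads.  Roughly
#: lead-II-dominant limb leads and an R-progression across the precordials.
DEFAULT_LEAD_SCALE = np.array(
    [0.6, 1.0, 0.5, -0.7, 0.3, 0.8, -0.4, 0.2, 0.6, 1.0, 0.9, 0.8]
)

#: Latent-group morphology deltas: (terminal-QRS notch amplitude in mV,
#: terminal-T flattening factor).  Group B carries both high-risk markers;
#: group C a mild flattening only.  These are the ONLY signal-level group
#: differences, which makes saliency localization falsifiable.
GROUP_MORPHOLOGY: dict[str, tuple[float, float]] = {
    "A": (0.0, 0.0),
    "B": (0.30, 0.60),
    "C": (0.0, 0.30),
}

#: Exaggerated morphology contrasts for method-property experiments that
#: need the generating clusters to be well separated in embedding space
#: ("strong group effects"): group B carries a large terminal-QRS notch,
#: group C a deep negative terminal deflection plus near-total T-terminal
#: flattening.  Differences remain confined to the terminal windows.
STRONG_GROUP_MORPHOLOGY: dict[str, tuple[float, float]] = {
    "A": (0.0, 0.0),
    "B": (3.0, 0.0),
    "C": (-2.0, 0.9),
}

#: Generating hazard multipliers (group A is the reference).
DEFAULT_HAZARD_MULTIPLIERS: dict[str, float] = {"A": 1.0, "B": 2.57, "C": 0.85}


class InvalidParameterError(ValueError):
    """A generator parameter violates its documented domain."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class BeatParams:
    """Parameters of a single beat as a sum of Gaussian waves.

    Amplitudes in mV, centers in ms relative to the R fiducial, widths are
    Gaussian sigmas in ms.  ``notch_mv`` adds a narrow deflection in the last
    third of the QRS window; ``t_flatten`` in [0, 1] scales the trailing half
    of the T wave down by that fraction.
    """

    amplitudes: dict[str, float]
    centers_ms: dict[str, float]
    widths_ms: dict[str, float]
    lead_scale: np.ndarray
    pr_ms: float = 160.0
    qrs_ms: float = 90.0
    qt_ms: float = 400.0
    notch_mv: float = 0.0
    t_flatten: float = 0.0

    def __post_init__(self) -> None:
        self.lead_scale = np.asarray(self.lead_scale, dtype=float)
        if self.lead_scale.shape != (12,):
            raise InvalidParameterError("lead_scale must have 12 entries")
        for w, width in self.widths_ms.items():
            if width <= 0:
                raise InvalidParameterError(f"width of wave {w!r} must be > 0")
        for name, val in (("pr_ms", self.pr_ms), ("qrs_ms", self.qrs_ms),
                          ("qt_ms", self.qt_ms)):
            if val <= 0:
                raise InvalidParameterError(f"{name} must be > 0")
        if not 0.0 <= self.t_flatten <= 1.0:
            raise InvalidParameterError("t_flatten must lie in [0, 1]")

    @classmethod
    def default(cls) -> "BeatParams":
        return cls(
            amplitudes={"P": 0.12, "Q": -0.10, "R": 1.00, "S": -0.20, "T": 0.30},
            centers_ms={"P": -180.0, "Q": -25.0, "R": 0.0, "S": 25.0, "T": 300.0},
            widths_ms={"P": 18.0, "Q": 6.0, "R": 9.0, "S": 7.0, "T": 55.0},
            lead_scale=DEFAULT_LEAD_SCALE.copy(),
        )

    def copy(self) -> "BeatParams":
        return dataclasses.replace(
            self,
            amplitudes=dict(self.amplitudes),
            centers_ms=dict(self.centers_ms),
            widths_ms=dict(self.widths_ms),
            lead_scale=self.lead_scale.copy(),
        )


@dataclass(frozen=True)
class DiagnosisLabels:
    """Six binary rhythm/conduction flags."""

    first_degree_avb: int = 0
    rbbb: int = 0
    lbbb: int = 0
    sinus_brady: int = 0
    afib: int = 0
    sinus_tachy: int = 0

    def __post_init__(self) -> None:
        for name in DIAGNOSES:
            if getattr(self, name) not in (0, 1):
                raise InvalidParameterError(f"label {name} must be 0/1")
        if self.afib + self.sinus_brady + self.sinus_tachy > 1:
            raise InvalidParameterError(
                "afib and the sinus-rate flags are mutually exclusive")

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, d) for d in DIAGNOSES], dtype=np.int8)


@dataclass(frozen=True)
class LatentGroup:
    """One of the three generating risk groups."""

    label: str
    hazard_multiplier: float
    notch_mv: float
    t_flatten: float

    def __post_init__(self) -> None:
        if self.label not in ("A", "B", "C"):
            raise InvalidParameterError("group label must be A, B or C")
        if self.hazard_multiplier <= 0:
            raise InvalidParameterError("hazard multiplier must be > 0")


@dataclass
class ECGRecord:
    """Raw 12-lead signal with its sampling rate and provenance metadata.

    ``fiducials`` holds the R-wave times (s) used to build the record; tests
    use them to re-derive the diagnosis labels from measurable properties.
    """

    signal: np.ndarray
    fs: float
    duration: float
    subject_id: str
    lead_names: tuple[str, ...] = LEAD_NAMES
    fiducials: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim != 2 or self.signal.shape[0] != 12:
            raise InvalidParameterError("signal must be a 12 x L matrix")
        if self.signal.shape[1] != round(self.duration * self.fs):
            raise InvalidParameterError("L must equal round(duration * fs)")
        if not np.all(np.isfinite(self.signal)):
            raise InvalidParameterError("signal must be finite")


@dataclass(frozen=True)
class SubjectSpec:
    """What to generate for one subject: a rhythm, conduction flags, a group."""

    rhythm: str = "sinus"
    first_degree_avb: bool = False
    bundle_branch_block: str = "none"   # none | rbbb | lbbb
    group: str = "A"

    def __post_init__(self) -> None:
        if self.rhythm not in RHYTHMS:
            raise InvalidParameterError(f"unknown rhythm {self.rhythm!r}")
        if self.bundle_branch_block not in ("none", "rbbb", "lbbb"):
            raise InvalidParameterError(
                f"unknown bundle branch block {self.bundle_branch_block!r}")
        if self.group not in GROUP_MORPHOLOGY:
            raise InvalidParameterError(f"unknown group {self.group!r}")


# ---------------------------------------------------------------------------
# Beat and record synthesis
# ---------------------------------------------------------------------------

def _base_trace(params: BeatParams, t: np.ndarray) -> np.ndarray:
    """Evaluate the single-lead beat template at times ``t`` (s, R at 0)."""
    tm = t * 1000.0  # work in ms
    out = np.zeros_like(tm, dtype=float)
    for w in ("P", "Q", "R", "S"):
        a = params.amplitudes.get(w, 0.0)
        if a == 0.0:
            continue
        c, s = params.centers_ms[w], params.widths_ms[w]
        out += a * np.exp(-0.5 * ((tm - c) / s) ** 2)
    # T wave, with optional flattening of its trailing half
    a_t = params.amplitudes.get("T", 0.0)
    if a_t != 0.0:
        c, s = params.centers_ms["T"], params.widths_ms["T"]
        tw = a_t * np.exp(-0.5 * ((tm - c) / s) ** 2)
        if params.t_flatten != 0.0:
            tw = np.where(tm > c, tw * (1.0 - params.t_flatten), tw)
        out += tw
    # terminal-QRS notch: narrow bump in the last third of the QRS window
    if params.notch_mv != 0.0:
        c = params.qrs_ms / 3.0
        s = params.qrs_ms / 12.0
        out += params.notch_mv * np.exp(-0.5 * ((tm - c) / s) ** 2)
    return out


def beat_waveform(params: BeatParams, fs: float, t: np.ndarray) -> np.ndarray:
    """12-lead beat waveform on an arbitrary time grid (s, R fiducial at 0)."""
    if fs <= 0:
        raise InvalidParameterError("fs must be > 0")
    base = _base_trace(params, np.asarray(t, dtype=float))
    return np.outer(params.lead_scale, base)


def simulate_beat(params: BeatParams, fs: float) -> np.ndarray:
    """Render one beat on its own support as a 12 x n matrix.

    The grid is sample-aligned so that a wave centered at an integer sample
    offset attains its analytic Gaussian peak exactly.
    """
    if fs <= 0:
        raise InvalidParameterError("fs must be > 0")
    lo = min(c - 5 * params.widths_ms[w]
             for w, c in params.centers_ms.items()) / 1000.0
    hi = max(c + 5 * params.widths_ms[w]
             for w, c in params.centers_ms.items()) / 1000.0
    k = np.arange(int(np.floor(lo * fs)), int(np.ceil(hi * fs)) + 1)
    return beat_waveform(params, fs, k / fs)


def _rr_sequence(rhythm: str, duration_s: float,
                 rng: np.random.Generator) -> np.ndarray:
    """Draw an RR-interval sequence (s) long enough to cover the record."""
    n_max = int(duration_s * 4) + 8  # enough beats even at 220 bpm
    if rhythm == "sinus":
        rate = rng.uniform(60.0, 100.0)
    elif rhythm == "sinus_brady":
        rate = rng.uniform(40.0, 49.0)
    elif rhythm == "sinus_tachy":
        rate = rng.uniform(105.0, 140.0)
    elif rhythm == "afib":
        # i.i.d. lognormal RR, coefficient of variation 0.30
        mean_rr, cv = 0.75, 0.30
        sigma = np.sqrt(np.log(1.0 + cv ** 2))
        mu = np.log(mean_rr) - 0.5 * sigma ** 2
        return rng.lognormal(mu, sigma, size=n_max)
    else:  # pragma: no cover - guarded by SubjectSpec
        raise InvalidParameterError(f"unknown rhythm {rhythm!r}")
    rr = 60.0 / rate
    return rr * (1.0 + rng.normal(0.0, 0.02, size=n_max))


def simulate_ecg(
    spec: SubjectSpec,
    duration_s: float = 10.0,
    fs: float = 400.0,
    rng: np.random.Generator | None = None,
    *,
    subject_id: str = "S0",
    noise_sd: float = 0.02,
    drift_amplitude: float = 0.10,
    group_morphology: Mapping[str, tuple[float, float]] | None = None,
) -> tuple[ECGRecord, DiagnosisLabels]:
    """Generate one 12-lead record and its consistent diagnosis labels.

    Rhythm rules: sinus 60-100 bpm with small jitter; sinus bradycardia
    < 50 bpm; sinus tachycardia > 100 bpm; AF replaces the P wave by nothing
    (amplitude 0) and draws i.i.d. RR intervals with CV >= 0.15.  First-degree
    AV block prolongs PR beyond 200 ms; bundle-branch blocks widen the QRS
    beyond 120 ms and flip the projection of V1/V6-analog leads.  Additive
    Gaussian noise and sub-0.5 Hz sinusoidal baseline drift are superimposed.
    """
    if duration_s <= 0:
        raise InvalidParameterError("duration_s must be > 0")
    if fs <= 0:
        raise InvalidParameterError("fs must be > 0")
    rng = np.random.default_rng() if rng is None else rng

    params = BeatParams.default()
    morph = GROUP_MORPHOLOGY if group_morphology is None else group_morphology
    notch, flatten = morph[spec.group]
    params.notch_mv = notch
    params.t_flatten = flatten

    if spec.rhythm == "afib":
        params.amplitudes["P"] = 0.0
    if spec.first_degree_avb:
        params.pr_ms = 240.0
        params.centers_ms["P"] = -(params.pr_ms + 20.0)
    if spec.bundle_branch_block != "none":
        factor = 140.0 / params.qrs_ms
        params.qrs_ms = 140.0
        for w in ("Q", "R", "S"):
            params.widths_ms[w] *= factor
        params.centers_ms["S"] = 35.0
        if spec.bundle_branch_block == "rbbb":
            # RSR' pattern: terminal R' deflection + V1-analog flip
            params.notch_mv += 0.5
            params.lead_scale[6] *= -1.0
            params.lead_scale[7] *= -1.0
        else:
            # discordant repolarization: inverted T, V5/V6-analog flip
            params.amplitudes["T"] *= -0.8
            params.lead_scale[10] *= -1.0
            params.lead_scale[11] *= -1.0

    rr = _rr_sequence(spec.rhythm, duration_s, rng)
    beat_times = 0.25 + np.cumsum(np.concatenate([[0.0], rr]))
    beat_times = beat_times[beat_times < duration_s + 0.5]

    L = round(duration_s * fs)
    t = np.arange(L) / fs
    trace = np.zeros(L)
    half_support = 0.6  # s, covers P..T at default centers/widths
    for tb in beat_times:
        i0 = max(0, int((tb - half_support) * fs))
        i1 = min(L, int((tb + half_support + 0.3) * fs) + 1)
        if i1 <= i0:
            continue
        trace[i0:i1] += _base_trace(params, t[i0:i1] - tb)

    signal = np.outer(params.lead_scale, trace)
    if noise_sd > 0:
        signal += rng.normal(0.0, noise_sd, size=signal.shape)
    if drift_amplitude > 0:
        freqs = rng.uniform(0.15, 0.45, size=12)
        phases = rng.uniform(0.0, 2 * np.pi, size=12)
        amps = drift_amplitude * rng.uniform(0.5, 1.0, size=12)
        signal += amps[:, None] * np.sin(
            2 * np.pi * freqs[:, None] * t[None, :] + phases[:, None])

    labels = DiagnosisLabels(
        first_degree_avb=int(spec.first_degree_avb),
        rbbb=int(spec.bundle_branch_block == "rbbb"),
        lbbb=int(spec.bundle_branch_block == "lbbb"),
        sinus_brady=int(spec.rhythm == "sinus_brady"),
        afib=int(spec.rhythm == "afib"),
        sinus_tachy=int(spec.rhythm == "sinus_tachy"),
    )
    record = ECGRecord(
        signal=signal, fs=fs, duration=duration_s, subject_id=subject_id,
        fiducials=beat_times[beat_times < duration_s],
        meta={
            "rhythm": spec.rhythm, "group": spec.group,
            "pr_ms": params.pr_ms, "qrs_ms": params.qrs_ms,
            "t_center_ms": params.centers_ms["T"],
            "t_width_ms": params.widths_ms["T"],
        },
    )
    return record, labels


def terminal_window_mask(record: ECGRecord, n_samples: int = 4096,
                         fs: float = 400.0, pad_left: int = 48) -> np.ndarray:
    """Boolean mask over the preprocessed sample grid covering the
    terminal-QRS and terminal-T windows of every beat in ``record``.

    The terminal-QRS window spans [QRS/6, QRS/2] after each R fiducial
    (the support of the notch deflection); the terminal-T window spans
    [T center, T center + 2 T widths] (the trailing half of the T wave).
    These are the only regions where latent-group morphology acts, so the
    mask is the ground-truth target for saliency-localization checks.
    """
    if record.fiducials is None or "qrs_ms" not in record.meta:
        raise ValueError("record lacks fiducials/morphology metadata")
    qrs = record.meta["qrs_ms"] / 1000.0
    tc = record.meta["t_center_ms"] / 1000.0
    tw = record.meta["t_width_ms"] / 1000.0
    mask = np.zeros(n_samples, dtype=bool)
    n_orig = round(record.duration * fs)
    for tb in record.fiducials:
        for lo, hi in ((tb + qrs / 6, tb + qrs / 2),
                       (tb + tc, tb + tc + 2 * tw)):
            i0 = max(0, int(lo * fs)) + pad_left
            i1 = min(n_orig, int(hi * fs)) + pad_left
            if i1 > i0:
                mask[i0:min(i1, n_samples)] = True
    return mask


# ---------------------------------------------------------------------------
# Survival and phenotypes
# ---------------------------------------------------------------------------

def simulate_survival(
    groups: Sequence[str],
    baseline_hazard: float,
    multipliers: Mapping[str, float] | None = None,
    censor_time: float = 5.0,
    rng: np.random.Generator | None = None,
    *,
    age: np.ndarray | None = None,
    age_log_hr: float = 0.0,
) -> pd.DataFrame:
    """Exponential event times with group-dependent hazards.

    hazard_i = baseline * multiplier(group_i) * exp(age_log_hr * (age_i - 55)).
    Administrative censoring at ``censor_time``; event = 0 iff censored.
    """
    if baseline_hazard <= 0:
        raise InvalidParameterError("baseline_hazard must be > 0")
    if censor_time <= 0:
        raise InvalidParameterError("censor_time must be > 0")
    multipliers = DEFAULT_HAZARD_MULTIPLIERS if multipliers is None else multipliers
    if any(m <= 0 for m in multipliers.values()):
        raise InvalidParameterError("hazard multipliers must be > 0")
    if abs(multipliers.get("A", 1.0) - 1.0) > 1e-12:
        raise InvalidParameterError("multiplier of reference group A must be 1")
    rng = np.random.default_rng() if rng is None else rng

    groups = np.asarray(groups)
    lam = baseline_hazard * np.array([multipliers[g] for g in groups])
    if age is not None and age_log_hr != 0.0:
        lam = lam * np.exp(age_log_hr * (np.asarray(age, dtype=float) - 55.0))
    raw = rng.exponential(1.0, size=len(groups)) / lam
    event = (raw <= censor_time).astype(int)
    time = np.minimum(raw, censor_time)
    return pd.DataFrame({
        "subject_id": [f"S{i}" for i in range(len(groups))],
        "time_years": time,
        "event": event,
    })


@dataclass(frozen=True)
class BinaryEffect:
    """Binary phenotype generated with log-odds = logit(base) + log(OR)*[group B]."""

    base_prevalence: float
    odds_ratio: float

    def __post_init__(self) -> None:
        if not 0.0 < self.base_prevalence < 1.0:
            raise InvalidParameterError("base prevalence must lie in (0, 1)")
        if self.odds_ratio <= 0:
            raise InvalidParameterError("odds ratio must be > 0")


@dataclass(frozen=True)
class ContinuousEffect:
    """Normal phenotype with a group-B mean shift (in phenotype units)."""

    mean: float
    sd: float
    group_b_shift: float

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise InvalidParameterError("sd must be > 0")


def default_phenotype_effects() -> dict[str, BinaryEffect | ContinuousEffect]:
    """Generating phenotype effects.

    The binary odds ratios mirror the incident-disease associations reported
    for the high-risk phenogroup (AF 2.89, IHD 1.44, AV block 4.88,
    cardiomyopathy 2.04, VT 2.00, cardiac arrest 6.68); continuous effects
    emulate chamber-volume-like measures that shift with risk group.
    """
    return {
        "afib_incident": BinaryEffect(0.05, 2.89),
        "ihd_incident": BinaryEffect(0.08, 1.44),
        "avb_incident": BinaryEffect(0.02, 4.88),
        "cardiomyopathy_incident": BinaryEffect(0.03, 2.04),
        "vt_incident": BinaryEffect(0.02, 2.00),
        "cardiac_arrest_incident": BinaryEffect(0.01, 6.68),
        "lv_end_diastolic_volume": ContinuousEffect(150.0, 30.0, 12.0),
        "left_atrial_volume": ContinuousEffect(75.0, 15.0, 6.0),
        "lv_ejection_fraction": ContinuousEffect(60.0, 6.0, -3.0),
        "resting_heart_rate": ContinuousEffect(68.0, 10.0, -2.0),
    }


def simulate_phenotypes(
    group_labels: Sequence[str],
    effect_table: Mapping[str, BinaryEffect | ContinuousEffect] | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Draw per-subject phenotypes whose group-B effects are known."""
    effect_table = default_phenotype_effects() if effect_table is None else effect_table
    rng = np.random.default_rng() if rng is None else rng
    groups = np.asarray(group_labels)
    is_b = (groups == "B").astype(float)
    out: dict[str, np.ndarray] = {
        "subject_id": np.array([f"S{i}" for i in range(len(groups))])}
    for name, eff in effect_table.items():
        if isinstance(eff, BinaryEffect):
            logit = np.log(eff.base_prevalence / (1 - eff.base_prevalence))
            p = 1.0 / (1.0 + np.exp(-(logit + np.log(eff.odds_ratio) * is_b)))
            out[name] = (rng.uniform(size=len(groups)) < p).astype(int)
        elif isinstance(eff, ContinuousEffect):
            out[name] = rng.normal(eff.mean + eff.group_b_shift * is_b, eff.sd)
        else:
            raise InvalidParameterError(f"unknown effect type for {name!r}")
    return pd.DataFrame(out)


def simulate_feature_clusters(
    n: int,
    n_groups: int = 3,
    dim: int = 64,
    separation: float = 10.0,
    sd: float = 0.5,
    weights: Sequence[float] | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Well-separated Gaussian clusters in feature space, one per latent group.

    Cluster centers sit on mutually orthogonal axes scaled so every pairwise
    centroid distance equals ``separation``; within-cluster draws are
    isotropic with standard deviation ``sd`` (default one-twentieth of the
    separation).  Used for clustering/elbow experiments that do not need the
    CNN in the loop.
    """
    if n_groups < 1 or dim < n_groups:
        raise InvalidParameterError("need dim >= n_groups >= 1")
    rng = np.random.default_rng() if rng is None else rng
    weights = np.full(n_groups, 1.0 / n_groups) if weights is None else np.asarray(weights)
    if abs(weights.sum() - 1.0) > 1e-8:
        raise InvalidParameterError("weights must sum to 1")
    centers = np.zeros((n_groups, dim))
    for g in range(n_groups):
        centers[g, g] = separation / np.sqrt(2.0)
    labels = rng.choice(n_groups, size=n, p=weights)
    X = centers[labels] + rng.normal(0.0, sd, size=(n, dim))
    return X, labels


# ---------------------------------------------------------------------------
# Full cohort
# ---------------------------------------------------------------------------

@dataclass
class CohortConfig:
    """Study conditions for one generated cohort."""

    n: int = 1000
    group_proportions: tuple[float, float, float] = (0.50, 0.35, 0.15)
    p_sinus_brady: float = 0.05
    p_sinus_tachy: float = 0.08
    p_afib: float = 0.08
    p_first_degree_avb: float = 0.06
    p_rbbb: float = 0.05
    p_lbbb: float = 0.04
    fs: float = 400.0
    duration_s: float = 10.0
    noise_sd: float = 0.02
    drift_amplitude: float = 0.10
    baseline_hazard: float = 0.02
    group_morphology: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(GROUP_MORPHOLOGY))
    hazard_multipliers: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_HAZARD_MULTIPLIERS))
    censor_time: float = 5.0
    age_log_hr: float = 0.0          # per-year log hazard of age
    group_b_age_shift: float = 0.0   # years added to group-B ages (confounding knob)
    seed: int = 0

    def validate(self) -> None:
        props = np.asarray(self.group_proportions, dtype=float)
        if props.shape != (3,) or abs(props.sum() - 1.0) > 1e-8 or (props < 0).any():
            raise InvalidParameterError(
                "group_proportions must be 3 nonnegative values summing to 1")
        p_rhythm = self.p_sinus_brady + self.p_sinus_tachy + self.p_afib
        if min(self.p_sinus_brady, self.p_sinus_tachy, self.p_afib,
               self.p_first_degree_avb, self.p_rbbb, self.p_lbbb) < 0 or p_rhythm > 1:
            raise InvalidParameterError("invalid diagnosis prevalences")
        if self.p_rbbb + self.p_lbbb > 1:
            raise InvalidParameterError("p_rbbb + p_lbbb must be <= 1")
        if self.n < 1:
            raise InvalidParameterError("n must be >= 1")


@dataclass
class Cohort:
    """One generated cohort bundle (one row per subject in every table)."""

    records: list[ECGRecord]
    labels: pd.DataFrame
    groups: pd.DataFrame
    survival: pd.DataFrame
    phenotypes: pd.DataFrame
    config: CohortConfig

    def signals_array(self, dtype=np.float32) -> np.ndarray:
        """Stack raw signals into an (n, 12, L) array."""
        return np.stack([r.signal for r in self.records]).astype(dtype)

    @property
    def subject_ids(self) -> list[str]:
        return [r.subject_id for r in self.records]


def simulate_cohort(config: CohortConfig,
                    rng: np.random.Generator | None = None) -> Cohort:
    """Generate a full cohort: signals, labels, groups, survival, phenotypes.

    All randomness flows from ``rng`` (or ``config.seed`` when omitted), so
    identical (config, seed) pairs give identical bundles.
    """
    config.validate()
    rng = np.random.default_rng(config.seed) if rng is None else rng

    props = np.asarray(config.group_proportions, dtype=float)
    group_idx = rng.choice(3, size=config.n, p=props)
    groups = np.array(["A", "B", "C"])[group_idx]

    p_r = np.array([config.p_sinus_brady, config.p_sinus_tachy, config.p_afib])
    rhythm_draw = rng.uniform(size=config.n)
    edges = np.cumsum(p_r)
    avb = rng.uniform(size=config.n) < config.p_first_degree_avb
    bbb_draw = rng.uniform(size=config.n)

    records: list[ECGRecord] = []
    label_rows: list[np.ndarray] = []
    ages = rng.normal(55.0, 12.0, size=config.n)
    ages = ages + config.group_b_age_shift * (groups == "B")
    sexes = rng.integers(0, 2, size=config.n)

    for i in range(config.n):
        if rhythm_draw[i] < edges[0]:
            rhythm = "sinus_brady"
        elif rhythm_draw[i] < edges[1]:
            rhythm = "sinus_tachy"
        elif rhythm_draw[i] < edges[2]:
            rhythm = "afib"
        else:
            rhythm = "sinus"
        if bbb_draw[i] < config.p_rbbb:
            bbb = "rbbb"
        elif bbb_draw[i] < config.p_rbbb + config.p_lbbb:
            bbb = "lbbb"
        else:
            bbb = "none"
        spec = SubjectSpec(rhythm=rhythm, first_degree_avb=bool(avb[i]),
                           bundle_branch_block=bbb, group=groups[i])
        rec, lab = simulate_ecg(
            spec, config.duration_s, config.fs, rng,
            subject_id=f"S{i}", noise_sd=config.noise_sd,
            drift_amplitude=config.drift_amplitude,
            group_morphology=config.group_morphology)
        records.append(rec)
        label_rows.append(lab.as_array())

    ids = [f"S{i}" for i in range(config.n)]
    labels = pd.DataFrame(np.array(label_rows), columns=list(DIAGNOSES))
    labels.insert(0, "subject_id", ids)

    group_df = pd.DataFrame({"subject_id": ids, "group": groups,
                             "age": ages, "sex": sexes})
    survival = simulate_survival(
        groups, config.baseline_hazard, config.hazard_multipliers,
        config.censor_time, rng, age=ages, age_log_hr=config.age_log_hr)
    survival["subject_id"] = ids
    survival["age"] = ages
    survival["sex"] = sexes
    phenotypes = simulate_phenotypes(groups, rng=rng)
    phenotypes["subject_id"] = ids
    return Cohort(records=records, labels=labels, groups=group_df,
                  survival=survival, phenotypes=phenotypes, config=config)
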