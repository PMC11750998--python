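"""Synthetic resting-state fNIRS cohort generator.

Produces cohorts of raw two-wavelength recordings, neuropsychological score
tables and group labels (NC / SCD / MCI) with *known* ground-truth ROI
coupling, so the whole downstream pipeline — preprocessing, connectivity,
group statistics, classifier screening — can be exercised and validated
without any subject data.

The forward model works backwards through the measurement chain:

1. latent band-limited (0.01-0.1 Hz) ROI oxy-hemoglobin signals are drawn
   with a configured pairwise correlation structure (the coupling matrix);
2. ROI signals are copied to their member channels; deoxy-hemoglobin is an
   anticorrelated scaled copy plus independent narrowband noise;
3. concentrations are pushed through the forward modified Beer-Lambert law
   to two-wavelength optical densities;
4. physiological nuisance (cardiac ~1 Hz, respiratory ~0.25 Hz, Mayer
   ~0.1 Hz), slow drift, motion artifacts (spikes and baseline shifts) and
   white measurement noise are added in the optical-density domain;
5. optical density is exponentiated into strictly positive intensities.

Because step 3 uses the same extinction table the preprocessing inverts,
the injected concentration series are recoverable up to band-pass
distortion, which the test-suite exploits.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from .montage import N_CHANNELS, N_ROIS, RoiMap, roi_channel_map
from .preprocess import RawRecording, mbll_forward

__all__ = [
    "GROUPS",
    "ScoreDistributionTable",
    "NuisanceAmplitudes",
    "CohortConfig",
    "RecordingTruth",
    "CohortDataset",
    "default_group_coupling",
    "generate_scores",
    "generate_recording",
    "generate_cohort",
]

GROUPS = ("NC", "SCD", "MCI")

SCORE_COLUMNS = ("mmse", "tmt_a", "tmt_b", "bnt", "hvlt", "cdt")

# Default score distributions per group: (mean, sd) for each test.
_DEFAULT_SCORES: dict[str, dict[str, tuple[float, float]]] = {
    "NC": {
        "mmse": (28.91, 1.20),
        "tmt_a": (40.73, 12.47),
        "tmt_b": (59.51, 22.59),
        "bnt": (27.29, 1.65),
        "hvlt": (26.91, 3.27),
        "cdt": (9.33, 0.71),
    },
    "SCD": {
        "mmse": (28.35, 1.30),
        "tmt_a": (57.41, 19.85),
        "tmt_b": (86.45, 28.51),
        "bnt": (25.41, 2.67),
        "hvlt": (21.85, 4.23),
        "cdt": (8.73, 1.10),
    },
    "MCI": {
        "mmse": (25.49, 2.56),
        "tmt_a": (98.22, 45.44),
        "tmt_b": (186.31, 102.84),
        "bnt": (20.63, 4.04),
        "hvlt": (13.50, 5.13),
        "cdt": (7.50, 1.63),
    },
}

# Instrument bounds and integer-valuedness per test. TMT scores are times
# in seconds (continuous, nonnegative); the others are point scales.
_SCORE_BOUNDS: dict[str, tuple[float, float, bool]] = {
    "mmse": (0.0, 30.0, True),
    "tmt_a": (0.0, np.inf, False),
    "tmt_b": (0.0, np.inf, False),
    "bnt": (0.0, 30.0, True),
    "hvlt": (0.0, 36.0, True),
    "cdt": (0.0, 10.0, True),
}


@dataclass
class ScoreDistributionTable:
    """Per group x test (mean, sd) plus instrument bounds."""

    params: dict[str, dict[str, tuple[float, float]]] = field(
        default_factory=lambda: {g: dict(_DEFAULT_SCORES[g]) for g in GROUPS}
    )
    bounds: dict[str, tuple[float, float, bool]] = field(
        default_factory=lambda: dict(_SCORE_BOUNDS)
    )

    def __post_init__(self) -> None:
        for g, tests in self.params.items():
            for t, (_, sd) in tests.items():
                if sd < 0:
                    raise ValueError(f"negative SD for {g}/{t}")


@dataclass
class NuisanceAmplitudes:
    """Amplitudes of the physiological nuisance components, expressed as
    optical-density oscillation amplitude relative to the OD standard
    deviation produced by the neural signal (so 1.0 means "as large as
    the signal")."""

    cardiac: float = 0.8  # ~1 Hz heartbeat
    respiratory: float = 0.4  # ~0.25 Hz breathing
    mayer: float = 0.4  # ~0.1 Hz blood-pressure waves
    drift: float = 1.0  # slow instrument drift over the recording

    cardiac_hz: float = 1.0
    respiratory_hz: float = 0.25
    mayer_hz: float = 0.1


def default_group_coupling(
    base: float = 0.3, deltas: dict[str, float] | None = None
) -> dict[str, np.ndarray]:
    """Default ground-truth ROI coupling per group.

    All ROI pairs share a baseline coupling; the three connections the
    pipeline is designed to resolve — ROI1-ROI3, ROI2-ROI7, ROI4-ROI7 —
    are enhanced in the impaired groups with ordering MCI > SCD > NC
    (the compensatory-hyperconnectivity direction).
    """
    deltas = deltas or {"NC": 0.0, "SCD": 0.2, "MCI": 0.4}
    enhanced_pairs = [(1, 3), (2, 7), (4, 7)]  # 1-based ROI ids
    out: dict[str, np.ndarray] = {}
    for g in GROUPS:
        c = np.full((N_ROIS, N_ROIS), base)
        np.fill_diagonal(c, 1.0)
        for i, j in enhanced_pairs:
            c[i - 1, j - 1] = c[j - 1, i - 1] = min(base + deltas[g], 1.0)
        out[g] = c
    return out


@dataclass
class CohortConfig:
    """Everything needed to generate one reproducible synthetic cohort."""

    group_sizes: dict[str, int] = field(
        default_factory=lambda: {"NC": 48, "SCD": 65, "MCI": 90}
    )
    duration_s: float = 300.0
    sampling_rate_hz: float = 8.138
    coupling: dict[str, np.ndarray] = field(default_factory=default_group_coupling)
    score_table: ScoreDistributionTable = field(default_factory=ScoreDistributionTable)
    nuisance: NuisanceAmplitudes = field(default_factory=NuisanceAmplitudes)
    artifact_rate_per_min: float = 0.5
    noise_sd: float = 0.005  # white measurement noise, OD units
    signal_sd_um: float = 0.5  # latent HbO fluctuation scale, uM
    hbr_ratio: float = 0.3  # HbR = -ratio * HbO + residual
    hbr_noise_frac: float = 0.3  # residual SD relative to ratio*signal
    baseline_intensity: float = 1000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_s <= 0 or self.sampling_rate_hz <= 0:
            raise ValueError("duration and sampling rate must be positive")
        if self.duration_s * self.sampling_rate_hz < 2:
            raise ValueError("recording must span at least 2 samples")
        for g, n in self.group_sizes.items():
            if n < 0:
                raise ValueError(f"negative group size for {g}")
        for g, c in self.coupling.items():
            c = np.asarray(c, dtype=float)
            if c.shape != (N_ROIS, N_ROIS):
                raise ValueError(f"coupling for {g} must be {N_ROIS}x{N_ROIS}")
            if not np.allclose(c, c.T):
                raise ValueError(f"coupling for {g} must be symmetric")
            if not np.allclose(np.diag(c), 1.0):
                raise ValueError(f"coupling for {g} must have unit diagonal")
            if c.min() < 0 or c.max() > 1:
                raise ValueError(f"coupling for {g} must lie in [0, 1]")

    @property
    def n_samples(self) -> int:
        return int(self.duration_s * self.sampling_rate_hz)


@dataclass
class RecordingTruth:
    """Ground truth behind one generated recording."""

    group: str
    coupling: np.ndarray
    artifact_times_s: dict[int, list[float]]  # channel id (1-based) -> event times
    latent_hbo: np.ndarray | None = None  # time x channel, uM (in-memory only)
    latent_hbr: np.ndarray | None = None


@dataclass
class CohortDataset:
    """A generated cohort: recordings, score table, labels, ground truth."""

    recordings: list[RawRecording]
    scores: pd.DataFrame  # subject_id, group, six score columns
    ground_truth: dict[str, RecordingTruth]  # subject_id -> truth

    @property
    def labels(self) -> pd.Series:
        return self.scores.set_index("subject_id")["group"]


def generate_scores(
    group: str,
    n: int,
    table: ScoreDistributionTable | None = None,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Draw one score row per subject for a group.

    Scores are normal draws with the configured group mean/SD, clipped to
    the instrument bounds; integer-valued tests are rounded.
    """
    if group not in GROUPS:
        raise ValueError(f"unknown group {group!r}; expected one of {GROUPS}")
    table = table or ScoreDistributionTable()
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    data: dict[str, np.ndarray] = {}
    for test in SCORE_COLUMNS:
        mean, sd = table.params[group][test]
        lo, hi, integer = table.bounds[test]
        vals = rng.normal(mean, sd, size=n) if sd > 0 else np.full(n, float(mean))
        vals = np.clip(vals, lo, hi)
        if integer:
            vals = np.round(vals)
        data[test] = vals
    return pd.DataFrame(data)


def _narrowband(
    rng: np.random.Generator,
    n_t: int,
    n_series: int,
    fs: float,
    band: tuple[float, float] = (0.01, 0.1),
) -> np.ndarray:
    """Unit-variance band-limited Gaussian noise, (n_t, n_series)."""
    white = rng.standard_normal((n_t, n_series))
    sos = signal.butter(3, band, btype="bandpass", fs=fs, output="sos")
    x = signal.sosfiltfilt(sos, white, axis=0)
    sd = x.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    return x / sd


def _coupling_mixer(coupling: np.ndarray) -> np.ndarray:
    """Mixing matrix L with L L^T = coupling (PSD-projected).

    Independent unit-variance sources mixed by L acquire exactly the
    coupling matrix as their correlation structure; for a single pair this
    is the shared-source + independent-residual construction with mixing
    weight equal to the coupling value.
    """
    c = np.asarray(coupling, dtype=float)
    if not np.allclose(c, c.T):
        raise ValueError("coupling matrix must be symmetric")
    w, v = np.linalg.eigh(c)
    w = np.clip(w, 0.0, None)
    L = v @ np.diag(np.sqrt(w))
    # renormalize rows so each latent keeps unit variance after projection
    norms = np.sqrt((L**2).sum(axis=1))
    norms[norms == 0] = 1.0
    return L / norms[:, None]


def generate_recording(
    coupling: np.ndarray,
    config: CohortConfig | None = None,
    seed: int | np.random.Generator = 0,
    subject_id: str = "synthetic",
    roi_map: RoiMap | None = None,
) -> tuple[RawRecording, RecordingTruth]:
    """Generate one raw recording with the given ground-truth ROI coupling.

    Returns the recording and its :class:`RecordingTruth` (including the
    injected channel-level concentration series for forward/inverse
    validation).
    """
    config = config or CohortConfig()
    roi_map = roi_map or roi_channel_map()
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    coupling = np.asarray(coupling, dtype=float)
    if coupling.shape != (N_ROIS, N_ROIS):
        raise ValueError(f"coupling must be {N_ROIS}x{N_ROIS}")
    if not np.allclose(coupling, coupling.T):
        raise ValueError("coupling matrix must be symmetric")

    fs = config.sampling_rate_hz
    n_t = config.n_samples

    # 1. latent ROI HbO with the configured correlation structure
    sources = _narrowband(rng, n_t, N_ROIS, fs)
    L = _coupling_mixer(coupling)
    roi_hbo = (sources @ L.T) * config.signal_sd_um  # (n_t, n_rois)

    # 2. channel concentrations: copy ROI signal to member channels
    hbo = np.zeros((n_t, N_CHANNELS))
    for r, roi in enumerate(roi_map.roi_ids):
        for c in roi_map.channel_indices(roi):
            hbo[:, c] = roi_hbo[:, r]
    resid_sd = config.hbr_ratio * config.signal_sd_um * config.hbr_noise_frac
    hbr = -config.hbr_ratio * hbo + resid_sd * _narrowband(
        rng, n_t, N_CHANNELS, fs
    )

    # 3. forward Beer-Lambert to optical density, (n_t, n_ch, 2)
    od = mbll_forward(hbo, hbr)
    signal_od_sd = float(od.std()) or 1.0

    # 4a. physiological nuisance: shared oscillators, per-channel gain
    nu = config.nuisance
    t = np.arange(n_t) / fs
    for amp, f0 in (
        (nu.cardiac, nu.cardiac_hz),
        (nu.respiratory, nu.respiratory_hz),
        (nu.mayer, nu.mayer_hz),
    ):
        if amp <= 0 or f0 >= fs / 2:
            continue
        phase = rng.uniform(0, 2 * np.pi)
        osc = np.sin(2 * np.pi * f0 * t + phase)
        gains = 1.0 + 0.2 * rng.standard_normal((N_CHANNELS, 2))
        od += amp * signal_od_sd * osc[:, None, None] * gains[None, :, :]
    if nu.drift > 0:
        slopes = rng.uniform(-1, 1, size=(N_CHANNELS, 2))
        od += nu.drift * signal_od_sd * slopes[None, :, :] * (t / t[-1])[:, None, None]

    # 4b. motion artifacts: probe-wide events, channel-specific amplitude
    artifact_times: dict[int, list[float]] = {}
    n_events = rng.poisson(config.artifact_rate_per_min * config.duration_s / 60.0)
    for _ in range(n_events):
        t0 = rng.uniform(0, config.duration_s)
        i0 = int(t0 * fs)
        kind = rng.choice(["spike", "shift"])
        amps = rng.uniform(5, 20, size=(N_CHANNELS, 2)) * signal_od_sd
        amps *= rng.choice([-1, 1], size=(N_CHANNELS, 2))
        if kind == "spike":
            dur = rng.uniform(0.5, 2.0)
            half = max(int(dur * fs / 2), 1)
            bump = np.exp(
                -0.5 * ((np.arange(n_t) - i0) / (half / 2.0)) ** 2
            )
            od += bump[:, None, None] * amps[None, :, :]
        else:
            step = np.zeros(n_t)
            step[i0:] = 1.0
            od += step[:, None, None] * amps[None, :, :]
        for ch in range(N_CHANNELS):
            artifact_times.setdefault(ch + 1, []).append(float(t0))

    # 4c. white measurement noise
    if config.noise_sd > 0:
        od += config.noise_sd * rng.standard_normal(od.shape)

    # 5. optical density -> strictly positive intensity
    intensity = config.baseline_intensity * np.exp(-od)

    rec = RawRecording(
        intensity=intensity,
        sampling_rate_hz=fs,
        subject_id=subject_id,
    )
    truth = RecordingTruth(
        group="",
        coupling=coupling,
        artifact_times_s=artifact_times,
        latent_hbo=hbo,
        latent_hbr=hbr,
    )
    return rec, truth


def generate_cohort(config: CohortConfig | None = None) -> CohortDataset:
    """Generate a full cohort: one recording + one score row per subject.

    Bit-reproducible from ``config.seed``: each subject gets an
    independent child random stream spawned from the root seed.
    """
    config = config or CohortConfig()
    root = np.random.SeedSequence(config.seed)
    n_total = sum(config.group_sizes.values())
    children = root.spawn(n_total + len(GROUPS))

    recordings: list[RawRecording] = []
    truths: dict[str, RecordingTruth] = {}
    score_frames: list[pd.DataFrame] = []
    k = 0
    for gi, group in enumerate(GROUPS):
        n = config.group_sizes.get(group, 0)
        if n == 0:
            continue
        scores = generate_scores(
            group,
            n,
            config.score_table,
            seed=np.random.default_rng(children[n_total + gi]),
        )
        ids = [f"{group}{i + 1:03d}" for i in range(n)]
        scores.insert(0, "group", group)
        scores.insert(0, "subject_id", ids)
        score_frames.append(scores)
        for sid in ids:
            rec, truth = generate_recording(
                config.coupling[group],
                config,
                seed=np.random.default_rng(children[k]),
                subject_id=sid,
            )
            truth.group = group
            recordings.append(rec)
            truths[sid] = truth
            k += 1
    scores_df = pd.concat(score_frames, ignore_index=True)
    return CohortDataset(recordings=recordings, scores=scores_df, ground_truth=truths)
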