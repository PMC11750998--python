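"""Continuous-wave fNIRS preprocessing.

Turns raw two-wavelength light-intensity recordings into artifact-corrected,
band-limited oxy-/deoxy-hemoglobin concentration-change series. The chain is
the standard resting-state one for a prefrontal continuous-wave device:

1. prune channels whose raw-intensity SNR falls below a dB threshold,
2. convert intensity to optical density (OD),
3. detect motion artifacts per channel (sliding-window excursion test),
4. correct flagged segments with a smoothing spline and level re-anchoring,
5. zero-phase Butterworth band-pass (0.01-0.1 Hz by default),
6. optionally project out leading principal components across channels
   (superficial/global physiology),
7. invert the modified Beer-Lambert law to HbO/HbR/HbT concentration changes.

All stage functions are pure (they return new containers); the driver
`preprocess_recording` applies them in order and keeps the intermediates.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal
from scipy.interpolate import make_smoothing_spline
from scipy.ndimage import maximum_filter1d, minimum_filter1d

__all__ = [
    "RawRecording",
    "PreprocessConfig",
    "OpticalDensitySeries",
    "ConcentrationSeries",
    "PreprocessResult",
    "EXTINCTION_TABLES",
    "prune_channels_by_snr",
    "intensity_to_od",
    "detect_motion_artifacts_by_channel",
    "spline_correct",
    "bandpass_filter",
    "pca_filter",
    "od_to_concentration",
    "preprocess_recording",
]

# Named molar extinction tables, units uM^-1 cm^-1, rows = wavelength
# (780, 850 nm), columns = (HbO, HbR). "prahl2002" is the standard
# compiled hemoglobin spectrum used by CW-fNIRS conversion routines.
EXTINCTION_TABLES: dict[str, np.ndarray] = {
    "prahl2002": np.array(
        [
            [7.10e-4, 1.07544e-3],  # 780 nm
            [1.058e-3, 6.9132e-4],  # 850 nm
        ]
    ),
}


@dataclass
class RawRecording:
    """A single-subject intensity recording, time x channel x wavelength."""

    intensity: np.ndarray
    sampling_rate_hz: float
    wavelengths_nm: tuple[float, float] = (780.0, 850.0)
    source_detector_distance_cm: float = 3.0
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.intensity.ndim != 3 or self.intensity.shape[2] != 2:
            raise ValueError(
                "intensity must be (time, channels, 2 wavelengths), got "
                f"{self.intensity.shape}"
            )
        if self.intensity.shape[0] < 2:
            raise ValueError("recording needs at least 2 time samples")
        if len(self.wavelengths_nm) != 2:
            raise ValueError("exactly two wavelengths required")
        if not np.all(self.intensity > 0):
            raise ValueError("intensities must be strictly positive")
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling rate must be positive")

    @property
    def n_samples(self) -> int:
        return self.intensity.shape[0]

    @property
    def n_channels(self) -> int:
        return self.intensity.shape[1]


@dataclass
class PreprocessConfig:
    """Parameters of the preprocessing chain (defaults are the pipeline's
    operating point for the NIRSIT montage)."""

    snr_threshold_db: float = 25.0
    t_motion_s: float = 2.0
    t_mask_s: float = 4.0
    stdev_thresh: float = 50.0
    amp_thresh: float = 5.0
    spline_p: float = 0.99
    hpf_hz: float = 0.01
    lpf_hz: float = 0.1
    pca_remove: int = 1
    ppf: float = 6.0
    extinction_table: str = "prahl2002"

    def validate(self, sampling_rate_hz: float) -> None:
        if not (0 < self.hpf_hz < self.lpf_hz < sampling_rate_hz / 2):
            raise ValueError(
                "need 0 < hpf < lpf < Nyquist, got "
                f"hpf={self.hpf_hz}, lpf={self.lpf_hz}, fs={sampling_rate_hz}"
            )
        if not (0 < self.spline_p <= 1):
            raise ValueError("spline_p must be in (0, 1]")
        if self.ppf <= 0:
            raise ValueError("ppf must be positive")
        if self.pca_remove < 0:
            raise ValueError("pca_remove must be >= 0")
        eps = extinction_matrix(self.extinction_table)
        if abs(np.linalg.det(eps)) < 1e-18:
            raise ValueError("extinction matrix is singular")


def extinction_matrix(table: str | np.ndarray) -> np.ndarray:
    """Resolve a named (or literal 2x2) extinction table, uM^-1 cm^-1."""
    if isinstance(table, str):
        try:
            return EXTINCTION_TABLES[table]
        except KeyError:
            raise KeyError(
                f"unknown extinction table {table!r}; "
                f"available: {sorted(EXTINCTION_TABLES)}"
            ) from None
    eps = np.asarray(table, dtype=float)
    if eps.shape != (2, 2):
        raise ValueError("extinction table must be 2x2 (wavelength x chromophore)")
    return eps


@dataclass
class OpticalDensitySeries:
    """Optical density, time x channel x wavelength, with bookkeeping."""

    od: np.ndarray
    sampling_rate_hz: float
    artifact_mask: np.ndarray | None = None  # bool, time x channel
    pruned_channels: frozenset[int] = frozenset()

    def __post_init__(self) -> None:
        self.od = np.asarray(self.od, dtype=float)
        if not np.all(np.isfinite(self.od)):
            raise ValueError("optical density must be finite")
        if self.artifact_mask is not None:
            self.artifact_mask = np.asarray(self.artifact_mask, dtype=bool)
            if self.artifact_mask.shape != self.od.shape[:2]:
                raise ValueError("artifact mask must be (time, channels)")


@dataclass
class ConcentrationSeries:
    """Relative concentration changes (uM), time x channel, per chromophore."""

    hbo: np.ndarray
    hbr: np.ndarray
    hbt: np.ndarray
    sampling_rate_hz: float
    pruned_channels: frozenset[int] = frozenset()

    def __post_init__(self) -> None:
        if not (self.hbo.shape == self.hbr.shape == self.hbt.shape):
            raise ValueError("hbo/hbr/hbt shapes must agree")


@dataclass
class PreprocessResult:
    """Output of the full chain plus auditable intermediates and a log."""

    concentration: ConcentrationSeries | None
    excluded: bool
    pruned_channels: frozenset[int]
    intermediates: dict[str, OpticalDensitySeries] = field(default_factory=dict)
    log: list[str] = field(default_factory=list)


def prune_channels_by_snr(
    rec: RawRecording, threshold_db: float = 25.0
) -> frozenset[int]:
    """Identify bad channels by raw-intensity SNR.

    SNR_dB = 20*log10(mean(I)/sd(I)) per channel and wavelength; a channel
    is pruned when SNR falls below ``threshold_db`` at either wavelength.
    A constant channel (sd = 0) has infinite SNR and is kept. Returns the
    0-based ids of pruned channels; the recording is not mutated.
    """
    mean = rec.intensity.mean(axis=0)  # (channel, wavelength)
    sd = rec.intensity.std(axis=0, ddof=0)
    with np.errstate(divide="ignore"):
        snr = 20.0 * np.log10(np.where(sd > 0, mean / sd, np.inf))
    bad = np.any(snr < threshold_db, axis=1)
    return frozenset(np.nonzero(bad)[0].tolist())


def intensity_to_od(rec: RawRecording) -> OpticalDensitySeries:
    """Convert intensity to optical density: od = -ln(I / temporal mean I).

    Invariant to per-channel intensity scaling (a gain change at the
    detector does not alter OD).
    """
    if not np.all(rec.intensity > 0):
        t, c, w = np.unravel_index(
            int(np.argmin(rec.intensity)), rec.intensity.shape
        )
        raise ValueError(
            f"nonpositive intensity at sample {t}, channel {c}, wavelength {w}"
        )
    od = -np.log(rec.intensity / rec.intensity.mean(axis=0, keepdims=True))
    return OpticalDensitySeries(od=od, sampling_rate_hz=rec.sampling_rate_hz)


def detect_motion_artifacts_by_channel(
    od: OpticalDensitySeries,
    t_motion_s: float = 2.0,
    t_mask_s: float = 4.0,
    stdev_thresh: float = 50.0,
    amp_thresh: float = 5.0,
) -> np.ndarray:
    """Flag motion-artifact samples per channel.

    For every sliding window of ``t_motion_s`` seconds the peak-to-peak
    excursion is compared against ``stdev_thresh`` times the channel's
    baseline OD standard deviation and against the absolute OD threshold
    ``amp_thresh``; windows exceeding either are flagged, then dilated by
    ``t_mask_s`` on each side. The baseline SD is computed in two passes:
    a robust (MAD-scaled) estimate first — so the artifacts themselves do
    not inflate the baseline — then an ordinary SD over the samples the
    first pass left unflagged. The returned mask (time x channel) is the
    union over both wavelengths.
    """
    if t_mask_s < 0:
        raise ValueError("t_mask_s must be >= 0")
    fs = od.sampling_rate_hz
    n_t, n_ch, n_wl = od.od.shape
    win = max(int(round(t_motion_s * fs)), 1)
    pad = int(round(t_mask_s * fs))

    def _excursion(x: np.ndarray) -> np.ndarray:
        # centered peak-to-peak over a window of `win` samples, per column
        hi = maximum_filter1d(x, size=win, axis=0, mode="nearest")
        lo = minimum_filter1d(x, size=win, axis=0, mode="nearest")
        return hi - lo

    def _flag(x: np.ndarray, sd: np.ndarray) -> np.ndarray:
        exc = _excursion(x)
        return (exc > stdev_thresh * sd) | (exc > amp_thresh)

    mask = np.zeros((n_t, n_ch), dtype=bool)
    for w in range(n_wl):
        x = od.od[:, :, w]
        mad = np.median(np.abs(x - np.median(x, axis=0)), axis=0)
        sd0 = np.where(mad > 0, 1.4826 * mad, x.std(axis=0, ddof=0))
        first = _flag(x, sd0)
        # second pass: baseline SD from artifact-free samples only
        sd1 = np.empty(n_ch)
        for c in range(n_ch):
            clean = x[~first[:, c], c]
            sd1[c] = clean.std(ddof=0) if clean.size >= 2 else sd0[c]
        mask |= _flag(x, sd1)

    if pad > 0:
        mask = maximum_filter1d(
            mask.astype(np.uint8), size=2 * pad + 1, axis=0, mode="constant"
        ).astype(bool)
    return mask


def _segments(flags: np.ndarray) -> list[tuple[int, int]]:
    """Contiguous True runs of a boolean vector as [start, stop) pairs."""
    if not flags.any():
        return []
    d = np.diff(flags.astype(np.int8))
    starts = list(np.nonzero(d == 1)[0] + 1)
    stops = list(np.nonzero(d == -1)[0] + 1)
    if flags[0]:
        starts.insert(0, 0)
    if flags[-1]:
        stops.append(len(flags))
    return list(zip(starts, stops))


def spline_correct(
    od: OpticalDensitySeries,
    artifact_mask: np.ndarray,
    spline_p: float = 0.99,
) -> OpticalDensitySeries:
    """Correct flagged motion segments with a smoothing spline.

    Within each flagged segment a smoothing spline (roughness trade-off
    parameter p, csaps convention) is fitted and subtracted, removing the
    artifact's slow trajectory while keeping the residual signal. Segments
    are then re-anchored with level shifts so the series stays continuous
    across segment boundaries; clean stretches keep their shape but may be
    shifted as a whole (this is what removes baseline-shift artifacts).
    Segments too short for a spline fit are linearly detrended instead.
    """
    artifact_mask = np.asarray(artifact_mask, dtype=bool)
    if artifact_mask.shape != od.od.shape[:2]:
        raise ValueError("mask must align with od (time, channels)")
    if not artifact_mask.any():
        return replace(od, artifact_mask=artifact_mask)

    lam = (1.0 - spline_p) / spline_p  # csaps p -> smoothing penalty
    out = od.od.copy()
    n_t = out.shape[0]
    for c in range(out.shape[1]):
        flags = artifact_mask[:, c]
        segs = _segments(flags)
        if not segs:
            continue
        for w in range(out.shape[2]):
            y = out[:, c, w]
            corrected = y.copy()
            for start, stop in segs:
                t = np.arange(start, stop, dtype=float)
                seg = y[start:stop]
                if len(seg) >= 4 and lam > 0:
                    trend = make_smoothing_spline(t, seg, lam=lam)(t)
                elif len(seg) >= 2:
                    coef = np.polyfit(t, seg, 1)
                    trend = np.polyval(coef, t)
                else:
                    trend = seg.copy()
                corrected[start:stop] = seg - trend
            # re-anchor: stitch segments with short-window mean levels so
            # boundaries are continuous without chasing single-sample noise
            wlen = max(int(round(od.sampling_rate_hz / 3)), 1)
            boundaries = sorted({s for s, _ in segs} | {e for _, e in segs})
            stitched = corrected.copy()
            for b in boundaries:
                if b == 0 or b >= n_t:
                    continue
                prev = stitched[max(b - wlen, 0) : b]
                cur = stitched[b : min(b + wlen, n_t)]
                stitched[b:] += prev.mean() - cur.mean()
            stitched += y[0] - stitched[0]
            out[:, c, w] = stitched
    return replace(od, od=out, artifact_mask=artifact_mask)


def bandpass_filter(
    od: OpticalDensitySeries, hpf_hz: float = 0.01, lpf_hz: float = 0.1
) -> OpticalDensitySeries:
    """Zero-phase band-pass: 3rd-order Butterworth run forward-backward.

    Passband gain is within a few percent at mid-band; DC and the cardiac
    (~1 Hz), respiratory (~0.25 Hz) and instrument drift components are
    strongly attenuated. Forward-backward application squares the magnitude
    response and cancels the phase, so band-limited components keep zero lag.
    """
    fs = od.sampling_rate_hz
    nyq = fs / 2
    if not (0 < hpf_hz < lpf_hz < nyq):
        raise ValueError(f"need 0 < hpf < lpf < Nyquist ({nyq} Hz)")
    sos = signal.butter(3, [hpf_hz, lpf_hz], btype="bandpass", fs=fs, output="sos")
    filtered = signal.sosfiltfilt(sos, od.od, axis=0)
    return replace(od, od=filtered)


def pca_filter(od: OpticalDensitySeries, pca_remove: int = 1) -> OpticalDensitySeries:
    """Project out the leading principal components across channels.

    Per wavelength, the channels-by-time OD matrix (pruned channels
    excluded) is decomposed and the ``pca_remove`` largest-variance
    components — typically superficial/global physiology common to many
    channels — are removed. ``pca_remove=0`` is the identity.
    """
    if pca_remove < 0:
        raise ValueError("pca_remove must be >= 0")
    keep = [c for c in range(od.od.shape[1]) if c not in od.pruned_channels]
    if pca_remove >= len(keep):
        raise ValueError(
            f"pca_remove={pca_remove} must be < number of unpruned channels "
            f"({len(keep)})"
        )
    if pca_remove == 0:
        return replace(od, od=od.od.copy())
    out = od.od.copy()
    for w in range(out.shape[2]):
        x = out[:, keep, w]  # time x channels
        mu = x.mean(axis=0, keepdims=True)
        xc = x - mu
        # principal directions of the channel covariance via SVD
        _, _, vt = np.linalg.svd(xc, full_matrices=False)
        basis = vt[:pca_remove]  # (k, channels)
        xc -= xc @ basis.T @ basis
        out[:, keep, w] = xc + mu
    return replace(od, od=out)


def od_to_concentration(
    od: OpticalDensitySeries,
    ppf: float = 6.0,
    distance_cm: float = 3.0,
    extinction_table: str | np.ndarray = "prahl2002",
) -> ConcentrationSeries:
    """Invert the modified Beer-Lambert law to concentration changes.

    Solves, per channel and sample, the 2x2 linear system
    ``dOD_w = (eps_HbO,w * dHbO + eps_HbR,w * dHbR) * d * ppf`` for the two
    wavelengths, with d the source-detector distance and ppf the partial
    pathlength factor. HbT = HbO + HbR by definition.
    """
    eps = extinction_matrix(extinction_table)
    if abs(np.linalg.det(eps)) < 1e-18:
        raise ValueError("extinction matrix is singular")
    inv = np.linalg.inv(eps) / (distance_cm * ppf)
    # od: (t, c, w) -> conc: (t, c, chromophore)
    conc = od.od @ inv.T
    hbo = conc[:, :, 0]
    hbr = conc[:, :, 1]
    return ConcentrationSeries(
        hbo=hbo,
        hbr=hbr,
        hbt=hbo + hbr,
        sampling_rate_hz=od.sampling_rate_hz,
        pruned_channels=od.pruned_channels,
    )


def mbll_forward(
    hbo: np.ndarray,
    hbr: np.ndarray,
    ppf: float = 6.0,
    distance_cm: float = 3.0,
    extinction_table: str | np.ndarray = "prahl2002",
) -> np.ndarray:
    """Forward modified Beer-Lambert map: concentrations (uM) to dOD.

    Returns an array shaped like ``hbo`` with a trailing wavelength axis.
    Exact inverse of :func:`od_to_concentration` for the same table.
    """
    eps = extinction_matrix(extinction_table)
    conc = np.stack([np.asarray(hbo, float), np.asarray(hbr, float)], axis=-1)
    return (conc @ eps.T) * (distance_cm * ppf)


def preprocess_recording(
    rec: RawRecording, config: PreprocessConfig | None = None
) -> PreprocessResult:
    """Run the full preprocessing chain on one recording.

    Stage order: SNR pruning -> OD conversion -> motion detection ->
    spline correction -> band-pass -> PCA -> Beer-Lambert inversion.
    If every channel is pruned the subject is marked excluded (not an
    exception), mirroring real-cohort quality exclusions.
    """
    config = config or PreprocessConfig()
    config.validate(rec.sampling_rate_hz)
    log: list[str] = []

    pruned = prune_channels_by_snr(rec, config.snr_threshold_db)
    log.append(f"pruned {len(pruned)}/{rec.n_channels} channels: {sorted(pruned)}")
    if len(pruned) == rec.n_channels:
        log.append("all channels pruned -> subject excluded")
        return PreprocessResult(
            concentration=None, excluded=True, pruned_channels=pruned, log=log
        )

    od = intensity_to_od(rec)
    od = replace(od, pruned_channels=pruned)
    intermediates = {"od": od}

    mask = detect_motion_artifacts_by_channel(
        od,
        t_motion_s=config.t_motion_s,
        t_mask_s=config.t_mask_s,
        stdev_thresh=config.stdev_thresh,
        amp_thresh=config.amp_thresh,
    )
    frac = float(mask.mean())
    log.append(f"motion artifacts: {100 * frac:.2f}% of samples flagged")

    corrected = spline_correct(od, mask, spline_p=config.spline_p)
    intermediates["motion_corrected"] = corrected

    filtered = bandpass_filter(corrected, config.hpf_hz, config.lpf_hz)
    intermediates["bandpassed"] = filtered

    if config.pca_remove > 0:
        filtered = pca_filter(filtered, config.pca_remove)
        intermediates["pca_filtered"] = filtered
        log.append(f"PCA: removed {config.pca_remove} component(s)")

    conc = od_to_concentration(
        filtered,
        ppf=config.ppf,
        distance_cm=rec.source_detector_distance_cm,
        extinction_table=config.extinction_table,
    )
    return PreprocessResult(
        concentration=conc,
        excluded=False,
        pruned_channels=pruned,
        intermediates=intermediates,
        log=log,
    )
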