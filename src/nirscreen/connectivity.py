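"""ROI-level functional connectivity: band-averaged coherence and PLV.

Channel concentration series are averaged within each ROI of the montage,
then every ROI pair is scored with two complementary coupling estimators
restricted to the resting-state hemodynamic band (0.01-0.1 Hz):

- COH: Welch magnitude-squared coherence averaged over band frequencies —
  linear amplitude/frequency coupling;
- PLV: phase-locking value of the analytic-signal instantaneous phases —
  phase synchronization independent of amplitude.

Both estimators live in [0, 1] and equal 1 for a series against itself.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .montage import N_ROIS, RoiMap, roi_channel_map
from .preprocess import ConcentrationSeries

__all__ = [
    "ROITimeSeries",
    "FCMatrixSet",
    "DegeneratePairError",
    "CHROMOPHORES",
    "ESTIMATORS",
    "average_rois",
    "coherence_fc",
    "plv_fc",
    "fc_matrix_set",
    "fc_feature_names",
]

CHROMOPHORES = ("hbo", "hbr", "hbt")
ESTIMATORS = ("coh", "plv")
DEFAULT_BAND = (0.01, 0.1)


class DegeneratePairError(ValueError):
    """Raised when an estimator is undefined (e.g. a constant input series)."""


@dataclass
class ROITimeSeries:
    """ROI-averaged concentrations: time x ROI x chromophore.

    ``n_contributing`` counts the unpruned channels behind each ROI; a ROI
    with zero contributing channels is invalid and its pairs are missing.
    """

    series: np.ndarray  # (time, n_rois, 3)
    sampling_rate_hz: float
    n_contributing: np.ndarray  # (n_rois,)

    @property
    def valid(self) -> np.ndarray:
        return self.n_contributing > 0

    @property
    def n_rois(self) -> int:
        return self.series.shape[1]


@dataclass
class FCMatrixSet:
    """Symmetric unit-diagonal FC matrices per estimator x chromophore.

    ``matrices[est][chrom]`` is an (n_rois, n_rois) array; entries for
    invalid/degenerate pairs are NaN (missing).
    """

    matrices: dict[str, dict[str, np.ndarray]]
    band_hz: tuple[float, float] = DEFAULT_BAND

    @property
    def n_rois(self) -> int:
        first = next(iter(next(iter(self.matrices.values())).values()))
        return first.shape[0]

    def to_feature_vector(self) -> np.ndarray:
        """Flatten to the fixed feature ordering: estimator -> chromophore ->
        upper-triangle pairs (i < j)."""
        n = self.n_rois
        iu = np.triu_indices(n, k=1)
        parts = [
            self.matrices[est][ch][iu]
            for est in ESTIMATORS
            for ch in CHROMOPHORES
            if est in self.matrices and ch in self.matrices[est]
        ]
        return np.concatenate(parts)


def fc_feature_names(n_rois: int = N_ROIS) -> list[str]:
    """Column names matching :meth:`FCMatrixSet.to_feature_vector` order."""
    iu = np.triu_indices(n_rois, k=1)
    return [
        f"{est}_{ch}_ROI{i + 1}_ROI{j + 1}"
        for est in ESTIMATORS
        for ch in CHROMOPHORES
        for i, j in zip(*iu)
    ]


def average_rois(
    conc: ConcentrationSeries, roi_map: RoiMap | None = None
) -> ROITimeSeries:
    """Average channel concentrations within each ROI (unweighted mean over
    unpruned member channels). ROIs whose member channels are all pruned are
    flagged invalid (zero contributing channels, NaN series)."""
    roi_map = roi_map or roi_channel_map()
    stacks = {"hbo": conc.hbo, "hbr": conc.hbr, "hbt": conc.hbt}
    n_t = conc.hbo.shape[0]
    roi_ids = roi_map.roi_ids
    series = np.full((n_t, len(roi_ids), len(CHROMOPHORES)), np.nan)
    n_contrib = np.zeros(len(roi_ids), dtype=int)
    for r, roi in enumerate(roi_ids):
        idx = [c for c in roi_map.channel_indices(roi) if c not in conc.pruned_channels]
        n_contrib[r] = len(idx)
        if not idx:
            continue
        for k, ch in enumerate(CHROMOPHORES):
            series[:, r, k] = stacks[ch][:, idx].mean(axis=1)
    return ROITimeSeries(
        series=series,
        sampling_rate_hz=conc.sampling_rate_hz,
        n_contributing=n_contrib,
    )


def _check_pair(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("series must be 1-D and of equal length")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegeneratePairError("constant series: estimator undefined")
    return x, y


def coherence_fc(
    x: np.ndarray,
    y: np.ndarray,
    band: tuple[float, float] = DEFAULT_BAND,
    rate_hz: float = 8.138,
    seg_len_s: float = 120.0,
) -> float:
    """Band-averaged Welch magnitude-squared coherence of two series.

    |S_xy|^2 / (S_xx * S_yy) is estimated with Hann windows of
    ``seg_len_s`` seconds at 50% overlap and averaged over the frequencies
    falling in ``band``; the result is clipped to [0, 1]. Invariant to
    affine rescaling of either input.
    """
    x, y = _check_pair(x, y)
    # cap the segment length so short records still yield >= ~3 averaged
    # segments (a single segment makes coherence identically 1)
    nperseg = min(int(round(seg_len_s * rate_hz)), len(x) // 2)
    nperseg = max(nperseg, 8)
    f, cxy = signal.coherence(
        x, y, fs=rate_hz, window="hann", nperseg=nperseg, noverlap=nperseg // 2
    )
    in_band = (f >= band[0]) & (f <= band[1])
    if not in_band.any():
        raise ValueError("no spectral bins fall inside the analysis band")
    return float(np.clip(np.nanmean(cxy[in_band]), 0.0, 1.0))


def plv_fc(
    x: np.ndarray,
    y: np.ndarray,
    band: tuple[float, float] = DEFAULT_BAND,
    rate_hz: float = 8.138,
    edge_frac: float = 0.05,
) -> float:
    """Phase-locking value of two series within the analysis band.

    Both series are zero-phase band-limited to ``band``, instantaneous
    phases are taken from the analytic (Hilbert) signal, and
    PLV = |mean_t exp(i (phi_x - phi_y))|. A fraction ``edge_frac`` of
    samples at each end is discarded before averaging to suppress
    analytic-signal edge effects.
    """
    x, y = _check_pair(x, y)
    sos = signal.butter(3, band, btype="bandpass", fs=rate_hz, output="sos")
    xb = signal.sosfiltfilt(sos, x)
    yb = signal.sosfiltfilt(sos, y)
    phx = np.angle(signal.hilbert(xb))
    phy = np.angle(signal.hilbert(yb))
    n = len(x)
    trim = int(edge_frac * n)
    sl = slice(trim, n - trim) if trim > 0 else slice(None)
    plv = np.abs(np.mean(np.exp(1j * (phx[sl] - phy[sl]))))
    return float(np.clip(plv, 0.0, 1.0))


def fc_matrix_set(
    roits: ROITimeSeries,
    band: tuple[float, float] = DEFAULT_BAND,
    coh_seg_len_s: float = 120.0,
) -> FCMatrixSet:
    """Compute the full estimator x chromophore stack of ROI-pair FC
    matrices: symmetric, unit diagonal, invalid/degenerate pairs NaN."""
    n = roits.n_rois
    valid = roits.valid
    out: dict[str, dict[str, np.ndarray]] = {e: {} for e in ESTIMATORS}
    for k, ch in enumerate(CHROMOPHORES):
        mats = {e: np.full((n, n), np.nan) for e in ESTIMATORS}
        for e in ESTIMATORS:
            np.fill_diagonal(mats[e], 1.0)
        for i in range(n):
            for j in range(i + 1, n):
                if not (valid[i] and valid[j]):
                    continue
                x = roits.series[:, i, k]
                y = roits.series[:, j, k]
                try:
                    coh = coherence_fc(
                        x, y, band, roits.sampling_rate_hz, coh_seg_len_s
                    )
                    plv = plv_fc(x, y, band, roits.sampling_rate_hz)
                except DegeneratePairError:
                    continue
                mats["coh"][i, j] = mats["coh"][j, i] = coh
                mats["plv"][i, j] = mats["plv"][j, i] = plv
        for e in ESTIMATORS:
            out[e][ch] = mats[e]
    return FCMatrixSet(matrices=out, band_hz=band)
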