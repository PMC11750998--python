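"""SNIRF (Shared Near-Infrared Spectroscopy Format) reading and writing.

SNIRF is an HDF5 container; recordings are stored as a time x measurement
matrix with one measurement-list entry per (channel, wavelength) column.
Only the two-wavelength continuous-wave layout of the 48-channel prefrontal
montage is supported. Channel ids (1-48) are carried in the source/detector
indices so a round trip preserves the montage ordering exactly.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np

from .preprocess import ConcentrationSeries, RawRecording

__all__ = ["write_snirf", "read_snirf", "write_concentration", "read_concentration"]

_FORMAT_VERSION = "1.0"


def write_snirf(rec: RawRecording, path: str | Path) -> None:
    """Write a recording as a CW-SNIRF file (dataType 1, amplitude)."""
    n_t, n_ch, n_wl = rec.intensity.shape
    data = rec.intensity.reshape(n_t, n_ch * n_wl)
    with h5py.File(path, "w") as f:
        f.create_dataset("formatVersion", data=_FORMAT_VERSION)
        nirs = f.create_group("nirs")
        meta = nirs.create_group("metaDataTags")
        meta.create_dataset("SubjectID", data=rec.subject_id or "unknown")
        meta.create_dataset("MeasurementDate", data="unknown")
        meta.create_dataset("MeasurementTime", data="unknown")
        meta.create_dataset("LengthUnit", data="cm")
        meta.create_dataset("TimeUnit", data="s")
        meta.create_dataset("FrequencyUnit", data="Hz")
        meta.create_dataset(
            "SourceDetectorDistance", data=rec.source_detector_distance_cm
        )
        probe = nirs.create_group("probe")
        probe.create_dataset(
            "wavelengths", data=np.asarray(rec.wavelengths_nm, dtype=float)
        )
        pos = np.zeros((n_ch, 3))
        pos[:, 0] = np.arange(n_ch)
        probe.create_dataset("sourcePos3D", data=pos)
        probe.create_dataset("detectorPos3D", data=pos)
        d1 = nirs.create_group("data1")
        d1.create_dataset("dataTimeSeries", data=data)
        d1.create_dataset(
            "time", data=np.arange(n_t, dtype=float) / rec.sampling_rate_hz
        )
        k = 1
        for ch in range(n_ch):
            for wl in range(n_wl):
                ml = d1.create_group(f"measurementList{k}")
                ml.create_dataset("sourceIndex", data=ch + 1)
                ml.create_dataset("detectorIndex", data=ch + 1)
                ml.create_dataset("wavelengthIndex", data=wl + 1)
                ml.create_dataset("dataType", data=1)
                ml.create_dataset("dataTypeIndex", data=1)
                k += 1


def _as_str(v) -> str:
    v = v[()] if hasattr(v, "shape") else v
    return v.decode() if isinstance(v, bytes) else str(v)


def read_snirf(
    path: str | Path,
    expected_rate_hz: float | None = None,
    rate_tol: float = 1e-3,
) -> RawRecording:
    """Read a two-wavelength CW-SNIRF recording into a RawRecording.

    The measurement list maps columns back to (channel, wavelength); files
    with a single wavelength or a mismatching sampling rate are rejected.
    """
    with h5py.File(path, "r") as f:
        nirs = f["nirs"] if "nirs" in f else f["nirs1"]
        d1 = nirs["data1"]
        data = np.asarray(d1["dataTimeSeries"])
        time = np.asarray(d1["time"])
        wavelengths = np.asarray(nirs["probe"]["wavelengths"], dtype=float)
        if wavelengths.size != 2:
            raise ValueError(
                f"expected a two-wavelength recording, found {wavelengths.size}"
            )
        if time.size == 2:  # [start, dt] form
            dt = float(time[1])
        else:
            dt = float(np.median(np.diff(time)))
        rate = 1.0 / dt
        if expected_rate_hz is not None and abs(rate - expected_rate_hz) > rate_tol:
            raise ValueError(
                f"sampling rate {rate:.4f} Hz does not match the expected "
                f"{expected_rate_hz:.4f} Hz"
            )
        ml_names = sorted(
            (k for k in d1 if k.startswith("measurementList")),
            key=lambda s: int(s[len("measurementList"):]),
        )
        if len(ml_names) != data.shape[1]:
            raise ValueError("measurement list does not match data columns")
        channels = []
        for name in ml_names:
            ml = d1[name]
            channels.append(
                (int(ml["sourceIndex"][()]), int(ml["wavelengthIndex"][()]))
            )
        wl_seen = {w for _, w in channels}
        if wl_seen != {1, 2}:
            raise ValueError("file must contain both wavelength indices 1 and 2")
        ch_ids = sorted({c for c, _ in channels})
        n_ch = len(ch_ids)
        ch_pos = {c: i for i, c in enumerate(ch_ids)}
        intensity = np.empty((data.shape[0], n_ch, 2))
        for col, (ch, wl) in enumerate(channels):
            intensity[:, ch_pos[ch], wl - 1] = data[:, col]
        meta = nirs["metaDataTags"]
        sid = _as_str(meta["SubjectID"]) if "SubjectID" in meta else ""
        dist = (
            float(meta["SourceDetectorDistance"][()])
            if "SourceDetectorDistance" in meta
            else 3.0
        )
    return RawRecording(
        intensity=intensity,
        sampling_rate_hz=rate,
        wavelengths_nm=(float(wavelengths[0]), float(wavelengths[1])),
        source_detector_distance_cm=dist,
        subject_id=sid,
    )


def write_concentration(conc: ConcentrationSeries, path: str | Path) -> None:
    """Store a concentration series as HDF5 (datasets hbo/hbr/hbt)."""
    with h5py.File(path, "w") as f:
        for name in ("hbo", "hbr", "hbt"):
            f.create_dataset(name, data=getattr(conc, name))
        f.attrs["sampling_rate_hz"] = conc.sampling_rate_hz
        f.attrs["pruned_channels"] = sorted(conc.pruned_channels)


def read_concentration(path: str | Path) -> ConcentrationSeries:
    with h5py.File(path, "r") as f:
        return ConcentrationSeries(
            hbo=np.asarray(f["hbo"]),
            hbr=np.asarray(f["hbr"]),
            hbt=np.asarray(f["hbt"]),
            sampling_rate_hz=float(f.attrs["sampling_rate_hz"]),
            pruned_channels=frozenset(
                int(c) for c in np.asarray(f.attrs["pruned_channels"]).ravel()
            ),
        )
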