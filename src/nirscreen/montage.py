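"""Prefrontal probe montage: the fixed 48-channel / 10-ROI layout.

The NIRSIT prefrontal montage has 48 source-detector channels at 3.0 cm
separation. Channels are grouped into ten regions of interest (ROIs)
covering the prefrontal subregions: right/left dorsolateral prefrontal
cortex (DLPFC), the DLPFC/rostral-PFC border regions, right/left medial
PFC, right/left orbitofrontal cortex (OFC) and right/left ventrolateral
PFC (VLPFC). ROI ids run 1..10; channel ids run 1..48.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = ["RoiMap", "roi_channel_map", "N_CHANNELS", "N_ROIS"]

N_CHANNELS = 48
N_ROIS = 10

_ROI_CHANNELS: dict[int, tuple[int, ...]] = {
    1: (1, 2, 6, 7, 11, 12),
    2: (34, 35, 37, 38, 42, 43),
    3: (3, 8, 13, 17, 21, 25),
    4: (20, 24, 28, 33, 36, 41),
    5: (18, 22, 26),
    6: (19, 23, 27),
    7: (14, 15, 16, 29, 30),
    8: (31, 32, 46, 47, 48),
    9: (4, 5, 9, 10),
    10: (39, 40, 44, 45),
}

_ROI_LABELS: dict[int, str] = {
    1: "right DLPFC",
    2: "left DLPFC",
    3: "right DLPFC/RPFC",
    4: "left DLPFC/RPFC",
    5: "right MPFC",
    6: "left MPFC",
    7: "right OFC",
    8: "left OFC",
    9: "right VLPFC",
    10: "left VLPFC",
}


@dataclass(frozen=True)
class RoiMap:
    """Mapping of ROI id (1-10) to its ordered member channel ids (1-48)."""

    channels: dict[int, tuple[int, ...]] = field(
        default_factory=lambda: dict(_ROI_CHANNELS)
    )
    labels: dict[int, str] = field(default_factory=lambda: dict(_ROI_LABELS))

    def __post_init__(self) -> None:
        all_channels: list[int] = []
        for roi, chans in self.channels.items():
            if len(set(chans)) != len(chans):
                raise ValueError(f"ROI {roi} lists a channel twice: {chans}")
            all_channels.extend(chans)
        if len(set(all_channels)) != len(all_channels):
            raise ValueError("ROI channel sets are not pairwise disjoint")

    @property
    def roi_ids(self) -> tuple[int, ...]:
        return tuple(sorted(self.channels))

    @property
    def n_channels(self) -> int:
        return sum(len(c) for c in self.channels.values())

    def channel_indices(self, roi: int) -> list[int]:
        """0-based channel indices for a ROI (channel id minus one)."""
        return [c - 1 for c in self.channels[roi]]


def roi_channel_map() -> RoiMap:
    """Return the fixed prefrontal channel-to-ROI partition.

    The ten ROIs partition the 48 channels disjointly with per-ROI
    channel counts (6, 6, 6, 6, 3, 3, 5, 5, 4, 4).
    """
    return RoiMap()
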