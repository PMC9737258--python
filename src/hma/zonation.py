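"""Concentric-zone ("circular sector") quantification of microwell aggregate images.

A 500-μm microwell is partitioned into ``n_zones`` concentric annuli of equal
radial width (Zone 1 innermost, Zone ``n`` outermost).  For every fluorescence
channel, pixels above a threshold are counted per zone and per z-slice, summed
over z, converted to μm² and normalised to occupancy fractions.  This is the
morphometric readout used to call a labeled cell population "internal"
(signal concentrated in the inner zones, strong homotypic affinity) or
"external" (signal at the periphery, weak affinity).

Zonation is cylindrical: the radius is measured in the xy plane only and each
z-slice is binned with the same mask.  Pixel distances use pixel-center
coordinates (0-based indices scaled by ``um_per_px``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Mapping

import numpy as np
import pandas as pd
from skimage.filters import threshold_otsu

__all__ = [
    "WellGeometry",
    "MultichannelStack",
    "CenterEstimate",
    "ChannelZones",
    "ZoneProfile",
    "locate_well_center",
    "zone_mask",
    "quantify_zones",
]


@dataclass(frozen=True)
class WellGeometry:
    """Physical description of one microwell and its zone partition.

    Parameters
    ----------
    diameter_um:
        Well diameter in μm.  Default 500 (the standard microwell array).
    n_zones:
        Number of equal-width concentric zones.  Default 5 (Zones I–V).
    um_per_px:
        Image scale in μm per pixel.
    center_um:
        Optional well center as ``(y, x)`` in μm.  When absent the center is
        estimated from the image (intensity-weighted centroid).
    """

    diameter_um: float = 500.0
    n_zones: int = 5
    um_per_px: float = 1.0
    center_um: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if not self.diameter_um > 0:
            raise ValueError(f"diameter_um must be > 0, got {self.diameter_um}")
        if not self.n_zones >= 1:
            raise ValueError(f"n_zones must be >= 1, got {self.n_zones}")
        if not self.um_per_px > 0:
            raise ValueError(f"um_per_px must be > 0, got {self.um_per_px}")

    @property
    def radius_um(self) -> float:
        return self.diameter_um / 2.0

    @property
    def zone_width_um(self) -> float:
        return self.radius_um / self.n_zones

    def with_center(self, center_um: tuple[float, float]) -> "WellGeometry":
        return replace(self, center_um=(float(center_um[0]), float(center_um[1])))


@dataclass
class MultichannelStack:
    """A multichannel, optionally z-stacked fluorescence image.

    ``pixels`` is indexed ``(channel, z, y, x)``; intensities are
    non-negative.  All channels share the spatial dimensions.
    """

    pixels: np.ndarray
    channel_names: list[str]
    um_per_px: float
    z_step_um: float | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 4:
            raise ValueError(
                f"pixels must be a (channel, z, y, x) array, got ndim={self.pixels.ndim}"
            )
        if len(self.channel_names) != self.pixels.shape[0]:
            raise ValueError(
                f"{len(self.channel_names)} channel names for "
                f"{self.pixels.shape[0]} channels"
            )
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValueError("channel names must be unique")
        if self.pixels.size and float(self.pixels.min()) < 0:
            raise ValueError("intensities must be non-negative")
        if not self.um_per_px > 0:
            raise ValueError(f"um_per_px must be > 0, got {self.um_per_px}")

    @property
    def n_channels(self) -> int:
        return self.pixels.shape[0]

    @property
    def n_slices(self) -> int:
        return self.pixels.shape[1]

    @property
    def spatial_shape(self) -> tuple[int, int]:
        return self.pixels.shape[2], self.pixels.shape[3]


@dataclass(frozen=True)
class CenterEstimate:
    """Well-center estimate in pixel coordinates ``(y, x)``."""

    y_px: float
    x_px: float
    fallback: bool  # True when the image carried no intensity


def locate_well_center(stack: MultichannelStack) -> CenterEstimate:
    """Intensity-weighted centroid of the channel- and z-summed image.

    For a radially symmetric aggregate the centroid coincides with the well
    center.  An all-zero image yields the geometric image center with the
    ``fallback`` flag set.
    """
    flat = stack.pixels.sum(axis=(0, 1), dtype=np.float64)
    total = float(flat.sum())
    h, w = flat.shape
    if total == 0.0:
        return CenterEstimate((h - 1) / 2.0, (w - 1) / 2.0, fallback=True)
    yy = np.arange(h, dtype=np.float64)
    xx = np.arange(w, dtype=np.float64)
    cy = float((flat.sum(axis=1) @ yy) / total)
    cx = float((flat.sum(axis=0) @ xx) / total)
    return CenterEstimate(cy, cx, fallback=False)


def zone_mask(geometry: WellGeometry, shape: tuple[int, int]) -> np.ndarray:
    """Per-pixel zone labels for an image of the given ``(y, x)`` shape.

    Pixel centers at radial distance r (μm) from the well center get label
    k when (k−1)·R/n ≤ r < k·R/n; the outermost bin is closed at r = R.
    Label 0 marks pixels outside the well.
    """
    if geometry.center_um is None:
        raise ValueError("geometry.center_um is unresolved; estimate it first")
    cy, cx = geometry.center_um
    r_well = geometry.radius_um
    upp = geometry.um_per_px
    h, w = shape
    tol = upp  # sub-pixel overhang is not a truncation of pixel centers
    if (
        cy - r_well < -tol
        or cx - r_well < -tol
        or cy + r_well > (h - 1) * upp + tol
        or cx + r_well > (w - 1) * upp + tol
    ):
        warnings.warn(
            "well circle is not fully inside the image; zone mask truncated",
            stacklevel=2,
        )
    dy = np.arange(h, dtype=np.float64) * upp - cy
    dx = np.arange(w, dtype=np.float64) * upp - cx
    r = np.sqrt(dy[:, None] ** 2 + dx[None, :] ** 2)
    width = geometry.zone_width_um
    labels = np.floor(r / width).astype(np.int64) + 1
    inside = r <= r_well
    labels[~inside] = 0
    # r == R lands one past the last bin; the outer bin is closed there.
    labels[inside & (labels > geometry.n_zones)] = geometry.n_zones
    return labels


@dataclass
class ChannelZones:
    """Zone quantification for a single channel."""

    areas_um2: np.ndarray  # per-zone thresholded pixel area, μm²
    fractions: np.ndarray | None  # occupancy fractions (None if no signal)
    total_area_um2: float  # in-well thresholded area
    outside_area_um2: float  # thresholded area outside the outermost zone
    threshold: float | None  # intensity threshold applied (None if undefined)


@dataclass
class ZoneProfile:
    """Per-channel, per-zone occupancy of one well (the distribution histogram)."""

    n_zones: int
    channels: dict[str, ChannelZones]

    def fractions(self, channel: str) -> np.ndarray | None:
        return self.channels[channel].fractions

    def to_frame(self, well_id: str | None = None) -> pd.DataFrame:
        rows = []
        for name, ch in self.channels.items():
            for k in range(self.n_zones):
                frac = np.nan if ch.fractions is None else float(ch.fractions[k])
                row = {
                    "channel": name,
                    "zone": k + 1,
                    "area_um2": float(ch.areas_um2[k]),
                    "fraction": frac,
                }
                if well_id is not None:
                    row = {"well_id": well_id, **row}
                rows.append(row)
        return pd.DataFrame(rows)


def _parse_threshold(threshold) -> tuple[str, float | None]:
    if isinstance(threshold, (int, float)) and not isinstance(threshold, bool):
        return "fixed", float(threshold)
    if isinstance(threshold, str):
        if threshold == "otsu":
            return "otsu", None
        if threshold.startswith("fixed:"):
            return "fixed", float(threshold.split(":", 1)[1])
    raise ValueError(f"threshold must be 'otsu', 'fixed:<v>' or a number, got {threshold!r}")


def quantify_zones(
    stack: MultichannelStack,
    geometry: WellGeometry | None = None,
    threshold="otsu",
) -> ZoneProfile:
    """Quantify per-channel thresholded pixel area in each concentric zone.

    The threshold is either Otsu's method computed per channel over the
    in-well region of the max-intensity z-projection (default) or a fixed
    value (``"fixed:v"`` or a number).  Thresholded pixels are counted per
    zone and per z-slice, summed over z and converted to μm²; fractions are
    normalised over zones 1..n.  Signal outside the outermost zone is
    reported separately and excluded from the fractions.

    A channel with no pixel above threshold is reported as missing
    (``fractions=None``) with a warning, never as a zero profile.
    """
    if geometry is None:
        geometry = WellGeometry(um_per_px=stack.um_per_px)
    mode, fixed_value = _parse_threshold(threshold)
    if geometry.center_um is None:
        est = locate_well_center(stack)
        geometry = geometry.with_center(
            (est.y_px * geometry.um_per_px, est.x_px * geometry.um_per_px)
        )
    mask = zone_mask(geometry, stack.spatial_shape)
    in_well = mask > 0
    n = geometry.n_zones
    px_area = geometry.um_per_px**2

    channels: dict[str, ChannelZones] = {}
    for ci, name in enumerate(stack.channel_names):
        chan = stack.pixels[ci]
        if mode == "otsu":
            vals = chan.max(axis=0)[in_well]
            if vals.size == 0 or float(vals.max()) == float(vals.min()):
                thr = None
            else:
                thr = float(threshold_otsu(vals))
        else:
            thr = fixed_value

        counts = np.zeros(n + 1, dtype=np.int64)
        if thr is not None:
            for z in range(stack.n_slices):
                above = chan[z] > thr
                counts += np.bincount(mask[above], minlength=n + 1)

        total = int(counts[1:].sum())
        areas = counts[1:].astype(np.float64) * px_area
        outside = float(counts[0]) * px_area
        if total == 0:
            warnings.warn(
                f"channel {name!r}: no pixel above threshold; fractions undefined",
                stacklevel=2,
            )
            fractions = None
        else:
            fractions = areas / areas.sum()
            if outside > 0.05 * (outside + areas.sum()):
                warnings.warn(
                    f"channel {name!r}: {outside:.0f} μm² of signal outside the "
                    "outermost zone (>5% of channel signal); the well may be "
                    "mis-centered",
                    stacklevel=2,
                )
        channels[name] = ChannelZones(
            areas_um2=areas,
            fractions=fractions,
            total_area_um2=float(areas.sum()),
            outside_area_um2=outside,
            threshold=thr,
        )
    return ZoneProfile(n_zones=n, channels=channels)
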