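"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import math

import numpy as np
import pytest

from hma.zonation import MultichannelStack, WellGeometry


def brute_force_zone_counts(
    pixels: np.ndarray,
    channel: int,
    center_um: tuple[float, float],
    um_per_px: float,
    radius_um: float,
    n_zones: int,
    threshold: float,
) -> np.ndarray:
    """Per-pixel loop oracle: threshold, compute r, bin into zones.

    Returns integer counts indexed 0..n_zones (0 = outside the well),
    summed over z.  Deliberately written as a plain loop, independent of the
    vectorised implementation.
    """
    cy, cx = center_um
    width = radius_um / n_zones
    counts = np.zeros(n_zones + 1, dtype=np.int64)
    _, n_z, h, w = pixels.shape
    for z in range(n_z):
        for y in range(h):
            dy = y * um_per_px - cy
            for x in range(w):
                if pixels[channel, z, y, x] > threshold:
                    dx = x * um_per_px - cx
                    r = math.sqrt(dy * dy + dx * dx)
                    if r > radius_um:
                        counts[0] += 1
                    else:
                        k = int(math.floor(r / width)) + 1
                        counts[min(k, n_zones)] += 1
    return counts


def make_stack(
    pixels: np.ndarray, channel_names=None, um_per_px: float = 1.0
) -> MultichannelStack:
    pixels = np.asarray(pixels, dtype=float)
    while pixels.ndim < 4:
        pixels = pixels[np.newaxis]
    if channel_names is None:
        channel_names = [f"ch{i}" for i in range(pixels.shape[0])]
    return MultichannelStack(pixels=pixels, channel_names=channel_names, um_per_px=um_per_px)


@pytest.fixture
def small_geometry() -> WellGeometry:
    """A 40-μm well at 1 μm/px with an explicit center inside a 41×41 image."""
    return WellGeometry(diameter_um=40.0, n_zones=5, um_per_px=1.0, center_um=(20.0, 20.0))
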