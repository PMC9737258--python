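"""Seeded synthetic data with the statistical structure the analysis assumes.

Three generators stand in for the study's raw inputs:

* :func:`generate_aggregate_image` — a microwell aggregate image: labeled
  populations rendered as anti-aliased disks whose radial placement follows
  either explicit per-zone occupancy probabilities or a core–shell
  segregation model (the sorted self-assembly pattern driven by differential
  intercellular affinity).
* :func:`generate_phenotype_tables` — dose–viability, growth and invasion
  tables whose drug-resistance structure can be coupled to (or decoupled
  from) a population's radial position.
* :func:`generate_survival` — two-group right-censored survival records with
  a configurable hazard ratio.

All three are pure functions of their configuration and seed: identical
inputs give bit-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .zonation import MultichannelStack, WellGeometry

__all__ = [
    "RadialPlacementModel",
    "PopulationSpec",
    "SimulationConfig",
    "PhenotypeCoupling",
    "generate_aggregate_image",
    "generate_phenotype_tables",
    "generate_survival",
]


@dataclass(frozen=True)
class RadialPlacementModel:
    """Radial placement of one cell population inside the well.

    ``zone_probabilities`` mode draws each cell's zone from ``zone_probs``
    and places it area-uniformly within that annulus, so the probabilities
    are occupancy probabilities (not center-density).  ``core_shell`` mode
    places a cell in the shell with probability ``shell_bias`` and in the
    core (radius ``core_fraction``·R) otherwise, again area-uniformly.
    Angles are uniform.
    """

    mode: str
    zone_probs: tuple[float, ...] | None = None
    core_fraction: float | None = None
    shell_bias: float | None = None

    def __post_init__(self) -> None:
        if self.mode == "zone_probabilities":
            if self.zone_probs is None:
                raise ValueError("zone_probs required for mode='zone_probabilities'")
            p = np.asarray(self.zone_probs, dtype=float)
            if (p < 0).any():
                raise ValueError(f"zone_probs must be non-negative, got {self.zone_probs}")
            if abs(float(p.sum()) - 1.0) > 1e-9:
                raise ValueError(f"zone_probs must sum to 1, got sum={p.sum()!r}")
        elif self.mode == "core_shell":
            if self.core_fraction is None or self.shell_bias is None:
                raise ValueError("core_fraction and shell_bias required for mode='core_shell'")
            if not 0.0 <= self.core_fraction <= 1.0:
                raise ValueError(f"core_fraction must be in [0,1], got {self.core_fraction}")
            if not 0.0 <= self.shell_bias <= 1.0:
                raise ValueError(f"shell_bias must be in [0,1], got {self.shell_bias}")
        else:
            raise ValueError(f"unknown placement mode {self.mode!r}")

    @classmethod
    def from_zone_probs(cls, probs: Sequence[float]) -> "RadialPlacementModel":
        return cls(mode="zone_probabilities", zone_probs=tuple(float(p) for p in probs))

    @classmethod
    def core_shell_model(cls, core_fraction: float, shell_bias: float) -> "RadialPlacementModel":
        return cls(mode="core_shell", core_fraction=core_fraction, shell_bias=shell_bias)

    def expected_zone_profile(self, n_zones: int, well_radius_um: float = 250.0) -> np.ndarray:
        """Expected occupancy fraction per zone under this placement model.

        Closed form: area-uniform placement puts probability proportional to
        the overlap area of each region with each zone annulus.
        """
        if self.mode == "zone_probabilities":
            p = np.asarray(self.zone_probs, dtype=float)
            if len(p) != n_zones:
                raise ValueError(f"zone_probs has {len(p)} entries for {n_zones} zones")
            return p
        r_core = self.core_fraction * well_radius_um
        edges = np.linspace(0.0, well_radius_um, n_zones + 1)
        core_area = math.pi * r_core**2
        shell_area = math.pi * (well_radius_um**2 - r_core**2)
        probs = np.zeros(n_zones)
        for k in range(n_zones):
            lo, hi = edges[k], edges[k + 1]
            ann = math.pi * (hi**2 - lo**2)
            core_overlap = math.pi * (min(hi, r_core) ** 2 - min(lo, r_core) ** 2)
            shell_overlap = ann - core_overlap
            if core_area > 0:
                probs[k] += (1.0 - self.shell_bias) * core_overlap / core_area
            if shell_area > 0:
                probs[k] += self.shell_bias * shell_overlap / shell_area
        return probs


@dataclass(frozen=True)
class PopulationSpec:
    """One labeled cell population to render on its own channel."""

    label: str
    channel: str
    n_cells: int
    cell_radius_um: float
    placement: RadialPlacementModel

    def __post_init__(self) -> None:
        if self.n_cells < 0:
            raise ValueError(f"n_cells must be >= 0, got {self.n_cells}")
        if not self.cell_radius_um > 0:
            raise ValueError(f"cell_radius_um must be > 0, got {self.cell_radius_um}")


@dataclass(frozen=True)
class SimulationConfig:
    """Full configuration of one synthetic microwell image."""

    geometry: WellGeometry
    populations: tuple[PopulationSpec, ...]
    z_slices: int = 1
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "populations", tuple(self.populations))
        if self.z_slices < 1:
            raise ValueError(f"z_slices must be >= 1, got {self.z_slices}")
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be >= 0, got {self.noise_sd}")
        labels = [p.label for p in self.populations]
        if len(set(labels)) != len(labels):
            raise ValueError(f"population labels must be unique, got {labels}")


def _sample_polar(
    placement: RadialPlacementModel,
    geometry: WellGeometry,
    n: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Sample (r, θ) for n cell centers; r area-uniform within the chosen region."""
    r_well = geometry.radius_um
    if placement.mode == "zone_probabilities":
        probs = np.asarray(placement.zone_probs, dtype=float)
        if len(probs) != geometry.n_zones:
            raise ValueError(
                f"zone_probs has {len(probs)} entries but geometry.n_zones="
                f"{geometry.n_zones}"
            )
        edges = np.linspace(0.0, r_well, geometry.n_zones + 1)
        zones = rng.choice(geometry.n_zones, size=n, p=probs / probs.sum())
        lo, hi = edges[zones], edges[zones + 1]
    else:
        r_core = placement.core_fraction * r_well
        in_shell = rng.random(n) < placement.shell_bias
        lo = np.where(in_shell, r_core, 0.0)
        hi = np.where(in_shell, r_well, r_core)
    u = rng.random(n)
    r = np.sqrt(lo**2 + u * (hi**2 - lo**2))
    theta = rng.uniform(0.0, 2.0 * math.pi, size=n)
    return r, theta


def _render_disks(plane: np.ndarray, y_px: np.ndarray, x_px: np.ndarray, r_px: float) -> None:
    """Accumulate anti-aliased unit-intensity disks onto a 2D plane (in place)."""
    h, w = plane.shape
    pad = r_px + 1.0
    for yc, xc in zip(y_px, x_px):
        y0 = max(int(math.floor(yc - pad)), 0)
        y1 = min(int(math.ceil(yc + pad)) + 1, h)
        x0 = max(int(math.floor(xc - pad)), 0)
        x1 = min(int(math.ceil(xc + pad)) + 1, w)
        if y0 >= y1 or x0 >= x1:
            continue
        dy = np.arange(y0, y1, dtype=np.float64) - yc
        dx = np.arange(x0, x1, dtype=np.float64) - xc
        d = np.sqrt(dy[:, None] ** 2 + dx[None, :] ** 2)
        cov = np.clip(r_px + 0.5 - d, 0.0, 1.0)
        plane[y0:y1, x0:x1] += cov


def well_image_center_um(geometry: WellGeometry) -> tuple[float, float]:
    """The (y, x) μm position of the well center in a generated image."""
    n_px = int(round(geometry.diameter_um / geometry.um_per_px)) + 1
    c = (n_px - 1) / 2.0 * geometry.um_per_px
    return c, c


def generate_aggregate_image(
    config: SimulationConfig, return_positions: bool = False
) -> MultichannelStack | tuple[MultichannelStack, dict[str, dict[str, np.ndarray]]]:
    """Render one synthetic microwell aggregate image.

    Each population is drawn as anti-aliased, unit-intensity filled disks of
    its cell radius on its own channel; disk intensities add where cells
    overlap.  The 2D render is replicated across z-slices; Gaussian pixel
    noise of sd ``noise_sd`` (clipped at zero) is added independently per
    slice.  With ``return_positions=True`` the sampled cell centers
    (μm, with their radial distances) are returned alongside the stack for
    ground-truth checks.
    """
    g = config.geometry
    if not g.diameter_um > 0:
        raise ValueError(f"diameter_um must be positive, got {g.diameter_um}")
    channels = [p.channel for p in config.populations]
    if len(set(channels)) != len(channels):
        raise ValueError(f"channel collision: channels must be distinct per population, got {channels}")
    for p in config.populations:
        if p.cell_radius_um >= g.radius_um:
            raise ValueError(
                f"cell_radius_um={p.cell_radius_um} of population {p.label!r} "
                f"must be smaller than the well radius {g.radius_um}"
            )

    rng = np.random.default_rng(config.seed)
    n_px = int(round(g.diameter_um / g.um_per_px)) + 1
    cy, cx = well_image_center_um(g)
    n_pop = len(config.populations)
    planes = np.zeros((n_pop, n_px, n_px), dtype=np.float64)
    positions: dict[str, dict[str, np.ndarray]] = {}

    for i, pop in enumerate(config.populations):
        r, theta = _sample_polar(pop.placement, g, pop.n_cells, rng)
        y_um = cy + r * np.sin(theta)
        x_um = cx + r * np.cos(theta)
        positions[pop.label] = {"r_um": r, "y_um": y_um, "x_um": x_um}
        _render_disks(
            planes[i], y_um / g.um_per_px, x_um / g.um_per_px, pop.cell_radius_um / g.um_per_px
        )

    pixels = np.repeat(planes[:, None, :, :], config.z_slices, axis=1)
    if config.noise_sd > 0:
        pixels = np.clip(pixels + rng.normal(0.0, config.noise_sd, size=pixels.shape), 0.0, None)
    pixels = pixels.astype(np.float32)

    stack = MultichannelStack(
        pixels=pixels, channel_names=list(channels), um_per_px=g.um_per_px
    )
    if return_positions:
        return stack, positions
    return stack


@dataclass(frozen=True)
class PhenotypeCoupling:
    """How phenotype tables relate to spatial scores.

    ``resistant_when_external`` makes the half-effect temozolomide dose
    increase monotonically with the radial score (external populations more
    resistant); ``independent`` draws drug response unrelated to position.
    Growth and invasion are always generated independently of the score.
    """

    direction: str = "resistant_when_external"
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.direction not in ("resistant_when_external", "independent"):
            raise ValueError(f"unknown coupling direction {self.direction!r}")
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be >= 0, got {self.noise_sd}")


_FOUR_PL_TOP = 1.0
_FOUR_PL_BOTTOM = 0.05
_FOUR_PL_HILL = 1.5


def _four_pl(dose: np.ndarray, log10_ec50: float) -> np.ndarray:
    ec50 = 10.0**log10_ec50
    v = np.where(
        dose > 0,
        _FOUR_PL_BOTTOM
        + (_FOUR_PL_TOP - _FOUR_PL_BOTTOM) / (1.0 + (dose / ec50) ** _FOUR_PL_HILL),
        _FOUR_PL_TOP,
    )
    return v


def generate_phenotype_tables(
    spatial_scores: Mapping[str, float],
    coupling: PhenotypeCoupling,
    doses_uM: Sequence[float] = (0.0, 10.0, 31.6, 100.0, 316.0, 1000.0),
    times_h: Sequence[float] = (0.0, 24.0, 48.0, 72.0),
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate dose–viability, growth and invasion tables for a label set.

    Dose–viability follows a four-parameter logistic.  Under
    ``resistant_when_external`` the log half-effect dose rises linearly with
    the (min–max normalised) spatial score, so noiseless resistance ranks
    reproduce the spatial ranks exactly; equal scores give identical curves.
    Growth (exponential OD, rate ~ U(0.01, 0.03) h⁻¹) and invasion (linear
    area expansion, 72-h fold change ~ U(0.5, 3)) never depend on the score.

    Noise: additive Gaussian (sd ``noise_sd``) on viability, multiplicative
    ``(1 + ε)`` on OD and area; all values clipped at zero.
    """
    labels = sorted(spatial_scores)
    if len(labels) < 2:
        raise ValueError("at least two labels required; ranking is undefined for one")
    scores = np.array([float(spatial_scores[l]) for l in labels])
    if not np.isfinite(scores).all():
        raise ValueError("spatial scores must be finite")

    rng = np.random.default_rng(coupling.seed)
    smin, smax = scores.min(), scores.max()
    if smax > smin:
        norm = (scores - smin) / (smax - smin)
    else:
        norm = np.full_like(scores, 0.5)

    doses = np.asarray(sorted(set(float(d) for d in doses_uM)))
    times = np.asarray(sorted(set(float(t) for t in times_h)))

    dose_rows, growth_rows, invasion_rows = [], [], []
    for label, t in zip(labels, norm):
        if coupling.direction == "resistant_when_external":
            log_ec50 = 1.0 + 2.5 * t
        else:
            log_ec50 = float(rng.uniform(1.0, 3.5))
        viability = _four_pl(doses, log_ec50)
        if coupling.noise_sd > 0:
            viability = np.clip(
                viability + rng.normal(0.0, coupling.noise_sd, size=doses.shape), 0.0, None
            )
        dose_rows += [
            {"label": label, "dose_uM": d, "viability": float(v)}
            for d, v in zip(doses, viability)
        ]

        rate = float(rng.uniform(0.01, 0.03))  # h⁻¹, typical glioma doubling 1–3 d
        od = 0.2 * np.exp(rate * times)
        if coupling.noise_sd > 0:
            od = np.clip(od * (1.0 + rng.normal(0.0, coupling.noise_sd, size=times.shape)), 0.0, None)
        growth_rows += [
            {"label": label, "time_h": h, "od": float(v)} for h, v in zip(times, od)
        ]

        fold = float(rng.uniform(0.5, 3.0))  # relative area gain over 72 h
        area = 1.0e4 * (1.0 + fold * times / 72.0)
        if coupling.noise_sd > 0:
            area = np.clip(area * (1.0 + rng.normal(0.0, coupling.noise_sd, size=times.shape)), 0.0, None)
        invasion_rows += [
            {"label": label, "time_h": h, "area_um2": float(v)} for h, v in zip(times, area)
        ]

    return (
        pd.DataFrame(dose_rows),
        pd.DataFrame(growth_rows),
        pd.DataFrame(invasion_rows),
    )


def generate_survival(
    groups: Mapping[str, str],
    hazard_ratio: float,
    baseline_median: float = 24.0,
    censor_prob: float = 0.0,
    n_per_group: int = 25,
    seed: int = 0,
) -> pd.DataFrame:
    """Two-group exponential survival records with a configurable hazard ratio.

    ``groups`` maps population labels to exactly two group names; the
    alphabetically first group is the baseline with hazard
    λ₀ = ln 2 / ``baseline_median``, the second has hazard λ₀·``hazard_ratio``.
    Each record is censored with probability ``censor_prob`` at a time drawn
    uniformly on (0, event time).  Columns: label, time, event, group.
    """
    if not hazard_ratio > 0:
        raise ValueError(f"hazard_ratio must be > 0, got {hazard_ratio}")
    if not baseline_median > 0:
        raise ValueError(f"baseline_median must be > 0, got {baseline_median}")
    if not 0.0 <= censor_prob <= 1.0:
        raise ValueError(f"censor_prob must be in [0,1], got {censor_prob}")
    if n_per_group < 1:
        raise ValueError(f"n_per_group must be >= 1, got {n_per_group}")
    names = sorted(set(groups.values()))
    if len(names) != 2:
        raise ValueError(f"exactly two distinct groups required, got {names}")

    rng = np.random.default_rng(seed)
    lam0 = math.log(2.0) / baseline_median
    rows = []
    for gi, gname in enumerate(names):
        lam = lam0 * (hazard_ratio if gi == 1 else 1.0)
        t_event = rng.exponential(1.0 / lam, size=n_per_group)
        censored = rng.random(n_per_group) < censor_prob
        t_cens = rng.uniform(0.0, t_event)
        for i in range(n_per_group):
            t = float(t_cens[i]) if censored[i] else float(t_event[i])
            rows.append(
                {
                    "label": f"{gname}-{i + 1:03d}",
                    "time": max(t, np.finfo(float).tiny),
                    "event": bool(not censored[i]),
                    "group": gname,
                }
            )
    return pd.DataFrame(rows)
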