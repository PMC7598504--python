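"""Synthetic topoisomer ladders, gel lanes and gyrase time courses.

The generator provides ground truth for every downstream stage.  A plasmid
population relaxed or supercoiled to a given extent is modelled as a
discretized Gaussian over integer apparent linking numbers (the standard
physical model for a thermal topoisomer distribution); a gel lane is the sum
of Gaussian band profiles, one per topoisomer, with amplitude proportional
to the topoisomer's probability, on a smooth (constant + linear) background
with optional additive Gaussian noise.  DNA gyrase acting on such a
population shifts the mean apparent Lk linearly in time, which is how the
activity statistic (delta-Lk per hour) is defined downstream.

Orientation contract: position 0 is the top of the gel (wells); bands with
larger Lk index lie further down the profile.  Lk indices are apparent /
relative only — no sign of supercoiling is implied.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .densitometry import LaneProfile, write_profile_csv
from .errors import ConfigError, GeometryError, InvalidParameterError

__all__ = [
    "TopoisomerDistribution",
    "GelGeometry",
    "NoiseModel",
    "ScenarioConfig",
    "Scenario",
    "make_topoisomer_distribution",
    "render_lane",
    "simulate_gyrase_timecourse",
    "generate_scenario",
    "render_gel_image",
]


@dataclass(frozen=True)
class TopoisomerDistribution:
    """Probability mass over integer apparent linking numbers."""

    lk_values: np.ndarray
    probabilities: np.ndarray

    def __post_init__(self) -> None:
        lk = np.asarray(self.lk_values, dtype=int)
        p = np.asarray(self.probabilities, dtype=float)
        if lk.ndim != 1 or p.ndim != 1 or lk.size != p.size or lk.size == 0:
            raise InvalidParameterError("lk_values and probabilities must be equal-length 1-D")
        if np.any(np.diff(lk) <= 0):
            raise InvalidParameterError("lk_values must be strictly increasing integers")
        if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
            raise InvalidParameterError("probabilities must be nonnegative and sum to 1")
        object.__setattr__(self, "lk_values", lk)
        object.__setattr__(self, "probabilities", p)

    @property
    def mean_lk(self) -> float:
        """Probability-weighted expectation of the Lk index."""
        return float(np.sum(self.probabilities * self.lk_values))

    @property
    def sd_lk(self) -> float:
        m = self.mean_lk
        return float(np.sqrt(np.sum(self.probabilities * (self.lk_values - m) ** 2)))

    @property
    def half_support(self) -> int:
        return (self.lk_values.size - 1) // 2


@dataclass(frozen=True)
class GelGeometry:
    """Maps Lk indices to band centers along a rendered lane.

    Band center for index k is ``origin_px + spacing_px*k - compression*k**2``;
    the quadratic term (default 0) lets tests exercise mildly non-uniform
    ladders.
    """

    origin_px: float = 300.0
    spacing_px: float = 60.0
    band_sigma_px: float = 8.0
    length_px: int = 1024
    compression: float = 0.0

    def __post_init__(self) -> None:
        if self.origin_px < 0 or self.spacing_px <= 0 or self.band_sigma_px <= 0:
            raise InvalidParameterError("origin_px >= 0, spacing_px > 0, band_sigma_px > 0 required")
        if self.length_px <= 0 or self.compression < 0:
            raise InvalidParameterError("length_px > 0 and compression >= 0 required")

    def band_center(self, lk: np.ndarray | int) -> np.ndarray:
        lk = np.asarray(lk, dtype=float)
        return self.origin_px + self.spacing_px * lk - self.compression * lk**2


@dataclass(frozen=True)
class NoiseModel:
    """Smooth background plus additive Gaussian noise.

    ``noise_sd_frac`` is the noise standard deviation as a fraction of the
    tallest rendered band; with ``noise_sd_frac == 0`` rendering is
    deterministic regardless of seed.
    """

    background_const: float = 0.0
    background_slope: float = 0.0
    noise_sd_frac: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.background_const < 0 or self.noise_sd_frac < 0:
            raise InvalidParameterError("background_const and noise_sd_frac must be >= 0")


def make_topoisomer_distribution(
    mean_lk: float, sd: float, half_support: int = 4
) -> TopoisomerDistribution:
    """Discretized Gaussian over the integers within ``half_support`` of
    ``round(mean_lk)``, renormalized to sum to 1.

    ``sd = 0`` yields a point mass at ``round(mean_lk)``.  The support should
    cover at least +-4 sd of the mean, otherwise the discrete mean is
    truncated toward the support center.
    """
    if sd < 0:
        raise InvalidParameterError(f"sd must be nonnegative, got {sd}")
    half_support = int(half_support)
    if half_support < 1:
        raise InvalidParameterError("half_support must be >= 1")
    center = int(round(mean_lk))
    lk = np.arange(center - half_support, center + half_support + 1)
    if sd == 0:
        p = (lk == center).astype(float)
    else:
        z = (lk - mean_lk) / sd
        p = np.exp(-0.5 * z**2)
        p /= p.sum()
    return TopoisomerDistribution(lk, p)


def render_lane(
    dist: TopoisomerDistribution,
    geom: GelGeometry = GelGeometry(),
    noise: NoiseModel = NoiseModel(),
    total_intensity: float = 1e5,
    lane_id: str = "lane",
) -> LaneProfile:
    """Render a topoisomer distribution into a 1-D lane profile.

    Each topoisomer contributes a Gaussian band of area
    ``total_intensity * p_i`` centered per the geometry; background and noise
    come from the noise model.  Identical inputs and seed give bit-identical
    output.
    """
    if total_intensity <= 0:
        raise InvalidParameterError("total_intensity must be positive")
    centers = geom.band_center(dist.lk_values)
    bad = (centers < 0) | (centers >= geom.length_px)
    if np.any(bad):
        raise GeometryError(
            f"band(s) for Lk {dist.lk_values[bad].tolist()} fall outside the "
            f"profile [0, {geom.length_px}) at centers {centers[bad].tolist()}"
        )
    pos = np.arange(geom.length_px, dtype=float)
    sigma = geom.band_sigma_px
    norm = 1.0 / (sigma * np.sqrt(2 * np.pi))
    signal = np.zeros_like(pos)
    for p_i, c in zip(dist.probabilities, centers):
        signal += total_intensity * p_i * norm * np.exp(-0.5 * ((pos - c) / sigma) ** 2)
    profile = noise.background_const + noise.background_slope * pos + signal
    if noise.noise_sd_frac > 0:
        rng = np.random.default_rng(noise.seed)
        profile = profile + rng.normal(0.0, noise.noise_sd_frac * signal.max(), pos.size)
    return LaneProfile(pos, np.clip(profile, 0.0, None), lane_id)


def simulate_gyrase_timecourse(
    dist0: TopoisomerDistribution, rate_dlk_per_h: float, hours: float
) -> TopoisomerDistribution:
    """Distribution after gyrase acts for ``hours`` at ``rate_dlk_per_h``.

    The mean apparent Lk shifts linearly in time (rate * hours) with the
    spread preserved; the result is re-discretized on an integer support of
    the same half-width.  The realized discrete mean matches the shifted mean
    up to Gaussian-truncation error, negligible when the support covers
    several sd.
    """
    if hours < 0:
        raise InvalidParameterError("hours must be nonnegative")
    target_mean = dist0.mean_lk + rate_dlk_per_h * hours
    sd = dist0.sd_lk
    if sd == 0:
        lk = np.array([int(round(target_mean))])
        return TopoisomerDistribution(lk, np.array([1.0]))
    return make_topoisomer_distribution(target_mean, sd, dist0.half_support)


@dataclass(frozen=True)
class ScenarioConfig:
    """Default multi-lane scenario mirroring the RSU normalization design.

    Two reference lanes anchor the RSU scale: ``ref0`` (the 0-RSU anchor,
    e.g. wild type grown in high Mg2+) and ``ref1`` (the 1-RSU anchor, wild
    type in low Mg2+), separated by 0.5 weighted delta-Lk so that one full
    linking number converts into 2 RSU.  Additional sample lanes are named
    with their true mean-Lk offsets from ref0.
    """

    base_mean_lk: float = 2.5
    sd_lk: float = 1.0
    half_support: int = 5
    lane_offsets: Mapping[str, float] = field(
        default_factory=lambda: {"ref0": 0.0, "ref1": 0.5, "sample_plus1": 1.0}
    )
    geometry: GelGeometry = field(default_factory=GelGeometry)
    total_intensity: float = 1e5
    background_const: float = 30.0
    background_slope: float = 0.01
    noise_sd_frac: float = 0.01

    def __post_init__(self) -> None:
        for ref in ("ref0", "ref1"):
            if ref not in self.lane_offsets:
                raise ConfigError(f"scenario config must name a {ref!r} lane")
        if len(self.lane_offsets) < 3:
            raise ConfigError("scenario config needs at least one sample lane besides ref0/ref1")


@dataclass(frozen=True)
class Scenario:
    """Rendered lanes plus a ground-truth manifest for tests."""

    profiles: dict[str, LaneProfile]
    distributions: dict[str, TopoisomerDistribution]
    manifest: pd.DataFrame  # lane_id, offset_lk, true_mean_lk

    def write(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for lane_id, profile in self.profiles.items():
            write_profile_csv(profile, directory / f"{lane_id}.csv")
        self.manifest.to_csv(directory / "manifest.tsv", sep="\t", index=False)


def generate_scenario(config: ScenarioConfig | None = None, seed: int = 0) -> Scenario:
    """Render every configured lane with a per-lane derived seed and record
    the true mean Lk of each lane in a manifest."""
    config = config or ScenarioConfig()
    profiles: dict[str, LaneProfile] = {}
    dists: dict[str, TopoisomerDistribution] = {}
    rows = []
    for i, (lane_id, offset) in enumerate(config.lane_offsets.items()):
        dist = make_topoisomer_distribution(
            config.base_mean_lk + offset, config.sd_lk, config.half_support
        )
        noise = NoiseModel(
            background_const=config.background_const,
            background_slope=config.background_slope,
            noise_sd_frac=config.noise_sd_frac,
            seed=(int(seed) * 1_000_003 + i) % 2**31,
        )
        profiles[lane_id] = render_lane(
            dist, config.geometry, noise, config.total_intensity, lane_id
        )
        dists[lane_id] = dist
        rows.append(
            {"lane_id": lane_id, "offset_lk": offset, "true_mean_lk": dist.mean_lk}
        )
    return Scenario(profiles, dists, pd.DataFrame(rows))


def render_gel_image(
    profiles: Mapping[str, LaneProfile],
    lane_width_px: int = 24,
    gap_px: int = 12,
    dtype=np.uint16,
) -> np.ndarray:
    """Tile lane profiles into a 2-D grayscale gel image (row 0 = top).

    Each lane occupies ``lane_width_px`` identical columns separated by
    blank gaps; intensities are linearly rescaled to the dtype range.
    """
    lanes = list(profiles.values())
    if not lanes:
        raise InvalidParameterError("no profiles to render")
    height = max(len(p) for p in lanes)
    width = len(lanes) * (lane_width_px + gap_px) + gap_px
    img = np.zeros((height, width), dtype=float)
    for i, lane in enumerate(lanes):
        c0 = gap_px + i * (lane_width_px + gap_px)
        img[: len(lane), c0 : c0 + lane_width_px] = lane.intensities[:, None]
    peak = img.max()
    if peak > 0:
        img = img / peak * np.iinfo(dtype).max
    return img.astype(dtype)
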