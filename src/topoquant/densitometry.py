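"""Lane densitometry: from a 1-D intensity profile to an integer topoisomer
ladder and its intensity-weighted mean linking number.

On an agarose/chloroquine gel a covalently closed plasmid resolves into a
ladder of discrete topoisomer bands, one per apparent linking number (Lk).
The convention implemented here indexes the topmost band (closest to the
wells) as Lk = 0, the band immediately below as Lk = 1, and so on; the index
scale is relative — no attempt is made to assign a sign (positive vs.
negative supercoiling) to the ladder.  The summary statistic of a lane is the
intensity-weighted mean of the band indices,

    <Lk> = sum_i I_i * Lk_i / sum_i I_i,

where I_i is the integrated intensity of band i.

The processing chain is: ``extract_lane_profile`` (image -> profile),
``subtract_background``, ``detect_bands``, ``assign_linking_numbers``,
``weighted_mean_lk``.  ``quantify_profile`` and ``quantify_lanes`` compose
the chain; the latter anchors all lanes of one gel to a common ladder origin
so that weighted-Lk differences between lanes are meaningful.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, signal

from .errors import (
    AmbiguousLadderError,
    BoundsError,
    InvalidBandError,
    InvalidParameterError,
    NoBandsError,
)

__all__ = [
    "LaneProfile",
    "Peak",
    "BandTable",
    "extract_lane_profile",
    "subtract_background",
    "detect_bands",
    "assign_linking_numbers",
    "weighted_mean_lk",
    "quantify_profile",
    "quantify_lanes",
    "read_profile_csv",
    "write_profile_csv",
    "read_band_tables",
    "write_band_tables",
]


@dataclass(frozen=True)
class LaneProfile:
    """1-D intensity trace of a single gel lane.

    ``positions`` increase down the gel: index 0 is the top (well side), so
    larger positions correspond to larger apparent Lk indices.
    """

    positions: np.ndarray
    intensities: np.ndarray
    lane_id: str = "lane"

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        inten = np.asarray(self.intensities, dtype=float)
        if pos.ndim != 1 or inten.ndim != 1 or pos.size != inten.size:
            raise InvalidParameterError(
                "positions and intensities must be 1-D arrays of equal length"
            )
        if pos.size and np.any(np.diff(pos) <= 0):
            raise InvalidParameterError("positions must be strictly increasing")
        if np.any(inten < 0):
            raise InvalidParameterError("intensities must be nonnegative")
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "intensities", inten)

    def __len__(self) -> int:
        return self.positions.size


@dataclass(frozen=True)
class Peak:
    """A detected band candidate before ladder indexing."""

    center_px: float
    height: float
    prominence: float
    integrated_intensity: float


@dataclass(frozen=True)
class BandTable:
    """Detected bands of one lane with integer Lk indices.

    Invariants: indices are unique nonnegative integers, strictly increasing
    with band center (position increases down the gel).  In the default
    per-lane assignment the topmost band has index 0; when a lane is anchored
    to a shared gel ladder (see :func:`quantify_lanes`) the topmost index may
    be positive.
    """

    lane_id: str
    centers_px: np.ndarray
    integrated_intensities: np.ndarray
    lk_indices: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.centers_px, dtype=float)
        ii = np.asarray(self.integrated_intensities, dtype=float)
        lk = np.asarray(self.lk_indices, dtype=int)
        if not (c.size == ii.size == lk.size):
            raise InvalidParameterError("band table columns must have equal length")
        if c.size:
            if np.any(np.diff(c) <= 0):
                raise InvalidParameterError("band centers must be strictly increasing")
            if np.any(np.diff(lk) <= 0):
                raise AmbiguousLadderError(
                    f"lk indices must be strictly increasing, got {lk.tolist()}"
                )
            if lk.min() < 0:
                raise InvalidParameterError("lk indices must be nonnegative")
        object.__setattr__(self, "centers_px", c)
        object.__setattr__(self, "integrated_intensities", ii)
        object.__setattr__(self, "lk_indices", lk)

    def __len__(self) -> int:
        return self.centers_px.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "lane_id": self.lane_id,
                "lk_index": self.lk_indices,
                "center_px": self.centers_px,
                "integrated_intensity": self.integrated_intensities,
            }
        )


def extract_lane_profile(
    image: np.ndarray,
    roi: tuple[int, int, int, int],
    lane_id: str = "lane",
) -> LaneProfile:
    """Average a rectangular lane region of a grayscale image into a profile.

    Parameters
    ----------
    image:
        2-D array, row 0 = top of the gel (well side).
    roi:
        ``(row_start, row_stop, col_start, col_stop)`` half-open pixel bounds.

    The profile value at each row is the mean intensity across the ROI width;
    positions are the absolute row indices.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise InvalidParameterError("image must be a 2-D grayscale array")
    r0, r1, c0, c1 = (int(v) for v in roi)
    if not (0 <= r0 < r1 <= img.shape[0] and 0 <= c0 < c1 <= img.shape[1]):
        raise BoundsError(f"roi {roi} outside image of shape {img.shape}")
    profile = img[r0:r1, c0:c1].mean(axis=1)
    return LaneProfile(np.arange(r0, r1, dtype=float), profile, lane_id)


def subtract_background(
    profile: LaneProfile, window_px: int, presmooth_sigma_px: float = 0.0
) -> LaneProfile:
    """Remove smooth background by a rolling minimum followed by a rolling
    mean of the same window; the result is clipped at zero.

    The window must be wider than a band (so the minimum dips to baseline
    under every peak) but short against the profile so slowly varying
    background is tracked.  On noisy profiles the rolling minimum chases the
    deepest noise trough in each window, which would leave a positive
    residual everywhere after subtraction; ``presmooth_sigma_px`` applies a
    Gaussian filter to the copy used for background estimation only (the
    signal itself is not smoothed here).
    """
    window_px = int(window_px)
    if window_px <= 0:
        raise InvalidParameterError("window_px must be positive")
    if window_px >= len(profile):
        raise InvalidParameterError(
            f"window_px={window_px} must be smaller than the profile length {len(profile)}"
        )
    base = profile.intensities
    if presmooth_sigma_px > 0:
        dx = float(np.median(np.diff(profile.positions))) if len(profile) > 1 else 1.0
        base = ndimage.gaussian_filter1d(base, presmooth_sigma_px / dx, mode="nearest")
    background = ndimage.minimum_filter1d(base, window_px, mode="nearest")
    background = ndimage.uniform_filter1d(background, window_px, mode="nearest")
    corrected = np.clip(profile.intensities - background, 0.0, None)
    return replace(profile, intensities=corrected)


def _integration_edges(centers: np.ndarray, positions: np.ndarray) -> np.ndarray:
    """Integration window edges: midpoints between adjacent peaks; the outer
    bands extend half the median ladder spacing beyond their centers (clipped
    at the profile ends).  Bounding the outer windows keeps residual
    background/noise in long band-free stretches of the lane from being
    attributed to the faint outermost topoisomers, which would bias the
    intensity-weighted mean."""
    if centers.size == 1:
        return np.array([[positions[0], positions[-1]]])
    inner = (centers[:-1] + centers[1:]) / 2.0
    half = float(np.median(np.diff(centers))) / 2.0
    lo = np.maximum(np.concatenate(([positions[0]], inner)), centers - half)
    hi = np.minimum(np.concatenate((inner, [positions[-1]])), centers + half)
    # windows are [lo_i, hi_i]; encode as shared edges only when contiguous
    return np.stack([lo, hi], axis=1)


def detect_bands(
    profile: LaneProfile,
    min_prominence_frac: float = 0.05,
    min_separation_px: float = 5.0,
    smoothing_sigma_px: float = 0.0,
    min_width_px: float = 0.0,
) -> list[Peak]:
    """Locate topoisomer bands as local maxima of a background-subtracted
    profile.

    A candidate must have topographic prominence of at least
    ``min_prominence_frac`` times the profile maximum and be at least
    ``min_separation_px`` away from a taller accepted peak (ties keep the
    topmost).  Each band's integrated intensity is the trapezoidal area over
    its window: bounded by the midpoints to its neighbouring peaks but never
    wider than half the median ladder spacing on either side of the center
    (a "band box"); for a complete ladder the two rules coincide.  A flat or
    empty profile yields an empty list.

    ``smoothing_sigma_px`` optionally applies a Gaussian filter before peak
    picking (area-preserving, no center shift for symmetric bands) and
    ``min_width_px`` rejects candidates narrower than a real band at half
    prominence; use both — a fraction of the band width and roughly the
    band FWHM respectively — to keep pixel noise from seeding spurious
    peaks when the prominence threshold is low.
    """
    if not 0 < min_prominence_frac <= 1:
        raise InvalidParameterError("min_prominence_frac must be in (0, 1]")
    if min_separation_px <= 0:
        raise InvalidParameterError("min_separation_px must be positive")
    if smoothing_sigma_px < 0 or min_width_px < 0:
        raise InvalidParameterError(
            "smoothing_sigma_px and min_width_px must be nonnegative"
        )
    y = profile.intensities
    if smoothing_sigma_px > 0:
        dx0 = float(np.median(np.diff(profile.positions))) if len(profile) > 1 else 1.0
        y = ndimage.gaussian_filter1d(y, smoothing_sigma_px / dx0, mode="nearest")
    x = profile.positions
    if y.size < 3 or y.max() <= 0 or np.ptp(y) == 0:
        return []
    dx = float(np.median(np.diff(x)))
    distance = max(1, int(round(min_separation_px / dx)))
    idx, props = signal.find_peaks(
        y,
        prominence=min_prominence_frac * y.max(),
        distance=distance,
        width=min_width_px / dx if min_width_px > 0 else None,
        rel_height=0.5,
    )
    if idx.size == 0:
        return []
    centers = x[idx]
    windows = _integration_edges(centers, x)
    peaks: list[Peak] = []
    for k, i in enumerate(idx):
        lo = np.searchsorted(x, windows[k, 0])
        hi = np.searchsorted(x, windows[k, 1], "right")
        area = float(np.trapezoid(y[lo:hi], x[lo:hi]))
        peaks.append(
            Peak(
                center_px=float(centers[k]),
                height=float(y[i]),
                prominence=float(props["prominences"][k]),
                integrated_intensity=area,
            )
        )
    return peaks


def assign_linking_numbers(
    peaks: Sequence[Peak],
    expected_spacing_px: float | str = "auto",
    lane_id: str = "lane",
    origin_px: float | None = None,
) -> BandTable:
    """Index detected bands with integer apparent linking numbers.

    The topmost band (smallest position) gets index 0 and each band below
    increments by the number of inter-band spacings it sits from the top, so
    a missing topoisomer leaves a gap in the indices.  With
    ``expected_spacing_px="auto"`` the spacing is the median inter-peak
    distance.  ``origin_px`` optionally anchors index 0 at a known ladder
    origin (e.g. the topmost band of a reference lane on the same gel)
    instead of this lane's own topmost band.
    """
    if len(peaks) == 0:
        raise NoBandsError("cannot assign linking numbers without peaks")
    centers = np.array([p.center_px for p in peaks], dtype=float)
    order = np.argsort(centers)
    centers = centers[order]
    intensities = np.array([peaks[i].integrated_intensity for i in order], dtype=float)
    if expected_spacing_px == "auto":
        if centers.size < 2:
            spacing = 1.0  # irrelevant for a single band
        else:
            # median inter-peak distance, dividing out the integer multiples a
            # missing band introduces (a skipped topoisomer doubles one gap)
            diffs = np.diff(centers)
            multiples = np.maximum(1, np.rint(diffs / diffs.min()))
            spacing = float(np.median(diffs / multiples))
    else:
        spacing = float(expected_spacing_px)
    if spacing <= 0:
        raise InvalidParameterError("expected_spacing_px must be positive")
    anchor = centers[0] if origin_px is None else float(origin_px)
    indices = np.rint((centers - anchor) / spacing).astype(int)
    if np.unique(indices).size != indices.size:
        dup = indices[np.concatenate(([False], np.diff(indices) == 0))]
        positions = centers[np.isin(indices, dup)]
        raise AmbiguousLadderError(
            f"peaks at positions {positions.tolist()} map to the same Lk index; "
            f"spacing {spacing:.3g} px is inconsistent with the peak layout"
        )
    return BandTable(lane_id, centers, intensities, indices)


def weighted_mean_lk(bands: BandTable) -> float:
    """Intensity-weighted mean linking number of a lane,
    sum(I_i * Lk_i) / sum(I_i)."""
    if len(bands) == 0:
        raise NoBandsError(f"lane {bands.lane_id!r} has no bands")
    if np.any(bands.integrated_intensities <= 0):
        raise InvalidBandError(
            f"lane {bands.lane_id!r} has a band with nonpositive intensity"
        )
    w = bands.integrated_intensities
    return float(np.sum(w * bands.lk_indices) / np.sum(w))


def quantify_profile(
    profile: LaneProfile,
    background_window_px: int = 180,
    min_prominence_frac: float = 0.05,
    min_separation_px: float = 5.0,
    smoothing_sigma_px: float = 0.0,
    min_width_px: float = 0.0,
    expected_spacing_px: float | str = "auto",
    origin_px: float | None = None,
) -> tuple[BandTable, float]:
    """Full single-lane chain: background subtraction, band detection, ladder
    indexing, weighted mean Lk.  Returns ``(band_table, weighted_lk)``."""
    corrected = subtract_background(profile, background_window_px,
                                    presmooth_sigma_px=smoothing_sigma_px)
    peaks = detect_bands(corrected, min_prominence_frac, min_separation_px,
                         smoothing_sigma_px, min_width_px)
    bands = assign_linking_numbers(
        peaks, expected_spacing_px, lane_id=profile.lane_id, origin_px=origin_px
    )
    return bands, weighted_mean_lk(bands)


def quantify_lanes(
    profiles: Mapping[str, LaneProfile] | Iterable[LaneProfile],
    background_window_px: int = 180,
    min_prominence_frac: float = 0.05,
    min_separation_px: float = 5.0,
    smoothing_sigma_px: float = 0.0,
    min_width_px: float = 0.0,
) -> tuple[dict[str, BandTable], pd.DataFrame]:
    """Quantify all lanes of one gel on a common ladder.

    Bands of every lane are detected independently, then a shared spacing
    (median of all inter-peak distances) and a shared origin (the topmost
    detected band across the gel) anchor all indices on one scale, as when
    reading aligned bands across lanes of a physical gel.  Returns the per-
    lane band tables and a tidy frame ``(lane_id, n_bands, weighted_lk)``.
    """
    if isinstance(profiles, Mapping):
        lanes = list(profiles.values())
    else:
        lanes = list(profiles)
    per_lane_peaks: dict[str, list[Peak]] = {}
    gaps: list[float] = []
    for lane in lanes:
        corrected = subtract_background(lane, background_window_px,
                                        presmooth_sigma_px=smoothing_sigma_px)
        peaks = detect_bands(corrected, min_prominence_frac, min_separation_px,
                             smoothing_sigma_px, min_width_px)
        per_lane_peaks[lane.lane_id] = peaks
        centers = sorted(p.center_px for p in peaks)
        gaps.extend(np.diff(centers).tolist())
    if not gaps:
        raise NoBandsError("no lane produced at least two bands; cannot infer spacing")
    spacing = float(np.median(gaps))
    origin = min(
        min((p.center_px for p in peaks), default=math.inf)
        for peaks in per_lane_peaks.values()
    )
    tables: dict[str, BandTable] = {}
    rows = []
    for lane in lanes:
        peaks = per_lane_peaks[lane.lane_id]
        if not peaks:
            raise NoBandsError(f"no bands detected in lane {lane.lane_id!r}")
        bands = assign_linking_numbers(
            peaks, spacing, lane_id=lane.lane_id, origin_px=origin
        )
        tables[lane.lane_id] = bands
        rows.append(
            {
                "lane_id": lane.lane_id,
                "n_bands": len(bands),
                "weighted_lk": weighted_mean_lk(bands),
            }
        )
    return tables, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Text I/O

def read_profile_csv(path, lane_id: str | None = None) -> LaneProfile:
    """Read a two-column CSV (position_px, intensity)."""
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise InvalidParameterError(f"{path}: expected columns position_px,intensity")
    return LaneProfile(
        df.iloc[:, 0].to_numpy(float),
        df.iloc[:, 1].to_numpy(float),
        lane_id or str(path),
    )


def write_profile_csv(profile: LaneProfile, path) -> None:
    pd.DataFrame(
        {"position_px": profile.positions, "intensity": profile.intensities}
    ).to_csv(path, index=False)


def write_band_tables(tables: Iterable[BandTable], path) -> None:
    """Write band tables as TSV (lane_id, lk_index, center_px, integrated_intensity)."""
    frames = [t.to_frame() for t in tables]
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


def read_band_tables(path) -> dict[str, BandTable]:
    df = pd.read_csv(path, sep="\t")
    out: dict[str, BandTable] = {}
    for lane_id, grp in df.groupby("lane_id", sort=False):
        grp = grp.sort_values("center_px")
        out[str(lane_id)] = BandTable(
            str(lane_id),
            grp["center_px"].to_numpy(float),
            grp["integrated_intensity"].to_numpy(float),
            grp["lk_index"].to_numpy(int),
        )
    return out
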