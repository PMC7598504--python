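"""Supercoiling statistics: RSU normalization, gyrase activity, and group
comparisons.

RSU (Relative Supercoiling Unit) is a cross-gel normalization of the
intensity-weighted mean linking number.  Two reference lanes run on every
gel anchor the scale: the 0-RSU reference (wild type grown in high Mg2+) and
the 1-RSU reference (wild type in low Mg2+); any lane's RSU is its linear
coordinate on that axis,

    RSU = (<Lk> - <Lk>_ref0) / (<Lk>_ref1 - <Lk>_ref0).

Because the scale is relative, no claim is made about which direction is
"more negative" supercoiling; results carry both reference lane labels.
With the references typically separated by about half a linking number, one
full linking number difference converts into about 2 RSU.

DNA gyrase activity is the signed change in weighted mean apparent Lk per
hour relative to the starting topoisomer distribution; relative activity is
the percent variation against a no-polyamine baseline.

Group comparisons implement Student/Welch t-tests and Tukey's HSD with a
compact-letter display.  The HSD procedure (one-way ANOVA mean squares,
Tukey-Kramer studentized-range statistics, insert-and-absorb lettering) is
implemented here from its definition; only the studentized-range
distribution function is delegated to scipy.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    DegenerateBaselineError,
    DegenerateReferenceError,
    InsufficientReplicatesError,
    InvalidDesignError,
    InvalidDurationError,
    InvalidParameterError,
)

__all__ = [
    "SupercoilingResult",
    "ActivityResult",
    "GroupComparison",
    "rsu",
    "rsu_from_table",
    "gyrase_activity",
    "relative_activity",
    "compare_groups",
]

REFERENCE_SEPARATION_TOL = 1e-9


@dataclass(frozen=True)
class SupercoilingResult:
    """Weighted mean Lk of a lane with its RSU coordinate and the labels of
    the two reference lanes that define the scale."""

    lane_id: str
    weighted_lk: float
    rsu: float
    ref0_lane: str
    ref1_lane: str


@dataclass(frozen=True)
class ActivityResult:
    condition: str
    activity_dlk_per_h: float
    relative_variation_pct: float


def rsu(weighted_lk: float, ref0_lk: float, ref1_lk: float) -> float:
    """Relative Supercoiling Units of a lane given the two reference lanes.

    Linear in weighted Lk: the ref0 lane maps to 0, the ref1 lane to 1, and a
    lane offset by one full linking number from ref0 maps to
    ``1/(ref1_lk - ref0_lk)``.
    """
    separation = ref1_lk - ref0_lk
    if abs(separation) <= REFERENCE_SEPARATION_TOL:
        raise DegenerateReferenceError(
            f"reference lanes are not separated in weighted Lk "
            f"(ref0={ref0_lk}, ref1={ref1_lk})"
        )
    return (weighted_lk - ref0_lk) / separation


def rsu_from_table(table: pd.DataFrame) -> list[SupercoilingResult]:
    """Normalize a weighted-Lk table to RSU, batch by batch.

    ``table`` needs columns ``lane_id``, ``weighted_lk``, ``role`` (one of
    ``ref0``, ``ref1``, ``sample``) and optionally ``batch`` (one gel per
    batch; a single batch is assumed when absent).  References are only ever
    used within their own batch, so cross-gel comparison happens on the RSU
    scale alone.
    """
    df = table.copy()
    if "batch" not in df.columns:
        df["batch"] = "batch0"
    results: list[SupercoilingResult] = []
    for batch, grp in df.groupby("batch", sort=False):
        refs = {}
        for role in ("ref0", "ref1"):
            sel = grp[grp["role"] == role]
            if len(sel) != 1:
                raise InvalidParameterError(
                    f"batch {batch!r} must contain exactly one {role} lane, found {len(sel)}"
                )
            refs[role] = sel.iloc[0]
        for _, row in grp.iterrows():
            results.append(
                SupercoilingResult(
                    lane_id=str(row["lane_id"]),
                    weighted_lk=float(row["weighted_lk"]),
                    rsu=rsu(
                        float(row["weighted_lk"]),
                        float(refs["ref0"]["weighted_lk"]),
                        float(refs["ref1"]["weighted_lk"]),
                    ),
                    ref0_lane=str(refs["ref0"]["lane_id"]),
                    ref1_lane=str(refs["ref1"]["lane_id"]),
                )
            )
    return results


def gyrase_activity(initial_wlk: float, final_wlk: float, hours: float) -> float:
    """Signed change in weighted mean apparent Lk per hour; relaxation gives
    negative values."""
    if hours <= 0:
        raise InvalidDurationError(f"hours must be positive, got {hours}")
    return (final_wlk - initial_wlk) / hours


def relative_activity(activity: float, baseline_activity: float) -> float:
    """Percent variation of an activity against the no-polyamine baseline;
    the baseline itself maps to 0%."""
    if baseline_activity == 0:
        raise DegenerateBaselineError("baseline activity is zero; relative variation undefined")
    return 100.0 * (activity - baseline_activity) / baseline_activity


# ---------------------------------------------------------------------------
# Group comparisons


@dataclass(frozen=True)
class GroupComparison:
    """Result of a multi-group comparison.

    ``letters`` is the compact-letter display: two groups share a letter if
    and only if their adjusted p-value is >= alpha.
    """

    method: str
    alpha: float
    summary: pd.DataFrame  # group, n, mean, sd, letters (ordered by mean desc)
    pairwise: pd.DataFrame  # group1, group2, statistic, p_adj, significant
    letters: dict[str, str]


def _tukey_pairwise(groups: dict[str, np.ndarray]) -> pd.DataFrame:
    """Tukey-Kramer pairwise p-values from the studentized-range distribution.

    q_ij = |mean_i - mean_j| / sqrt(MSE/2 * (1/n_i + 1/n_j)) with MSE the
    one-way ANOVA within-group mean square on N - k degrees of freedom;
    p_ij = P(Q_{k, N-k} >= q_ij).
    """
    labels = list(groups)
    k = len(labels)
    n = {g: v.size for g, v in groups.items()}
    means = {g: float(v.mean()) for g, v in groups.items()}
    big_n = sum(n.values())
    df_err = big_n - k
    sse = sum(float(((v - means[g]) ** 2).sum()) for g, v in groups.items())
    mse = sse / df_err
    rows = []
    for a, b in itertools.combinations(labels, 2):
        diff = abs(means[a] - means[b])
        if mse == 0:
            q = np.inf if diff > 0 else 0.0
            p = 0.0 if diff > 0 else 1.0
        else:
            se = np.sqrt(mse / 2.0 * (1.0 / n[a] + 1.0 / n[b]))
            q = diff / se
            p = float(stats.studentized_range.sf(q, k, df_err))
        rows.append({"group1": a, "group2": b, "statistic": q, "p_adj": p})
    return pd.DataFrame(rows)


def _compact_letters(ordered: Sequence[str], sig_pairs: set[frozenset]) -> dict[str, str]:
    """Insert-and-absorb compact-letter display.

    Start from one column holding every group; for each significantly
    different pair, split every column containing both, then absorb columns
    that became subsets of others.  Sharing a letter is then equivalent to
    non-significance.
    """
    columns: list[set[str]] = [set(ordered)]
    for pair in sig_pairs:
        a, b = tuple(pair)
        for col in [c for c in columns if a in c and b in c]:
            columns.remove(col)
            columns.extend([col - {a}, col - {b}])
        # absorb: drop empties, proper subsets of other columns, and duplicates
        kept: list[set[str]] = []
        for c in columns:
            if not c or any(c < d for d in columns):
                continue
            if c not in kept:
                kept.append(c)
        columns = kept
    # order columns by the rank of their top-most (largest-mean) member for
    # deterministic letter assignment
    rank = {g: i for i, g in enumerate(ordered)}
    columns.sort(key=lambda c: min(rank[g] for g in c))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters: dict[str, list[str]] = {g: [] for g in ordered}
    for i, col in enumerate(columns):
        letter = alphabet[i % len(alphabet)] * (1 + i // len(alphabet))
        for g in col:
            letters[g].append(letter)
    return {g: "".join(sorted(v)) for g, v in letters.items()}


def compare_groups(
    samples: Mapping[str, Sequence[float]],
    method: str = "tukey",
    alpha: float = 0.05,
) -> GroupComparison:
    """Compare groups of replicate measurements.

    ``method`` is one of ``tukey`` (one-way ANOVA + Tukey's HSD, any number
    of groups, each with n >= 2), ``student_t`` (two groups, pooled
    variance) or ``welch_t`` (two groups, unequal variances).  Groups of
    n = 2 are accepted for Tukey — small designs are common in gel work —
    with a low-replication warning.
    """
    if not 0 < alpha < 1:
        raise InvalidParameterError("alpha must be in (0, 1)")
    groups = {str(g): np.asarray(v, dtype=float) for g, v in samples.items()}
    if len(groups) < 2:
        raise InvalidDesignError("need at least two groups to compare")
    if method == "tukey":
        for g, v in groups.items():
            if v.size < 2:
                raise InsufficientReplicatesError(
                    f"group {g!r} has n={v.size}; Tukey's HSD needs n >= 2 per group"
                )
        if min(v.size for v in groups.values()) == 2:
            warnings.warn(
                "a group has only n = 2 replicates; Tukey's HSD p-values will have "
                "very low power",
                stacklevel=2,
            )
        pairwise = _tukey_pairwise(groups)
    elif method in ("student_t", "welch_t"):
        if len(groups) != 2:
            raise InvalidDesignError(f"{method} compares exactly two groups, got {len(groups)}")
        (a, va), (b, vb) = groups.items()
        res = stats.ttest_ind(va, vb, equal_var=(method == "student_t"))
        pairwise = pd.DataFrame(
            [{"group1": a, "group2": b, "statistic": abs(float(res.statistic)),
              "p_adj": float(res.pvalue)}]
        )
    else:
        raise InvalidParameterError(f"unknown method {method!r}")
    pairwise["significant"] = pairwise["p_adj"] < alpha
    # deterministic ordering: mean descending, ties by label
    ordered = sorted(groups, key=lambda g: (-groups[g].mean(), g))
    sig_pairs = {
        frozenset((r.group1, r.group2)) for r in pairwise.itertuples() if r.significant
    }
    letters = _compact_letters(ordered, sig_pairs)
    summary = pd.DataFrame(
        {
            "group": ordered,
            "n": [groups[g].size for g in ordered],
            "mean": [float(groups[g].mean()) for g in ordered],
            "sd": [float(groups[g].std(ddof=1)) for g in ordered],
            "letters": [letters[g] for g in ordered],
        }
    )
    return GroupComparison(method, alpha, summary, pairwise, letters)
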