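"""Landmark-based accuracy statistics for age-to-age transformations.

A panel of raters independently records a set of anatomical landmarks in
each template age; the automated transform ("matrix") places the same
landmarks by warping the adult coordinates. Each subject's error at a
landmark is its Euclidean distance (in µm) to the *median* coordinate of
the other raters — the median, not the mean, because it is robust to the
occasional gross outlier (e.g. a typo in a manually recorded coordinate).
Since each rater is scored against the median of the R−1 others, the matrix
is scored the same way: against the median of every size-(R−1) subset of
raters, averaged over subsets. Per-age matrix-vs-average-rater differences
are compared with a two-tailed t test.

The "median coordinate" of a point set is taken componentwise (per axis);
this is the convention that yields a well-defined coordinate for any rater
count. A geometric (spatial) median would be a defensible alternative.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .core import AtlasSpace, IntensityVolume, LabelVolume, DEFAULT_SPACING_UM
from .fields import round_half_down

__all__ = [
    "MATRIX_ID",
    "LandmarkTable",
    "TTestResult",
    "ConcordanceReport",
    "median_of_others",
    "rater_error",
    "matrix_error",
    "compare_errors",
    "concordance_report",
    "error_heatmap",
    "group_by_region",
]

#: Reserved subject id for the automated transformation's coordinates.
MATRIX_ID = "matrix"

_REQUIRED_COLUMNS = ("landmark_id", "rater_id", "age", "x", "y", "z")


@dataclass
class LandmarkTable:
    """Long-format landmark records: one row per (landmark, subject, age).

    ``rater_id`` is a rater name or :data:`MATRIX_ID` for the automated
    transform. Coordinates are voxels; ``spacing`` (µm) converts distances.
    A landmark not identified by *all* raters at an age is excluded from
    that age's statistics.
    """

    df: pd.DataFrame
    spacing: float = DEFAULT_SPACING_UM

    def __post_init__(self) -> None:
        missing = [c for c in _REQUIRED_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"landmark table missing columns {missing}")
        if not (self.spacing > 0):
            raise ValueError("spacing must be positive")
        dup = self.df.duplicated(subset=["landmark_id", "rater_id", "age"])
        if dup.any():
            rows = (self.df.index[dup] + 2).tolist()  # +2: header + 0-base
            raise ValueError(
                f"duplicate (landmark_id, rater_id, age) rows at lines {rows}"
            )
        if not np.all(np.isfinite(self.df[["x", "y", "z"]].to_numpy(float))):
            raise ValueError("non-finite landmark coordinate")

    def raters(self, age: float) -> list:
        sub = self.df[(self.df["age"] == age)
                      & (self.df["rater_id"] != MATRIX_ID)]
        return sorted(sub["rater_id"].unique().tolist())

    def ages(self) -> list:
        return sorted(self.df["age"].unique().tolist())

    def coords(self, age: float, subjects: list) -> pd.DataFrame:
        """Wide table landmark → subject → (x, y, z), restricted to
        landmarks present for *every* listed subject at ``age``."""
        sub = self.df[(self.df["age"] == age)
                      & (self.df["rater_id"].isin(subjects))]
        counts = sub.groupby("landmark_id")["rater_id"].nunique()
        complete = counts[counts == len(subjects)].index
        sub = sub[sub["landmark_id"].isin(complete)]
        return sub.set_index(["landmark_id", "rater_id"])[["x", "y", "z"]]


def median_of_others(coords: dict, excluded_rater) -> np.ndarray:
    """Componentwise median of all raters' coordinates except one."""
    others = [np.asarray(v, dtype=float)
              for r, v in coords.items() if r != excluded_rater]
    if len(others) < 2:
        raise ValueError(
            f"need >= 2 raters besides {excluded_rater!r}, have {len(others)}"
        )
    return np.median(np.stack(others), axis=0)


def rater_error(table: LandmarkTable, rater, age: float):
    """Mean distance (µm) of one rater's landmarks to the componentwise
    median of the other raters, plus the per-landmark distances."""
    raters = table.raters(age)
    if rater not in raters:
        raise ValueError(f"rater {rater!r} not present at age P{age}")
    wide = table.coords(age, raters)
    landmarks = wide.index.get_level_values("landmark_id").unique()
    if len(landmarks) == 0:
        raise ValueError(f"no landmarks common to all raters at age P{age}")
    dists = {}
    for lm in landmarks:
        pts = {r: wide.loc[(lm, r)].to_numpy(float) for r in raters}
        med = median_of_others(pts, rater)
        dists[lm] = float(np.linalg.norm(pts[rater] - med)) * table.spacing
    per_landmark = pd.Series(dists, name=f"{rater}")
    return float(per_landmark.mean()), per_landmark


def matrix_error(table: LandmarkTable, age: float, n_subset: int | None = None):
    """Mean distance (µm) of the automated transform's landmarks to rater
    subset medians, averaged over every size-``n_subset`` rater combination
    (default: one fewer than the rater count, mirroring the per-rater
    statistic). Also returns per-landmark distances."""
    raters = table.raters(age)
    if n_subset is None:
        n_subset = len(raters) - 1
    if not (2 <= n_subset <= len(raters)):
        raise ValueError(f"subset size {n_subset} invalid for {len(raters)} raters")
    wide = table.coords(age, raters + [MATRIX_ID])
    if MATRIX_ID not in wide.index.get_level_values("rater_id"):
        raise ValueError(f"no matrix coordinates at age P{age}")
    landmarks = wide.index.get_level_values("landmark_id").unique()
    if len(landmarks) == 0:
        raise ValueError(f"no landmarks common to all subjects at age P{age}")
    dists = {}
    for lm in landmarks:
        m = wide.loc[(lm, MATRIX_ID)].to_numpy(float)
        subset_d = [
            float(np.linalg.norm(
                m - np.median(np.stack([wide.loc[(lm, r)].to_numpy(float)
                                        for r in combo]), axis=0)))
            for combo in combinations(raters, n_subset)
        ]
        dists[lm] = float(np.mean(subset_d)) * table.spacing
    per_landmark = pd.Series(dists, name=MATRIX_ID)
    return float(per_landmark.mean()), per_landmark


@dataclass(frozen=True)
class TTestResult:
    statistic: float
    pvalue: float
    dof: int
    paired: bool
    degenerate: bool = False


def compare_errors(per_landmark_rater_avg, per_landmark_matrix,
                   paired: bool = True) -> TTestResult:
    """Two-tailed t test of average-rater vs matrix per-landmark errors.

    Paired over landmarks by default (both subjects are scored on the same
    landmark set); an unpaired Welch variant is available via
    ``paired=False``. Zero variance of the paired differences yields
    t = 0, p = 1 with a degenerate flag instead of a NaN.
    """
    a = np.asarray(per_landmark_rater_avg, dtype=float)
    b = np.asarray(per_landmark_matrix, dtype=float)
    if paired:
        if a.shape != b.shape:
            raise ValueError("paired comparison needs equal-length vectors")
        d = a - b
        if np.allclose(d.var(ddof=0), 0.0):
            return TTestResult(0.0, 1.0, dof=len(d) - 1, paired=True,
                               degenerate=True)
        res = stats.ttest_rel(a, b)
        return TTestResult(float(res.statistic), float(res.pvalue),
                           dof=len(d) - 1, paired=True)
    if np.allclose(a.var(ddof=0), 0.0) and np.allclose(b.var(ddof=0), 0.0):
        return TTestResult(0.0, 1.0, dof=len(a) + len(b) - 2, paired=False,
                           degenerate=True)
    res = stats.ttest_ind(a, b, equal_var=False)
    return TTestResult(float(res.statistic), float(res.pvalue),
                       dof=int(res.df), paired=False)


@dataclass
class ConcordanceReport:
    """Per-(age, subject) mean distances, per-landmark distances, and the
    per-age matrix-vs-average-rater test."""

    mean_errors: pd.DataFrame  # columns: age, subject, mean_um
    per_landmark: pd.DataFrame  # columns: age, subject, landmark_id, distance_um
    tests: pd.DataFrame  # columns: age, statistic, pvalue, dof, degenerate


def concordance_report(table: LandmarkTable,
                       ages: list | None = None,
                       paired: bool = True) -> ConcordanceReport:
    """Full accuracy report: every rater, the average rater, and the
    automated matrix, per age, with significance tests."""
    ages = ages if ages is not None else table.ages()
    means, per_lm, tests = [], [], []
    for age in ages:
        raters = table.raters(age)
        rater_series = []
        for r in raters:
            m, s = rater_error(table, r, age)
            means.append({"age": age, "subject": r, "mean_um": m})
            rater_series.append(s)
            per_lm.extend({"age": age, "subject": r, "landmark_id": lm,
                           "distance_um": d} for lm, d in s.items())
        avg = pd.concat(rater_series, axis=1).mean(axis=1)
        means.append({"age": age, "subject": "average_rater",
                      "mean_um": float(avg.mean())})
        mm, ms = matrix_error(table, age)
        means.append({"age": age, "subject": MATRIX_ID, "mean_um": mm})
        per_lm.extend({"age": age, "subject": MATRIX_ID, "landmark_id": lm,
                       "distance_um": d} for lm, d in ms.items())
        common = avg.index.intersection(ms.index)
        t = compare_errors(avg.loc[common], ms.loc[common], paired=paired)
        tests.append({"age": age, "statistic": t.statistic,
                      "pvalue": t.pvalue, "dof": t.dof,
                      "degenerate": t.degenerate})
    return ConcordanceReport(
        mean_errors=pd.DataFrame(means),
        per_landmark=pd.DataFrame(per_lm),
        tests=pd.DataFrame(tests),
    )


def error_heatmap(sites: np.ndarray, errors: np.ndarray,
                  space: AtlasSpace) -> IntensityVolume:
    """Nearest-landmark error map: every voxel takes the error of its
    nearest assessed coordinate (Euclidean; ties toward the smaller
    landmark index). Gives the 3D heatmap rendering of per-landmark
    errors."""
    sites = np.atleast_2d(np.asarray(sites, dtype=float))
    errors = np.asarray(errors, dtype=float)
    if sites.shape[0] == 0:
        raise ValueError("need at least one landmark site")
    if sites.shape[0] != errors.shape[0]:
        raise ValueError("one error value per site required")
    grid = np.indices(space.shape, dtype=float)
    best_d2 = np.full(space.shape, np.inf)
    out = np.zeros(space.shape, dtype=float)
    # ascending site order + strict '<' keeps ties on the smaller index
    for site, err in zip(sites, errors):
        d2 = ((grid[0] - site[0]) ** 2 + (grid[1] - site[1]) ** 2
              + (grid[2] - site[2]) ** 2)
        closer = d2 < best_d2
        best_d2[closer] = d2[closer]
        out[closer] = err
    return IntensityVolume(space=space, values=out)


def group_by_region(sites: np.ndarray, errors: np.ndarray,
                    labels: LabelVolume) -> pd.DataFrame:
    """Average per-landmark errors by the brain region containing each
    landmark (label at the rounded voxel). Landmarks outside the grid are
    excluded with a warning. Returns columns region_id, region_name,
    mean_error_um, n_landmarks."""
    sites = np.atleast_2d(np.asarray(sites, dtype=float))
    errors = np.asarray(errors, dtype=float)
    idx = round_half_down(sites)
    shape = np.asarray(labels.space.shape)
    inside = np.all((idx >= 0) & (idx < shape), axis=1)
    if not inside.all():
        warnings.warn(
            f"{int((~inside).sum())} landmark(s) outside the grid excluded "
            "from region grouping", RuntimeWarning,
        )
    idx, errors = idx[inside], errors[inside]
    region = labels.labels[idx[:, 0], idx[:, 1], idx[:, 2]]
    df = pd.DataFrame({"region_id": region, "error_um": errors})
    grouped = df.groupby("region_id")["error_um"].agg(["mean", "size"])
    name = (labels.table.name if labels.table is not None
            else (lambda i, default="": default))
    return pd.DataFrame({
        "region_id": grouped.index,
        "region_name": [name(i, default=str(i)) for i in grouped.index],
        "mean_error_um": grouped["mean"].to_numpy(),
        "n_landmarks": grouped["size"].to_numpy(),
    }).reset_index(drop=True)
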