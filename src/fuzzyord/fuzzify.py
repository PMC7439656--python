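"""Build discrete fuzzy sets on the 0-100 grid from elicited perceptions.

Each ordinal level gets a fuzzy set represented by a non-negative weight
function over the integer grid 0..100 (or coarser bin centers after
binning).  Three construction routes are available, mirroring the three
kinds of elicited information:

* ``fuzzify_from_points`` — count how often each value was named as the
  representative point of the level;
* ``fuzzify_from_interval_centers`` — reduce each elicited interval to its
  midpoint and count midpoints;
* ``fuzzify_from_whole_intervals`` — spread each interval [l, u] over its
  member values with weight 1/(u - l + 1), so every interval contributes
  total mass exactly 1.

The resulting sets need not be convex or unimodal fuzzy numbers; they are
whatever the respondents' collective perception produced.  Two normalised
views are derived on demand: ``membership`` (weights divided by their
maximum, so the modal value has membership 1) and ``prob`` (weights divided
by their sum, a probability distribution over the grid).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .survey_io import IntervalResponse, _round_half_up

#: The elicitation grid: integer values 0..100.
DEFAULT_GRID = np.arange(101)


class DegenerateInputError(ValueError):
    """Raised when a fuzzy set would be built from no data (or zero mass)."""


@dataclass
class FuzzySet:
    """A discrete weight function over a value grid for one ordinal level.

    Attributes
    ----------
    level
        The ordinal label the set gives semantics to.
    grid
        Strictly increasing grid values (integers 0..100 for raw sets, bin
        centers after :func:`bin_fuzzy_set`).
    raw_weight
        Non-negative weight per grid value; at least one entry is positive.
    """

    level: str
    grid: np.ndarray
    raw_weight: np.ndarray

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.raw_weight = np.asarray(self.raw_weight, dtype=float)
        if self.grid.shape != self.raw_weight.shape or self.grid.ndim != 1:
            raise ValueError("grid and raw_weight must be 1-d arrays of equal length")
        if np.any(np.diff(self.grid) <= 0):
            raise ValueError("grid must be strictly increasing")
        if np.any(self.raw_weight < 0):
            raise ValueError("raw_weight must be non-negative")
        if not np.any(self.raw_weight > 0):
            raise DegenerateInputError(f"fuzzy set for {self.level!r} has zero total mass")

    @property
    def total_mass(self) -> float:
        return float(self.raw_weight.sum())

    @property
    def membership(self) -> np.ndarray:
        """Max-normalised weights: the modal grid value has membership 1."""
        return self.raw_weight / self.raw_weight.max()

    @property
    def prob(self) -> np.ndarray:
        """Sum-normalised weights: a probability distribution over the grid."""
        return self.raw_weight / self.raw_weight.sum()

    def support(self) -> tuple[float, float]:
        """(min, max) grid values with positive weight."""
        pos = self.grid[self.raw_weight > 0]
        return float(pos.min()), float(pos.max())

    def membership_at(self, x: float) -> float:
        """Membership at grid value *x*; 0 if *x* is not on the grid."""
        idx = np.nonzero(self.grid == x)[0]
        return float(self.membership[idx[0]]) if idx.size else 0.0

    # -- serialization: only level/grid/raw_weight are stored; the
    #    normalised views are always recomputed on load.
    def to_dict(self) -> dict:
        return {
            "level": self.level,
            "grid": self.grid.tolist(),
            "raw_weight": self.raw_weight.tolist(),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "FuzzySet":
        return cls(level=d["level"], grid=np.asarray(d["grid"]), raw_weight=np.asarray(d["raw_weight"]))

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_json(cls, s: str) -> "FuzzySet":
        return cls.from_dict(json.loads(s))


def _check_points(points: Sequence[int], level: str) -> np.ndarray:
    pts = np.asarray(list(points))
    if pts.size == 0:
        raise DegenerateInputError(f"no points to fuzzify for level {level!r}")
    if np.any((pts < 0) | (pts > 100)):
        raise ValueError("points must lie in [0, 100]")
    return pts.astype(int)


def fuzzify_from_points(points: Sequence[int], level: str) -> FuzzySet:
    """Fuzzy set from single-value elicitations: weight(x) = #occurrences of x."""
    pts = _check_points(points, level)
    counts = np.bincount(pts, minlength=101).astype(float)
    return FuzzySet(level=level, grid=DEFAULT_GRID.copy(), raw_weight=counts)


def interval_central_tendency(r: IntervalResponse, method: str = "midpoint") -> int:
    """Collapse an interval to a single value.

    For one interval the centroid and the median coincide at the midpoint,
    so ``midpoint`` is the only method; the result is rounded half-up to the
    integer grid.
    """
    if method != "midpoint":
        raise ValueError(f"unknown central-tendency method {method!r}")
    return _round_half_up((r.lower + r.upper) / 2)


def fuzzify_from_interval_centers(
    responses: Sequence[IntervalResponse], level: str
) -> FuzzySet:
    """Fuzzy set from interval midpoints (central-tendency route)."""
    if len(responses) == 0:
        raise DegenerateInputError(f"no intervals to fuzzify for level {level!r}")
    return fuzzify_from_points([interval_central_tendency(r) for r in responses], level)


def fuzzify_from_whole_intervals(
    responses: Sequence[IntervalResponse], level: str
) -> FuzzySet:
    """Fuzzy set from whole intervals with inverse-width weights.

    Each interval [l, u] adds weight 1/(u - l + 1) to every grid value it
    covers, so each interval contributes total mass exactly 1 and the total
    mass equals the number of intervals.  A degenerate interval [x, x] is a
    unit point mass.
    """
    if len(responses) == 0:
        raise DegenerateInputError(f"no intervals to fuzzify for level {level!r}")
    weight = np.zeros(101)
    for r in responses:
        weight[r.lower : r.upper + 1] += 1.0 / (r.upper - r.lower + 1)
    return FuzzySet(level=level, grid=DEFAULT_GRID.copy(), raw_weight=weight)


def bin_fuzzy_set(f: FuzzySet, granularity: int) -> FuzzySet:
    """Coarsen a fuzzy set by summing weights over consecutive bins.

    Grid values are partitioned, starting from the smallest grid value, into
    consecutive runs of ``granularity`` values (the last bin may be short).
    A bin is represented by the arithmetic mean of its grid values and
    carries the sum of their weights, so total mass is preserved.
    """
    if granularity < 1:
        raise ValueError("granularity must be >= 1")
    if granularity == 1:
        return FuzzySet(level=f.level, grid=f.grid.copy(), raw_weight=f.raw_weight.copy())
    centers = []
    weights = []
    for start in range(0, len(f.grid), granularity):
        sl = slice(start, start + granularity)
        centers.append(float(f.grid[sl].mean()))
        weights.append(float(f.raw_weight[sl].sum()))
    return FuzzySet(level=f.level, grid=np.asarray(centers), raw_weight=np.asarray(weights))


def fuzzify_survey(
    responses: Iterable[IntervalResponse],
    levels: Sequence[str],
    route: str = "whole_intervals",
) -> dict[str, FuzzySet]:
    """Build one fuzzy set per level from a flat list of interval responses.

    ``route`` is one of ``points`` (representative points), ``interval_centers``
    or ``whole_intervals``.
    """
    by_level: dict[str, list[IntervalResponse]] = {v: [] for v in levels}
    for r in responses:
        if r.level in by_level:
            by_level[r.level].append(r)
    out: dict[str, FuzzySet] = {}
    for v in levels:
        rs = by_level[v]
        if route == "points":
            pts = [r.representative_point for r in rs if r.representative_point is not None]
            out[v] = fuzzify_from_points(pts, v)
        elif route == "interval_centers":
            out[v] = fuzzify_from_interval_centers(rs, v)
        elif route == "whole_intervals":
            out[v] = fuzzify_from_whole_intervals(rs, v)
        else:
            raise ValueError(f"unknown fuzzification route {route!r}")
    return out
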