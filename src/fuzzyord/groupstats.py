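"""Compare perception distributions across rater strata and summarise the
qualitative inverse mapping.

The quantitative comparison works on *interval extreme distributions*
(IEDs): for one level and one stratum, the pooled lower and upper interval
endpoints (or interval midpoints, or representative points).  Strata are
compared per level with a two-sample Kolmogorov-Smirnov test (shape) and a
Mann-Whitney U test (location / mean ranks); no multiplicity correction is
applied across levels.

The qualitative summary bins the 1-99 value range and classifies each bin's
most common label by prevalence: *superiority* (mode), *majority* (mode
share > 50%), *statistical majority* (additionally, a 1-df chi-square
goodness-of-fit test between the two most common labels rejects equality at
p < 0.05).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .scale import OrdinalScale, SEVERITY
from .survey_io import IntervalResponse, QualitativeResponse
from .fuzzify import interval_central_tendency

SOURCES = ("extremes", "centroids", "rps")


class DegenerateSampleError(ValueError):
    """A comparison was requested on an empty sample."""


@dataclass
class IEDSample:
    """Values observed for one (level, stratum), tagged by their source."""

    level: str
    stratum: str
    values: np.ndarray
    source: str = "extremes"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size == 0:
            raise DegenerateSampleError(
                f"empty sample for level {self.level!r}, stratum {self.stratum!r}"
            )
        if np.any((self.values < 0) | (self.values > 100)):
            raise ValueError("IED values must lie in [0, 100]")


def ied_sample(
    responses: Iterable[IntervalResponse], level: str, stratum: str, source: str = "extremes"
) -> IEDSample:
    """Extract the IED sample for one (level, stratum) from raw responses.

    ``extremes`` pools both interval endpoints (two values per respondent),
    ``centroids`` takes interval midpoints, ``rps`` the representative
    points (responses without one are skipped).
    """
    if source not in SOURCES:
        raise ValueError(f"unknown IED source {source!r}")
    rs = [r for r in responses if r.level == level and r.stratum == stratum]
    if source == "extremes":
        values = [x for r in rs for x in (r.lower, r.upper)]
    elif source == "centroids":
        values = [interval_central_tendency(r) for r in rs]
    else:
        values = [r.representative_point for r in rs if r.representative_point is not None]
    if not values:
        raise DegenerateSampleError(
            f"no {source} values for level {level!r}, stratum {stratum!r}"
        )
    return IEDSample(level=level, stratum=stratum, values=np.asarray(values), source=source)


def ks_compare(a: IEDSample, b: IEDSample) -> tuple[float, float]:
    """Two-sample two-sided Kolmogorov-Smirnov test between two IEDs.

    Returns (D, p) where D = sup |ECDF_a - ECDF_b|.
    """
    res = stats.ks_2samp(a.values, b.values, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)


def mw_compare(a: IEDSample, b: IEDSample) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test with tie correction.

    Returns (U, p) with U counting pairs where a exceeds b (ties count
    half), i.e. U = 0 when every b value exceeds every a value.  The exact
    null distribution is used for small tie-free samples, the
    normal approximation otherwise (scipy's automatic policy).
    """
    res = stats.mannwhitneyu(a.values, b.values, alternative="two-sided", method="auto")
    return float(res.statistic), float(res.pvalue)


def compare_all_levels(
    responses: Iterable[IntervalResponse],
    scale: OrdinalScale = SEVERITY,
    source: str = "extremes",
    strata: tuple[str, str] | None = None,
) -> pd.DataFrame:
    """Per-level stratum comparison table (KS and Mann-Whitney, raw p-values).

    Returns a DataFrame indexed by level with columns
    ``ks_stat, ks_p, mw_u, mw_p, n_a, n_b``; stratum names are stored in
    ``df.attrs["strata"]``.  Raises a configuration error naming the level
    if either stratum is unrepresented at some level.
    """
    responses = list(responses)
    if strata is None:
        found = sorted({r.stratum for r in responses})
        if len(found) != 2:
            raise ValueError(f"need exactly two strata, found {found}")
        strata = (found[0], found[1])
    rows = []
    for level in scale:
        try:
            a = ied_sample(responses, level, strata[0], source)
            b = ied_sample(responses, level, strata[1], source)
        except DegenerateSampleError as e:
            raise ValueError(f"level {level!r} missing in one stratum: {e}") from e
        d, ks_p = ks_compare(a, b)
        u, mw_p = mw_compare(a, b)
        rows.append(
            {"level": level, "ks_stat": d, "ks_p": ks_p, "mw_u": u, "mw_p": mw_p,
             "n_a": a.values.size, "n_b": b.values.size}
        )
    df = pd.DataFrame(rows).set_index("level")
    df.attrs["strata"] = strata
    df.attrs["source"] = source
    return df


@dataclass
class BinSummary:
    """Label counts and prevalence classification for one value bin."""

    bin_center: float
    bin_lo: int
    bin_hi: int
    counts: dict[str, int]
    mode_level: str
    prevalence_class: str  # superiority | majority | statistical_majority
    p_value: float | None

    @property
    def total(self) -> int:
        return sum(self.counts.values())


def _classify_bin(counts: dict[str, int], scale: OrdinalScale) -> tuple[str, str, float | None]:
    """Mode (tie-break: lower scale rank) and escalated prevalence class."""
    max_count = max(counts.values())
    mode_level = min(
        (v for v, c in counts.items() if c == max_count), key=scale.rank
    )
    total = sum(counts.values())
    ordered = sorted(counts.values(), reverse=True)
    top = ordered[0]
    second = ordered[1] if len(ordered) > 1 else 0
    # chi-square GOF between the two most common labels, equal expectation,
    # no continuity correction; second count is 0 for single-label bins.
    if top + second > 0:
        chi2, p = stats.chisquare([top, second])
        p_value = float(p)
    else:  # pragma: no cover - empty bins are never classified
        p_value = None
    prevalence = "superiority"
    if top / total > 0.5:
        prevalence = "majority"
        if p_value is not None and p_value < 0.05:
            prevalence = "statistical_majority"
    return mode_level, prevalence, p_value


def qualitative_bin_summary(
    responses: Sequence[QualitativeResponse],
    granularity: int,
    scale: OrdinalScale = SEVERITY,
    value_range: tuple[int, int] = (1, 99),
) -> list[BinSummary]:
    """Summarise value-to-label choices by consecutive value bins.

    The value range (default 1-99) is partitioned into consecutive bins of
    width ``granularity`` starting at the range minimum (the last bin may be
    short); with the defaults and granularity 3 this yields 33 bins.  Empty
    bins are omitted.
    """
    if granularity < 1:
        raise ValueError("granularity must be >= 1")
    lo, hi = value_range
    summaries: list[BinSummary] = []
    for start in range(lo, hi + 1, granularity):
        end = min(start + granularity - 1, hi)
        in_bin = [r for r in responses if start <= r.value <= end]
        if not in_bin:
            continue
        counts: dict[str, int] = {}
        for r in in_bin:
            counts[r.chosen_level] = counts.get(r.chosen_level, 0) + 1
        mode_level, prevalence, p_value = _classify_bin(counts, scale)
        summaries.append(
            BinSummary(
                bin_center=(start + end) / 2,
                bin_lo=start,
                bin_hi=end,
                counts=counts,
                mode_level=mode_level,
                prevalence_class=prevalence,
                p_value=p_value,
            )
        )
    return summaries


def bin_summaries_frame(summaries: Sequence[BinSummary], scale: OrdinalScale = SEVERITY) -> pd.DataFrame:
    """Tabular view of bin summaries (one row per bin)."""
    rows = []
    for s in summaries:
        row = {
            "bin_lo": s.bin_lo,
            "bin_hi": s.bin_hi,
            "bin_center": s.bin_center,
            "mode_level": s.mode_level,
            "prevalence_class": s.prevalence_class,
            "p_value": s.p_value,
        }
        for v in scale:
            row[f"n_{v}"] = s.counts.get(v, 0)
        rows.append(row)
    return pd.DataFrame(rows)
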