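"""Read, validate and clean elicitation-survey tables.

Two kinds of survey tables are supported, both plain UTF-8 CSV with a
mandatory header row:

* **Interval elicitation** — one row per (respondent, level): the respondent
  marked, on a 0-100 visual-analogue continuum, the interval of values they
  associate with an ordinal severity label, plus an optional single
  *representative point* (RP).
* **Qualitative inverse mapping** — one row per respondent: given a numeric
  value in 1-99, the respondent chose the ordinal label they found most
  appropriate for it.

Cleaning is purely mechanical: each dropped row is counted under a named
reason code in a :class:`CleaningReport` so that the accounting
``n_read = n_kept + n_discarded`` always holds.  No attempt is made to
detect "random-looking" answers; only verifiable validity rules apply.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .scale import OrdinalScale, SEVERITY

INTERVAL_COLUMNS = ("respondent_id", "stratum", "level", "lower", "upper", "representative_point")
QUALITATIVE_COLUMNS = ("respondent_id", "value", "chosen_level")


class FormatError(ValueError):
    """A survey file does not declare a mandatory column."""


def _round_half_up(x: float) -> int:
    return int(math.floor(float(x) + 0.5))


def _parse_number(raw: str) -> int | None:
    """Parse a cell to an integer, rounding half-up; None if not numeric."""
    raw = str(raw).strip()
    if not raw:
        return None
    try:
        return _round_half_up(float(raw))
    except ValueError:
        return None


@dataclass
class IntervalResponse:
    """One respondent's interval (plus optional representative point) for one level."""

    respondent_id: str
    stratum: str
    level: str
    lower: int
    upper: int
    representative_point: int | None = None


@dataclass
class QualitativeResponse:
    """One respondent's label choice for a randomly assigned value in 1-99."""

    respondent_id: str
    value: int
    chosen_level: str
    sex: str | None = None
    age_range: str | None = None


@dataclass
class CleaningReport:
    """Accounting of what a reader kept and discarded, by reason.

    ``flags`` counts anomalies that did *not* cause a drop (e.g. a
    representative point lying outside its interval).
    """

    n_read: int = 0
    n_kept: int = 0
    n_discarded: int = 0
    reasons: dict[str, int] = field(default_factory=dict)
    flags: dict[str, int] = field(default_factory=dict)

    def keep(self) -> None:
        self.n_read += 1
        self.n_kept += 1

    def discard(self, reason: str) -> None:
        self.n_read += 1
        self.n_discarded += 1
        self.reasons[reason] = self.reasons.get(reason, 0) + 1

    def flag(self, name: str) -> None:
        self.flags[name] = self.flags.get(name, 0) + 1

    def to_json(self) -> str:
        return json.dumps(
            {
                "n_read": self.n_read,
                "n_kept": self.n_kept,
                "n_discarded": self.n_discarded,
                "reasons": self.reasons,
                "flags": self.flags,
            },
            indent=2,
        )


def _read_csv(path, required: Sequence[str]) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    for col in required:
        if col not in df.columns:
            raise FormatError(f"missing mandatory column {col!r} in {path}")
    return df


def read_interval_responses(
    path, scale: OrdinalScale = SEVERITY
) -> tuple[list[IntervalResponse], CleaningReport]:
    """Read and validate an interval-elicitation CSV.

    Rows failing a validity rule are discarded and counted in the report
    under one of the reason codes ``non-numeric``, ``out-of-range``,
    ``lower>upper``, ``unknown-level``, ``duplicate`` (only the first row per
    (respondent, level) is kept).  A representative point outside its own
    interval is kept but flagged ``rp_outside_interval`` — intervals and RPs
    are separate elicitations and one does not constrain the other.
    The expected strata are ``doctor`` and ``patient``, but any non-empty
    string is accepted.
    """
    df = _read_csv(path, INTERVAL_COLUMNS[:5])  # representative_point may be absent entirely
    has_rp = "representative_point" in df.columns
    report = CleaningReport()
    kept: list[IntervalResponse] = []
    seen: set[tuple[str, str]] = set()
    for row in df.itertuples(index=False):
        lower = _parse_number(row.lower)
        upper = _parse_number(row.upper)
        if lower is None or upper is None:
            report.discard("non-numeric")
            continue
        if not (0 <= lower <= 100 and 0 <= upper <= 100):
            report.discard("out-of-range")
            continue
        if lower > upper:
            report.discard("lower>upper")
            continue
        level = str(row.level).strip()
        if level not in scale:
            report.discard("unknown-level")
            continue
        rid = str(row.respondent_id).strip()
        key = (rid, level)
        if key in seen:
            report.discard("duplicate")
            continue
        seen.add(key)
        rp: int | None = None
        if has_rp:
            raw_rp = str(row.representative_point).strip()
            if raw_rp:
                rp = _parse_number(raw_rp)
                if rp is None:
                    report.flag("rp_non_numeric")
                elif not (0 <= rp <= 100):
                    report.flag("rp_out_of_range")
                    rp = None
                elif not (lower <= rp <= upper):
                    report.flag("rp_outside_interval")
        kept.append(
            IntervalResponse(
                respondent_id=rid,
                stratum=str(row.stratum).strip(),
                level=level,
                lower=lower,
                upper=upper,
                representative_point=rp,
            )
        )
        report.keep()
    return kept, report


def read_qualitative_responses(
    path, scale: OrdinalScale = SEVERITY
) -> tuple[list[QualitativeResponse], CleaningReport]:
    """Read and validate a qualitative inverse-mapping CSV.

    Rows with a missing value or missing chosen label are discarded with
    reason ``incomplete``; non-numeric values with ``non-numeric``; values
    outside [1, 99] with ``out-of-range``; labels not in the scale with
    ``unknown-level``.
    """
    df = _read_csv(path, QUALITATIVE_COLUMNS)
    has_sex = "sex" in df.columns
    has_age = "age_range" in df.columns
    report = CleaningReport()
    kept: list[QualitativeResponse] = []
    for row in df.itertuples(index=False):
        raw_value = str(row.value).strip()
        level = str(row.chosen_level).strip()
        if not raw_value or not level:
            report.discard("incomplete")
            continue
        value = _parse_number(raw_value)
        if value is None:
            report.discard("non-numeric")
            continue
        if not (1 <= value <= 99):
            report.discard("out-of-range")
            continue
        if level not in scale:
            report.discard("unknown-level")
            continue
        kept.append(
            QualitativeResponse(
                respondent_id=str(row.respondent_id).strip(),
                value=value,
                chosen_level=level,
                sex=(str(row.sex).strip() or None) if has_sex else None,
                age_range=(str(row.age_range).strip() or None) if has_age else None,
            )
        )
        report.keep()
    return kept, report


def write_interval_responses(responses: Iterable[IntervalResponse], path) -> None:
    """Write interval responses back to the CSV dialect the reader consumes."""
    rows = [
        {
            "respondent_id": r.respondent_id,
            "stratum": r.stratum,
            "level": r.level,
            "lower": r.lower,
            "upper": r.upper,
            "representative_point": "" if r.representative_point is None else r.representative_point,
        }
        for r in responses
    ]
    pd.DataFrame(rows, columns=list(INTERVAL_COLUMNS)).to_csv(path, index=False)


def write_qualitative_responses(responses: Iterable[QualitativeResponse], path) -> None:
    rows = [
        {
            "respondent_id": r.respondent_id,
            "value": r.value,
            "chosen_level": r.chosen_level,
            "sex": r.sex or "",
            "age_range": r.age_range or "",
        }
        for r in responses
    ]
    pd.DataFrame(rows, columns=list(QUALITATIVE_COLUMNS) + ["sex", "age_range"]).to_csv(
        path, index=False
    )


def group_by_level_and_stratum(
    responses: Iterable[IntervalResponse],
) -> dict[tuple[str, str], list[IntervalResponse]]:
    """Partition responses by (level, stratum), preserving input order."""
    groups: dict[tuple[str, str], list[IntervalResponse]] = {}
    for r in responses:
        groups.setdefault((r.level, r.stratum), []).append(r)
    return groups
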