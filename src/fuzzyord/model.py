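"""Estimator-style front end for the perception-fuzzification pipeline.

:class:`PerceptionModel` is built from interval-elicitation responses and a
fuzzification route; :meth:`PerceptionModel.fit` returns a
:class:`PerceptionResults` carrying the per-level fuzzy sets, the derived
encoding maps (CoIED, membership, sampling tables) and a ``summary()``
table, in the spirit of statistical modelling packages where a model object
is constructed from data and ``fit()`` yields a results object.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .encode import EncodingMap, build_coied_map, build_membership_map, build_sampling_map
from .fuzzify import FuzzySet, bin_fuzzy_set, fuzzify_survey
from .scale import OrdinalScale, SEVERITY
from .survey_io import IntervalResponse, read_interval_responses

ROUTES = ("points", "interval_centers", "whole_intervals")


class PerceptionModel:
    """Fuzzy-set representation of an ordinal scale, learned from a survey.

    Parameters
    ----------
    responses
        Interval-elicitation responses (one stratum, or pre-filtered).
    scale
        The ordinal scale being fuzzified.
    route
        ``points`` (representative points), ``interval_centers`` or
        ``whole_intervals`` (inverse-width weighted; default).
    stratum
        If given, only responses of this stratum are used.
    """

    def __init__(
        self,
        responses: Iterable[IntervalResponse],
        scale: OrdinalScale = SEVERITY,
        route: str = "whole_intervals",
        stratum: str | None = None,
    ) -> None:
        if route not in ROUTES:
            raise ValueError(f"unknown route {route!r}; choose from {ROUTES}")
        responses = list(responses)
        if stratum is not None:
            responses = [r for r in responses if r.stratum == stratum]
        self.responses = responses
        self.scale = scale
        self.route = route
        self.stratum = stratum

    @classmethod
    def from_csv(
        cls,
        path,
        scale: OrdinalScale = SEVERITY,
        route: str = "whole_intervals",
        stratum: str | None = None,
    ) -> "PerceptionModel":
        responses, _ = read_interval_responses(path, scale)
        return cls(responses, scale=scale, route=route, stratum=stratum)

    def fit(self, granularity: int = 1) -> "PerceptionResults":
        """Build per-level fuzzy sets (optionally binned) and encoding maps."""
        fuzzy_sets = fuzzify_survey(self.responses, self.scale.levels, self.route)
        if granularity > 1:
            fuzzy_sets = {v: bin_fuzzy_set(f, granularity) for v, f in fuzzy_sets.items()}
        return PerceptionResults(model=self, fuzzy_sets=fuzzy_sets, granularity=granularity)


@dataclass
class PerceptionResults:
    """Fitted fuzzy sets and encodings for one scale / stratum / route."""

    model: PerceptionModel
    fuzzy_sets: dict[str, FuzzySet]
    granularity: int = 1

    def __post_init__(self) -> None:
        scale = self.model.scale
        self.coied_map: EncodingMap = build_coied_map(self.fuzzy_sets, scale)
        self.membership_map: EncodingMap = build_membership_map(self.fuzzy_sets, scale)
        self.sampling_map: EncodingMap = build_sampling_map(self.fuzzy_sets, scale)

    @property
    def order_preserving(self) -> bool:
        return bool(self.coied_map.order_preserving)

    def summary(self) -> pd.DataFrame:
        """Per-level table: n responses, CoIED, modal value, support bounds."""
        from .encode import modal_value

        scale = self.model.scale
        n_by_level = {v: 0 for v in scale}
        for r in self.model.responses:
            if r.level in n_by_level:
                n_by_level[r.level] += 1
        rows = []
        for v in scale:
            f = self.fuzzy_sets[v]
            lo, hi = f.support()
            rows.append(
                {
                    "level": v,
                    "n": n_by_level[v],
                    "coied": self.coied_map.per_level[v],
                    "modal_value": modal_value(f),
                    "support_lo": lo,
                    "support_hi": hi,
                }
            )
        df = pd.DataFrame(rows).set_index("level")
        df.attrs["route"] = self.model.route
        df.attrs["order_preserving"] = self.order_preserving
        return df

    def encode(self, column: Sequence[str], kind: str, seed: int | None = None):
        """Encode a column of levels with one of the fitted encodings."""
        from .encode import baseline_encode, weighted_sampling_encode
        import numpy as np

        scale = self.model.scale
        if kind == "coied":
            return np.asarray([float(self.coied_map.per_level[v]) for v in column])
        if kind == "membership":
            return np.vstack(
                [np.asarray(self.membership_map.per_level[v], dtype=float) for v in column]
            )
        if kind == "weighted_sampling":
            if seed is None:
                raise ValueError("weighted_sampling requires a seed")
            return weighted_sampling_encode(column, self.fuzzy_sets, seed, scale=scale)
        return baseline_encode(column, scale, kind)
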