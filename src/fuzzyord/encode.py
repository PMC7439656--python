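"""Turn per-level fuzzy sets into feature encodings.

Three user-informed encodings are derived from the fuzzy sets:

* **CoIED** — the centroid (center of gravity) of a level's weight
  function, ``sum(x * mu(x)) / sum(mu(x))``: one scalar per level on the
  0-100 scale.  Scale-invariant in the weights, so it is identical whether
  computed from raw weights, memberships or probabilities.
* **Weighted Sampling** — each occurrence of a level is replaced by a value
  drawn from the level's probability distribution ``p(x) = mu(x)/sum(mu)``;
  a Monte-Carlo-style encoding that can locally reverse the label order
  when supports overlap.
* **Membership** — a level maps to the vector of all k levels' memberships
  evaluated at its own modal value (argmax of its membership, smallest grid
  value on ties).  With pairwise-disjoint supports this degenerates to
  one-hot.

Classical baselines (rank index, one-hot, rank-hot) are provided for
comparison.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .fuzzify import FuzzySet
from .scale import OrdinalScale

KINDS = ("coied", "weighted_sampling", "membership", "ordinal_rank", "one_hot", "rank_hot")


class ConfigurationError(ValueError):
    """A level is missing a fuzzy set / encoding entry, or kinds mismatch."""


@dataclass
class EncodingMap:
    """A serializable per-level encoding rule.

    ``per_level`` maps each level to a scalar (coied, ordinal_rank), a
    length-k vector (membership, one_hot, rank_hot) or a probability table
    ``{"grid": [...], "prob": [...]}`` (weighted_sampling).
    """

    scale: OrdinalScale
    kind: str
    per_level: dict = field(default_factory=dict)
    order_preserving: bool | None = None

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ConfigurationError(f"unknown encoding kind {self.kind!r}")
        for v in self.scale:
            if v not in self.per_level:
                raise ConfigurationError(f"encoding map has no entry for level {v!r}")

    def to_dict(self) -> dict:
        def conv(x):
            if isinstance(x, np.ndarray):
                return x.tolist()
            if isinstance(x, dict):
                return {k: conv(v) for k, v in x.items()}
            return x

        return {
            "scale": list(self.scale.levels),
            "kind": self.kind,
            "per_level": {v: conv(e) for v, e in self.per_level.items()},
            "order_preserving": self.order_preserving,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "EncodingMap":
        return cls(
            scale=OrdinalScale(tuple(d["scale"])),
            kind=d["kind"],
            per_level=dict(d["per_level"]),
            order_preserving=d.get("order_preserving"),
        )

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_json(cls, s: str) -> "EncodingMap":
        return cls.from_dict(json.loads(s))


def coied(f: FuzzySet) -> float:
    """Center of gravity of a fuzzy set: sum(x * w(x)) / sum(w(x))."""
    total = f.raw_weight.sum()
    if total <= 0:
        raise ValueError(f"cannot take centroid of zero-mass set {f.level!r}")
    return float((f.grid * f.raw_weight).sum() / total)


def _require_sets(fuzzy_sets: Mapping[str, FuzzySet], scale: OrdinalScale) -> None:
    for v in scale:
        if v not in fuzzy_sets:
            raise ConfigurationError(f"no fuzzy set for level {v!r}")


def build_coied_map(fuzzy_sets: Mapping[str, FuzzySet], scale: OrdinalScale) -> EncodingMap:
    """CoIED scalar per level, with an order-preservation flag.

    ``order_preserving`` is true iff the centroids are non-decreasing in
    scale order (ties allowed).
    """
    _require_sets(fuzzy_sets, scale)
    per_level = {v: coied(fuzzy_sets[v]) for v in scale}
    values = [per_level[v] for v in scale]
    order_preserving = all(a <= b for a, b in zip(values, values[1:]))
    return EncodingMap(scale=scale, kind="coied", per_level=per_level, order_preserving=order_preserving)


def modal_value(f: FuzzySet) -> float:
    """Grid value maximising membership; smallest such value on ties."""
    return float(f.grid[int(np.argmax(f.membership))])


def membership_encode(
    v: str, fuzzy_sets: Mapping[str, FuzzySet], scale: OrdinalScale
) -> np.ndarray:
    """Membership vector of level *v*: all levels' memberships at v's modal value.

    The component for *v* itself is exactly 1 (memberships are
    max-normalised); components for levels whose support does not contain
    the modal value are 0.
    """
    _require_sets(fuzzy_sets, scale)
    x_v = modal_value(fuzzy_sets[v])
    return np.array([fuzzy_sets[w].membership_at(x_v) for w in scale])


def build_membership_map(fuzzy_sets: Mapping[str, FuzzySet], scale: OrdinalScale) -> EncodingMap:
    per_level = {v: membership_encode(v, fuzzy_sets, scale) for v in scale}
    return EncodingMap(scale=scale, kind="membership", per_level=per_level)


def build_sampling_map(fuzzy_sets: Mapping[str, FuzzySet], scale: OrdinalScale) -> EncodingMap:
    """Per-level probability tables p(x) = mu(x)/sum(mu) for weighted sampling."""
    _require_sets(fuzzy_sets, scale)
    per_level = {
        v: {"grid": fuzzy_sets[v].grid.tolist(), "prob": fuzzy_sets[v].prob.tolist()}
        for v in scale
    }
    return EncodingMap(scale=scale, kind="weighted_sampling", per_level=per_level)


def weighted_sampling_encode(
    column: Sequence[str],
    fuzzy_sets: Mapping[str, FuzzySet],
    rng_seed: int,
    mode: str = "per_cell",
    scale: OrdinalScale | None = None,
) -> np.ndarray:
    """Replace each level occurrence by a draw from its fuzzy set's p(x).

    ``mode="per_cell"`` samples every occurrence independently;
    ``mode="per_label"`` draws one value per level and reuses it for all of
    that level's occurrences.  Output is a pure function of
    (column, fuzzy_sets, seed, mode).
    """
    if mode not in ("per_cell", "per_label"):
        raise ValueError(f"unknown sampling mode {mode!r}")
    column = list(column)
    levels_in_order = (
        list(scale.levels) if scale is not None else sorted(set(column))
    )
    for v in set(column):
        if v not in fuzzy_sets:
            raise ConfigurationError(f"no fuzzy set for level {v!r}")
    rng = np.random.default_rng(rng_seed)
    out = np.empty(len(column), dtype=float)
    col = np.asarray(column, dtype=object)
    for v in levels_in_order:
        idx = np.nonzero(col == v)[0]
        f = fuzzy_sets.get(v)
        if f is None:
            continue
        if mode == "per_cell":
            if idx.size:
                out[idx] = rng.choice(f.grid, size=idx.size, p=f.prob)
        else:
            x = rng.choice(f.grid, p=f.prob)
            out[idx] = x
    return out


def baseline_encode(column: Sequence[str], scale: OrdinalScale, kind: str):
    """Classical encodings: rank index, one-hot, rank-hot.

    ``ordinal_rank`` maps the i-th level to i-1 (0, 1, 2, ...); ``one_hot``
    to the unit vector at its position; ``rank_hot`` to the staircase vector
    with ones up to and including its position.
    """
    k = len(scale)
    ranks = np.array([scale.rank(v) for v in column])
    if kind == "ordinal_rank":
        return ranks.astype(float)
    if kind == "one_hot":
        out = np.zeros((len(ranks), k))
        out[np.arange(len(ranks)), ranks] = 1.0
        return out
    if kind == "rank_hot":
        return (np.arange(k)[None, :] <= ranks[:, None]).astype(float)
    raise ValueError(f"unknown baseline encoding {kind!r}")
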