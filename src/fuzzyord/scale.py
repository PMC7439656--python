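"""Ordered label sets for severity-style ordinal scales.

An :class:`OrdinalScale` is nothing more than an ordered tuple of unique
label strings.  The default instance is the five-level severity terminology
used throughout digital-health records (HL7 FHIR severity):
``Absent < Mild < Moderate < Severe < Extreme``.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class OrdinalScale:
    """An ordered set of unique category labels.

    Parameters
    ----------
    levels
        Label strings in increasing order of the underlying attribute.
        The order is total and fixed at construction.
    """

    levels: tuple[str, ...]

    def __post_init__(self) -> None:
        levels = tuple(str(v) for v in self.levels)
        object.__setattr__(self, "levels", levels)
        if len(levels) < 1:
            raise ValueError("an ordinal scale needs at least one level")
        if len(set(levels)) != len(levels):
            raise ValueError(f"duplicate levels in scale: {levels}")

    def rank(self, level: str) -> int:
        """Zero-based position of *level* in the scale order."""
        try:
            return self.levels.index(level)
        except ValueError:
            raise ValueError(f"unknown level {level!r}; scale is {self.levels}") from None

    def __contains__(self, level: object) -> bool:
        return level in self.levels

    def __len__(self) -> int:
        return len(self.levels)

    def __iter__(self):
        return iter(self.levels)


#: Default five-level severity scale (HL7 FHIR severity terminology).
SEVERITY = OrdinalScale(("Absent", "Mild", "Moderate", "Severe", "Extreme"))
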