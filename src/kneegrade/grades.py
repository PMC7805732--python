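"""The Kellgren-Lawrence (KL) ordinal grading scale for knee osteoarthritis."""

from __future__ import annotations

from enum import IntEnum

from .exceptions import InvalidArgumentError

__all__ = ["KLGrade", "GRADE_LABELS"]


class KLGrade(IntEnum):
    """Five-level ordinal radiographic severity scale.

    Normal (0) through Severe (4); ordinal order matters for tie-breaking
    in classification and for the gap-narrowing monotonicity of phantoms.
    """

    NORMAL = 0
    DOUBTFUL = 1
    MILD = 2
    MODERATE = 3
    SEVERE = 4

    @property
    def label(self) -> str:
        return self.name.capitalize()

    @classmethod
    def coerce(cls, value) -> "KLGrade":
        """Accept a KLGrade, its ordinal, or its label (case-insensitive)."""
        if isinstance(value, cls):
            return value
        if isinstance(value, str):
            try:
                return cls[value.strip().upper()]
            except KeyError:
                raise InvalidArgumentError(f"no KL grade named {value!r}") from None
        try:
            ordinal = int(value)
        except (TypeError, ValueError):
            raise InvalidArgumentError(f"cannot interpret {value!r} as a KL grade") from None
        if ordinal != value:
            raise InvalidArgumentError(f"cannot interpret {value!r} as a KL grade")
        try:
            return cls(ordinal)
        except ValueError:
            raise InvalidArgumentError(f"no KL grade with ordinal {value!r}") from None


GRADE_LABELS = tuple(g.label for g in KLGrade)
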