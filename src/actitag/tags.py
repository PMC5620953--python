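"""The ten activity tags used throughout the package.

Four sustained activities (sit, stand, lie, walk) and six postural
transitions.  The canonical ordering below fixes the row/column order of
every confusion matrix and adjacency matrix in the package.
"""

from __future__ import annotations

import enum


class ActivityTag(str, enum.Enum):
    """One of the ten activity labels predicted per 3-second window."""

    SIT = "sit"
    STAND = "stand"
    LIE = "lie"
    WALK = "walk"
    SIT2STAND = "sit2stand"
    STAND2SIT = "stand2sit"
    LIE2SIT = "lie2sit"
    SIT2LIE = "sit2lie"
    LIE2STAND = "lie2stand"
    STAND2LIE = "stand2lie"

    def __str__(self) -> str:  # serialize as the bare value
        return self.value

    @property
    def is_transition(self) -> bool:
        return self in TRANSITION_TAGS

    @property
    def is_static(self) -> bool:
        return self in STATIC_TAGS


#: Canonical tag order (index used for matrices and one-hot states).
TAG_ORDER: tuple[ActivityTag, ...] = tuple(ActivityTag)

TAG_INDEX: dict[ActivityTag, int] = {t: i for i, t in enumerate(TAG_ORDER)}

STATIC_TAGS = frozenset({ActivityTag.SIT, ActivityTag.STAND, ActivityTag.LIE})

TRANSITION_TAGS = frozenset(
    {
        ActivityTag.SIT2STAND,
        ActivityTag.STAND2SIT,
        ActivityTag.LIE2SIT,
        ActivityTag.SIT2LIE,
        ActivityTag.LIE2STAND,
        ActivityTag.STAND2LIE,
    }
)

#: (source posture, destination posture) of each transition tag.
TRANSITION_ENDPOINTS: dict[ActivityTag, tuple[ActivityTag, ActivityTag]] = {
    ActivityTag.SIT2STAND: (ActivityTag.SIT, ActivityTag.STAND),
    ActivityTag.STAND2SIT: (ActivityTag.STAND, ActivityTag.SIT),
    ActivityTag.LIE2SIT: (ActivityTag.LIE, ActivityTag.SIT),
    ActivityTag.SIT2LIE: (ActivityTag.SIT, ActivityTag.LIE),
    ActivityTag.LIE2STAND: (ActivityTag.LIE, ActivityTag.STAND),
    ActivityTag.STAND2LIE: (ActivityTag.STAND, ActivityTag.LIE),
}


def as_tag(value: "ActivityTag | str") -> ActivityTag:
    """Coerce a string (CSV cell) or enum member to an :class:`ActivityTag`."""
    if isinstance(value, ActivityTag):
        return value
    try:
        return ActivityTag(value)
    except ValueError as exc:
        raise ValueError(f"unknown activity tag: {value!r}") from exc
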