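"""The seven-class cattle ethogram used throughout the package.

Five sustained behaviours (feeding, grazing, walking, lying resting,
standing resting) plus the two posture transitions that bridge any change
between a standing-type behaviour and lying rest.
"""

from __future__ import annotations

import enum


class BehaviorLabel(str, enum.Enum):
    """Closed set of collar-annotated cattle behaviours.

    Serialized as lowercase snake-case text in every CSV/JSON artifact.
    """

    FEEDING = "feeding"
    GRAZING = "grazing"
    WALKING = "walking"
    LYING_RESTING = "lying_resting"
    STANDING_RESTING = "standing_resting"
    STAND_TO_LIE = "stand_to_lie"
    LIE_TO_STAND = "lie_to_stand"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value

    @classmethod
    def parse(cls, text: str) -> "BehaviorLabel":
        """Map free text to a label, case-insensitively; spaces/hyphens → underscores."""
        key = text.strip().lower().replace(" ", "_").replace("-", "_")
        try:
            return cls(key)
        except ValueError:
            valid = ", ".join(m.value for m in cls)
            raise ValueError(
                f"unknown behavior {text!r}; valid names are: {valid}"
            ) from None


#: Order used for transition matrices and any per-class vectors.
LABEL_ORDER: tuple[BehaviorLabel, ...] = (
    BehaviorLabel.FEEDING,
    BehaviorLabel.GRAZING,
    BehaviorLabel.WALKING,
    BehaviorLabel.LYING_RESTING,
    BehaviorLabel.STANDING_RESTING,
    BehaviorLabel.STAND_TO_LIE,
    BehaviorLabel.LIE_TO_STAND,
)

#: The five sustained (non-transition) behaviours, in matrix order.
MAIN_LABELS: tuple[BehaviorLabel, ...] = LABEL_ORDER[:5]

TRANSITION_LABELS: tuple[BehaviorLabel, ...] = (
    BehaviorLabel.STAND_TO_LIE,
    BehaviorLabel.LIE_TO_STAND,
)

#: Resting classes carry only sensor noise on top of the gravity vector.
REST_LABELS: tuple[BehaviorLabel, ...] = (
    BehaviorLabel.LYING_RESTING,
    BehaviorLabel.STANDING_RESTING,
)


def is_lying(label: BehaviorLabel) -> bool:
    """True for the lying posture; everything else is a standing-type posture."""
    return label is BehaviorLabel.LYING_RESTING
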