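"""Gait vocabularies and label mappings.

Three label systems coexist in this package:

* the five model classes (:class:`Gait`) used for training and evaluation,
* the 10-label vocabulary emitted by the limb-sensor labelling system
  ("TS labels"), one event per hoof-on,
* the judge vocabulary used in the agreement study (:class:`JudgeLabel`),
  which keeps halt as a class and distinguishes left from right canter.
"""

from __future__ import annotations

import enum


class Gait(enum.IntEnum):
    """The five gaits of the Icelandic horse, with fixed model output codes."""

    WALK = 0
    TROT = 1
    TOLT = 2
    CANTER = 3
    FLYING_PACE = 4


#: Sentinel for TS labels that are excluded from model training ("Standing").
DISCARDED = "discarded"

#: The closed 10-label vocabulary of the limb-sensor system.
TS_LABELS: tuple[str, ...] = (
    "Standing",
    "Walk",
    "Trot",
    "Tölt",
    "L Canter",
    "R Canter",
    "L Cross Canter",
    "R Cross Canter",
    "Flying Pace",
    "Halt",
)

# "Halt" and "Standing" are distinct strings in the wild; both are stationary
# and neither is used for model training.
_TS_TO_GAIT: dict[str, "Gait | str"] = {
    "Standing": DISCARDED,
    "Halt": DISCARDED,
    "Walk": Gait.WALK,
    "Trot": Gait.TROT,
    "Tölt": Gait.TOLT,
    "L Canter": Gait.CANTER,
    "R Canter": Gait.CANTER,
    "L Cross Canter": Gait.CANTER,
    "R Cross Canter": Gait.CANTER,
    "Flying Pace": Gait.FLYING_PACE,
}


class VocabularyError(ValueError):
    """A label string outside the closed vocabulary."""


def map_ts_label(ts_label: str) -> "Gait | str":
    """Map a TS label to one of the five gaits, or :data:`DISCARDED`.

    Parameters
    ----------
    ts_label:
        One of the 10 TS label strings (e.g. ``"L Cross Canter"``).

    Returns
    -------
    Gait or str
        The gait class, or :data:`DISCARDED` for stationary labels.

    Raises
    ------
    VocabularyError
        If the string is not in the closed vocabulary.
    """
    try:
        return _TS_TO_GAIT[ts_label]
    except KeyError:
        raise VocabularyError(f"unknown TS label: {ts_label!r}") from None


class JudgeLabel(enum.IntEnum):
    """Labels used in the judge-agreement study (integer codes fixed)."""

    NO_MAJORITY = -2
    NOT_CLASSIFIED = -1
    HALT = 0
    WALK = 1
    TROT = 2
    TOLT = 3
    LEFT_CANTER = 4
    RIGHT_CANTER = 5
    PACE = 6


# TS labels re-coded into the judge vocabulary for the agreement protocol
# (distinct from the five-gait training map: halt stays a class, canter
# sides stay separate).
_TS_TO_JUDGE: dict[str, JudgeLabel] = {
    "Standing": JudgeLabel.HALT,
    "Halt": JudgeLabel.HALT,
    "Walk": JudgeLabel.WALK,
    "Trot": JudgeLabel.TROT,
    "Tölt": JudgeLabel.TOLT,
    "L Canter": JudgeLabel.LEFT_CANTER,
    "R Canter": JudgeLabel.RIGHT_CANTER,
    "L Cross Canter": JudgeLabel.LEFT_CANTER,
    "R Cross Canter": JudgeLabel.RIGHT_CANTER,
    "Flying Pace": JudgeLabel.PACE,
}


def ts_label_to_judge_code(ts_label: str) -> JudgeLabel:
    """Re-code a TS label into the judge vocabulary (agreement study only)."""
    try:
        return _TS_TO_JUDGE[ts_label]
    except KeyError:
        raise VocabularyError(f"unknown TS label: {ts_label!r}") from None
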