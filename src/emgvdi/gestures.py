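"""The five indicative hand gestures used throughout the package.

Gesture classes are fixed by the recognition task: thumbs up, "V" sign,
"OK" sign, clenched fist and open hand, numbered 1-5.  The integer label
is what classifiers and feature tables carry; the name is for humans.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True, order=True)
class GestureLabel:
    """One of the five gesture classes (id in 1..5, bijective with name)."""

    id: int
    name: str

    def __post_init__(self) -> None:
        if self.id not in _ID_TO_NAME:
            raise ValueError(f"gesture id must be in 1..5, got {self.id}")
        if _ID_TO_NAME[self.id] != self.name:
            raise ValueError(
                f"gesture id {self.id} is named {_ID_TO_NAME[self.id]!r}, "
                f"not {self.name!r}"
            )


_ID_TO_NAME = {
    1: "thumbs_up",
    2: "v_sign",
    3: "ok_sign",
    4: "fist",
    5: "open_hand",
}
_NAME_TO_ID = {v: k for k, v in _ID_TO_NAME.items()}

#: The five gestures in label order.
GESTURES: tuple[GestureLabel, ...] = tuple(
    GestureLabel(i, n) for i, n in _ID_TO_NAME.items()
)


def gesture_by_id(gid: int) -> GestureLabel:
    """Return the gesture with integer label ``gid`` (1..5)."""
    if gid not in _ID_TO_NAME:
        raise ValueError(f"unknown gesture id {gid}; valid ids are 1..5")
    return GESTURES[gid - 1]


def gesture_by_name(name: str) -> GestureLabel:
    """Return the gesture called ``name`` (e.g. ``"fist"``)."""
    if name not in _NAME_TO_ID:
        raise ValueError(
            f"unknown gesture name {name!r}; valid names are "
            f"{sorted(_NAME_TO_ID)}"
        )
    return GESTURES[_NAME_TO_ID[name] - 1]
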