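"""Grating and plaid stimulus spaces.

A plaid is the superposition of two drifting gratings.  It is parameterised
by its *pattern direction* (the perceived direction, bisecting the two
component directions) and *dOri*, the angle between the two component
directions.  Two presentation paradigms are modelled:

* ``streaming`` — rapid serial presentation (3 Hz update) of 16 grating
  directions, 7 dOri values x 16 pattern directions of plaids, and a blank.
* ``classic`` — 1 s presentations of 16 grating directions, 16 directions of
  dOri = 135 deg plaids, and a blank.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DIRECTIONS_DEG",
    "STREAMING_DORI_DEG",
    "CLASSIC_DORI_DEG",
    "StimulusCondition",
    "StimulusSet",
    "component_directions",
    "build_streaming_set",
    "build_classic_set",
]

#: The 16-point direction grid (deg), multiples of 22.5 starting at 0.
DIRECTIONS_DEG = np.arange(16) * 22.5

#: Component intersection angles used in the streaming paradigm (deg).
STREAMING_DORI_DEG = np.array([22.5, 45.0, 67.5, 90.0, 112.5, 135.0, 157.5])

#: The single dOri used in the classic paradigm (deg).
CLASSIC_DORI_DEG = 135.0


def component_directions(pattern_direction: float, dori: float) -> tuple[float, float]:
    """Directions of the two component gratings of a plaid.

    The pattern direction bisects the two components, so the components move
    at ``pattern_direction -/+ dori/2`` (mod 360).

    Parameters
    ----------
    pattern_direction : float
        Plaid pattern direction in degrees.
    dori : float
        Angle between the component directions, strictly in (0, 180) deg.
    """
    if not 0.0 < dori < 180.0:
        raise ValueError(f"dori must be in (0, 180) deg, got {dori}")
    lo = (pattern_direction - dori / 2.0) % 360.0
    hi = (pattern_direction + dori / 2.0) % 360.0
    return lo, hi


@dataclass(frozen=True)
class StimulusCondition:
    """One stimulus condition: a grating, a plaid, or a blank screen.

    Gratings have ``dori = 0`` and a single component; plaid component
    directions are ``pattern_direction +/- dori/2``.
    """

    kind: str  # {"grating", "plaid", "blank"}
    pattern_direction: float = 0.0  # deg in [0, 360)
    dori: float = 0.0  # deg; 0 for gratings, in (0, 180) for plaids
    contrast: float = 1.0  # per-component contrast fraction

    def __post_init__(self) -> None:
        if self.kind not in ("grating", "plaid", "blank"):
            raise ValueError(f"unknown stimulus kind {self.kind!r}")
        if self.kind == "plaid" and not 0.0 < self.dori < 180.0:
            raise ValueError(f"plaid dori must be in (0, 180), got {self.dori}")
        if self.kind == "grating" and self.dori != 0.0:
            raise ValueError("grating must have dori = 0")

    @property
    def components(self) -> tuple[float, ...]:
        """Directions of the component gratings."""
        if self.kind == "blank":
            return ()
        if self.kind == "grating":
            return (self.pattern_direction,)
        return component_directions(self.pattern_direction, self.dori)

    def key(self) -> tuple[str, float, float]:
        return (self.kind, self.pattern_direction, self.dori)


@dataclass(frozen=True)
class StimulusSet:
    """An ordered set of stimulus conditions plus presentation metadata."""

    conditions: tuple[StimulusCondition, ...]
    paradigm: str  # {"streaming", "classic"}
    reps: int
    window_s: float
    directions: np.ndarray = field(default_factory=lambda: DIRECTIONS_DEG.copy())
    dori_values: np.ndarray = field(default_factory=lambda: STREAMING_DORI_DEG.copy())

    def __post_init__(self) -> None:
        if self.window_s <= 0:
            raise ValueError("window_s must be positive")
        if self.reps < 1:
            raise ValueError("reps must be >= 1")

    @property
    def n_conditions(self) -> int:
        return len(self.conditions)

    @property
    def n_directions(self) -> int:
        return len(self.directions)

    def condition_index(self) -> dict[tuple[str, float, float], int]:
        """Map (kind, pattern_direction, dori) -> position in ``conditions``."""
        return {c.key(): i for i, c in enumerate(self.conditions)}

    def grating_indices(self) -> np.ndarray:
        return np.array([i for i, c in enumerate(self.conditions) if c.kind == "grating"])

    def plaid_indices(self, dori: float | None = None) -> np.ndarray:
        return np.array(
            [
                i
                for i, c in enumerate(self.conditions)
                if c.kind == "plaid" and (dori is None or c.dori == dori)
            ]
        )

    def blank_index(self) -> int:
        for i, c in enumerate(self.conditions):
            if c.kind == "blank":
                return i
        raise ValueError("stimulus set has no blank condition")


def _grid_conditions(dori_values: np.ndarray, contrast: float) -> list[StimulusCondition]:
    conds: list[StimulusCondition] = []
    for d in DIRECTIONS_DEG:
        conds.append(StimulusCondition("grating", float(d), 0.0, contrast))
    for dori in dori_values:
        for d in DIRECTIONS_DEG:
            conds.append(StimulusCondition("plaid", float(d), float(dori), contrast))
    conds.append(StimulusCondition("blank", 0.0, 0.0, 0.0))
    return conds


def build_streaming_set(reps: int = 10, window_s: float = 1.0 / 3.0) -> StimulusSet:
    """Streaming-paradigm stimulus set.

    16 gratings (100% contrast), 7 dOri x 16 directions of plaids, and one
    blank: 129 conditions.  The default window corresponds to the 3 Hz
    stimulus update rate of the streaming sequences.
    """
    conds = _grid_conditions(STREAMING_DORI_DEG, contrast=1.0)
    return StimulusSet(
        conditions=tuple(conds),
        paradigm="streaming",
        reps=reps,
        window_s=window_s,
        dori_values=STREAMING_DORI_DEG.copy(),
    )


def build_classic_set(reps: int = 5) -> StimulusSet:
    """Classic-paradigm stimulus set.

    16 gratings and 16 directions of dOri = 135 deg plaids (each component at
    50% contrast) plus a blank, presented for 1 s with 5 repetitions by
    default.
    """
    conds = _grid_conditions(np.array([CLASSIC_DORI_DEG]), contrast=0.5)
    return StimulusSet(
        conditions=tuple(conds),
        paradigm="classic",
        reps=reps,
        window_s=1.0,
        dori_values=np.array([CLASSIC_DORI_DEG]),
    )
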