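"""Per-neuron response summaries, selectivity indices and inclusion screens.

Trial data are carried as pandas DataFrames with one row per presentation and
columns ``animal_id, neuron_id, trial, kind, pattern_direction_deg, dori_deg,
contrast, count, window_s`` (see :mod:`plaidpss.io` for the file format).
Mean responses per condition are summarised in a :class:`TuningProfile2D`:
a (dOri x pattern direction) grid of plaid rates, a grating direction-tuning
row and a blank rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .stimuli import DIRECTIONS_DEG, StimulusSet

__all__ = [
    "TuningProfile2D",
    "ScreenResult",
    "SelectivityIndices",
    "mean_responses",
    "estimate_latency",
    "selectivity_indices",
    "screen_streaming",
    "screen_classic",
    "relative_plaid_profile",
    "relative_plaid_by_dori",
    "max_plaid_grating_ratio",
    "wilson_hilferty",
]

#: Default latency search grid for streaming extraction: 0-150 ms in 10 ms steps.
DEFAULT_LATENCY_GRID_S = np.arange(0.0, 0.1501, 0.010)


@dataclass
class TuningProfile2D:
    """Mean responses over the (dOri x pattern direction) stimulus grid.

    ``plaid_rates`` has shape ``(n_dori, n_directions)``; ``grating_rates``
    has shape ``(n_directions,)``.  Rates are in Hz.  ``pref_direction`` is
    defined as the argmax of the grating tuning row.
    """

    plaid_rates: np.ndarray
    grating_rates: np.ndarray
    blank_rate: float
    dori_values: np.ndarray
    directions: np.ndarray = field(default_factory=lambda: DIRECTIONS_DEG.copy())

    def __post_init__(self) -> None:
        self.plaid_rates = np.asarray(self.plaid_rates, dtype=float)
        self.grating_rates = np.asarray(self.grating_rates, dtype=float)
        if self.plaid_rates.shape != (len(self.dori_values), len(self.directions)):
            raise ValueError(
                f"plaid_rates shape {self.plaid_rates.shape} does not match "
                f"({len(self.dori_values)}, {len(self.directions)})"
            )

    @property
    def pref_index(self) -> int:
        return int(np.argmax(self.grating_rates))

    @property
    def pref_direction(self) -> float:
        return float(self.directions[self.pref_index])

    def rectified(self) -> "TuningProfile2D":
        """Copy with negative rates floored at 0 (for ratio-based indices)."""
        return TuningProfile2D(
            np.maximum(self.plaid_rates, 0.0),
            np.maximum(self.grating_rates, 0.0),
            max(self.blank_rate, 0.0),
            self.dori_values.copy(),
            self.directions.copy(),
        )


@dataclass
class SelectivityIndices:
    """Direction and orientation selectivity indices (grating based).

    ``dsi = 1 - R(null)/R(pref)``; ``osi = 1 - R(orth)/R(pref)`` with
    ``R(orth)`` the mean response at the two directions orthogonal to the
    preferred one.  Both are 1 for perfect selectivity and 0 for none.
    """

    dsi: float
    osi: float


@dataclass
class ScreenResult:
    """Outcome of an inclusion screen: pass/fail plus the failed criteria."""

    passed: bool
    reasons: list[str]

    def __post_init__(self) -> None:
        assert self.passed == (len(self.reasons) == 0)


def _rates_per_trial(trials: pd.DataFrame) -> pd.Series:
    return trials["count"] / trials["window_s"]


def _condition_groups(trials: pd.DataFrame) -> pd.core.groupby.DataFrameGroupBy:
    return trials.groupby(["kind", "pattern_direction_deg", "dori_deg"], sort=False)


def mean_responses(trials: pd.DataFrame, stim_set: StimulusSet) -> TuningProfile2D:
    """Average per-condition firing rates into a :class:`TuningProfile2D`.

    Classic-paradigm responses are baseline corrected by subtracting the
    blank rate (stand-in for the pre-stimulus rate); corrected rates may be
    negative and are kept as-is for ANOVA screens (rectify downstream for
    ratio-based indices).  Streaming rates are raw counts/window.
    """
    rates = trials.assign(rate=_rates_per_trial(trials))
    means = rates.groupby(["kind", "pattern_direction_deg", "dori_deg"])["rate"].mean()

    missing = [
        c.key()
        for c in stim_set.conditions
        if (c.kind, c.pattern_direction, c.dori) not in means.index
    ]
    if missing:
        raise ValueError(f"trial table is missing conditions: {missing}")

    blank = float(means.get(("blank", 0.0, 0.0), 0.0))
    grating = np.array(
        [means[("grating", float(d), 0.0)] for d in stim_set.directions]
    )
    plaid = np.array(
        [
            [means[("plaid", float(d), float(dori))] for d in stim_set.directions]
            for dori in stim_set.dori_values
        ]
    )
    if stim_set.paradigm == "classic":
        grating = grating - blank
        plaid = plaid - blank
        blank_out = 0.0
    else:
        blank_out = blank
    return TuningProfile2D(plaid, grating, blank_out, np.asarray(stim_set.dori_values))


def profile_from_rates(rates: np.ndarray, stim_set: StimulusSet) -> TuningProfile2D:
    """Arrange a per-condition rate vector (in stimulus-set order) as a profile."""
    rates = np.asarray(rates, dtype=float)
    if rates.shape != (stim_set.n_conditions,):
        raise ValueError(
            f"expected {stim_set.n_conditions} condition rates, got {rates.shape}"
        )
    index = stim_set.condition_index()
    grating = np.array([rates[index[("grating", float(d), 0.0)]] for d in stim_set.directions])
    plaid = np.array(
        [
            [rates[index[("plaid", float(d), float(dori))]] for d in stim_set.directions]
            for dori in stim_set.dori_values
        ]
    )
    blank = float(rates[stim_set.blank_index()])
    return TuningProfile2D(plaid, grating, blank, np.asarray(stim_set.dori_values))


def estimate_latency(extract, grid=DEFAULT_LATENCY_GRID_S) -> float:
    """Pick the response latency that maximises stimulus tuning.

    ``extract(latency_s)`` must return a trial table extracted with spike
    counts shifted by that latency.  For each grid value the between-condition
    variance of mean rates is computed; the latency maximising it is
    returned, with ties broken toward the smallest latency.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("latency grid must be non-empty")
    order = np.argsort(grid, kind="stable")
    best_lat, best_var = None, -np.inf
    for i in order:
        lat = float(grid[i])
        table = extract(lat)
        rates = table.assign(rate=_rates_per_trial(table))
        cond_means = rates.groupby(["kind", "pattern_direction_deg", "dori_deg"])[
            "rate"
        ].mean()
        v = float(np.var(cond_means.to_numpy()))
        if v > best_var + 1e-12:  # strict improvement; ties keep smaller latency
            best_lat, best_var = lat, v
    return best_lat


def selectivity_indices(
    grating_rates: np.ndarray, directions: np.ndarray = DIRECTIONS_DEG
) -> SelectivityIndices:
    """DSI and OSI from a grating direction-tuning curve.

    The null direction is 180 deg from the preferred, the orthogonals are at
    +/- 90 deg; all land on exact grid points of the 22.5 deg direction grid.
    """
    grating_rates = np.asarray(grating_rates, dtype=float)
    pref = int(np.argmax(grating_rates))
    r_pref = grating_rates[pref]
    if r_pref <= 0:
        raise ValueError("preferred-direction response must be positive")
    n = len(directions)
    step = 360.0 / n
    null = (pref + int(round(180.0 / step))) % n
    orth = int(round(90.0 / step))
    r_null = grating_rates[null]
    r_orth = 0.5 * (grating_rates[(pref + orth) % n] + grating_rates[(pref - orth) % n])
    return SelectivityIndices(dsi=1.0 - r_null / r_pref, osi=1.0 - r_orth / r_pref)


def _anova_p(groups: list[np.ndarray]) -> float:
    for g in groups:
        if len(g) < 2:
            raise ValueError("ANOVA needs at least 2 repetitions per condition")
    return float(sstats.f_oneway(*groups).pvalue)


def _trial_rate_groups(trials: pd.DataFrame, keys: list[tuple]) -> list[np.ndarray]:
    rates = trials.assign(rate=_rates_per_trial(trials))
    grouped = rates.groupby(["kind", "pattern_direction_deg", "dori_deg"])["rate"]
    return [grouped.get_group(k).to_numpy() for k in keys]


def screen_streaming(profile: TuningProfile2D, trials: pd.DataFrame) -> ScreenResult:
    """Inclusion screen for streaming-paradigm neurons.

    A neuron passes if a one-way ANOVA over the 16 dOri = 90 plaid conditions
    plus the blank gives p < 0.01, the best grating exceeds 2 Hz, the best
    dOri = 90 plaid exceeds 1.5 Hz, and it is tuned (OSI > 0.6, DSI > 0.7,
    strict inequalities, computed on gratings only).
    """
    reasons: list[str] = []
    keys = [("plaid", float(d), 90.0) for d in profile.directions] + [
        ("blank", 0.0, 0.0)
    ]
    p = _anova_p(_trial_rate_groups(trials, keys))
    if not p < 0.01:
        reasons.append(f"anova_dori90_p={p:.4g}>=0.01")
    best_grating = float(np.max(profile.grating_rates))
    if not best_grating > 2.0:
        reasons.append(f"best_grating={best_grating:.3g}<=2Hz")
    i90 = int(np.argmin(np.abs(profile.dori_values - 90.0)))
    best_plaid90 = float(np.max(profile.plaid_rates[i90]))
    if not best_plaid90 > 1.5:
        reasons.append(f"best_plaid_dori90={best_plaid90:.3g}<=1.5Hz")
    try:
        sel = selectivity_indices(profile.grating_rates, profile.directions)
        if not sel.osi > 0.6:
            reasons.append(f"osi={sel.osi:.3g}<=0.6")
        if not sel.dsi > 0.7:
            reasons.append(f"dsi={sel.dsi:.3g}<=0.7")
    except ValueError:
        reasons.append("selectivity undefined (no positive grating response)")
    return ScreenResult(passed=not reasons, reasons=reasons)


def screen_classic(
    profile: TuningProfile2D, trials: pd.DataFrame, experiment: str = "plaid"
) -> ScreenResult:
    """Inclusion screen for classic-paradigm neurons.

    Direction experiments require the best condition >= 2 Hz and one ANOVA
    over all conditions plus blank at p < 0.01.  Plaid experiments require
    the best condition >= 2 Hz and two ANOVAs (gratings + blank, plaids +
    blank) each at p < 0.05.
    """
    if experiment not in ("direction", "plaid"):
        raise ValueError(f"unknown experiment type {experiment!r}")
    reasons: list[str] = []
    best = float(max(np.max(profile.grating_rates), np.max(profile.plaid_rates)))
    if best < 2.0:
        reasons.append(f"best_rate={best:.3g}<2Hz")
    grating_keys = [("grating", float(d), 0.0) for d in profile.directions]
    plaid_keys = [
        ("plaid", float(d), float(dori))
        for dori in profile.dori_values
        for d in profile.directions
    ]
    blank_key = [("blank", 0.0, 0.0)]
    if experiment == "direction":
        p = _anova_p(_trial_rate_groups(trials, grating_keys + plaid_keys + blank_key))
        if not p < 0.01:
            reasons.append(f"anova_p={p:.4g}>=0.01")
    else:
        p_g = _anova_p(_trial_rate_groups(trials, grating_keys + blank_key))
        p_p = _anova_p(_trial_rate_groups(trials, plaid_keys + blank_key))
        if not p_g < 0.05:
            reasons.append(f"anova_gratings_p={p_g:.4g}>=0.05")
        if not p_p < 0.05:
            reasons.append(f"anova_plaids_p={p_p:.4g}>=0.05")
    return ScreenResult(passed=not reasons, reasons=reasons)


def relative_plaid_profile(
    profile: TuningProfile2D, normalizer: str = "mean_grating"
) -> tuple[np.ndarray, np.ndarray]:
    """Plaid grid normalised by grating response, aligned to the preferred direction.

    Divides the plaid grid by the mean (or max) grating response and
    circularly shifts the direction axis so the preferred direction maps to
    0 deg.  Returns ``(grid, relative_directions)``.
    """
    prof = profile.rectified()
    if normalizer == "mean_grating":
        denom = float(np.mean(prof.grating_rates))
    elif normalizer == "max_grating":
        denom = float(np.max(prof.grating_rates))
    else:
        raise ValueError(f"unknown normalizer {normalizer!r}")
    if denom <= 0:
        raise ValueError("grating normalizer is zero")
    grid = np.roll(prof.plaid_rates / denom, -prof.pref_index, axis=1)
    rel_dirs = (prof.directions - prof.pref_direction) % 360.0
    return grid, np.roll(rel_dirs, -prof.pref_index)


def relative_plaid_by_dori(normalized_grid: np.ndarray) -> np.ndarray:
    """Average a relative plaid grid across directions, per dOri."""
    return np.asarray(normalized_grid, dtype=float).mean(axis=1)


def max_plaid_grating_ratio(profile: TuningProfile2D, dori: float = 90.0) -> float:
    """Ratio of the best plaid response at ``dori`` to the best grating response."""
    prof = profile.rectified()
    denom = float(np.max(prof.grating_rates))
    if denom <= 0:
        raise ValueError("maximum grating response is zero")
    i = int(np.argmin(np.abs(prof.dori_values - dori)))
    if abs(prof.dori_values[i] - dori) > 1e-9:
        raise ValueError(f"dori {dori} not in profile grid")
    return float(np.max(prof.plaid_rates[i]) / denom)


def wilson_hilferty(x):
    """Cube-root transform that approximately normalises chi-square-like data."""
    arr = np.asarray(x, dtype=float)
    if np.any(arr < 0):
        raise ValueError("Wilson-Hilferty transform requires nonnegative input")
    out = np.cbrt(arr)
    return float(out) if np.isscalar(x) or arr.ndim == 0 else out
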