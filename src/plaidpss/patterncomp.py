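"""Pattern/component classification of plaid responses.

Pattern cells respond to the integrated plaid (pattern) direction; component
cells respond whenever one component grating moves in their preferred
direction.  Each neuron's measured tuning is compared against a pattern and
a component prediction via partial correlations, Fisher-Z transformed to
account for the number of points, and classified using the standard
one-sided p = 0.1 boundary (critical value 1.28).

Streaming-paradigm predictions are 2D (dOri x direction) and use N = 112
points (7 dOri x 16 directions); classic-paradigm predictions are 16-point
direction curves built from the grating tuning curve.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tuning import TuningProfile2D

__all__ = [
    "CLASSIFICATION_BOUNDARY",
    "PredictionPair",
    "CorrelationScores",
    "dori_curve",
    "direction_curve_pattern",
    "direction_curve_component",
    "build_predictions_streaming",
    "build_predictions_classic",
    "partial_correlations",
    "fisher_z",
    "classify_cell",
    "score_profile",
    "per_animal_medians",
]

#: One-sided standard-normal critical value at p = 0.1 (2 decimals).
CLASSIFICATION_BOUNDARY = 1.28

#: |r| clip used by the end-to-end scorer so that noise-free profiles (which
#: match a prediction exactly, r = 1) map to a large finite Z.
_R_CLIP = 1.0 - 1e-9

#: Half-step direction lattice (deg) on which component directions of all
#: streaming plaids land (pattern +/- dOri/2 with dOri a multiple of 22.5).
HALF_STEP_DIRECTIONS_DEG = np.arange(32) * 11.25


@dataclass
class PredictionPair:
    """Pattern and component predictions matched to a measured profile."""

    pattern_pred: np.ndarray
    component_pred: np.ndarray
    n_points: int


@dataclass
class CorrelationScores:
    """Partial correlations, Z scores, pattern index and class of one neuron."""

    r_pattern: float
    r_component: float
    z_pattern: float
    z_component: float
    pattern_index: float
    cls: str  # {"pattern", "component", "unclassified"}


def dori_curve(profile: TuningProfile2D) -> np.ndarray:
    """Mean plaid response per dOri, averaged over the 16 pattern directions."""
    return profile.plaid_rates.mean(axis=1)


def direction_curve_pattern(profile: TuningProfile2D) -> np.ndarray:
    """Direction tuning curve treating each plaid as moving in its pattern direction.

    Entry theta is the mean of the grating response at theta and the 7 plaid
    responses with pattern direction theta.
    """
    stacked = np.vstack([profile.grating_rates, profile.plaid_rates])
    return stacked.mean(axis=0)


def direction_curve_component(profile: TuningProfile2D) -> np.ndarray:
    """Direction tuning curve built from component directions.

    Each plaid (dOri, phi) contributes its rate at both component directions
    phi -/+ dOri/2; gratings contribute at their own direction.  Component
    directions land on the half-step 11.25 deg lattice, so the curve is
    returned on that 32-point grid (:data:`HALF_STEP_DIRECTIONS_DEG`).
    """
    step = HALF_STEP_DIRECTIONS_DEG[1]
    n = len(HALF_STEP_DIRECTIONS_DEG)
    sums = np.zeros(n)
    counts = np.zeros(n)

    def bin_of(direction: float) -> int:
        idx = (direction % 360.0) / step
        if abs(idx - round(idx)) > 1e-9:
            raise ValueError(f"component direction {direction} deg off the lattice")
        return int(round(idx)) % n

    for d, r in zip(profile.directions, profile.grating_rates):
        b = bin_of(float(d))
        sums[b] += r
        counts[b] += 1
    for i, dori in enumerate(profile.dori_values):
        for j, d in enumerate(profile.directions):
            r = profile.plaid_rates[i, j]
            for comp in (d - dori / 2.0, d + dori / 2.0):
                b = bin_of(float(comp))
                sums[b] += r
                counts[b] += 1
    if np.any(counts == 0):
        raise ValueError("half-step lattice has empty bins; unexpected stimulus grid")
    return sums / counts


def build_predictions_streaming(profile: TuningProfile2D) -> PredictionPair:
    """2D pattern and component predictions for a streaming profile.

    The dOri curve g sets each row's mean response; direction structure comes
    from the pattern (resp. component) direction tuning curve.  Both
    predictions therefore share the data's dOri-marginal, letting peak height
    change with dOri, as the measured responses do.
    """
    g = dori_curve(profile)
    f_pat = direction_curve_pattern(profile)
    comp_curve = direction_curve_component(profile)
    step = HALF_STEP_DIRECTIONS_DEG[1]
    n_half = len(HALF_STEP_DIRECTIONS_DEG)

    mean_pat = f_pat.mean()
    if mean_pat <= 0:
        raise ValueError("pattern direction curve has nonpositive mean")
    pattern_pred = np.outer(g, f_pat / mean_pat)

    component_pred = np.empty_like(profile.plaid_rates)
    for i, dori in enumerate(profile.dori_values):
        half = dori / 2.0
        row = np.empty(len(profile.directions))
        for j, d in enumerate(profile.directions):
            idx_lo = int(round(((d - half) % 360.0) / step)) % n_half
            idx_hi = int(round(((d + half) % 360.0) / step)) % n_half
            row[j] = 0.5 * (comp_curve[idx_lo] + comp_curve[idx_hi])
        m = row.mean()
        if g[i] == 0:
            component_pred[i] = 0.0  # no response at this dOri predicts none
        elif m <= 0:
            component_pred[i] = g[i]  # flat row: marginal kept, no direction info
        else:
            component_pred[i] = g[i] * row / m
    return PredictionPair(pattern_pred, component_pred, n_points=profile.plaid_rates.size)


def build_predictions_classic(
    grating_rates: np.ndarray, dori: float = 135.0
) -> PredictionPair:
    """Direction-curve predictions for the classic (single-dOri) paradigm.

    The pattern prediction is the grating tuning curve itself; the component
    prediction averages the curve shifted by +/- dOri/2 (67.5 deg for the
    standard dOri = 135 plaids, an exact multiple of the 22.5 deg grid).
    """
    grating_rates = np.asarray(grating_rates, dtype=float)
    n = len(grating_rates)
    shift = (dori / 2.0) / (360.0 / n)
    if abs(shift - round(shift)) > 1e-9:
        raise ValueError(f"dori/2 = {dori / 2} deg is not a direction-grid multiple")
    s = int(round(shift))
    component = 0.5 * (np.roll(grating_rates, s) + np.roll(grating_rates, -s))
    return PredictionPair(grating_rates.copy(), component, n_points=n)


def partial_correlations(
    data: np.ndarray, pred_pattern: np.ndarray, pred_component: np.ndarray
) -> tuple[float, float]:
    """First-order partial correlations of data with each prediction.

    ``r_p = (rho_dp - rho_dc rho_pc) / sqrt((1 - rho_dc^2)(1 - rho_pc^2))``
    and symmetrically for the component, with rho the pairwise Pearson
    correlations among the flattened data (d), pattern (p) and component (c)
    predictions.
    """
    d = np.asarray(data, dtype=float).ravel()
    p = np.asarray(pred_pattern, dtype=float).ravel()
    c = np.asarray(pred_component, dtype=float).ravel()
    if not (len(d) == len(p) == len(c)) or len(d) < 4:
        raise ValueError("inputs must share a common length >= 4")
    for name, v in (("data", d), ("pattern", p), ("component", c)):
        if np.std(v) == 0:
            raise ValueError(f"{name} vector has zero variance")
    rho = np.corrcoef(np.vstack([d, p, c]))
    r_dp, r_dc, r_pc = rho[0, 1], rho[0, 2], rho[1, 2]
    if abs(r_pc) >= 1.0 - 1e-12:
        raise ValueError("pattern and component predictions are collinear")
    # Noise-free data can match a prediction exactly; nudge the data-side
    # correlations just inside +/-1 so the limit r -> +/-1 is returned finitely.
    r_dp = np.clip(r_dp, -1 + 1e-15, 1 - 1e-15)
    r_dc = np.clip(r_dc, -1 + 1e-15, 1 - 1e-15)
    r_p = (r_dp - r_dc * r_pc) / np.sqrt((1 - r_dc**2) * (1 - r_pc**2))
    r_c = (r_dc - r_dp * r_pc) / np.sqrt((1 - r_dp**2) * (1 - r_pc**2))
    return float(r_p), float(r_c)


def fisher_z(r: float, n_points: int) -> float:
    """Fisher Z score of a correlation: ``sqrt(N - 3) * atanh(r)``."""
    if n_points <= 3:
        raise ValueError("n_points must exceed 3")
    if not np.isfinite(r) or abs(r) >= 1.0:
        raise ValueError(f"correlation must satisfy |r| < 1, got {r}")
    return float(np.sqrt(n_points - 3) * np.arctanh(r))


def classify_cell(z_pattern: float, z_component: float) -> tuple[str, float]:
    """Classify a neuron from its Z-scored partial correlations.

    Pattern cells satisfy ``Z_P - Z_C > 1.28`` when ``Z_C >= 0`` and
    ``Z_P > 1.28`` otherwise; component cells meet the mirrored criterion;
    everything else is unclassified.  The pattern index floors negative Z
    values at 0 before subtracting: ``max(Z_P, 0) - max(Z_C, 0)``.
    """
    if not (np.isfinite(z_pattern) and np.isfinite(z_component)):
        raise ValueError("Z scores must be finite")
    b = CLASSIFICATION_BOUNDARY
    index = max(z_pattern, 0.0) - max(z_component, 0.0)
    is_pattern = (z_component >= 0 and z_pattern - z_component > b) or (
        z_component < 0 and z_pattern > b
    )
    is_component = (z_pattern >= 0 and z_component - z_pattern > b) or (
        z_pattern < 0 and z_component > b
    )
    if is_pattern:
        cls = "pattern"
    elif is_component:
        cls = "component"
    else:
        cls = "unclassified"
    return cls, float(index)


def score_profile(profile: TuningProfile2D, paradigm: str) -> CorrelationScores:
    """End-to-end per-neuron scoring: predictions, partial r, Z, class.

    For streaming profiles the 7 x 16 plaid grid (N = 112) is correlated with
    the 2D predictions; for classic profiles the single dOri = 135 row
    (N = 16) is correlated with the grating-derived direction predictions.
    Correlations are clipped to |r| < 1 before the Z transform so noise-free
    profiles that match a prediction exactly score a large finite Z.
    """
    if paradigm == "streaming":
        preds = build_predictions_streaming(profile)
        data = profile.plaid_rates
    elif paradigm == "classic":
        preds = build_predictions_classic(
            profile.grating_rates, dori=float(profile.dori_values[0])
        )
        data = profile.plaid_rates[0]
    else:
        raise ValueError(f"unknown paradigm {paradigm!r}")
    r_p, r_c = partial_correlations(data, preds.pattern_pred, preds.component_pred)
    z_p = fisher_z(float(np.clip(r_p, -_R_CLIP, _R_CLIP)), preds.n_points)
    z_c = fisher_z(float(np.clip(r_c, -_R_CLIP, _R_CLIP)), preds.n_points)
    cls, index = classify_cell(z_p, z_c)
    return CorrelationScores(r_p, r_c, z_p, z_c, index, cls)


def per_animal_medians(scores: pd.DataFrame, min_neurons: int = 3) -> pd.DataFrame:
    """Median pattern index per animal.

    ``scores`` needs columns ``animal_id`` and ``pattern_index``.  Animals
    contributing fewer than ``min_neurons`` neurons are flagged ``low_n``.
    """
    if scores.empty:
        return pd.DataFrame(columns=["animal_id", "n_neurons", "median_pattern_index", "low_n"])
    rows = []
    for animal, grp in scores.groupby("animal_id"):
        rows.append(
            {
                "animal_id": animal,
                "n_neurons": len(grp),
                "median_pattern_index": float(grp["pattern_index"].median()),
                "low_n": len(grp) < min_neurons,
            }
        )
    return pd.DataFrame(rows)
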