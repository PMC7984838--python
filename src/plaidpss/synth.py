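"""Synthetic ground-truth neurons and Poisson trial generation.

This module produces every input the analysis consumes: idealised pattern
and component tuning profiles (the noise-free reference shapes), preset mean
V1 response profiles standing in for age-group averages, populations of
ground-truth PSS neurons with known integration parameters, and per-trial
Poisson spike counts with the statistical structure the analysis assumes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .pathway import PARAM_BOUNDS, PSSParams, V1FilterBank, pss_response_rates
from .stimuli import StimulusSet
from .tuning import TuningProfile2D

__all__ = [
    "GroundTruthNeuron",
    "DEFAULT_PARAM_RANGES",
    "ideal_profile",
    "v1_profile_preset",
    "simulate_population",
    "generate_trials",
    "streaming_extractor",
]


def _vm(theta_deg: np.ndarray, kappa: float) -> np.ndarray:
    """Peak-normalised circular bump: exp(kappa (cos(theta) - 1))."""
    return np.exp(kappa * (np.cos(np.deg2rad(theta_deg)) - 1.0))


def ideal_profile(
    kind: str,
    pref_direction: float,
    stim_set: StimulusSet,
    tuning_width: float = 3.0,
) -> TuningProfile2D:
    """Noise-free tuning profile of an ideal pattern or component cell.

    A pattern cell responds maximally to plaids moving in its preferred
    (pattern) direction at every dOri, giving a single ridge; a component
    cell responds when either component moves in the preferred direction,
    giving the characteristic V shape.  Every dOri row is rescaled so the
    area (row sum over the 16 directions) is constant across dOri, so the
    only dOri dependence left is the one implied by the component geometry.

    ``tuning_width`` is the von Mises concentration of the underlying
    direction tuning bump (unitless; larger = sharper).
    """
    if kind not in ("pattern", "component"):
        raise ValueError(f"unknown ideal-cell kind {kind!r}")
    dirs = np.asarray(stim_set.directions, dtype=float)
    f = _vm(dirs - pref_direction, tuning_width)
    target_sum = f.sum()
    rows = []
    for dori in stim_set.dori_values:
        if kind == "pattern":
            row = f.copy()
        else:
            row = 0.5 * (
                _vm(dirs - dori / 2.0 - pref_direction, tuning_width)
                + _vm(dirs + dori / 2.0 - pref_direction, tuning_width)
            )
        rows.append(row * target_sum / row.sum())
    return TuningProfile2D(
        np.vstack(rows), f, 0.0, np.asarray(stim_set.dori_values), dirs.copy()
    )


def v1_profile_preset(age_group: str, tuning_width: float = 3.0) -> TuningProfile2D:
    """Deterministic mean V1 profile preset for the model's front end.

    Both presets are component-dominated (V-shaped) with a smooth dOri gain
    that weakens responses to wide-angle plaids (cross-orientation
    suppression grows with dOri).  The ``"middle"`` preset adds a localised
    response boost on the pattern ridge (preferred direction) at
    intermediate dOri values, emulating the transient enhancement of V1
    pattern responses seen around P44-47; the ``"young"`` preset (P37-40
    like) has no such boost.  Profiles are centred (preferred direction
    0 deg) and normalised to a unit maximum grating response.
    """
    if age_group not in ("young", "middle"):
        raise ValueError(f"unknown age group {age_group!r}")
    from .stimuli import build_streaming_set

    stim_set = build_streaming_set()
    dirs = np.asarray(stim_set.directions, dtype=float)
    dori = np.asarray(stim_set.dori_values, dtype=float)
    f = _vm(dirs, tuning_width)
    gain = 0.65 + 0.35 * np.cos(np.deg2rad(dori))  # smooth dOri-dependent suppression
    plaid = np.vstack(
        [
            g * 0.5 * (_vm(dirs - d / 2.0, tuning_width) + _vm(dirs + d / 2.0, tuning_width))
            for g, d in zip(gain, dori)
        ]
    )
    if age_group == "middle":
        ridge = _vm(dirs, 4.0)  # boost concentrated at the preferred direction
        dori_bump = np.exp(-(((dori - 90.0) / 45.0) ** 2))
        plaid = plaid + 0.35 * np.outer(dori_bump, ridge)
    return TuningProfile2D(plaid, f, 0.0, dori, dirs.copy())


#: Default uniform sampling ranges for ground-truth PSS parameters.  Chosen
#: well inside the fitting bounds, spanning sharp-to-broad excitation,
#: moderate-to-strong null-direction inhibition and sub- to supra-linear
#: output exponents at realistic peak rates.
DEFAULT_PARAM_RANGES: dict[str, tuple[float, float]] = {
    "k_e": (0.5, 3.0),
    "k_i": (0.5, 3.0),
    "i_amp": (0.2, 1.5),
    "t_pss": (0.5, 2.5),
    "resp_max": (5.0, 30.0),
}


@dataclass(frozen=True)
class GroundTruthNeuron:
    """A synthetic PSS neuron with known integration parameters."""

    params: PSSParams
    pref_direction: float
    baseline_rate: float = 0.0
    v1_profile_id: str = "young"

    def __post_init__(self) -> None:
        if self.baseline_rate < 0:
            raise ValueError("baseline_rate must be nonnegative")
        self.params.validate()


def simulate_population(
    n_neurons: int,
    param_ranges: dict[str, tuple[float, float]] | None = None,
    seed: int = 0,
    v1_profile_id: str = "young",
    baseline_rate: float = 0.0,
) -> list[GroundTruthNeuron]:
    """Sample a deterministic population of ground-truth neurons.

    Parameters are drawn uniformly within ``param_ranges`` (defaults to
    :data:`DEFAULT_PARAM_RANGES`); preferred directions are drawn from the
    16-point grid.  Ranges outside the fitting bounds raise.
    """
    if n_neurons < 1:
        raise ValueError("n_neurons must be >= 1")
    ranges = dict(DEFAULT_PARAM_RANGES)
    if param_ranges:
        ranges.update(param_ranges)
    for name, (lo, hi) in ranges.items():
        if name in PARAM_BOUNDS:
            blo, bhi = PARAM_BOUNDS[name]
            if lo < blo or hi > bhi:
                raise ValueError(f"sampling range for {name} outside fitting bounds")
        if lo > hi:
            raise ValueError(f"empty sampling range for {name}")
    rng = np.random.default_rng(seed)
    neurons = []
    for _ in range(n_neurons):
        draw = {k: float(rng.uniform(lo, hi)) for k, (lo, hi) in ranges.items()}
        pref = float(rng.integers(16) * 22.5)
        neurons.append(
            GroundTruthNeuron(
                PSSParams(**draw), pref, baseline_rate, v1_profile_id
            )
        )
    return neurons


def _condition_lambdas(
    neuron: GroundTruthNeuron, stim_set: StimulusSet, bank: V1FilterBank
) -> np.ndarray:
    """Expected spike count per condition (model rate + baseline, times window).

    Conditions are matched to the bank's stimulus grid by (kind, direction,
    dOri), so any set whose conditions are a subset of the bank's grid (for
    example the classic set against a streaming-grid bank) can be simulated.
    """
    bank_rates = pss_response_rates(bank, neuron.params, neuron.pref_direction)
    bank_index = bank.stim_set.condition_index()
    lam = np.empty(stim_set.n_conditions)
    for c, cond in enumerate(stim_set.conditions):
        if cond.kind == "blank":
            lam[c] = neuron.baseline_rate * stim_set.window_s
            continue
        key = cond.key()
        if key not in bank_index:
            raise ValueError(f"condition {key} not on the V1 bank's stimulus grid")
        lam[c] = (bank_rates[bank_index[key]] + neuron.baseline_rate) * stim_set.window_s
    return lam


def generate_trials(
    neuron: GroundTruthNeuron,
    stim_set: StimulusSet,
    bank: V1FilterBank,
    seed: int = 0,
    animal_id: str = "sim",
    neuron_id: int = 0,
    true_latency_s: float = 0.0,
    extract_latency_s: float = 0.0,
) -> pd.DataFrame:
    """Poisson per-trial spike counts for one neuron over a stimulus set.

    Counts are drawn as ``Poisson((model rate + baseline) * window)``; blank
    conditions carry baseline only.  ``true_latency_s`` and
    ``extract_latency_s`` emulate streaming extraction: when the extraction
    latency misses the neuron's true latency, the counting window overlaps
    the neighbouring (random) stimulus, attenuating each condition's rate
    toward the sequence-mean rate by the non-overlap fraction.
    """
    lam = _condition_lambdas(neuron, stim_set, bank)
    mismatch = abs(extract_latency_s - true_latency_s)
    overlap = max(0.0, 1.0 - mismatch / stim_set.window_s)
    if overlap < 1.0:
        lam = overlap * lam + (1.0 - overlap) * lam.mean()
    rng = np.random.default_rng(seed)
    rows = []
    for c, cond in enumerate(stim_set.conditions):
        counts = rng.poisson(lam[c], size=stim_set.reps)
        for t, k in enumerate(counts):
            rows.append(
                (
                    animal_id,
                    neuron_id,
                    t,
                    cond.kind,
                    cond.pattern_direction,
                    cond.dori,
                    cond.contrast,
                    int(k),
                    stim_set.window_s,
                )
            )
    return pd.DataFrame(
        rows,
        columns=[
            "animal_id",
            "neuron_id",
            "trial",
            "kind",
            "pattern_direction_deg",
            "dori_deg",
            "contrast",
            "count",
            "window_s",
        ],
    )


def streaming_extractor(
    neuron: GroundTruthNeuron,
    stim_set: StimulusSet,
    bank: V1FilterBank,
    seed: int = 0,
    true_latency_s: float = 0.0,
):
    """Return ``extract(latency_s) -> trial table`` for latency estimation.

    Emulates re-binning one recorded spike train at different latencies:
    counts at every latency are generated by inverse-CDF sampling from a
    single shared uniform draw per trial, so they are strongly correlated
    across latencies (as re-extractions of the same spikes are), with the
    expected rate attenuated toward the sequence mean by the window
    mismatch.  Deterministic given ``seed``.
    """
    from scipy.stats import poisson as _poisson

    rng = np.random.default_rng(seed)
    u = rng.uniform(size=(stim_set.n_conditions, stim_set.reps))
    base_lam = _condition_lambdas(neuron, stim_set, bank)

    def extract(latency_s: float) -> pd.DataFrame:
        mismatch = abs(latency_s - true_latency_s)
        overlap = max(0.0, 1.0 - mismatch / stim_set.window_s)
        lam = overlap * base_lam + (1.0 - overlap) * base_lam.mean()
        counts = _poisson.ppf(u, lam[:, None]).astype(int)
        rows = []
        for c, cond in enumerate(stim_set.conditions):
            for t in range(stim_set.reps):
                rows.append(
                    (
                        "sim",
                        0,
                        t,
                        cond.kind,
                        cond.pattern_direction,
                        cond.dori,
                        cond.contrast,
                        int(counts[c, t]),
                        stim_set.window_s,
                    )
                )
        return pd.DataFrame(
            rows,
            columns=[
                "animal_id",
                "neuron_id",
                "trial",
                "kind",
                "pattern_direction_deg",
                "dori_deg",
                "contrast",
                "count",
                "window_s",
            ],
        )

    return extract
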