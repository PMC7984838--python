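"""In-silico developmental perturbations of a model PSS population.

Starting from a baseline population (per-neuron integration parameters on a
shared, young-like V1 bank), three manipulations probe which developmental
change drives motion integration:

* raising the inhibition amplitude ``I`` (``K_I`` untouched) until the
  population-mean ``W_inh`` matches an older-age target;
* lowering ``K_E`` (broadening excitation) until the mean ``W_exc`` matches;
* swapping the V1 front end for an older-age preset while freezing the PSS
  parameters;

plus their combination.  Summaries are computed on noise-free model
responses: the aligned, grating-normalised average 2D profile, per-neuron
pattern indices and class counts.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .patterncomp import score_profile
from .pathway import PARAM_BOUNDS, PSSParams, V1FilterBank, pss_response_rates, w_areas
from .tuning import profile_from_rates, relative_plaid_profile

__all__ = [
    "ModelPopulation",
    "PopulationSummary",
    "match_mean_winh",
    "match_mean_wexc",
    "swap_v1",
    "population_summary",
]

_MATCH_RTOL = 1e-6


@dataclass
class ModelPopulation:
    """A set of model PSS neurons sharing one V1 filter bank."""

    params: list[PSSParams]
    pref_directions: list[float]
    bank: V1FilterBank
    label: str = ""

    def __post_init__(self) -> None:
        if not self.params:
            raise ValueError("population must be non-empty")
        if len(self.params) != len(self.pref_directions):
            raise ValueError("params and pref_directions lengths differ")

    def mean_winh(self) -> float:
        return float(
            np.mean([w_areas(p, self.bank.channel_directions)[1] for p in self.params])
        )

    def mean_wexc(self) -> float:
        return float(
            np.mean([w_areas(p, self.bank.channel_directions)[0] for p in self.params])
        )


@dataclass
class PopulationSummary:
    """Population-level summary of noise-free model responses."""

    mean_profile: np.ndarray  # aligned, grating-normalised (n_dori, 16) average
    relative_directions: np.ndarray
    dori_values: np.ndarray
    pattern_indices: np.ndarray
    classes: list[str]

    @property
    def class_counts(self) -> dict[str, int]:
        out = {"pattern": 0, "component": 0, "unclassified": 0}
        for c in self.classes:
            out[c] += 1
        return out

    @property
    def median_pattern_index(self) -> float:
        return float(np.nanmedian(self.pattern_indices))


def _bisect_increment(apply, target: float, hi: float, what: str) -> float:
    """Find the common increment in [0, hi] whose population mean hits target."""
    current = apply(0.0)
    if target < current * (1 - _MATCH_RTOL):
        raise ValueError(f"target mean {what} {target} below current {current}")
    if abs(target - current) <= _MATCH_RTOL * max(abs(target), 1.0):
        return 0.0
    attainable = apply(hi)
    if target > attainable * (1 + _MATCH_RTOL):
        raise ValueError(
            f"target mean {what} {target} unreachable within bounds "
            f"(max attainable {attainable})"
        )
    lo_d, hi_d = 0.0, hi
    for _ in range(200):
        mid = 0.5 * (lo_d + hi_d)
        if apply(mid) < target:
            lo_d = mid
        else:
            hi_d = mid
        if hi_d - lo_d < 1e-14:
            break
    return 0.5 * (lo_d + hi_d)


def match_mean_winh(pop: ModelPopulation, target_mean_winh: float) -> ModelPopulation:
    """Raise inhibition amplitude ``I`` to hit a target population-mean ``W_inh``.

    A single additive increment is applied to every neuron's ``I`` (clipped
    per neuron to the upper bound); ``K_I`` is left unchanged.  The increment
    is found by bisection to within 1e-6 relative tolerance.
    """
    i_hi = PARAM_BOUNDS["i_amp"][1]
    dirs = pop.bank.channel_directions

    def mean_at(delta: float) -> float:
        vals = [
            w_areas(replace(p, i_amp=min(p.i_amp + delta, i_hi)), dirs)[1]
            for p in pop.params
        ]
        return float(np.mean(vals))

    delta = _bisect_increment(mean_at, target_mean_winh, i_hi, "W_inh")
    new_params = [replace(p, i_amp=min(p.i_amp + delta, i_hi)) for p in pop.params]
    return ModelPopulation(
        new_params, list(pop.pref_directions), pop.bank, label=f"{pop.label}+winh"
    )


def match_mean_wexc(pop: ModelPopulation, target_mean_wexc: float) -> ModelPopulation:
    """Lower ``K_E`` (broaden excitation) to hit a target mean ``W_exc``.

    A single additive decrement of ``K_E`` is applied to every neuron
    (clipped to the lower bound); all other parameters are unchanged.
    """
    k_lo = PARAM_BOUNDS["k_e"][0]
    dirs = pop.bank.channel_directions
    max_delta = float(max(p.k_e for p in pop.params) - k_lo)

    def mean_at(delta: float) -> float:
        vals = [
            w_areas(replace(p, k_e=max(p.k_e - delta, k_lo)), dirs)[0]
            for p in pop.params
        ]
        return float(np.mean(vals))

    delta = _bisect_increment(mean_at, target_mean_wexc, max_delta, "W_exc")
    new_params = [replace(p, k_e=max(p.k_e - delta, k_lo)) for p in pop.params]
    return ModelPopulation(
        new_params, list(pop.pref_directions), pop.bank, label=f"{pop.label}+wexc"
    )


def swap_v1(pop: ModelPopulation, new_bank: V1FilterBank) -> ModelPopulation:
    """Replace the V1 front end, keeping every neuron's PSS parameters fixed."""
    if new_bank.responses.shape != pop.bank.responses.shape:
        raise ValueError("new bank is not on the same stimulus grid")
    if new_bank.stim_set.n_conditions != pop.bank.stim_set.n_conditions:
        raise ValueError("new bank is not on the same stimulus grid")
    return ModelPopulation(
        list(pop.params), list(pop.pref_directions), new_bank, label=f"{pop.label}+v1swap"
    )


def population_summary(pop: ModelPopulation) -> PopulationSummary:
    """Noise-free population summary: mean aligned profile, indices, classes.

    Each neuron's mean responses over the streaming set are computed from the
    model without noise, normalised by its mean grating response, aligned so
    the preferred direction sits at 0 deg, and averaged; the streaming
    pattern index and class are computed per neuron on the same noise-free
    profile (model indices are therefore noise-free-inflated relative to
    trial-based ones, deliberately).

    A manipulated neuron whose plaid responses are fully suppressed (zero
    grid) cannot be scored; it is kept in the mean profile but carries a NaN
    pattern index and is reported ``unclassified``, mirroring how an
    unresponsive cell would fail the screens.  The summary median ignores
    NaNs.
    """
    grids = []
    indices = []
    classes = []
    rel_dirs = None
    for params, pref in zip(pop.params, pop.pref_directions):
        rates = pss_response_rates(pop.bank, params, pref)
        profile = profile_from_rates(rates, pop.bank.stim_set)
        grid, rel = relative_plaid_profile(profile, normalizer="mean_grating")
        grids.append(grid)
        rel_dirs = rel
        try:
            scores = score_profile(profile, paradigm="streaming")
            indices.append(scores.pattern_index)
            classes.append(scores.cls)
        except ValueError:  # degenerate (fully suppressed) plaid responses
            indices.append(np.nan)
            classes.append("unclassified")
    return PopulationSummary(
        mean_profile=np.mean(grids, axis=0),
        relative_directions=rel_dirs,
        dori_values=np.asarray(pop.bank.stim_set.dori_values),
        pattern_indices=np.asarray(indices),
        classes=classes,
    )
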