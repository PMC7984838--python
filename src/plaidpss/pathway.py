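"""Two-stage V1-to-PSS motion-pathway model and its Poisson ML fit.

The model is strictly feedforward.  Stage one is a bank of 16 direction
channels whose responses to every grating/plaid condition are derived from a
measured (or synthetic) mean V1 response profile: the profile is symmetrised
around the preferred direction, replicated by circular shifts to cover
direction space, and made perfectly direction selective by motion opponency
(``P - P(o) O``, where ``O`` is the opposite channel's response and ``P(o)``
the channel's own response to a null-direction grating; negatives are
rectified to 0, which forces an exact zero response at the null direction).

Stage two integrates the 16 channel responses with a weight function made of
two von Mises components — excitation centred at the preferred direction,
inhibition (amplitude ``I``) centred at the null direction — followed by an
exponential output nonlinearity ``resp = Resp_max * Lhat^T_PSS``, with
``Lhat`` the rectified linear drive normalised to a unit maximum over the
stimulus set.  Free parameters are ``K_E, K_I, I, T_PSS, Resp_max``; they are
fit per neuron by maximising the Poisson log-likelihood of the per-trial
spike counts with bounded dual annealing.  The width/amplitude pairs are
summarised as the areas under the two weight components, ``W_exc`` and
``W_inh``.
"""

from __future__ import annotations

import inspect
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.optimize import dual_annealing
from scipy.special import gammaln

from .stimuli import StimulusSet
from .tuning import TuningProfile2D, profile_from_rates

__all__ = [
    "PARAM_BOUNDS",
    "PSSParams",
    "V1FilterBank",
    "build_v1_bank",
    "weight_function",
    "w_areas",
    "pss_response_rates",
    "poisson_loglik",
    "fit_quality",
    "MotionPathwayModel",
    "MotionPathwayResults",
    "fit_pss",
]

#: Fitting bounds for the shape parameters (Resp_max bounds are data-driven).
PARAM_BOUNDS = {
    "k_e": (-5.0, 6.0),
    "k_i": (-5.0, 6.0),
    "i_amp": (0.0, 2.0),
    "t_pss": (0.0, 3.0),
}

#: Poisson rate floor, in spikes per window, keeping the log-likelihood finite.
RATE_FLOOR = 1e-6


@dataclass(frozen=True)
class PSSParams:
    """PSS integration-stage parameters.

    ``k_e``/``k_i`` are the von Mises concentrations of the excitatory and
    inhibitory weight components (negative values give inverted/broad
    components, allowed by the fitting bounds), ``i_amp`` the inhibitory peak
    amplitude relative to the unit excitatory peak, ``t_pss`` the output
    exponent, and ``resp_max`` the rate scale in Hz.
    """

    k_e: float
    k_i: float
    i_amp: float
    t_pss: float
    resp_max: float

    def validate(self, resp_max_bounds: tuple[float, float] | None = None) -> None:
        for name in ("k_e", "k_i", "i_amp", "t_pss"):
            lo, hi = PARAM_BOUNDS[name]
            v = getattr(self, name)
            if not lo <= v <= hi:
                raise ValueError(f"{name}={v} outside bounds [{lo}, {hi}]")
        if resp_max_bounds is not None:
            lo, hi = resp_max_bounds
            if not lo <= self.resp_max <= hi:
                raise ValueError(f"resp_max={self.resp_max} outside [{lo}, {hi}]")


@dataclass
class V1FilterBank:
    """Responses of 16 direction channels to every stimulus condition.

    ``responses[j, c]`` is channel ``j``'s rectified, opponency-corrected
    response to condition ``c`` of ``stim_set`` (grating-max normalised
    units).  The bank is shift-symmetric across channels and responds exactly
    0 to each channel's anti-preferred grating.
    """

    channel_directions: np.ndarray
    responses: np.ndarray
    stim_set: StimulusSet

    def null_grating_responses(self) -> np.ndarray:
        """Each channel's response to the grating opposite its preference."""
        index = self.stim_set.condition_index()
        out = np.empty(len(self.channel_directions))
        for j, d in enumerate(self.channel_directions):
            null = (float(d) + 180.0) % 360.0
            out[j] = self.responses[j, index[("grating", null, 0.0)]]
        return out


def _symmetrize_row(row: np.ndarray) -> np.ndarray:
    """Average entries at equal angular distance either side of index 0."""
    idx = np.arange(len(row))
    return 0.5 * (row + row[(-idx) % len(row)])


def build_v1_bank(mean_profile: TuningProfile2D) -> V1FilterBank:
    """Construct the direction-channel bank from a mean V1 profile.

    The profile must be centred (preferred direction at 0 deg, i.e. grating
    argmax at index 0) and normalised to a unit maximum grating response.
    """
    g = mean_profile.grating_rates
    if abs(np.max(g) - 1.0) > 1e-9:
        raise ValueError("profile must be normalised to max grating response = 1")
    if mean_profile.pref_index != 0:
        raise ValueError("profile must be centred with the preferred direction at 0 deg")

    g_sym = _symmetrize_row(g)
    p_sym = np.vstack([_symmetrize_row(row) for row in mean_profile.plaid_rates])

    stim_set = (
        _streaming_set_like(mean_profile)
        if mean_profile.plaid_rates.shape[0] > 1
        else _classic_set_like(mean_profile)
    )
    directions = mean_profile.directions
    n_dir = len(directions)
    step = 360.0 / n_dir
    dori_index = {float(d): i for i, d in enumerate(mean_profile.dori_values)}

    raw = np.zeros((n_dir, stim_set.n_conditions))
    for c, cond in enumerate(stim_set.conditions):
        if cond.kind == "blank":
            continue
        for j in range(n_dir):
            rel = int(round((cond.pattern_direction - directions[j]) / step)) % n_dir
            if cond.kind == "grating":
                raw[j, c] = g_sym[rel]
            else:
                raw[j, c] = p_sym[dori_index[cond.dori], rel]

    p_o = g_sym[n_dir // 2]  # response to the null-direction grating
    opposite = np.roll(np.arange(n_dir), -n_dir // 2)
    out = np.maximum(raw - p_o * raw[opposite], 0.0)
    return V1FilterBank(directions.copy(), out, stim_set)


def _streaming_set_like(profile: TuningProfile2D) -> StimulusSet:
    from .stimuli import build_streaming_set

    s = build_streaming_set()
    if not np.allclose(s.dori_values, profile.dori_values):
        raise ValueError("profile dOri grid does not match the streaming set")
    return s


def _classic_set_like(profile: TuningProfile2D) -> StimulusSet:
    from .stimuli import build_classic_set

    s = build_classic_set()
    if not np.allclose(s.dori_values, profile.dori_values):
        raise ValueError("profile dOri grid does not match the classic set")
    return s


def weight_function(params: PSSParams, offsets_deg: np.ndarray) -> np.ndarray:
    """Integration weights at channel offsets (deg) from the preferred direction.

    ``w = exp(K_E (cos d - 1)) - I exp(K_I (cos(d - 180) - 1))``: both von
    Mises components are peak-normalised, so the excitatory peak is 1 and the
    inhibitory peak is ``I``.
    """
    d = np.deg2rad(np.asarray(offsets_deg, dtype=float))
    exc = np.exp(params.k_e * (np.cos(d) - 1.0))
    inh = params.i_amp * np.exp(params.k_i * (np.cos(d - np.pi) - 1.0))
    return exc - inh


def w_areas(
    params: PSSParams, channel_directions: np.ndarray | None = None
) -> tuple[float, float]:
    """Areas under the excitatory and inhibitory weight components.

    Discrete sums over the 16-channel direction grid; ``W_inh`` is linear in
    ``I`` and 0 when inhibition is off.
    """
    if channel_directions is None:
        channel_directions = np.arange(16) * 22.5
    d = np.deg2rad(np.asarray(channel_directions, dtype=float))
    w_exc = float(np.sum(np.exp(params.k_e * (np.cos(d) - 1.0))))
    w_inh = float(params.i_amp * np.sum(np.exp(params.k_i * (np.cos(d - np.pi) - 1.0))))
    return w_exc, w_inh


def pss_response_rates(
    bank: V1FilterBank, params: PSSParams, pref_direction: float = 0.0
) -> np.ndarray:
    """Model PSS firing rate (Hz) for every condition of the bank's stimulus set.

    The linear drive is rectified at 0 and normalised by its maximum over the
    set before the exponent is applied, making ``T_PSS`` shape-only and
    ``Resp_max`` the peak rate.  Blank (and zero-drive) conditions map to 0.
    """
    offsets = bank.channel_directions - pref_direction
    w = weight_function(params, offsets)
    drive = np.maximum(w @ bank.responses, 0.0)
    peak = drive.max()
    if peak <= 0:
        raise ValueError("degenerate model: linear stage is zero for every stimulus")
    lhat = drive / peak
    powed = np.zeros_like(lhat)
    np.power(lhat, params.t_pss, out=powed, where=lhat > 0)
    rates = params.resp_max * powed
    rates[bank.stim_set.blank_index()] = 0.0
    return rates


def poisson_loglik(
    counts: np.ndarray,
    rates: np.ndarray,
    window_s: float,
    floor: float = RATE_FLOOR,
) -> float:
    """Poisson log-likelihood of spike counts given model rates (Hz).

    ``LL = sum_k [k ln(lambda) - lambda - ln k!]`` with
    ``lambda = max(floor, rate * window_s)`` per trial.
    """
    counts = np.asarray(counts)
    if np.any(counts < 0):
        raise ValueError("spike counts must be nonnegative")
    if window_s <= 0:
        raise ValueError("window_s must be positive")
    lam = np.maximum(np.asarray(rates, dtype=float) * window_s, floor)
    return float(np.sum(counts * np.log(lam) - lam - gammaln(counts + 1)))


def fit_quality(model_rates: np.ndarray, empirical_rates: np.ndarray) -> float:
    """Pearson correlation of model and empirical mean rates across conditions."""
    m = np.asarray(model_rates, dtype=float).ravel()
    e = np.asarray(empirical_rates, dtype=float).ravel()
    if len(m) != len(e) or len(m) < 4:
        raise ValueError("need >= 4 matched conditions")
    if np.std(m) == 0 or np.std(e) == 0:
        raise ValueError("zero variance in rates")
    return float(np.corrcoef(m, e)[0, 1])


class MotionPathwayModel:
    """Poisson ML model of one PSS neuron's responses given a V1 bank.

    Parameters
    ----------
    trials : pandas.DataFrame
        Per-trial spike counts for a single neuron (trial-table schema).
    bank : V1FilterBank
        Front-end channel bank; its stimulus set defines the condition grid.
    pref_direction : float, optional
        The neuron's preferred direction (deg).  Defaults to the argmax of
        the empirical grating tuning curve; it is not a fitted parameter.
    """

    param_names = ("k_e", "k_i", "i_amp", "t_pss", "resp_max")

    def __init__(
        self,
        trials: pd.DataFrame,
        bank: V1FilterBank,
        pref_direction: float | None = None,
    ):
        self.bank = bank
        self.stim_set = bank.stim_set
        index = self.stim_set.condition_index()
        n_cond = self.stim_set.n_conditions

        counts_sum = np.zeros(n_cond)
        counts_n = np.zeros(n_cond, dtype=int)
        lnfact = 0.0
        window = None
        for (kind, pdir, dori), grp in trials.groupby(
            ["kind", "pattern_direction_deg", "dori_deg"]
        ):
            key = (kind, float(pdir), float(dori))
            if key not in index:
                raise ValueError(f"condition {key} not in the bank's stimulus set")
            c = index[key]
            k = grp["count"].to_numpy()
            if np.any(k < 0):
                raise ValueError("negative spike counts")
            counts_sum[c] = k.sum()
            counts_n[c] = len(k)
            lnfact += float(np.sum(gammaln(k + 1)))
            w = grp["window_s"].unique()
            window = float(w[0]) if window is None else window
            if len(w) > 1 or abs(float(w[0]) - window) > 1e-12:
                raise ValueError("all trials must share one window duration")
        if np.any(counts_n == 0):
            missing = [self.stim_set.conditions[i].key() for i in np.where(counts_n == 0)[0]]
            raise ValueError(f"missing conditions in trial table: {missing}")

        self.window_s = window
        self._counts_sum = counts_sum
        self._counts_n = counts_n
        self._lnfact = lnfact
        self.empirical_rates = counts_sum / counts_n / window

        nonblank = np.ones(n_cond, dtype=bool)
        nonblank[self.stim_set.blank_index()] = False
        self._nonblank = nonblank
        max_rate = float(self.empirical_rates[nonblank].max())
        if max_rate <= 0:
            raise ValueError("neuron has no stimulus-evoked response to fit")
        self.resp_max_bounds = (0.8 * max_rate, 1.2 * max_rate)

        if pref_direction is None:
            # circular vector average of the grating tuning curve, snapped to
            # the grid: robust to rep noise flattening the peak, unlike argmax
            gi = self.stim_set.grating_indices()
            dirs = np.array(
                [self.stim_set.conditions[i].pattern_direction for i in gi]
            )
            r = np.maximum(self.empirical_rates[gi], 0.0)
            vec = np.sum(r * np.exp(1j * np.deg2rad(dirs)))
            if np.abs(vec) > 0:
                ang = np.rad2deg(np.angle(vec)) % 360.0
                step = 360.0 / len(dirs)
                pref_direction = (round(ang / step) % len(dirs)) * step
            else:
                pref_direction = dirs[int(np.argmax(r))]
        self.pref_direction = float(pref_direction)

    # -- likelihood ---------------------------------------------------------

    def rates(self, params: PSSParams) -> np.ndarray:
        return pss_response_rates(self.bank, params, self.pref_direction)

    def loglike(self, params: PSSParams) -> float:
        lam = np.maximum(self.rates(params) * self.window_s, RATE_FLOOR)
        return float(
            np.sum(self._counts_sum * np.log(lam) - self._counts_n * lam) - self._lnfact
        )

    def _objective(self, x: np.ndarray) -> float:
        params = PSSParams(*x)
        try:
            return -self.loglike(params)
        except ValueError:  # degenerate linear stage
            return 1e12

    # -- fitting ------------------------------------------------------------

    def fit(
        self, seed: int = 0, restarts: int = 3, maxfun: int = 5000
    ) -> "MotionPathwayResults":
        """Maximise the Poisson log-likelihood by bounded dual annealing.

        Runs ``restarts`` independent annealing runs (seeded deterministically
        from ``seed``) and keeps the best.  Returns a results object carrying
        the parameter estimates, derived weight areas, the model-data
        correlation and the log-likelihood.
        """
        bounds = [PARAM_BOUNDS[n] for n in ("k_e", "k_i", "i_amp", "t_pss")]
        bounds.append(self.resp_max_bounds)
        children = np.random.SeedSequence(seed).spawn(restarts)
        best_x, best_fun = None, np.inf
        for child in children:
            rng = np.random.default_rng(child)
            res = _annealing(self._objective, bounds, rng, maxfun)
            if res.fun < best_fun:
                best_x, best_fun = np.clip(
                    res.x, [b[0] for b in bounds], [b[1] for b in bounds]
                ), res.fun
        params = PSSParams(*best_x)
        return MotionPathwayResults(self, params, llf=-best_fun, seed=seed)


def _annealing(func, bounds, rng, maxfun):
    kwargs = {"maxfun": maxfun}
    sig = inspect.signature(dual_annealing)
    if "rng" in sig.parameters:
        kwargs["rng"] = rng
    else:  # older scipy
        kwargs["seed"] = rng
    return dual_annealing(func, bounds, **kwargs)


class MotionPathwayResults:
    """Fit results: parameter estimates, weight areas and diagnostics."""

    def __init__(self, model: MotionPathwayModel, params: PSSParams, llf: float, seed: int):
        self.model = model
        self.params = params
        self.llf = llf
        self.seed = seed
        self.w_exc, self.w_inh = w_areas(params, model.bank.channel_directions)
        self.fitted_rates = model.rates(params)
        nb = model._nonblank
        self.fit_r = fit_quality(self.fitted_rates[nb], model.empirical_rates[nb])

    @property
    def passes_quality_cut(self) -> bool:
        """Fit retained if model-data correlation >= 0.5."""
        return self.fit_r >= 0.5

    def fitted_profile(self) -> TuningProfile2D:
        return profile_from_rates(self.fitted_rates, self.model.stim_set)

    def to_dict(self) -> dict:
        return {
            "K_E": self.params.k_e,
            "K_I": self.params.k_i,
            "I": self.params.i_amp,
            "T_PSS": self.params.t_pss,
            "Resp_max": self.params.resp_max,
            "W_exc": self.w_exc,
            "W_inh": self.w_inh,
            "fit_r": self.fit_r,
            "loglik": self.llf,
            "seed": self.seed,
        }

    def summary(self) -> str:
        d = self.to_dict()
        lines = ["Motion-pathway model fit (Poisson ML, dual annealing)"]
        lines.append("-" * 54)
        lines.append(f"{'pref direction':<16}{self.model.pref_direction:>10.1f} deg")
        for k in ("K_E", "K_I", "I", "T_PSS", "Resp_max"):
            lines.append(f"{k:<16}{d[k]:>10.4f}")
        lines.append(f"{'W_exc':<16}{d['W_exc']:>10.4f}")
        lines.append(f"{'W_inh':<16}{d['W_inh']:>10.4f}")
        lines.append(f"{'fit r':<16}{d['fit_r']:>10.4f}"
                     + ("" if self.passes_quality_cut else "   (below 0.5 cut)"))
        lines.append(f"{'log-likelihood':<16}{d['loglik']:>10.2f}")
        return "\n".join(lines)


def fit_pss(
    trials: pd.DataFrame,
    bank: V1FilterBank,
    seed: int = 0,
    restarts: int = 3,
    pref_direction: float | None = None,
    maxfun: int = 5000,
) -> MotionPathwayResults:
    """Convenience wrapper: build a :class:`MotionPathwayModel` and fit it."""
    return MotionPathwayModel(trials, bank, pref_direction).fit(
        seed=seed, restarts=restarts, maxfun=maxfun
    )
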