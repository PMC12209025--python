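"""Bayesian sigmoid change-point models for NEG time series.

A NEG series is modelled as a sum of one or two zero-anchored logistic
growth phases,

    m(t) = sum_i A_i / (1 + exp(-k_i (t - t0_i)))    (anchored so m(0) = 0),

with binomial observation noise on the visited-segment counts (the natural
model for grid data; a logit-normal family on the bounded percent scale is
available for non-count inputs).  The dual-phase model is
parameterised with an ordered inflexion pair (t0_2 = t0_1 + dt, dt > 0),
which removes label switching.  Posteriors are sampled with the affine-
invariant ensemble sampler (emcee), walkers are treated as chains for the
Rhat/ESS diagnostics, and phase models are compared by Pareto-smoothed
importance-sampling leave-one-out cross-validation (PSIS-LOO): the higher
elpd_loo wins, and when the difference is within its standard error the
model with fewer parameters is selected.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import arviz as az
import emcee
import numpy as np

from .neg import NEGSeries

__all__ = [
    "PhaseModelSpec",
    "SamplerSettings",
    "ChangePointFit",
    "ModelComparison",
    "fit_phase_model",
    "diagnostics",
    "predictive_check",
    "compare_models",
    "select_by_rule",
    "mean_series",
]

_EPS = 1e-4  # proportion clamp for the logit transform


class FitError(RuntimeError):
    """Raised for unusable input to the change-point sampler."""


@dataclass(frozen=True)
class PhaseModelSpec:
    """One- or two-phase sigmoid growth model with weakly-informative priors.

    Priors: amplitudes uniform on [0, 100] with their sum bounded by 100;
    inflexions uniform over the test duration (ordered in the dual model);
    log growth rate (and, for the logit-normal family, log observation
    scale) are Gaussian.

    ``family`` is the observation model: 'binomial' treats the NEG series
    as visited-segment counts out of ``n_trials`` (the scope's segment
    count) and is the natural choice for grid data; 'logit-normal' models
    the bounded percent series directly and suits non-count inputs.
    """

    n_phases: int = 1
    duration: float = 300.0
    family: str = "binomial"
    n_trials: int | None = None
    log_rate_loc: float = float(np.log(0.1))
    log_rate_scale: float = 1.0
    log_sigma_loc: float = float(np.log(0.5))
    log_sigma_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.n_phases not in (1, 2):
            raise ValueError("n_phases must be 1 or 2")
        if self.family not in ("binomial", "logit-normal"):
            raise ValueError("family must be 'binomial' or 'logit-normal'")

    @property
    def n_parameters(self) -> int:
        base = 3 if self.n_phases == 1 else 6
        return base + (1 if self.family == "logit-normal" else 0)

    @property
    def parameter_names(self) -> tuple[str, ...]:
        if self.n_phases == 1:
            names = ["amplitude", "log_rate", "inflexion"]
        else:
            names = [
                "amplitude_1", "amplitude_2", "log_rate_1", "log_rate_2",
                "inflexion_1", "delta_inflexion",
            ]
        if self.family == "logit-normal":
            names.append("log_sigma")
        return tuple(names)


@dataclass(frozen=True)
class SamplerSettings:
    """Ensemble-sampler configuration (walkers double as chains).

    Walkers start in a small ball around a multi-start MAP estimate, and
    the ensemble mixes with differential-evolution moves, which handle the
    strong rate/inflexion correlations of sigmoid growth models.
    """

    walkers: int = 48
    steps: int = 2600
    burn: int = 900
    thin: int = 1
    seed: int = 0
    map_restarts: int = 4
    #: Reruns with doubled chains when convergence diagnostics fail.
    auto_extend: int = 1


@dataclass
class ChangePointFit:
    """Posterior draws, pointwise log-likelihood and diagnostics for one fit."""

    spec: PhaseModelSpec
    posterior: dict[str, np.ndarray]  # name -> (chains, draws)
    log_likelihood: np.ndarray  # (chains, draws, n_obs)
    times: np.ndarray
    observed: np.ndarray  # percent
    rhat: dict[str, float]
    ess: dict[str, float]
    divergence_rate: float = 0.0
    name: str = ""

    @property
    def n_draws(self) -> int:
        first = next(iter(self.posterior.values()))
        return first.shape[0] * first.shape[1]

    def draws(self, name: str) -> np.ndarray:
        """Flattened posterior draws of one parameter."""
        return self.posterior[name].reshape(-1)

    def inflexions(self) -> np.ndarray:
        """Flattened draws of the (ordered) inflexion times, (n, n_phases)."""
        if self.spec.n_phases == 1:
            return self.draws("inflexion")[:, None]
        t1 = self.draws("inflexion_1")
        return np.column_stack([t1, t1 + self.draws("delta_inflexion")])

    def mean_curve_draws(self, times: np.ndarray | None = None) -> np.ndarray:
        """Posterior draws of the mean NEG curve, (n_draws, n_times)."""
        t = self.times if times is None else np.asarray(times, dtype=float)
        theta = np.column_stack(
            [self.draws(name) for name in self.spec.parameter_names]
        )
        return _mean_curve(theta, t, self.spec)

    def draws_frame(self):
        """Posterior draws as a tidy table (chain, draw, one column per
        parameter), suitable for delimited-text serialisation."""
        import pandas as pd

        first = next(iter(self.posterior.values()))
        chains, draws = first.shape
        frame = pd.DataFrame(
            {
                "chain": np.repeat(np.arange(chains), draws),
                "draw": np.tile(np.arange(draws), chains),
            }
        )
        for name, values in self.posterior.items():
            frame[name] = values.reshape(-1)
        return frame

    def to_inference_data(self) -> az.InferenceData:
        return az.from_dict(
            posterior={k: v for k, v in self.posterior.items()},
            log_likelihood={"neg": self.log_likelihood},
        )


@dataclass
class ModelComparison:
    """PSIS-LOO ranking over candidate phase models."""

    names: list[str]
    elpd_loo: list[float]
    se: list[float]
    p_loo: list[float]
    pareto_k_max: list[float]
    passed: list[bool]
    selected: str
    selected_index: int
    rationale: str


def _logit(p: np.ndarray) -> np.ndarray:
    p = np.clip(p, _EPS, 1.0 - _EPS)
    return np.log(p / (1.0 - p))


def _anchored(theta_a, theta_k, theta_t0, t) -> np.ndarray:
    """Zero-anchored sigmoid phases, broadcasting draws x times."""
    s = 1.0 / (1.0 + np.exp(-theta_k * (t - theta_t0)))
    s0 = 1.0 / (1.0 + np.exp(theta_k * theta_t0))
    return theta_a * (s - s0) / (1.0 - s0)


def _mean_curve(theta: np.ndarray, t: np.ndarray, spec: PhaseModelSpec) -> np.ndarray:
    """Mean curve for a batch of parameter vectors; (n, len(t))."""
    t = t[None, :]
    if spec.n_phases == 1:
        a, lk, t0 = theta[:, 0:1], theta[:, 1:2], theta[:, 2:3]
        return _anchored(a, np.exp(lk), t0, t)
    a1, a2 = theta[:, 0:1], theta[:, 1:2]
    k1, k2 = np.exp(theta[:, 2:3]), np.exp(theta[:, 3:4])
    t01 = theta[:, 4:5]
    t02 = t01 + theta[:, 5:6]
    return _anchored(a1, k1, t01, t) + _anchored(a2, k2, t02, t)


def _log_prior(theta: np.ndarray, spec: PhaseModelSpec) -> np.ndarray:
    """Vectorised log prior over a batch of parameter vectors."""
    if spec.n_phases == 1:
        a, lk, t0 = theta[:, 0], theta[:, 1], theta[:, 2]
        ok = (a >= 0) & (a <= 100) & (t0 >= 0) & (t0 <= spec.duration)
        lrates = lk[:, None]
    else:
        a1, a2 = theta[:, 0], theta[:, 1]
        t01, dt = theta[:, 4], theta[:, 5]
        a = a1 + a2
        ok = (
            (a1 >= 0) & (a2 >= 0) & (a <= 100)
            & (t01 >= 0) & (dt > 0) & (t01 + dt <= spec.duration)
        )
        lrates = theta[:, 2:4]
    lp = np.where(ok, 0.0, -np.inf)
    lp = lp - 0.5 * np.sum(
        ((lrates - spec.log_rate_loc) / spec.log_rate_scale) ** 2, axis=1
    )
    if spec.family == "logit-normal":
        ls = theta[:, -1]
        lp = lp - 0.5 * ((ls - spec.log_sigma_loc) / spec.log_sigma_scale) ** 2
    return lp


def _pointwise_loglik(theta: np.ndarray, t, obs, spec) -> np.ndarray:
    """Pointwise log likelihood, (n_batch, n_obs).

    ``obs`` is the logit-transformed series for the logit-normal family or
    the integer count vector for the binomial family.
    """
    if spec.family == "binomial":
        from scipy.special import gammaln

        n = float(spec.n_trials)
        p = np.clip(_mean_curve(theta, t, spec) / 100.0, 1e-9, 1 - 1e-9)
        y = obs[None, :]
        const = gammaln(n + 1) - gammaln(obs + 1) - gammaln(n - obs + 1)
        return const[None, :] + y * np.log(p) + (n - y) * np.log(1.0 - p)
    mu = _logit(_mean_curve(theta, t, spec) / 100.0)
    sigma = np.exp(theta[:, -1])[:, None]
    return (
        -0.5 * ((obs[None, :] - mu) / sigma) ** 2
        - np.log(sigma)
        - 0.5 * np.log(2 * np.pi)
    )


def _initial_guess(t, y, spec, rng, nwalkers):
    """Moment-based walker initialisation around a crude curve fit."""
    # Pooled series carry duplicate times; initialise from the mean profile.
    tu, inv = np.unique(t, return_inverse=True)
    yu = np.bincount(inv, weights=y) / np.bincount(inv)
    a_tot = max(float(np.max(yu)), 1.0)
    above = np.nonzero(yu >= a_tot / 2.0)[0]
    half_t = float(tu[above[0]]) if above.size else spec.duration / 2
    slopes = np.gradient(yu, tu) if tu.size > 1 else np.array([0.01])
    k0 = float(np.clip(4.0 * np.max(slopes) / a_tot, 1e-3, 2.0))
    if spec.n_phases == 1:
        centre = [a_tot, np.log(k0), half_t]
        scale = [3.0, 0.3, 8.0]
    else:
        # Split the amplitude and spread the inflexions around the half-time.
        centre = [a_tot / 2, a_tot / 2, np.log(k0), np.log(k0),
                  max(half_t - 25.0, 1.0), 50.0]
        scale = [3.0, 3.0, 0.3, 0.3, 8.0, 10.0]
    if spec.family == "logit-normal":
        centre.append(np.log(0.3))
        scale.append(0.3)
    centre, scale = np.asarray(centre), np.asarray(scale)
    pos = centre[None, :] + scale[None, :] * rng.standard_normal((nwalkers, centre.size))
    # Clip into the prior support.
    if spec.n_phases == 1:
        pos[:, 0] = np.clip(pos[:, 0], 1.0, 99.0)
        pos[:, 2] = np.clip(pos[:, 2], 1.0, spec.duration - 1.0)
    else:
        pos[:, 0] = np.clip(pos[:, 0], 1.0, 49.0)
        pos[:, 1] = np.clip(pos[:, 1], 1.0, 49.0)
        pos[:, 4] = np.clip(pos[:, 4], 1.0, spec.duration / 2)
        pos[:, 5] = np.clip(pos[:, 5], 5.0, spec.duration / 3)
    return pos


def _map_ball(log_prob, starts: np.ndarray, spec, rng, nwalkers: int) -> np.ndarray:
    """Walker ball around the best of several local posterior modes."""
    from scipy.optimize import minimize

    best_x, best_f = None, np.inf
    for x0 in starts:
        res = minimize(
            lambda th: -float(log_prob(th[None, :])[0]),
            x0,
            method="Nelder-Mead",
            options={"maxiter": 400 * spec.n_parameters, "fatol": 1e-3, "xatol": 1e-3},
        )
        if res.fun < best_f:
            best_x, best_f = res.x, res.fun
    jitter = 1e-3 * np.maximum(np.abs(best_x), 1.0)
    pos = best_x[None, :] + jitter[None, :] * rng.standard_normal((nwalkers, best_x.size))
    # Keep every walker inside the prior support.
    bad = ~np.isfinite(log_prob(pos))
    for _ in range(20):
        if not np.any(bad):
            break
        pos[bad] = best_x[None, :] + jitter[None, :] * rng.standard_normal((int(bad.sum()), best_x.size))
        bad = ~np.isfinite(log_prob(pos))
    return pos


def _stack_series(series) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(series, NEGSeries):
        series = [series]
    t = np.concatenate([s.times for s in series])
    y = np.concatenate([s.neg for s in series])
    order = np.argsort(t, kind="stable")
    return t[order], y[order]


def fit_phase_model(
    series,
    spec: PhaseModelSpec,
    settings: SamplerSettings = SamplerSettings(),
    seed: int | None = None,
    name: str = "",
    enforce_monotone: bool = True,
) -> ChangePointFit:
    """Sample the posterior of a phase model for one or more NEG series.

    ``series`` is a single :class:`NEGSeries` or a list (pooled subjects).
    Input curves must be monotone within [0, 100]; ``enforce_monotone``
    may be disabled for raw (pre-aggregation) count series.  The pointwise
    log-likelihood matrix is retained for PSIS-LOO comparison.
    """
    t, y = _stack_series(series)
    if np.any(y < -1e-9) or np.any(y > 100 + 1e-9):
        raise FitError("NEG observations must lie in [0, 100]")
    if enforce_monotone:
        for s in [series] if isinstance(series, NEGSeries) else series:
            if np.any(np.diff(s.neg) < -1e-9):
                raise FitError("NEG series must be monotone non-decreasing")

    if spec.family == "binomial" and not spec.n_trials:
        raise FitError("binomial family requires n_trials (scope segment count)")
    seed = settings.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    if spec.family == "binomial":
        obs = np.round(np.asarray(y, dtype=float) * spec.n_trials / 100.0)
    else:
        obs = _logit(np.asarray(y, dtype=float) / 100.0)

    def log_prob(theta: np.ndarray) -> np.ndarray:
        theta = np.atleast_2d(theta)
        lp = _log_prior(theta, spec)
        out = np.full(theta.shape[0], -np.inf)
        okay = np.isfinite(lp)
        if np.any(okay):
            ll = _pointwise_loglik(theta[okay], t, obs, spec).sum(axis=1)
            out[okay] = lp[okay] + ll
        return out

    ndim = spec.n_parameters
    nwalkers = max(settings.walkers, 2 * ndim + 2)
    starts = _initial_guess(t, y, spec, rng, max(settings.map_restarts, 1))
    pos = _map_ball(log_prob, starts, spec, rng, nwalkers)
    sampler = emcee.EnsembleSampler(
        nwalkers,
        ndim,
        log_prob,
        vectorize=True,
        moves=[(emcee.moves.DEMove(), 0.5), (emcee.moves.StretchMove(), 0.5)],
    )
    sampler.random_state = np.random.RandomState(seed).get_state()
    sampler.run_mcmc(pos, settings.steps, progress=False, skip_initial_state_check=True)

    chain = sampler.get_chain(discard=settings.burn, thin=settings.thin)
    # (steps, walkers, ndim) -> (walkers, steps, ndim): walkers act as chains.
    chain = np.transpose(chain, (1, 0, 2))
    names = spec.parameter_names
    posterior = {nm: chain[:, :, i] for i, nm in enumerate(names)}

    flat = chain.reshape(-1, ndim)
    ll = _pointwise_loglik(flat, t, obs, spec)
    log_likelihood = ll.reshape(chain.shape[0], chain.shape[1], t.size)

    idata = az.from_dict(posterior=posterior)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rhat_ds = az.rhat(idata)
        ess_ds = az.ess(idata)
    rhat = {nm: float(rhat_ds[nm].values) for nm in names}
    ess = {nm: float(ess_ds[nm].values) for nm in names}

    accept = float(np.mean(sampler.acceptance_fraction))
    converged = all(0.9 <= v <= 1.1 for v in rhat.values()) and all(
        v > 1000 for v in ess.values()
    )
    if not converged and settings.auto_extend > 0:
        # Ensemble mixing is occasionally slow from an unlucky start; a
        # doubled rerun with a fresh seed resolves it.
        longer = SamplerSettings(
            walkers=settings.walkers,
            steps=2 * settings.steps,
            burn=2 * settings.burn,
            thin=settings.thin,
            seed=settings.seed,
            map_restarts=settings.map_restarts,
            auto_extend=settings.auto_extend - 1,
        )
        return fit_phase_model(series, spec, longer, seed=seed + 1, name=name)
    return ChangePointFit(
        spec=spec,
        posterior=posterior,
        log_likelihood=log_likelihood,
        times=t,
        observed=y,
        rhat=rhat,
        ess=ess,
        divergence_rate=1.0 - accept,
        name=name or f"{spec.n_phases}-phase",
    )


def diagnostics(
    fit: ChangePointFit,
    rhat_tolerance: tuple[float, float] = (0.9, 1.1),
    ess_min: float = 1000.0,
    coverage_min: float = 0.8,
) -> dict:
    """Convergence and posterior-predictive report for one fit.

    Passes when every Rhat lies within the tolerance range, every ESS
    exceeds ``ess_min``, and the central 95% posterior-predictive interval
    covers at least ``coverage_min`` of the observations.
    """
    rhat_ok = all(rhat_tolerance[0] <= v <= rhat_tolerance[1] for v in fit.rhat.values())
    ess_ok = all(v > ess_min for v in fit.ess.values())
    coverage = posterior_predictive_coverage(fit)
    cover_ok = coverage >= coverage_min
    return {
        "rhat": fit.rhat,
        "ess": fit.ess,
        "rhat_ok": rhat_ok,
        "ess_ok": ess_ok,
        "predictive_coverage": coverage,
        "coverage_ok": cover_ok,
        "passed": rhat_ok and ess_ok and cover_ok,
    }


def posterior_predictive_coverage(
    fit: ChangePointFit, interval: float = 0.95, max_draws: int = 500, seed: int = 0
) -> float:
    """Fraction of observations inside the central predictive interval."""
    rng = np.random.default_rng(seed)
    theta = np.column_stack([fit.draws(nm) for nm in fit.spec.parameter_names])
    idx = rng.choice(theta.shape[0], size=min(max_draws, theta.shape[0]), replace=False)
    theta = theta[idx]
    lo_q, hi_q = (1 - interval) / 2, 1 - (1 - interval) / 2
    if fit.spec.family == "binomial":
        n = int(fit.spec.n_trials)
        p = np.clip(_mean_curve(theta, fit.times, fit.spec) / 100.0, 0.0, 1.0)
        rep = rng.binomial(n, p)
        obs = np.round(fit.observed * n / 100.0)
    else:
        mu = _logit(_mean_curve(theta, fit.times, fit.spec) / 100.0)
        sigma = np.exp(theta[:, -1])[:, None]
        rep = mu + sigma * rng.standard_normal(mu.shape)
        obs = _logit(fit.observed / 100.0)
    lo = np.quantile(rep, lo_q, axis=0)
    hi = np.quantile(rep, hi_q, axis=0)
    return float(np.mean((obs >= lo) & (obs <= hi)))


def predictive_check(
    spec: PhaseModelSpec | None = None,
    fit: ChangePointFit | None = None,
    series: NEGSeries | None = None,
    n_draws: int = 500,
    seed: int = 0,
    max_step_pct_per_s: float = 30.0,
) -> dict:
    """Prior (given ``spec``) or posterior (given ``fit``) predictive check.

    The prior check samples curves from the priors and reports the fraction
    that stay within [0, 100] and are monotone; the posterior check reports
    predictive-interval coverage of the observed series.
    """
    if fit is not None:
        return {
            "mode": "posterior",
            "coverage": posterior_predictive_coverage(fit, seed=seed),
        }
    if spec is None:
        raise ValueError("provide spec (prior check) or fit (posterior check)")
    rng = np.random.default_rng(seed)
    # 1-s resolution so single-second jumps are visible to the rate check.
    t = np.arange(0.0, spec.duration + 1.0)
    thetas = []
    for _ in range(n_draws):
        if spec.n_phases == 1:
            a = rng.uniform(0, 100)
            theta = [a, rng.normal(spec.log_rate_loc, spec.log_rate_scale),
                     rng.uniform(0, spec.duration)]
        else:
            a1 = rng.uniform(0, 100)
            a2 = rng.uniform(0, 100 - a1)
            t01 = rng.uniform(0, spec.duration)
            theta = [a1, a2,
                     rng.normal(spec.log_rate_loc, spec.log_rate_scale),
                     rng.normal(spec.log_rate_loc, spec.log_rate_scale),
                     t01, rng.uniform(0, spec.duration - t01)]
        if spec.family == "logit-normal":
            theta.append(rng.normal(spec.log_sigma_loc, spec.log_sigma_scale))
        thetas.append(theta)
    curves = _mean_curve(np.asarray(thetas), t, spec)
    in_bounds = np.mean(np.all((curves >= -1e-9) & (curves <= 100 + 1e-9), axis=1))
    monotone = np.mean(np.all(np.diff(curves, axis=1) >= -1e-6, axis=1))
    # A rodent cannot first-visit more than a bounded share of the grid per
    # second (movement speed caps the visit rate), so prior curves jumping
    # faster than max_step_pct_per_s are implausible.
    dt = t[1] - t[0]
    steps = np.diff(curves, axis=1) / dt
    physical = np.mean(np.all(steps <= max_step_pct_per_s + 1e-9, axis=1))
    plausible = float(min(in_bounds, monotone, physical))
    return {
        "mode": "prior",
        "fraction_in_bounds": float(in_bounds),
        "fraction_monotone": float(monotone),
        "fraction_physical": float(physical),
        "plausible": plausible,
        "flagged": plausible < 0.99,
    }


def select_by_rule(
    elpds: list[float],
    pointwise: list[np.ndarray],
    n_params: list[int],
    eligible: list[int],
) -> tuple[int, str]:
    """The phase-selection rule: highest elpd_loo, parsimony on equivalence.

    Two models are equivalent when |Delta elpd_loo| does not exceed the
    standard error of the pointwise elpd difference.
    """
    order = sorted(eligible, key=lambda i: -elpds[i])
    best = order[0]
    rationale = f"highest elpd_loo ({elpds[best]:.1f})"
    if len(order) > 1:
        runner = order[1]
        diff_pw = pointwise[best] - pointwise[runner]
        se_diff = float(np.sqrt(diff_pw.size * np.var(diff_pw, ddof=1)))
        delta = float(elpds[best] - elpds[runner])
        if abs(delta) <= se_diff and n_params[runner] < n_params[best]:
            best = runner
            rationale = (
                f"elpd_loo difference {delta:.2f} within its SE {se_diff:.2f}; "
                "most parsimonious model selected"
            )
    return best, rationale


def compare_models(
    fits: list[ChangePointFit],
    require_diagnostics: bool = True,
    ess_min: float = 1000.0,
) -> ModelComparison:
    """Select a phase model by PSIS-LOO with a parsimony tie-break.

    Only fits passing the convergence criteria are eligible.  The fit with
    the highest elpd_loo is preferred; when the difference between the two
    best is within its standard error, the fit with fewer parameters wins.
    """
    if len(fits) < 2:
        raise ValueError("need at least two fits to compare")
    loos = []
    for f in fits:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            loos.append(az.loo(f.to_inference_data(), pointwise=True))
    passed = [
        diagnostics(f, ess_min=ess_min)["passed"] if require_diagnostics else True
        for f in fits
    ]
    if not any(passed):
        raise FitError("no candidate model passed the convergence diagnostics")

    eligible = [i for i, ok in enumerate(passed) if ok]
    pointwise = [np.asarray(l.loo_i.values) for l in loos]
    best, rationale = select_by_rule(
        [float(l.elpd_loo) for l in loos],
        pointwise,
        [f.spec.n_parameters for f in fits],
        eligible,
    )
    return ModelComparison(
        names=[f.name for f in fits],
        elpd_loo=[float(l.elpd_loo) for l in loos],
        se=[float(l.se) for l in loos],
        p_loo=[float(l.p_loo) for l in loos],
        pareto_k_max=[float(np.max(l.pareto_k.values)) for l in loos],
        passed=passed,
        selected=fits[best].name,
        selected_index=best,
        rationale=rationale,
    )


def mean_series(series: list[NEGSeries], subject_id: str = "cohort-mean") -> NEGSeries:
    """Pointwise cohort-mean NEG series (all inputs on a common time grid)."""
    times = series[0].times
    for s in series[1:]:
        if not np.array_equal(s.times, times):
            raise ValueError("series must share a common time grid")
    return NEGSeries(
        subject_id=subject_id,
        scope=series[0].scope,
        times=times,
        neg=np.mean([s.neg for s in series], axis=0),
    )
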