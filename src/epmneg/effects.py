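"""Time-resolved effect estimation on NEG with ROPE equivalence decisions.

NEG count data (first-visited segments out of a scope's total) are modelled
with a binomial-logit additive model: one penalised smooth of time per group
(phenotype or arm type), a free intercept per group, and subject-level
random intercepts.  The smooth uses a cubic B-spline basis with a
second-difference penalty — the one-dimensional analogue of the thin-plate
penalty — and the smoothing variance is chosen by maximising the Laplace
approximation to the marginal likelihood.  The posterior over coefficients
is the Gaussian (Laplace) approximation at the penalised fit, the standard
empirical-Bayes treatment of penalised additive models.

Effects are posterior draws of group contrasts on the percent-NEG scale,
summarised per timepoint with the SeXiT quartet — median (centrality), 95%
HDI (uncertainty), probability of direction (existence), and the fraction
of the posterior inside a region of practical equivalence (significance).
The three-way decision rule: equivalent when > 97.5% of the posterior lies
inside the ROPE, not-equivalent when < 2.5% does, undecided otherwise.

Conventional open-arm measures are analysed with a conjugate Bayesian
linear regression on phenotype, with the linear ROPE +/- 0.1 x SD(y).
"""

from __future__ import annotations

from dataclasses import dataclass

import arviz as az
import numpy as np
import pandas as pd
from scipy.interpolate import BSpline

from .neg import NEGSeries

__all__ = [
    "RopeInterval",
    "EffectModel",
    "EffectSeries",
    "DecisionSeries",
    "build_rope",
    "fit_neg_effects",
    "contrast_over_time",
    "sexit",
    "decision_landmarks",
    "fit_conventional_effects",
]

#: Decision thresholds on the ROPE inside-fraction.
EQUIV_THRESHOLD = 0.975
NOT_EQUIV_THRESHOLD = 0.025


@dataclass(frozen=True)
class RopeInterval:
    """Region of practical equivalence around zero.

    ``scale`` is 'response' (the effect is compared on the response scale:
    proportion difference for growth models, raw units for linear models)
    or 'logit' (difference of logits of the scope proportions).
    """

    low: float
    high: float
    scale: str = "response"

    def __post_init__(self) -> None:
        if not self.low < 0 < self.high:
            raise ValueError("ROPE must straddle zero")
        if self.scale not in ("response", "logit"):
            raise ValueError("scale must be 'response' or 'logit'")


def build_rope(family: str, sd_y: float | None = None) -> RopeInterval:
    """Default ROPE per model family.

    Linear models: +/- 0.1 x SD of the response.  Growth (binomial-logit)
    models: +/- 0.18, applied by default to the proportion-difference scale
    (18 percentage points of NEG), matching the published equivalence bands.
    """
    if family in ("gaussian", "linear", "gaussian-linear"):
        if sd_y is None:
            raise ValueError("linear-family ROPE requires sd_y")
        if sd_y <= 0:
            raise ValueError("sd_y must be positive")
        return RopeInterval(-0.1 * sd_y, 0.1 * sd_y, scale="response")
    if family in ("binomial", "growth", "binomial-logit"):
        return RopeInterval(-0.18, 0.18, scale="response")
    raise ValueError(f"unknown family {family!r}")


# ---------------------------------------------------------------------------
# Penalised B-spline basis
# ---------------------------------------------------------------------------


def _bspline_basis(t: np.ndarray, t_min: float, t_max: float, n_basis: int):
    degree = 3
    n_inner = n_basis - degree + 1
    inner = np.linspace(t_min, t_max, n_inner)
    knots = np.concatenate([[t_min] * degree, inner, [t_max] * degree])
    return BSpline.design_matrix(
        np.clip(t, t_min, t_max), knots, degree
    ).toarray()


def _diff_penalty(n_basis: int) -> np.ndarray:
    d = np.diff(np.eye(n_basis), n=2, axis=0)
    return d.T @ d


@dataclass
class EffectModel:
    """Laplace posterior of a per-group additive model on NEG counts."""

    family: str
    groups: list[str]
    n_segments: int
    t_range: tuple[float, float]
    n_basis: int
    beta_hat: np.ndarray
    beta_draws: np.ndarray  # (n_draws, p)
    columns: dict[str, tuple[int, slice]]  # group -> (intercept col, basis cols)
    smooth_variance: float
    subject_sd: float
    subjects: list[str]

    def linpred_draws(self, group: str, times: np.ndarray) -> np.ndarray:
        """Population-level linear predictor draws, (n_draws, n_times)."""
        if group not in self.columns:
            raise KeyError(f"unknown group {group!r}")
        icol, bcols = self.columns[group]
        B = _bspline_basis(np.asarray(times, float), *self.t_range, self.n_basis)
        return (
            self.beta_draws[:, icol][:, None]
            + self.beta_draws[:, bcols] @ B.T
        )

    def curve_draws(self, group: str, times: np.ndarray) -> np.ndarray:
        """Posterior draws of the group mean NEG curve in percent."""
        eta = self.linpred_draws(group, times)
        return 100.0 / (1.0 + np.exp(-eta))


@dataclass
class EffectSeries:
    """Posterior draws of a group contrast over time."""

    contrast: str
    times: np.ndarray
    draws_percent: np.ndarray  # (n_draws, n_times), percent-NEG difference
    draws_logit: np.ndarray  # same shape, difference of logits

    def draws_on(self, scale: str) -> np.ndarray:
        if scale == "response":
            return self.draws_percent / 100.0  # proportion difference
        if scale == "logit":
            return self.draws_logit
        raise ValueError(f"unknown scale {scale!r}")


@dataclass
class DecisionSeries:
    """Per-timepoint SeXiT summary and three-way equivalence decision."""

    contrast: str
    times: np.ndarray
    median: np.ndarray  # percent-NEG difference
    hdi_low: np.ndarray
    hdi_high: np.ndarray
    pd: np.ndarray
    rope_frac: np.ndarray
    decision: np.ndarray  # 'equivalent' | 'not-equivalent' | 'undecided'
    rope: RopeInterval | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "contrast": self.contrast,
                "time_s": self.times,
                "median": self.median,
                "hdi_low": self.hdi_low,
                "hdi_high": self.hdi_high,
                "pd": self.pd,
                "rope_frac": self.rope_frac,
                "decision": self.decision,
            }
        )


def _counts_frame(
    series_by_group: dict[str, list[NEGSeries]], n_segments: int
) -> pd.DataFrame:
    rows = []
    for group, series in series_by_group.items():
        for s in series:
            counts = np.round(s.neg * n_segments / 100.0).astype(int)
            rows.append(
                pd.DataFrame(
                    {
                        "group": group,
                        "subject": f"{group}:{s.subject_id}",
                        "time": s.times,
                        "count": counts,
                    }
                )
            )
    return pd.concat(rows, ignore_index=True)


def fit_neg_effects(
    series_by_group: dict[str, list[NEGSeries]],
    n_segments: int,
    structure: str = "multiphase",
    basis_size: int | None = None,
    n_draws: int = 4000,
    seed: int = 0,
    intercept_prior_sd: float = 10.0,
    subject_sd: float = 1.0,
) -> EffectModel:
    """Fit the binomial additive model to multi-group NEG observations.

    ``series_by_group`` maps a group label (phenotype or arm type) to that
    group's per-subject NEG series for one scope; counts are reconstructed
    as ``neg / 100 * n_segments``.  ``structure`` ('single-phase' or
    'multiphase') follows the change-point model comparison and sets the
    default smooth basis size (8 vs 12); both structures share the binomial
    family, since a single growth phase is still a nonlinear curve in time.
    """
    if len(series_by_group) < 2:
        raise ValueError("need at least two groups to estimate contrasts")
    if basis_size is None:
        basis_size = 8 if structure == "single-phase" else 12
    df = _counts_frame(series_by_group, n_segments)
    groups = list(series_by_group)
    subjects = sorted(df["subject"].unique())
    t_min, t_max = float(df["time"].min()), float(df["time"].max())

    n_obs = len(df)
    n_g = len(groups)
    n_sub = len(subjects)
    p = n_g * (1 + basis_size) + n_sub
    X = np.zeros((n_obs, p))
    columns: dict[str, tuple[int, slice]] = {}
    for gi, g in enumerate(groups):
        icol = gi * (1 + basis_size)
        bcols = slice(icol + 1, icol + 1 + basis_size)
        columns[g] = (icol, bcols)
        mask = (df["group"] == g).to_numpy()
        X[mask, icol] = 1.0
        X[mask, bcols] = _bspline_basis(
            df.loc[mask, "time"].to_numpy(float), t_min, t_max, basis_size
        )
    sub_base = n_g * (1 + basis_size)
    sub_idx = {s: sub_base + i for i, s in enumerate(subjects)}
    X[np.arange(n_obs), df["subject"].map(sub_idx).to_numpy()] = 1.0

    y = df["count"].to_numpy(float)
    N = float(n_segments)

    ridge = np.full(p, intercept_prior_sd**-2)
    ridge[sub_base:] = subject_sd**-2
    pen_block = _diff_penalty(basis_size)

    def penalty(lam: float, sd_u: float) -> np.ndarray:
        S = np.diag(ridge.copy())
        S[range(sub_base, p), range(sub_base, p)] = sd_u**-2
        for g in groups:
            _, bcols = columns[g]
            S[bcols, bcols] += lam * pen_block
        return S

    def penalised_nll(beta: np.ndarray, S: np.ndarray) -> float:
        eta = np.clip(X @ beta, -30.0, 30.0)
        mu = np.clip(1.0 / (1.0 + np.exp(-eta)), 1e-10, 1 - 1e-10)
        ll = float(np.sum(y * np.log(mu) + (N - y) * np.log(1 - mu)))
        return -ll + 0.5 * float(beta @ S @ beta)

    # Empirical-logit start shared by every smoothing-grid fit.
    eta0 = np.log((y + 0.5) / (N - y + 0.5))
    beta0 = np.linalg.solve(X.T @ X + np.diag(ridge) + np.eye(p) * 1e-6, X.T @ eta0)

    def pirls(S: np.ndarray):
        beta = beta0.copy()
        obj = penalised_nll(beta, S)
        for _ in range(60):
            eta = np.clip(X @ beta, -30.0, 30.0)
            mu = np.clip(1.0 / (1.0 + np.exp(-eta)), 1e-6, 1 - 1e-6)
            w = np.maximum(N * mu * (1 - mu), 1e-4)
            z = eta + (y - N * mu) / w
            H = X.T @ (X * w[:, None]) + S
            beta_prop = np.linalg.solve(H, X.T @ (w * z))
            # Step-halving keeps the penalised deviance monotone.
            step, accepted = 1.0, False
            for _ in range(30):
                cand = beta + step * (beta_prop - beta)
                obj_new = penalised_nll(cand, S)
                if obj_new <= obj + 1e-10:
                    accepted = True
                    break
                step *= 0.5
            if not accepted:
                break
            converged = np.max(np.abs(cand - beta)) < 1e-7
            beta, obj = cand, obj_new
            if converged:
                break
        eta = np.clip(X @ beta, -30.0, 30.0)
        mu = np.clip(1.0 / (1.0 + np.exp(-eta)), 1e-10, 1 - 1e-10)
        ll = float(np.sum(y * np.log(mu) + (N - y) * np.log(1 - mu)))
        H = X.T @ (X * np.maximum(N * mu * (1 - mu), 1e-4)[:, None]) + S
        return beta, H, ll

    # Smoothing and subject-effect variances by sequential Laplace-marginal
    # likelihood passes over coarse grids.
    def laml_at(lam: float, sd_u: float):
        S = penalty(lam, sd_u)
        beta, H, ll = pirls(S)
        _, logdet_s = np.linalg.slogdet(S)
        _, logdet_h = np.linalg.slogdet(H)
        laml = ll - 0.5 * beta @ S @ beta + 0.5 * logdet_s - 0.5 * logdet_h
        return laml, beta, H

    best = None
    for lam in 10.0 ** np.arange(-2.0, 4.5, 1.0):
        laml, beta, H = laml_at(lam, subject_sd)
        if best is None or laml > best[0]:
            best = (laml, lam, subject_sd, beta, H)
    lam = best[1]
    for sd_u in (0.05, 0.1, 0.2, 0.4, 0.8, 1.6):
        laml, beta, H = laml_at(lam, sd_u)
        if laml > best[0]:
            best = (laml, lam, sd_u, beta, H)
    _, lam, sd_u, beta_hat, H = best

    rng = np.random.default_rng(seed)
    L = np.linalg.cholesky(H)
    z = rng.standard_normal((p, n_draws))
    beta_draws = beta_hat[None, :] + np.linalg.solve(L.T, z).T

    return EffectModel(
        family="binomial-logit",
        groups=groups,
        n_segments=n_segments,
        t_range=(t_min, t_max),
        n_basis=basis_size,
        beta_hat=beta_hat,
        beta_draws=beta_draws,
        columns=columns,
        smooth_variance=1.0 / lam,
        subject_sd=sd_u,
        subjects=subjects,
    )


def contrast_over_time(
    model: EffectModel, contrast: tuple[str, str], times: np.ndarray | None = None
) -> EffectSeries:
    """Posterior draws of group A minus group B over a time grid.

    The difference is taken after inverse-linking, on the percent-NEG
    scale; the logit-scale difference is retained for logit-scale ROPEs.
    """
    a, b = contrast
    if times is None:
        times = np.arange(model.t_range[0], model.t_range[1] + 1.0)
    times = np.asarray(times, dtype=float)
    eta_a = model.linpred_draws(a, times)
    eta_b = model.linpred_draws(b, times)
    inv = lambda e: 100.0 / (1.0 + np.exp(-e))
    return EffectSeries(
        contrast=f"{a} - {b}",
        times=times,
        draws_percent=inv(eta_a) - inv(eta_b),
        draws_logit=eta_a - eta_b,
    )


def _hdi(draws: np.ndarray, mass: float = 0.95) -> tuple[np.ndarray, np.ndarray]:
    """Columnwise HDI of a (draws, times) matrix."""
    srt = np.sort(draws, axis=0)
    n = srt.shape[0]
    k = max(int(np.floor(mass * n)), 1)
    widths = srt[k - 1 :, :] - srt[: n - k + 1, :]
    start = np.argmin(widths, axis=0)
    cols = np.arange(srt.shape[1])
    return srt[start, cols], srt[start + k - 1, cols]


def sexit(
    series: EffectSeries, rope: RopeInterval, hdi_mass: float = 0.95
) -> DecisionSeries:
    """SeXiT summary with the three-way ROPE decision per timepoint.

    The effect is mapped to the ROPE's scale before the inside-fraction is
    computed; centrality/uncertainty are reported on the percent-NEG scale.
    PD is max(P(effect > 0), P(effect < 0)); an exactly symmetric posterior
    reports 0.5.
    """
    pct = series.draws_percent
    on_scale = series.draws_on(rope.scale)
    median = np.median(pct, axis=0)
    lo, hi = _hdi(pct, hdi_mass)
    p_pos = np.mean(on_scale > 0, axis=0)
    p_neg = np.mean(on_scale < 0, axis=0)
    pd_ = np.maximum(np.maximum(p_pos, p_neg), 0.5)
    frac = np.mean((on_scale >= rope.low) & (on_scale <= rope.high), axis=0)
    decision = np.where(
        frac > EQUIV_THRESHOLD,
        "equivalent",
        np.where(frac < NOT_EQUIV_THRESHOLD, "not-equivalent", "undecided"),
    )
    return DecisionSeries(
        contrast=series.contrast,
        times=series.times,
        median=median,
        hdi_low=lo,
        hdi_high=hi,
        pd=pd_,
        rope_frac=frac,
        decision=decision,
        rope=rope,
    )


def decision_landmarks(dec: DecisionSeries) -> dict:
    """Timeline landmarks of a decision series.

    Reports the earliest time the contrast becomes not-equivalent
    (significance onset), the earliest return to equivalence after a
    not-equivalent spell, the duration of the initial equivalent spell,
    and the total time spent in each decision state.
    """
    times = dec.times
    states = dec.decision
    dt = np.diff(times, append=times[-1] + (times[-1] - times[-2] if times.size > 1 else 1.0))
    durations = {
        s: float(np.sum(dt[states == s]))
        for s in ("equivalent", "not-equivalent", "undecided")
    }
    onset = None
    ne_idx = np.nonzero(states == "not-equivalent")[0]
    if ne_idx.size:
        onset = float(times[ne_idx[0]])
    ret = None
    if ne_idx.size:
        after = np.nonzero((states == "equivalent") & (np.arange(states.size) > ne_idx[0]))[0]
        if after.size:
            ret = float(times[after[0]])
    init = 0.0
    for i, s in enumerate(states):
        if s != "equivalent":
            init = float(times[i] - times[0])
            break
    else:
        init = float(times[-1] - times[0])
    return {
        "significance_onset": onset,
        "return_to_equivalence": ret,
        "initial_equivalent_duration": init,
        "state_durations": durations,
    }


def fit_conventional_effects(
    draws: pd.DataFrame,
    seed: int = 0,
    n_draws: int = 4000,
    hdi_mass: float = 0.95,
    measures: tuple[str, ...] = ("latency_open", "entries_open", "time_open"),
) -> dict[str, dict[str, DecisionSeries]]:
    """Bayesian linear regression of each conventional measure on phenotype.

    ``draws`` is the tidy output of ``simulate_conventional`` (or measured
    data with the same columns).  Cell-means coding with a flat prior on
    the means and Jeffreys prior on the residual variance gives the exact
    conjugate posterior; pairwise phenotype contrasts are summarised via
    SeXiT with the linear ROPE +/- 0.1 x SD(y).

    Returns ``{measure: {"a vs b": DecisionSeries (single timepoint)}}``.
    """
    phenotypes = list(dict.fromkeys(draws["phenotype"]))
    if len(phenotypes) < 2:
        raise ValueError("need at least two phenotypes")
    rng = np.random.default_rng(seed)
    out: dict[str, dict[str, DecisionSeries]] = {}
    for measure in measures:
        y_all = draws[measure].to_numpy(float)
        sd_y = float(np.std(y_all, ddof=1))
        rope = build_rope("linear", sd_y=sd_y)
        stats_ = {
            p: (
                float(np.mean(draws.loc[draws["phenotype"] == p, measure])),
                int(np.sum(draws["phenotype"] == p)),
            )
            for p in phenotypes
        }
        n_total = len(y_all)
        rss = float(
            sum(
                np.sum(
                    (draws.loc[draws["phenotype"] == p, measure] - stats_[p][0]) ** 2
                )
                for p in phenotypes
            )
        )
        dof = n_total - len(phenotypes)
        # sigma^2 ~ Inv-Gamma(dof/2, rss/2); mu_p | sigma^2 ~ N(ybar_p, sigma^2/n_p)
        sigma2 = rss / (2.0 * rng.gamma(dof / 2.0, 1.0, size=n_draws))
        mu_draws = {
            p: stats_[p][0] + np.sqrt(sigma2 / stats_[p][1]) * rng.standard_normal(n_draws)
            for p in phenotypes
        }
        res: dict[str, DecisionSeries] = {}
        for i, a in enumerate(phenotypes):
            for b in phenotypes[i + 1 :]:
                eff = (mu_draws[a] - mu_draws[b])[:, None]
                series = EffectSeries(
                    contrast=f"{a} - {b} ({measure})",
                    times=np.array([0.0]),
                    draws_percent=eff,
                    draws_logit=eff,
                )
                res[f"{a} vs {b}"] = _sexit_raw(series, rope, hdi_mass)
        out[measure] = res
    return out


def _sexit_raw(series: EffectSeries, rope: RopeInterval, hdi_mass: float) -> DecisionSeries:
    """SeXiT for effects already on the ROPE's raw response scale."""
    eff = series.draws_percent
    median = np.median(eff, axis=0)
    lo, hi = _hdi(eff, hdi_mass)
    p_pos = np.mean(eff > 0, axis=0)
    p_neg = np.mean(eff < 0, axis=0)
    frac = np.mean((eff >= rope.low) & (eff <= rope.high), axis=0)
    decision = np.where(
        frac > EQUIV_THRESHOLD,
        "equivalent",
        np.where(frac < NOT_EQUIV_THRESHOLD, "not-equivalent", "undecided"),
    )
    return DecisionSeries(
        contrast=series.contrast,
        times=series.times,
        median=median,
        hdi_low=lo,
        hdi_high=hi,
        pd=np.maximum(np.maximum(p_pos, p_neg), 0.5),
        rope_frac=frac,
        decision=decision,
        rope=rope,
    )
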