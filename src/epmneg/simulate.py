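"""Synthetic cohorts for the three exploratory phenotypes.

Per-arm-type NEG curves are generated from zero-anchored sigmoid growth
functions; the three phenotypes are

* ``exploratory`` — arm-agnostic exploration from test onset: both arm types
  share the same growth-rate and inflexion distributions;
* ``delayed`` — closed arms explored first; the open arms are entered only at
  the test mid-point (~150 s into a 300-s test) and fully explored after
  ~200 s, produced by a late open-arm inflexion;
* ``avoidant`` — the open arms are never explored (open growth rate and
  inflexion both 0, curve identically 0).

Conventional open-arm measures (latency, entries, time) are drawn from
Gaussians truncated to [0, duration], the generating model used for the
conventional-measure comparison study.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .geometry import MazeGeometry
from .neg import NEGSeries

__all__ = [
    "ArmSigmoid",
    "PhenotypeParams",
    "ConventionalSimConfig",
    "PHENOTYPES",
    "default_params",
    "default_conventional_config",
    "sigmoid_curve",
    "simulate_neg",
    "simulate_conventional",
]

PHENOTYPES = ("exploratory", "delayed", "avoidant")


@dataclass(frozen=True)
class ArmSigmoid:
    """Sigmoid growth parameters for one arm type.

    ``rate`` (1/s) and ``inflexion`` (s) parameterise the logistic curve
    ``A / (1 + exp(-rate * (t - inflexion)))``; ``asymptote`` is in percent of
    the arm type's segments.  Rate 0 with inflexion 0 encodes "never
    explored" (curve identically zero).
    """

    rate: float
    inflexion: float
    asymptote: float = 100.0

    def __post_init__(self) -> None:
        if self.rate < 0:
            raise ValueError("rate must be >= 0")
        if not 0 <= self.asymptote <= 100:
            raise ValueError("asymptote must be in [0, 100]")


@dataclass(frozen=True)
class PhenotypeParams:
    """Generating parameters for one simulated phenotype."""

    phenotype: str
    open_arm: ArmSigmoid
    closed_arm: ArmSigmoid
    duration: float = 300.0
    noise: bool = True  # binomial noise on visited-segment counts
    rate_sd: float = 0.015  # inter-subject sd of the growth rate (1/s)
    inflexion_sd: float = 8.0  # inter-subject sd of the inflexion (s)

    def __post_init__(self) -> None:
        for arm in (self.open_arm, self.closed_arm):
            if not 0 <= arm.inflexion <= self.duration:
                raise ValueError("inflexion must lie within [0, duration]")
        if self.phenotype == "avoidant" and (
            self.open_arm.rate != 0 or self.open_arm.inflexion != 0
        ):
            raise ValueError("avoidant phenotype requires zero open-arm parameters")


def default_params(phenotype: str, duration: float = 300.0) -> PhenotypeParams:
    """Package-default generating parameters per phenotype.

    Exploratory draws both arm types from the same parameter distribution
    (rate 0.10/s, inflexion 30 s).  Delayed explores the closed arms early
    (inflexion 30 s) and the open arms late: rate 0.11/s with inflexion at
    200 s places the first open-arm entry at the 150-s test mid-point and
    completes open-arm exploration after ~200 s.  Avoidant has open-arm rate
    and inflexion fixed at 0 (no open exploration).
    """
    if phenotype == "exploratory":
        arm = ArmSigmoid(rate=0.10, inflexion=30.0)
        return PhenotypeParams(phenotype, open_arm=arm, closed_arm=arm, duration=duration)
    if phenotype == "delayed":
        return PhenotypeParams(
            phenotype,
            open_arm=ArmSigmoid(rate=0.11, inflexion=200.0 * duration / 300.0),
            closed_arm=ArmSigmoid(rate=0.11, inflexion=30.0),
            duration=duration,
        )
    if phenotype == "avoidant":
        return PhenotypeParams(
            phenotype,
            open_arm=ArmSigmoid(rate=0.0, inflexion=0.0),
            closed_arm=ArmSigmoid(rate=0.11, inflexion=30.0),
            duration=duration,
        )
    raise ValueError(f"unknown phenotype {phenotype!r}")


def sigmoid_curve(times: np.ndarray, arm: ArmSigmoid) -> np.ndarray:
    """Zero-anchored expected NEG curve (percent) for one arm type.

    The raw logistic is positive at t = 0; the curve is shifted and rescaled
    so that exploration starts at exactly 0, preserving the asymptote.
    """
    times = np.asarray(times, dtype=float)
    if arm.rate == 0:
        return np.zeros_like(times)
    s = 1.0 / (1.0 + np.exp(-arm.rate * (times - arm.inflexion)))
    s0 = 1.0 / (1.0 + np.exp(arm.rate * arm.inflexion))
    return arm.asymptote * (s - s0) / (1.0 - s0)


def _subject_arm(arm: ArmSigmoid, params: PhenotypeParams, rng) -> ArmSigmoid:
    """Jitter one arm's parameters for inter-subject variability."""
    if arm.rate == 0:
        return arm
    rate = max(float(rng.normal(arm.rate, params.rate_sd)), 1e-3)
    infl = float(np.clip(rng.normal(arm.inflexion, params.inflexion_sd), 0, params.duration))
    return ArmSigmoid(rate=rate, inflexion=infl, asymptote=arm.asymptote)


def simulate_neg(
    params: PhenotypeParams,
    geometry: MazeGeometry,
    n_subjects: int,
    seed: int | np.random.SeedSequence,
) -> dict[str, list[NEGSeries]]:
    """Simulate per-subject NEG series for the open, closed and total scopes.

    Each subject receives jittered sigmoid parameters; when ``params.noise``
    is set, each segment draws a latent first-visit threshold so that the
    visited count at every second is binomial around the expected curve
    while remaining a monotone counting process.  The total-maze series is
    derived from the two arm-type counts through the composite identity
    (total visited = open visited + closed visited).
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    rng = np.random.default_rng(seed)
    times = np.arange(int(params.duration) + 1, dtype=float)
    n_open = geometry.n_segments("open")
    n_closed = geometry.n_segments("closed")
    out: dict[str, list[NEGSeries]] = {"open": [], "closed": [], "total": []}
    # An arm-agnostic phenotype (identical arm parameters) explores both arm
    # types on one schedule, so subject-level jitter is shared across arms;
    # otherwise each arm type is jittered independently.
    coupled = params.open_arm == params.closed_arm
    for i in range(n_subjects):
        sid = f"{params.phenotype}_{i + 1:02d}"
        counts = {}
        shared = _subject_arm(params.open_arm, params, rng) if coupled else None
        for scope, arm, n_seg in (
            ("open", params.open_arm, n_open),
            ("closed", params.closed_arm, n_closed),
        ):
            subject_arm = shared if coupled else _subject_arm(arm, params, rng)
            mu = sigmoid_curve(times, subject_arm) / 100.0
            if params.noise and arm.rate > 0:
                # Latent first-visit threshold per segment: the visited count
                # at every second is marginally Binomial(n_seg, mu(t)) and the
                # series is monotone by construction (a counting process).
                u = rng.uniform(size=n_seg)
                counts[scope] = (u[None, :] <= np.clip(mu, 0.0, 1.0)[:, None]).sum(
                    axis=1
                ).astype(float)
            else:
                counts[scope] = np.round(mu * n_seg)
        counts["total"] = counts["open"] + counts["closed"]
        for scope, n_seg in (("open", n_open), ("closed", n_closed), ("total", n_open + n_closed)):
            out[scope].append(
                NEGSeries(sid, scope, times, 100.0 * counts[scope] / n_seg)
            )
    return out


@dataclass(frozen=True)
class TruncGauss:
    """Mean/sd of a Gaussian truncated to [0, duration]; sd 0 is degenerate."""

    mean: float
    sd: float


@dataclass(frozen=True)
class ConventionalSimConfig:
    """Generating distributions for the conventional-measure study."""

    measures: dict[str, dict[str, TruncGauss]]  # phenotype -> measure -> dist
    duration: float = 300.0
    n_reps: int = 1000

    def __post_init__(self) -> None:
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        for phen, ms in self.measures.items():
            for name, d in ms.items():
                if not 0 <= d.mean <= self.duration:
                    raise ValueError(f"{phen}/{name}: mean outside [0, duration]")
                if d.sd < 0:
                    raise ValueError(f"{phen}/{name}: sd must be >= 0")


def default_conventional_config(
    duration: float = 300.0, n_reps: int = 1000
) -> ConventionalSimConfig:
    """Defaults mirroring the simulation heuristics.

    Exploratory and delayed share the entry-count and open-time
    distributions (two full-exploration entries, identical speed) and differ
    only in latency (test onset vs the 150-s mid-point).  Avoidant never
    enters: latency pinned at the full duration, entries and time at 0.
    """
    # Two full-exploration entries; open-arm time = 2 arms x (in + out) at
    # the default 5 cm/s over 50-cm arms = 40 s, identical across phenotypes.
    entries = TruncGauss(2.0, 0.15)
    time_open = TruncGauss(40.0, 5.0)
    return ConventionalSimConfig(
        measures={
            "exploratory": {
                "latency_open": TruncGauss(15.0, 8.0),
                "entries_open": entries,
                "time_open": time_open,
            },
            "delayed": {
                "latency_open": TruncGauss(150.0, 15.0),
                "entries_open": entries,
                "time_open": time_open,
            },
            "avoidant": {
                "latency_open": TruncGauss(duration, 0.0),
                "entries_open": TruncGauss(0.0, 0.0),
                "time_open": TruncGauss(0.0, 0.0),
            },
        },
        duration=duration,
        n_reps=n_reps,
    )


def _trunc_gauss_draws(d: TruncGauss, lo: float, hi: float, n: int, rng) -> np.ndarray:
    if d.sd == 0:
        return np.full(n, float(np.clip(d.mean, lo, hi)))
    a, b = (lo - d.mean) / d.sd, (hi - d.mean) / d.sd
    # Inverse-CDF sampling for exactness under seeding.
    u = rng.uniform(size=n)
    return stats.truncnorm.ppf(u, a, b, loc=d.mean, scale=d.sd)


def simulate_conventional(
    config: ConventionalSimConfig, seed: int | np.random.SeedSequence
):
    """Draw ``n_reps`` conventional-measure replicates per phenotype.

    Returns a tidy DataFrame (phenotype, rep, latency_open, entries_open,
    time_open), each value truncated to [0, duration].
    """
    import pandas as pd

    rng = np.random.default_rng(seed)
    rows = []
    for phen, ms in config.measures.items():
        draws = {
            name: _trunc_gauss_draws(d, 0.0, config.duration, config.n_reps, rng)
            for name, d in ms.items()
        }
        for r in range(config.n_reps):
            rows.append(
                {
                    "phenotype": phen,
                    "rep": r + 1,
                    **{name: float(v[r]) for name, v in draws.items()},
                }
            )
    return pd.DataFrame(rows)
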