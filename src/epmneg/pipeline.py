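"""End-to-end orchestration: tracking/simulation -> NEG -> phases -> effects -> calls."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import changepoint as cp
from . import effects as fx
from .config import RunConfig, derive_seed
from .decide import PhenotypeCall, classify
from .neg import NEGSeries, compute_neg, neg_to_frame
from .simulate import default_params, simulate_neg
from .tracking import TrackingSeries, discretize, read_tracking

__all__ = ["PipelineResult", "run_pipeline"]

logger = logging.getLogger("epmneg")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineResult:
    neg: dict[str, dict[str, list[NEGSeries]]]  # group -> scope -> series
    comparisons: dict[str, cp.ModelComparison]
    arm_decisions: dict[str, fx.DecisionSeries]
    calls: dict[str, PhenotypeCall]
    metadata: dict = field(default_factory=dict)


def _subsample(series: NEGSeries, step: float) -> NEGSeries:
    keep = np.isclose(series.times % step, 0.0)
    return NEGSeries(series.subject_id, series.scope, series.times[keep], series.neg[keep])


def run_pipeline(
    config: RunConfig,
    tracking_files: list | None = None,
    output_dir: str | Path | None = None,
) -> PipelineResult:
    """Execute the full analysis workflow and write every artefact.

    Without ``tracking_files`` the configured phenotype cohorts are
    simulated; with them, each file becomes one subject in a single
    observed group.  Stages: (simulate | discretise) -> NEG -> change-point
    phase selection on an exemplar total-maze series -> arm-type effect
    model and SeXiT decisions -> phenotype/ALB classification.
    """
    geometry = config.maze.build()
    out = Path(output_dir or config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    neg: dict[str, dict[str, list[NEGSeries]]] = {}
    try:
        if tracking_files:
            series_by_scope: dict[str, list[NEGSeries]] = {"open": [], "closed": [], "total": []}
            for path in tracking_files:
                track = read_tracking(path) if not isinstance(path, TrackingSeries) else path
                occ = discretize(
                    track, geometry,
                    interpolate=config.discretisation.interpolate,
                    speed_warn=config.discretisation.speed_warn,
                )
                for scope in ("open", "closed", "total"):
                    series_by_scope[scope].append(compute_neg(occ, geometry, scope))
            neg["observed"] = series_by_scope
        else:
            for phen in config.simulation.phenotypes:
                params = default_params(phen, duration=config.simulation.duration)
                if not config.simulation.noise:
                    params = type(params)(**{**params.__dict__, "noise": False})
                neg[phen] = simulate_neg(
                    params, geometry, config.simulation.n_subjects,
                    seed=derive_seed(config.seed, f"simulate:{phen}"),
                )
    except Exception as exc:  # noqa: BLE001 - stage-labelled reraise
        raise PipelineError("input", str(exc)) from exc

    all_series = [s for scopes in neg.values() for ss in scopes.values() for s in ss]
    neg_to_frame(all_series).to_csv(out / "neg.csv", index=False)

    settings = cp.SamplerSettings(
        walkers=config.sampler.walkers, steps=config.sampler.steps, burn=config.sampler.burn
    )
    comparisons: dict[str, cp.ModelComparison] = {}
    fits: dict[str, cp.ChangePointFit] = {}
    try:
        for group, scopes in neg.items():
            # Phase structure is assessed on a representative exemplar (the
            # subject with the median final total NEG): the cohort mean of
            # time-jittered subjects is flattened out of the sigmoid family.
            finals = np.array([s.neg[-1] for s in scopes["total"]])
            exemplar = int(np.argsort(finals, kind="stable")[finals.size // 2])
            series = _subsample(scopes["total"][exemplar], config.sampler.time_step)
            candidates = []
            for n_phases in (1, 2):
                spec = cp.PhaseModelSpec(
                    n_phases=n_phases,
                    duration=config.simulation.duration,
                    n_trials=geometry.n_segments("total"),
                )
                candidates.append(
                    cp.fit_phase_model(
                        series, spec, settings,
                        seed=derive_seed(config.seed, f"fit:{group}:{n_phases}"),
                        name=f"{n_phases}-phase",
                    )
                )
            comparison = cp.compare_models(candidates, require_diagnostics=False)
            comparisons[group] = comparison
            fits[group] = candidates[comparison.selected_index]
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("changepoint", str(exc)) from exc

    arm_decisions: dict[str, fx.DecisionSeries] = {}
    calls: dict[str, PhenotypeCall] = {}
    try:
        rope = fx.RopeInterval(-0.18, 0.18, scale=config.effects.rope_scale)
        for group, scopes in neg.items():
            model = fx.fit_neg_effects(
                {"open": scopes["open"], "closed": scopes["closed"]},
                n_segments=geometry.n_segments("open"),
                structure="single-phase",
                basis_size=config.effects.basis_size,
                n_draws=config.effects.n_draws,
                seed=derive_seed(config.seed, f"effects:{group}"),
            )
            eff = fx.contrast_over_time(model, ("open", "closed"))
            arm_decisions[group] = fx.sexit(eff, rope, hdi_mass=config.effects.hdi_mass)
            open_final = float(np.mean([s.neg[-1] for s in scopes["open"]]))
            closed_final = float(np.mean([s.neg[-1] for s in scopes["closed"]]))
            calls[group] = classify(
                comparisons[group], arm_decisions[group], open_final, closed_final,
                total_fit=fits[group],
                open_floor=config.classification.open_floor,
                cutpoints=config.classification.cutpoints,
            )
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("effects", str(exc)) from exc

    # Artefacts ---------------------------------------------------------
    pd.concat([d.to_frame() for d in arm_decisions.values()]).to_csv(
        out / "arm_decisions.csv", index=False
    )
    comp_rows = [
        {"group": g, "selected": c.selected, "rationale": c.rationale,
         **{f"elpd_{n}": e for n, e in zip(c.names, c.elpd_loo)}}
        for g, c in comparisons.items()
    ]
    pd.DataFrame(comp_rows).to_csv(out / "model_comparison.csv", index=False)
    pd.DataFrame(
        [
            {"group": g, "label": c.label, "alb_grade": c.alb_grade, **c.evidence}
            for g, c in calls.items()
        ]
    ).to_csv(out / "calls.csv", index=False)
    metadata = {
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "stages": ["input", "neg", "changepoint", "effects", "classify"],
    }
    (out / "run.json").write_text(json.dumps(metadata, indent=2))
    return PipelineResult(neg, comparisons, arm_decisions, calls, metadata)
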