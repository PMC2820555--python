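"""Named in-silico experiments over the two-stage protocol.

Every published perturbation — conditional clv3 knockout/knockdown,
receptor backgrounds, graded CLV3 overexpression, WUS knockdowns, WUS
misexpression from the CLV3 promoter, laser ablation of the meristem
centre, facX variation, and the structural model variants (no WUS-to-facX
feedback, constant anchoring) — is encoded as a :class:`ScenarioRecipe`
that resolves to concrete stage-2 parameters, an optional tissue edit and a
machine-checkable expected-outcome descriptor.  The catalogue therefore
doubles as the regression suite for the model's qualitative claims.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence
import warnings

import numpy as np
import pandas as pd

from .domains import (DELTA_ST, DELTA_WUS, DomainLabeling, OutcomeReport,
                      check_outcome, label_domains, summarize_sweep)
from .geometry import MeristemGeometry, ablate
from .integrator import (DEFAULT_DT, STAGE1_DURATION, STAGE2_DURATION,
                         Trajectory, run_stage, two_stage_protocol)
from .model import (ModelParameters, ScenarioParameters, scenario_preset)

__all__ = [
    "ScenarioRecipe",
    "RunResult",
    "catalogue",
    "get_recipe",
    "run_scenario",
    "run_sweep",
    "SWEEP_GRID",
    "FACX_VARIATION_GRID",
]

#: endogenous-CLV3 effectiveness sweep: 10% to 620% in 10% steps
SWEEP_GRID = np.round(np.arange(0.1, 6.21, 0.1), 10)

#: facX basal-production multipliers explored by the facX-variation recipe
FACX_VARIATION_GRID = (0.5, 0.75, 1.0, 1.5, 2.0)


@dataclass(frozen=True)
class ScenarioRecipe:
    """A named, fully parameterized run recipe.

    ``kind`` is ``"two_stage"`` for a single perturb-and-relax experiment
    or ``"sweep"`` for a family of stage-2 runs over a knob grid.
    """

    name: str
    stage2: ScenarioParameters
    kind: str = "two_stage"
    ablation_rule: str | None = None        # "expressing_cells"
    expected_outcome: dict | None = None
    sweep_knob: str | None = None           # ScenarioParameters field or
                                            # "facx_basal" (ModelParameters)
    sweep_values: tuple = ()
    description: str = ""


@dataclass
class RunResult:
    recipe: ScenarioRecipe
    stage1: Trajectory
    stage2: Trajectory
    labelings: list[DomainLabeling]
    outcome: OutcomeReport | None
    geometry_stage2: MeristemGeometry


def catalogue() -> list[ScenarioRecipe]:
    """All published experiments as concrete recipes."""
    wt = scenario_preset("wild_type")
    recipes = [
        ScenarioRecipe(
            "wild_type", wt,
            expected_outcome={"kind": "wild_type_arrangement"},
            description="identity recipe: stage 2 re-runs the wild type"),
        ScenarioRecipe(
            "clv3_knockout", scenario_preset("clv3_knockout"),
            expected_outcome={"kind": "oc_expansion_tipward"},
            description="conditional clv3 loss of function: OC expands "
                        "and shifts towards the tip"),
        ScenarioRecipe(
            "clv3_knockdown_gradual", scenario_preset("clv3_knockdown_gradual"),
            expected_outcome={"kind": "oc_expansion_tipward"},
            description="CLV3 at 20% effectiveness: milder OC expansion"),
        ScenarioRecipe(
            "clv1_background", scenario_preset("clv1_background"),
            expected_outcome={"kind": "mild_derepression"},
            description="partial receptor background (c1_ko = 0.2): weak "
                        "derepression, domains at least wild-type sized"),
        ScenarioRecipe(
            "clv1_knockout", scenario_preset("clv1_knockout"),
            expected_outcome={"kind": "oc_expansion_tipward"},
            description="complete receptor loss: CLV3 no longer read"),
        ScenarioRecipe(
            "clv3_overexpression_low", scenario_preset("clv3_overexpression_low"),
            expected_outcome={"kind": "smaller_nonempty"},
            description="[CLV3_ext] = 0.7: new equilibrium with smaller "
                        "OC and SCD"),
        ScenarioRecipe(
            "clv3_overexpression_medium",
            scenario_preset("clv3_overexpression_medium"),
            expected_outcome={"kind": "collapse_recovery"},
            description="[CLV3_ext] = 1: transient stem-cell loss, then "
                        "recovery"),
        ScenarioRecipe(
            "clv3_overexpression_strong",
            scenario_preset("clv3_overexpression_strong"),
            expected_outcome={"kind": "collapse_no_recovery"},
            description="[CLV3_ext] = 1.5: permanent loss of OC and SCD"),
        ScenarioRecipe(
            "clv3_endogenous_sweep", wt, kind="sweep",
            sweep_knob="clv3_endogenous_scale",
            sweep_values=tuple(SWEEP_GRID),
            description="endogenous CLV3 effectiveness from 10% to 620% "
                        "in 10% steps"),
        ScenarioRecipe(
            "wus_knockdown_mild", scenario_preset("wus_knockdown_mild"),
            expected_outcome={"kind": "smaller_nonempty"},
            description="w_ko = 0.6"),
        ScenarioRecipe(
            "wus_knockdown_intermediate",
            scenario_preset("wus_knockdown_intermediate"),
            expected_outcome={"kind": "smaller_nonempty"},
            description="w_ko = 0.4"),
        ScenarioRecipe(
            "wus_knockout", scenario_preset("wus_knockout"),
            expected_outcome={"kind": "collapse_no_recovery"},
            description="w_ko = 0: loss of both domains"),
        ScenarioRecipe(
            "clv3_promoter_wus", scenario_preset("clv3_promoter_wus"),
            expected_outcome={"kind": "coalescence"},
            description="CLV3>>WUS: CLV3 action on WUS flipped from "
                        "repressive to activating; OC and SCD coalesce"),
        ScenarioRecipe(
            "laser_ablation", scenario_preset("laser_ablation"),
            ablation_rule="expressing_cells",
            expected_outcome={"kind": "regeneration"},
            description="remove all WUS- or CLV3-expressing cells at the "
                        "stage-1 equilibrium; domains partially regenerate"),
        ScenarioRecipe(
            "facx_variation", wt, kind="sweep",
            sweep_knob="facx_basal",
            sweep_values=FACX_VARIATION_GRID,
            description="vary the facX basal production rate"),
        ScenarioRecipe(
            "no_facx_feedback", scenario_preset("no_facx_feedback"),
            expected_outcome={"kind": "overproliferation"},
            description="drop the consumption of facX by WUS: the "
                        "meristem overproliferates"),
        ScenarioRecipe(
            "constant_anchoring", scenario_preset("constant_anchoring"),
            expected_outcome={"kind": "patterned"},
            description="tip-peaked anchoring replaced by a constant "
                        "rate: one OC + adjacent SCD at a noise-dependent "
                        "location"),
    ]
    return recipes


def get_recipe(name: str) -> ScenarioRecipe:
    for r in catalogue():
        if r.name == name:
            return r
    raise KeyError(f"unknown scenario {name!r}; valid: "
                   + ", ".join(r.name for r in catalogue()))


def _resolve_descriptor(recipe: ScenarioRecipe,
                        wt_label: DomainLabeling,
                        geometry: MeristemGeometry) -> dict | None:
    if recipe.expected_outcome is None:
        return None
    desc = dict(recipe.expected_outcome)
    desc.setdefault("wt_oc_count", wt_label.oc_count)
    desc.setdefault("wt_scd_count", wt_label.scd_count)
    desc.setdefault("wt_oc_tip_distance", wt_label.oc_tip_distance)
    desc.setdefault("wt_stemness_total", wt_label.stemness_total)
    desc.setdefault("wt_wus_total", wt_label.wus_total)
    desc.setdefault("n_competent", int(geometry.competent.sum()))
    desc.setdefault("n_cells", geometry.n_cells)
    return desc


def run_scenario(recipe: ScenarioRecipe,
                 geometry: MeristemGeometry,
                 params: ModelParameters,
                 seed: int = 0,
                 dt: float = DEFAULT_DT,
                 durations: tuple[float, float] = (STAGE1_DURATION,
                                                   STAGE2_DURATION),
                 delta_st: float = DELTA_ST,
                 delta_wus: float = DELTA_WUS,
                 snapshot_every: int = 500,
                 **stage_kwargs) -> RunResult:
    """Execute a two-stage recipe and label domains at every snapshot.

    Snapshots default to a dense cadence (every 500 steps) so transient
    features — e.g. the rapid stemness dip after CLV3 overexpression —
    are resolved by the labeling time series.

    Discretization thresholds are always relative to a wild-type stage-1
    equilibrium on the intact tissue.  For ordinary perturbations that is
    the recipe's own stage 1; structural variants (no facX feedback,
    constant anchoring) additionally run a plain wild-type stage 1 to
    provide the reference concentrations.
    """
    if recipe.kind != "two_stage":
        raise ValueError(f"recipe {recipe.name!r} is a sweep; "
                         "use run_sweep instead")
    stage_kwargs.setdefault("snapshot_every", snapshot_every)

    if recipe.ablation_rule is None:
        traj1, traj2 = two_stage_protocol(
            geometry, params, recipe.stage2, durations=durations, dt=dt,
            seed=seed, **stage_kwargs)
        geom1 = geom2 = _stage_geometry(geometry, params, recipe.stage2)
        reference = traj1.final_state
        wt_reference = reference
        wt_geom = geom1
        if (not recipe.stage2.facx_feedback_enabled
                or recipe.stage2.anchoring_mode == "constant"):
            # structural variants never run a wild-type stage 1, but the
            # discretization thresholds are defined relative to wild-type
            # concentrations, so compute the true wild-type equilibrium
            wt_traj, _ = _stage1_only(geometry, params,
                                      ScenarioParameters(), dt,
                                      durations[0], seed, **stage_kwargs)
            wt_reference = wt_traj.final_state
            wt_geom = _stage_geometry(geometry, params,
                                      ScenarioParameters())
            reference = wt_reference
    else:
        # equilibrate, pick the expressing cells, then integrate stage 2
        # on the edited tissue from the restricted equilibrium state
        traj1, noise = _stage1_only(geometry, params, recipe.stage2, dt,
                                    durations[0], seed, **stage_kwargs)
        geom1 = _stage_geometry(geometry, params, recipe.stage2)
        ref_label = label_domains(traj1.final_state, traj1.final_state,
                                  delta_st, delta_wus, geom1)
        remove = np.union1d(ref_label.oc_cells, ref_label.scd_cells)
        if remove.size == 0:
            warnings.warn("ablation selected no cells; tissue unchanged",
                          RuntimeWarning)
            keep = np.arange(geom1.n_cells)
            geom2 = geom1
        else:
            geom2 = ablate(geom1, remove)
            keep = np.setdiff1d(np.arange(geom1.n_cells), remove)
        traj2 = run_stage(traj1.final_state[:, keep].copy(), durations[1],
                          dt, params, recipe.stage2, geom2, noise[keep],
                          stage="stage2", **stage_kwargs)
        # thresholds stay relative to the intact wild-type equilibrium
        reference = traj1.final_state
        wt_reference = traj1.final_state
        wt_geom = geom1

    wt_label = label_domains(wt_reference, wt_reference,
                             delta_st, delta_wus, wt_geom)
    labelings = [label_domains(snap, reference, delta_st, delta_wus,
                               geom2, time=t)
                 for t, snap in zip(traj2.times, traj2.snapshots)]
    desc = _resolve_descriptor(recipe, wt_label, geom2)
    outcome = check_outcome(desc, labelings) if desc else None
    return RunResult(recipe=recipe, stage1=traj1, stage2=traj2,
                     labelings=labelings, outcome=outcome,
                     geometry_stage2=geom2)


def _stage_geometry(geometry, params, scenario):
    from .integrator import _apply_anchoring_mode
    return _apply_anchoring_mode(geometry, params, scenario)


def _stage1_only(geometry, params, scenario_stage2, dt, duration, seed,
                 **stage_kwargs):
    from .integrator import initial_state
    from .model import sample_anchoring_noise
    scenario1 = ScenarioParameters(
        facx_feedback_enabled=scenario_stage2.facx_feedback_enabled,
        anchoring_mode=scenario_stage2.anchoring_mode)
    geom1 = _stage_geometry(geometry, params, scenario1)
    noise = sample_anchoring_noise(geom1, params.noise_amplitude, seed)
    traj1 = run_stage(initial_state(geom1), duration, dt, params, scenario1,
                      geom1, noise, stage="stage1", **stage_kwargs)
    return traj1, noise


def run_sweep(recipe: ScenarioRecipe,
              geometry: MeristemGeometry,
              params: ModelParameters,
              seed: int = 0,
              dt: float = DEFAULT_DT,
              durations: tuple[float, float] = (STAGE1_DURATION,
                                                STAGE2_DURATION),
              delta_st: float = DELTA_ST,
              delta_wus: float = DELTA_WUS,
              values: Sequence[float] | None = None,
              **stage_kwargs) -> pd.DataFrame:
    """Run a sweep recipe: one shared stage 1, one stage 2 per grid point.

    The per-point runs are independent; results are returned as the
    response table of :func:`samsim.domains.summarize_sweep`.
    """
    if recipe.kind != "sweep":
        raise ValueError(f"recipe {recipe.name!r} is not a sweep")
    values = list(values if values is not None else recipe.sweep_values)
    traj1, noise = _stage1_only(geometry, params, recipe.stage2, dt,
                                durations[0], seed, **stage_kwargs)
    geom = _stage_geometry(geometry, params, recipe.stage2)
    reference = traj1.final_state
    labelings = []
    for v in values:
        if recipe.sweep_knob in ScenarioParameters.__dataclass_fields__:
            scen = replace(recipe.stage2, **{recipe.sweep_knob: float(v)})
            p = params
        elif recipe.sweep_knob in ModelParameters.__dataclass_fields__:
            scen = recipe.stage2
            base = getattr(params, recipe.sweep_knob)
            p = replace(params, **{recipe.sweep_knob: float(v) * base})
        else:
            raise ValueError(f"unknown sweep knob {recipe.sweep_knob!r}")
        traj2 = run_stage(reference.copy(), durations[1], dt, p, scen,
                          geom, noise, stage="stage2", **stage_kwargs)
        labelings.append(label_domains(traj2.final_state, reference,
                                       delta_st, delta_wus, geom,
                                       time=traj2.final_time))
    return summarize_sweep(values, labelings)
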