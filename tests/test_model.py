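"""Reaction kinetics: parameters, presets and the right-hand side."""

import dataclasses

import numpy as np
import pytest

import samsim as s
from samsim.model import (CLV3, FACX, SIGNAL, STEMNESS, WUS, ACTIVATION_CAP,
                          ModelParameters, ScenarioParameters, reaction_rhs)
from samsim.fixtures import single_cell_geometry


def test_dataclass_defaults_match_canonical_file(params):
    """The packaged parameter file is the single source of defaults."""
    assert params == ModelParameters()
    table = s.canonical_parameter_table()["parameters"]
    flat = {k: v["value"] for k, v in table.items()}
    anchor = params.anchoring
    for key in ("peak", "width", "floor", "mode", "constant_value"):
        assert flat.pop(key) == getattr(anchor, key)
    for key, value in flat.items():
        assert getattr(params, key) == value


def test_parameter_validation():
    with pytest.raises(ValueError):
        ModelParameters(deg_wus=-1)
    with pytest.raises(ValueError):
        ModelParameters(stemness_hill=0.5)
    with pytest.raises(ValueError):
        ModelParameters(diff_wus=0.5)  # leakage above free diffusion


@pytest.mark.parametrize("name, expected", [
    ("wild_type", {"clv3_exogenous": 0.0, "clv3_endogenous_scale": 1.0}),
    ("laser_ablation", {"clv3_exogenous": 0.0, "clv3_endogenous_scale": 1.0}),
    ("clv3_overexpression_medium", {"clv3_exogenous": 1.0,
                                    "clv3_endogenous_scale": 1.0}),
    ("clv3_overexpression_strong", {"clv3_exogenous": 1.5}),
    ("clv3_overexpression_low", {"clv3_exogenous": 0.7}),
    ("clv3_knockout", {"clv3_exogenous": 0.0, "clv3_endogenous_scale": 0.0}),
    ("clv3_knockdown_gradual", {"clv3_endogenous_scale": 0.2}),
    ("clv1_background", {"receptor_background": 0.2}),
    ("wus_knockdown_mild", {"wus_scale": 0.6}),
    ("wus_knockdown_intermediate", {"wus_scale": 0.4}),
    ("wus_knockout", {"wus_scale": 0.0}),
    ("clv3_promoter_wus", {"clv3_effect_sign": "activating"}),
    ("no_facx_feedback", {"facx_feedback_enabled": False}),
    ("constant_anchoring", {"anchoring_mode": "constant"}),
])
def test_scenario_presets_published_values(name, expected):
    preset = s.scenario_preset(name)
    for key, value in expected.items():
        assert getattr(preset, key) == value


def test_unknown_preset_lists_valid_names():
    with pytest.raises(KeyError, match="wild_type"):
        s.scenario_preset("banana")


def _single_cell(params=None, **kw):
    g = single_cell_geometry(**kw)
    return g, np.zeros(1)


def test_zero_state_zero_basal_is_fixed_point(params):
    g, noise = _single_cell(anchoring=0.01)
    p = dataclasses.replace(params, facx_basal=0.0)
    state = np.zeros((5, 1))
    rhs = reaction_rhs(state, p, ScenarioParameters(), g, noise)
    assert np.all(rhs == 0.0)


def test_noncompetent_cell_never_gains_stemness(params):
    g, noise = _single_cell(competent=False, anchoring=0.01)
    state = np.zeros((5, 1))
    state[SIGNAL] = 50.0   # far above the stemness threshold
    rhs = reaction_rhs(state, params, ScenarioParameters(), g, noise)
    assert rhs[STEMNESS][0] == 0.0
    state[STEMNESS] = 2.0
    rhs = reaction_rhs(state, params, ScenarioParameters(), g, noise)
    assert rhs[STEMNESS][0] == pytest.approx(-params.deg_stemness * 2.0)


def test_single_cell_rhs_matches_hand_evaluation(params):
    """Independent transcription of the kinetics at one arbitrary state."""
    rho = 0.009
    g, _ = _single_cell(anchoring=rho)
    noise = np.array([0.0004])
    u, x, y, st, c = 1.3, 2.1, 0.8, 0.4, 0.9
    state = np.array([[u], [x], [y], [st], [c]])
    sc = ScenarioParameters(clv3_exogenous=0.2, clv3_endogenous_scale=1.4,
                            receptor_background=0.25, wus_scale=0.8)
    p = params

    r_eff = rho + 0.0004
    conv_shape = u**2 / (1 + p.wus_saturation * u**2) + p.wus_basal
    c_seen = (1 - 0.25) * c
    resp = 1.0 / (1.0 + (p.clv3_inhibition * c_seen)**p.clv3_inhibition_hill)
    conv = 0.8 * r_eff * x * conv_shape * resp
    hill = y**p.stemness_hill / (p.stemness_threshold**p.stemness_hill
                                 + y**p.stemness_hill)
    expected = np.array([
        conv - p.deg_wus * u,
        p.facx_basal - conv - p.deg_facx * x,
        p.signal_production * u - p.deg_signal * y,
        p.stemness_production * hill - p.deg_stemness * st,
        1.4 * p.clv3_production * st + p.deg_clv3 * 0.2 - p.deg_clv3 * c,
    ])
    rhs = reaction_rhs(state, p, sc, g, noise)
    assert np.allclose(rhs.ravel(), expected, rtol=1e-12, atol=0)


def test_activating_response_exceeds_one_and_saturates(params):
    g, noise = _single_cell(anchoring=0.01)
    state = np.array([[1.0], [1.0], [0.0], [0.0], [3.0]])
    rep = reaction_rhs(state, params, ScenarioParameters(), g, noise)
    act = reaction_rhs(state, params,
                       ScenarioParameters(clv3_effect_sign="activating"),
                       g, noise)
    assert act[WUS][0] > rep[WUS][0]
    # the activating boost is bounded by the saturation ceiling
    state_hi = np.array([[1.0], [1.0], [0.0], [0.0], [1000.0]])
    act_hi = reaction_rhs(state_hi, params,
                          ScenarioParameters(clv3_effect_sign="activating"),
                          g, noise)
    neutral = reaction_rhs(np.array([[1.0], [1.0], [0.0], [0.0], [0.0]]),
                           params, ScenarioParameters(), g, noise)
    boost = (act_hi[WUS][0] + params.deg_wus) / (neutral[WUS][0]
                                                 + params.deg_wus)
    assert boost <= 1 + ACTIVATION_CAP + 1e-9


def test_rhs_is_cell_local(toy, params):
    rng = np.random.default_rng(0)
    state = rng.uniform(0.1, 2.0, size=(5, toy.n_cells))
    noise = s.sample_anchoring_noise(toy, params.noise_amplitude, 3)
    base = reaction_rhs(state, params, ScenarioParameters(), toy, noise)
    bumped = state.copy()
    bumped[:, 4] *= 1.7
    after = reaction_rhs(bumped, params, ScenarioParameters(), toy, noise)
    mask = np.ones(toy.n_cells, dtype=bool)
    mask[4] = False
    assert np.array_equal(base[:, mask], after[:, mask])
    assert not np.array_equal(base[:, 4], after[:, 4])


def test_endogenous_scale_acts_linearly_on_clv3_production(params):
    g, noise = _single_cell(anchoring=0.01)
    state = np.array([[0.0], [0.0], [0.0], [0.7], [0.0]])
    r1 = reaction_rhs(state, params,
                      ScenarioParameters(clv3_endogenous_scale=1.0), g, noise)
    r3 = reaction_rhs(state, params,
                      ScenarioParameters(clv3_endogenous_scale=3.0), g, noise)
    assert r3[CLV3][0] == pytest.approx(3 * r1[CLV3][0])


def test_negative_concentration_rejected(params):
    g, noise = _single_cell()
    state = np.zeros((5, 1))
    state[WUS] = -1e-9
    with pytest.raises(ValueError, match="negative"):
        reaction_rhs(state, params, ScenarioParameters(), g, noise)


def test_parameter_file_loading(tmp_path, params):
    cfg = tmp_path / "p.yaml"
    cfg.write_text("deg_wus: 0.02\npeak: 0.02\n")
    p = s.load_parameters(cfg)
    assert p.deg_wus == 0.02
    assert p.anchoring.peak == 0.02
    assert p.deg_clv3 == params.deg_clv3  # untouched default
    cfg.write_text("not_a_parameter: 1\n")
    with pytest.raises(ValueError, match="unknown parameter"):
        s.load_parameters(cfg)
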