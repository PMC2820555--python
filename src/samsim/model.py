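"""Reaction kinetics of the coupled WUS/facX and WUS-signal/stemness/CLV3
feedback systems.

Five dimensionless species live on every cell of the tessellation:

``[WUS]``
    immobile (leakage-diffusion only) transcription factor of the
    organizing centre; autocatalytic, fuelled by facX, repressed by CLV3.
``[facX]``
    freely diffusing substrate that activates WUS and is consumed by it —
    together with WUS an activator–depleted-substrate (Turing) pair.
``[signal]``
    diffusible WUS-dependent signal produced proportionally to WUS.
``[stemness]``
    cell-state variable; steep sigmoidal (high Hill coefficient) response
    to the WUS signal, restricted to competent outer-layer cells.
``[CLV3]``
    diffusible peptide produced proportionally to stemness; represses WUS
    production, closing the long-range negative feedback loop.

Per-cell reaction terms (diffusion is handled by the integrator)::

    C(c)       = w_ko * rho(c) * [facX] * A([WUS]) * R([CLV3])
    d[WUS]/dt  = C(c) - d_w [WUS]
    d[facX]/dt = sigma_x - C(c) - d_x [facX]
    d[sig]/dt  = k_y [WUS] - d_y [sig]
    d[st]/dt   = I(c) * k_s * H([sig]) - d_s [st]
    d[CLV3]/dt = k_ko * k_c [st] + d_c [CLV3_ext] - d_c [CLV3]

Here ``A(u) = u^2 / (1 + kappa u^2) + b_w`` is the saturating WUS
autocatalysis (``b_w`` a small basal conversion that lets WUS ignite from
near-zero concentrations), ``R(c) = 1 / (1 + (k_r c')^m_r)`` with
``c' = (1 - c1_ko) c`` the sharply cooperative CLV3 response (the
activating variant for WUS misexpression from the CLV3 promoter uses a
saturating ``R = 1 + E/(1 + E/E_max)`` instead), and
``H(y) = y^n / (K^n + y^n)`` the stemness switch with a large Hill
exponent ``n``.

``C`` is the conversion of the substrate facX into WUS activity; CLV3
signalling gates this conversion, so repression slows both WUS production
and facX consumption — the substrate pool then buffers WUS against
perturbations, which is the slow compensation the circuit is built
around.

``rho(c)`` is the tip-peaked anchoring field carried by the geometry,
perturbed once per cell by a small frozen uniform random value — the
symmetry-breaking heterogeneity the patterning subsystem needs.  The
default constants, with their documentation, live in the canonical
parameter file ``data/parameters.yaml``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping

import numpy as np
import yaml

from .geometry import AnchoringParams, MeristemGeometry

__all__ = [
    "SPECIES",
    "WUS", "FACX", "SIGNAL", "STEMNESS", "CLV3",
    "ModelParameters",
    "ScenarioParameters",
    "scenario_preset",
    "preset_names",
    "reaction_rhs",
    "sample_anchoring_noise",
    "wus_facx_dispersion",
    "canonical_parameter_table",
    "parameters_from_mapping",
    "load_parameters",
]

SPECIES = ("wus", "facx", "signal", "stemness", "clv3")
WUS, FACX, SIGNAL, STEMNESS, CLV3 = range(5)

#: ceiling on the activating CLV3 response (WUS misexpression variant)
ACTIVATION_CAP = 20.0


# ----------------------------------------------------------------------
# Parameters
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class ModelParameters:
    """Kinetic constants of the model (all dimensionless).

    Defaults are the calibrated wild-type set; see ``data/parameters.yaml``
    for the symbol-by-symbol documentation of every value.
    """

    # anchoring field (spatially varying WUS/facX reaction rate) + noise
    anchoring: AnchoringParams = field(default_factory=AnchoringParams)
    noise_amplitude: float = 0.002

    # WUS / facX activator-substrate pair
    wus_basal: float = 0.004           # b_w  basal autocatalysis offset
    wus_saturation: float = 0.15       # kappa
    clv3_inhibition: float = 0.74      # k_r  inverse CLV3 threshold
    clv3_inhibition_hill: float = 16.0 # m_r  steepness of the CLV3 response
    facx_basal: float = 0.02           # sigma_x

    # signal / stemness / CLV3 chain
    signal_production: float = 0.05   # k_y
    stemness_production: float = 0.05 # k_s
    stemness_threshold: float = 1.6   # K
    stemness_hill: float = 10.0       # n
    clv3_production: float = 0.2      # k_c

    # degradation rates (one per species); facX turns over slowly and so
    # acts as the buffering reservoir of the circuit
    deg_wus: float = 0.01
    deg_facx: float = 0.001
    deg_signal: float = 0.05
    deg_stemness: float = 0.05
    deg_clv3: float = 0.05

    # diffusion rates; WUS and stemness only leak weakly
    diff_wus: float = 0.002
    diff_facx: float = 0.2
    diff_signal: float = 0.2
    diff_stemness: float = 0.0002
    diff_clv3: float = 0.02

    def __post_init__(self) -> None:
        for name in self.__dataclass_fields__:
            if name == "anchoring":
                continue
            if getattr(self, name) < 0:
                raise ValueError(f"parameter {name} must be nonnegative")
        if self.stemness_hill < 1:
            raise ValueError("Hill exponent must be >= 1")
        free = min(self.diff_facx, self.diff_signal, self.diff_clv3)
        if not (self.diff_wus < free and self.diff_stemness < free):
            raise ValueError(
                "WUS/stemness leakage diffusion must be below free diffusion")

    def diffusion_rates(self) -> np.ndarray:
        return np.array([self.diff_wus, self.diff_facx, self.diff_signal,
                         self.diff_stemness, self.diff_clv3])

    def degradation_rates(self) -> np.ndarray:
        return np.array([self.deg_wus, self.deg_facx, self.deg_signal,
                         self.deg_stemness, self.deg_clv3])


@dataclass(frozen=True)
class ScenarioParameters:
    """Scenario knobs accommodating the modelled mutants and experiments.

    ``clv3_exogenous``
        constitutive uniform exogenous CLV3 level [CLV3_ext] maintained in
        every cell (0 = wild type).
    ``clv3_endogenous_scale``
        multiplier k_ko on stemness-driven CLV3 production (1 = wild type,
        0 = knockout, >1 = endogenous overexpression).
    ``receptor_background``
        c1_ko-style attenuation of CLV3 action on WUS: 0 = full wild-type
        signalling, 1 = complete receptor loss.
    ``wus_scale``
        multiplier w_ko on WUS production (graded knockdowns).
    ``clv3_effect_sign``
        "repressive" (wild type) or "activating" (WUS expressed from the
        CLV3 promoter).
    ``facx_feedback_enabled``
        keep/drop the consumption of facX by WUS (structural variant).
    ``anchoring_mode``
        "distribution" (tip-peaked) or "constant" (no positional bias).
    """

    clv3_exogenous: float = 0.0
    clv3_endogenous_scale: float = 1.0
    receptor_background: float = 0.0
    wus_scale: float = 1.0
    clv3_effect_sign: str = "repressive"
    facx_feedback_enabled: bool = True
    anchoring_mode: str = "distribution"

    def __post_init__(self) -> None:
        for name in ("clv3_exogenous", "clv3_endogenous_scale",
                     "receptor_background", "wus_scale"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.clv3_effect_sign not in ("repressive", "activating"):
            raise ValueError("clv3_effect_sign must be repressive|activating")
        if self.anchoring_mode not in ("distribution", "constant"):
            raise ValueError("anchoring_mode must be distribution|constant")


_PRESETS: dict[str, dict] = {
    "wild_type": {},
    "laser_ablation": {},
    "clv3_knockout": {"clv3_exogenous": 0.0, "clv3_endogenous_scale": 0.0},
    "clv3_knockdown_gradual": {"clv3_endogenous_scale": 0.2},
    "clv1_background": {"receptor_background": 0.2},
    "clv1_knockout": {"receptor_background": 1.0},
    "clv3_overexpression_low": {"clv3_exogenous": 0.7},
    "clv3_overexpression_medium": {"clv3_exogenous": 1.0},
    "clv3_overexpression_strong": {"clv3_exogenous": 1.5},
    "wus_knockdown_mild": {"wus_scale": 0.6},
    "wus_knockdown_intermediate": {"wus_scale": 0.4},
    "wus_knockout": {"wus_scale": 0.0},
    "clv3_promoter_wus": {"clv3_effect_sign": "activating"},
    "no_facx_feedback": {"facx_feedback_enabled": False},
    "constant_anchoring": {"anchoring_mode": "constant"},
}


def preset_names() -> list[str]:
    return sorted(_PRESETS)


def scenario_preset(name: str) -> ScenarioParameters:
    """Return the published knob settings for a named scenario."""
    try:
        return ScenarioParameters(**_PRESETS[name])
    except KeyError:
        raise KeyError(
            f"unknown scenario {name!r}; valid presets: "
            + ", ".join(preset_names())) from None


# ----------------------------------------------------------------------
# Reaction right-hand side
# ----------------------------------------------------------------------

def sample_anchoring_noise(geometry: MeristemGeometry,
                           amplitude: float, seed: int) -> np.ndarray:
    """Frozen per-cell uniform perturbation xi ~ U[-amplitude, +amplitude].

    Sampled once at initialization; the same field is reused for the whole
    run, which keeps trajectories deterministic while still breaking the
    symmetry the activator-substrate pair needs to pattern.
    """
    rng = np.random.default_rng(seed)
    return rng.uniform(-amplitude, amplitude, size=geometry.n_cells)


def reaction_rhs(state: np.ndarray,
                 params: ModelParameters,
                 scenario: ScenarioParameters,
                 geometry: MeristemGeometry,
                 noise: np.ndarray) -> np.ndarray:
    """Cell-local reaction derivatives (no diffusion), shape ``(5, n)``.

    ``state`` holds one row per species in :data:`SPECIES` order.  Negative
    input concentrations are rejected: they indicate an integrator bug, not
    a model state.
    """
    if state.shape != (len(SPECIES), geometry.n_cells):
        raise ValueError("state shape does not match geometry")
    if np.any(state < 0):
        raise ValueError("negative concentration passed to reaction_rhs")
    if noise.shape != (geometry.n_cells,):
        raise ValueError("noise must provide one sample per cell")

    u, s, y, st, c = state
    p, sc = params, scenario

    rho = np.clip(geometry.anchoring + noise, 0.0, None)
    auto = u * u / (1.0 + p.wus_saturation * u * u) + p.wus_basal

    c_seen = (1.0 - min(sc.receptor_background, 1.0)) * c
    eff = (p.clv3_inhibition * c_seen) ** p.clv3_inhibition_hill
    if sc.clv3_effect_sign == "repressive":
        response = 1.0 / (1.0 + eff)
    else:
        # activating variant saturates: the conversion machinery has a
        # finite maximal stimulation, which also keeps the explicit
        # reaction step well-conditioned
        response = 1.0 + eff / (1.0 + eff / ACTIVATION_CAP)

    # CLV3 gates the facX->WUS conversion itself, so repression slows the
    # consumption of the substrate along with the production of WUS
    conversion = sc.wus_scale * rho * s * auto * response

    out = np.empty_like(state)
    out[WUS] = conversion - p.deg_wus * u
    out[FACX] = p.facx_basal - p.deg_facx * s
    if sc.facx_feedback_enabled:
        out[FACX] -= conversion
    out[SIGNAL] = p.signal_production * u - p.deg_signal * y
    hill = y ** p.stemness_hill
    sig = hill / (p.stemness_threshold ** p.stemness_hill + hill)
    out[STEMNESS] = (geometry.competent * p.stemness_production * sig
                     - p.deg_stemness * st)
    out[CLV3] = (sc.clv3_endogenous_scale * p.clv3_production * st
                 + p.deg_clv3 * sc.clv3_exogenous - p.deg_clv3 * c)
    return out


# ----------------------------------------------------------------------
# Linear stability of the WUS/facX pair (Turing capability)
# ----------------------------------------------------------------------

def wus_facx_dispersion(params: ModelParameters,
                        geometry: MeristemGeometry,
                        rho_const: float | None = None):
    """Dispersion relation of the isolated WUS/facX pair on the cell graph.

    With a spatially constant conversion rate ``rho`` (default: the
    anchoring parameters' constant value), no CLV3 and competence switched
    off, the pair has a homogeneous steady state ``(u*, s*)``.  For every
    eigenvalue ``lambda_k <= 0`` of the graph Laplacian the linear growth
    rate is the largest real part of the eigenvalues of
    ``J + diag(D_w, D_x) * lambda_k``.  A positive band away from the
    uniform mode is the patterning (Turing) capability of the pair.

    Returns ``(laplacian_eigenvalues, growth_rates, (u_star, s_star))``.
    """
    from scipy.optimize import brentq
    from scipy.sparse.csgraph import laplacian as _csgraph_laplacian

    p = params
    rho = float(rho_const if rho_const is not None
                else p.anchoring.constant_value)

    def conv_shape(u):
        return u * u / (1.0 + p.wus_saturation * u * u) + p.wus_basal

    def s_of_u(u):
        return p.facx_basal / (p.deg_facx + rho * conv_shape(u))

    def f(u):
        return rho * s_of_u(u) * conv_shape(u) - p.deg_wus * u

    # lowest positive root: the homogeneous state reached from near-zero
    # concentrations, whose instability ignites the pattern
    grid = np.logspace(-6, 3, 400)
    u_star = None
    prev_u, prev_f = grid[0], f(grid[0])
    for u in grid[1:]:
        fu = f(u)
        if prev_f > 0 and fu <= 0:
            u_star = brentq(f, prev_u, u)
            break
        prev_u, prev_f = u, fu
    if u_star is None:
        raise RuntimeError("no homogeneous steady state found")
    s_star = s_of_u(u_star)

    du = 1e-7 * max(u_star, 1.0)
    dA = (conv_shape(u_star + du) - conv_shape(u_star - du)) / (2 * du)
    j11 = rho * s_star * dA - p.deg_wus
    j12 = rho * conv_shape(u_star)
    j21 = -rho * s_star * dA
    j22 = -rho * conv_shape(u_star) - p.deg_facx

    adj = geometry.adjacency_matrix().toarray()
    lam = np.linalg.eigvalsh(-(_csgraph_laplacian(adj)))
    lam = np.sort(lam)[::-1]  # 0 first, increasingly negative
    growth = np.empty_like(lam)
    for i, lk in enumerate(lam):
        jac = np.array([[j11 + p.diff_wus * lk, j12],
                        [j21, j22 + p.diff_facx * lk]])
        growth[i] = np.max(np.linalg.eigvals(jac).real)
    return lam, growth, (u_star, s_star)


# ----------------------------------------------------------------------
# Canonical parameter file
# ----------------------------------------------------------------------

def canonical_parameter_table() -> dict:
    """Parsed contents of the canonical parameter file shipped with the
    package (symbol, value and role of every model constant)."""
    text = resources.files("samsim").joinpath("data/parameters.yaml")
    return yaml.safe_load(text.read_text())


def parameters_from_mapping(mapping: Mapping) -> ModelParameters:
    """Build :class:`ModelParameters` from a flat ``key: value`` mapping
    (e.g. a parsed plain-text config); unknown keys are rejected."""
    mapping = dict(mapping)
    anchor_keys = {f.name for f in
                   AnchoringParams.__dataclass_fields__.values()}
    anchoring = {k: mapping.pop(k) for k in list(mapping)
                 if k in anchor_keys}
    known = set(ModelParameters.__dataclass_fields__) - {"anchoring"}
    unknown = set(mapping) - known
    if unknown:
        raise ValueError(f"unknown parameter keys: {sorted(unknown)}")
    kwargs = dict(mapping)
    if anchoring:
        kwargs["anchoring"] = AnchoringParams(**anchoring)
    return ModelParameters(**kwargs)


def load_parameters(path: str | Path | None = None) -> ModelParameters:
    """Load parameters from a YAML config, or the packaged defaults."""
    if path is None:
        table = canonical_parameter_table()
        flat = {name: entry["value"]
                for name, entry in table["parameters"].items()}
        return parameters_from_mapping(flat)
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return parameters_from_mapping(data)
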