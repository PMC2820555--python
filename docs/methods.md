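# Methods

## The model

`samsim` simulates stem-cell homeostasis in the *Arabidopsis* shoot apical
meristem (SAM) as a reaction–diffusion system on a static cellular
tessellation. Two coupled feedback circuits merge on the regulation of the
homeodomain factor WUSCHEL (WUS):

1. **WUS/facX — an activator–substrate pair.** WUS is autocatalytic and is
   produced by converting a hypothetical diffusible substrate, *facX*,
   which WUS itself consumes. This is the classic activator–depleted-
   substrate (Turing) mechanism; it creates a single, mobile, spatially
   confined WUS spot — the organizing centre (OC).
2. **WUS-signal/stemness/CLV3 — the CLAVATA loop.** WUS drives a mobile
   signal; outer-layer (competent) cells respond to that signal with a
   steep sigmoidal *stemness* state; stem cells secrete CLV3, which
   diffuses and represses WUS. This loop positions the stem cell domain
   (SCD) above the OC and keeps both domains in check.

Per cell `c` with concentrations `u = [WUS]`, `x = [facX]`,
`y = [signal]`, `st = [stemness]`, `v = [CLV3]`:

```
C       = w_ko · (ρ(c) + ξ(c)) · x · A(u) · R(v)        # facX→WUS conversion
du/dt   = C            − d_w u   + D_w Δu
dx/dt   = σ_x − C      − d_x x   + D_x Δx
dy/dt   = k_y u        − d_y y   + D_y Δy
dst/dt  = I(c) k_s H(y) − d_s st + D_s Δst
dv/dt   = k_ko k_c st + d_c·[CLV3_ext] − d_c v + D_c Δv
```

with

- `A(u) = u²/(1 + κu²) + b_w` — saturating autocatalysis with a small
  basal conversion `b_w` that lets WUS ignite from near-zero levels;
- `R(v) = 1/(1 + (k_r (1 − c1_ko) v)^m_r)` — a sharply cooperative
  (high-Hill) CLV3 response. In the misexpression variant
  (*CLV3≫WUS*) the same input acts positively,
  `R = 1 + E/(1 + E/E_max)` with `E = (k_r v')^m_r` capped at
  `E_max = 20`;
- `H(y) = y^n/(K^n + y^n)` — the stemness switch, `n = 10` for a sharp
  stem-cell/non-stem-cell transition;
- `I(c) ∈ {0,1}` — competence, 1 only in the outermost two cell layers;
- `Δ` — the unweighted graph Laplacian on the cell adjacency
  (`(Δu)(c) = Σ_{n∈N(c)} u(n) − u(c)`), which realizes zero-flux
  boundaries automatically because rim cells simply have fewer
  neighbours;
- `ρ(c)` — the *anchoring* field: a tip-peaked Gaussian profile in
  geodesic (hop) distance from the apex cell, providing the positional
  bias that pins the pattern to the tip; `ξ(c)` is a frozen per-cell
  uniform perturbation on `[−ε, +ε]`, sampled once per run from the run
  seed, which breaks the symmetry the pair needs to pattern.

Two modelling decisions deserve emphasis because they shape most of the
behaviour:

- **CLV3 gates the conversion, not just WUS output.** The repressive
  response multiplies the whole `facX→WUS` conversion term, so repressed
  cells also stop draining the substrate. The slowly turning-over facX
  pool (`d_x = 0.001`, time constant 1000 units — an order of magnitude
  slower than every other species) then acts as a compensatory buffer:
  when WUS is suppressed, substrate accumulates and later re-ignites or
  re-amplifies the OC. This reproduces the recovery after intermediate
  CLV3 overexpression and the robustness of the OC against changes in
  endogenous CLV3 levels. With repression applied to WUS production only,
  a repressed OC wastes substrate and no recovery regime exists.
- **The CLV3 response is a threshold, not a gradient.** `m_r = 16` with
  threshold `1/k_r ≈ 1.35` splits the tissue into a crushed zone (the SCD
  and its immediate surroundings, CLV3 ≈ 2–4) and an untouched zone (the
  OC, local CLV3 ≈ 0.3–0.6). This produces the wild-type separation of
  domains, the near-invariance of the OC under the endogenous-CLV3 sweep,
  and the qualitative difference between exogenous CLV3 at 0.7 / 1.0 /
  1.5: the three levels fall below, near, and beyond the threshold once
  endogenous CLV3 has collapsed.

### Scenario semantics

Scenario knobs follow the published catalogue: `k_ko` scales endogenous
(stemness-driven) CLV3 production (1 wild type, 0 knockout, >1
overexpression); `[CLV3_ext]` is a constitutive uniform exogenous CLV3
level, implemented as the production term `d_c·[CLV3_ext]` so its uniform
steady-state contribution equals the quoted level and it is sensed by the
same repressive response as endogenous CLV3; `c1_ko` attenuates CLV3's
action (`0` wild type, `1` complete receptor loss); `w_ko` scales the
conversion (WUS knockdowns); the sign flip models WUS expressed from the
CLV3 promoter; structural variants drop the facX feedback term or replace
the anchoring distribution by a constant rate.

## Geometry

The tissue is an artificial longitudinal section through the SAM dome:
seven concentric semicircular layers of cells at unit spacing (radius 7
to 1), 95 cells by default, with a small seeded jitter to remove
co-circular degeneracies. Cell walls come from the Voronoi decomposition
of the centres; adjacency = shared Voronoi wall, pruned of walls longer
than 2.5 cell spacings (unbounded rim regions otherwise meet far outside
the tissue and would link distant base cells). Cell volumes and wall
lengths are deliberately ignored (unweighted Laplacian): on a Voronoi
tessellation of roughly evenly spaced centres they approximately even
out, and only qualitative behaviour is sought. Competence marks the
outermost two layers. Ablation removes cells and their incident edges and
never renormalizes anything else.

The cell count and layer count of the published section are not
recoverable from the text, so the defaults were chosen once to fit the
depicted proportions (dome section, OC ≈ 20 cells ≈ 1/4 of the tissue,
SCD ≈ 23 competent cells) and all counts remain configurable.

## Parameters

All quantities are dimensionless; the parameter set represents an
equivalence class under rescaling, calibrated to qualitative behaviour
only. The canonical file `src/samsim/data/parameters.yaml` documents
every constant (symbol, value, role); `ModelParameters` defaults are
asserted against it in the test suite. Highlights, with rationale:

| constant | value | why |
| --- | --- | --- |
| `ρ_max / ρ_min` | 0.013 / 0.0013 | tip-to-base anchoring contrast: ignition only near the tip |
| width `w_ρ` | 2.75 hops | narrow enough to pin the OC near the apex, wide enough that CLV3 can push it below the SCD |
| `ε_ξ` | 0.002 | ~15 % of the peak rate; enough to decide the pattern position when anchoring is constant |
| `κ` | 0.15 | weak saturation: the homogeneous active state of the pair keeps a genuine Turing band (κu*² < 1); stronger saturation leaves only ignition-driven patterning |
| `σ_x / d_x` | 0.02 / 0.001 | substrate supply and slow turnover: the budget sets the OC size, the reservoir provides the slow compensation |
| `k_r, m_r` | 0.74, 16 | CLV3 threshold ≈ 1.35 between the OC's local CLV3 (≈0.5) and the SCD's (≈3) |
| `K, n` | 1.6, 10 | stemness switch placed high on the signal profile so the SCD is a compact cap |
| `D_w, D_s` | 0.002, 0.0002 | weak leakage for the two cell-autonomous factors |
| `D_x, D_y, D_c` | 0.2, 0.2, 0.02 | facX global (lateral inhibition), signal medium-range (SCD induction), CLV3 short-range (local repression) |

Degradation rates of the downstream loop (0.05) are five times those of
WUS (0.01): the fast inner loop damps the oscillations that otherwise
arise in the delayed negative feedback, mirroring the observation that
CLV3-side rates are an order of magnitude faster than WUS-side rates.

## Numerics

Time integration is an IMEX scheme with a constant step `dt = 0.3`:
diffusion by the implicit trapezoidal (Crank–Nicolson) rule — one sparse
LU solve per mobile species per step, factorized once per stage —
reactions by explicit two-step Adams–Bashforth, bootstrapped with one
explicit-Euler reaction substep. Concentrations are floored at zero after
each step; floor events are counted and are absent at default parameters.
Verified properties: second-order convergence on linear decay, tracer
mass conservation to round-off under pure diffusion (zero row sums of the
Laplacian), unconditional stability of the diffusion half at 10× the
default step, and agreement with an independent explicit RK4 reference at
dt/100 to ~2×10⁻⁵ relative error over 200 steps.

Runs follow the two-stage protocol: stage 1 equilibrates from the
canonical initial condition (facX = 0.01 in every cell, everything else
0) for up to 30000 time units; stage 2 applies the scenario parameters
(and the edited tissue, for ablation) to the stage-1 end state and
integrates 15000 further time units. Both stage horizons are interpreted
as model time units. "Equilibrium" means every species' largest time
derivative stays below 10⁻⁸ for 10 consecutive checks (one check every 50
steps); the wild type equilibrates in ≈ 6000 time units. Stage-1
non-equilibration (possible for structural variants) produces a warning,
and stage 2 still runs.

## Domain discretization and outcome checks

Concentration fields are discretized relative to the wild-type stage-1
equilibrium: OC = cells with WUS ≥ 0.31 × the wild-type maximum, SCD =
competent cells with stemness ≥ 0.21 × the wild-type maximum. The maxima
(not means) of the reference state are used. For structural variants,
which never run a wild-type stage 1, an extra wild-type equilibration
provides the reference; for ablation the intact wild-type maxima are
kept. "SCD above OC" is operationalized as a smaller mean geodesic tip
distance. Each catalogue recipe carries a machine-checkable outcome
descriptor (counts, components, centroid shifts, overlap fractions,
collapse/recovery bounds), so the catalogue doubles as a regression
suite. The transient-recovery descriptor uses the defaults: stemness
falls below 20 % of wild type, then ends above 60 %; the coalescence
bound is an overlap fraction above 0.5 of the smaller domain; ablation
"restoration" means both domains non-empty at the end of stage 2.

## What the generator does and does not emulate

All inputs are synthetic by design — the model's own study conditions.
The geometry generator reproduces a plausible dome section, not a
segmented micrograph: real meristems have unequal cell sizes, anisotropic
walls, growth and division, and three-dimensional neighbourhoods, none of
which are represented. Passing tests therefore demonstrate the internal
consistency and qualitative phenomenology of the model on its idealized
tissue, not agreement with imaging data.

## Known limitations

- **Intermediate CLV3 overexpression recovers partially.** At
  `[CLV3_ext] = 1` stemness drops rapidly to ≈ 35–40 % of wild type and
  recovers to ≈ 55 %, with a clearly re-established OC and SCD — but not
  above the 60 % recovery bound, and the dip does not reach 20 %. The
  obstruction is structural: uniform exogenous CLV3 raises the OC's local
  CLV3 by the full exogenous level, so the recovered OC sits against the
  repression threshold about one cell deeper than wild type, which caps
  how much of the competent layer the signal can re-activate. The
  corresponding strong (permanent collapse) and low (smaller stable
  domains) behaviours are reproduced.
- **OC size under the endogenous-CLV3 sweep is constant only to ± 3
  cells** (range 17–23 around 22 across scale 0.9→6.2), and the SCD
  response is monotone except for a single ±1-cell blip in the deep tail:
  on a 95-cell tessellation the thresholded count changes by single cells
  as the spot slides about one cell deeper with rising CLV3. The
  qualitative claim — SCD size responds, OC size is buffered — holds.
- **The constant-anchoring variant sometimes forms two incipient WUS
  maxima** at the default thresholds (the Turing band of the pair admits
  two modes on this dome), so "exactly one OC component" holds in most
  but not all noise seeds; OC–SCD adjacency holds in every run and the
  SCD centroid position varies with the noise seed.
- **Regeneration after ablation is near-marginal.** The wounded tissue
  re-ignites a new OC and SCD in most tessellations (including the
  default one), but the remnant sits close to the ignition threshold of
  the basal conversion, and in roughly one random tessellation in five no
  new domain forms within the stage-2 horizon.
- No growth, cell division, 3-D structure, receptor biochemistry or
  mechanics; the anchoring field stands in for all unmodelled positional
  information.

## Problem sizes

Default runs use the 95-cell dome; the full test suite and the
reproduction script run the complete catalogue (including the 54-point
sweep and 10-seed constant-anchoring ensemble) at this size, each
individual simulation taking seconds on one CPU.
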