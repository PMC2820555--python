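# samsim

A seeded, scriptable simulator of stem-cell homeostasis in the
*Arabidopsis thaliana* shoot apical meristem (SAM).

Plant shoots grow from a small dome of cells whose tip harbours a
stem cell domain (SCD) maintained by an organizing centre (OC) beneath
it. The two domains regulate each other: OC cells express the
transcription factor *WUSCHEL* (WUS), which induces stem cell identity in
the competent outer cell layers through a mobile signal; stem cells
secrete the peptide CLAVATA3 (CLV3), which diffuses back and represses
*WUS*. `samsim` implements this circuitry as a reaction–diffusion model
on a static 2-D Voronoi tessellation of a meristem section and
reproduces, from a near-zero initial state, the emergence, shape and
placement of both domains — plus an entire catalogue of in-silico
genetics: *clv3* and receptor knockouts, graded CLV3 overexpression, WUS
knockdowns, WUS misexpression from the CLV3 promoter, laser ablation of
the meristem centre, and structural model variants.

The model couples two feedback systems through WUS. First, WUS and a
hypothetical diffusible substrate *facX* form an activator–substrate
(Turing-class) pair,

    d[WUS]/dt  = C − d_w [WUS] + D_w Δ[WUS]
    d[facX]/dt = σ_x − C − d_x [facX] + D_x Δ[facX]
    C = w_ko (ρ + ξ) [facX] · A([WUS]) · R([CLV3]),

where `A(u) = u²/(1+κu²) + b_w` is saturating autocatalysis, `ρ` a
tip-peaked "anchoring" rate providing positional bias (`ξ` a small frozen
random perturbation), and `R` a steeply cooperative CLV3 response that
gates the conversion of substrate into WUS. Second, the CLAVATA loop

    d[sig]/dt = k_y [WUS] − d_y [sig] + D_y Δ[sig]
    d[st]/dt  = I(c) k_s H([sig]) − d_s [st] + D_s Δ[st]
    d[CLV3]/dt = k_ko k_c [st] + d_c [CLV3_ext] − d_c [CLV3] + D_c Δ[CLV3]

drives stemness `[st]` in competent outer-layer cells (`I(c)=1`) through
a sharp Hill switch `H` and closes the negative feedback via CLV3.
Diffusion `Δ` is the unweighted graph Laplacian on the cell adjacency
(zero-flux boundaries); time stepping is IMEX — Crank–Nicolson for
diffusion, two-step Adams–Bashforth for reactions. Every run follows a
two-stage protocol: equilibrate the wild type from `[facX] = 0.01`
everywhere (30000 time units), then apply the scenario and integrate
15000 further units. See `docs/methods.md` for the full account.

## Worked example

Run the wild type and inspect the discretized domains (OC = cells with
WUS ≥ 0.31 × the wild-type maximum, SCD = competent cells with stemness
≥ 0.21 × the wild-type maximum):

```
$ samsim simulate --scenario wild_type --seed 1 --out runs/wt
wild_type: stage1 eq=True outcome=True
$ samsim report --run runs/wt | head -3
 time  oc_count  scd_count  overlap  oc_components  scd_components  adjacency  wus_total  stemness_total
  0.0        23         23        0              1               1       True 167.889535       17.107526
150.0        23         23        0              1               1       True 167.889539       17.107527
```

The 95-cell dome reached equilibrium (`eq=True`) and carries exactly one
connected OC of 23 cells and one connected SCD of 23 cells, which do not
overlap but touch (`adjacency True`) — the wild-type arrangement, with
the SCD tip-ward of the OC. `runs/wt/outcome.json` records the
machine-checked outcome:

```
"diagnostics": {
    "kind": "wild_type_arrangement",
    "final_oc_count": 23,
    "final_scd_count": 23,
    "overlap": 0,
    "adjacency": true,
    "scd_tip_distance": 3.13,
    "oc_tip_distance": 3.74,
    "tip_in_oc": false
}
```

(`*_tip_distance` is the mean geodesic distance of the domain's cells
from the apex, in cell hops: the SCD sits above the OC, and the tip cell
itself expresses no WUS.) Other scenarios run the same way, e.g.
`samsim simulate --scenario clv3_knockout ...` (the OC expands and
shifts to the tip) or `samsim sweep --scenario clv3_endogenous_sweep
--out sweep.tsv` for the 10 %–620 % endogenous-CLV3 response table.
`samsim scenarios` lists the full catalogue. Everything is also
available as a library:

```python
import samsim as s
geometry = s.build_dome_geometry(seed=1)
params = s.load_parameters()
result = s.run_scenario(s.get_recipe("clv3_knockout"), geometry, params, seed=1)
print(result.labelings[-1].oc_count, result.outcome.passed)
```

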