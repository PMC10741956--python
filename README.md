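# porevertex

A 2-D vertex-model simulator of tissue colonizing a scaffold pore in a
perfusion bioreactor, for researchers studying scaffold design and
flow-conditioned tissue growth.

Each cell is a polygon in a confluent mesh.  Cell *i* carries the elastic
energy

    E_i = ½ [ μ (L_i − L0)² + η (A_i − A0)² ],

with the reference perimeter/area of a regular hexagon of diameter *a*
(L0 = 3a, A0 = (3√3/8)a²).  Nodes move without inertia under the exact
energy gradient, `v = k F·H(|F|² − F0)`, and slide along the pore walls
(slip condition).  The tissue grows by stochastic mitotic division,

    P_i = P0 · H(A_i − m·A0) · T(τ) · q^(n_i − 6),

and relaxes by T1 intercalation (a short edge flips perpendicular, 5 %
longer, swapping neighbours).  The factor
`T(τ) = 1/[(1 − τ²)² + δτ²]` couples division to the shear stress of the
nutrient flow: it peaks (≈ 25× for δ = 0.04) at the resonant stress
`τ_res = √(1 − δ/2)`.  The flow itself is a closed-form Stokes solution —
plane Poiseuille in a straight channel, a first-order stream-function
expansion for walls `y = ±h(1 + ε sin(Kx + φ))` — so the stress field is
analytic and static.

## Worked example

`examples/04_pore_colonization_run.py` grows a tissue from one seeded
cell in a short straight pore (0 ≤ x ≤ 30, h = 4.5):

```
   t     N    A1     p1     E1
   ...
   400    28  0.90   0.11   0.18
   500    44  0.86   0.17   0.35
   600    80  0.79   0.28   0.72
   700   107  0.76   0.34   0.95

pore filled (>=98% area) at t = 785 with 137 cells
```

`N` is the cell count; `A1` and `E1` are the mean cell area (units of A0)
and elastic energy per cell; `p1 = <A0/A_i − 1>` is the bubble-analogy
pressure.  As crowding sets in, `A1` falls below 1 while pressure and
energy rise — the tissue packs under compression until it covers 98 % of
the pore area.

`examples/03_wavy_channel_stress_map.py` prints the structure of the
wavy-channel stress field (ε = 0.2, K = π, h = 1):

```
peak wall stress  |tau/tau0| = 1.457 at x = 0.90 (half-width 1.06 > h: expansion)
lowest wall stress |tau/tau0| = 0.497 at x = 1.50 (half-width 0.80 < h: bottleneck)
stress along the channel axis stays below 0.0000 (the centreline jet is nearly stress-free)
```

With the division–flow coupling on, the widened wall sections therefore
become growth zones.  (See docs/methods.md for the two sign conventions
of the first-order correction and why the default places the peak at the
expansion.)

Other entry points: `porevertex run --scenario wavy-shear --seed 1`
(time-series CSVs + JSON snapshots) and
`porevertex flowmap --epsilon 0.2 --k 3.14 --out grid.csv`.

## Scenarios

Four presets share the reference parameter table and the pore
0 ≤ x ≤ 120, h = 4.5: `straight-uniform`, `wavy-uniform` (ε = 0.2,
K = 1/6, φ = −π/2), and their `-shear` variants with the division–flow
coupling enabled.  `run_scenario(name, seeds=...)` returns per-seed
trajectories plus ensemble means.

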