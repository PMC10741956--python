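# Methods

`porevertex` simulates a two-dimensional tissue colonizing the pore of a
perfusion-bioreactor scaffold.  The pore is a planar channel, either
straight or with harmonically wavy walls; a nutrient solution creeps
through it and its shear stress can stimulate the cells to divide.  This
note records the model, its closures, the numerical choices, and what the
synthetic scenarios do and do not establish.

## Tissue model

The tissue is a confluent mesh of polygonal cells sharing vertices and
edges (a 2-D apical vertex model).  Cell *i* with perimeter `L_i` and
area `A_i` carries the elastic energy

    E_i = 1/2 [ mu (L_i - L0)^2 + eta (A_i - A0)^2 ],

with the reference geometry of a regular hexagon of diameter `a`:
`L0 = 3a`, `A0 = (3*sqrt(3)/8) a^2 = (sqrt(3)/24) L0^2`.  Node forces are
the exact negative gradient of the total energy.  Motion is overdamped
and thresholded,

    v = k F . H(|F|^2 - F0),     H(0) = 0,

so nodes move only while the squared force magnitude exceeds `F0`; this
leaves a small frozen residual strain in the tissue, which is intended
(it stabilizes the packing).  The printed threshold compares `|F|^2`
with `F0`; `MechParams.threshold_on_magnitude` switches to `|F| > F0`
for users who prefer the dimensional reading.  On the pore wall the
velocity obeys a slip condition (`v . n = 0`): wall nodes slide along
the wall curve.  Wall contact is unilateral: a free vertex that crosses
the wall is projected onto it and flagged; a wall vertex whose velocity
points into the fluid is released.

Reference parameters (all simulations):
`mu = 1`, `eta = 4`, `k = 0.5`, `F0 = 0.1`, `a = 2` (so `L0 = 6`,
`A0 = 3*sqrt(3)/2`), `P0 = 5e-5`, `q = 1.4`, `m = 0.7`, `delta = 0.04`,
`l0 = 0.15`.  Lengths are in units of the cell diameter scale; no
physical unit conversion happens inside the simulator.

### Division

Cell *i* divides with per-trial probability

    P_i = P0 . H(A_i - m A0) . T(tau) . q^(n_i - 6),

where `n_i` is the side count, the Heaviside gate blocks cells that have
not regrown to 70 % of the reference area, and

    T(tau) = 1 / [ (1 - tau^2)^2 + delta tau^2 ]

is the resonant response to the local dimensionless shear stress:
`T(0) = 1`, maximum `1/[delta (1 - delta/4)] ~ 25` at
`tau_res = sqrt(1 - delta/2)`, and `T -> 0` at high stress.  The division
cut runs from the midpoint of the longest side to the midpoint of the
opposite side (the farther/longer of the two candidates for odd `n`,
ties broken by vertex-id order).  Both midpoints become shared vertices,
so the two neighbours incident to the cut sides gain a vertex and the
mesh stays conformal; daughter areas sum exactly to the mother area.

**Trial-rate closure.**  The model states a per-trial probability but no
time base.  We schedule trials at a rate `R = trials_per_unit_time` per
cell (per step the division probability is `P_i * R * dt_eff`, exact for
small values).  `R` is the one calibrated constant of the package: it was
set once so that uniform growth in the straight reference channel
reproduces the population magnitude of the study scenario (a few hundred
cells by `t = 1000`), giving `R = 137`.  The early phase of a run is a
pure birth process and therefore heavy-tailed: single realizations of
`N(t = 1000)` scatter over roughly a decade, and ensemble means over five
seeds inherit a large spread.  Fill-completion times are less volatile.

### Intercalation and mesh maintenance

An interior edge shorter than `l0` shared by two cells, whose endpoints
are three-fold junctions (or wall vertices shared by exactly two cells —
the wall acts as the fourth neighbour), is replaced by a perpendicular
edge 5 % longer than the original (`extrusion_factor = 1.05`), swapping
which cell pairs are adjacent (T1).  Two pieces of maintenance keep the
discrete dynamics well-posed; both are below the scale of the biology:

* **T1 refractory time** (`t1_cooldown = 1`): a freshly flipped edge may
  not flip again for one time unit.  Without it a persistently
  compressed edge ping-pongs around the critical length every few steps.
* **Edge collapse** (`l_merge = 0.05`): edges that cannot intercalate —
  free-front edges, wall edges, blocked junctions — are merged into one
  vertex once shorter than `l_merge` (the merged vertex takes the
  midpoint and the union of the wall flags; merges that would break
  conformity or create a two-sided cell are skipped).  Such edges
  otherwise shrink indefinitely and stall the Courant-limited step.

## Flow and shear stress

The pore flow is laminar (`Re = u0 h / nu ~ 0.1` for water in a
100-micron pore at 1 mm/s), so the Stokes equations apply.  A straight
channel carries plane Poiseuille flow with wall stress
`tau0 = 2 eta0 u0 / h`.  For walls `y = +/- h (1 + eps sin(Kx + phase))`
the stream function is expanded to first order in `eps` on the mapped
strip `phi = y / w(x)`:

    psi = (phi - phi^3/3) + eps sin(beta theta + phase) g(phi),
    g(phi) = f(phi) + phi - phi^3,    beta = K h,

with `f` the odd biharmonic profile satisfying `f(+-1) = 0`,
`f'(+-1) = 2`.  Velocities come from exact chain-rule differentiation,
so no-slip holds exactly on the mapped walls and the field is exactly
divergence-free.  The flow-aligned shear stress is evaluated from the
analytic velocity gradient and reported in units of `tau0`.

**Two sign conventions.**  Because `f` satisfies homogeneous wall
conditions, `-f` is also admissible — it is the solution for the channel
with *inverted* waviness.  The two variants place the peak wall stress
at opposite stations:

* `field_source = "printed"` (default): peak at the **expansion**,
  minimum at the bottleneck, peak value above the straight-wall stress.
  This is the structure the scenario results of this package are built
  on (shear-stimulated growth zones sit at the widened wall sections).
* `field_source = "consistent"`: the solution of the stated first-order
  problem; peak at the **bottleneck** (the classical lubrication
  result).  An independent oracle in the test suite — the residual of
  the harmonic-vorticity condition `lap(omega) = 0`, which scales as
  `eps^2` for this variant and only as `eps` for the printed one —
  identifies it as the self-consistent field.

The coupling to biology is one-way and static: the field is computed for
the empty channel, cells do not perturb it.  Per-cell stress is `|tau|`
sampled at the cell centroid and rescaled once so that the largest
wall-adjacent stress equals `stress_amplitude * tau_res`
(`stress_amplitude = 1` by default: cells at the peak-stress walls
divide at the resonant rate).  `stress_amplitude = 0` recovers uniform
growth.

## Time stepping and measurements

Explicit Euler with base step `dt = 0.01` and a Courant guard: the step
is reduced to `0.1 * l_min / v_max` whenever the fastest node would move
more than a tenth of the shortest relevant edge (edges below `l_merge`
are excluded from the length scale, since they are merged away).  Event
order per step: forces -> motion/slip/snap -> division trials -> T1 scan
-> edge collapse -> measurements.  Runs are bit-reproducible given the
seed.

Every `1.0` time units the driver records `N`, `A1 = <A_i>/A0`,
`L1 = <L_i>/L0`, the bubble-analogy pressure `p1 = <A0/A_i - 1>`, the
specific energy `E1 = <E_i>` and the polygon-class census.  A run ends
at `t_end` or when the tissue covers 98 % of the channel area
("fill"; the channel area is evaluated analytically).  The 98 % figure
is an operational definition — wall-hugging cells meet the curved wall
by straight chords and the channel corners fill last, so coverage
saturates slightly below 1.

## Scenarios

All four presets share the reference parameters and the pore
`0 <= x <= 120`, `h = 4.5` with closed (slip-wall) ends, seeded with a
single relaxed hexagon at `(x_min + a, 0)`:
`straight-uniform` / `straight-shear` (`eps = 0`) and
`wavy-uniform` / `wavy-shear`
(`eps = 0.2`, `K = 1/6`, `phase = -pi/2`, so the channel starts at a
bottleneck).  The `-shear` variants multiply the division probability by
`T(tau)`.  Ensembles use five seeds; the same seed list serves every
scenario, so scenario contrasts are paired.

## What the scenarios do and do not show

The generator emulates the study conditions: a single seeded cell, the
reference parameter set, uniform nutrition (no transport or depletion),
no cell death, a static one-way flow field, and a rigid pore.  Passing
tests therefore demonstrate properties of this model — exact division
bookkeeping, adjacency swaps, energy descent, the stress-field
structure, the scenario orderings (straight fills before wavy; shear
stimulation accelerates the wavy channel) — not the behaviour of real
dynamic cell cultures.

Known quantitative limitations, measured and deliberate (no parameter
was adjusted to mask them):

* With the trial rate calibrated to the straight-channel population
  magnitude, the ensemble-mean fill time of the straight channel lands
  within ~10 % of the study value, but the wavy-channel *excess* fill
  time is substantially smaller than reported: in this implementation
  the growing front relieves compression efficiently (T1s, slip walls,
  a free front), so bottlenecks impede it only mildly.
* For the same reason the tissue stays much closer to mechanical
  equilibrium than the study's: the specific-energy plateau of the wavy
  scenario measures order 1 here versus order 6 there, and the mean cell
  area at fill is ~0.7 A0 rather than ~0.6 A0.  No choice of the trial
  rate reproduces the reported strain level (it was re-measured across
  a 20x range of rates).
* The final census keeps more four- and five-sided cells than reported,
  because divisions at the free front add fewer sides than interior
  divisions (a cut edge on the front has no neighbour to inherit a
  midpoint vertex).

## Numerical details

* Forces, geometry and motion run in compiled (numba) kernels over a
  flattened corner representation; a pure-python assembly is kept and
  tested for exact agreement.  Topology edits operate on the cell
  objects and invalidate the compiled cache.
* Degenerate inputs: polygons need three or more points; zero-length
  edges contribute no perimeter force; inverted (clockwise) cells are
  re-oriented with a logged warning before the step proceeds; division
  or T1 edits that would create a two-sided polygon are skipped.
* Mesh conformity (edge incidence, ring sizes) is asserted after every
  step that edits topology; the full invariant set (orientation,
  duplicate vertices, optional overlap via shapely) is checked at output
  times.  Vertices pinned into a channel corner by two walls may
  legitimately coincide and are exempt from the coincidence check.
* Snapshots are JSON (positions, wall flags, cell rings, config hash)
  and round-trip exactly.
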