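# Model and methods

`flowmigrate` simulates flow-mediated vascular remodelling as an agent-based
model of endothelial cells (ECs) migrating against blood flow in an
idealised bifurcated vessel network, coupled to a one-dimensional
Hagen–Poiseuille flow solver. The question it is built to answer is which
cell decision behaviours at a flow-convergent bifurcation preserve the
bifurcation during remodelling, and which collapse the network into a
single flow path (a functional shunt).

## Network geometries and discretisation

Two idealised geometries are provided.

* **A-branch** (default): a feeding vessel splits at a flow-divergent
  bifurcation into a short *proximal* branch and a longer *distal* branch,
  which reconverge at a flow-convergent bifurcation into a draining vessel.
  The distal branch is twice the proximal length; the proximal branch is
  twice the feeding/draining length. With the default 40 segments the
  allocation is 5 / 10 / 20 / 5 (feeding / proximal / distal / draining),
  so the inlet→outlet round trip through the distal path is 30 segments.
  A variant multiplies the distal length (e.g. 10× the proximal path),
  which changes the initial shear ratio at the convergent bifurcation from
  2:1 to 10:1.
* **Y-branch**: two inlet branches of equal length converging into a single
  draining stem — a single flow-convergent bifurcation whose initial shear
  ratio is set directly by boundary conditions (equal inlet pressures for
  1:1, prescribed inlet flows for other ratios). Branch and stem lengths
  default to 10 segments each; the supplement-style results are qualitative,
  so these lengths are a package choice, configurable by the caller.

Each segment has length `l_seg = 10 µm`, the distance one cell travels per
time step (`v·dt = l_seg`, with `v = 3 µm/hr` and `dt = 3⅓ hr`). Each
segment initially holds `n0 = 8` cells (320 cells in the default network).

**Mesh convention.** Each vessel is discretised independently and the
junction endpoints are welded together. At the flow-convergent junction the
two branch segments keep their own endpoint nodes — these are the two
segments whose cell counts and shear stresses drive the branch decision and
the loss analysis — identified hydraulically with the draining vessel's
first node (equal pressure, merged flow balance). Node-id count is
therefore `n_seg + 1` (41 for the default A-branch); the physics is
identical to a fully merged mesh. The Y-branch is a tree and needs no
identified pair.

## Flow model

Blood is Newtonian with constant viscosity `µ = 3.5 mPa·s`. The lumen
diameter of a segment holding `n` cells of lateral width `w = 5 µm` comes
from wrapping the cells into a circle, `d = n·w/π`. Segment conductance is
the Poiseuille value

    G = n⁴w⁴ / (128 π³ µ l_seg),

so conductance scales with the fourth power of cell number — the
physical origin of the competition analysed below. Empty segments receive a
floor conductance of 1e−25 m³/s/Pa to keep the nodal system invertible.
Nodal pressures solve the flow-balance (Kirchhoff) system with Dirichlet
pressures (default 100 Pa inlet, 0 Pa outlet, chosen so initial wall shear
stresses sit in the 1–5 Pa range of developing capillary plexuses) imposed
by row substitution; the prescribed-inlet-flow variant replaces the inlet
balance row with a source term. The system is dense and tiny (≤ ~121
nodes), solved directly; interior flow balance is asserted post hoc to
1e−10 relative at every step. Per-segment flow is `q = −G·Δp` with
`Δp = p_downstream − p_upstream`, and wall shear stress magnitude is
`τ = |n·w·Δp| / (4π·l_seg)`.

Degenerate inputs: equal boundary pressures (or all-zero prescribed
inflows) return an exact zero-flow state rather than solver round-off, and
migration treats it as "no flow direction". Flows with magnitude below
1e−30 m³/s are treated as stagnant; the floor-conductance trickle through a
dead branch (~1e−23 m³/s) stays above this threshold, which is what lets a
regressing branch finish draining.

## Migration

All cells advance one segment against the local flow direction per step,
synchronously from the pre-step state (a sequential update would make
outcomes order-dependent, which nothing in the model motivates). A
segment's cells exit on the side its flow comes from; the destination is
the neighbouring segment that feeds flow into that node. At the divergent
junction the two branch heads merge into the feeding vessel. At the
convergent junction, cells in the draining vessel's first segment face two
upstream paths and apply the selected bifurcation rule, each cell
independently.

**Intercalation smoothing.** A segment whose planned efflux exceeds its
planned (positive) influx retains one cell that step, damping sharp
diameter fluctuations. Segments incident to either bifurcation node are
exempt so the smoothing cannot interfere with the decision dynamics or the
loss analysis at the junctions — and, importantly, so that regression
remains possible at all: with retention active at the branch entry
segments, an entry holding cells could never empty. Because agents are
exchangeable integer counts, "choosing" the retained cell consumes no
random draws; the only stochastic draws in a run are the per-cell branch
choices, taken in a fixed order from one `numpy` `default_rng` stream
seeded once per run. Runs are bitwise reproducible given (seed, config).

**Cell boundary conditions.** *Periodic* (default): cells exiting at the
inlet re-enter at the outlet the same step; total cell count is exactly
conserved. *Dirichlet*: at most `n_fixed` (default `n0`) cells enter at the
outlet per step and surplus exiting cells are removed; since the merged
branch traffic regularly pushes more than `n_fixed` cells out of the inlet,
the total declines over time. Discarding (rather than queueing) the surplus
is a package choice consistent with that monotone decline.

## Bifurcation rules

* **BR1** — deterministic: enter the branch with larger wall shear stress
  (ties to branch 2). On the A-branch this starves the distal branch.
* **BR2** — deterministic: enter the branch with the smallest direction
  change; branch angles at the convergent node are −π/2 (proximal) and 0
  (distal), so cells always continue into the distal branch and the
  proximal branch regresses.
* **BR3 / BR4** — stochastic with fixed probabilities (0.5/0.5 and
  0.7/0.3). Both preserve the bifurcation; BR4 renders diameter control
  (the favoured high-flow branch stabilises wider).
* **BR5** — the mechanistic rule. Per step, from the pre-step flow state,
  each branch's entry probability is

      P_i = α·P_τi + (1−α)·P_ni,
      P_τi = τ_i/(τ_1+τ_2),   P_ni = n_i/(n_1+n_2),

  where τ_i and n_i belong to the two branch segments directly incident to
  the convergent node (not whole-branch aggregates). α ∈ [0, 1] weighs the
  shear cue (flow-migration) against the cell-number cue (junction-force /
  collective migration). Substituting τ = n·w·|Δp|/(4πl) shows
  P_τi = n_i|Δp_i| / Σ n|Δp|; both forms are computed and asserted equal to
  1e−12 at every step. Probabilities are recomputed once per step and
  shared by all cells deciding in that step; recomputing between individual
  draws is not supported (nothing in the model's description requires it,
  and it would couple outcomes to an arbitrary within-step ordering). If
  both shears are zero (no flow) the shear component degenerates to
  (0.5, 0.5); this cannot arise under the default boundary conditions.

The competition in BR5 is haemodynamic: a branch narrowing from cell efflux
suffers a resistance spike (`R ∝ n⁻⁴`), which concentrates pressure drop on
the narrowed segment and raises its shear share, attracting cells back — a
built-in rescue against regression. Stable runs show alternating peaks of
P_τ and P_n (negative correlation of their step changes) and inverse
correlation between a branch segment's cell number and its pressure drop.

## Bifurcation loss

A run monitors the two branches at the flow-convergent node. Under BR5 an
empty entry segment is absorbing — its shear and cell number are both zero,
so its entry probability is exactly zero — which makes two equivalent
criteria available, separated by the time the emptying wave takes to
traverse the branch (one segment per step):

* `segment`: loss at the first step either branch *entry segment* is empty
  (regression onset);
* `branch` (default, used for all ensemble statistics): loss once a whole
  branch is empty (regression complete).

Ensemble statistics use the branch criterion because completed regressions
are what the model's loss percentages and branch attributions describe;
onset-counting inflates late-window losses whose regressions do not
complete within the simulated window. Both criteria are exposed.
Simulation continues after loss (the floor conductance carries the dead
branch); a dead branch cannot be re-entered under BR5, which is asserted as
a property rather than forbidden.

## Ensembles and the stability analysis

The α sweep runs BR5 over a grid of α (0.0–1.0, step 0.01 by default) with
a shared list of seeds (`generate_seeds`: uniform integers in [1, 1e9] from
a documented meta-seed, reused across every α so ensembles are paired).
Default runs last 6 simulated days (43 steps) — the developmental
remodelling window — with loss day-bins `(d−1)·24 < t ≤ d·24`. Reported
per α: fraction of runs lost over time (monotone by construction), final
loss fraction, and the proximal/distal attribution over lost runs
(simultaneous losses counted half-half). The acceptance script uses
ensembles of 1000 seeds per α at the three diagnostic weightings
(α = 0.0, 0.45, 1.0); the test suite uses 200 with binomial-error bands.

Mean branch diameters average the per-segment `d = n·w/π` over equal-sized
subsets of the two branches (the 10 distal segments adjacent to the
convergent node, matching the 10 proximal segments); which distal subset
enters the average is a package choice. The BR2 oscillation period is
measured as the mean spacing of prominence-filtered peaks
(`scipy.signal.find_peaks`, prominence ≥ 10% of the trace range) in the
distal mean-diameter trace of a 30-day run.

## What the simulations do and do not show

The generator of all data here is the model itself; there is no external
data. The networks are idealised (two fixed topologies, no 2D/3D
embedding beyond branch angles), cells are rigid identical agents without
proliferation, apoptosis or deformation, and blood is Newtonian without
haematocrit effects, pulsatility or compliance. Shear at bifurcations is
1D; no molecular signalling is represented — α is a single static weight,
not a function of signalling state. Passing tests therefore show that the
*mechanism* (competition of shear and collective cues stabilising
bifurcations, with maximal stability near equal weighting) is an emergent
property of the coupled flow-migration system, not that the parameter
values transfer quantitatively to real vasculature.

Known limitations: the loss-*timing* distribution depends on the loss
criterion (onset vs completion) in a way the loss fractions do not; with
the completion criterion the shear-only ensembles plateau around day 4
rather than day 2, because the 20-segment distal drain adds ~2 days to the
onset time. Ensemble percentages carry binomial noise of order
±1–3 points at 1000 seeds, and the attribution fold-ratios (distal:proximal
regression) amplify small attribution differences.
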