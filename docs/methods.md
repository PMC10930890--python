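# Methods

## Model and event semantics

The simulator is a boundary-driven (Eden-type) stochastic model on a square
2D lattice with Moore neighborhoods. One *event* is: (1) pick an occupied
voxel uniformly at random; (2) it attempts division with probability
`min(1, b(1+s)^n)` — division requires at least one empty Moore neighbor,
the daughter lands on a uniformly chosen empty neighbor and gains
`Poisson(mu)` new driver mutations (globally unique ids, infinite sites); a
division that adds drivers founds a new clone; (3) the *same chosen cell*
then dies with its regional death probability. The daughter placed in step
(2) is never the death candidate of its own event, but it does occupy space
for the quiescent check. Time is measured in *sweeps*: the clock advances by
`1/m` per event at population size `m`, so one sweep is one expected pick
per cell. Death is evaluated regardless of whether the division attempt
succeeded; the two sub-steps are independent coin flips of the same event.

Regions: a cell belongs to the sanctuary core when its Euclidean distance
from the founder voxel is `<= R` (ties inclusive). Before detection every
cell dies at `d1`; detection latches irreversibly once the occupied count
reaches `ceil(pi * detection_radius^2)` — a count threshold rather than a
measured radius, which is robust to ragged fronts and matches the size/radius
equivalence used for calibration. After detection, cells outside the core
die at `d2`. No treatment-shrinkage step is modeled: detection changes the
environment and nothing else.

Variants. *Quiescent* growth skips death for cells with zero empty
neighbors (evaluated after the daughter placement). *Death-rate selection*
leaves birth at `b` and multiplies the regional death rate by `(1-s)^n`,
compounding per driver in mirror image of the birth-rate form.

Terminal conditions: extinction, reaching `max_voxels`, an optional sweep
cap (a safety valve for parameter corners where the invasion waiting time
diverges), or — as a hard error — the tumor touching the lattice boundary.
The grid half-width is sized at four times the radius of a disc holding
`max_voxels`, so the boundary abort never fires in ordinary use.

## Implementation

Two implementations of the identical event semantics exist on purpose.
`lattice_engine.step` is a plain-Python single event used by unit and
property tests (bookkeeping oracles, surrounded-cell behavior, death-order
semantics). `run_simulation` drives a numba-compiled kernel over flat
arrays with O(1) occupancy updates and an incremental per-clone census
(core/edge counts and distance sums maintained on every birth and death);
full runs at the sizes used here take 10⁶–10⁷ events, which the kernel
covers in seconds. All kernel randomness comes from numba's internal
generator seeded once per run, so a fixed seed reproduces a run
bit-for-bit; the analysis stages use an independent numpy `Generator`.
Clone founding events are journaled by the kernel and registered in the
Python-side genealogy (`CloneLedger`) between chunks; mutation ids are
assigned sequentially at registration.

Per-mutation censuses exploit infinite sites: a mutation's carriers are
exactly the genealogical subtree of its founding clone, so tissue frequency
`f_m`, carrier mean death rate `d̄_m`, and mean carrier distance all come
from one linear pass over the clone table (children have larger ids than
parents, so a reverse scan aggregates subtrees). Tests verify this against
direct per-cell enumeration on small simulated states.

## Shedding calibration

Constants and their defaults: plasma DNA concentration 29 ng/mL; haploid
genome mass 0.0033 ng (hence 8788 haploid genome equivalents per mL); blood
volume 5 L, 55% plasma; ctDNA tumor fraction 1% at detection; fragment
half-life 30 min, i.e. decay `eps = 48 ln 2 ≈ 33.27`/day; 15 mL blood draw
= 0.3% of supply; tumor growth term `r = 0` (fragment decay is ~3 orders of
magnitude faster than tumor growth). The shedding probability per cell
death solves `C = N d q / eps` at the detection anchor (`N = 3e9`,
`d = d1 = 0.1`, `C = 5000*0.55*8788*0.01 = 241,670`), giving `q = 0.0268`
at full precision. Two deliberate quirks are preserved because they are
part of the published chain: the total-fragment mean at detection uses the
rounded 8800 HGE/mL (so `Ctot0 = 72,600` per draw) while the tumor chain
uses 8788, and `q` rounds to 0.026-0.027 at two significant digits; all
constants are overridable.

For desk-scale runs (smaller detection radius), `calibration_for(params)`
re-anchors `n_at_detection` at the 3D-equivalent population of the run's
own detection threshold, which keeps the 1% tumor fraction at detection —
without this the blood model of a reduced lattice would correspond to no
consistent physical tumor.

VAF sampling: one blood draw shares a single Poisson denominator draw
(total fragments `Ct + Ch`) across all mutations; numerators are
independent Poisson draws of half the mutant-fragment mean (diploid cells,
one mutated copy). The draw-fraction thinning is applied to the Poisson
means; by Poisson thinning this is distributionally identical to
subsampling fragments after the draw. For clonal mutations the biased and
unbiased means coincide and the numerator draw is reused for both, making
the two models identical realization-by-realization, not just in
distribution. A zero denominator (possible only for implausibly small
means) yields a missing VAF, which counts as undetected. Healthy fragments
are held at a constant mean `Ch = 0.99 * Ctot0` over time.

## Distortion metrics

Blood clone fractions are death-rate-weighted censuses
`Σ_j d_j N_ij / Σ_ij d_j N_ij`; with `d1 = d2` they collapse exactly onto
tissue fractions (tested on random fixtures). Per-clone differences
(blood − tissue) are averaged separately by sign over clones holding at
least 10% of the tumor. The two-compartment bound
`f(x) = d2 x/(d2 x + d1 S) − x/(x+S)` is maximized numerically by bounded
scalar search; the closed form of the peak —
`f* = (√d2 − √d1)/(√d2 + √d1)` at `x* = S√(d1/d2)`, independent of `S` —
was derived by hand and is asserted against the numeric optimum in the
tests (at `d1=0.1, d2=0.9`: `f* = 0.5`, not the superficially similar
linear form `(d2−d1)/(d2+d1) = 0.8`). Diversity uses the inverse Simpson
index on blood and tissue fractions. Detectability counts distinct drivers
with sampled VAF at or above a limit (10⁻³ and 10⁻² by default), and the
percent spatial bias is `100 (n_biased − n_unbiased)/n_unbiased`, undefined
(NaN) when nothing is detectable under the unbiased null. Cross-run curves
are compared on normalized time (sweep / final sweep), bin-averaged per run
and summarized as mean ± sample s.d. across runs.

## Study conditions at desk scale

The published parameter set is `b=0.7, s=0.1, mu=1e-3, d1=0.1` with
`d2=0.9` (driver-dependent) or `d2=0.69` (driver-independent), sanctuary
radii 20-60, detection radius 90, final size 60,000 voxels. The test suite
and the acceptance script run the same rates on a lattice halved linearly:
detection radius 45 (≈6,362 voxels, ≈3.8×10⁸ equivalent cells), final size
15,000 voxels, sanctuary radii 10 (small) and 30 (large), calibration
re-anchored as above. These sizes preserve the regime structure (the
driver-dependent invasion barrier still requires three drivers,
`0.7·1.1³ ≈ 0.93 > 0.9`) while one replicate completes in seconds.
Replicates are conditioned on non-extinction: a single founder dies out in
roughly 15% of attempts, and discarded attempts are reseeded
deterministically.

## What the simulations do and do not show

The generator reproduces the qualitative machinery the model was built to
study: stall-and-escape population trajectories under driver-dependent
invasion, continuous growth under driver-independent invasion, blood
over-representation of young invasive clones and under-representation of
sanctuary-trapped clones, inflated blood diversity for driver-independent
growth with a large sanctuary, and rarity of blood-detectable drivers.
It does not emulate sequencing error, copy-number change, germline or
hematopoietic background mutations, vasculature or immune agents, 3D
geometry, or treatment pharmacokinetics — conclusions about real assays are
correspondingly limited to the spatial-shedding mechanism itself.

## Numerical choices and edge cases

Birth probabilities are clamped at 1 (they parameterize Bernoulli trials;
the clamp binds only at `n >= 4` for the default rates). Daughter placement
breaks ties uniformly among empty neighbors enumerated in fixed row-major
offset order. Distance ties at exactly `R` belong to the core. An empty
tumor raises a distinct error from an occupied tumor with zero shedding
mass (possible with `d = 0`). The bounded maximization of `f` uses an
absolute x-tolerance of `1e-10·S`, comfortably below the `1e-6` agreement
asserted in tests. Extinction leaves a final census record with zero cells;
clones with zero live cells stay in the ledger (their trajectories remain
plottable) but drop out of fraction tables.
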