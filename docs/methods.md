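# Methods

## The lattice model of SIR silencing

The telomeric region is modelled as a single one-dimensional lattice of
`L = 200` nucleosomes.  Each site is in one of five states — unmodified
(U), acetylated (A), methylated (M), transcriptionally active (E), or
silenced/Sir-bound (S).  The reactions are:

| reaction | propensity per site | meaning |
|---|---|---|
| U → A | `k_basal_acetyl` | Sas-mediated basal acetylation |
| A → E | `k_activation` | establishment of the active state |
| U/A → M | `k_txn_feedback · Σ_kernel(E)` | transcription-coupled methylation next to active sites |
| A → U | `f(I) · k_sir_deacetyl · Σ_kernel(S)` | Sir-mediated deacetylation next to silenced sites |
| U → S | `f(I) · k_sir_bind · (free/N) · Σ_kernel(S)` | cooperative Sir binding (polymerization) |
| S → U | `k_sir_unbind` | Sir unbinding (returns one Sir to the pool) |
| A/M/E/S → U | `k_mark_loss = 1` | uniform mark loss; the clock |

All rates are expressed in units of the uniform mark-loss rate, which
stands in for cell-cycle dilution of marks; one mark-loss time is
therefore roughly one cell generation.  `Σ_kernel(X)` is the
kernel-weighted count of neighbouring sites in state X within range R.
Methylated nucleosomes bind no Sir and decay only by mark loss, so
methylation shields active chromatin against re-silencing; which states
methylation targets, and whether deacetylation also strips methyl marks,
are stored as data on the `RateSet` so graph variants are testable.

**Sir titration.** The total Sir supply is fixed at `N_sir_total = 100`
site-equivalents, held as an exact integer invariant
`count(S) + free_sir == N_sir_total` after every event.  Binding is
proportional to the free fraction, so a growing silenced domain starves
its own growth — the negative feedback that produces a finite domain and,
near the transition, the continuous merging of branches.

**Boundaries.** The telomere-proximal end carries a virtual permanent-S
nucleation source feeding the Sir kernels of the first R sites, scaled by
`nucleation_strength`; the distal end is pinned in state E.  The
nucleation strength is a distinct physical quantity from Sir–Sir
cooperativity (it reflects silencer/telomere recruitment, not
polymerization), and keeping it well below 1 is what separates the slow
establishment of silencing from scratch from the fast maintenance of an
existing domain.  With a nearest-neighbour kernel and full-strength
nucleation, a fresh toe-hold and an established front are locally
identical, and no choice of rates exhibits hysteresis; the shipped model
therefore uses an exponential kernel (`exp(-d/ξ)`, ξ = 1.54, R = 8) —
supra-molecular cooperativity over a few nucleosomes.

**Inhibitor.** Splitomycin enters as a scaled concentration
`I = [drug]/K_D` multiplying all Sir-mediated rates by the
non-cooperative competitive-inhibition factor `f(I) = 1/(1+I)`
(pluggable).

**Simulation.** Exact Gillespie sampling, with a numba-compiled event
loop for production runs and a pure-Python reference enumeration of the
same reaction graph; the two routes are asserted propensity-for-propensity
on random states in the test suite.  Occupancy of the locus window
(sites 5–50 from the telomere) is recorded every 0.1 time units; a single
seeded generator makes runs bit-reproducible.

## The shipped wild-type rate set

The wild-type parameters are a random draw accepted by
`find_bistable_rates`: log-uniform sampling within physiologically ordered
bounds, accepting the first candidate whose history-conditioned occupancy
gap at I = 0 exceeds the criterion while the gap probed at I = 4 closes.
The shipped values (rounded) are

    k_basal_acetyl = 2.48   k_sir_deacetyl = 9.84   k_txn_feedback = 10.8
    k_sir_bind     = 6.9    k_activation   = 0.91   k_sir_unbind    = 0.2
    kernel = exponential(xi = 1.54, R = 8)          nucleation_strength = 0.05

This regime has a readable logic: binding is weak enough that a silencing
front advances slower than the mark-loss clock through methylation-shielded
active chromatin (so the active branch is metastable for tens of
generations), while strong Sir-mediated deacetylation keeps the interior
of an established domain healed (so the silenced branch persists).  At
I = 4 the fivefold-suppressed binding can no longer heal the domain and it
collapses within a few generations.

## The hysteresis protocol

Ensembles are pre-grown for 150 time units at I = 0 (LOW history) and
I = 4 (HIGH history).  Each history starts in the basin of the branch it
occupies — LOW from an established telomeric S-domain, HIGH from the
all-active lattice — because in a robustly bistable system spontaneous
branch switching is far slower than any feasible pre-growth horizon; the
initial basin, not the pre-growth noise, decides the branch (both init
modes are parameters, and equal modes make the two ensembles
exchangeable).  Every member is then exposed to an intermediate I.

Short-time dynamics is discarded with `t_burn = 8` and the occupancy
averaged up to `t_record = 20` time units, a 12-unit reporting window
matching the 12–15 generations of intermediate drug exposure in the
assays.  The burn-in is long enough for the collapse transient of the
silenced branch at high I to complete, so branch closure is measured on
relaxed states.

With the shipped rates and 50 replicates per history, the mean occupancy
gap (LOW minus HIGH) falls from ≈ 0.24 at I = 0 (≈ 6.6 standard errors)
through ≈ 0.18 at I = 0.5 to indistinguishable from zero at I = 4
(≈ 1 standard error), with no single-step collapse — the scan classifies
as a continuous merge, the titration signature.

## Bifurcation classification

`classify_bifurcation` reduces a scan to per-I branch means, gaps and
standard errors.  The threshold I* is the smallest grid point from which
|gap| stays within `gap_tol` (default 2) pooled SEs of zero; a later point
only disqualifies a candidate when it re-opens beyond twice the tolerance,
since with many post-threshold points a pure per-point band would reject
valid thresholds by multiple comparison alone.  The transition is a
discontinuous jump when the branches are still separated by more than
`jump_tol` (default 0.5) × max-gap immediately below I*, a continuous
merge when the gap declines below tolerance with no such step, and
flagged ambiguous when the grid cannot distinguish the two.  The
uncertainty on I* is the local grid spacing.

## 5-FOA survival analysis

The survival fraction of one plate pair is
`S = (N_FOA/d_FOA) / (N_YPD/d_YPD)` with dilution factors in (0, 1]; its
relative error is the Poisson counting error
`sqrt(1/max(N_FOA,1) + 1/N_YPD)`, and a zero 5-FOA count is reported as
the one-colony upper bound rather than zero.  Curves from the two
histories converge at the smallest concentration where the log10 gap is
within `k_se = 2` combined log-scale errors and never significantly
re-separates; the uncertainty is one grid step.  The mutational escape
floor (default 1e-6) is handled by subtraction with flagging.  Steepness
is quantified as orders of magnitude of survival lost per decade of
concentration.  The Hill straw man `A(c) = A_0/(1+(c/K_d)^n)` is provided
to contrast the cooperativity (n ≈ 5–6, K_d of a few µM) that a
single-molecule explanation of the drop would demand with the
non-cooperative in-vitro behaviour (n = 1, IC50 ≈ 60 µM).

## ADE2 pigmentation analysis

Per plate, colony mean RGB vectors are divided by the grand mean over all
channels and colonies, cancelling illumination exactly (the normalized
grand mean is 1).  Each plate is fit with one- and two-component
full-covariance 3-D Gaussian mixtures (EM, tolerance 1e-8, up to 500
iterations, 10 seeded restarts, ridge 1e-6 × mean channel variance; the
fits are scikit-learn `GaussianMixture` behind this module's surface, and
EM's likelihood ascent is exposed through a warm-started per-iteration
trace for the monotonicity check).  A plate is bimodal only if BIC
favours two components *and* the component means are ≥ 2 pooled-covariance
Mahalanobis units apart *and* neither weight is below 0.05 — the
separation requirement is what stops a second component from merely
absorbing non-Gaussian unimodal shape.  The 'off' (silenced, pigmented)
component is the one with the larger red-channel mean.  Branch means are
projected on the leading principal component (uncentred SVD) of the
off-minus-on mean differences, sign-fixed so off minus on is
non-negative.  The merge concentration is the first plate of the final
unimodal run, with one grid step of uncertainty; the transition is
labelled mean-merging when the projected gap has shrunk below 0.6 of its
maximum by the last bimodal plate, and weight-vanishing when the gap
persists while the off weight has fallen below half its initial value.

## Synthetic data: what it emulates, and what it does not

No raw data were deposited, so the pipelines are validated by parameter
recovery on generators that emulate each assay's statistical structure.

**Plate counts.** A two-state population: per generation, off cells
desilence with probability `p_desilence_base + p_max·x/(1+x)` and on
cells establish silencing with probability `p_establish_0/(1+x)`, where
`x = (c/c_star)^s` (c_star = 25 µM, sharpness s = 8 — the minimal family
that reproduces both a ≥ 5-decade drop within one concentration decade
and memory retention below threshold).  Histories start at silenced
fractions 0.999 (LOW) and 0.001 (HIGH); exposure is g = 14 generations
(within the assays' 12–15; 2^14 > 1e4, so pre-existing reporter protein
is fully diluted); off cells survive 5-FOA, on cells only via mutation at
1e-6.  Establishment is rare (1e-5 at c = 0): above threshold the
stationary silenced fraction then sits well below the mutational floor,
matching the observation that high-drug survivors are mutants.  Plating
draws Poisson counts at dilutions auto-adjusted to ≈ 200 expected
colonies.  The 18-point concentration design is 0–60 µM; note 25 µM lies
between the grid points 20 and 30, so the threshold detector's expected
answer is 30 µM with one grid step of uncertainty.

**Colony colours.** Two 3-D Gaussian components around means with the
off component redder, channel noise SD 0.05, lognormal per-plate
illumination (SD 0.1), 200 colonies per plate over 0–15 µM.  In the
pitchfork scenario the mean separation scales as `(1 - c/10)^0.5` (the
supercritical square-root exponent) with fixed weights; in the saddle
scenario the separation is constant while the off weight falls linearly
to zero at 10 µM.

**Scan fixtures.** Gaussian branch ensembles following a linear-merge or
step-jump gap profile, for classifier calibration.

These generators reproduce the statistical *structure* the analyses
assume — not colony growth, pigment chemistry, camera optics, or
plating-volume variability.  Passing recovery tests therefore shows the
pipelines are correct and calibrated under the stated noise models, not
that those models exhaust real-data complexity; in particular the
survival error model is counting error only.

## Numerical choices and degenerate inputs

Sir units are integers, so conservation is exact, not approximate.
Propensity enumeration excludes pinned boundary sites; an all-zero
propensity state is signalled as absorbing rather than advanced.  The
mixture fitter flags plates of identical points as degenerate and
regularizes covariances rather than failing; an exact red-channel tie
between components is broken by total intensity and flagged.  A bimodal
plate reappearing above a unimodal one is flagged and the merge taken at
the start of the final unimodal run.  Classifier and convergence
detectors treat "stays closed" with a 2× re-opening guard (see above).
Every CLI invocation writes a manifest (config hash, seed, versions);
per-stage seeds derive from the global seed by crc32 of
`"<seed>:<stage>"`, masked to 31 bits.

## Problem sizes

Defaults keep every stage desk-scale: hysteresis ensembles of 50 per
history (pre-growth 150 time units) complete a two-point scan in a few
minutes on one core and a full 9-point scan in under ten; the survival
and pigmentation reproductions run in seconds per seed.

## Known limitations

The silenced branch's window occupancy saturates near 0.35–0.40 under
the shipped rates — the titration balance caps the domain well below
full window coverage — so the two branches are distinguished by their
gap (several SEs) rather than by absolute levels near 1 and 0.  The
wild-type rate set is a searched draw, not fitted biochemistry; only its
qualitative behaviour (bistability, memory, closure, continuous merge)
is meaningful.  Classification near the threshold is statistical: on
grids too coarse to separate a fast merge from a jump the classifier
reports ambiguity rather than a label.
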