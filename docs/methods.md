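# Methods

This note records the models, numeric conventions, and design choices
behind `striamap`, and what the synthetic-data validation does and does not
establish.

## Geometry model

A reconstructed neuron is a rooted tree of nodes with position (µm, 3D,
right-handed frame) and radius. The root is the soma, modelled as a single
sphere; a multi-node soma in an SWC file is merged onto its largest-radius
node. Every parent–child pair defines a conical frustum with linearly
interpolated radius. A segment whose parent is the soma node takes the
*child's* radius at both ends: dendrites emerge from the soma at their own
calibre, and the soma's membrane is accounted for by the sphere alone.
(Inheriting the soma radius would create a wide cone overlapping the
sphere, double-counting membrane and pulling shaft-input labels toward the
soma.) Spine branches use a configurable custom SWC type code (default 10;
SWC has no standard spine type) and must attach to shaft nodes.

Membrane areas: soma = 4πr²; shaft and spine = summed lateral frustum
areas π(r₀+r₁)·slant. The three compartment areas add exactly to the total.
Path (geodesic) distance to a point addressed as (segment, arc fraction) is
the sum of segment lengths along the unique root path plus the partial arc.
The dendritic-field diameter is the maximum pairwise distance between node
XY projections — the caliper measurement one would take on a maximum
projection; the z-range is the node z extent. Note the imaging-based
equivalent is measured on the stack between first and last appearance of
any process, which coincides with the node extent only when the
reconstruction spans the stack.

## Edge rule and compartment assignment

A punctum is a sphere (centre, diameter ≥ 1 µm). Its *edge distance* to the
neuron is the minimum over all frusta of (distance from the centre to the
nearest point of the segment axis, minus the local interpolated radius)
minus the punctum radius, with the soma sphere included analogously.
Negative values (overlap) are legal. A punctum is a putative input when
edge distance ≤ 0.5 µm — the threshold is *inclusive*; the boundary case is
retained. This axis-based clearance is exact for cylinders and for sphere
queries, and a very close approximation for gently tapering frusta (taper
in the generated morphologies is < 0.1 µm per 10 µm segment).

Compartment labels follow the subtraction order of the original masking
workflow: an input within threshold of any spine frustum is a spine input;
otherwise within threshold of the soma sphere, somatic; otherwise shaft.
The three labels partition the retained set exactly. Somatic inputs take a
soma path distance equal to their Euclidean offset from the root centre
capped at the soma radius (placing them in the 0–10 µm bin); all others
take the geodesic distance to their attachment point. Densities are
reported per 10 µm² of the compartment's membrane; the conventional
"dendrite" density pools shaft + spine area. (Figure legends elsewhere
sometimes print "contacts per 10 µm"; the computation here, as in the text
it follows, divides by membrane *area*.)

## Spatial statistics

Nearest-neighbour (NN) and colocalization distances are centre-to-centre
Euclidean in 3D, matching spot-to-spot statistics of reconstruction
software; whether geodesic distances would be more appropriate is not
settled, and path distances for every input are available to compute them.
NN statistics are directional (S1→M1 ≠ M1→S1). The cluster criterion is a
cross-channel neighbour within 5 µm; per-cell colocalized fractions are
tested against the 50 % chance level with the normality-gated one-sample
branch. Distance histograms use half-open 10 µm bins [k·10, (k+1)·10);
regions are proximal < 30 µm ≤ medial < 100 µm ≤ distal, i.e. 30 µm falls
in medial and 100 µm in distal. Per-cell summaries are averaged with equal
weight across cells (mean ± SEM over N cells), never pooled over spots.

On an unbranched cable carrying n uniformly placed points, the mean
same-origin NN distance approaches L/(2n): spacings are approximately
exponential with rate n/L and each point's NN is the minimum of two
adjacent spacings. This closed form anchors the NN implementation at n =
215 (within 10 %, dominated by edge effects of order 1/n).

## Electrophysiology

Sweeps follow an 11-step protocol (−500…+500 pA, 100 pA, 500 ms) sampled at
20 kHz. AP events are marked by a slope rule: the threshold is the first
sample whose forward-difference dV/dt reaches 20 mV/ms (configurable) on
the approach to a peak; one event spans one excursion above the threshold
voltage, so double-peaked rises yield a single event with the global
maximum as peak; the AHP is the voltage minimum before the next threshold
(or the step offset). The marking rule is this package's own — published
workflows delegate it to feature-extraction libraries without stating one.

HHW resamples the threshold→AHP window onto 1,000 evenly spaced points by
linear interpolation and measures the time between first rising and last
falling crossing of threshold + amplitude/2, refining each crossing
linearly between resample points. On piecewise-linear templates the error
is bounded by twice the resample step. ISI is the difference of consecutive
threshold times; IFF = 1000/ISI (Hz); MFF = max IFF; IFF·ISI ≡ 1000 by
construction. Steady-state firing requires ≥ 4 events and a coefficient of
variation of the last half of the ISIs below 0.25.

Passive properties (unstated in the source workflow, defined here): RMP is
the mean voltage over the 50 ms before step onset averaged across sweeps;
input resistance is the least-squares slope of steady-state ΔV (last 10 %
of the step) against injected current, in MΩ. Classification uses mean HHW
and mean IFF at steady state with cuts at 0.8 ms and 50 Hz — midway between
the SPN and FSI group means — returning AMBIGUOUS off the two diagonal
quadrants or without steady state. No liquid-junction correction anywhere.

## Test selection

Every comparison first gates on Shapiro–Wilk normality at α = 0.05 (the
gate's α is a choice; sources rarely state it). Normal unpaired data take
an F-test on variances (two-sided) and then Student's or Welch's t; normal
paired data a paired t; one-sample designs a one-sample t against the null
value (1 for ratios, 50 for percent-chance). Any non-normal group routes to
Mann–Whitney U, Wilcoxon signed-rank, or the one-sample Wilcoxon. Levene's
test (median-centred) serves variance comparisons between cell types. The
full decision trail (normality and variance p-values) is recorded in each
result. Simulated under matched normal and heavy-tailed nulls at n = 12 vs
7, the selector's type-I error stays within [0.04, 0.06] at α = 0.05 over
10,000 replicates. Two-way repeated-measures ANOVA is a thin pass-through
to `statsmodels` AnovaRM.

## Synthetic data: what it emulates

Generator defaults are the published group means for the two cell types:

| parameter | SPN | FSI |
|---|---|---|
| primary dendrites | 5 | 7 |
| soma diameter (µm) | 14.08 | 17.86 |
| field diameter (µm) | 256.1 | 242.0 |
| z-range (µm) | 60.49 | 67.49 |
| expected M1+S1 inputs | 352.4 | 309.6 |
| M1 fraction mean (SD) | 0.6166 (0.0882) | 0.5505 (0.2188) |
| compartment probs (spine, shaft, soma) | 0.6046, 0.1641, 0.2313 | 0, 0.7921, 0.2079 |
| S1-near-M1 probability | 0.7807 | 0.5465 |
| HHW (ms) / ISI (ms) | 1.282 / 42.11 | 0.4043 / 13.65 |
| R_in (MΩ) / RMP (mV) | 117.7 / −75 | 108.6 / −67.94 |

The between-cell SD of the M1 fraction is the reported SEM·√N. It is not a
free dial: the group mean proportion (61.66 %) and the group mean of
per-cell ratios (1.802) are jointly consistent only with between-cell
spread (Jensen's inequality: 0.6166/0.3834 = 1.61 < 1.80), and this SD
reproduces both. Cohort simulations pin each cell's fraction to stratified
quantiles (i+0.5)/n of that distribution rather than i.i.d. draws — a
variance-reduction design that leaves the planted distribution unchanged
while making a 12-cell cohort a balanced sample of it instead of a noisy
resample. Channel counts are Poisson around the per-cell means (a
fixed-count mode exists for exact bookkeeping tests) so SEM behaviour
across simulated cells mimics between-cell variability.

Morphologies grow by a seeded stochastic branching walk (10 µm steps,
angular jitter, bifurcation probability per step, radius taper), rescaled
in XY to the exact target field diameter and in z to the target depth;
spine tips may extend a few µm past the shaft envelope. Spines (SPN only)
are single-node branches with calibre inside the 0.6–2.5 µm detection
bounds, placed only on shafts distal to the first branch point, matching
where spines are prominent on these neurons. Inputs sample a compartment
from the placement probabilities and a uniform area-weighted surface
location with edge offset uniform in [−0.2, +0.5] µm. With probability
`p_cluster` an S1 input relocates onto the membrane within 5 µm (Euclidean)
of a random M1 input; the remainder is rejection-sampled beyond 5 µm of
every M1 input (the compartment is redrawn on each rejection try — a
saturated soma would otherwise make the condition unsatisfiable and bias
the planted fraction). Setting `subtract_chance_coloc=False` keeps the
remainder plain-uniform with its natural chance level of proximity.
Background puncta are placed uniformly in the padded bounding volume at
0.045 per 1000 µm³ (≈ one-third of raw spots rejected by the edge filter,
qualitatively matching dense neuropil; exposed in config) with edge
distance forced > 1 µm. VGLUT1 validation spots colocalize with a random
~20 % subset of inputs.

Sweep templates are piecewise linear (threshold → peak → AHP → recovery)
with threshold and peak vertices snapped to the 20 kHz grid, so the
sampled trace represents the planted waveform exactly and HHW/ISI round
trips are limited only by interpolation (< 2·window/999 ms). Planted ISIs
snap to the 0.05 ms grid (≤ 0.2 % shift). Subthreshold sweeps settle
exponentially (τ = 15 ms) to ΔV = I·R_in.

**What passing recovery tests does not show.** The generator plants
spherical puncta on an idealized tree with independent placements; real
data carry ellipsoidal spots, reconstruction errors, spatially correlated
background, undetected synapses (the VGLUT1-validated detection rate is
~20 %), and z-anisotropic localization error. Recovery here validates the
*measurement pipeline* — filtering, geodesics, partitioning, NN statistics,
feature extraction — not the biological detection process upstream of it.

## Numerical choices and degenerate inputs

Seeds: all randomness flows through `numpy.random.default_rng` seeded per
cell and per stage (seed lists keep streams independent); identical seeds
give byte-identical SWC/CSV/JSON outputs. Simulation sizes in the test and
acceptance runs (12 SPNs, 7 FSIs, 20-cell partition audits, 10,000-replicate
selector calibration, 50-repetition NN cable) complete in about a minute
each on one core. Degenerate inputs are flagged or raised, never silently
zeroed: fewer than two APs leaves ISI-derived features undefined; a cell
with no S1 inputs has an undefined ratio; empty query sets make
colocalized fractions undefined; zero-variance groups under a t-branch and
zero membrane areas raise explicit errors; chance tests are skipped below
three cells. Boundary conventions — inclusive 0.5 µm edge rule, half-open
bins, 30 µm → medial, 100 µm → distal — are fixed in `AnalysisConfig`.

## Known limitations

* Frustum clearance uses the nearest axis point with interpolated radius
  (exact only for cylinders); error is second-order in taper.
* The z-range is a node statistic, not a stack statistic.
* Geodesic cluster distances are available but not the default report.
* The AP marking rule is a reasonable stand-in for library-based marking,
  not a reimplementation of any specific one; thresholds are exposed.
* The generator's branching walk is statistical, not biophysical; it
  matches first-order morphometrics (primaries, field, depth, calibre
  bounds), not branch-angle or Sholl structure.
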