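# Methods

## The snapshot-to-profile model

In steady exponential growth with binary division, the density of cells over
cell-cycle age `a ∈ [0, 1)` (in units of the cycle time Tc) is
`g(a) = 2 ln2 · 2^(−a)`: newborns are twice as frequent as dividing cells.
The cumulative fraction of cells younger than `t` is `F(t) = 2(1 − 2^(−t))`.
A single fixed-time measurement of such a population therefore samples every
cell-cycle position, with sampling weight `g`.

If a marker's expression is a single-valued function of cycle position along
a connected, unidirectional trajectory through measurement space, then
ordering the population along that trajectory and cutting it into contiguous
regions recovers the expression program: region `i` with cell fraction `f_i`
is plotted at `x_i = Σ_{j<i} f_j + f_i/2` with the within-region median as
its center statistic. `x` is cumulative cell frequency, a monotone surrogate
for time; `frequency_to_time(x, "age_corrected") = −log2(1 − x/2)` converts
it exactly to normalized time under the age distribution above. Profiles
keep the raw-frequency axis by default (the convention in which results are
usually plotted); the division-doubling wrap (one M cell → two G1 cells) is
deliberately not corrected.

Two constraints govern region design:

1. **Unidirectionality.** Within any view used for segmentation, earlier and
   later cells must not overlap in the same place. A DNA-vs-mitotic-marker
   view violates this (PHH3 rises and falls at constant 4C DNA); adding a
   mitotic cyclin resolves it.
2. **Statistical irreducibility.** Where expression is constant (the G1
   cluster, mitotic plateaus) the data spread is measurement error only;
   such clusters must be enclosed by single regions, because slicing them
   produces ordered noise quantiles that masquerade as expression change.

## Synthetic study conditions (`flowworm.synth`)

The default `PhaseModel` emulates an asynchronous, exponentially growing
lymphoblastoid (Molt4-like) culture stained for DNA, cyclin A2, cyclin B1,
PHH3, side scatter and pulse width.

- **Phase time fractions** G1/S/G2/M = 0.28/0.47/0.19/0.06, giving
  age-weighted event occupancies of ≈35% G1, ≈46% S, ≈15% G2 and ≈4.3% M —
  a fast-cycling culture whose G1 frequency (~0.35) and mitotic frequency
  (~4%) match the regimes the method is typically applied to.
- **DNA**: constant 2C (=100) through G1, linear 2C→4C across S, constant 4C
  after; the 4C/2C ratio is exactly 2 by construction.
- **Cyclin A2**: zero through G1; from the G1/S boundary a second-order
  polynomial rise (0→90) over early S, an exponential rise (90→300) through
  late S/G2; an abrupt decline to a prophase plateau (210) at mitotic entry;
  steep exponential degradation to a floor of 2 completed at u = 0.975.
- **Cyclin B1**: low but nonzero (8) in G1, beginning accumulation at
  u = 0.25 (before A2); a slow exponential (k≈3.6) to 40 through S, then a
  fast exponential (k≈9.0) to 320 through G2 — the two-rate structure the
  trend fits must recover, with B1 the "more exponential" cyclin; entry dip
  to 260, plateau, degradation to floor 3 completed at u = 0.9875.
- **PHH3**: baseline 5 through interphase; a smooth 20× rise across late
  G2/mitotic entry (u 0.88–0.9475); plateau at 100; dephosphorylation from
  u = 0.9825 ending the cycle at 30 — still 6× baseline at cytokinesis, so
  no late-mitotic cell ever falls below a mitotic gate threshold. Newborn G1
  cells restart at baseline: the generator is a one-generation snapshot with
  no inheritance model.
- **Degradation order** (asserted on the curve definitions):
  A2 floor (0.975) < B1 floor (0.9875) < PHH3 decay completion (~0.998).
- **Noise**: multiplicative log-normal, mean 1, per-channel CV
  (DNA 3%, immunofluorescence 12%, SSC 15%, pulse width 5%).
  Immunofluorescence is approximately log-normal; zero noise reproduces the
  curves exactly.
- **Replicates** (`sample_replicates`): independently stained samples of one
  culture carry per-channel staining gains (log-normal, CV 1.5% for the DNA
  dye, 3% for antibodies) on top of sampling error — replicate data contain
  staining error as well as sampling error, and replicate CIs are
  meaningless without it.
- **Doublets** (optional): G1–G1 aggregates with doubled pulse width and
  summed fluorescence, for preprocessing tests. The pulse-width curve also
  rises to 1.8× in late mitosis, so elongated telophase/cytokinetic cells
  fall outside the singlet gate and must be restored via the mitotic gate.

The DNA-histogram generator (`make_dna_mixture`) builds one G1 and one G2+M
Gaussian (SD = CV×mean) plus `n` equal-area S components whose means are
evenly spaced between the bounding clusters' ±3 SD edges (SDs interpolated
between the bounding SDs). Spacing S components clear of the terminal
clusters' measurement variation is what makes "terminal regions enclose the
bounding clusters" a consistent convention; `margin_sd=0` restores spacing
over the full open 2C–4C interval.

### What the generator does *not* emulate

Spectral spillover between fluorochromes, acquisition-time drift, debris,
cell-to-cell growth-rate variability, endoreduplicating sub-cycles,
inheritance of marker levels across division, and non-log-normal outliers.
Passing tests therefore demonstrate the correctness of the frequency
bookkeeping, geometry and statistics — not robustness to every artifact of
real list-mode data.

## Preprocessing (`flowworm.preprocess`)

Contour gates are level sets of a binned kernel density estimate (128×128
histogram smoothed with a Silverman-rule Gaussian): the smallest density
region containing the stated percentage of probability mass. The singlet
gate additionally keeps only the level-set component containing the global
mode, so a detached aggregate blob is excluded regardless of the enclosed
mass level. The mitotic gate thresholds PHH3 at the midpoint of the density
valley floor between the interphase and mitotic modes (far more
sample-stable than the literal minimum of a flat valley); a manual override
is supported. Background subtraction fits a Theil–Sen slope β of cyclin on
SSC within G1 reference cells (2C cluster, mode + 2 robust SD) and subtracts
β·SSC from all events; β < 0 is clamped to zero. Theil–Sen pairs are thinned
deterministically to ≤2000 points (the estimator is O(n²)). The final gate is
`((R2 AND R4 AND R5) OR R3)`.

## Scheme construction (`flowworm.pipeline.build_cycle_scheme`)

The analyst layer for a cyclin-vs-PHH3 panel, operating in asinh display
coordinates (cofactor 5):

- **Sections.** Interphase (NOT mitotic) runs from the G1 cluster up the
  cyclin accumulation stretch; a *pre-mitotic rise* leg (cyclin high, PHH3
  above interphase noise but below the mitotic gate) covers the worm's
  upward bend that a cyclin-ordered backbone cannot see; mitosis is split
  into three sub-gated legs — PHH3 rise (cyclin high), the top run (ordered
  by descending cyclin: entry dip, plateau, degradation), and the fall
  (cyclin below its floor-cluster edge, ordered by descending PHH3).
  Sub-gating makes the legs disjoint by construction and each leg's backbone
  nearly straight.
- **Backbones** are quantile-binned median ridges of the leg's events,
  smoothed and extended 3σ beyond the data at both ends so terminal regions
  enclose the bounding clusters' full measurement variation.
- **Boundaries** sit on a uniform arc grid at pitch
  `max(2.2·σ_perp, share of the leg)`; intervals holding fewer than 50
  events are merged into their smaller neighbour, and adjacent intervals
  whose median arc positions differ by less than 1.5× the log-scale marker
  noise (measured once on the interphase PHH3 cluster) are merged — slices
  of a static cluster separate by ≈1.35σ, real motion by the full pitch, so
  this implements the irreducibility rule operationally. The G1 cluster is
  always one region, its edge at the cyclin mode + max(2 robust SD, 0.15).
- **Widths**: half-width per leg from the 99.7th percentile of perpendicular
  residuals, with an automatic 0.7× retry if high curvature makes dividing
  sides cross.
- **Region polygons** are consecutive quadrilaterals with dividing sides
  perpendicular to the local backbone tangent; shared sides reuse the same
  vertex pair, so neighbouring regions can neither overlap nor gap. Events
  on a shared edge are assigned to the earlier region (regions are tested in
  global order; `shapely.covers` makes the boundary inclusive).
- **Boundary points**: synthetic points are extrapolated at x = 0 and 1 and
  at stretch junctions (G1 edge, gate-context changes), but only where the
  local frequency gap is wide relative to neighbouring point spacing and
  each side's support points are spaced more tightly than the gap —
  elsewhere extrapolated points only amplify local estimation noise.

Typical output under the default study conditions (50k events): 30–35
regions, zero overlap area, <1% of gated events unassigned, median true
position strictly increasing with global order, and relative RMSE against
the programmed curves ≤5% of each channel's dynamic range for DNA, both
cyclins and PHH3 (DNA and cyclin B1 read indirectly).

## Numerical choices

- Center statistic: median within regions; mean of medians across
  replicates, with SEM and t-based 95% CI.
- The direct 1-D DNA route estimates the 2C/4C clusters by smoothed-histogram
  modes and mirrored MADs; nine contiguous intervals with the terminal pair
  at ±3 SD. (The constrained EM fit is not used for boundary placement: on a
  continuous S ramp it converges too slowly for what is a two-moment
  problem.)
- The multi-Gaussian EM (`fit_multigaussian`) holds the S components on a
  fixed lattice (free areas, free bounding components) by default; freeing
  all parameters is supported but the interior components are then barely
  identifiable and EM needs thousands of iterations to settle, although the
  bounding-cluster areas still converge correctly.
- Exponential trend fits are nonlinear least squares seeded by a log-linear
  fit; segment "rates" for comparisons are mean logarithmic slopes over the
  fitted domain, with near-zero endpoints floored. The onset threshold
  (2% of the fitted maximum) sits below cyclin B1's basal-to-peak ratio so a
  cyclin with measurable basal expression registers onset where accumulation
  begins.
- Frequency bookkeeping under boundary perturbation: moving the boundary
  between the first two segments by fraction δ shifts those two centers by
  δ/2 and leaves all later x unchanged; admitting extra front mass δ
  rescales downstream centers as `x' = (δ + x)/(1 + δ)`. Early-region
  placement therefore propagates into the whole curve exactly through these
  identities — the reason the G1-region boundary is the most sensitive
  analyst choice.
- All randomness flows from explicit integer seeds; reruns are
  byte-identical.

## Known limitations

- **View-blind windows.** When both channels of a view are statically
  expressed over some stretch (e.g. cyclin A2 floored while PHH3 has not yet
  measurably decayed), that view cannot order cells there; the profile
  chords across the window. A panel carrying a still-changing channel
  resolves the same stretch, so independently measured panels can disagree
  locally by ~10% of a channel's range at such windows even though both are
  individually faithful. Merging panels through a shared channel is
  validated by ordering and by visual/quantitative agreement, but a strict
  global max-deviation band of a few percent is not attainable with
  hard-region segmentation at 12% measurement CV.
- Region medians at the first/last slab of an ordered stretch carry a
  noise-selection bias of order half the measurement SD when a denser
  adjacent state leaks events across the ordering threshold.
- Automatic backbone tracing assumes a connected ridge; strongly
  multi-modal views require manual anchors (supported, and the normal mode
  of use in practice).
- The gate-context formulas of a saved scheme reference per-sample masks
  (mitotic gate, leg splits); applying a scheme to a new sample requires
  recreating those masks with the recorded thresholds.
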