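# Methods

This note documents the statistical machinery in `ptmrhythm`: the models
and tests, the parameters that matter, what the synthetic-data generator
does and does not emulate, and the numerical and design choices made where
the design was genuinely open.

## Study design assumed throughout

Time-course tables follow a zeitgeber-time (ZT) sampling design: one 24-h
day–night cycle sampled every 4 h (ZT3, 7, 11, 15, 19, 23) with 3
replicates per timepoint, and a two-timepoint site-level design (day ZT11
vs night ZT23, 4 replicates) for feeding-regime comparisons. Time always
lives on a 24-h circle; positions are 1-based residue indices, matching
proteomics site nomenclature. Missing values are explicit and propagate —
no stage imputes.

## Synthetic-data generator

The generator is the test bed for every stage; no generative model for
these data exists in the upstream literature, so the one used here is an
explicit stand-in, chosen for positivity and right-skew:

    y = B · (1 + a·cos(2π(t − φ)/24)) · exp(ε),  ε ~ N(0, σ²)

- `B` lognormal across features (`baseline_log_mean` 7.0,
  `baseline_log_sd` 1.0, arbitrary abundance units);
- `a` uniform on `rel_amplitude_range` (default 0.3–0.8, unitless; capped
  at 1 so the mean never goes negative, `a = 0` for arrhythmic features);
- `φ` uniform on [0, 24) hours by default;
- `σ = noise_sd` (default 0.2, log scale), multiplicative lognormal noise;
- optional Poisson sampling for count-like data.

Defaults mirror the target study's conditions: 30% of features rhythmic,
6×3 design, noise comparable to replicate scatter in TMT/label-free data.
"Low-noise" end-to-end runs use `noise_sd = 0.1`.

One global seed spawns per-operation substreams keyed by a stable hash of
the operation name, so adding a stage never perturbs another stage's
draws, and the same seed is bit-reproducible across platforms.

Specific emulations:

- **Capture pairs** (identification): true O-GlcNAc features appear in the
  labeled table at `capture_efficiency`×signal and in the no-enzyme
  control at `background_rate`×signal; decoys sit at background in both.
  Setting the rates equal produces the exchangeable null used for
  calibration.
- **Site universe** (crosstalk): random 120-residue proteins carry planted
  glyco/phospho site pairs at chosen residue distances (1–10 aa) with
  planted phase offsets. Planted phases sit on the sampling grid — locked
  pairs share a peak (Δφ = 0), shifted pairs are offset 8 or 12 h —
  because phase estimates are grid-valued and off-grid planting would make
  class recovery ill-posed at 4-h sampling. Background proteins carry a
  proximal decoy pair that is arrhythmic on both sides, with rhythmic
  background sites only at distant (>10 aa) positions: under a per-site
  FDR gate, pair-level precision is only well-defined when a false pair
  requires two false gates (a truly rhythmic site with an arrhythmic
  proximal partner would otherwise produce "false" pairs at the FDR rate).
  Interplay motifs are written into dedicated sequence windows clear of
  all site positions.
- **Feeding regimes**: every feature gets a 60% day–night difference under
  night-restricted feeding; under day-restricted feeding a planted
  fraction inverts the day–night ratio, a fraction dampens to 5% (below
  the 20% differential threshold), and the rest are unaltered.

What the generator does **not** emulate: peptide/spectrum-level structure,
shared peptides and protein inference, missingness beyond
missing-completely-at-random, batch effects, and waveforms other than
cosines (except the test suite's sawtooth constructions). Passing tests
therefore demonstrate correctness of the statistical chain under the
stated model, not robustness to every artifact of real mass-spectrometry
data.

## Rhythm detection

Both detectors are rank-based (invariant under strictly monotone
transforms of abundance) with the period fixed at 24 h — the designs
analyzed cover a single day–night cycle, so period scanning is out of
scope.

**JTK-style test.** For each candidate peak phase the reference is the
rank pattern of `cos(2π(t − φ)/24)` evaluated at each sample's timepoint
(replicates inherit their timepoint's reference rank); the statistic is
the maximum Kendall τ_b over the phase grid. The default grid is hourly:
at 4-h sampling, neighboring hourly phases still differ through the
reference's tie structure (ties arise exactly when the phase bisects two
sampling times), so peaks between samples are resolvable; ties in the
argmax resolve to the earliest phase.

**Umbrella test.** For every circular (peak, trough) layout, groups are
reordered from just after the trough around to the trough, and the
Mack–Wolfe umbrella statistic sums Mann–Whitney counts up the rising limb
and down the falling limb. Scanning all troughs, not just the antipodal
one, is what lets the test follow asymmetric waveforms. Per-layout
statistics are studentized against the permutation sample (max-T) before
the max, so neither unbalanced group sizes nor the layout count biases
peak selection. In paired simulations at the 6×3 design the umbrella test
matches or beats the cosine-reference test on slow-rise/fast-fall
sawtooths at moderate noise and recovers their peaks far more accurately;
at high noise the cosine test's smaller selection space can win.

**Permutation null.** Values are shuffled across samples (10,000 shuffles
by default, seeded) and the max statistic recomputed per shuffle, so the
selection over phases/layouts is inside the null and needs no further
correction. Designs with ≤ 8 samples switch to exact enumeration of all
orderings. Because both statistics are discrete, the default p-value uses
a seeded randomized tie-break, which is exactly uniform under
exchangeability; `tie_break="conservative"` gives the standard
`(1 + #{null ≥ obs})/(B + 1)` upper bound. A completely tied series
short-circuits to p = 1. Features sharing the complete-case design share
one seeded permutation set (their p-values remain independent, since each
feature's null statistics depend only on its own values); features with
missing samples get per-feature engines and need ≥ 4 values spanning ≥ 3
timepoints.

**Multiple testing.** Benjamini–Hochberg step-up q-values (via
statsmodels); the rhythmic gate is strict `q < 0.2`. The amplitude proxy
is (max − min of per-timepoint medians) / overall median.

**Phase resolution.** Estimated phases are grid-valued with ±1–2 h error
even at low noise. Consequently, phase-relation classes whose planted
difference sits exactly on an inclusive boundary (Δ = 0 against the 2-h
lock boundary under noise, or Δ = 8 exactly) can be called
"intermediate"; locked and shifted plants never swap, and antiphase pairs
(Δ = 12) classify unambiguously.

## Identification

Pooled equal-variance two-sample t across all timepoints per side
(maximizing degrees of freedom for a global "is this protein
O-GlcNAcylated" call), two-sided p with a direction requirement (labeled
mean > unlabeled). Degenerate inputs follow fixed contracts: zero pooled
variance with equal means gives t = 0, p = 1; with unequal means the call
is made and p is reported below machine precision (logged). Under the
exchangeable null the directional call rate is nominally α/2 = 2.5%;
with lognormal noise at n = 18 per side the observed rate runs slightly
conservative (≈1.5–2.2% in calibration runs).

## Normalization

Three rules, applied in the fixed order input-amount → channel-sum →
protein-level:

1. **Channel sum (TMT).** Each channel scaled so its summed abundance
   equals the mean of the original channel sums. In the pipeline the
   factors are computed on the deep proteome run and re-applied to the
   PTM tables from the same channels: deriving factors from a small PTM
   table itself lets strong shared rhythms leak inverted rhythms into
   flat features (composition bias).
2. **PTM-to-protein.** Cell-wise division by the master protein's
   abundance per sample, removing protein-level rhythm so PTM rhythm
   reflects modification stoichiometry. Unquantified proteins: values
   pass through unchanged, flagged `normalized = False`. Zero or missing
   denominators yield missing cells (logged), never infinities.
   Single application is enforced through the report flag.
3. **Input amount (label-free).** Counts divided by per-sample input
   protein mass; amounts must be positive and complete. Applied before
   background subtraction by default (the alternative order is a
   configurable choice; the two compositions do not commute).

## Day–night calls and feeding regimes

The symmetric fold `100·(max(r, 1/r) − 1)`, `r = night/day` of the
per-timepoint means, must strictly exceed 20%; the ratio convention is
symmetric so swapping day and night flips direction but preserves the
fold. A Student t p-value is reported alongside; gating on it is off by
default because the differential-site counts are defined by the fold
criterion, and a `p_gate` config turns co-gating on. Zero means make a
site not-evaluable. The five regime classes (inverted, dampened,
unaltered, emergent, absent) partition all outcomes of the two
differential flags and directions. Global regime comparison reports the
medians of per-sample mean signal and an equal-variance t p-value.

## Crosstalk inference

Phase difference is the circle metric folded to [0, 12]; class boundaries
are inclusive exactly as defined (locked ≤ 2 h, shifted ≥ 8 h). Proximity
is |Δposition| ≤ 10 residues on the primary sequence (no structural
distance), distance 0 labeled same-site competition. Motif patterns are
input data, not hard-coded (the shipped defaults are archetypes: same-site
Ser/Thr-Pro competition, a proximal S/T pair, and a PV-context same-site
motif); patterns support exact residues, residue classes, wildcards, and
fixed repeats, and matches report both implied acceptor positions,
flagged when they coincide with observed sites. Phosphosite flanks are
15-mers ('-'-padded at termini; the flank length is a package choice).
Kinase selection is the intersection of three filters: motif match on ≥ 1
substrate flank, the kinase's own rhythm at q < 0.2, and circular phase
within ±4 h of the substrate phase (the window is configurable; no
quantitative standard exists for "phase-matched"). Protein-level
O-GlcNAc phases (label-free capture is protein-level) pair against
site-level phosphorylation phases; for two-timepoint TMT site data,
day–night direction concordance replaces phase.

## Complexes

Complex membership is reported, not enrichment: every complex with ≥ 1
rhythmic member, ordered by descending rhythmic-member count; a protein in
k complexes appears k times (overlapping-complex semantics). A
hypergeometric enrichment option is a documented extension, off by
default. Mean complex profiles are missing-aware per-timepoint averages
over member traces.

## Pipeline and reproducibility

All thresholds live in one YAML config (alpha 0.05, q 0.2, fold 20%,
lock 2 h, shift 8 h, proximity 10 aa, kinase window 4 h, permutations
10,000); CLI flags override. Every run writes a manifest (config
snapshot, seed, per-stage counts) and reruns under the same seed are
byte-identical; logs record feature counts in/out and thresholds at every
filter. Problem sizes in the shipped verification runs — 2,000 features ×
2,000 permutations for null calibration, 400 features for recovery, a
40-protein universe with 20 planted pairs end-to-end — keep full runs in
the tens of seconds while leaving Monte-Carlo tolerances comfortably
inside the asserted bounds.

## Known limitations

- The umbrella test is an openly documented approximation in the spirit
  of published umbrella-alternative detectors, not a re-implementation of
  any released package's internals.
- Phase classes at inclusive boundaries are resolution-limited (above).
- The generator's independence assumptions (no shared peptides, no
  correlated noise between sites beyond the shared protein denominator)
  make the planted-truth precision/recall results upper bounds on
  real-data performance.
- The t-based identification assumes roughly symmetric noise on each
  side; heavy skew at small n makes it mildly conservative.
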