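# ptmrhythm

Daily-rhythm detection and O-GlcNAc–phosphorylation crosstalk inference
for time-course PTM proteomics.

## The problem

Nutrient-sensitive post-translational modifications couple feeding–fasting
cycles to daily protein function. In liver nuclei, O-GlcNAcylation of
transcriptional regulators oscillates over the 24-h day–night cycle and
interacts with phosphorylation — competing at the same Ser/Thr residue or
inhibiting modification of nearby residues. Quantifying this requires a
chain of post-processing steps on label-free capture and TMT
mass-spectrometry tables: background-controlled identification,
normalization of PTM signals to protein abundance, nonparametric
rhythmicity testing with peak-phase estimation, day–night differential
calling under altered feeding regimes, and glycosylation–phosphorylation
(G–P) crosstalk inference from phase relations, residue proximity,
interplay motifs, and phase-matched kinases.

`ptmrhythm` implements that chain as a tested, reusable pipeline for
proteomics analysts. A first-class synthetic-data generator plants known
rhythms, crosstalk pairs, and motifs, so every stage is verifiable
end-to-end without any raw mass-spectrometry data.

## Methods at the core

**Signal model (synthetic data).** Abundance follows a relative-amplitude
cosine with multiplicative lognormal noise,

```
y = B · (1 + a·cos(2π(t − φ)/24)) · e^ε,   ε ~ N(0, σ²),
```

with baseline `B` lognormal across features, relative amplitude
`a ∈ (0, 1]` (`a = 0` for arrhythmic features), and peak phase `φ` in ZT
hours.

**Rhythm detection.** Two rank-based detectors with seeded permutation
nulls (period fixed at 24 h):

- *JTK-style max-tau test*: Kendall τ_b of the observed values against the
  rank pattern of a phased cosine, maximized over an hourly phase grid;
- *umbrella test*: a Mack–Wolfe umbrella statistic over every circular
  (peak, trough) layout, max-T studentized, which tracks asymmetric
  rise/fall waveforms.

The max-over-candidates selection is absorbed into the permutation null
(shuffle values across samples, recompute the max), so no extra
multiplicity correction is needed across phases. p-values are
Benjamini–Hochberg adjusted; downstream stages gate at `q < 0.2` (strict).

**Identification.** Labeled capture vs no-enzyme control compared by a
pooled two-sample Student t test (`p < 0.05`) with a direction requirement
(labeled mean > unlabeled mean).

**Normalization.** TMT channel-sum factors computed on the proteome run
and re-applied to PTM tables; cell-wise division of each PTM feature by
its master protein's abundance (pass-through with a `normalized = False`
flag when the protein was not quantified); label-free counts divided by
per-sample input amounts.

**Day–night and regime comparison.** Two-timepoint (ZT11/ZT23) site data
are differential when the symmetric fold change `100·(max(r, 1/r) − 1)`
with `r = night/day` strictly exceeds 20%; NRF-vs-DRF feeding regimes are
classified per site as inverted / dampened / unaltered / emergent / absent.

**Crosstalk.** Circular phase difference `min(|Δ|, 24 − |Δ|)`;
phase-locked when ≤ 2 h, phase-shifted when ≥ 8 h (both inclusive);
same-protein site pairs within 10 amino acids (inclusive; distance 0 =
same-site competition); interplay-motif scanning over FASTA sequences; and
kinases passing a triple filter (motif match on the phosphosite flank, own
rhythm at `q < 0.2`, circular phase within ±4 h of the substrate).

## Worked example

```python
import numpy as np
from ptmrhythm import simulate as sim, rhythm as rh, crosstalk as ct

params = sim.SimParams(n_features=200, frac_rhythmic=0.3, noise_sd=0.2, seed=7)
table, truth = sim.simulate_timecourse(params)          # 6 timepoints x 3 reps
results = rh.rhythm_scan(table, method="jtk", n_perm=2000, seed=7)
hits = rh.gate_rhythmic(results, q_cutoff=0.2)
print(f"features: {len(results)}  rhythmic at q<0.2: {len(hits)}  "
      f"planted: {int(truth.rhythmic.sum())}")

est = results.set_index("feature_id").loc[truth.loc[truth.rhythmic, "feature_id"], "phase"]
err = np.abs(est.to_numpy() - truth.loc[truth.rhythmic, "phase"].to_numpy())
print(f"median phase error: {np.median(np.minimum(err, 24 - err)):.2f} h")

d = ct.phase_difference(20, 8)
print(f"phase_difference(20, 8) = {d} h ->", ct.classify_phase_relation(d))
```

prints

```
features: 200  rhythmic at q<0.2: 71  planted: 60
median phase error: 0.48 h
phase_difference(20, 8) = 12 h -> phase-shifted
```

60 planted rhythms are all recovered plus 11 false calls among 140
arrhythmic features — an observed false-discovery proportion of 11/71 ≈
15%, inside the q < 0.2 gate's guarantee. Median peak-phase error is well
under the 2-h half-grid resolution of 4-h sampling. A protein
O-GlcNAcylated with peak ZT20 whose phosphosite peaks at ZT8 is antiphase
(Δ = 12 h), a phase-shifted — i.e., potentially antagonistic — G–P pair.

The same stages are available from a shell:

```
ptmrhythm simulate --out data --seed 3
ptmrhythm run-nrf --in data --out results_nrf --seed 3
ptmrhythm run-regimes --in data --out results_regimes --seed 3
```

`run-nrf` writes identification, rhythm, crosstalk-pair, motif, kinase and
complex tables plus a `manifest.json` recording the config, seed, and
per-stage feature counts; reruns with the same seed are byte-identical.

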