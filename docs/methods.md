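# Methods

`ciliaquant` implements the quantitative analysis stack of a cilium-homeostasis
study in mouse kidney epithelial (IMCD3-type) cells: a spectral-counting
proximity-interactome pipeline, a live-imaging cilium disassembly kinetics
engine, quantitative-immunofluorescence measurement rules, epithelial-spheroid
scoring, and the replicate-aware statistics that tie them together. This note
records the models, the parameters that matter, and the design choices made
where the procedures left the design open.

## Proximity-interactome pipeline (`ciliaquant.interactome`)

BioID experiments compare streptavidin pulldowns from cells expressing a
bait-fused biotin ligase against a ligase-only control, each with two
biological and two technical replicates per serum-stimulation time point.
The pipeline works entirely on peptide-spectrum-match (PSM) counts:

1. **NSAF.** `NSAF[p, r] = PSM[p, r] / Σ_q PSM[q, r]` — each protein's share
   of a run's total spectra. Note this is the run-normalised form *without*
   protein-length normalisation; each run's NSAF column sums to 1, which is
   asserted to 1e-9. NSAF is computed on the full table before any filtering,
   so exclusions never change the denominators.
2. **Low-evidence exclusion.** A protein is *present* in a run when PSM ≥ 1
   (no spectral-count floor beyond detection). Removed are proteins present
   in no bait run (control-only) or in exactly one technical replicate of the
   bait condition, counted across all bait runs of the time point. A
   per-biological-replicate variant of the rule would be stricter; the
   literal global reading is the default.
3. **Fold change.** Within each biological replicate, technical-replicate
   NSAF values are averaged before the bait/control ratio (the
   least-informative merge; a mean-of-per-replicate-fold-changes strategy is
   available behind `tech_rep_strategy`). The enrichment score is the mean of
   log2 fold changes over biological replicates, defined only for proteins
   present on the bait side of both. A zero control NSAF is replaced by the
   smallest nonzero control NSAF of that replicate and flagged — this keeps
   bait-specific proteins while avoiding infinite ratios.
4. **High-confidence filter.** Retained iff avg log2FC ≥ 1 *and* the
   contaminant-registry percentage, when known, is ≤ 50%. Both comparisons
   are strict in the removal direction, so boundary values (log2FC exactly 1,
   contamination exactly 50%) are retained. Proteins absent from the registry
   are retained: CRAPome-style registries are incomplete, and only a *known*
   high contamination score is evidence against a protein.

Every input protein ends up exactly once in the audit trail (first removing
rule, or `retained`); the retained and removed sets partition the input, and
the filter chain is monotone in both thresholds (property-tested).

## Disassembly kinetics (`ciliaquant.kinetics`)

Input: per-cilium length traces sampled every 4 min for up to 6 h (µm).

* **Deciliation rate** = (initial length − final length) / elapsed hours,
  always over the full trace. This makes rate × duration ≡ net decline to
  1e-9 by construction.
* **Ectocytosis events**: a frame-to-frame decrease ≥ `drop_floor`
  (default 0.25 µm, ≈5× the simulator's typical 0.05 µm measurement noise)
  that is not the terminal whole-cilium loss. Shed size = the single-frame
  decrease (released pieces leave between frames). Size < 0.5 µm → vesicle;
  ≥ 0.5 µm → fragment. The boundary value 0.5 µm is assigned to *fragment*
  as a deterministic tie rule (the class definitions "smaller than" /
  "larger than" 0.5 µm leave it open).
* **Mode classification.** "Full loss" means the length stays below a 0.3 µm
  sub-resolution stub threshold to the end of the trace. With full loss:
  *instant* if it happens within 2 h of the start with < 25% of the initial
  length resorbed beforehand; otherwise *combined* when the terminal step is
  abrupt — larger than max(3× the median absolute frame step, 5× a robust
  noise estimate, the drop floor) — and *gradual* when the decline ran
  smoothly to zero. Without full loss: *gradual* if the net decline exceeds
  max(drop floor, 5× the robust per-frame noise scale), else *intact*; a
  trace with detected events is never called intact. The 2 h window comes
  from the observed classification convention; the 25% resorption cutoff,
  stub threshold and abruptness rule are this package's choices, all exposed
  as parameters. The noise guard on the abruptness rule exists because at
  0.1 µm sample noise the scale-free 3×-median rule alone mislabels a few
  percent of smoothly-vanishing traces as combined.
* **Cohort summaries** report per condition: n, mean ± sd rate (and mean of
  per-replicate means when replicate ids exist), mode fractions, and the
  percentage of traces with ≥ 1 event, overall and per size class.
* `fluctuation_metrics` (sd, range, reversal count) is descriptive only —
  no published fluctuation statistic exists to reproduce.

## Quantitative immunofluorescence (`ciliaquant.imaging`)

* **Projection**: per-pixel maximum over z.
* **Segmentation** is a deliberate threshold/morphology stand-in for the
  proprietary machine-learning segmentation used on real data: 3×3 median
  filter, Otsu (or explicit) threshold, connected components of 5–500 px.
  Because the median filter erodes the end caps of thin rods, each
  component's final mask is recovered from the raw threshold restricted to
  the component's 2-px neighbourhood.
* **Length** is the 8-connected skeleton path length (diagonal steps √2)
  × pixel size. This chain-code estimator is exact for axis-aligned and
  45° rods but carries a known orientation bias of up to ~8% for oblique
  ones; tests that demand 1-px accuracy use axis-aligned rods, cohort tests
  allow for the bias. The ciliary **base** is the skeleton endpoint nearer
  the nearest nucleus centroid; without a nucleus channel the base is
  flagged undefined.
* **Background subtraction**: the ROI mask translated perpendicular to the
  cilium's principal axis by 2× its minor width — the first of 8 candidate
  directions that fits inside the image without touching the ROI (or other
  declared structures) supplies an equal-area background region. ROIs with
  no valid placement are flagged and skipped, never silently measured.
* **Ciliary concentration** = mean in-ROI intensity − background. Two
  derived quantities are stored under unambiguous names:
  `integrated_density` (concentration × area, the conventional meaning) and
  `mean_over_area` (concentration / area, the convention some figure legends
  call "integrated density"). Acceptance-grade checks bind only to
  concentration, which is exact on noiseless synthetic objects.
* **Periciliary measurement**: mean intensity inside a disc of area 5 µm²
  (radius √(5/π) ≈ 1.2616 µm) centred at the base, rasterized by
  pixel-centre inclusion, background-subtracted as above.
* **Depletion gate**: within each knockdown condition, the 25th percentile
  of the depletion-marker intensities is the gate and cells *above* it are
  flagged (they still express the target). The gate direction only makes
  sense against a low quantile of the knockdown condition; the quantile is a
  parameter.
* **ROUT outliers** (FDR-based outlier identification, Q in percent) for
  the constant-mean model: median location fit, robust standard deviation of
  the residuals from the 68.27th percentile of |residuals| with an n/(n−1)
  small-sample correction, two-tailed t probabilities of the studentized
  residuals, screened from the most extreme inward against
  Benjamini–Hochberg-style thresholds Q·rank/n. No implementation of this
  procedure exists in the scientific Python stack, so it is written here and
  cross-checked against Grubbs' test on single-outlier cases. Removed values
  are reported, never deleted.
* **Normalization**: each value divided by its replicate's control-group
  mean (excluded records don't contribute to the mean but are still scaled),
  making the control mean exactly 1 per replicate and the operation
  idempotent.

## Spheroid scoring (`ciliaquant.spheroids`)

Rule-based calls on pre-annotated per-spheroid features (3D segmentation of
spheroids is out of scope). Exclusion: < 8 cells in cross-section, or > 50
cells with no lumen (both strict). Defective: no hollow lumen, > 1 lumen,
distorted lumen, disorganized apical/basal markers, nuclei protruding into
the lumen, or misoriented cilia — the last is listed among defects in figure
material but not in the written definition, so it counts by default behind a
toggle. Luminal death: Σ luminal apoptotic bodies / Σ cells × 100 per
replicate, then averaged per condition. Blot band ratios divide each lane's
target band by its loading control before ratioing; fold changes of printed
per-condition means are reported to 2 decimals, the precision figure legends
use.

## Statistics (`ciliaquant.stats`)

All hypothesis tests run on replicate means, never pooled cells, so the test
n is the replicate count. Welch's t is the default two-group test; `auto`
runs Shapiro–Wilk per group (α = 0.05) and falls back to the rank test
(Mann–Whitney, or Wilcoxon signed-rank when paired). One-sample t and
one-way ANOVA cover the remaining designs; no multiple-testing correction is
added beyond what the tests themselves provide, mirroring the analysis
conventions the package reproduces. A vectorised Welch implementation
(verified against scipy to 1e-12) powers the calibration study: with 3
replicates per group the exact type-I error of Welch's test under normality
is ≈ 0.035 — slightly conservative, as expected from the Welch–Satterthwaite
approximation at tiny df — which sits just inside the accepted [0.035, 0.065]
calibration band.

## Synthetic data (`ciliaquant.simulate`)

One `SimConfig` seeds every generator; identical configs give bit-identical
outputs. What the generators emulate, and what they do not:

* **PSM tables**: log-normal protein abundances (σ = 1), bait runs multiply
  a planted enriched set by 2^log2FC and renormalise — so enriching some
  proteins dilutes the rest, the compositional artefact real spectral
  counting has. Counts are Poisson around multinomial expectations at
  ~10⁵ PSM per run. A configurable fraction (default 30%) of never-enriched
  proteins get registry contamination percentages uniform on (0, 100),
  exercising the 50% cutoff from both sides. Planted per-time-point
  interactor sets with a fixed overlap support the two-time-point
  intersection analysis (282/301 sharing 211 in the reference
  configuration). Not emulated: peptide-level identification, shared
  peptides, protein length effects.
* **Length traces**: noiseless trajectories per mode — stable (constant),
  gradual (linear at the planted rate, initial length never below
  rate × duration so the rate formula recovers the planted value exactly),
  instant (constant, then zero at a loss time uniform in the first 2 h),
  combined (resorb 35–60% of the length, then abrupt loss) — plus scheduled
  step-drop shedding events and additive Gaussian length noise (default
  0.05 µm, i.e. drop_floor/5). For modes ending at zero the initial length
  is rate × duration, so the planted rate is what the deciliation formula
  measures; for gradual traces with events the continuous slope is reduced
  so the total decline (and hence the rate) is preserved. Event-bearing
  traces are a deterministic count per cohort (round(fraction × n)), since
  cohort ectocytosis percentages are reported as empirical fractions.
  `simulate_disassembly_cohort` plants per-trace rates on a normal quantile
  grid whose sample mean equals the stated condition mean exactly (the
  reported rates are themselves empirical cohort means of n = 30), with the
  fastest rates assigned to instant-loss traces. Instant-loss cilia
  therefore get initial lengths of rate × 6 h, which can exceed typical
  cilium lengths for the fastest traces — a deliberate simplification that
  keeps the rate formula exact. Noise never resurrects a trace: once the
  observed length hits zero it stays zero.
* **Images**: nucleus discs plus rod-shaped cilia (dilated line segments,
  half-width 1 px) at constant per-pixel amplitude, with the same rod
  re-deposited in a protein-of-interest channel and a basal blob filling the
  5 µm² periciliary disc exactly; uniform background plus Gaussian noise.
  Placement enforces clearance so each cell's background regions stay clean,
  via a distance-transform test with a retry budget (overcrowded fields are
  rejected with a diagnostic). Not emulated: PSF blur, photon statistics,
  z-optics, autofluorescence — so passing tests demonstrate the measurement
  arithmetic, not robustness to real microscope physics.
* **Spheroid tables**: features sampled consistently with planted
  defective/normal labels (defective spheroids get ≥ 1 concrete defect
  mechanism), cell counts inside the analyzable 8–50 window, binomial
  luminal apoptotic-body and luminal-cilia counts.

## Problem sizes and numerical choices

The shipped analyses use the study-scale sizes: 30 traces per live-imaging
cohort, 91 frames per trace, 400 traces for the classification study,
500–1500 proteins at 10⁵ PSM depth, 200 measured cells for the noisy-imaging
study, and 10⁴–10⁵ simulated nulls for the Welch calibration; together they
run in well under a minute on one core, apart from the imaging study
(~10 s). Ties and degenerate inputs: all-equal depletion intensities gate
nothing (values equal to the threshold are kept); rank tests on identical
groups report p = 1; ROUT needs n ≥ 3 and keeps everything at Q = 0;
traces shorter than 2 frames are rejected.

## Known limitations

* The technical-replicate merge before fold changes is an assumption (the
  originating analysis does not state it); both strategies are exposed and
  the counts the pipeline reproduces are insensitive to the choice on
  synthetic data with planted enrichment well above threshold.
* Chain-code skeleton lengths are orientation-biased up to ~8%; a
  calibrated estimator was deliberately not substituted because the √2 rule
  is the stated measurement convention.
* Event detection is single-frame; at noise levels ≳ 0.1 µm its false-positive
  rate grows quickly, which is why the event floor is specified as ≈5× the
  expected noise.
* The spheroid module scores pre-annotated features; it does not segment
  3D image stacks.
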