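# ciliaquant

Quantitative analysis of primary-cilium homeostasis for cell biologists
studying cilium maintenance and disassembly in epithelial cells. The package
bundles the four analysis layers such studies need, each usable as a library
module, from the command line, and against built-in synthetic data with
known ground truth:

* **`ciliaquant.interactome`** — BioID proximity-interactome calling from
  spectral counts. NSAF (a protein's share of a run's total peptide-spectrum
  matches, NSAF<sub>p,r</sub> = PSM<sub>p,r</sub> / Σ<sub>q</sub> PSM<sub>q,r</sub>),
  low-evidence exclusion, per-biological-replicate bait/control fold changes,
  and the high-confidence filter (avg log₂FC ≥ 1, CRAPome-style contamination
  ≤ 50%), with a complete audit trail.
* **`ciliaquant.kinetics`** — live-imaging length traces: deciliation rate
  (ΔL / Δt in µm/h), disassembly-mode classification (gradual resorption,
  instant whole-cilium loss within 2 h, combined, intact), and ciliary
  ectocytosis event detection with the 0.5 µm vesicle/fragment size rule.
* **`ciliaquant.imaging`** — quantitative immunofluorescence: threshold
  segmentation with skeleton lengths, ciliary and 5 µm² periciliary
  intensities with adjacent-region background subtraction, depletion gating,
  ROUT (FDR-based) outlier removal, normalization to the per-replicate
  control mean.
* **`ciliaquant.spheroids`** — rule-based 3D spheroid scoring (defects,
  exclusions, luminal death) and loading-control-normalized blot ratios.
* **`ciliaquant.stats`** — replicate-aware tests (Welch/rank/ANOVA on
  replicate means, never pooled cells) and superplot tables.
* **`ciliaquant.simulate`** — seeded generators for all four input classes,
  each returning a ground-truth record.

## Worked example

Simulate a BioID experiment with a planted enriched set, run the filtering
pipeline, and compare against ground truth:

```python
from ciliaquant import interactome as ia
from ciliaquant.simulate import SimConfig, simulate_psm_tables

config = SimConfig(seed=1, n_proteins=500, psm_depth=100_000,
                   enrichment_log2fc=3.0, frac_enriched=0.1)
table, truth = simulate_psm_tables(config, time_points=("1h",))
registry = ia.ContaminantRegistry(truth.contaminant_registry)
result = ia.run_pipeline(table, registry)

hc, enriched = result.protein_set, truth.enriched_proteins
print(f"high-confidence: {len(hc)}")
print(f"sensitivity:     {len(hc & enriched) / len(enriched):.3f}")
print(f"false discovery: {len(hc - enriched) / len(hc):.3f}")
```

prints

```
high-confidence: 50
sensitivity:     1.000
false discovery: 0.000
```

— all 50 planted interactors (log₂FC = 3 at 10⁵ PSM depth) clear the
avg log₂FC ≥ 1 filter and nothing else does. The same chain on two time
points with planted interactor sets of 282 and 301 sharing 211 proteins
recovers exactly those counts (`tests/test_acceptance.py`).

Disassembly kinetics on simulated serum-stimulation cohorts:

```python
from ciliaquant import kinetics as kin
from ciliaquant.simulate import SimConfig, simulate_disassembly_cohort

config = SimConfig(seed=1)
depleted, _ = simulate_disassembly_cohort(
    config, "shCcdc66", rate_mean_um_per_h=1.03, rate_sd_um_per_h=0.53,
    mode_mix={"gradual": 0.3, "instant": 0.4, "combined": 0.3},
    event_fraction=0.7712, n_traces=30)
calls = [kin.classify_mode(t, kin.detect_events(t)) for t in depleted]
print(kin.summarize_cohort(calls)[
    ["condition", "rate_mean_um_per_h", "pct_with_event", "frac_instant"]])
```

prints

```
  condition  rate_mean_um_per_h  pct_with_event  frac_instant
0  shCcdc66            1.030127            80.0      0.366667
```

— the engine recovers the planted cohort mean deciliation rate of
1.03 µm/h to three decimals, finds ectocytosis in 24 of 30 traces (23
planted plus one noise-level detection, vs. the planted 77%), and calls
11 of the 12 planted instant losses instant (the twelfth shed large
fragments before its terminal drop and is called combined, a defensible
reading of such a trace).

The same pipelines are exposed as a CLI:

```bash
ciliaquant simulate --what traces --seed 1 --out-dir sim/
ciliaquant kinetics --traces sim/traces.csv --out-dir out/
```

All run parameters are CLI flags; every subcommand writes a `provenance.json` (package version, configuration
hash, input checksums) next to its outputs.

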