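# cofrac

Analytics for co-fractionation mass spectrometry (SEC elution profiles) and
single-temperature thermal shift assays, built around a synthetic-data
generator with known ground truth.

The package covers the stages of a growth-phase comparison study:

- **`cofrac.synthetic`** — seeded generator of SEC elution profiles
  (Gaussian peaks per programmed oligomeric state, metabolites split into a
  protein-bound pool under the partner's peaks plus a free low-MW pool),
  sigmoid-melting thermal-shift intensities, and replicate abundance tables;
  the programmed complexes, binding events and melting parameters are the
  recovery oracle for everything downstream.
- **`cofrac.profiles`** — max-normalization, replicate aggregation, peak
  deconvolution (local maxima above 10% of the main maximum, boundaries at
  the deepest inter-peak minima), and log-linear molecular-weight
  calibration from reference standards.
- **`cofrac.abundance`** — median normalization (sample medians equalized to
  the global median) and pairwise differential testing: two-sided t-test on
  log2 intensities, Benjamini–Hochberg FDR, fold-change gate.
- **`cofrac.itsa`** — thermal-stability values (per-temperature median
  normalization scaled to room-temperature abundance) and per-temperature
  differential-stability calls with the union set.
- **`cofrac.fractionation`** — differential elution by the Manhattan-distance
  criterion (MD > 1.5 × median MD), a permutation-based dis-elution
  surrogate for replicated profiles, and presence/absence calls.
- **`cofrac.pools`** — bound/free metabolite pool sums (fractions 1–40 vs
  41–60), total-abundance tests, and paired Wilcoxon comparison of
  bound/free ratio distributions between phases.
- **`cofrac.networks`** — Pearson correlation between deconvolved peaks,
  PCC ≥ 0.7 networks, seeded Louvain communities, the interaction-rate
  percentage (100 × n_interactions / (n_dipeptide_peaks × n_protein_peaks)),
  group × pathway rate matrices, and Ward clustering of a user-supplied
  distance matrix cut at a fixed height.
- **`cofrac.integration`** — overlap (Venn) reports, scalar Pearson
  correlations, and group-wise chain-length comparisons (Mann–Whitney U).
- **`cofrac.io` / `cofrac.config` / `cofrac.pipeline` / `cofrac.cli`** —
  TSV/CSV/JSON dialects, validated YAML configuration, and end-to-end
  orchestration.

## CLI

```sh
cofrac simulate --n-proteins 200 --n-metabolites 60 --seed 1 --outdir sim/
cofrac abundance sim/abundance.tsv sim/samples.csv --phase-a glucose --phase-b early_stationary
cofrac itsa sim/itsa.tsv --phase-a glucose --phase-b early_stationary --outdir itsa_out/
cofrac promis sim/profiles.tsv --phase-a glucose --phase-b early_stationary
cofrac pools sim/profiles.tsv --outdir pools_out/
cofrac networks sim/profiles.tsv --phase glucose --outdir net_out/
cofrac run-all --seed 1 --outdir full_run/
```

`run-all` simulates a dataset (or consumes the configured input files),
runs every stage, and writes per-stage TSVs, GraphML networks and a
`summary.json` with headline counts. A full run is reproducible from the
config seeds alone.

## File dialects

- Profiles: long TSV `molecule_id, molecule_class, phase, replicate,
  fraction, intensity` with 1-based fractions ordered by decreasing
  molecular size.
- iTSA: long TSV `protein_id, phase, temperature, replicate, intensity`
  with temperature labels `RT, 48, 52, 56`.
- Abundance: wide TSV (rows features, columns sample ids) plus a
  sample-sheet CSV `sample_id, phase, replicate`.
- MW calibration standards: two-column CSV `fraction, mass_kDa`.
- Ground truth: JSON sidecar written next to simulated datasets.
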