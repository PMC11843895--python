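# g4methyl

Strand-resolved CpG methylation analysis for G/C-rich promoter amplicons:
G4Hunter-style potential-quadruplex (PQS) scoring, confidence-thresholded
methylation pileup from per-read modification probabilities, region × strand
differential-methylation statistics, and binding/inhibition model fitting —
plus synthetic-data generators standing in for the sequencing and instrument
inputs.

## What it does

- **`g4methyl.sequence`** — FASTA loading, CpG-site indexing (0-based
  internally, reporting-style site numbers via a configurable offset),
  G4Hunter run scoring (G runs +min(k,4), C runs −min(k,4), sliding-window
  means) and PQS interval calling; BED/bedGraph output. The study's oligo
  and amplicon sequences ship with the package
  (`g4methyl.study_sequence("MGMT-752")`, 752 nt, 95 CpG sites numbered
  3–97).
- **`g4methyl.pileup`** — per-read (p_C, p_5mC, p_5hmC) call tables (native
  TSV or SAM/BAM with MM/ML tags), argmax classification with a 0.65
  confidence threshold, strand-resolved pileup counts, and the
  modification-calling accuracy statistic
  `100 × (mean p_C − 1/3) / (2/3)` computed on **unfiltered** calls
  (methylation fractions use **filtered** calls — two separate paths).
- **`g4methyl.stats`** — per-(region, strand) mean ± SEM of per-site %5mC
  and Welch unequal-variance t-tests contrasting the G-rich vs C-rich strand
  inside and outside the primary PQS region (default site numbers 47–72,
  overridable).
- **`g4methyl.binding`** — 1:1 BLI forward model and least-squares fit of
  (kon, koff, Rmax) with Kd = koff/kon; two-parameter log-logistic IC50 fit
  (hill fixed at 1 by default); restriction-protection methylation
  efficiency `(w0 − w_meth)/w0`.
- **`g4methyl.simulate`** — seeded generators for per-read modification
  calls (region/strand-dependent truth, Dirichlet-based confidence noise
  with a PQS-elevated low-confidence component), two-phase sensorgrams
  (300 s association / 120 s dissociation, 690 nM analyte) and inhibition
  curves. Presets: `control`, `dnmt3a`, `msssi` (see
  `src/g4methyl/data/presets.yaml`). **Note:** the preset region × strand
  means are *inputs* to the generator, so downstream recovery of those
  numbers validates the pipeline, not the original findings.

## CLI

```sh
g4methyl pqs --bed pqs.bed                      # PQS intervals on the bundled amplicon
g4methyl simulate-reads --preset dnmt3a --n-reads 500 --seed 1 --out calls.tsv
g4methyl pileup --calls calls.tsv --out pileup.bedmethyl.tsv
g4methyl compare-strands --calls calls.tsv --out report.tsv
g4methyl simulate-bli --out sg.tsv --sidecar sg.yaml
g4methyl fit-bli --sensorgram sg.tsv --sidecar sg.yaml --out fit.json
g4methyl simulate-inhibition --out inh.tsv
g4methyl fit-ic50 --table inh.tsv --out ic50.json
g4methyl run-all --preset dnmt3a --seed 1 --outdir out/   # full pipeline + manifest
```

`run-all` accepts a YAML config (`--config`); command-line flags override
config values. Exit codes: 0 success, 2 validation error, 3 computation
error. Outputs are byte-identical for a fixed config and seed.

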