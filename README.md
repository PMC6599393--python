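# statedyn

Latent brain-state dynamics for parcellated resting-state fMRI time courses.

`statedyn` fits a Gaussian-emission hidden Markov model to each sex ×
diagnosis group of a cohort of ROI time-course runs, aligns the independently
fitted states across groups by k-means on their mean-activation maps, decodes
per-run state sequences, and computes state-switching metrics — fractional
occupancy (FO), empirical transition probability matrices (TPM),
inter-transition intervals (ITI), and transition rate (NT) — followed by
factorial group inference (two-way and repeated-measures ANOVAs with partial
eta squared, per-state tests with Cohen's d, ITI–NT correlation, and a
matched sub-sample robustness analysis). A synthetic cohort generator with
injectable sex/diagnosis effects makes every stage testable without any
external data.

## Layout

| module | contents |
| --- | --- |
| `statedyn.io_cohort` | ROI time-course / phenotype ingestion, per-run z-scoring, group assembly with run boundaries |
| `statedyn.synthetic` | ground-truth HMM cohorts: sticky transition matrices, per-run logit-jittered matrices, template emission maps |
| `statedyn.hmm` | forward–backward, Viterbi, EM fitting (diagonal or full covariance), 1..K state scan, elbow selection |
| `statedyn.alignment` | k-means state matching across groups, validity report, consensus maps and relabeling tables |
| `statedyn.dynamics` | decoding, FO, empirical TPMs, dwell episodes, ITI/NT, 3-SD outlier screening |
| `statedyn.stats` | two-way ANOVA (Type II/III), repeated-measures FO ANOVA, Cohen's d, per-state tests, subsampling |
| `statedyn.pipeline` / `statedyn.cli` | YAML config, seeded orchestration, run manifest, `statedyn` CLI |

## CLI

```bash
# full pipeline on a synthetic cohort (simulate -> ingest -> fit -> align -> metrics -> stats)
statedyn run-all --config config.yaml --seed 1 --out output/

# individual stages (each deterministic re-runs its predecessors)
statedyn simulate --config config.yaml --out cohort/
statedyn fit --config config.yaml
statedyn validate --config config.yaml
```

A minimal `config.yaml` (all keys optional; unknown keys are rejected):

```yaml
seed: 1
simulate:
  n_states: 5
  n_channels: 190
  runs_per_group: [99, 347, 251, 257]
  run_length_range: [80, 230]
  on_diag_by_group: 0.53
hmm:
  scan: [1, 10]        # or: k: 5
dynamics:
  iti_convention: dwell_minus_one
stats:
  ss_type: III
```

Outputs land under `output/`: per-group model JSON, scan tables,
`alignment/consensus_maps.csv`, `metrics/dynamics.csv` (one row per run with
FO, ITI, NT and outlier flags), per-group `tpm_*.csv`, ANOVA tables, and a
`manifest.json` with per-stage seeds and output checksums; identical
config + seed reproduces every file byte-for-byte.

## Conventions

- Scans (runs) are the unit of analysis; multiple runs of one subject are
  separate rows.
- Channels are z-scored per run (sample SD) before concatenation; run
  boundaries break the Markov chain in fitting and decoding.
- ITI default convention is dwell length minus one (`dwell` also available):
  at stay probability p the expected ITI is 1/(1−p) − 1.
- Outlier screening is a single pooled pass at |z| > 3 (strict), applied to
  the ITI family and NT separately.
- States are 0-based internally and 1..K in all written outputs.
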