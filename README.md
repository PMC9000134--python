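# ppidisp

Structural-interactome analysis toolkit for estimating the dispensable
fraction of protein–protein interactions (PPIs) among transient versus
permanent interactions.

The package covers the full pipeline:

- **`ppidisp.interactome`** — structural interactome data model, interface
  residues from inter-chain atomic contacts (5 Å rule, PDB input via
  Biopython), template annotation from alignment records (E-value ≤ 1e-5,
  ≥50% interface coverage), and mutually-exclusive-PPI counting.
- **`ppidisp.mutations`** — common/disease missense cohorts: MAF ≥ 1%
  filtering, position dedup, disease-position exclusion, flank-based
  position verification, and mapping onto PPI interfaces.
- **`ppidisp.classify`** — eight transient/permanent property families:
  binding strength (ΔG ≥ −25 kcal/mol ⇒ weak), temporal and spatial
  co-expression (Pearson vs. dataset median, strict inequalities),
  stoichiometric balance (mean |log10 difference| vs. median), and
  interface exclusivity bins (0 / 1–4 / ≥5).
- **`ppidisp.edgotype`** — disruption calls (interfacial AND ΔΔG > 0.5
  kcal/mol, strict), edgetic / quasi-wild-type / mono-edgetic assignment,
  per-property count tabulation, and ΔΔG-cutoff robustness sweeps.
- **`ppidisp.dispensability`** — the Bayesian estimator
  P(N|T) = P(T|N)P(N) / P(T) with priors (0.27, 0.53, 0.20), its
  ratio-only closed form, log ratio-of-proportions 95% confidence
  intervals, prior-sensitivity grids, and report generation at the
  published table's printed precision. The published disruption-count
  table ships as package data (`ppidisp/data/published_counts.tsv`).
- **`ppidisp.benchmark`** — balanced accuracy / precision / TPR / FPR,
  two-sided Fisher's exact test, and Kd ↔ ΔG conversion for
  affinity-derived ground-truth labels.
- **`ppidisp.synth`** — seeded generator of complete synthetic input
  bundles (toy coordinates whose geometric interfaces match the declared
  sets exactly, expression experiments with per-pair correlation and
  abundance-offset targets, mutation cohorts with exact Bernoulli
  disruption ground truth) for offline validation and parameter-recovery
  studies.

## CLI

Everything is exposed under one `ppidisp` entry point; all formats are
plain text (TSV / FASTA / PDB / JSON / YAML).

```bash
# generate a synthetic input bundle
ppidisp synth generate --seed 1 --out bundle/

# classification, edgotype prediction, and the full report
ppidisp classify all --bundle bundle/ --out labels.tsv
ppidisp edgotype predict --bundle bundle/ --ddg-cutoff 0.5 --out edgotypes.tsv
ppidisp dispensable run-all --bundle bundle/ --out analysis/

# estimator on an arbitrary counts table, and the published-counts report
ppidisp dispensable estimate --counts counts.tsv --priors 0.27,0.53,0.20 --out report.tsv
ppidisp dispensable published --out published_report.tsv

# robustness sweep over ddG cutoffs
ppidisp dispensable sweep --bundle bundle/ --labels labels.tsv --ddg-cutoffs 0.5,1,2,3 --out sweep.tsv

# interface geometry from PDB files
ppidisp interactome build --ppis pairs.tsv --structures pdbs/ --fasta proteins.fasta --cutoff 5.0 --out interactome.tsv

# validation metrics
ppidisp benchmark metrics --pred pred.tsv --truth truth.tsv --out metrics.json
```

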