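# ipondtmt

Quantitative analysis of iPOND-TMT nascent-chromatin proteomics: what does
transcription contribute to the protein composition of newly replicated
chromatin?

In an iPOND (isolation of Proteins On Nascent DNA) time course, newly
replicated DNA is EdU-pulse-labelled, chased with thymidine (Nascent, 1 h,
2 h), and its associated proteins quantified by multiplexed TMT mass
spectrometry — here under transcription inhibition (triptolide/TPL blocks
RNAPII loading, DRB blocks elongation) against a DMSO control.  This
package implements the downstream inference for that design, from
MaxQuant-style `proteinGroups.txt` tables to the final biology-level calls:

- **Preprocessing** — QC filtering (≥3 unique+razor peptides, no decoys or
  contaminants), log10 transformation, per-sample median normalization, and
  per-protein least-squares batch correction with the treatment/time
  covariates protected.
- **Differential abundance** — per-protein additive model
  `log2(abundance) ~ treatment + time_point`, empirical-Bayes moderated
  t-statistics with variance shrinkage
  `s̃²_g = (d₀s₀² + df_g s²_g)/(d₀ + df_g)`, Benjamini–Hochberg FDR, and the
  volcano significance rule |log2FC| ≥ 0.5 & FDR ≤ 0.05.
- **Bootstrap gene-set depletion test** — the observed mean log2FC of a
  protein set (a DNA-repair pathway, a remodeller family) is compared
  against 100,000 size-matched random sets drawn from all quantified
  proteins; the lower-tail p is the proportion of null means below the
  observed one.
- **TF kinetic classification** — five categories (significant/
  non-significant gain or loss between nascent and 2 h-mature chromatin,
  flat) with Wilson confidence intervals on category proportions.
- **Histone-PTM relative abundance** — per-residue 100% normalization of
  peptide areas, isobaric-form splitting from fragment-ion ratios, and
  paired t-tests across the time course.
- **Synthetic data** — a generator that emulates the full design (log-normal
  baselines, scaled inverse-χ² protein variances, planted set-level effects,
  batch offsets, intensity-dependent missingness, decoy/contaminant rows)
  with a ground-truth record, so every stage is testable without any
  deposited raw data.

## Worked example

```python
import pandas as pd
from ipondtmt import synthetic_data as sd, preprocess as pp
from ipondtmt import diffabund as da, groupboot as gb

cfg = sd.SimConfig(n_proteins=2000, seed=42)
sets = sd.default_gene_sets(cfg)
table, design, truth = sd.simulate_dataset(cfg, sd.default_effects(), sets)

filtered, tally = pp.qc_filter(table, min_razor=3)
matrix = pp.log_median_normalize(filtered)
matrix, _ = pp.batch_correct(matrix, design)

fit = da.fit_linear_models(matrix, design)
prior, s2_post = da.ebayes_moderate(fit.s2, fit.df)
res = da.moderated_contrasts(fit, prior, s2_post,
                             ["TPL-vs-DMSO", "DRB-vs-DMSO"])

gene_of = dict(zip(filtered.meta.index, filtered.match_key()))
fc = {c: pd.Series(sub["log2fc"].to_numpy(),
                   index=[gene_of[p] for p in sub["protein_id"]])
      for c, sub in res.groupby("contrast")}
families = [s for s in sets if s.category == "remodeller_family"]
suite = gb.run_group_suite(fc, families, B=100000, seed=42)
```

Output (abridged):

```
qc_filter: {'low_peptides': 190, 'reverse': 100, 'contaminant': 40,
            'removed': 306, 'kept': 1834}
eBayes prior: d0=4.06, s0^2=0.0361
set_name    contrast  n_members_used  observed_mean_log2fc      p    fdr  significant
 SWI/SNF DRB-vs-DMSO              15               -0.3227 0.0000 0.0000         True
 SWI/SNF TPL-vs-DMSO              15               -0.4152 0.0000 0.0000         True
     CHD DRB-vs-DMSO              14                0.0180 0.6494 0.7422        False
     CHD TPL-vs-DMSO              14               -0.4794 0.0000 0.0000         True
    ISWI TPL-vs-DMSO              13               -0.4443 0.0000 0.0000         True
   INO80 TPL-vs-DMSO              14               -0.4782 0.0000 0.0000         True
```

Reading it: the QC filter removed 306 of 2140 simulated protein groups
(decoys, contaminants, and groups with fewer than three unique+razor
peptides).  The variance-prior estimate (d₀ ≈ 4, s₀² ≈ 0.036) recovers the
generator's truth (4, 0.04).  The bootstrap test flags all four remodeller
families as significantly depleted under TPL and only SWI/SNF under DRB —
the planted effect structure, analogous to the loss of chromatin-remodeller
binding to replicated DNA when RNAPII loading is blocked.

The same run is available from a shell:

```bash
ipondtmt all --config run.yaml      # simulate → preprocess → diffabund →
                                    # groupboot → tfcat → ptm, plus manifest
```

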