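# ripchip

Analysis toolkit for **RIP-Chip** experiments probing miRNA target
recruitment by RISC proteins (e.g. AGO2, GW182/TNRC6A).  A RIP
experiment yields three fractions per replicate — the input lysate
(IN), the immunoprecipitated fraction (IP) and the unbound flow-through
(FT).  Genes enriched in IP over FT are candidate RISC cargo; the
question the toolkit addresses is *which sequence and expression
features explain that enrichment*.

## What it computes

For every gene *j*, with miRNA expression *e<sub>i</sub>* and mRNA
expression *g<sub>j</sub>* from one IN sample and binding-site count
matrices *BS* (3'UTR and CDS; densities *dBS = BS / length*):

| variable | formula | region |
|---|---|---|
| F1 | Σ<sub>i</sub> e<sub>i</sub>·BS<sub>ij</sub>·g<sub>j</sub> | 3'UTR (F5: CDS) |
| F2 | Σ<sub>i</sub> e<sub>i</sub>·BS<sub>ij</sub> | 3'UTR (F6: CDS) |
| F3 | Σ<sub>i</sub> BS<sub>ij</sub>·g<sub>j</sub> | 3'UTR (F7: CDS) |
| F4 | Σ<sub>i</sub> BS<sub>ij</sub> | 3'UTR (F8: CDS) |
| F1d–F8d | the same with dBS | |
| F9, L1, L2 | g<sub>j</sub>, 3'UTR length, CDS length | |

The sums run over a configurable miRNA subset (default: top 50
expressed).  The stages:

1. **sequences** — select one sequence per gene and region (longest,
   ≥ 50 nt), count exact reverse-complement seed matches (6/7/8-mer),
   build BS/dBS matrices.
2. **expression** — quantile normalization, replicate averaging,
   average-linkage clustering at distance 1 − Pearson r.
3. **enrichment** — SAM-style moderated d-statistic
   d = (mean<sub>IP</sub> − mean<sub>FT</sub>) / (s + s₀) with a
   permutation-estimated FDR; UP/LOW calls at q ≤ 5%.  Plus exact
   hypergeometric / one-tailed Fisher set-overlap tests and the
   2^−ΔΔCt qPCR fold-change normalization.
4. **variables / evaluation** — the 19-variable table, per-variable
   ROC-AUC (Mann–Whitney concordance) and rank-sum p against the
   UP/LOW calls, DeLong tests between paired AUCs, ECDFs.
5. **models** — linear SVMs on variable pairs, scored by leave-one-out
   cross-validated decision values (19 × 19 AUC matrix).
6. **shuffling** — the expression-profile shuffling validation: if a
   variable's power really comes from the miRNA profile, permuting the
   top-k expression values must collapse its AUC.  Reported as the
   exceedance fraction (share of shuffled profiles reaching the
   original AUC), including hold-top-n-fixed sweeps.
7. **synthetic** — a generator of complete synthetic studies (lengths,
   heavy-tailed miRNA profile with one dominant species, Poisson site
   counts scaling with region length, logistic UP/LOW labels planted
   on a chosen driver variable, IP/FT intensities with multiplicative
   enrichment) so the whole pipeline is testable without downloads.

## Worked example

```python
import numpy as np
from ripchip import (SyntheticConfig, generate_dataset, compute_variables,
                     sam_enrichment, quantile_normalize, VariableInputs,
                     ShuffleScheme, simulate_auc_distribution)
from ripchip.evaluation import variable_auc_table

cfg = SyntheticConfig(n_genes=2000, n_mirnas=50, mode="ago2_like", seed=1)
ds = generate_dataset(cfg)                      # F6 signal planted

calls = sam_enrichment(quantile_normalize(ds.expression), n_perm=200, seed=1)
print(f"SAM calls at q<=5%: {len(calls.genes('UP'))} UP, {len(calls.genes('LOW'))} LOW")

vt = compute_variables(ds.mirna_profile, ds.mrna_profile, ds.bs_utr, ds.bs_cds,
                       ds.dbs_utr, ds.dbs_cds, ds.lengths)
print(variable_auc_table(vt, calls.calls).head(5).to_string(index=False))

inputs = VariableInputs(mirna_profile=ds.mirna_profile, mrna_profile=ds.mrna_profile,
                        bs_utr=ds.bs_utr, bs_cds=ds.bs_cds, dbs_utr=ds.dbs_utr,
                        dbs_cds=ds.dbs_cds, lengths=ds.lengths)
res = simulate_auc_distribution("F6", inputs, calls.calls,
                                ShuffleScheme("within_top", k=50), n_sim=200, seed=1)
print(f"F6 original AUC {res.original_auc:.3f}; "
      f"median shuffled AUC {np.median(res.simulated_aucs):.3f}; "
      f"exceedance {res.exceedance_fraction:.3f}")
```

Output:

```
SAM calls at q<=5%: 351 UP, 350 LOW
variable      auc      p_value  n_up  n_low
      F6 0.849357 1.098347e-57   351    350
     F6d 0.835474 2.475563e-53   351    350
      F5 0.826545 1.261823e-50   351    350
     F5d 0.815075 2.965492e-47   351    350
      F8 0.701197 2.215306e-20   351    350
F6 original AUC 0.849; median shuffled AUC 0.642; exceedance 0.000
```

The SAM stage recovers the planted enrichment (351 UP / 350 LOW of the
~700 genes with a true IP shift).  The planted driver F6 tops the AUC
ranking, trailed by its correlated CDS-cluster variables; shuffling the
top-50 expression values drops the median AUC from 0.849 to 0.642 and
no shuffled profile reaches the original AUC (exceedance 0.000) —
the signal genuinely lives in the expression weighting.

## Command line

```bash
ripchip --seed 1 simulate --out data/ --mode ago2_like
ripchip --seed 1 enrich --data data/ --out enrichment.tsv
ripchip --seed 1 full --out run/          # all stages, manifest + hashes
```

Subcommands: `simulate`, `sites`, `variables`, `enrich`, `evaluate`,
`svm`, `shuffle`, `full`.  Exit codes: 0 success, 2 validation error,
1 stage failure.

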