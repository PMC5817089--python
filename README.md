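# dualmeth

Comparative 5-methylcytosine (5mC) / 5-hydroxymethylcytosine (5hmC)
differential methylation analysis between two species on methylation-array
beta values, for epigenomics researchers working with paired
bisulfite / TET-assisted-bisulfite (TAB) designs.

Sodium bisulfite conversion alone cannot distinguish 5mC from 5hmC: a
bisulfite (BS) array reports the *composite* 5mC + 5hmC fraction, while a
TAB-treated array reports 5hmC alone. `dualmeth` runs both arms through a
common pipeline and resolves loci significant in one or both assays into
differentially methylated (DML) versus differentially hydroxymethylated
(DhML) loci:

1. **Preprocessing** — beta values are masked where the detection p-value
   exceeds 0.01, technical replicate pairs are averaged, and probes missing
   in more than one sample are discarded.
2. **Confounder-adjusted testing** — per probe, the model
   `beta ~ species + beadchip + F₁ + … + F_k` is fit by OLS, where the `F_j`
   are latent-factor scores estimated from the residual beta matrix
   (truncated SVD; factor count `k` by Horn's parallel analysis).  The
   genomic inflation factor λ = median(χ²)/0.455 diagnoses calibration.
3. **HMM-LIS multiple testing** — probe z-scores, ordered along each
   chromosome, are modelled as a two-state hidden Markov chain
   (null / non-null) with an empirical Gaussian null and a nonparametric
   kernel alternative, fitted by EM.  The local index of significance
   LIS_i = P(state_i = null | all z on the chromosome) is thresholded
   through its running mean over ranks (aLIS): loci with aLIS < 0.01 are
   called significant, which controls the marginal FDR under the serial
   dependence that per-probe rules such as Benjamini–Hochberg ignore.
4. **Attribution** — loci significant in *both* assays carry their signal
   in the 5hmC component and are classed DhML; BS-only loci are DML.  All
   calls are split into human-specific / monkey-specific by the sign of
   Δβ = mean(human) − mean(monkey).
5. **Enrichment** — permutation over/under-representation of calls across
   gene-anatomy structures (TSS1500, TSS200, 5'UTR, 1st exon, body, 3'UTR,
   intergenic) and CpG-island relations (island / shore / shelf / open
   sea), plus Yates-corrected chi-square gene-set overlap tests.

A first-class synthetic-data generator (`simulate_dataset`) produces paired
BS/TAB two-species datasets with Markov-dependent differential states,
latent confounders, beadchip batches, technical replicates and per-probe
ground truth, so every stage is testable without any external download.

## Worked example

```python
import dualmeth as dm

data = dm.simulate_dataset(dm.SimulationConfig(n_probes=20_000, seed=8))
result = dm.run_dual_assay(data, k_factors="auto", alpha=0.01)

print(len(result.dml_ids), len(result.dhml_ids))
print(len(result.human_dml), len(result.monkey_dml))
print(round(result.bs.tester.lambda_, 3))
```

prints

```
211 201
90 121
1.023
```

i.e. 211 DMLs and 201 DhMLs at aLIS < 0.01 (the dataset has ~3.8% truly
differential probes, half 5hmC-driven), the DMLs split 90 human-specific
versus 121 monkey-specific, and the BS-arm genomic inflation factor after
factor adjustment is 1.02 — close to the calibrated value of 1.

Each estimator is also usable on its own, scikit-learn style:

```python
est = dm.HmmLisFdr(alpha=0.01).fit(z_scores, chromosomes)
est.lis_, est.alis_, est.significant_, est.transition_
```

A `dualmeth` command-line interface exposes the same steps
(`simulate`, `preprocess`, `diff`, `call`, `attribute`, `enrich`,
`overlap`); see `dualmeth --help`.

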