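# fosnet

Regional c-Fos activation patterns and co-activation network inference for
2 × 2 factorial immediate-early-gene studies.

Counting c-Fos-immunopositive cells per brain region is a standard proxy for
recent neuronal activity. In a factorial design — drug treatment (e.g.
methamphetamine, `MA`, vs saline, `SAL`) crossed with circadian phase
(`light` vs `dark`), with a panel of brain regions quantified per animal —
two complementary questions arise:

1. **Which regions respond to what?** Per region, a two-way ANOVA with
   treatment and time as factors classifies the region by which effects are
   significant: treatment only (pattern 1), time only (2), treatment plus a
   treatment × time interaction (3), treatment and time without interaction
   (4), or nothing (5). Interaction regions get Bonferroni-corrected
   simple-effect post hocs (MA vs SAL within each phase, light vs dark
   within each treatment).
2. **Which regions act together?** Within one group, regional counts are
   correlated across animals; the *connectivity* of region *r* is the
   unthresholded node strength
   *k*ᵣ = Σ_{s≠r} |corr(*r*, *s*)|.
   Chance levels of *k*ᵣ are estimated by independently shuffling each
   region column (destroying cross-region alignment, preserving marginals)
   and summarizing the observed value as *Z* = (*k*ᵣ − null mean)/null sd,
   with *Z* > 2 the conventional significance cutoff. Group differences
   Δ*k*ᵣ = *k*ᵣ(A) − *k*ᵣ(B) are tested with a group-relabeling bootstrap:
   pool both groups, re-split into the original sizes *n*-boot times, and
   compare the observed Δ*k*ᵣ with that null (Z-score plus an add-one
   empirical two-sided p).

A synthetic-data module generates count tables from a latent Gaussian
copula with configurable factorial cell means, overdispersion, and latent
inter-regional correlation networks (including a group-specific "hub"), so
every stage can be validated against known ground truth.

## Worked example

```python
import fosnet as fn

table = fn.simulate_counts(fn.study_config(seed=1))          # 40 animals x 17 regions
results, labels, _ = fn.analyze_activation(table, posthoc=False)
print({lab.region: lab.pattern for lab in labels})

ma = table[table.treatment == "MA"]
perm = fn.permutation_null(ma, n_perm=10_000, seed=2, group="MA")
print(perm.to_frame().round(2).loc[["SCN", "PVN", "VMH"]])

diff = fn.bootstrap_compare(table, n_boot=10_000, seed=3)
print(diff.to_frame().round(3).loc[["VMH", "PVN", "SCN"]])
```

prints

```
{'SCN': '2', 'PVN': '3', 'PVT': '3', 'CEA': '1', 'BLA': '5', 'MEA': '5',
 'DG': '5', 'CA1': '1', 'CA3': '4', 'ILC': '1', 'ARC': '3', 'VMH': '2',
 'DMH': '2', 'BNST': '1', 'CIN': '1', 'NACc': '1', 'NACs': '4'}
        connectivity  null_mean  null_sd     z
region
SCN             7.22       2.97     0.54  7.82
PVN             6.95       2.97     0.54  7.40
VMH             7.03       2.97     0.54  7.52
        delta_connectivity  null_mean  null_sd      z      p   p_bh
region
VMH                  1.665      0.026    1.770  0.926  0.388  0.849
PVN                  3.075      0.006    1.397  2.197  0.027  0.462
SCN                  0.704     -0.015    2.068  0.348  0.799  0.849
```

The pattern dictionary recovers the generator's ground truth for all 17
regions at this seed (e.g. SCN/VMH/DMH time-only, PVN/PVT/ARC interaction).
The permutation table says observed SCN connectivity (7.22 of a possible
16) sits 7.8 null standard deviations above the shuffled-order null — far
beyond the Z > 2 cutoff. The comparison table gives each region's MA-minus-
SAL connectivity difference with its relabeling-null Z and empirical p;
here PVN gains the most (Δk = 3.08, p = 0.027 raw, not significant after
Benjamini–Hochberg across 17 regions).

The same pipeline runs from a shell on any CSV with columns
`animal_id,treatment,phase,<region>,...`:

```bash
fosnet simulate --n-per-cell 10 --seed 1 --out study.csv
fosnet all --input study.csv --n-perm 10000 --n-boot 10000 --seed 1 --outdir results/
```

writing per-region ANOVA/pattern/post-hoc tables, per-group correlation
matrices, connectivity Z tables, edge lists, the bootstrap comparison, and
a manifest that reproduces the run bit for bit.

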