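# netcontrol

Network controllability analysis of structural brain connectomes, with the
covariate-adjusted group-statistics pipeline used in clinical case-control
imaging studies.

## The problem

Diffusion-MRI tractography yields, per subject, a structural connectome: a
symmetric matrix of streamline counts between parcellated brain regions
(114 regions in the default configuration), with fractional-anisotropy (FA)
edge weights alongside. Network control theory treats this graph as the
coupling matrix of a discrete linear time-invariant system

    x(k+1) = A x(k) + B u(k)

where `x` is the vector of regional activity, `A` the binary adjacency
matrix (an edge is kept when supported by at least 3 streamlines), and `u`
an external control input injected through `B`. Two node-level quantities
summarize how much leverage a region has over the network's state
transitions:

- **Average controllability** `AC_j = Tr(W_j)`, the trace of the
  controllability Gramian `W_j = Σ_i A^i e_j e_jᵀ (Aᵀ)^i` with single-node
  input `B = e_j` — the region's capacity to steer the brain to many nearby
  states at low energy. For symmetric Schur-stable `A`,
  `AC_j = Σ_n v_nj² / (1 − ξ_n²)`.
- **Modal controllability** `MC_j = Σ_n (1 − ξ_n²) v_nj²` over the
  eigenpairs `(ξ_n, v_n)` of `A` — the region's grip on fast-decaying,
  hard-to-reach modes.

Whole-brain values are the arithmetic means over all regions. Group and
individual differences in these measures are then tested with an ANCOVA per
construct (diagnosis, age, gender, symptom severity, remission status,
familial risk, polygenic scores, BMI, ...) controlling for age, gender,
scanner site and the number of present edges, with partial η² effect sizes,
percentile bootstrap CIs (1000 case resamples), 3-SD outlier removal on the
dependent variable, and Benjamini–Hochberg FDR across regions for
per-node analyses. A four-metric quality screen (mean streamline count,
mean FA, mean prevalence of present edges, mean prevalence of absent edges,
each with Tukey 1.5·IQR fences) excludes poorly reconstructed subjects
before any analysis.

Because raw clinical cohort data cannot be redistributed, the package ships
a seeded synthetic-cohort generator that reproduces the structural features
the pipeline depends on (consensus edge-prevalence backbone with hubs,
overdispersed streamline counts straddling the 3-streamline threshold,
clinical covariate tables, plantable group/regional/QC effects), so every
stage is testable end to end.

## Worked example

```python
import numpy as np
from netcontrol import (GeneratorConfig, generate_cohort, binarize,
                        node_controllability, AncovaSpec, fit_ancova)
from netcontrol.controllability import controllability_table

cfg = GeneratorConfig(n_nodes=114, n_hc=200, n_mdd=200, seed=7,
                      group_effect=0.05)   # patients: hub edges thinned 5%
cohort, covariates, truth = generate_cohort(cfg)

profiles = [node_controllability(binarize(sc), sc.subject_id)
            for sc in cohort]
table = covariates.join(controllability_table(profiles, cohort[0].node_labels))

spec = AncovaSpec(dependent="wb_modal", effect="diagnosis",
                  covariates=("age", "gender", "site", "edge_count"),
                  n_boot=1000)
r = fit_ancova(spec, table, rng=np.random.default_rng(7))
print(f"F({r.df1},{r.df2}) = {r.F:.2f}, p = {r.p:.3g}, "
      f"partial eta^2 = {r.partial_eta_sq:.6f} "
      f"[{r.ci95[0]:.6f}, {r.ci95[1]:.6f}], n = {r.n_used}")
```

Output:

```
F(1,393) = 73.21, p = 2.64e-16, partial eta^2 = 0.157037 [0.102052, 0.231659], n = 400
```

Patients' hub edges were generated 5% less prevalent, which lowers their
whole-brain modal controllability; the ANCOVA detects the group difference
(F-test of the diagnosis term over and above age, gender, site and edge
count) with partial η² ≈ 0.16, and the bracketed interval is the percentile
bootstrap 95% CI from 1000 case resamples.

The same analysis runs from the shell:

```bash
netcontrol run --config config.yaml --seed 7 --out results/
```

with a YAML config naming either a `simulate:` block or an `input:` block
(delimited-text matrices or one HDF5 container), and an `analyses:` roster.

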