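# scfc

Structure–function coupling analysis for brain networks: how much of the
variability in measured functional connectivity (FC) is real dynamical
richness, and how much is a degenerate reflection of the static anatomical
wiring (structural connectivity, SC)?

`scfc` implements a complete, reusable pipeline for asking that question on
synthetic whole-brain data:

- **Synthetic cohorts** — two-hemisphere region atlases with homotopic
  pairing, a shared ground-truth connectome, per-subject SC as
  `gain × core + noise` (thresholded at 0.001), and tractography-style
  degradation that deletes interhemispheric links.
- **Generative dynamics** — five SC-conditioned models (spatial
  autoregressive, linear rate, Wilson–Cowan, Kuramoto, FitzHugh–Nagumo),
  Balloon–Windkessel hemodynamics, global-signal regression, and global
  coupling tuned by grid search.
- **FC measures** — Pearson correlation (cFC), Kraskov k-nearest-neighbor
  mutual information (mFC), 3-way total correlation (CT3), and windowed
  dynamic FC, with the Gaussian closed forms
  `I(X_i, X_j) = -1/2 ln(1 - rho_ij^2)` and `-1/2 ln det R` as analytic
  references.
- **Bootstrap SVD** — uncentered SVD of feature × subject matrices,
  bootstrap-over-subjects confidence intervals on the singular values
  `s_i`, variance fractions `s_i^2 / sum_j s_j^2`, a reproducible-dimension
  rule based on CI separation, average-projection patterns, pooling of
  empirical with model-generated data, and three label-permutation
  controls.
- **Connectome inversion** — estimate SC from FC by fitting a 4th-order
  polynomial to the first-dimension SC′–FC relationship
  (`SC' = ln(SC / 0.0001)`) and inverting it on its monotone branch
  (`SC_hat = 0.001 exp(P4^-1(FC))`).

## Worked example

Bootstrap SVD of a 21-subject synthetic SC cohort (40 regions, 780 links):

```python
import numpy as np
from scfc import CohortSpec, generate_cohort, vectorize_upper
from scfc.subspace import DataMatrix, bootstrap_svd

spec = CohortSpec(n_subjects=21, gain_sd=0.2, noise_sd=3e-3, seed=0)
gt, subjects = generate_cohort(40, spec)
X = np.column_stack(
    [vectorize_upper(sc.weights, gt.atlas).values for sc in subjects]
)
dm = DataMatrix(X=X, subject_ids=[f"s{j:02d}" for j in range(21)],
                source_tags=["sc"] * 21)
res = bootstrap_svd(dm, B=1000, alpha=0.05, seed=0)
print(f"reproducible dimension: {res.reproducible_dim}")
for i in range(2):
    print(f"dim {i+1}: {100*res.boot_fraction_mean[i]:.1f}% "
          f"+/- {100*res.boot_fraction_sd[i]:.1f}% of variance")
```

```
reproducible dimension: 1
dim 1: 94.4% +/- 0.3% of variance
dim 2: 0.9% +/- 0.2% of variance
```

One reproducible linear dimension carries ~94% of the cohort's sum of
squares: subjects share a common connectome core and differ essentially by
a global multiplicative constant. Independently permuting each subject's
link labels (`permute_dataset(..., mode="links")`) drops the reproducible
dimension to 0 — the structure lives in the anatomical labeling, not in
the value distribution.

## Experiments and CLI

Thirteen named, seeded experiment tags
(`d1_sc`, `d1_cfc`, `d1_mfc`, `d1_ct3`, `d1_bold`, `d2_nogsr`,
`d5_permutations`, `d6_simulated`, `d7_pooled`, `d8_intrahemispheric`,
`d9_residual`, `d10_average_subject`, `d11_dynamic`) each run one analysis
design on a shared synthetic study and emit a JSON report:

```sh
scfc cohort --n-regions 40 --n-subjects 5 --seed 1 --out out/cohort
scfc experiment d7_pooled --seed 1 --out out/reports
scfc experiment all --seed 1 --out out/reports
scfc invert --seed 1 --out out/inversion
```

`scfc simulate`, `scfc fc` and `scfc svd` expose the individual stages on
delimited-text files. See `docs/methods.md` for the model equations,
parameter defaults, and the design choices behind the synthetic study.

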