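# iscn — individual structural covariance networks

`iscn` builds per-subject morphological brain networks from regional
gray-matter value distributions and relates their graph-theoretic properties
to neuropsychiatric symptom burden. It is aimed at neuroimaging groups
studying biologically-defined Alzheimer's disease cohorts (CSF or
amyloid-PET confirmed) with behavioral instruments such as the Mild
Behavioral Impairment Checklist (MBI-C), and at methodologists who need a
fully synthetic, ground-truthed testbed for this class of pipeline.

## The method

For each subject, the gray-matter values inside each of *n* atlas regions
(e.g. AAL-90) are collected and each region's probability density *p* is
estimated by Gaussian-kernel KDE (Silverman bandwidth). Every region pair is
scored with the symmetric Kullback–Leibler similarity

```
KLS(p, q) = exp(−KL(p‖q) − KL(q‖p)) ∈ (0, 1],   KLS = 1 ⇔ p = q,
```

giving an n × n connectivity matrix per subject. Matrices are proportionally
thresholded into binary graphs over a density grid (d = 0.10–0.40, step
0.02); at each density the pipeline computes nodal degree, clustering, path
length and efficiency, and global small-world statistics normalized by
degree-preserving Maslov–Sneppen null networks:

```
γ = Cp_real / Cp_random,   λ = Lp_real / Lp_random,   σ = γ/λ  (small-world iff σ > 1.1).
```

Metric curves are integrated over the density grid (trapezoid AUC) to
threshold-free scalars, and each region's AUC metric is related to MBI-C
total and domain subscores by partial correlation adjusted for sex, age,
disease duration and MMSE, with Benjamini–Hochberg FDR correction within
each (score, metric) family of regions. Clinical utilities cover MBI-C
scoring (34 items, 5 domains, high-burden split ≥ 16), CSF AT(N)
classification (Aβ42 < 599, t-Tau > 342, p-Tau181 > 57 pg/mL, with the
t-Tau/Aβ42 ratio rescue), eligibility screening (biomarker-compatible,
CDR ≤ 1, typical phenotype), anticholinergic burden and normative z-scores.

Because no imaging data ship with the package, a first-class synthetic
cohort generator (`iscn.cohort`) produces regional value samples whose
distributions covary through community-structured latent factors, MBI-C
responses with optional planted factor→domain effects, and CSF values
straddling the cutoffs — see `docs/methods.md` for the generative model and
its calibration.

## Worked example

```python
from iscn import (CohortConfig, build_matrix, generate_cohort, small_world,
                  threshold_by_density)

cohort = generate_cohort(CohortConfig(n_subjects=1, n_regions=90, seed=7))
matrix = build_matrix(cohort.samples[0])
print(matrix.values.shape, round(float(matrix.values[0, 1]), 3))

graph = threshold_by_density(matrix, 0.24)
sw = small_world(graph, n_random=100, seed=0)
print(f"sigma={sw.sigma:.2f} gamma={sw.gamma:.2f} lambda={sw.lambda_:.2f}")
```

prints

```
(90, 90) 0.955
sigma=1.58 gamma=3.14 lambda=1.99
```

i.e. regions 1 and 2 (same community) have nearly identical gray-matter
distributions (KLS 0.96), and at density 0.24 this subject's network is
clearly small-world: 3.1× the clustering of degree-matched random networks
(γ) at 2.0× their path length (λ), σ = γ/λ ≈ 1.6 > 1.1.

The same end to end from the shell:

```
iscn run --seed 1 --n-random 100 --out runs/demo
```

writes the cohort TSVs, per-subject matrices, an AUC table, the exclusion
log and the FDR-corrected association table under `runs/demo/`.

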