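# Methods

## Overview

`iscn` implements a per-subject ("individual") structural covariance network
analysis for gray-matter morphometry, together with the clinical scoring and
statistics that surround it in a typical biologically-defined Alzheimer's
disease study:

1. **Network construction** — for each subject, the distribution of
   gray-matter values inside each atlas region is estimated by Gaussian-kernel
   KDE and every region pair is scored with the symmetric Kullback–Leibler
   similarity `KLS(p, q) = exp(−[KL(p‖q) + KL(q‖p)])`, giving a symmetric
   region × region matrix with entries in (0, 1] and unit diagonal.
2. **Graph metrics** — each matrix is proportionally thresholded over a grid
   of connection densities (default 0.10–0.40, step 0.02, 16 values) into
   binary graphs. Nodal degree, clustering, path length and efficiency are
   computed at every density and integrated to area-under-curve (AUC)
   scalars; global clustering and characteristic path length are normalized
   by the means of a Maslov–Sneppen degree-preserving null ensemble to give
   γ, λ and the small-world index σ = γ/λ (criterion σ > 1.1).
3. **Clinical scoring** — MBI-C (34 items, five domains, severities 0–3,
   high-burden split at a configurable total, default ≥ 16), CSF AT(N)
   classification with strict cutoffs (A+ iff Aβ42 < 599 pg/mL, N+ iff
   t-Tau > 342, T+ iff p-Tau181 > 57) plus a t-Tau/Aβ42 ratio rescue for
   A+T−N+ profiles, roster screening (biomarker-compatible, CDR ≤ 1, typical
   phenotype), anticholinergic burden totals, normative z-scores and the
   actuarial MCI rule (≥ 2 tests < −1.5 SD, complaint, preserved ADL, no
   dementia).
4. **Association statistics** — Shapiro–Wilk-gated group comparisons
   (t-test vs Wilcoxon–Mann–Whitney), Spearman screens, and the headline
   analysis: partial correlations between nodal AUC metrics and MBI-C scores
   adjusted for sex, age, disease duration and MMSE, with Benjamini–Hochberg
   FDR within each (score, metric) family of regions.

A note on the small-world convention: the literature this method descends
from defines σ = γ/λ, and that is what `iscn` computes; an alternative
reading (λ/γ) circulates in some criterion statements but is inconsistent
with σ > 1.1 indicating simultaneous high clustering and short paths, so it
is not used here.

## Density estimation and similarity

* **Bandwidth** — Silverman's rule, `h = (3n/4)^(−1/5) · sd` (the same rule
  scipy's `gaussian_kde` applies in one dimension; the test suite checks
  agreement to ~1e−10). A numerically constant sample falls back to
  `h = 1e−3 · max(|mean|, 1)` so the kernel never degenerates.
* **Pair grid** — the PDFs of a region pair are evaluated on a shared
  128-point equispaced grid spanning the pooled sample range extended by 3
  bandwidths (the larger of the two), which bounds kernel mass lost at the
  boundary below ~0.3% and makes the entry invariant to the order of the
  pair's regions.
* **Discretization** — densities are converted to probability masses
  (density × spacing), floored at ε = 1e−12 and renormalized, so every KL
  term is finite even for disjoint supports.
* **Accuracy** — for two Gaussians with common sd σ and mean separation Δ
  the closed form is `KL_sym = (Δ/σ)²`. At n = 50 000 the plug-in estimate
  carries (i) a small positive KLS bias from bandwidth smoothing
  (σ_eff² = σ² + h²) and (ii) a negative KLS bias from sampling noise in the
  tails, which grows with Δ; the net accuracy at Δ = 2σ is about −8% with a
  per-draw sd of the same order, which is why the oracle test averages
  independent replicate draws rather than trusting one draw.
* The batched evaluation of all pair grids is a numba kernel (exact Gaussian
  kernel sums, no approximation); `scipy.stats.gaussian_kde` is used as the
  reference implementation in the tests.

## Thresholding and graph metrics

* Proportional thresholding keeps the `floor(d · n(n−1)/2)` largest
  off-diagonal weights as unweighted edges; ties at the cut are broken by
  (larger weight, then lexicographic node pair), so edge sets are
  deterministic and nested across densities.
* Conventions for fragmented graphs: clustering is 0 for degree < 2;
  characteristic path length averages over reachable pairs only (count of
  unreachable pairs is logged); nodal efficiency counts unreachable nodes as
  0; the nodal path length of an isolated node is undefined (NaN), and any
  node-metric curve containing an undefined value propagates NaN to its AUC
  rather than inventing a finite value. Downstream association analyses drop
  missing AUCs listwise per analysis.
* The null ensemble applies `swaps_per_edge × E` attempted double-edge swaps
  per replicate (default 100 × E; proposals creating self-loops or
  multi-edges are rejected and still count, the convention of standard
  `randmio`-style implementations). Degree sequences are preserved exactly;
  a graph with no valid swap (star, complete graph) is returned unchanged
  with a warning. Ensemble statistics (`Cp_random`, `Lp_random`) are means
  over `n_random` replicates — 1000 by default for production use; the
  calibration tests use 100 (standard error of ensemble means scales as
  1/√n_random, so 100 replicates already pin σ to a few percent).
* AUC uses the trapezoid rule on the scheduled densities.
* All heavy inner loops (swaps, BFS path lengths, clustering of null
  replicates) are numba kernels operating on boolean adjacency matrices;
  the test suite proves exact agreement with hand-written brute-force
  BFS/triangle-enumeration oracles and with networkx on random graphs.

## Synthetic cohort generator

The generator produces the statistical structure the analysis assumes, so
the whole pipeline can be exercised and calibrated without any imaging data.

Per subject *s* and region *r* in community *c*:

    value = μ_r + δ_{s,r} + ε,            ε ~ N(0, noise_sd), clipped to (0, 1.5]
    δ_{s,r} = s₀ · [ w·f_{s,c} + √(1−w²) · exp(−g·tanh f_{s,c}) · u_{s,r} ]

with community factors `f ~ N(0,1)`, idiosyncratic `u ~ N(0,1)`, loading
`w = within_community_loading` (default 0.8) and fixed scales
`s₀ = 0.10` (shift) and `g = 1.6` (coherence gain). Community base means are
evenly spaced over 0.35–0.75 with ±0.05 per-region jitter, on the scale of
modulated gray-matter intensities; voxel noise sd defaults to 0.1.

Why this form:

* The `w·f` term shifts all of a community's regional distributions
  together, giving the *covariance across subjects* that structural
  covariance analysis presupposes.
* The `exp(−g·tanh f)` term tightens a community's internal spread as its
  factor grows, so `f` is a *monotone driver of its regions' within-community
  similarity and hence of their degree/efficiency* — the property the
  planted-effect machinery needs. `tanh` bounds the modulation to
  `[e^−g, e^g]` so an extreme factor loosens a community without destroying
  its identity.
* The scales were set from the Gaussian closed form `KL_sym = (Δmean/sd)²`
  so that within-community similarities straddle the proportional-threshold
  boundary (the thresholded graphs then sit in the small-world regime,
  σ ≈ 1.2–4 over densities 0.10–0.40) while adjacent communities overlap
  enough that the graphs do not trivially split into cliques. At low
  densities some subjects' graphs still fragment — as real proportionally
  thresholded covariance networks do — which is precisely why the analysis
  integrates metrics over a density range instead of trusting one threshold.

MBI-C items: each domain has a latent trait; planted effects make the trait
a correlation-`effect_size` mixture of the chosen region's community factor.
Items load 0.7 on their domain trait and are thresholded at (0.5, 1.2, 2.0)
into severities 0–3, giving realistic endorsement rates (~30%) and totals
whose median sits near the high-burden split of 16. With a planted effect of
0.6 the domain subscore correlates ~0.5 with the factor (discretization
attenuates the item-sum correlation to ~0.8 of the trait's).

CSF triplets are drawn from truncated normals on the correct side of each
cutoff for the requested AT(N) profile mix (default 90% A+T+N+, 10% A+T−N+),
with location/scale matching typical early-AD assay values; demographics
(age ≈ 70 ± 7, ~30% male, CDR 0.5/1.0, MMSE ≈ 22 ± 4, log-normal disease
duration ≈ 2.7 ± 1.7 y) are drawn independently of the network factors, so
covariate adjustment is exercised but unconfounded by construction.

What the generator does **not** emulate: spatial structure (no volumes,
registration or smoothing artifacts), scanner/site effects, age- or
atrophy-dependent covariance, missing data, and any dependence of
demographics on the network factors. Passing calibration tests on this
cohort therefore demonstrates the *statistical machinery* (effect recovery,
FDR control, small-world detection), not robustness to real-data
confounding.

## Problem sizes used by the test and acceptance runs

Chosen once, as the package's own balance between statistical resolution and
a tractable default test run:

* Small-world acceptance run: 30 subjects × 90 regions at 500 voxels/region,
  16 densities, 100 null networks per graph at 30 × E attempted swaps per
  replicate (σ shifts by less than the ensemble standard error relative to
  100 × E on these graphs, i.e. the chains are fully mixed).
* Effect-recovery calibration: planted effect 0.6 on the impulse-dyscontrol
  domain, 20 seeds × 200 subjects, 30 regions in 6 communities at the
  generator's default 500 voxels/region, 64-point pair grids, nodal metrics
  only (associations do not consume the null ensemble). Null (no-effect)
  calibration: 20 seeds × 100 subjects at 200 voxels/region (FDR control
  does not depend on the network's measurement precision), all 6 scores ×
  4 metrics × 30 regions.
* Gaussian-oracle accuracy: mean over 100 replicate draws at n = 50 000 per
  separation.

## Numerical and design choices

* Partial correlation is Pearson-on-residuals (both variables residualized
  on an intercept plus standardized covariates by least squares), p from
  `t = R√((n−2−k)/(1−R²))` with `n−2−k` df. Standardizing covariates
  changes nothing mathematically (correlation is affine-invariant, which the
  tests assert) but conditions the solve. A rank-based variant can be had by
  rank-transforming inputs upstream; the default follows the common practice
  of reporting plain R.
* FDR families: per (score, metric) across regions, the narrowest family a
  regions × metrics × scores screen naturally defines; configurable.
  Undefined results (zero-variance, insufficient n) are excluded from the
  family before adjustment and reported with NaN p-values.
* Sex is coded 0/1 (F/M) before adjustment; subjects with missing values are
  dropped listwise per analysis with the per-analysis n reported.
* Eligibility rules run in the fixed order biomarker → CDR → phenotype and
  log exactly one reason per excluded subject; retained + excluded always
  equals the roster size.
* The MBI-C item→domain map (5/6/12/5/6 items) and all cutoffs are
  configuration with the published defaults; the t-Tau/Aβ42 ratio threshold
  has no published assay value and defaults to 0.52, a conventional choice
  that must be reviewed per laboratory.
* Determinism: every stage seeds its own RNG stream derived from a single
  root seed; reruns with the same configuration reproduce the association
  table byte-identically.

## Known limitations

* KLS similarity saturates near 0 for well-separated regional distributions,
  so very low similarities are estimated with large relative noise (see the
  accuracy note above); the analysis only consumes similarity *ranks* through
  proportional thresholding, which is far more stable.
* σ is undefined (error) when the null ensemble is triangle-free
  (`Cp_random = 0`), which happens for very sparse graphs on few nodes; the
  default density grid on 90 nodes stays clear of this regime.
* The generator's single-factor-per-community structure makes all regions of
  a planted community carry the association signal; region-level resolution
  inside a community is not a claim the synthetic calibration can support.
* Real-mode inputs assume voxel values are already extracted (or NIfTI
  volumes already segmented, modulated and registered); no preprocessing is
  provided.
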