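# On-disk formats

All artifacts are plain TSV/JSON so runs are diffable and portable.

## Regional values TSV (`regional_values.tsv`)

Long format, one row per voxel value:

| column | type | meaning |
|---|---|---|
| `subject_id` | str | unique subject identifier |
| `region_id` | int | 1-based atlas region index (1..90 for AAL-90) |
| `value` | float | gray-matter value (modulated intensity), unitless |

Every subject must provide ≥ 30 values per region for a stable KDE.

## Clinical TSV (`clinical.tsv`)

One row per subject.

| column | type | meaning |
|---|---|---|
| `subject_id` | str | matches the regional values TSV |
| `age` | float | years |
| `sex` | `M`/`F` | coded 1/0 for covariate adjustment |
| `education` | float | years |
| `disease_duration` | float | years since symptom onset |
| `cdr_global` | float | Clinical Dementia Rating global stage (0, 0.5, 1, 2, 3) |
| `cdr_sob` | float | CDR sum of boxes |
| `mmse` | int | Mini-Mental State Examination, 0–30 |
| `phenotype` | str | `typical` or an atypical label (e.g. `lvPPA`) |
| `csf_profile` | str | AT(N) label (synthetic cohorts only; informative) |
| `abeta42`, `ttau`, `ptau181` | float | CSF biomarkers, pg/mL; may be empty |
| `amyloid_pet_positive` | bool | may be empty; used when CSF is absent |
| `med_antidepressant` … `med_memantine` | bool | medication flags |
| `acb_total` | int | summed anticholinergic burden score |
| `mbic_item_1` … `mbic_item_34` | int | MBI-C severities, 0 (not endorsed) to 3 |

Eligibility requires at least one of CSF triplet / PET status per subject.

## Truth JSON (`truth.json`, synthetic cohorts)

`seed`, `planted_effects` (list of `{region_index, mbic_domain,
effect_size}` with 0-based region indices), `communities` (0-based community
per region), and `latent_factors` (per subject, per community).

## Connectivity matrix TSV (`matrices/<subject>.tsv`)

Square table, region labels (`R001`…) as header and `region` index column;
symmetric, unit diagonal, full float precision.

## AUC table (`auc_metrics.tsv`)

Long format: `subject_id`, `scope` (`node`/`global`), `region_label`
(empty for global rows), `metric`, `auc`. Nodal metrics: `degree`,
`clustering`, `path_length`, `efficiency`; global: `cp_real`, `lp_real`,
`cp_random`, `lp_random`, `gamma`, `lambda`, `sigma`. A NaN AUC marks a
node-metric curve undefined somewhere on the density grid.

## Association table (`associations.tsv`)

`region_label`, `metric`, `score`, `R` (partial correlation), `p_raw`,
`p_fdr` (Benjamini–Hochberg within the (score, metric) family of regions),
`n` (subjects entering that analysis after listwise deletion),
`significant` (`p_fdr` < α).

## Exclusion log (`exclusion_log.tsv`)

`subject_id`, `rule` (`biomarker`/`cdr`/`phenotype`), `detail` — one row per
excluded subject, under the first violated rule.
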