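"""End-to-end orchestration: screening -> scoring -> networks -> metrics -> stats.

A single :class:`RunConfig` drives the whole analysis in either mode
(``synthetic`` generates a cohort; ``real`` reads the long-format
regional-values TSV and the clinical TSV).  Every random draw derives from
the root seed through a fixed fan-out scheme, so a rerun with the same
configuration reproduces the association table bit-identically.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .clinical import ATNCutoffs, apply_eligibility, score_mbic_frame
from .cohort import CohortConfig, generate_cohort, read_clinical, read_regional_values, write_cohort
from .graphs import DensitySchedule, MetricCurves, metric_curves
from .network import ConnectivityMatrix, build_matrix
from .stats import DEFAULT_COVARIATES, DEFAULT_METRICS, DEFAULT_SCORES, run_association_analysis

__all__ = [
    "RunConfig",
    "RunReport",
    "run_pipeline",
    "summarize_small_world",
    "write_matrix_tsv",
    "read_matrix_tsv",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    mode: str = "synthetic"
    out_dir: str = "iscn_run"
    seed: int = 0
    # synthetic mode
    cohort: CohortConfig | None = None
    # real mode
    regional_values_path: str | None = None
    clinical_path: str | None = None
    # analysis parameters
    schedule: DensitySchedule = field(default_factory=DensitySchedule)
    grid_points: int = 128
    n_random: int = 1000
    swaps_per_edge: int = 100
    compute_global: bool = True
    mbic_threshold: int = 16
    cutoffs: ATNCutoffs = field(default_factory=ATNCutoffs)
    covariates: tuple[str, ...] = DEFAULT_COVARIATES
    scores: tuple[str, ...] = DEFAULT_SCORES
    metrics: tuple[str, ...] = DEFAULT_METRICS
    alpha: float = 0.05
    correlation_method: str = "pearson"

    def __post_init__(self) -> None:
        if self.mode not in ("synthetic", "real"):
            raise ValueError(f"mode must be 'synthetic' or 'real', got {self.mode!r}")
        if self.mode == "real":
            for name in ("regional_values_path", "clinical_path"):
                path = getattr(self, name)
                if path is None or not Path(path).exists():
                    raise ValueError(f"real mode requires an existing {name}, got {path!r}")
        if self.mode == "synthetic" and self.cohort is None:
            object.__setattr__(self, "cohort", CohortConfig(n_subjects=30, seed=self.seed))
        if not 0 < self.alpha < 1:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")

    def fingerprint(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class RunReport:
    config_fingerprint: str
    seed: int
    stage_counts: dict[str, int]
    exclusion_log: pd.DataFrame
    sigma_range: tuple[float, float] | None
    small_world_flag: bool | None
    associations: pd.DataFrame

    def summary(self) -> dict:
        return {
            "config_fingerprint": self.config_fingerprint,
            "seed": self.seed,
            "stage_counts": self.stage_counts,
            "sigma_range": self.sigma_range,
            "small_world_flag": self.small_world_flag,
            "n_significant": int(self.associations["significant"].sum()),
        }


def summarize_small_world(sigma_values) -> tuple[float, float, bool]:
    """(min sigma, max sigma, flag) over subjects x densities.

    The flag is True iff the minimum exceeds the small-world criterion 1.1,
    i.e. every subject's network is small-world at every scheduled density.
    """
    sigma = np.asarray(sigma_values, dtype=float).ravel()
    if sigma.size == 0:
        raise ValueError("need sigma values for at least one subject")
    lo, hi = float(np.min(sigma)), float(np.max(sigma))
    return lo, hi, lo > 1.1


def _subject_seed(root: int, index: int) -> int:
    # deterministic per-subject stream from the root seed
    return int((root + 7919 * (index + 1)) % 2147483647)


def write_matrix_tsv(matrix: ConnectivityMatrix, path) -> None:
    frame = pd.DataFrame(matrix.values, index=matrix.labels, columns=matrix.labels)
    frame.to_csv(path, sep="\t", index_label="region", float_format="%.17g")


def read_matrix_tsv(path, subject_id: str | None = None) -> ConnectivityMatrix:
    frame = pd.read_csv(path, sep="\t", index_col="region")
    if subject_id is None:
        subject_id = Path(path).stem
    return ConnectivityMatrix(
        subject_id=subject_id, values=frame.to_numpy(float), labels=list(frame.columns)
    )


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute eligibility -> scoring -> networks -> metrics/AUC -> associations."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    counts: dict[str, int] = {}

    # --- input stage -------------------------------------------------------
    if config.mode == "synthetic":
        cohort_cfg = CohortConfig(**{**asdict_cohort(config.cohort), "seed": config.seed})
        cohort = generate_cohort(cohort_cfg)
        write_cohort(cohort, out / "cohort")
        samples = cohort.samples
        clinical = cohort.clinical
    else:
        samples = read_regional_values(config.regional_values_path)
        clinical = read_clinical(config.clinical_path)
    counts["input_subjects"] = len(samples)
    logger.info("stage input: %d subjects", len(samples))

    # --- clinical scoring and screening -----------------------------------
    clinical = pd.concat(
        [
            clinical.reset_index(drop=True),
            score_mbic_frame(clinical.reset_index(drop=True), threshold=config.mbic_threshold),
        ],
        axis=1,
    )
    retained, exclusion_log = apply_eligibility(clinical, cutoffs=config.cutoffs)
    counts["retained_subjects"] = len(retained)
    exclusion_log.to_csv(out / "exclusion_log.tsv", sep="\t", index=False)
    if retained.empty:
        raise RuntimeError("screening stage retained no subjects")
    retained_ids = set(retained["subject_id"])
    samples = [s for s in samples if s.subject_id in retained_ids]
    if len(samples) != len(retained):
        raise RuntimeError("screening stage: clinical and sample subjects out of sync")

    # --- network construction ---------------------------------------------
    matrices = []
    matrix_dir = out / "matrices"
    matrix_dir.mkdir(exist_ok=True)
    for sample in samples:
        matrix = build_matrix(sample, n_points=config.grid_points)
        write_matrix_tsv(matrix, matrix_dir / f"{sample.subject_id}.tsv")
        matrices.append(matrix)
    counts["matrices"] = len(matrices)
    logger.info("stage networks: %d matrices of size %d", len(matrices), matrices[0].n_regions)

    # --- graph metrics ------------------------------------------------------
    curves: list[MetricCurves] = []
    for i, matrix in enumerate(matrices):
        curves.append(
            metric_curves(
                matrix,
                schedule=config.schedule,
                n_random=config.n_random,
                seed=_subject_seed(config.seed, i),
                compute_global=config.compute_global,
                swaps_per_edge=config.swaps_per_edge,
            )
        )
    auc = pd.concat([c.auc_frame() for c in curves], ignore_index=True)
    auc.to_csv(out / "auc_metrics.tsv", sep="\t", index=False)
    counts["metric_subjects"] = len(curves)

    if config.compute_global:
        sigma = np.stack([c.global_curves["sigma"] for c in curves])
        sigma_lo, sigma_hi, flag = summarize_small_world(sigma)
    else:
        sigma_lo = sigma_hi = None
        flag = None

    # --- associations -------------------------------------------------------
    nodal_auc = auc[auc["scope"] == "node"].rename(columns={"auc": "auc"})
    associations = run_association_analysis(
        nodal_auc,
        retained,
        scores=config.scores,
        metrics=config.metrics,
        covariates=config.covariates,
        alpha=config.alpha,
        method=config.correlation_method,
    )
    counts["association_rows"] = len(associations)
    associations.to_csv(out / "associations.tsv", sep="\t", index=False)

    report = RunReport(
        config_fingerprint=config.fingerprint(),
        seed=config.seed,
        stage_counts=counts,
        exclusion_log=exclusion_log,
        sigma_range=None if sigma_lo is None else (sigma_lo, sigma_hi),
        small_world_flag=flag,
        associations=associations,
    )
    (out / "report.json").write_text(json.dumps(report.summary(), indent=1))
    return report


def asdict_cohort(cohort: CohortConfig) -> dict:
    return {
        "n_subjects": cohort.n_subjects,
        "n_regions": cohort.n_regions,
        "voxels_per_region": cohort.voxels_per_region,
        "n_communities": cohort.n_communities,
        "within_community_loading": cohort.within_community_loading,
        "noise_sd": cohort.noise_sd,
        "planted_effects": cohort.planted_effects,
        "csf_profile_mix": dict(cohort.csf_profile_mix),
        "seed": cohort.seed,
    }
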