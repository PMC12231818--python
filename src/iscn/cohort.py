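"""Synthetic cohorts with the statistical structure the pipeline assumes.

The generator emulates the data a gray-matter covariance study feeds the
analysis: per-region voxel-value samples whose distributions covary across
subjects through community-structured latent factors, MBI-C item responses
with optional planted monotone effects of a region's community factor on a
chosen domain subscore, and CSF triplets straddling the assay cutoffs.

Generative model (per subject s, region r in community c):

    value = mu_r + delta_{s,r} + eps,    eps ~ N(0, noise_sd), clipped to (0, 1.5]
    delta_{s,r} = s0 * [ w * f_{s,c} + sqrt(1 - w^2) * exp(-g * f_{s,c}) * u_{s,r} ]

with community factors f_{s,c} ~ N(0,1), region-idiosyncratic u_{s,r} ~ N(0,1),
loading w = ``within_community_loading`` and fixed scales s0 (shift) and g
(coherence gain).  The factor f thus acts twice: it shifts all of its
community's distributions together (covariance across subjects) and it
tightens the community's internal spread as it grows (the exp(-g f) term), so
a larger f monotonically increases within-community similarity — f is a
monotone driver of its regions' network centrality.  Planted effects couple a
domain's latent trait to f with a chosen correlation, giving ground truth for
the association stage.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from .clinical import MBIC_DOMAINS, compute_acb
from .network import RegionalSampleSet

__all__ = [
    "PlantedEffect",
    "CohortConfig",
    "SyntheticCohort",
    "generate_cohort",
    "write_cohort",
    "read_regional_values",
    "read_clinical",
    "read_truth",
]

# Fixed design scales of the generator (GM-intensity units), set from the
# Gaussian closed form KL_sym = (d(mean)/sd)^2 so that within-community
# similarities straddle the proportional-threshold boundary (keeping the
# thresholded graphs in the small-world regime across 0.10-0.40) while
# adjacent communities overlap enough to connect; see docs/methods.md.
SHIFT_SCALE = 0.10
COHERENCE_GAIN = 1.6
BASE_MEAN_RANGE = (0.35, 0.75)
BASE_MEAN_JITTER = 0.05
VALUE_CLIP = (1e-6, 1.5)

# MBI-C item model: item latent = a * trait + sqrt(1-a^2) * noise, thresholded
# at the cuts below into severities 0..3.
ITEM_LOADING = 0.7
ITEM_CUTS = (0.5, 1.2, 2.0)

CSF_PROFILES = ("A+T+N+", "A+T-N+", "A-T-N-")


@dataclass(frozen=True)
class PlantedEffect:
    """Ground-truth coupling: domain trait correlates ``effect_size`` with the
    community factor of ``region_index`` (0-based)."""

    region_index: int
    mbic_domain: str
    effect_size: float


@dataclass(frozen=True)
class CohortConfig:
    n_subjects: int
    n_regions: int = 90
    voxels_per_region: int = 500
    n_communities: int = 6
    within_community_loading: float = 0.8
    noise_sd: float = 0.1
    planted_effects: tuple[PlantedEffect, ...] = ()
    csf_profile_mix: dict[str, float] = field(
        default_factory=lambda: {"A+T+N+": 0.9, "A+T-N+": 0.1, "A-T-N-": 0.0}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError(f"n_subjects must be >= 1, got {self.n_subjects}")
        if self.n_regions < 2:
            raise ValueError(f"n_regions must be >= 2, got {self.n_regions}")
        if self.voxels_per_region < 30:
            raise ValueError(
                f"voxels_per_region must be >= 30 for stable KDE, got {self.voxels_per_region}"
            )
        if not 1 <= self.n_communities <= self.n_regions:
            raise ValueError(f"n_communities must be in 1..n_regions, got {self.n_communities}")
        if not 0.0 <= self.within_community_loading <= 1.0:
            raise ValueError(
                f"within_community_loading must be in [0, 1], got {self.within_community_loading}"
            )
        if self.noise_sd <= 0:
            raise ValueError(f"noise_sd must be positive, got {self.noise_sd}")
        effects = tuple(
            e if isinstance(e, PlantedEffect) else PlantedEffect(*e) for e in self.planted_effects
        )
        object.__setattr__(self, "planted_effects", effects)
        for e in effects:
            if not 0 <= e.region_index < self.n_regions:
                raise ValueError(f"planted region_index {e.region_index} >= n_regions")
            if e.mbic_domain not in MBIC_DOMAINS:
                raise ValueError(f"unknown mbic_domain {e.mbic_domain!r}")
            if not -1.0 <= e.effect_size <= 1.0:
                raise ValueError(f"effect_size must be in [-1, 1], got {e.effect_size}")
        if set(self.csf_profile_mix) - set(CSF_PROFILES):
            raise ValueError(f"csf_profile_mix keys must be among {CSF_PROFILES}")
        if abs(sum(self.csf_profile_mix.values()) - 1.0) > 1e-9:
            raise ValueError("csf_profile_mix proportions must sum to 1")

    @property
    def communities(self) -> np.ndarray:
        """0-based community assignment per region (contiguous blocks)."""
        return (np.arange(self.n_regions) * self.n_communities // self.n_regions).astype(int)


@dataclass
class SyntheticCohort:
    config: CohortConfig
    samples: list[RegionalSampleSet]
    clinical: pd.DataFrame
    latent_factors: pd.DataFrame  # subjects x communities
    truth: tuple[PlantedEffect, ...]

    def __post_init__(self) -> None:
        ids = [s.subject_id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise ValueError("subject identifiers must be unique")
        if list(self.clinical["subject_id"]) != ids:
            raise ValueError("clinical table subjects must match sample subjects")


def generate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Draw a fully reproducible synthetic cohort from ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    n_s, n_r, n_v = config.n_subjects, config.n_regions, config.voxels_per_region
    comm = config.communities
    n_c = config.n_communities

    base_means = np.linspace(*BASE_MEAN_RANGE, n_c)[comm]
    base_means = base_means + rng.uniform(-BASE_MEAN_JITTER, BASE_MEAN_JITTER, n_r)

    factors = rng.standard_normal((n_s, n_c))
    idio = rng.standard_normal((n_s, n_r))
    w = config.within_community_loading
    f_region = factors[:, comm]  # (n_s, n_r)
    # tanh bounds the spread modulation to [e^-g, e^g] so extreme factors
    # loosen/tighten a community without destroying its identity
    delta = SHIFT_SCALE * (
        w * f_region
        + np.sqrt(1.0 - w**2) * np.exp(-COHERENCE_GAIN * np.tanh(f_region)) * idio
    )

    subject_ids = [f"S{i + 1:04d}" for i in range(n_s)]
    samples = []
    for s in range(n_s):
        noise = rng.normal(0.0, config.noise_sd, size=(n_r, n_v))
        vox = np.clip(base_means[:, None] + delta[s][:, None] + noise, *VALUE_CLIP)
        samples.append(
            RegionalSampleSet(
                subject_id=subject_ids[s],
                values={r + 1: vox[r] for r in range(n_r)},
            )
        )

    items = _draw_mbic_items(rng, factors, comm, config.planted_effects, n_s)
    csf = _draw_csf(rng, config.csf_profile_mix, n_s)
    clinical = _draw_clinical(rng, subject_ids, n_s)
    clinical = pd.concat([clinical, csf, items], axis=1)

    latent = pd.DataFrame(
        factors, index=subject_ids, columns=[f"community_{c}" for c in range(n_c)]
    )
    latent.index.name = "subject_id"
    return SyntheticCohort(
        config=config,
        samples=samples,
        clinical=clinical,
        latent_factors=latent,
        truth=config.planted_effects,
    )


def _draw_mbic_items(rng, factors, comm, planted, n_s) -> pd.DataFrame:
    """Severities 0-3 for items 1..34 with planted domain-trait couplings."""
    from .clinical import DEFAULT_MBIC_DOMAIN_MAP

    traits = {}
    for domain in MBIC_DOMAINS:
        effects = [e for e in planted if e.mbic_domain == domain]
        loadings = np.array([e.effect_size for e in effects])
        drivers = np.stack(
            [factors[:, comm[e.region_index]] for e in effects], axis=1
        ) if effects else np.zeros((n_s, 0))
        resid_var = max(0.0, 1.0 - float(np.sum(loadings**2)))
        traits[domain] = drivers @ loadings + np.sqrt(resid_var) * rng.standard_normal(n_s)

    cols = {}
    a = ITEM_LOADING
    for item in range(1, 35):
        t = traits[DEFAULT_MBIC_DOMAIN_MAP[item]]
        latent = a * t + np.sqrt(1 - a**2) * rng.standard_normal(n_s)
        severity = np.digitize(latent, ITEM_CUTS)  # 0..3
        cols[f"mbic_item_{item}"] = severity.astype(int)
    return pd.DataFrame(cols)


def _truncnorm(rng, mean, sd, lo, hi, size):
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return sps.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def _draw_csf(rng, mix, n_s) -> pd.DataFrame:
    """CSF triplets per profile, drawn around the assay cutoffs (599/342/57)."""
    profiles = rng.choice(CSF_PROFILES, size=n_s, p=[mix.get(k, 0.0) for k in CSF_PROFILES])
    abeta = np.empty(n_s)
    ttau = np.empty(n_s)
    ptau = np.empty(n_s)
    for i, prof in enumerate(profiles):
        a_pos = prof[1] == "+"
        t_pos = prof[3] == "+"
        n_pos = prof[5] == "+"
        abeta[i] = (
            _truncnorm(rng, 530, 90, 150, 599, 1) if a_pos else _truncnorm(rng, 700, 90, 599, 1200, 1)
        )[0]
        ptau[i] = (
            _truncnorm(rng, 130, 55, 57, 400, 1) if t_pos else _truncnorm(rng, 45, 8, 5, 57, 1)
        )[0]
        ttau[i] = (
            _truncnorm(rng, 830, 300, 342, 2500, 1) if n_pos else _truncnorm(rng, 250, 60, 50, 342, 1)
        )[0]
    return pd.DataFrame(
        {
            "csf_profile": profiles,
            "abeta42": np.round(abeta, 1),
            "ttau": np.round(ttau, 1),
            "ptau181": np.round(ptau, 1),
        }
    )


def _draw_clinical(rng, subject_ids, n_s) -> pd.DataFrame:
    """Demographics and instruments for an early-AD cohort (MCI to CDR 1)."""
    age = np.clip(rng.normal(69.75, 6.88, n_s), 55, 90).round(1)
    sex = np.where(rng.random(n_s) < 10 / 33, "M", "F")
    education = np.clip(rng.normal(10, 4, n_s), 3, 20).round(0)
    duration = np.round(rng.lognormal(mean=0.838, sigma=0.582, size=n_s), 2)
    cdr = rng.choice([0.5, 1.0], size=n_s)
    cdr_sob = np.round(np.clip(rng.normal(3.0, 2.2, n_s), 0.5, 9.0) * 2) / 2
    mmse = np.clip(rng.normal(22, 4, n_s), 10, 30).round(0).astype(int)
    meds = {
        "med_antidepressant": rng.random(n_s) < 0.48,
        "med_antipsychotic": rng.random(n_s) < 0.10,
        "med_hypnotic": rng.random(n_s) < 0.15,
        "med_anxiolytic": rng.random(n_s) < 0.15,
        "med_achei": rng.random(n_s) < 0.60,
        "med_memantine": rng.random(n_s) < 0.20,
    }
    acb = [
        compute_acb(rng.choice([0, 1, 2, 3], size=3, p=[0.6, 0.25, 0.1, 0.05]))
        for _ in range(n_s)
    ]
    return pd.DataFrame(
        {
            "subject_id": subject_ids,
            "age": age,
            "sex": sex,
            "education": education,
            "disease_duration": duration,
            "cdr_global": cdr,
            "cdr_sob": cdr_sob,
            "mmse": mmse,
            "phenotype": "typical",
            "amyloid_pet_positive": pd.array([pd.NA] * n_s, dtype="boolean"),
            **meds,
            "acb_total": acb,
        }
    )


# ---------------------------------------------------------------------------
# On-disk round trip: the exact formats the real-mode pipeline reads.


def write_cohort(cohort: SyntheticCohort, directory) -> dict[str, Path]:
    """Write regional-values TSV, clinical TSV, and truth JSON to ``directory``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "regional_values": directory / "regional_values.tsv",
        "clinical": directory / "clinical.tsv",
        "truth": directory / "truth.json",
    }
    frames = []
    for sample in cohort.samples:
        for region in sample.region_ids:
            vals = sample.values[region]
            frames.append(
                pd.DataFrame(
                    {
                        "subject_id": sample.subject_id,
                        "region_id": region,
                        "value": vals,
                    }
                )
            )
    long = pd.concat(frames, ignore_index=True)
    long.to_csv(paths["regional_values"], sep="\t", index=False, float_format="%.17g")
    cohort.clinical.to_csv(paths["clinical"], sep="\t", index=False)
    truth = {
        "seed": cohort.config.seed,
        "planted_effects": [
            {
                "region_index": e.region_index,
                "mbic_domain": e.mbic_domain,
                "effect_size": e.effect_size,
            }
            for e in cohort.truth
        ],
        "communities": cohort.config.communities.tolist(),
        "latent_factors": {
            sid: row.tolist() for sid, row in cohort.latent_factors.iterrows()
        },
    }
    paths["truth"].write_text(json.dumps(truth, indent=1))
    return paths


def read_regional_values(path) -> list[RegionalSampleSet]:
    """Read a long-format regional-values TSV back into per-subject samples."""
    long = pd.read_csv(path, sep="\t", float_precision="round_trip")
    required = {"subject_id", "region_id", "value"}
    if not required <= set(long.columns):
        raise ValueError(f"{path}: regional-values TSV needs columns {sorted(required)}")
    samples = []
    for sid, group in long.groupby("subject_id", sort=False):
        values = {
            int(region): sub["value"].to_numpy(dtype=float)
            for region, sub in group.groupby("region_id", sort=True)
        }
        samples.append(RegionalSampleSet(subject_id=str(sid), values=values))
    return samples


def read_clinical(path) -> pd.DataFrame:
    clinical = pd.read_csv(path, sep="\t")
    if "subject_id" not in clinical.columns:
        raise ValueError(f"{path}: clinical TSV needs a subject_id column")
    clinical["subject_id"] = clinical["subject_id"].astype(str)
    return clinical


def read_truth(path) -> list[PlantedEffect]:
    payload = json.loads(Path(path).read_text())
    return [
        PlantedEffect(e["region_index"], e["mbic_domain"], e["effect_size"])
        for e in payload["planted_effects"]
    ]
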