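"""Clinical instrument scoring, CSF biomarker classification, and screening.

Covers the clinical side of the pipeline: the Mild Behavioral Impairment
Checklist (MBI-C; 34 caregiver-rated items in five domains, each absent or
rated 1-3 for severity), AT(N) classification from the CSF triplet
(Abeta42, t-Tau, p-Tau181) against assay cutoffs, roster screening
(biomarker-compatible, CDR <= 1, typical phenotype), anticholinergic burden
(ACB) totals, normative z-scoring of neuropsychological tests, and the
actuarial MCI rule (>= 2 tests below -1.5 SD plus complaint, preserved ADL,
no dementia).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "MBIC_DOMAINS",
    "DEFAULT_MBIC_DOMAIN_MAP",
    "MBICResponse",
    "MBICScore",
    "CSFTriplet",
    "ATNCutoffs",
    "ATNProfile",
    "score_mbic",
    "score_mbic_frame",
    "classify_atn",
    "apply_eligibility",
    "compute_acb",
    "domain_zscores",
    "classify_mci",
]

logger = logging.getLogger(__name__)

MBIC_DOMAINS = (
    "decreased_motivation",
    "affective_dysregulation",
    "impulse_dyscontrol",
    "social_inappropriateness",
    "perception_thought",
)

# Published MBI-C structure: 5 + 6 + 12 + 5 + 6 = 34 items, in instrument order.
DEFAULT_MBIC_DOMAIN_MAP: dict[int, str] = {
    **{i: "decreased_motivation" for i in range(1, 6)},
    **{i: "affective_dysregulation" for i in range(6, 12)},
    **{i: "impulse_dyscontrol" for i in range(12, 24)},
    **{i: "social_inappropriateness" for i in range(24, 29)},
    **{i: "perception_thought" for i in range(29, 35)},
}

#: Sample-derived median split on the MBI-C total: high burden iff total >= 16.
DEFAULT_MBIC_THRESHOLD = 16


@dataclass(frozen=True)
class MBICResponse:
    """One MBI-C item: endorsed yes/no, severity 1-3 when endorsed else 0."""

    item_id: int
    endorsed: bool
    severity: int

    def __post_init__(self) -> None:
        if not 1 <= self.item_id <= 34:
            raise ValueError(f"item_id must be in 1..34, got {self.item_id}")
        if self.endorsed and self.severity not in (1, 2, 3):
            raise ValueError(
                f"item {self.item_id}: endorsed items need severity in 1..3, got {self.severity}"
            )
        if not self.endorsed and self.severity != 0:
            raise ValueError(
                f"item {self.item_id}: non-endorsed items must have severity 0, got {self.severity}"
            )

    @classmethod
    def from_severity(cls, item_id: int, severity: int) -> "MBICResponse":
        return cls(item_id=item_id, endorsed=severity > 0, severity=severity)


@dataclass(frozen=True)
class MBICScore:
    total: int
    subscores: dict[str, int]
    high_burden: bool


def score_mbic(
    responses,
    threshold: int = DEFAULT_MBIC_THRESHOLD,
    domain_map: dict[int, str] | None = None,
) -> MBICScore:
    """Sum severities into domain subscores and the MBI-C total.

    Requires exactly one response per item 1..34; high burden is a total at
    or above ``threshold``.
    """
    if domain_map is None:
        domain_map = DEFAULT_MBIC_DOMAIN_MAP
    if set(domain_map) != set(range(1, 35)) or set(domain_map.values()) != set(MBIC_DOMAINS):
        raise ValueError("domain map must cover items 1..34 across the 5 MBI-C domains")
    seen = [r.item_id for r in responses]
    duplicates = sorted({i for i in seen if seen.count(i) > 1})
    missing = sorted(set(range(1, 35)) - set(seen))
    if duplicates or missing:
        raise ValueError(
            f"invalid MBI-C response set: duplicate items {duplicates}, missing items {missing}"
        )
    subscores = {d: 0 for d in MBIC_DOMAINS}
    for r in responses:
        subscores[domain_map[r.item_id]] += r.severity
    total = sum(subscores.values())
    return MBICScore(total=total, subscores=subscores, high_burden=total >= threshold)


def score_mbic_frame(
    clinical: pd.DataFrame,
    item_prefix: str = "mbic_item_",
    threshold: int = DEFAULT_MBIC_THRESHOLD,
    domain_map: dict[int, str] | None = None,
) -> pd.DataFrame:
    """Score MBI-C item columns of a clinical table.

    Expects columns ``{item_prefix}1`` .. ``{item_prefix}34`` holding
    severities 0-3; returns a frame indexed like ``clinical`` with
    ``mbic_total``, ``mbic_<domain>`` and ``mbic_high_burden`` columns.
    """
    cols = [f"{item_prefix}{i}" for i in range(1, 35)]
    missing = [c for c in cols if c not in clinical.columns]
    if missing:
        raise ValueError(f"clinical table lacks MBI-C item columns: {missing}")
    out = []
    for _, row in clinical[cols].iterrows():
        responses = [
            MBICResponse.from_severity(i, int(row[f"{item_prefix}{i}"])) for i in range(1, 35)
        ]
        score = score_mbic(responses, threshold=threshold, domain_map=domain_map)
        record = {"mbic_total": score.total, "mbic_high_burden": score.high_burden}
        record.update({f"mbic_{d}": v for d, v in score.subscores.items()})
        out.append(record)
    return pd.DataFrame(out, index=clinical.index)


@dataclass(frozen=True)
class CSFTriplet:
    """CSF biomarker triplet in pg/mL."""

    abeta42: float
    ttau: float
    ptau181: float

    def __post_init__(self) -> None:
        for name in ("abeta42", "ttau", "ptau181"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise ValueError(f"CSF {name} must be strictly positive, got {v}")


@dataclass(frozen=True)
class ATNCutoffs:
    """Assay cutoffs: A+ iff Abeta42 < 599; N+ iff t-Tau > 342; T+ iff p-Tau181 > 57.

    ``ttau_abeta_ratio`` is the positivity threshold for the t-Tau/Abeta42
    ratio used to rescue A+T-N+ profiles as AD-compatible; the source assay
    documentation does not print a value, so it is configuration (default
    0.52, a conventional choice in the AT(N) literature).
    """

    abeta42: float = 599.0
    ttau: float = 342.0
    ptau181: float = 57.0
    ttau_abeta_ratio: float = 0.52

    def __post_init__(self) -> None:
        for name in ("abeta42", "ttau", "ptau181", "ttau_abeta_ratio"):
            if getattr(self, name) <= 0:
                raise ValueError(f"cutoff {name} must be positive")


@dataclass(frozen=True)
class ATNProfile:
    a_positive: bool
    t_positive: bool
    n_positive: bool
    ad_compatible: bool

    def label(self) -> str:
        return (
            f"A{'+' if self.a_positive else '-'}"
            f"T{'+' if self.t_positive else '-'}"
            f"N{'+' if self.n_positive else '-'}"
        )


def classify_atn(csf: CSFTriplet, cutoffs: ATNCutoffs | None = None) -> ATNProfile:
    """AT(N) profile from the CSF triplet, with the ratio rescue rule.

    Inequalities are strict as printed: a value exactly at a cutoff is
    negative.  A profile is AD-compatible iff A+ and either T+ or a positive
    t-Tau/Abeta42 ratio (> ``cutoffs.ttau_abeta_ratio``).
    """
    if cutoffs is None:
        cutoffs = ATNCutoffs()
    a = csf.abeta42 < cutoffs.abeta42
    t = csf.ptau181 > cutoffs.ptau181
    n = csf.ttau > cutoffs.ttau
    ratio_positive = (csf.ttau / csf.abeta42) > cutoffs.ttau_abeta_ratio
    return ATNProfile(
        a_positive=a,
        t_positive=t,
        n_positive=n,
        ad_compatible=a and (t or ratio_positive),
    )


_EXCLUSION_RULES = ("biomarker", "cdr", "phenotype")


def apply_eligibility(
    roster: pd.DataFrame,
    cutoffs: ATNCutoffs | None = None,
    max_cdr: float = 1.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Screen a clinical roster; returns (retained, exclusion_log).

    Retains subjects that are biomarker AD-compatible (CSF profile or amyloid
    PET positivity), have global CDR <= ``max_cdr``, and a typical phenotype.
    Each excluded subject is logged once, under the first violated rule in
    the fixed order biomarker -> CDR -> phenotype; subjects with no biomarker
    information are excluded with reason "unassessable".
    """
    if roster.empty:
        raise ValueError("roster is empty")
    if cutoffs is None:
        cutoffs = ATNCutoffs()
    retained_rows = []
    log_rows = []
    for _, row in roster.iterrows():
        rule, detail = _first_exclusion(row, cutoffs, max_cdr)
        if rule is None:
            retained_rows.append(row)
        else:
            log_rows.append({"subject_id": row["subject_id"], "rule": rule, "detail": detail})
    retained = pd.DataFrame(retained_rows, columns=roster.columns).reset_index(drop=True)
    log = pd.DataFrame(log_rows, columns=["subject_id", "rule", "detail"])
    assert len(retained) + len(log) == len(roster)
    return retained, log


def _has_value(row: pd.Series, col: str) -> bool:
    return col in row.index and pd.notna(row[col])


def _first_exclusion(row: pd.Series, cutoffs: ATNCutoffs, max_cdr: float):
    csf_present = all(_has_value(row, c) for c in ("abeta42", "ttau", "ptau181"))
    pet_present = _has_value(row, "amyloid_pet_positive")
    if not csf_present and not pet_present:
        return "biomarker", "unassessable: no CSF and no amyloid PET"
    compatible = False
    detail = []
    if csf_present:
        profile = classify_atn(
            CSFTriplet(float(row["abeta42"]), float(row["ttau"]), float(row["ptau181"])),
            cutoffs,
        )
        compatible = profile.ad_compatible
        detail.append(f"CSF {profile.label()}")
    if not compatible and pet_present:
        compatible = bool(row["amyloid_pet_positive"])
        detail.append(f"PET {'positive' if compatible else 'negative'}")
    if not compatible:
        return "biomarker", "not AD-compatible: " + ", ".join(detail)
    if float(row["cdr_global"]) > max_cdr:
        return "cdr", f"CDR {row['cdr_global']} > {max_cdr}"
    if str(row["phenotype"]) != "typical":
        return "phenotype", f"atypical phenotype: {row['phenotype']}"
    return None, ""


def compute_acb(med_scores) -> int:
    """Total anticholinergic burden: the sum of per-drug ACB scores (0-3)."""
    total = 0
    for s in med_scores:
        if s not in (0, 1, 2, 3):
            raise ValueError(f"ACB scores must be integers in 0..3, got {s!r}")
        total += int(s)
    return total


@dataclass(frozen=True)
class TestNorm:
    """Normative mean/SD for one neuropsychological test.

    ``higher_is_better`` orients the z-score so that positive always means
    better performance (timed tests, error counts, etc. are negated).
    """

    mean: float
    sd: float
    higher_is_better: bool = True

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise ValueError(f"norm SD must be positive, got {self.sd}")


def domain_zscores(
    raw: dict[str, float],
    norms: dict[str, TestNorm],
    domain_map: dict[str, list[str]],
) -> tuple[dict[str, float], dict[str, float]]:
    """Normative z-scores per test and their mean per cognitive domain.

    Missing tests are excluded from the domain mean (count logged); a domain
    with no available test scores NaN.  Returns (domain_scores, test_z).
    """
    test_z: dict[str, float] = {}
    for test, value in raw.items():
        if test not in norms:
            raise ValueError(f"no norm provided for test {test!r}")
        if value is None or (isinstance(value, float) and np.isnan(value)):
            continue
        norm = norms[test]
        z = (float(value) - norm.mean) / norm.sd
        test_z[test] = z if norm.higher_is_better else -z
    domain_scores: dict[str, float] = {}
    n_missing = 0
    for domain, tests in domain_map.items():
        zs = [test_z[t] for t in tests if t in test_z]
        n_missing += len(tests) - len(zs)
        domain_scores[domain] = float(np.mean(zs)) if zs else float("nan")
    if n_missing:
        logger.info("domain_zscores: %d test score(s) missing from domain means", n_missing)
    return domain_scores, test_z


def classify_mci(
    test_z: dict[str, float],
    complaint: bool,
    adl_preserved: bool,
    dementia_dx: bool = False,
    z_cut: float = -1.5,
    min_tests: int = 2,
) -> bool:
    """Actuarial MCI rule.

    MCI iff at least ``min_tests`` tests fall below ``z_cut`` (more than 1.5
    SD below the normative mean by default), a cognitive complaint is
    reported, activities of daily living are preserved, and there is no
    dementia diagnosis.
    """
    n_impaired = sum(1 for z in test_z.values() if z < z_cut)
    return bool(n_impaired >= min_tests and complaint and adl_preserved and not dementia_dx)
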