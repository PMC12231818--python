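"""Association statistics: normality-gated comparisons, partial correlation, FDR.

The inferential stage mirrors a standard clinical-neuroimaging workflow:
Shapiro-Wilk decides between the two-sample t-test and the
Wilcoxon-Mann-Whitney test for group contrasts; Spearman correlations screen
instrument scores against clinical variables; the headline analysis is the
partial correlation between each region's AUC network metric and each MBI-C
score, adjusting for sex, age, disease duration, and MMSE, with
Benjamini-Hochberg FDR correction within each (score, metric) family of
regions.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .clinical import MBIC_DOMAINS

__all__ = [
    "GroupComparison",
    "normality_gate",
    "compare_groups",
    "spearman_screen",
    "partial_correlation",
    "fdr_bh",
    "run_association_analysis",
    "DEFAULT_COVARIATES",
    "DEFAULT_SCORES",
]

logger = logging.getLogger(__name__)

DEFAULT_COVARIATES = ("sex", "age", "disease_duration", "mmse")
DEFAULT_SCORES = ("mbic_total",) + tuple(f"mbic_{d}" for d in MBIC_DOMAINS)
DEFAULT_METRICS = ("degree", "clustering", "path_length", "efficiency")


@dataclass(frozen=True)
class GroupComparison:
    variable: str
    test: str  # "t" or "wilcoxon-mann-whitney"
    statistic: float
    p_raw: float
    p_fdr: float | None = None


def normality_gate(groups, alpha: float = 0.05) -> str:
    """Shapiro-Wilk gate: "normal" iff every group's test has p > alpha.

    Groups smaller than 3 or with zero variance cannot be assessed and gate
    to "non-normal" with a warning.
    """
    for g in groups:
        g = np.asarray(g, dtype=float)
        if g.size < 3:
            warnings.warn(f"group of size {g.size} < 3; gating to non-normal", stacklevel=2)
            return "non-normal"
        if np.ptp(g) == 0:
            warnings.warn("constant group; gating to non-normal", stacklevel=2)
            return "non-normal"
        if sps.shapiro(g).pvalue <= alpha:
            return "non-normal"
    return "normal"


def compare_groups(x, y, variable: str = "", alpha: float = 0.05) -> GroupComparison:
    """Two-sided two-sample comparison with the normality-gated test choice."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs at least 2 observations")
    if normality_gate([x, y], alpha=alpha) == "normal":
        stat, p = sps.ttest_ind(x, y)
        test = "t"
    else:
        stat, p = sps.mannwhitneyu(x, y, alternative="two-sided")
        test = "wilcoxon-mann-whitney"
    return GroupComparison(variable=variable, test=test, statistic=float(stat), p_raw=float(p))


def spearman_screen(scores: pd.DataFrame, variables: pd.DataFrame) -> pd.DataFrame:
    """Spearman rho and two-sided p for every (score, variable) pair.

    Pairs are evaluated on their jointly non-missing subjects; a pair with
    zero variance in either vector is flagged undefined (NaN rho/p).
    """
    rows = []
    for score in scores.columns:
        for var in variables.columns:
            s = pd.to_numeric(scores[score], errors="coerce")
            v = pd.to_numeric(variables[var], errors="coerce")
            ok = s.notna() & v.notna()
            n = int(ok.sum())
            if n < 4:
                raise ValueError(f"pair ({score}, {var}) has fewer than 4 paired values")
            if s[ok].nunique() < 2 or v[ok].nunique() < 2:
                rows.append((score, var, np.nan, np.nan, n, True))
                continue
            res = sps.spearmanr(s[ok], v[ok])
            rows.append((score, var, float(res.statistic), float(res.pvalue), n, False))
    return pd.DataFrame(
        rows, columns=["score", "variable", "rho", "p_raw", "n", "undefined"]
    )


def partial_correlation(x, y, covariates=None, method: str = "pearson") -> tuple[float, float]:
    """Pearson correlation of x and y after residualizing both on covariates.

    Both variables are regressed (least squares) on an intercept plus the
    standardized covariate columns; R is the Pearson correlation of the
    residuals and p comes from ``t = R * sqrt((n-2-k) / (1-R^2))`` with
    ``n-2-k`` degrees of freedom (two-sided).  With no covariates this is
    exactly the ordinary Pearson correlation.  ``method="spearman"`` rank
    transforms x, y and the covariates first (rank-based partial
    correlation).
    """
    if method not in ("pearson", "spearman"):
        raise ValueError(f"method must be 'pearson' or 'spearman', got {method!r}")
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if method == "spearman":
        x = sps.rankdata(x)
        y = sps.rankdata(y)
        if covariates is not None:
            cov_arr = np.asarray(covariates, dtype=float)
            if cov_arr.ndim == 1:
                cov_arr = cov_arr[:, None]
            covariates = np.column_stack(
                [sps.rankdata(cov_arr[:, j]) for j in range(cov_arr.shape[1])]
            )
    n = x.size
    if y.size != n:
        raise ValueError("x and y must have equal length")
    if covariates is None:
        cov = np.empty((n, 0))
    else:
        cov = np.asarray(covariates, dtype=float)
        if cov.ndim == 1:
            cov = cov[:, None]
    k = cov.shape[1]
    if n <= k + 2:
        raise ValueError(f"need n > k + 2 (n={n}, k={k})")
    if k:
        sd = cov.std(axis=0)
        if np.any(sd == 0):
            zero = np.nonzero(sd == 0)[0].tolist()
            raise ValueError(f"covariate column(s) {zero} are constant (collinear with intercept)")
        cov = (cov - cov.mean(axis=0)) / sd
    design = np.column_stack([np.ones(n), cov])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        corr = np.corrcoef(cov, rowvar=False)
        pairs = [
            (i, j)
            for i in range(k)
            for j in range(i + 1, k)
            if abs(corr[i, j]) > 1 - 1e-10
        ]
        raise ValueError(f"rank-deficient covariates; collinear column pairs: {pairs}")
    rx = x - design @ np.linalg.lstsq(design, x, rcond=None)[0]
    ry = y - design @ np.linalg.lstsq(design, y, rcond=None)[0]
    if float(rx @ rx) == 0.0 or float(ry @ ry) == 0.0:
        warnings.warn("zero residual variance; partial correlation undefined", stacklevel=2)
        return float("nan"), float("nan")
    r = float(rx @ ry / np.sqrt((rx @ rx) * (ry @ ry)))
    df = n - 2 - k
    r_clamped = min(max(r, -1.0), 1.0)
    if abs(r_clamped) == 1.0:
        return r_clamped, 0.0
    t = r_clamped * np.sqrt(df / (1.0 - r_clamped**2))
    p = float(2.0 * sps.t.sf(abs(t), df))
    return r, p


def fdr_bh(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must be finite and in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _encode_sex(series: pd.Series) -> pd.Series:
    if pd.api.types.is_numeric_dtype(series):
        return pd.to_numeric(series)
    return series.map({"F": 0.0, "f": 0.0, "M": 1.0, "m": 1.0})


def run_association_analysis(
    auc: pd.DataFrame,
    clinical: pd.DataFrame,
    scores=DEFAULT_SCORES,
    metrics=DEFAULT_METRICS,
    covariates=DEFAULT_COVARIATES,
    alpha: float = 0.05,
    method: str = "pearson",
) -> pd.DataFrame:
    """Partial correlations of nodal AUC metrics with MBI-C scores, FDR-corrected.

    ``auc`` is the long-format nodal AUC table (subject_id, region_label,
    metric, auc); ``clinical`` holds one row per subject with the score and
    covariate columns.  For each (score, metric) family the correlation is
    computed across regions and Benjamini-Hochberg corrected within the
    family; subjects with missing values are dropped per analysis (listwise,
    with the per-analysis n reported).
    """
    needed = {"subject_id", "region_label", "metric", "auc"}
    if not needed <= set(auc.columns):
        raise ValueError(f"auc table needs columns {sorted(needed)}")
    clin = clinical.set_index("subject_id")
    if "sex" in covariates:
        clin = clin.assign(sex=_encode_sex(clin["sex"]))
    wide = auc.pivot_table(
        index="subject_id", columns=["metric", "region_label"], values="auc"
    )

    results = []
    for score in scores:
        for metric in metrics:
            if metric not in wide.columns.get_level_values(0):
                raise ValueError(f"metric {metric!r} absent from the AUC table")
            block = wide[metric]
            family = []
            for region in block.columns:
                frame = pd.concat(
                    [
                        block[region].rename("x"),
                        clin[score].rename("y"),
                        clin[list(covariates)],
                    ],
                    axis=1,
                ).dropna()
                n = len(frame)
                if n <= len(covariates) + 2:
                    family.append((region, np.nan, np.nan, n))
                    continue
                r, p = partial_correlation(
                    frame["x"].to_numpy(),
                    frame["y"].to_numpy(),
                    frame[list(covariates)].to_numpy(),
                    method=method,
                )
                family.append((region, r, p, n))
            defined = [f for f in family if np.isfinite(f[2])]
            if not defined:
                raise ValueError(f"empty family for score={score}, metric={metric}")
            adjusted = dict(
                zip([f[0] for f in defined], fdr_bh([f[2] for f in defined]))
            )
            n_dropped = len(family) - len(defined)
            if n_dropped:
                logger.info(
                    "family (%s, %s): %d region(s) undefined and excluded from FDR",
                    score,
                    metric,
                    n_dropped,
                )
            for region, r, p, n in family:
                p_adj = adjusted.get(region, np.nan)
                results.append(
                    {
                        "region_label": region,
                        "metric": metric,
                        "score": score,
                        "R": r,
                        "p_raw": p,
                        "p_fdr": p_adj,
                        "n": n,
                        "significant": bool(np.isfinite(p_adj) and p_adj < alpha),
                    }
                )
    return pd.DataFrame(results)
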