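"""Individual structural covariance networks from regional value distributions.

A subject's network is built by (i) collecting the gray-matter voxel values of
each parcellated region, (ii) estimating each region's probability density
function with a Gaussian-kernel KDE (Silverman bandwidth), and (iii) scoring
every region pair with the symmetric Kullback–Leibler divergence of the two
densities, mapped to a similarity::

    KLS(p, q) = exp(-KL_sym(p, q)),
    KL_sym(p, q) = sum_i p_i log(p_i / q_i) + sum_i q_i log(q_i / p_i)

KLS is 1 iff the two distributions coincide and decays toward 0 as they
separate, so each subject yields a symmetric region-by-region similarity
matrix with unit diagonal — an individual morphological connectome.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from ._kernels import kde_gauss_eval

__all__ = [
    "DensityGrid",
    "RegionalPDF",
    "RegionalSampleSet",
    "ConnectivityMatrix",
    "silverman_bandwidth",
    "estimate_pdf",
    "symmetric_kl",
    "kls",
    "build_matrix",
    "extract_regional_values",
]

#: Probability-mass floor applied before renormalization so that every
#: Kullback-Leibler term is finite even for disjoint supports.
MASS_FLOOR = 1e-12

#: Minimum number of voxel values required for a stable density estimate.
MIN_REGION_SAMPLES = 30


@dataclass(frozen=True)
class DensityGrid:
    """Evaluation support for a regional PDF: ``n_points`` equispaced points."""

    lower: float
    upper: float
    n_points: int = 128

    def __post_init__(self) -> None:
        if not np.isfinite(self.lower) or not np.isfinite(self.upper):
            raise ValueError("DensityGrid bounds must be finite")
        if not self.lower < self.upper:
            raise ValueError(
                f"DensityGrid requires lower < upper, got [{self.lower}, {self.upper}]"
            )
        if self.n_points < 16:
            raise ValueError(f"DensityGrid requires n_points >= 16, got {self.n_points}")

    @property
    def points(self) -> np.ndarray:
        return np.linspace(self.lower, self.upper, self.n_points)

    @property
    def spacing(self) -> float:
        return (self.upper - self.lower) / (self.n_points - 1)


@dataclass(frozen=True)
class RegionalPDF:
    """A discretized regional density: probability masses on a grid."""

    grid: DensityGrid
    mass: np.ndarray

    def __post_init__(self) -> None:
        mass = np.asarray(self.mass, dtype=float)
        if mass.shape != (self.grid.n_points,):
            raise ValueError(
                f"mass vector has shape {mass.shape}, expected ({self.grid.n_points},)"
            )
        if not np.all(mass > 0):
            raise ValueError("probability masses must be strictly positive (floored)")
        if abs(float(mass.sum()) - 1.0) > 1e-9:
            raise ValueError("probability masses must sum to 1 within 1e-9")
        object.__setattr__(self, "mass", mass)


@dataclass
class RegionalSampleSet:
    """Per-region gray-matter value samples for one subject.

    ``values`` maps a 1-based region id to the vector of voxel values inside
    that region.  Regions whose sample is smaller than
    :data:`MIN_REGION_SAMPLES` are listed in ``flagged``.
    """

    subject_id: str
    values: dict[int, np.ndarray]
    flagged: frozenset[int] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        clean: dict[int, np.ndarray] = {}
        for region, vals in self.values.items():
            arr = np.asarray(vals, dtype=float).ravel()
            if arr.size and not np.all(np.isfinite(arr)):
                raise ValueError(f"region {region} contains non-finite values")
            clean[int(region)] = arr
        self.values = clean
        auto_flagged = {r for r, v in clean.items() if v.size < MIN_REGION_SAMPLES}
        self.flagged = frozenset(self.flagged) | frozenset(auto_flagged)

    @property
    def region_ids(self) -> list[int]:
        return sorted(self.values)

    @property
    def n_regions(self) -> int:
        return len(self.values)


@dataclass
class ConnectivityMatrix:
    """Symmetric region-by-region KLS similarity matrix with unit diagonal."""

    subject_id: str
    values: np.ndarray
    labels: list[str]

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if values.shape != (n, n):
            raise ValueError(f"matrix shape {values.shape} does not match {n} labels")
        if not np.allclose(values, values.T):
            raise ValueError("connectivity matrix must be symmetric")
        if not np.allclose(np.diag(values), 1.0):
            raise ValueError("connectivity matrix diagonal must be 1")
        off = values[~np.eye(n, dtype=bool)]
        if off.size and (np.any(off <= 0) or np.any(off > 1)):
            raise ValueError("off-diagonal similarities must lie in (0, 1]")
        self.values = values

    @property
    def n_regions(self) -> int:
        return len(self.labels)


def silverman_bandwidth(values: np.ndarray) -> float:
    """Silverman's rule-of-thumb bandwidth, ``(3n/4)**(-1/5) * sd``.

    A zero-variance sample falls back to ``1e-3 * max(|mean|, 1)`` so the
    kernel never degenerates to a point mass.
    """
    values = np.asarray(values, dtype=float)
    n = values.size
    if n < 2:
        raise ValueError("bandwidth requires at least 2 values")
    sd = float(values.std(ddof=1))
    scale = max(abs(float(values.mean())), 1.0)
    if sd <= 1e-12 * scale:  # numerically constant sample
        return 1e-3 * scale
    return float((n * 3.0 / 4.0) ** (-0.2) * sd)


def estimate_pdf(values: np.ndarray, grid: DensityGrid) -> RegionalPDF:
    """Gaussian-kernel KDE of ``values`` discretized to probability masses.

    The continuous density is evaluated at the grid points, converted to
    masses (density times grid spacing), floored at :data:`MASS_FLOOR` and
    renormalized to sum to one.
    """
    values = np.asarray(values, dtype=float).ravel()
    if values.size < MIN_REGION_SAMPLES:
        raise ValueError(
            f"PDF estimation requires >= {MIN_REGION_SAMPLES} values, got {values.size}"
        )
    if not np.all(np.isfinite(values)):
        raise ValueError("PDF estimation requires finite values")
    h = silverman_bandwidth(values)
    density = kde_gauss_eval(values, grid.points, h)
    return _masses_from_density(density, grid)


def _masses_from_density(density: np.ndarray, grid: DensityGrid) -> RegionalPDF:
    mass = np.maximum(density * grid.spacing, MASS_FLOOR)
    mass /= mass.sum()
    return RegionalPDF(grid=grid, mass=mass)


def _check_same_grid(p: RegionalPDF, q: RegionalPDF) -> None:
    if p.grid != q.grid:
        raise ValueError(f"PDF grids differ: {p.grid} vs {q.grid}")


def symmetric_kl(p: RegionalPDF, q: RegionalPDF) -> float:
    """Symmetric Kullback–Leibler divergence (nats), ``KL(p||q) + KL(q||p)``."""
    _check_same_grid(p, q)
    log_ratio = np.log(p.mass) - np.log(q.mass)
    return float(np.sum((p.mass - q.mass) * log_ratio))


def kls(p: RegionalPDF, q: RegionalPDF) -> float:
    """KL-based similarity ``exp(-KL_sym(p, q))`` in (0, 1]; 1 iff p == q."""
    return float(np.exp(-symmetric_kl(p, q)))


def pair_grid(
    values_a: np.ndarray, values_b: np.ndarray, n_points: int = 128
) -> DensityGrid:
    """Shared evaluation grid for one region pair.

    Spans the pooled sample range extended by three times the larger of the
    two Silverman bandwidths, so both kernels decay essentially to zero at
    the boundary.
    """
    h = max(silverman_bandwidth(values_a), silverman_bandwidth(values_b))
    lo = min(float(np.min(values_a)), float(np.min(values_b))) - 3.0 * h
    hi = max(float(np.max(values_a)), float(np.max(values_b))) + 3.0 * h
    return DensityGrid(lo, hi, n_points)


def build_matrix(
    samples: RegionalSampleSet,
    n_points: int = 128,
    allow_flagged: bool = False,
) -> ConnectivityMatrix:
    """KLS similarity matrix over all region pairs of one subject.

    For every unordered pair the two regional KDEs are evaluated on a shared
    pair-specific grid (see :func:`pair_grid`), discretized to probability
    masses and scored with :func:`kls`.  The result is symmetric by
    construction, has unit diagonal, and is invariant to the order in which
    the pair's regions are given.
    """
    if samples.flagged and not allow_flagged:
        raise ValueError(
            "regions with fewer than "
            f"{MIN_REGION_SAMPLES} values: {sorted(samples.flagged)}; "
            "pass allow_flagged=True to override"
        )
    regions = samples.region_ids
    n = len(regions)
    if n < 2:
        raise ValueError("need at least 2 regions to build a matrix")

    vals = [samples.values[r] for r in regions]
    bandwidths = np.array([silverman_bandwidth(v) for v in vals])
    mins = np.array([float(v.min()) for v in vals])
    maxs = np.array([float(v.max()) for v in vals])

    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    n_pairs = len(pairs)
    pi = np.array([p[0] for p in pairs])
    pj = np.array([p[1] for p in pairs])

    h_pair = np.maximum(bandwidths[pi], bandwidths[pj])
    lo = np.minimum(mins[pi], mins[pj]) - 3.0 * h_pair
    hi = np.maximum(maxs[pi], maxs[pj]) + 3.0 * h_pair
    spacing = (hi - lo) / (n_points - 1)
    # (n_pairs, n_points) grids; row k is the shared support of pair k
    grids = lo[:, None] + spacing[:, None] * np.arange(n_points)[None, :]

    # Evaluate each region's KDE once over the concatenated grids of all the
    # pairs it participates in; scatter the results into P (first region of
    # the pair) and Q (second region).
    dens_p = np.empty((n_pairs, n_points))
    dens_q = np.empty((n_pairs, n_points))
    for idx in range(n):
        rows_p = np.nonzero(pi == idx)[0]
        rows_q = np.nonzero(pj == idx)[0]
        pts = np.concatenate([grids[rows_p].ravel(), grids[rows_q].ravel()])
        dens = kde_gauss_eval(vals[idx], pts, float(bandwidths[idx]))
        split = rows_p.size * n_points
        dens_p[rows_p] = dens[:split].reshape(rows_p.size, n_points)
        dens_q[rows_q] = dens[split:].reshape(rows_q.size, n_points)

    p_mass = np.maximum(dens_p * spacing[:, None], MASS_FLOOR)
    p_mass /= p_mass.sum(axis=1, keepdims=True)
    q_mass = np.maximum(dens_q * spacing[:, None], MASS_FLOOR)
    q_mass /= q_mass.sum(axis=1, keepdims=True)

    kl_sym = np.sum((p_mass - q_mass) * (np.log(p_mass) - np.log(q_mass)), axis=1)
    sim = np.exp(-kl_sym)

    matrix = np.eye(n)
    matrix[pi, pj] = sim
    matrix[pj, pi] = sim
    labels = [f"R{r:03d}" for r in regions]
    return ConnectivityMatrix(subject_id=samples.subject_id, values=matrix, labels=labels)


def extract_regional_values(
    gm_volume,
    label_volume,
    subject_id: str = "subject",
    n_regions: int | None = None,
) -> RegionalSampleSet:
    """Collect gray-matter values per atlas region from voxel maps.

    Parameters
    ----------
    gm_volume, label_volume
        Either numpy arrays of identical shape or nibabel spatial images
        (``.nii``/``.nii.gz``); the label map holds 0 for background and
        1..n_regions for atlas regions.
    n_regions
        Number of atlas regions; defaults to the maximum label present.
    """
    gm = _as_array(gm_volume)
    labels = _as_array(label_volume)
    if gm.shape != labels.shape:
        raise ValueError(f"volume shapes differ: {gm.shape} vs {labels.shape}")
    labels = np.rint(labels).astype(int)
    if labels.min() < 0:
        raise ValueError("label volume contains negative labels")
    max_label = int(labels.max())
    if n_regions is None:
        n_regions = max_label
    if max_label > n_regions:
        raise ValueError(f"label {max_label} exceeds n_regions={n_regions}")
    if n_regions == 0:
        raise ValueError("label volume is all background; no regions to extract")

    values: dict[int, np.ndarray] = {}
    empty: list[int] = []
    for region in range(1, n_regions + 1):
        sample = gm[labels == region]
        values[region] = sample
        if sample.size == 0:
            empty.append(region)
    if len(empty) == n_regions:
        raise ValueError(f"all regions have zero voxels: {empty}")
    result = RegionalSampleSet(subject_id=subject_id, values=values)
    if result.flagged:
        warnings.warn(
            f"subject {subject_id}: regions with fewer than {MIN_REGION_SAMPLES} "
            f"voxels flagged: {sorted(result.flagged)}",
            stacklevel=2,
        )
    return result


def _as_array(volume) -> np.ndarray:
    if hasattr(volume, "get_fdata"):  # nibabel spatial image
        return np.asarray(volume.get_fdata())
    return np.asarray(volume, dtype=float)
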