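"""Sample QC, genotype PCA, classical MDS, and ratio-matched downsampling."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._util import ValidationError

DEFAULT_MISSINGNESS_MAX = 0.05
DEFAULT_OUTLIER_SD = 2.0


@dataclass
class StructureResult:
    """PCA/MDS coordinates with eigenvalues and exclusion bookkeeping."""

    coordinates: np.ndarray    # samples x k
    eigenvalues: np.ndarray    # length k, non-increasing
    method: str                # "pca" or "mds"

    def __post_init__(self):
        if np.any(np.diff(self.eigenvalues) > 1e-9):
            raise ValidationError("eigenvalues must be non-increasing")


def filter_sample_missingness(dosages: np.ndarray,
                              max_rate: float = DEFAULT_MISSINGNESS_MAX) -> np.ndarray:
    """Inclusion flags: a sample is excluded iff its missing fraction
    strictly exceeds ``max_rate`` (a sample at exactly the threshold stays)."""
    if not 0.0 < max_rate < 1.0:
        raise ValidationError("max_rate must lie in (0,1)")
    d = np.asarray(dosages, dtype=float)
    rate = np.mean(~np.isfinite(d), axis=1)
    return rate <= max_rate


def _fix_signs(components: np.ndarray) -> np.ndarray:
    """Deterministic sign convention: the largest-magnitude entry of each
    column is made positive."""
    out = components.copy()
    for j in range(out.shape[1]):
        col = out[:, j]
        if col[np.argmax(np.abs(col))] < 0:
            out[:, j] = -col
    return out


def genotype_pca(dosages: np.ndarray, k: int = 10) -> StructureResult:
    """PCA of a complete dose matrix with allele-frequency scaling.

    Each variant column is centered at 2*f and scaled by sqrt(2 f (1-f)),
    f being the observed allele frequency; monomorphic columns are dropped.
    Components come from the SVD of the scaled matrix with the
    largest-|loading| sign convention applied to the sample coordinates.
    """
    d = np.asarray(dosages, dtype=float)
    if not np.all(np.isfinite(d)):
        raise ValidationError("PCA needs a complete matrix; impute first")
    n = d.shape[0]
    if n < 2:
        raise ValidationError("need at least 2 samples")
    f = d.mean(axis=0) / 2.0
    poly = (f > 0) & (f < 1)
    x = (d[:, poly] - 2.0 * f[poly]) / np.sqrt(2.0 * f[poly] * (1.0 - f[poly]))
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    rank = int(np.sum(s > s[0] * 1e-10)) if s.size else 0
    k_eff = min(k, rank)
    coords = _fix_signs(u[:, :k_eff] * s[:k_eff])
    eigenvalues = (s[:k_eff] ** 2) / max(n - 1, 1)
    return StructureResult(coordinates=coords, eigenvalues=eigenvalues,
                           method="pca")


def pca_outlier_filter(pc_coords: np.ndarray,
                       n_sd: float = DEFAULT_OUTLIER_SD) -> np.ndarray:
    """Inclusion flags: excluded iff |PC1 or PC2 deviation from the mean|
    exceeds ``n_sd`` standard deviations.  With zero SD nothing is excluded."""
    c = np.asarray(pc_coords, dtype=float)
    if c.ndim != 2 or c.shape[1] < 2:
        raise ValidationError("need at least two PC columns")
    keep = np.ones(c.shape[0], dtype=bool)
    for j in (0, 1):
        sd = c[:, j].std(ddof=0)
        if sd == 0:
            continue
        keep &= np.abs(c[:, j] - c[:, j].mean()) <= n_sd * sd
    return keep


def allele_sharing_distance(dosages: np.ndarray) -> np.ndarray:
    """1 - IBS pairwise distance from doses.

    IBS proportion for a sample pair is 1 - |d_i - d_j| / 2 averaged over
    variants where both samples are observed.
    """
    d = np.asarray(dosages, dtype=float)
    obs = np.isfinite(d)
    d0 = np.where(obs, d, 0.0)
    obs_f = obs.astype(float)
    # sum over shared variants of |di - dj| via the identity on dose levels:
    # |di-dj| with levels {0,1,2} = di+dj - 2*min(di,dj); use direct loop-free
    # expansion over the three dose indicators
    n = d.shape[0]
    diff = np.zeros((n, n))
    shared = obs_f @ obs_f.T
    ind = [np.where(obs, (d == lvl).astype(float), 0.0) for lvl in (0.0, 1.0, 2.0)]
    for a, ia in enumerate(ind):
        for b, ib in enumerate(ind):
            if a != b:
                diff += abs(a - b) * (ia @ ib.T)
    with np.errstate(invalid="ignore", divide="ignore"):
        dist = np.where(shared > 0, diff / (2.0 * shared), 0.0)
    np.fill_diagonal(dist, 0.0)
    return dist


def classical_mds(distance_matrix: np.ndarray, dims: int = 2) -> StructureResult:
    """Torgerson MDS: double-center the squared distances, eigendecompose,
    embed on the top ``dims`` eigenvectors scaled by sqrt(eigenvalue)."""
    dmat = np.asarray(distance_matrix, dtype=float)
    if dmat.ndim != 2 or dmat.shape[0] != dmat.shape[1]:
        raise ValidationError("distance matrix must be square")
    if not np.allclose(dmat, dmat.T, atol=1e-8):
        raise ValidationError("distance matrix must be symmetric")
    if not np.allclose(np.diag(dmat), 0.0, atol=1e-8):
        raise ValidationError("distance matrix must have a zero diagonal")
    n = dmat.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (dmat ** 2) @ j
    eigval, eigvec = np.linalg.eigh(b)
    order = np.argsort(eigval)[::-1][:dims]
    lam = np.clip(eigval[order], 0.0, None)
    coords = _fix_signs(eigvec[:, order] * np.sqrt(lam))
    return StructureResult(coordinates=coords, eigenvalues=lam, method="mds")


def ratio_matched_downsample(metadata: pd.DataFrame, target_ratio: float,
                             seed: int, tolerance: float = 0.01) -> np.ndarray:
    """Random subset whose case:control ratio approximates ``target_ratio``.

    Keeps as many samples as the ratio allows: controls = min(available,
    floor(cases / ratio)) with cases trimmed to round(ratio * controls).
    Returns a boolean inclusion mask aligned with ``metadata`` rows; raises
    when the achievable ratio misses the target by more than ``tolerance``
    (relative).
    """
    if target_ratio <= 0:
        raise ValidationError("target_ratio must be positive")
    status = metadata["status"].to_numpy()
    case_idx = np.flatnonzero(status == "case")
    ctrl_idx = np.flatnonzero(status == "control")
    if case_idx.size == 0 or ctrl_idx.size == 0:
        raise ValidationError("need both cases and controls")
    n_ctrl = min(ctrl_idx.size, int(np.floor(case_idx.size / target_ratio)))
    n_case = min(case_idx.size, int(round(target_ratio * n_ctrl)))
    if n_ctrl == 0 or n_case == 0:
        raise ValidationError(
            f"ratio {target_ratio} unattainable with {case_idx.size} cases / "
            f"{ctrl_idx.size} controls"
        )
    achieved = n_case / n_ctrl
    if abs(achieved - target_ratio) / target_ratio > tolerance:
        raise ValidationError(
            f"achievable ratio {achieved:.4f} misses target {target_ratio:.4f}; "
            f"best with {case_idx.size} cases / {ctrl_idx.size} controls"
        )
    rng = np.random.default_rng(seed)
    keep = np.zeros(len(metadata), dtype=bool)
    keep[rng.choice(case_idx, size=n_case, replace=False)] = True
    keep[rng.choice(ctrl_idx, size=n_ctrl, replace=False)] = True
    return keep
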