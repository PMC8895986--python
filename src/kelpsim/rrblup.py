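"""Ridge-regression BLUP: marker effects, GEBVs and prediction accuracy.

The genomic-selection model is the standard marker mixed model
``y = 1*mu + X u + e`` with ``u ~ N(0, sigma_u^2 I)`` and
``e ~ N(0, sigma_e^2 I)``; the ridge solution is
``u = (Xc' Xc + lambda I)^-1 Xc' (y - ybar)`` with shrinkage ratio
``lambda = sigma_e^2 / sigma_u^2`` and ``Xc`` the column-centered dosage
matrix.  By default ``lambda`` is estimated by REML through a spectral
decomposition of the marker kernel (taken on whichever side of the duality
is smaller), with a one-dimensional optimisation of the variance ratio.

A fixed-``lambda`` override bypasses REML; the training set keeps running
Gram-matrix accumulators so recurrent refits on a growing record base cost
one Cholesky solve each.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import linalg, optimize
from scipy.linalg import blas as _blas

__all__ = ["TrainingSet", "RRBLUPFit", "fit_rrblup", "predict_gebv", "gs_accuracy"]


class TrainingSet:
    """Accumulated phenotyped sporophyte records on a fixed marker panel.

    Cohorts are appended as (dosage matrix, phenotype vector, year) blocks.
    Raw blocks are retained (uint8) for REML; sufficient statistics
    (Gram matrix, cross-products, sums) are maintained incrementally for the
    fixed-shrinkage fast path.
    """

    def __init__(self, n_markers: int):
        if n_markers < 1:
            raise ValueError("need at least one marker")
        self.n_markers = int(n_markers)
        self._blocks: list[np.ndarray] = []
        self._phenos: list[np.ndarray] = []
        self._years: list[np.ndarray] = []
        self._gram = np.zeros((n_markers, n_markers), dtype=np.float32, order="F")
        self._xty = np.zeros(n_markers)
        self._colsum = np.zeros(n_markers)
        self._ysum = 0.0
        self._yss = 0.0
        self.n_records = 0

    def add_cohort(self, dosages: np.ndarray, phenotypes: np.ndarray, year: int) -> None:
        dosages = np.asarray(dosages)
        phenotypes = np.asarray(phenotypes, dtype=np.float64)
        if dosages.ndim != 2 or dosages.shape[1] != self.n_markers:
            raise ValueError("dosage block does not match the marker panel")
        if dosages.shape[0] != phenotypes.shape[0]:
            raise ValueError("dosage and phenotype row counts differ")
        self._blocks.append(np.ascontiguousarray(dosages, dtype=np.uint8))
        self._phenos.append(phenotypes)
        self._years.append(np.full(phenotypes.shape[0], year, dtype=np.int64))
        x32 = np.asfortranarray(dosages, dtype=np.float32)
        self._gram = _blas.ssyrk(
            1.0, x32, beta=1.0, c=self._gram, trans=1, lower=1, overwrite_c=1
        )
        self._xty += dosages.T.astype(np.float64) @ phenotypes
        self._colsum += dosages.sum(axis=0, dtype=np.float64)
        self._ysum += float(phenotypes.sum())
        self._yss += float((phenotypes**2).sum())
        self.n_records += dosages.shape[0]

    @property
    def dosage_matrix(self) -> np.ndarray:
        return (
            np.concatenate(self._blocks, axis=0)
            if self._blocks
            else np.empty((0, self.n_markers), dtype=np.uint8)
        )

    @property
    def phenotypes(self) -> np.ndarray:
        return np.concatenate(self._phenos) if self._phenos else np.empty(0)

    @property
    def years(self) -> np.ndarray:
        return (
            np.concatenate(self._years) if self._years else np.empty(0, dtype=np.int64)
        )

    def centered_normal_equations(self) -> tuple[np.ndarray, np.ndarray]:
        """(Xc'Xc, Xc'yc) from the running accumulators."""
        n = self.n_records
        mbar = self._colsum / n
        ybar = self._ysum / n
        gram = np.tril(self._gram.astype(np.float64))
        gram = gram + gram.T - np.diag(np.diag(gram))
        gram -= n * np.outer(mbar, mbar)
        xty = self._xty - ybar * self._colsum
        return gram, xty


@dataclass
class RRBLUPFit:
    """Fitted ridge model: intercept, marker effects and variance ratio."""

    intercept: float
    marker_effects: np.ndarray
    marker_means: np.ndarray  # training column means used for centering
    shrinkage_ratio: float  # lambda = sigma_e^2 / sigma_u^2
    reml_converged: bool
    sigma2_u: float = np.nan
    sigma2_e: float = np.nan


def _reml_spectrum(xc: np.ndarray, yc: np.ndarray):
    """Spectral pieces of the restricted likelihood on the smaller side.

    Returns (d, w2, w2_rest, n_rest): nonzero kernel eigenvalues, squared
    projections of yc on the corresponding directions, the aggregated squared
    projection on the remaining zero-eigenvalue directions, and their count
    (out of the n-1 degrees of freedom left after the intercept).
    """
    n, m = xc.shape
    if n - 1 <= m:
        k = xc @ xc.T
        d, u = linalg.eigh(k)
        w = u.T @ yc
        w2_all = w**2
    else:
        g = xc.T @ xc
        d, v = linalg.eigh(g)
        xty = xc.T @ yc
        proj = v.T @ xty
        with np.errstate(divide="ignore", invalid="ignore"):
            w2_all = np.where(d > 0, proj**2 / np.where(d > 0, d, 1.0), 0.0)
    tol = max(d.max(), 0.0) * max(n, m) * np.finfo(float).eps
    nz = d > tol
    d_nz, w2_nz = d[nz], w2_all[nz]
    rank = int(nz.sum())
    n_rest = (n - 1) - rank
    w2_rest = max(float(yc @ yc - w2_nz.sum()), 0.0) if n_rest > 0 else 0.0
    return d_nz, w2_nz, w2_rest, n_rest


def _reml_lambda(xc: np.ndarray, yc: np.ndarray) -> tuple[float, float, float, bool]:
    """REML estimate of (lambda, sigma2_u, sigma2_e) for the marker model."""
    n = xc.shape[0]
    d, w2, w2_rest, n_rest = _reml_spectrum(xc, yc)

    def neg_restricted_ll(log_delta: float) -> float:
        delta = np.exp(log_delta)
        q = float((w2 / (d + delta)).sum()) + w2_rest / delta
        return (
            (n - 1) * np.log(q)
            + float(np.log(d + delta).sum())
            + n_rest * np.log(delta)
        )

    res = optimize.minimize_scalar(
        neg_restricted_ll,
        bounds=(np.log(1e-8), np.log(1e10)),
        method="bounded",
        options={"xatol": 1e-6},
    )
    delta = float(np.exp(res.x))
    q = float((w2 / (d + delta)).sum()) + w2_rest / delta
    sigma2_u = q / (n - 1)
    return delta, sigma2_u, delta * sigma2_u, bool(res.success)


def fit_rrblup(train: TrainingSet, lambda_: float | None = None) -> RRBLUPFit:
    """Fit the ridge model on the accumulated training records.

    With ``lambda_=None`` the shrinkage ratio is estimated by REML.  A finite
    ``lambda_`` solves the ridge system directly from the running normal
    equations; ``lambda_=inf`` returns the null model (all effects zero).
    """
    n, m = train.n_records, train.n_markers
    if n < 2:
        raise ValueError("need at least 2 training records")
    mbar = train._colsum / n
    ybar = train._ysum / n
    pheno_ss = train._yss - n * ybar**2
    if pheno_ss <= 0 or (lambda_ is not None and np.isinf(lambda_)):
        converged = not (pheno_ss <= 0)
        return RRBLUPFit(
            intercept=ybar,
            marker_effects=np.zeros(m),
            marker_means=mbar,
            shrinkage_ratio=np.inf,
            reml_converged=converged,
        )
    if lambda_ is None:
        x = train.dosage_matrix.astype(np.float64)
        xc = x - mbar
        yc = train.phenotypes - ybar
        lam, s2u, s2e, ok = _reml_lambda(xc, yc)
        rhs = xc.T @ yc
        if n - 1 <= m:
            # dual solve: u = Xc'(XcXc' + lam I)^-1 yc
            k = xc @ xc.T
            k[np.diag_indices_from(k)] += lam
            u = xc.T @ linalg.solve(k, yc, assume_a="pos")
        else:
            g = xc.T @ xc
            g[np.diag_indices_from(g)] += lam
            u = linalg.solve(g, rhs, assume_a="pos")
        return RRBLUPFit(
            intercept=ybar,
            marker_effects=u,
            marker_means=mbar,
            shrinkage_ratio=lam,
            reml_converged=ok,
            sigma2_u=s2u,
            sigma2_e=s2e,
        )
    if lambda_ <= 0:
        raise ValueError("lambda must be positive")
    gram, xty = train.centered_normal_equations()
    # single-precision Cholesky is ample for truncation ranking on large panels
    dtype = np.float32 if m >= 1024 else np.float64
    gram = gram.astype(dtype)
    gram[np.diag_indices_from(gram)] += dtype(lambda_)
    u = linalg.solve(
        gram, xty.astype(dtype), assume_a="pos", check_finite=False
    ).astype(np.float64)
    return RRBLUPFit(
        intercept=ybar,
        marker_effects=u,
        marker_means=mbar,
        shrinkage_ratio=float(lambda_),
        reml_converged=True,
    )


def predict_gebv(
    fit: RRBLUPFit, genotypes: np.ndarray, ploidy: int | None = None
) -> np.ndarray:
    """GEBVs for candidate genomes at the training marker panel.

    ``genotypes`` may be diploid haplotypes (n, 2, m), haploid haplotypes
    (n, m) with ``ploidy=1`` (coded as twice the haploid allele so
    gametophytes sit on the diploid dosage scale), or a ready-made dosage
    matrix (n, m) with ``ploidy=None``.
    """
    genotypes = np.asarray(genotypes)
    scale = 1.0
    if genotypes.ndim == 3:
        if genotypes.shape[1] != 2:
            raise ValueError("diploid genotypes must have shape (n, 2, m)")
        dosages = genotypes.sum(axis=1, dtype=np.float32)
    elif genotypes.ndim == 2:
        dosages = genotypes.astype(np.float32)
        if ploidy == 1:
            scale = 2.0
    else:
        raise ValueError("genotypes must be 2-D or 3-D")
    if dosages.shape[1] != fit.marker_effects.shape[0]:
        raise ValueError(
            f"marker mismatch: {dosages.shape[1]} candidate markers vs "
            f"{fit.marker_effects.shape[0]} in the fit"
        )
    # centering folded into the offset to avoid a centered-matrix copy
    offset = fit.intercept - float(fit.marker_means @ fit.marker_effects)
    raw = (dosages @ fit.marker_effects.astype(np.float32)).astype(np.float64)
    return offset + scale * raw


def write_fit(
    path,
    fit: RRBLUPFit,
    genetic_map=None,
    marker_sites: np.ndarray | None = None,
    training_size: int | None = None,
) -> None:
    """Serialize a fit as a delimited effects table with a metadata header.

    The header comment lines carry the scalar block (intercept, shrinkage
    ratio, training size); the table has one row per marker with its flat
    site index, chromosome, map position and effect.
    """
    import pandas as pd

    m = fit.marker_effects.shape[0]
    if marker_sites is None:
        marker_sites = np.arange(m)
    frame = pd.DataFrame(
        {
            "marker": marker_sites,
            "chromosome": (
                genetic_map.chrom_of_site[marker_sites] + 1
                if genetic_map is not None
                else -1
            ),
            "position_morgans": (
                genetic_map.flat_positions[marker_sites]
                if genetic_map is not None
                else np.nan
            ),
            "effect": fit.marker_effects,
        }
    )
    with open(path, "w") as fh:
        fh.write(f"# intercept\t{fit.intercept!r}\n")
        fh.write(f"# shrinkage_ratio\t{fit.shrinkage_ratio!r}\n")
        if training_size is not None:
            fh.write(f"# training_size\t{training_size}\n")
        frame.to_csv(fh, sep="\t", index=False)


def gs_accuracy(gebv: np.ndarray, true_values: np.ndarray) -> float:
    """Prediction accuracy: Pearson correlation of GEBVs with true values."""
    gebv = np.asarray(gebv, dtype=np.float64)
    true_values = np.asarray(true_values, dtype=np.float64)
    if gebv.shape != true_values.shape or gebv.size < 3:
        raise ValueError("need equal-length vectors with at least 3 entries")
    if gebv.std() == 0 or true_values.std() == 0:
        warnings.warn("zero variance in accuracy computation; returning NaN")
        return np.nan
    return float(np.corrcoef(gebv, true_values)[0, 1])
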