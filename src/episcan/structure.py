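"""Ancestry principal components and the regression covariate matrix.

PCA follows the Eigenstrat construction: each SNP column is centered at
2*p-hat and scaled by sqrt(p-hat*(1-p-hat)) where p-hat is the shrunk
allele-frequency estimate (1 + sum d) / (2 + 2n); missing dosages are
mean-imputed per SNP before the decomposition.  The top-k eigenvectors of
the resulting sample-by-sample covariance are the ancestry coordinates used
to adjust every interaction model for population stratification.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import scipy.linalg

from .types import (
    CovariateMatrix,
    DosageMatrix,
    PcResult,
    ValidationError,
    validate_sample_table,
)


def _standardize(D: np.ndarray, shrunk: bool = True) -> tuple[np.ndarray, np.ndarray]:
    """Eigenstrat standardization; returns (Z, keep-mask over SNPs)."""
    n = D.shape[0]
    missing = ~np.isfinite(D)
    n_obs = (~missing).sum(axis=0)
    with np.errstate(invalid="ignore"):
        col_sum = np.nansum(D, axis=0)
        mean = col_sum / np.maximum(n_obs, 1)
    if shrunk:
        phat = (1.0 + col_sum) / (2.0 + 2.0 * np.maximum(n_obs, 1))
    else:
        phat = mean / 2.0
    variable = np.zeros(D.shape[1], dtype=bool)
    for j in range(D.shape[1]):
        obs = D[~missing[:, j], j]
        variable[j] = obs.size > 0 and not np.all(obs == obs[0])
    scale = np.sqrt(np.clip(phat * (1.0 - phat), 1e-12, None))
    Z = D.copy()
    # mean-impute missing entries, then center/scale
    for j in np.nonzero(missing.any(axis=0))[0]:
        Z[missing[:, j], j] = mean[j]
    Z = (Z - 2.0 * phat) / scale
    return Z[:, variable], variable


def ld_prune_snps(
    dosages: DosageMatrix,
    window: int = 50,
    step: int = 5,
    r2_max: float = 0.2,
) -> list[str]:
    """Greedy window-based LD pruning on dosage correlation.

    Slides a ``window``-SNP window by ``step`` columns; within each window,
    whenever a pair of retained SNPs correlates above ``r2_max`` the
    later-positioned SNP is dropped.  Returns the retained SNP ids in
    column order.
    """
    D = dosages.dosages
    missing = ~np.isfinite(D)
    if missing.any():
        D = D.copy()
        for j in np.nonzero(missing.any(axis=0))[0]:
            col = D[:, j]
            col[missing[:, j]] = np.nanmean(dosages.dosages[:, j])
    m = D.shape[1]
    keep = np.ones(m, dtype=bool)
    for start in range(0, max(m - 1, 1), step):
        idx = [j for j in range(start, min(start + window, m)) if keep[j]]
        for a_pos, a in enumerate(idx):
            if not keep[a]:
                continue
            for b in idx[a_pos + 1 :]:
                if not keep[b]:
                    continue
                sa, sb = D[:, a].std(), D[:, b].std()
                if sa == 0 or sb == 0:
                    continue
                r = np.corrcoef(D[:, a], D[:, b])[0, 1]
                if r * r > r2_max:
                    keep[b] = False
    return [s for s, k_ in zip(dosages.snp_ids, keep) if k_]


def eigenstrat_pca(
    dosages: DosageMatrix,
    k: int = 2,
    shrunk: bool = True,
    ld_prune: tuple[int, int, float] | None = None,
) -> PcResult:
    """Top-k ancestry principal components of the dosage matrix.

    Constant SNPs are skipped with a warning.  ``ld_prune`` is an optional
    (window, step, max r^2) triple applied before the decomposition; it is
    off by default.  Eigenvector signs are fixed so the entry of largest
    magnitude in each component is positive (determinism across LAPACK
    builds).
    """
    n = dosages.n_samples
    if n < k + 1:
        raise ValidationError(f"need at least {k + 1} samples for k={k} components")
    if ld_prune is not None:
        window, step, r2_max = ld_prune
        dosages = dosages.subset(
            snps=ld_prune_snps(dosages, window=window, step=step, r2_max=r2_max)
        )
    Z, variable = _standardize(dosages.dosages, shrunk=shrunk)
    n_const = int((~variable).sum())
    if n_const:
        warnings.warn(f"eigenstrat_pca: skipped {n_const} constant SNPs")
    m = Z.shape[1]
    if m == 0:
        raise ValidationError("no variable SNPs for PCA")
    K = (Z @ Z.T) / m
    if k > n - 1:
        raise ValidationError(f"k={k} exceeds available rank {n - 1}")
    vals, vecs = scipy.linalg.eigh(K, subset_by_index=(n - k, n - 1))
    order = np.argsort(vals)[::-1]
    vals = vals[order]
    vecs = vecs[:, order]
    for j in range(k):
        i = np.argmax(np.abs(vecs[:, j]))
        if vecs[i, j] < 0:
            vecs[:, j] = -vecs[:, j]
    return PcResult(
        sample_ids=list(dosages.sample_ids),
        coordinates=vecs,
        eigenvalues=np.clip(vals, 0.0, None),
        snps_used=[s for s, v in zip(dosages.snp_ids, variable) if v],
    )


def build_covariates(
    samples: pd.DataFrame,
    pcs: PcResult | None = None,
    k: int = 2,
) -> CovariateMatrix:
    """Site indicator columns (reference-coded) plus the first k PCs.

    Rows follow the sample-table order; PCs are realigned on sample id.  A
    single-site cohort contributes no site columns, and ``pcs=None`` (or
    ``k=0``) no PC columns.
    """
    samples = validate_sample_table(samples)
    sample_ids = samples["sample_id"].tolist()
    cols: list[np.ndarray] = []
    labels: list[str] = []

    sites = pd.unique(samples["site"])
    for s in sites[1:]:  # first site is the reference level
        cols.append((samples["site"] == s).to_numpy(dtype=np.float64))
        labels.append(f"site_{s}")

    if pcs is not None and k > 0:
        if k > pcs.coordinates.shape[1]:
            raise ValidationError(
                f"requested k={k} PCs but only {pcs.coordinates.shape[1]} available"
            )
        lookup = {s: i for i, s in enumerate(pcs.sample_ids)}
        try:
            idx = np.array([lookup[s] for s in sample_ids], dtype=np.intp)
        except KeyError as exc:
            raise ValidationError(f"sample {exc.args[0]!r} missing from PCA result")
        for j in range(k):
            col = pcs.coordinates[idx, j]
            # eigenvectors are unit-norm (entries ~ 1/sqrt(n)); standardize
            # so PC effects live on the same scale as the other regressors
            sd = col.std()
            cols.append(col / sd if sd > 0 else col)
            labels.append(f"PC{j + 1}")

    values = np.column_stack(cols) if cols else np.empty((len(sample_ids), 0))
    return CovariateMatrix(sample_ids=sample_ids, values=values, labels=labels)
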