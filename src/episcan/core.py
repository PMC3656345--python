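"""SNP x SNP dosage-interaction logistic regression.

The model for one pair of SNPs (A in the index gene, B in a partner gene) is

    logit P(case) = b0 + b1*dA + b2*dB + b3*dA*dB + g'c

with dA, dB the minor-allele dosages, c the per-sample covariates (study-site
indicators and ancestry principal components) and b3 the epistasis
coefficient of interest.  Significance of b3 comes from the Wald z = b3/SE
referred to the standard normal, two-sided.
"""

from __future__ import annotations

import math

import numpy as np

from . import _engine
from .types import (
    STATUS_COLLINEAR,
    STATUS_NON_CONVERGED,
    STATUS_OK,
    CovariateMatrix,
    DosageMatrix,
    GenePairScan,
    InteractionResult,
    LogisticFit,
    ValidationError,
)

_STATUS_NAMES = {
    _engine.OK: STATUS_OK,
    _engine.COLLINEAR: STATUS_COLLINEAR,
    _engine.NON_CONVERGED: STATUS_NON_CONVERGED,
}


def fit_logistic(
    y: np.ndarray,
    X: np.ndarray,
    max_iter: int = _engine.MAX_ITER,
    score_tol: float = _engine.SCORE_TOL,
    ll_tol: float = _engine.LL_TOL,
    beta_bound: float = _engine.BETA_BOUND,
) -> LogisticFit:
    """Maximum-likelihood logistic regression by Newton/IRLS.

    ``X`` must include the intercept column.  Standard errors come from the
    inverse observed information at the optimum.  Separation is flagged when
    a coefficient escapes ``beta_bound`` (on the dosage scale) or the fit
    fails to converge within ``max_iter`` iterations; rank-deficient designs
    are flagged COLLINEAR.
    """
    y = np.asarray(y, dtype=np.float64).ravel()
    X = np.ascontiguousarray(X, dtype=np.float64)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValidationError("X and y are misaligned")
    if not np.isfinite(X).all() or not np.isfinite(y).all():
        raise ValidationError("non-finite values in design or outcome")
    classes = np.unique(y)
    if not np.isin(classes, (0.0, 1.0)).all():
        raise ValidationError("y must be binary 0/1")
    if classes.size < 2:
        raise ValidationError("outcome has a single class")
    beta, cov, ll, niter, status = _engine.newton_logistic(
        X, y, max_iter, score_tol, ll_tol, beta_bound
    )
    se = np.sqrt(np.diag(cov)) if status == _engine.OK else np.full(X.shape[1], np.nan)
    return LogisticFit(
        coefficients=beta,
        standard_errors=se,
        covariance=cov,
        log_likelihood=float(ll),
        converged=status == _engine.OK,
        n_iterations=int(niter),
        status=_STATUS_NAMES[status],
    )


def interaction_test(
    dos_a: np.ndarray,
    dos_b: np.ndarray,
    covariates: np.ndarray | None,
    y: np.ndarray,
    snp_a: str = "snp_a",
    snp_b: str = "snp_b",
) -> InteractionResult:
    """Wald test of the dosage-interaction coefficient for one SNP pair.

    Samples with a missing value in either dosage, any covariate or the
    outcome are dropped (pairwise complete case) before fitting.
    """
    dos_a = np.asarray(dos_a, dtype=np.float64).ravel()
    dos_b = np.asarray(dos_b, dtype=np.float64).ravel()
    y = np.asarray(y, dtype=np.float64).ravel()
    n = y.shape[0]
    if dos_a.shape[0] != n or dos_b.shape[0] != n:
        raise ValidationError("dosage vectors misaligned with outcome")
    if covariates is None:
        covariates = np.empty((n, 0))
    covariates = np.asarray(covariates, dtype=np.float64)
    if covariates.shape[0] != n:
        raise ValidationError("covariates misaligned with outcome")

    keep = (
        np.isfinite(dos_a)
        & np.isfinite(dos_b)
        & np.isfinite(y)
        & np.isfinite(covariates).all(axis=1)
    )
    da, db, yy, cc = dos_a[keep], dos_b[keep], y[keep], covariates[keep]
    if np.unique(yy).size < 2:
        raise ValidationError("single outcome class after missing-data drop")

    X = np.column_stack([np.ones(da.shape[0]), da, db, da * db, cc])
    # the separation bound polices only the dosage-model terms: covariate
    # columns have arbitrary scale, so their coefficients are exempt
    beta, cov, _ll, _niter, status = _engine.newton_logistic(
        X, yy, _engine.MAX_ITER, _engine.SCORE_TOL, _engine.LL_TOL,
        _engine.BETA_BOUND, 4,
    )
    res = InteractionResult(
        snp_a=snp_a, snp_b=snp_b, status=_STATUS_NAMES[status], n_used=int(keep.sum())
    )
    if status == _engine.OK and cov[3, 3] > 0:
        res.beta3 = float(beta[3])
        res.se3 = float(math.sqrt(cov[3, 3]))
        res.wald_z = res.beta3 / res.se3
        res.p = float(_engine.wald_p(res.wald_z))
    elif status == _engine.OK:
        res.status = STATUS_NON_CONVERGED
    return res


def _covariate_values(
    covariates: CovariateMatrix | np.ndarray | None, n: int
) -> np.ndarray:
    if covariates is None:
        return np.empty((n, 0))
    if isinstance(covariates, CovariateMatrix):
        return covariates.values
    return np.asarray(covariates, dtype=np.float64)


def _is_hard(arr: np.ndarray) -> bool:
    return bool(np.all(np.isfinite(arr)) and np.all(arr == np.round(arr)))


def scan_gene_pair(
    dosages: DosageMatrix,
    snps_index: list[str],
    snps_partner: list[str],
    covariates: CovariateMatrix | np.ndarray | None,
    y: np.ndarray,
    gene_index: str = "index",
    gene_partner: str = "partner",
) -> GenePairScan:
    """All pairwise interaction tests between two genes' SNP lists.

    Results are ordered by index-SNP position then partner-SNP position
    (the order of the input lists).  Pairs whose design is rank-deficient or
    whose fit does not converge are carried with their status and excluded
    from the gene minimum.
    """
    if not snps_index:
        raise ValidationError(f"no SNPs for index gene {gene_index!r}")
    if not snps_partner:
        raise ValidationError(f"no SNPs for partner gene {gene_partner!r}")
    y = np.asarray(y, dtype=np.float64).ravel()
    if y.shape[0] != dosages.n_samples:
        raise ValidationError("outcome misaligned with dosage matrix")
    DA = dosages.dosages[:, dosages.snp_index(snps_index)]
    DB = dosages.dosages[:, dosages.snp_index(snps_partner)]
    C = _covariate_values(covariates, dosages.n_samples)

    complete = (
        np.isfinite(DA).all()
        and np.isfinite(DB).all()
        and np.isfinite(C).all()
        and np.isfinite(y).all()
    )
    results: list[InteractionResult] = []
    if complete:
        if C.shape[1] == 0 and _is_hard(DA) and _is_hard(DB):
            b3, se3, pv, st = _engine.scan_pairs_hard(
                DA.astype(np.int64),
                DB.astype(np.int64),
                y,
                _engine.MAX_ITER,
                _engine.SCORE_TOL,
                _engine.LL_TOL,
                _engine.BETA_BOUND,
            )
        else:
            b3, se3, pv, st = _engine.scan_pairs(
                np.ascontiguousarray(DA),
                np.ascontiguousarray(DB),
                np.ascontiguousarray(C),
                y,
                _engine.MAX_ITER,
                _engine.SCORE_TOL,
                _engine.LL_TOL,
                _engine.BETA_BOUND,
            )
        n_used = dosages.n_samples
        for a, sa in enumerate(snps_index):
            for b, sb in enumerate(snps_partner):
                results.append(
                    InteractionResult(
                        snp_a=sa,
                        snp_b=sb,
                        beta3=float(b3[a, b]),
                        se3=float(se3[a, b]),
                        wald_z=float(b3[a, b] / se3[a, b])
                        if st[a, b] == _engine.OK
                        else np.nan,
                        p=float(pv[a, b]),
                        status=_STATUS_NAMES[int(st[a, b])],
                        n_used=n_used,
                    )
                )
    else:
        for a, sa in enumerate(snps_index):
            for b, sb in enumerate(snps_partner):
                results.append(
                    interaction_test(DA[:, a], DB[:, b], C, y, snp_a=sa, snp_b=sb)
                )

    skipped: dict[str, int] = {}
    for r in results:
        if not r.ok:
            skipped[r.status] = skipped.get(r.status, 0) + 1
    return GenePairScan(
        gene_a=gene_index, gene_b=gene_partner, results=results, skipped=skipped
    )


def gene_min_p(scan: GenePairScan) -> tuple[float, list[InteractionResult]]:
    """Gene-level minimum p over OK tests, with every pair attaining it.

    Raises when the scan has no OK result (gene untestable).
    """
    ok = scan.ok_results()
    if not ok:
        raise ValidationError(
            f"gene {scan.gene_b!r} untestable: no converged interaction test"
        )
    min_p = min(r.p for r in ok)
    best = [r for r in ok if r.p == min_p]
    return min_p, best
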