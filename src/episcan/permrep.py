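"""Label-permutation min-p null, empirical significance and replication.

Family-wise error control follows the min-p/max-T construction: case-control
labels are permuted B times (default 1,000); in each replicate every
gene-pair interaction scan is recomputed with covariates and genotypes
travelling with the individuals, and the experiment-wide minimum p over all
tests is stored.  A gene's observed minimum p is referred to this single
null: its empirical p is the fraction of replicates at least as extreme
(count/B, ties counting as exceedances), and the study-wide significance
threshold is the floor(alpha*B)-th smallest null minimum — with B = 1,000
and alpha = 0.05, the 50th most significant permuted value.

Replication re-runs the same interaction test for each surviving pair in an
independent cohort at nominal alpha; the driving-SNP rescan tests a few
partner-gene SNPs against every index-gene SNP without permutation
correction and is labelled exploratory.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from . import _engine
from .core import _covariate_values, _is_hard, interaction_test
from .types import (
    ConfigurationError,
    CovariateMatrix,
    DosageMatrix,
    GenePairScan,
    ValidationError,
)


@dataclass
class PermutationNull:
    """B experiment-wide minimum p-values under label permutation."""

    B: int
    null_min_p: np.ndarray  # length B
    alpha: float
    seeds: np.ndarray  # per-replicate permutation seeds
    per_gene: pd.DataFrame | None = None  # optional B x gene minima

    def __post_init__(self) -> None:
        self.null_min_p = np.asarray(self.null_min_p, dtype=float)
        if self.null_min_p.shape[0] != self.B:
            raise ValidationError("null_min_p length must equal B")

    @property
    def threshold(self) -> float:
        return significance_threshold(self, self.alpha)


@dataclass
class EmpiricalResult:
    gene: str
    observed_min_p: float
    empirical_p: float
    passes: bool


def permute_labels(
    y: np.ndarray,
    seed: int | np.random.Generator,
    stratify: np.ndarray | None = None,
) -> np.ndarray:
    """Random permutation of the case/control labels (multiset preserved).

    With ``stratify`` the labels are shuffled within each stratum only
    (e.g. within study site).
    """
    y = np.asarray(y)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if stratify is None:
        return rng.permutation(y)
    out = y.copy()
    for s in pd.unique(np.asarray(stratify)):
        idx = np.nonzero(np.asarray(stratify) == s)[0]
        out[idx] = rng.permutation(y[idx])
    return out


def _prepare_scan_arrays(
    dosages: DosageMatrix,
    covariates: CovariateMatrix | np.ndarray | None,
    index_snps: list[str],
    gene_snp_lists: dict[str, list[str]],
) -> tuple[np.ndarray, dict[str, np.ndarray], np.ndarray, bool]:
    DA = np.ascontiguousarray(dosages.dosages[:, dosages.snp_index(index_snps)])
    DBs = {
        g: np.ascontiguousarray(dosages.dosages[:, dosages.snp_index(snps)])
        for g, snps in gene_snp_lists.items()
    }
    C = np.ascontiguousarray(_covariate_values(covariates, dosages.n_samples))
    hard = (
        C.shape[1] == 0
        and _is_hard(DA)
        and all(_is_hard(DB) for DB in DBs.values())
    )
    return DA, DBs, C, hard


def _replicate_minima(
    DA: np.ndarray,
    DBs: dict[str, np.ndarray],
    C: np.ndarray,
    y: np.ndarray,
    hard: bool,
) -> dict[str, float]:
    out = {}
    for g, DB in DBs.items():
        if hard:
            out[g] = _engine.scan_min_p_hard(
                DA.astype(np.int64), DB.astype(np.int64), y,
                _engine.MAX_ITER, _engine.SCORE_TOL, _engine.LL_TOL, _engine.BETA_BOUND,
            )
        else:
            out[g] = _engine.scan_min_p(
                DA, DB, C, y,
                _engine.MAX_ITER, _engine.SCORE_TOL, _engine.LL_TOL, _engine.BETA_BOUND,
            )
    return out


def build_null(
    dosages: DosageMatrix,
    y: np.ndarray,
    covariates: CovariateMatrix | np.ndarray | None,
    index_snps: list[str],
    gene_snp_lists: dict[str, list[str]],
    B: int = 1000,
    master_seed: int = 0,
    alpha: float = 0.05,
    stratify: np.ndarray | None = None,
    keep_per_gene: bool = False,
) -> PermutationNull:
    """Monte-Carlo min-p null over B label permutations.

    Covariate columns stay attached to individuals; only the case/control
    labels move.  Each replicate's statistic is the experiment-wide minimum
    p over all gene-pair tests (the per-gene minima are retained when
    ``keep_per_gene``).  A replicate in which no test converges aborts the
    run — that signals pathological data, not a valid null draw.
    """
    if B < 20:
        raise ConfigurationError("B must be >= 20 for a usable null")
    y = np.asarray(y, dtype=np.float64).ravel()
    DA, DBs, C, hard = _prepare_scan_arrays(
        dosages, covariates, index_snps, gene_snp_lists
    )
    seed_rng = np.random.default_rng(master_seed)
    seeds = seed_rng.integers(0, 2**31, size=B)
    minima = np.empty(B)
    per_gene_rows = []
    for b in range(B):
        yp = permute_labels(y, int(seeds[b]), stratify=stratify)
        gene_min = _replicate_minima(DA, DBs, C, yp, hard)
        vals = np.array(list(gene_min.values()))
        if np.all(np.isnan(vals)):
            raise ValidationError(
                f"permutation replicate {b} produced no converged test"
            )
        minima[b] = np.nanmin(vals)
        if keep_per_gene:
            per_gene_rows.append(gene_min)
    per_gene = pd.DataFrame(per_gene_rows) if keep_per_gene else None
    return PermutationNull(
        B=B, null_min_p=minima, alpha=alpha, seeds=seeds, per_gene=per_gene
    )


def exhaustive_null(
    dosages: DosageMatrix,
    y: np.ndarray,
    covariates: CovariateMatrix | np.ndarray | None,
    index_snps: list[str],
    gene_snp_lists: dict[str, list[str]],
) -> np.ndarray:
    """Experiment-wide minimum p for every distinct label arrangement.

    Only feasible for tiny cohorts (C(n, n_cases) arrangements); used as the
    exact reference against which the Monte-Carlo null converges.
    Arrangements with no converged test are skipped.
    """
    y = np.asarray(y, dtype=np.float64).ravel()
    n = y.shape[0]
    n_cases = int(y.sum())
    DA, DBs, C, hard = _prepare_scan_arrays(
        dosages, covariates, index_snps, gene_snp_lists
    )
    minima = []
    for cases in combinations(range(n), n_cases):
        yp = np.zeros(n)
        yp[list(cases)] = 1.0
        gene_min = _replicate_minima(DA, DBs, C, yp, hard)
        vals = np.array(list(gene_min.values()))
        if not np.all(np.isnan(vals)):
            minima.append(np.nanmin(vals))
    return np.array(minima)


def empirical_p(
    observed_min_p: float,
    null: PermutationNull,
    estimator: str = "count",
) -> float:
    """Fraction of null replicates at least as significant as observed.

    ``count`` is the plain count/B convention (5 exceedances out of 1,000
    -> 0.005); ``add-one`` gives the (count+1)/(B+1) estimator.
    """
    if not (0.0 < observed_min_p <= 1.0):
        raise ValidationError("observed min p must lie in (0, 1]")
    count = int((null.null_min_p <= observed_min_p).sum())
    if estimator == "count":
        return count / null.B
    if estimator == "add-one":
        return (count + 1) / (null.B + 1)
    raise ConfigurationError(f"unknown estimator {estimator!r}")


def significance_threshold(null: PermutationNull, alpha: float = 0.05) -> float:
    """The floor(alpha*B)-th smallest null minimum (rank threshold)."""
    rank = int(np.floor(alpha * null.B))
    if rank < 1:
        raise ConfigurationError(
            f"alpha*B = {alpha * null.B:.2f} < 1: no attainable threshold"
        )
    return float(np.sort(null.null_min_p)[rank - 1])


def summarize_genes(
    observed: dict[str, float],
    null: PermutationNull,
    alpha: float = 0.05,
    estimator: str = "count",
) -> pd.DataFrame:
    """Empirical p and pass flag per gene against the experiment-wide null."""
    thr = significance_threshold(null, alpha)
    rows = [
        EmpiricalResult(
            gene=g,
            observed_min_p=p,
            empirical_p=empirical_p(p, null, estimator=estimator),
            passes=bool(p <= thr),
        )
        for g, p in observed.items()
    ]
    return pd.DataFrame(
        {
            "gene": [r.gene for r in rows],
            "observed_min_p": [r.observed_min_p for r in rows],
            "empirical_p": [r.empirical_p for r in rows],
            "passes": [r.passes for r in rows],
        }
    ).sort_values("observed_min_p", kind="mergesort").reset_index(drop=True)


def select_significant_pairs(
    scans: list[GenePairScan],
    threshold: float,
) -> pd.DataFrame:
    """All OK pairs with p <= threshold, ordered by p (ties kept)."""
    frames = [s.to_frame() for s in scans]
    allp = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["gene", "snp_a", "snp_b", "beta3", "se3", "wald_z", "p", "status"]
    )
    hits = allp[(allp["status"] == "OK") & (allp["p"] <= threshold)]
    return hits.sort_values(
        ["p", "gene", "snp_a", "snp_b"], kind="mergesort"
    ).reset_index(drop=True)


def replicate_pairs(
    pairs: pd.DataFrame,
    dosages: DosageMatrix,
    covariates: CovariateMatrix | np.ndarray | None,
    y: np.ndarray,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Re-test selected SNP pairs in an independent cohort.

    Pairs whose SNPs are absent from the replication data are reported with
    status MISSING and excluded from significance counts.  Sign concordance
    with the discovery coefficient is recorded whenever the discovery table
    carries a ``beta3`` column.
    """
    C = _covariate_values(covariates, dosages.n_samples)
    known = set(dosages.snp_ids)
    rows = []
    for _, pair in pairs.iterrows():
        sa, sb = pair["snp_a"], pair["snp_b"]
        row = {"gene": pair.get("gene", ""), "snp_a": sa, "snp_b": sb}
        if sa not in known or sb not in known:
            row.update(
                beta3=np.nan, se3=np.nan, p=np.nan,
                status="MISSING", significant=False, direction_consistent=np.nan,
            )
        else:
            res = interaction_test(
                dosages.column(sa), dosages.column(sb), C, y, snp_a=sa, snp_b=sb
            )
            sig = bool(res.ok and res.p < alpha)
            direction = np.nan
            if res.ok and "beta3" in pair.index and np.isfinite(pair["beta3"]):
                direction = bool(np.sign(res.beta3) == np.sign(pair["beta3"]))
            row.update(
                beta3=res.beta3, se3=res.se3, p=res.p,
                status=res.status, significant=sig, direction_consistent=direction,
            )
        rows.append(row)
    return pd.DataFrame(
        rows,
        columns=[
            "gene", "snp_a", "snp_b", "beta3", "se3", "p",
            "status", "significant", "direction_consistent",
        ],
    )


def cross_gene_rescan(
    driving_snps: list[str],
    partner_gene_snps: list[str],
    dosages: DosageMatrix,
    covariates: CovariateMatrix | np.ndarray | None,
    y: np.ndarray,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Exploratory allelic-heterogeneity rescan (no permutation correction).

    Tests every driving SNP against every SNP of the partner gene in the
    given cohort and flags nominal significance at ``alpha``.  Intended for
    asking whether the same driving SNPs interact with *different* partner
    variants in a cohort where the original pairs did not replicate.
    """
    missing = [s for s in driving_snps if s not in set(dosages.snp_ids)]
    if missing:
        raise ValidationError(f"driving SNPs absent from cohort: {missing}")
    C = _covariate_values(covariates, dosages.n_samples)
    rows = []
    for sd in driving_snps:
        for sp in partner_gene_snps:
            if sp not in set(dosages.snp_ids):
                rows.append(
                    {
                        "driving_snp": sd, "partner_snp": sp,
                        "beta3": np.nan, "se3": np.nan, "p": np.nan,
                        "status": "MISSING", "significant": False,
                    }
                )
                continue
            res = interaction_test(
                dosages.column(sd), dosages.column(sp), C, y, snp_a=sd, snp_b=sp
            )
            rows.append(
                {
                    "driving_snp": sd, "partner_snp": sp,
                    "beta3": res.beta3, "se3": res.se3, "p": res.p,
                    "status": res.status,
                    "significant": bool(res.ok and res.p < alpha),
                }
            )
    return pd.DataFrame(rows)
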