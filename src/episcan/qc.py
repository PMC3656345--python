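"""Sample/SNP quality control, gene assignment and candidate selection.

Default thresholds follow common GWAS practice for imputed case-control
panels: drop samples with >=5% missing genotypes, then drop SNPs with >=5%
missingness, minor allele frequency below 1%, Hardy-Weinberg exact p below
1e-6 among controls, or imputation r^2 below 0.3.  Filters are applied in
that fixed order and each dropped SNP is attributed to the first rule it
fails, so reports are reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

from .types import (
    DosageMatrix,
    GeneRegion,
    QcReport,
    ValidationError,
    validate_sample_table,
)

_X_CHROMS = {"x", "chrx", "23"}
_Y_CHROMS = {"y", "chry", "24"}


@dataclass
class QcThresholds:
    """QC cutoffs; defaults are the standard imputed-GWAS values."""

    sample_miss: float = 0.05  # drop sample when missingness >= this
    snp_miss: float = 0.05  # drop SNP when missingness >= this
    maf: float = 0.01  # drop SNP when MAF strictly below this
    hwe: float = 1e-6  # drop SNP when control HWE p strictly below this
    min_r2: float = 0.3  # drop SNP when imputation r^2 strictly below this


def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact conditional Hardy-Weinberg test.

    Given observed genotype counts, conditions on the allele counts and sums
    the probabilities of all heterozygote counts no more probable than the
    observed one (the Wigginton/Cutler/Abecasis construction).  Returns the
    exact p-value; 1.0 for monomorphic input (a single attainable
    configuration).
    """
    counts = (n_AA, n_Aa, n_aa)
    if any(int(c) != c or c < 0 for c in counts):
        raise ValidationError(f"genotype counts must be non-negative integers: {counts}")
    n_AA, n_Aa, n_aa = (int(c) for c in counts)
    n = n_AA + n_Aa + n_aa
    if n == 0:
        raise ValidationError("total genotype count must be positive")
    n_a = 2 * n_aa + n_Aa
    rare = min(n_a, 2 * n - n_a)
    if rare == 0:
        return 1.0

    hets = np.arange(rare % 2, rare + 1, 2)
    homr = (rare - hets) // 2
    homc = n - hets - homr
    # log P(het = h | allele counts), up to the common normalizer
    logp = (
        hets * np.log(2.0)
        - gammaln(homr + 1.0)
        - gammaln(hets + 1.0)
        - gammaln(homc + 1.0)
    )
    logp -= logsumexp(logp)
    obs_het = n_Aa
    p_obs = logp[hets == obs_het]
    if p_obs.size == 0:  # pragma: no cover - unreachable for valid counts
        raise ValidationError("observed heterozygote count inconsistent with alleles")
    probs = np.exp(logp)
    p = probs[logp <= p_obs[0] + 1e-10].sum()
    return float(min(1.0, p))


def hard_call(dosages: np.ndarray) -> np.ndarray:
    """Round fractional dosages to the nearest genotype in {0, 1, 2}.

    Halfway values round away from zero (0.5 -> 1, 1.5 -> 2); NaN passes
    through.
    """
    d = np.asarray(dosages, dtype=np.float64)
    return np.clip(np.floor(d + 0.5), 0, 2)


def compute_snp_stats(
    dosages: DosageMatrix,
    samples: pd.DataFrame,
    snp_meta: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-SNP MAF, missingness, control-HWE p and monomorphic flag.

    MAF is the folded mean dosage over non-missing samples; HWE is the exact
    test on control genotypes hard-called from dosage.  SNPs with zero
    non-missing values get NaN statistics and the monomorphic flag.
    Existing metadata in ``snp_meta`` (chrom, pos, alleles, imputation r^2)
    is carried through on ``snp_id``.
    """
    samples = validate_sample_table(samples)
    order = {s: i for i, s in enumerate(dosages.sample_ids)}
    unknown = set(samples["sample_id"]) - set(order)
    if unknown or len(samples) != dosages.n_samples:
        raise ValidationError("sample table not aligned to dosage matrix")
    status = np.empty(dosages.n_samples, dtype=np.int64)
    status[[order[s] for s in samples["sample_id"]]] = samples["status"].to_numpy()
    is_control = status == 0

    D = dosages.dosages
    missing = ~np.isfinite(D)
    n_obs = (~missing).sum(axis=0)
    with np.errstate(invalid="ignore"):
        mean_d = np.where(n_obs > 0, np.nansum(D, axis=0) / np.maximum(n_obs, 1), np.nan)
    maf = np.minimum(mean_d / 2.0, 1.0 - mean_d / 2.0)
    missingness = missing.mean(axis=0)

    hwe_p = np.full(dosages.n_snps, np.nan)
    mono = np.zeros(dosages.n_snps, dtype=bool)
    G = hard_call(D[is_control])
    for j in range(dosages.n_snps):
        col = D[:, j]
        obs = col[np.isfinite(col)]
        if obs.size == 0:
            mono[j] = True
            continue
        if np.all(obs == obs[0]):
            mono[j] = True
        g = G[:, j]
        g = g[np.isfinite(g)]
        if g.size:
            counts = [int((g == k).sum()) for k in (0, 1, 2)]
            hwe_p[j] = hwe_exact_test(*counts)

    stats = pd.DataFrame(
        {
            "snp_id": dosages.snp_ids,
            "maf": maf,
            "missingness": missingness,
            "hwe_p_controls": hwe_p,
            "monomorphic": mono,
        }
    )
    if snp_meta is not None:
        keep = [c for c in snp_meta.columns if c not in stats.columns or c == "snp_id"]
        stats = stats.merge(snp_meta[keep], on="snp_id", how="left")
    return stats


def apply_qc(
    dosages: DosageMatrix,
    samples: pd.DataFrame,
    snp_meta: pd.DataFrame | None = None,
    thresholds: QcThresholds | None = None,
) -> tuple[DosageMatrix, pd.DataFrame, pd.DataFrame, QcReport]:
    """Apply sample then SNP filters; returns filtered data and a report.

    Samples failing the missingness cutoff are dropped first; SNP statistics
    are then recomputed on the surviving samples before the SNP rules run in
    the fixed order missingness -> MAF -> HWE -> imputation r^2, each SNP
    attributed to the first rule it fails.  Boundary semantics: MAF, HWE and
    r^2 rules are strict ``<`` (a SNP at exactly the MAF cutoff survives);
    missingness rules are ``>=``.
    """
    th = thresholds or QcThresholds()
    samples = validate_sample_table(samples)

    missing = ~np.isfinite(dosages.dosages)
    sample_miss = missing.mean(axis=1)
    drop_sample = sample_miss >= th.sample_miss
    dropped_samples = [
        s for s, d in zip(dosages.sample_ids, drop_sample) if d
    ]
    surviving_samples = [s for s, d in zip(dosages.sample_ids, drop_sample) if not d]
    if not surviving_samples:
        raise ValidationError("QC removed every sample")
    filtered = dosages.subset(samples=surviving_samples)
    samples_out = samples[samples["sample_id"].isin(surviving_samples)].reset_index(
        drop=True
    )

    stats = compute_snp_stats(filtered, samples_out, snp_meta)
    r2 = (
        stats["imputation_r2"].to_numpy(dtype=float)
        if "imputation_r2" in stats.columns
        else np.full(len(stats), np.nan)
    )

    dropped: dict[str, list[str]] = {"missingness": [], "maf": [], "hwe": [], "r2": []}
    surviving_snps: list[str] = []
    for idx, row in stats.iterrows():
        sid = row["snp_id"]
        maf = row["maf"]
        if row["missingness"] >= th.snp_miss:
            dropped["missingness"].append(sid)
        elif not np.isfinite(maf) or maf < th.maf:
            dropped["maf"].append(sid)
        elif np.isfinite(row["hwe_p_controls"]) and row["hwe_p_controls"] < th.hwe:
            dropped["hwe"].append(sid)
        elif np.isfinite(r2[idx]) and r2[idx] < th.min_r2:
            dropped["r2"].append(sid)
        else:
            surviving_snps.append(sid)

    report = QcReport(
        n_samples_in=dosages.n_samples,
        n_snps_in=dosages.n_snps,
        samples_dropped_missingness=dropped_samples,
        snps_dropped=dropped,
        surviving_samples=surviving_samples,
        surviving_snps=surviving_snps,
    )
    filtered = filtered.subset(snps=surviving_snps)
    stats_out = stats[stats["snp_id"].isin(surviving_snps)].reset_index(drop=True)
    return filtered, samples_out, stats_out, report


def assign_snps_to_gene(snp_table: pd.DataFrame, region: GeneRegion) -> list[str]:
    """SNP ids falling in the padded gene region, ordered by position.

    SNP positions are 1-based; the region is 0-based half-open, so a SNP at
    1-based position p is included when ``start - pad <= p - 1 < end + pad``.
    An empty result is returned (not an error).
    """
    required = {"snp_id", "chrom", "pos"}
    if not required <= set(snp_table.columns):
        raise ValidationError(f"SNP table needs columns {sorted(required)}")
    chrom = snp_table["chrom"].astype(str).str.removeprefix("chr")
    target = str(region.chrom).removeprefix("chr")
    pos0 = snp_table["pos"].astype(int) - 1
    inside = (
        (chrom == target)
        & (pos0 >= region.padded_start)
        & (pos0 < region.padded_end)
    )
    hits = snp_table.loc[inside].sort_values("pos", kind="mergesort")
    return hits["snp_id"].tolist()


def select_candidate_genes(
    table: pd.DataFrame,
    min_score: float = 0.7,
    autosomes_only: bool = True,
) -> pd.DataFrame:
    """Filter partner genes by interaction-confidence score and chromosome.

    Keeps genes with score >= ``min_score`` (inclusive) and, when
    ``autosomes_only``, removes X/Y entries.  Output is sorted by descending
    score then gene symbol.
    """
    required = {"gene", "chrom", "score"}
    if not required <= set(table.columns):
        raise ValidationError(f"candidate table needs columns {sorted(required)}")
    score = table["score"].astype(float)
    if ((score < 0) | (score > 1)).any():
        raise ValidationError("confidence scores must lie in [0, 1]")
    keep = score >= min_score
    if autosomes_only:
        chrom = table["chrom"].astype(str).str.lower().str.removeprefix("chr")
        keep &= ~chrom.isin(_X_CHROMS | _Y_CHROMS)
    out = table.loc[keep].copy()
    out["score"] = out["score"].astype(float)
    return out.sort_values(
        ["score", "gene"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
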