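"""Core in-memory containers shared across the pipeline.

Tabular per-sample and per-SNP metadata live in pandas DataFrames with fixed
column contracts (see :data:`SAMPLE_COLUMNS`, :data:`SNP_COLUMNS`); the dosage
matrix itself is a thin dataclass around a float64 array because it needs an
explicit missingness convention (NaN) and id/axis bookkeeping that a bare
DataFrame makes too easy to silently break.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

#: Required columns of a sample table. ``status`` is 1=case, 0=control.
SAMPLE_COLUMNS = ("sample_id", "status", "site")

#: Required columns of a SNP metadata table.
SNP_COLUMNS = ("snp_id", "chrom", "pos", "minor", "major", "imputation_r2")

#: Statistic columns added by :func:`episcan.qc.compute_snp_stats`.
SNP_STAT_COLUMNS = ("maf", "missingness", "hwe_p_controls", "monomorphic")

STATUS_OK = "OK"
STATUS_COLLINEAR = "COLLINEAR"
STATUS_NON_CONVERGED = "NON_CONVERGED"
STATUS_MISSING = "MISSING"


class ConfigurationError(ValueError):
    """Invalid simulation or analysis configuration."""


class ValidationError(ValueError):
    """Input data violating a format or range contract."""


@dataclass
class DosageMatrix:
    """Samples x SNPs fractional minor-allele dosages in [0, 2].

    Missing entries are NaN.  ``sample_ids`` and ``snp_ids`` are ordered and
    unique; ``dosages[i, j]`` is the expected minor-allele count of sample
    ``sample_ids[i]`` at SNP ``snp_ids[j]``.
    """

    sample_ids: list[str]
    snp_ids: list[str]
    dosages: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = list(map(str, self.sample_ids))
        self.snp_ids = list(map(str, self.snp_ids))
        self.dosages = np.asarray(self.dosages, dtype=np.float64)
        if self.dosages.shape != (len(self.sample_ids), len(self.snp_ids)):
            raise ValidationError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.snp_ids)} SNPs"
            )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValidationError("duplicate sample ids")
        if len(set(self.snp_ids)) != len(self.snp_ids):
            raise ValidationError("duplicate SNP ids")
        finite = self.dosages[np.isfinite(self.dosages)]
        if finite.size and (finite.min() < 0.0 or finite.max() > 2.0):
            raise ValidationError("dosage values outside [0, 2]")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    def snp_index(self, snp_ids: Sequence[str]) -> np.ndarray:
        """Column indices of ``snp_ids`` (error on unknown id)."""
        lookup = {s: i for i, s in enumerate(self.snp_ids)}
        try:
            return np.array([lookup[s] for s in snp_ids], dtype=np.intp)
        except KeyError as exc:  # pragma: no cover - message only
            raise KeyError(f"unknown SNP id {exc.args[0]!r}") from None

    def column(self, snp_id: str) -> np.ndarray:
        return self.dosages[:, self.snp_index([snp_id])[0]]

    def subset(
        self,
        samples: Sequence[str] | None = None,
        snps: Sequence[str] | None = None,
    ) -> "DosageMatrix":
        """Row/column subset preserving the requested order."""
        sid = list(samples) if samples is not None else self.sample_ids
        nid = list(snps) if snps is not None else self.snp_ids
        rows = {s: i for i, s in enumerate(self.sample_ids)}
        ridx = np.array([rows[s] for s in sid], dtype=np.intp)
        cidx = self.snp_index(nid)
        return DosageMatrix(sid, nid, self.dosages[np.ix_(ridx, cidx)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.dosages, index=self.sample_ids, columns=self.snp_ids)


def validate_sample_table(samples: pd.DataFrame) -> pd.DataFrame:
    """Check the sample-table contract and normalize dtypes."""
    missing = [c for c in SAMPLE_COLUMNS if c not in samples.columns]
    if missing:
        raise ValidationError(f"sample table missing columns {missing}")
    out = samples.copy()
    out["sample_id"] = out["sample_id"].astype(str)
    status = out["status"].astype(int)
    if not status.isin((0, 1)).all():
        raise ValidationError("status must be binary (1=case, 0=control)")
    out["status"] = status
    out["site"] = out["site"].astype(str)
    if out["sample_id"].duplicated().any():
        raise ValidationError("duplicate sample ids in sample table")
    return out


@dataclass
class GeneRegion:
    """Gene interval: 0-based half-open transcript union plus a flank."""

    gene: str
    chrom: str
    start: int
    end: int
    pad: int = 10_000

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValidationError(f"{self.gene}: start must be < end")
        if self.pad < 0:
            raise ValidationError("pad must be >= 0")

    @property
    def padded_start(self) -> int:
        return max(0, self.start - self.pad)

    @property
    def padded_end(self) -> int:
        return self.end + self.pad


@dataclass
class LogisticFit:
    """Maximum-likelihood logistic fit with Wald machinery."""

    coefficients: np.ndarray
    standard_errors: np.ndarray
    covariance: np.ndarray
    log_likelihood: float
    converged: bool
    n_iterations: int
    status: str = STATUS_OK


@dataclass
class InteractionResult:
    """One SNP-pair dosage-interaction test."""

    snp_a: str
    snp_b: str
    beta3: float = np.nan
    se3: float = np.nan
    wald_z: float = np.nan
    p: float = np.nan
    status: str = STATUS_OK
    n_used: int = 0

    @property
    def ok(self) -> bool:
        return self.status == STATUS_OK


@dataclass
class GenePairScan:
    """All pairwise interaction tests between an index gene and one partner."""

    gene_a: str
    gene_b: str
    results: list[InteractionResult]
    skipped: dict[str, int] = field(default_factory=dict)

    def ok_results(self) -> list[InteractionResult]:
        return [r for r in self.results if r.ok]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene": self.gene_b,
                "snp_a": [r.snp_a for r in self.results],
                "snp_b": [r.snp_b for r in self.results],
                "beta3": [r.beta3 for r in self.results],
                "se3": [r.se3 for r in self.results],
                "wald_z": [r.wald_z for r in self.results],
                "p": [r.p for r in self.results],
                "status": [r.status for r in self.results],
            }
        )


@dataclass
class QcReport:
    """Per-rule drop accounting for one QC pass."""

    n_samples_in: int
    n_snps_in: int
    samples_dropped_missingness: list[str]
    snps_dropped: dict[str, list[str]]  # rule -> snp ids (first failing rule)
    surviving_samples: list[str]
    surviving_snps: list[str]

    def summary(self) -> dict[str, int]:
        out = {
            "samples_in": self.n_samples_in,
            "samples_dropped": len(self.samples_dropped_missingness),
            "samples_out": len(self.surviving_samples),
            "snps_in": self.n_snps_in,
            "snps_out": len(self.surviving_snps),
        }
        for rule, ids in self.snps_dropped.items():
            out[f"snps_dropped_{rule}"] = len(ids)
        return out


@dataclass
class PcResult:
    """Top-k principal components of the standardized genotype matrix."""

    sample_ids: list[str]
    coordinates: np.ndarray  # samples x k
    eigenvalues: np.ndarray  # k, non-increasing
    snps_used: list[str]

    def to_frame(self) -> pd.DataFrame:
        k = self.coordinates.shape[1]
        df = pd.DataFrame(
            self.coordinates, columns=[f"PC{i + 1}" for i in range(k)]
        )
        df.insert(0, "sample_id", self.sample_ids)
        return df


@dataclass
class CovariateMatrix:
    """Per-sample regression covariates (site indicators + PCs)."""

    sample_ids: list[str]
    values: np.ndarray  # samples x c
    labels: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (len(self.sample_ids), len(self.labels)):
            raise ValidationError("covariate matrix shape mismatch")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.labels)
        df.insert(0, "sample_id", self.sample_ids)
        return df
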