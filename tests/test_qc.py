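"""QC filters, the Hardy-Weinberg exact test, gene assignment, candidates."""

from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from episcan.gwasio import read_candidate_genes
from episcan.qc import (
    QcThresholds,
    apply_qc,
    assign_snps_to_gene,
    compute_snp_stats,
    hard_call,
    hwe_exact_test,
    select_candidate_genes,
)
from episcan.types import DosageMatrix, GeneRegion, ValidationError


def hwe_enumeration_oracle(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact-rational enumeration over heterozygote counts of matching parity."""
    n = n_AA + n_Aa + n_aa
    n_a = 2 * n_aa + n_Aa
    rare = min(n_a, 2 * n - n_a)
    if rare == 0:
        return 1.0

    def weight(h: int) -> int:
        hom_rare = (rare - h) // 2
        return (2**h) * comb(n, hom_rare) * comb(n - hom_rare, h)

    hets = range(rare % 2, rare + 1, 2)
    total = sum(weight(h) for h in hets)
    w_obs = weight(n_Aa)
    tail = sum(weight(h) for h in hets if weight(h) <= w_obs)
    return float(Fraction(tail, total))


class TestHweExactTest:
    def test_monomorphic_is_one(self):
        assert hwe_exact_test(0, 0, 50) == 1.0
        assert hwe_exact_test(50, 0, 0) == 1.0

    def test_total_heterozygote_deficit_is_extreme(self):
        assert hwe_exact_test(100, 0, 100) < 1e-6

    def test_balanced_sample_matches_enumeration(self):
        assert hwe_exact_test(25, 50, 25) == pytest.approx(
            hwe_enumeration_oracle(25, 50, 25), abs=1e-12
        )

    def test_negative_counts_rejected(self):
        with pytest.raises(ValidationError):
            hwe_exact_test(-1, 2, 3)
        with pytest.raises(ValidationError):
            hwe_exact_test(0, 0, 0)

    @settings(max_examples=80, derandomize=True, deadline=None)
    @given(
        n=st.integers(min_value=1, max_value=166),
        f_AA=st.floats(min_value=0.0, max_value=1.0),
        f_Aa=st.floats(min_value=0.0, max_value=1.0),
    )
    def test_matches_enumeration_oracle(self, n, f_AA, f_Aa):
        """Property: agreement with exhaustive enumeration for totals <= 500."""
        n_AA = int(round(n * f_AA))
        n_Aa = int(round((n - n_AA) * f_Aa))
        n_aa = n - n_AA - n_Aa
        assert hwe_exact_test(n_AA, n_Aa, n_aa) == pytest.approx(
            hwe_enumeration_oracle(n_AA, n_Aa, n_aa), abs=1e-12
        )


class TestSnpStats:
    @staticmethod
    def _samples(n, n_cases):
        return pd.DataFrame(
            {
                "sample_id": [f"s{i}" for i in range(n)],
                "status": [1] * n_cases + [0] * (n - n_cases),
                "site": "site0",
            }
        )

    def test_maf_and_monomorphic_flags(self):
        dm = DosageMatrix(
            [f"s{i}" for i in range(4)],
            ["zero", "half"],
            np.array([[0, 0.0], [0, 1.0], [0, 2.0], [0, 1.0]]),
        )
        stats = compute_snp_stats(dm, self._samples(4, 2))
        zero = stats.set_index("snp_id").loc["zero"]
        half = stats.set_index("snp_id").loc["half"]
        assert zero["maf"] == 0.0 and bool(zero["monomorphic"])
        assert half["maf"] == 0.5 and not bool(half["monomorphic"])

    def test_control_hwe_flags_het_deficit(self):
        # controls: 100 of each homozygote, zero heterozygotes
        controls = np.repeat([0.0, 2.0], 100)
        cases = np.ones(20)
        dm = DosageMatrix(
            [f"s{i}" for i in range(220)],
            ["snp"],
            np.concatenate([cases, controls])[:, None],
        )
        stats = compute_snp_stats(dm, self._samples(220, 20))
        assert stats.loc[0, "hwe_p_controls"] < 1e-6

    def test_hard_call_rounds_half_up(self):
        assert hard_call(np.array([0.49, 0.5, 1.49, 1.5, 2.0])).tolist() == [
            0, 1, 1, 2, 2,
        ]


def _qc_fixture():
    """100 samples x 6 SNPs: one SNP violating each rule, two clean, and one
    sample with excess missingness.

    With only six SNPs a single missing genotype already exceeds 5% sample
    missingness, so the fixture is analysed with ``sample_miss=0.35``: the
    designated bad sample (3/6 missing) is dropped while samples missing the
    one bad SNP (1/6) survive.
    """
    rng = np.random.default_rng(5)
    n = 100
    clean1 = rng.binomial(2, 0.3, n).astype(float)
    clean2 = rng.binomial(2, 0.4, n).astype(float)
    miss = rng.binomial(2, 0.3, n).astype(float)
    miss[1:7] = np.nan  # 6/99 missing after the bad sample is dropped
    rare = np.zeros(n)
    rare[1] = 1.0  # MAF ~0.005
    hwe = np.tile([0.0, 2.0], n // 2)  # both homozygotes, no heterozygotes
    lowr2 = rng.binomial(2, 0.3, n).astype(float)
    D = np.column_stack([clean1, miss, rare, hwe, lowr2, clean2])
    # one sample missing half its SNPs
    D[0, [0, 3, 5]] = np.nan
    dm = DosageMatrix(
        [f"s{i}" for i in range(n)],
        ["clean1", "miss", "rare", "hwe", "lowr2", "clean2"],
        D,
    )
    samples = pd.DataFrame(
        {
            "sample_id": dm.sample_ids,
            "status": [1] * 50 + [0] * 50,
            "site": "site0",
        }
    )
    meta = pd.DataFrame(
        {
            "snp_id": dm.snp_ids,
            "chrom": "1",
            "pos": np.arange(1, 7) * 1000,
            "minor": "A",
            "major": "G",
            "imputation_r2": [0.95, 0.95, 0.95, 0.95, 0.2, 0.95],
        }
    )
    return dm, samples, meta


class TestApplyQc:
    def test_one_snp_dropped_per_rule(self):
        dm, samples, meta = _qc_fixture()
        filtered, samples_out, stats, report = apply_qc(
            dm, samples, meta, QcThresholds(sample_miss=0.35)
        )
        assert report.samples_dropped_missingness == ["s0"]
        assert report.snps_dropped["missingness"] == ["miss"]
        assert report.snps_dropped["maf"] == ["rare"]
        assert report.snps_dropped["hwe"] == ["hwe"]
        assert report.snps_dropped["r2"] == ["lowr2"]
        assert report.surviving_snps == ["clean1", "clean2"]
        assert filtered.n_samples == 99 and filtered.n_snps == 2

    def test_accounting_adds_up(self):
        dm, samples, meta = _qc_fixture()
        *_, report = apply_qc(dm, samples, meta, QcThresholds(sample_miss=0.35))
        dropped = sum(len(v) for v in report.snps_dropped.values())
        assert dropped + len(report.surviving_snps) == report.n_snps_in
        assert (
            len(report.samples_dropped_missingness) + len(report.surviving_samples)
            == report.n_samples_in
        )

    def test_clean_input_is_identity(self):
        rng = np.random.default_rng(6)
        D = rng.binomial(2, 0.3, size=(60, 3)).astype(float)
        dm = DosageMatrix([f"s{i}" for i in range(60)], ["a", "b", "c"], D)
        samples = pd.DataFrame(
            {"sample_id": dm.sample_ids, "status": [1, 0] * 30, "site": "x"}
        )
        filtered, _, _, report = apply_qc(dm, samples)
        assert filtered.snp_ids == dm.snp_ids
        assert filtered.n_samples == 60
        assert all(not v for v in report.snps_dropped.values())

    def test_maf_exactly_at_cutoff_is_retained(self):
        """The frequency rule is strict: only MAF < 1% is dropped."""
        n = 100
        D = np.zeros((n, 1))
        D[:2, 0] = 1.0  # mean dosage 0.02 -> MAF exactly 0.01
        dm = DosageMatrix([f"s{i}" for i in range(n)], ["edge"], D)
        samples = pd.DataFrame(
            {"sample_id": dm.sample_ids, "status": [1] * 50 + [0] * 50, "site": "x"}
        )
        filtered, *_ = apply_qc(dm, samples)
        assert filtered.snp_ids == ["edge"]

    def test_idempotent(self):
        dm, samples, meta = _qc_fixture()
        th = QcThresholds(sample_miss=0.35)
        filtered, samples_out, stats, _ = apply_qc(dm, samples, meta, th)
        again, _, _, report2 = apply_qc(filtered, samples_out, stats, th)
        assert again.snp_ids == filtered.snp_ids
        assert again.n_samples == filtered.n_samples
        assert all(not v for v in report2.snps_dropped.values())

    def test_all_samples_removed_is_fatal(self):
        D = np.full((3, 2), np.nan)
        dm = DosageMatrix(["a", "b", "c"], ["x", "y"], D)
        samples = pd.DataFrame(
            {"sample_id": ["a", "b", "c"], "status": [1, 0, 1], "site": "s"}
        )
        with pytest.raises(ValidationError):
            apply_qc(dm, samples)


class TestAssignSnpsToGene:
    region = GeneRegion(gene="G", chrom="1", start=100_000, end=120_000, pad=10_000)

    @staticmethod
    def _table(positions):
        return pd.DataFrame(
            {
                "snp_id": [f"r{i}" for i in range(len(positions))],
                "chrom": "1",
                "pos": positions,
            }
        )

    def test_pad_boundary_semantics(self):
        # 0-based region start 100,000: the SNP exactly 10 kb upstream
        # (0-based 90,000 = 1-based 90,001) is in; one bp further is out
        table = self._table([90_000, 90_001, 110_000, 130_000, 130_001])
        assert assign_snps_to_gene(table, self.region) == ["r1", "r2", "r3"]

    def test_other_chromosome_excluded_and_empty_ok(self):
        table = self._table([110_000]).assign(chrom="2")
        assert assign_snps_to_gene(table, self.region) == []

    def test_ordered_by_position(self):
        table = self._table([115_000, 105_000, 110_000])
        assert assign_snps_to_gene(table, self.region) == ["r1", "r2", "r0"]


class TestSelectCandidateGenes:
    def test_packaged_table_yields_fourteen_autosomal_genes(self):
        table = read_candidate_genes()
        assert len(table) == 16
        selected = select_candidate_genes(table)
        assert len(selected) == 14
        assert not set(selected["gene"]) & {"L1CAM", "DMD"}
        assert "KCNQ2" in set(selected["gene"])

    def test_score_exactly_at_threshold_is_retained(self):
        table = pd.DataFrame(
            {"gene": ["A", "B"], "chrom": ["1", "2"], "score": [0.7, 0.6999]}
        )
        assert select_candidate_genes(table)["gene"].tolist() == ["A"]

    def test_empty_input(self):
        table = pd.DataFrame({"gene": [], "chrom": [], "score": []})
        assert len(select_candidate_genes(table)) == 0

    def test_x_genes_kept_when_autosome_filter_off(self):
        table = read_candidate_genes()
        assert len(select_candidate_genes(table, autosomes_only=False)) == 16
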