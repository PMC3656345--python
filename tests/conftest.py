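"""Shared fixtures: small synthetic cohorts reused across test modules."""

import numpy as np
import pandas as pd
import pytest

from episcan.synthdata import GeneSpec, SimulationConfig, simulate_study


def tiny_config(**overrides) -> SimulationConfig:
    """A fast two-partner-gene study; callers override what they test."""
    defaults = dict(
        index_gene=GeneSpec(name="ANK3", chrom="10", n_snps=6, start=61_780_000),
        partner_genes=[
            GeneSpec(
                name="KCNQ2", chrom="20", n_snps=4, start=61_500_000,
                duplicate_pairs=[(0, 1)],
            ),
            GeneSpec(name="SPTB", chrom="14", n_snps=3, start=64_200_000),
        ],
        n_cases=250,
        n_controls=250,
        beta3=float(np.log(2.5)),
        planted_pair=(("ANK3", 2), ("KCNQ2", 0)),
        n_background_snps=60,
        seed=123,
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults)


@pytest.fixture(scope="session")
def small_bundle():
    """One simulated two-cohort study with a planted interaction."""
    return simulate_study(tiny_config(), seed=123)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


def two_snp_cohort(
    n: int,
    beta0: float = 0.0,
    beta1: float = 0.0,
    beta2: float = 0.0,
    beta3: float = 0.0,
    maf: float = 0.3,
    seed: int = 0,
    confound: float = 0.0,
):
    """Direct two-locus logistic draw (prospective, no ascertainment).

    Returns (dA, dB, y, site, ancestry).  With ``confound`` nonzero, both
    SNP frequencies shift along ancestry coordinate 1 and the coordinate
    loads on risk, creating genuine confounding.
    """
    rg = np.random.default_rng(seed)
    anc = rg.standard_normal((n, 2))
    site = rg.integers(0, 2, size=n)
    if confound:
        fa = np.clip(maf + 0.1 * anc[:, 0], 0.02, 0.98)
        fb = np.clip(maf + 0.1 * anc[:, 0], 0.02, 0.98)
        dA = rg.binomial(2, fa).astype(float)
        dB = rg.binomial(2, fb).astype(float)
    else:
        dA = rg.binomial(2, maf, size=n).astype(float)
        dB = rg.binomial(2, maf, size=n).astype(float)
    eta = (
        beta0 + beta1 * dA + beta2 * dB + beta3 * dA * dB
        + 0.4 * site + confound * anc[:, 0]
    )
    y = (rg.random(n) < 1.0 / (1.0 + np.exp(-eta))).astype(float)
    return dA, dB, y, site, anc


def site_ancestry_covariates(site: np.ndarray, anc: np.ndarray) -> np.ndarray:
    return np.column_stack([site.astype(float), anc])
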