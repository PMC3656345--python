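"""Synthetic case-control GWAS cohorts with a planted two-locus interaction.

The generator emulates the features of an imputed candidate-gene dataset
that the downstream scan depends on, without any controlled-access data:

* LD-blocked SNPs inside gene regions, drawn from a pool of binary
  haplotypes (a latent Gaussian AR(1) per block thresholded at each SNP's
  MAF quantile, so LD decays with index distance inside a block and is zero
  across blocks), including designated perfectly correlated SNP pairs;
* fractional dosages with per-SNP imputation noise calibrated to a target
  dosage-vs-truth r^2;
* study-site structure and a two-dimensional latent ancestry that shifts
  the allele frequencies of a subset of background SNPs (so PCA has signal
  to recover) and loads on disease risk (so it confounds);
* a retrospective case-control draw from a logistic disease model with a
  planted dosage-dosage interaction between one index-gene SNP and one
  partner-gene SNP.

Two cohorts (discovery and replication) are independent draws from the same
generative process; the full configuration is kept as the truth record.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.stats import norm

from .gwasio import (
    read_dosages,
    read_gene_regions_bed,
    read_samples_tsv,
    write_dosages_tsv,
    write_gene_regions_bed,
    write_samples_tsv,
)
from .types import ConfigurationError, DosageMatrix, GeneRegion

_ANCESTRY_COLS = ("a1", "a2")


@dataclass
class GeneSpec:
    """Layout of one simulated gene region."""

    name: str
    chrom: str
    n_snps: int
    start: int = 1_000_000  # 1-based position of the first SNP
    spacing: int = 2_000  # bp between adjacent SNPs
    maf_low: float = 0.10
    maf_high: float = 0.45
    block_size: int = 5
    # (source, copy) SNP indices forced into perfect LD (r^2 = 1 in the pool)
    duplicate_pairs: list[tuple[int, int]] = field(default_factory=list)
    # allele-frequency shift per unit of ancestry coordinate 1; genes with a
    # nonzero shift are drawn per-sample (binomial) instead of from the pool
    ancestry_shift: float = 0.0

    def validate(self) -> None:
        if self.n_snps <= 0:
            raise ConfigurationError(f"{self.name}: n_snps must be positive")
        if not (0.0 < self.maf_low <= self.maf_high <= 0.5):
            raise ConfigurationError(f"{self.name}: MAF range must lie in (0, 0.5]")
        if self.block_size <= 0:
            raise ConfigurationError(f"{self.name}: block_size must be positive")
        for src, dst in self.duplicate_pairs:
            if not (0 <= src < self.n_snps and 0 <= dst < self.n_snps) or src == dst:
                raise ConfigurationError(f"{self.name}: bad duplicate pair {(src, dst)}")

    def snp_ids(self) -> list[str]:
        return [f"{self.name}_s{i:02d}" for i in range(self.n_snps)]


@dataclass
class SimulationConfig:
    """Full generative description of a two-cohort interaction study."""

    index_gene: GeneSpec
    partner_genes: list[GeneSpec]
    n_cases: int = 1000
    n_controls: int = 1000
    n_cases_replication: int | None = None  # None -> same as discovery
    n_controls_replication: int | None = None
    beta0: float = -0.5  # baseline log-odds
    beta1: float = 0.0  # main effect, planted index SNP
    beta2: float = 0.0  # main effect, planted partner SNP
    beta3: float = float(np.log(2.0))  # interaction log-odds
    planted_pair: tuple[tuple[str, int], tuple[str, int]] = (
        ("ANK3", 2),
        ("KCNQ2", 0),
    )  # (gene name, SNP index) x 2
    site_count: int = 2
    site_effects: tuple[float, ...] = (0.0, 0.3)  # log-odds offset per site
    ancestry_effect: tuple[float, float] = (0.4, 0.0)  # log-odds per coordinate
    n_background_snps: int = 200
    background_informative_fraction: float = 0.5
    background_shift: float = 0.08  # allele-freq shift per unit of coordinate 1
    imputation_r2_low: float = 0.7
    imputation_r2_high: float = 0.99
    n_haplotypes: int = 2000
    ld_rho: float = 0.9  # latent AR(1) correlation between adjacent SNPs
    seed: int = 0

    def validate(self) -> None:
        self.index_gene.validate()
        for g in self.partner_genes:
            g.validate()
        names = [self.index_gene.name] + [g.name for g in self.partner_genes]
        if len(set(names)) != len(names):
            raise ConfigurationError("gene names must be unique")
        if self.n_cases <= 0 or self.n_controls <= 0:
            raise ConfigurationError("cohort sizes must be positive")
        if len(self.site_effects) != self.site_count:
            raise ConfigurationError("site_effects length must equal site_count")
        if not (0.0 < self.imputation_r2_low <= self.imputation_r2_high <= 1.0):
            raise ConfigurationError("imputation r^2 targets must lie in (0, 1]")
        if not (0.0 <= self.ld_rho < 1.0):
            raise ConfigurationError("ld_rho must lie in [0, 1)")
        genes = {g.name: g for g in [self.index_gene] + self.partner_genes}
        for gene, idx in self.planted_pair:
            if gene not in genes or not (0 <= idx < genes[gene].n_snps):
                raise ConfigurationError(f"planted SNP ({gene}, {idx}) does not exist")

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["planted_pair"] = [list(p) for p in self.planted_pair]
        d["site_effects"] = list(self.site_effects)
        d["ancestry_effect"] = list(self.ancestry_effect)
        for key in ("index_gene",):
            d[key]["duplicate_pairs"] = [list(p) for p in d[key]["duplicate_pairs"]]
        for g in d["partner_genes"]:
            g["duplicate_pairs"] = [list(p) for p in g["duplicate_pairs"]]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        d["index_gene"] = _genespec_from_dict(d["index_gene"])
        d["partner_genes"] = [_genespec_from_dict(g) for g in d["partner_genes"]]
        d["planted_pair"] = tuple((p[0], int(p[1])) for p in d["planted_pair"])
        d["site_effects"] = tuple(float(x) for x in d["site_effects"])
        d["ancestry_effect"] = tuple(float(x) for x in d["ancestry_effect"])
        return cls(**d)

    def planted_snp_ids(self) -> tuple[str, str]:
        (ga, ia), (gb, ib) = self.planted_pair
        return f"{ga}_s{ia:02d}", f"{gb}_s{ib:02d}"


def _genespec_from_dict(d: dict) -> GeneSpec:
    d = dict(d)
    d["duplicate_pairs"] = [tuple(int(v) for v in p) for p in d.get("duplicate_pairs", [])]
    return GeneSpec(**d)


@dataclass
class HaplotypePool:
    """Pool of binary haplotypes with block structure and target MAFs."""

    snp_ids: list[str]
    block_assignments: np.ndarray  # per SNP
    haplotypes: np.ndarray  # n_haplotypes x n_snps, 0/1
    target_mafs: np.ndarray

    @property
    def n_haplotypes(self) -> int:
        return self.haplotypes.shape[0]


@dataclass
class Cohort:
    """One simulated cohort: dosages + sample and SNP tables."""

    dosages: DosageMatrix
    samples: pd.DataFrame
    snps: pd.DataFrame


@dataclass
class CohortBundle:
    """Discovery + replication cohorts, gene regions and the truth record."""

    discovery: Cohort
    replication: Cohort
    regions: list[GeneRegion]
    truth: SimulationConfig

    def save(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, cohort in (("discovery", self.discovery), ("replication", self.replication)):
            write_dosages_tsv(
                outdir / f"{name}.dosages.tsv", cohort.dosages, meta=cohort.snps
            )
            write_samples_tsv(outdir / f"{name}.samples.tsv", cohort.samples)
        write_gene_regions_bed(outdir / "genes.bed", self.regions)
        with open(outdir / "truth.yaml", "w") as fh:
            yaml.safe_dump(self.truth.to_dict(), fh, sort_keys=True)

    @classmethod
    def load(cls, outdir: str | Path) -> "CohortBundle":
        outdir = Path(outdir)
        cohorts = {}
        for name in ("discovery", "replication"):
            dm, meta = read_dosages(outdir / f"{name}.dosages.tsv", format="tsv")
            samples = read_samples_tsv(outdir / f"{name}.samples.tsv")
            cohorts[name] = Cohort(dosages=dm, samples=samples, snps=meta)
        regions = read_gene_regions_bed(outdir / "genes.bed")
        with open(outdir / "truth.yaml") as fh:
            truth = SimulationConfig.from_dict(yaml.safe_load(fh))
        return cls(
            discovery=cohorts["discovery"],
            replication=cohorts["replication"],
            regions=regions,
            truth=truth,
        )


# ---------------------------------------------------------------------------
# generative operations
# ---------------------------------------------------------------------------


def simulate_haplotype_pool(
    n_haplotypes: int,
    snp_layout: pd.DataFrame,
    ld_block_size: int,
    seed: int | np.random.SeedSequence,
    rho: float = 0.9,
) -> HaplotypePool:
    """Draw a pool of binary haplotypes with block-wise LD.

    ``snp_layout`` needs columns ``snp_id`` and ``target_maf`` and may carry
    ``duplicate_of`` (source snp_id whose column is copied verbatim,
    yielding r^2 = 1).  Consecutive SNPs are grouped into blocks of
    ``ld_block_size``; within a block the latent AR(1) correlation ``rho``
    makes genotype r^2 decay with index distance, across blocks SNPs are
    independent.
    """
    if n_haplotypes < 2:
        raise ConfigurationError("n_haplotypes must be >= 2")
    if ld_block_size <= 0:
        raise ConfigurationError("ld_block_size must be positive")
    mafs = snp_layout["target_maf"].to_numpy(dtype=float)
    if ((mafs <= 0) | (mafs > 0.5)).any():
        raise ConfigurationError("target MAFs must lie in (0, 0.5]")
    m = len(snp_layout)
    rng = np.random.default_rng(seed)
    blocks = np.arange(m) // ld_block_size
    H = np.empty((n_haplotypes, m), dtype=np.int8)
    thresholds = norm.ppf(mafs)
    z_prev = np.empty(n_haplotypes)
    for j in range(m):
        eps = rng.standard_normal(n_haplotypes)
        if j > 0 and blocks[j] == blocks[j - 1]:
            z = rho * z_prev + np.sqrt(1.0 - rho**2) * eps
        else:
            z = eps
        H[:, j] = (z < thresholds[j]).astype(np.int8)
        z_prev = z
    if "duplicate_of" in snp_layout.columns:
        ids = snp_layout["snp_id"].tolist()
        col = {s: i for i, s in enumerate(ids)}
        for i, src in enumerate(snp_layout["duplicate_of"]):
            if isinstance(src, str) and src:
                H[:, i] = H[:, col[src]]
                blocks[i] = blocks[col[src]]
    return HaplotypePool(
        snp_ids=snp_layout["snp_id"].tolist(),
        block_assignments=blocks,
        haplotypes=H,
        target_mafs=mafs,
    )


def simulate_genotypes(
    pool: HaplotypePool,
    n_samples: int,
    seed: int | np.random.SeedSequence,
) -> DosageMatrix:
    """Integer genotypes: each sample is the sum of two pool haplotypes."""
    if n_samples <= 0:
        raise ConfigurationError("n_samples must be positive")
    if pool.n_haplotypes == 0:
        raise ConfigurationError("empty haplotype pool")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, pool.n_haplotypes, size=(n_samples, 2))
    G = pool.haplotypes[idx[:, 0]] + pool.haplotypes[idx[:, 1]]
    sample_ids = [f"s{i:05d}" for i in range(n_samples)]
    return DosageMatrix(sample_ids, pool.snp_ids, G.astype(np.float64))


def add_imputation_noise(
    dosages: DosageMatrix,
    r2_targets: np.ndarray | float,
    seed: int | np.random.SeedSequence,
) -> tuple[DosageMatrix, np.ndarray]:
    """Degrade hard dosages into fractional ones with target dosage r^2.

    Gaussian noise is added per SNP and the result clipped to [0, 2]; the
    noise scale is found by bisection against the realized (post-clip)
    squared correlation with the true dosage, and the realized value — not
    the target — is returned, mirroring how imputation quality is an
    estimated property of the delivered dosages.  Constant SNPs have no
    defined correlation: they are left unchanged with recorded r^2 = 0.
    """
    m = dosages.n_snps
    targets = np.broadcast_to(np.asarray(r2_targets, dtype=float), (m,)).copy()
    if ((targets <= 0) | (targets > 1)).any():
        raise ConfigurationError("imputation r^2 targets must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    D = dosages.dosages.copy()
    realized = np.empty(m)
    for j in range(m):
        d = dosages.dosages[:, j]
        sd = np.std(d)
        if sd == 0.0:
            realized[j] = 0.0
            continue
        if targets[j] >= 1.0:
            realized[j] = 1.0
            continue
        eps = rng.standard_normal(d.shape[0])
        lo, hi = 0.0, sd * np.sqrt((1.0 - targets[j]) / targets[j])

        def _r2(scale: float) -> float:
            noisy = np.clip(d + scale * eps, 0.0, 2.0)
            if np.std(noisy) == 0.0:
                return 0.0
            return float(np.corrcoef(d, noisy)[0, 1] ** 2)

        # grow hi until the realized r^2 falls below target (clipping damps
        # the noise, so the unclipped-calibration scale may be too small)
        for _ in range(60):
            if _r2(hi) < targets[j]:
                break
            hi *= 1.5
        for _ in range(50):
            mid = 0.5 * (lo + hi)
            if _r2(mid) > targets[j]:
                lo = mid
            else:
                hi = mid
        scale = 0.5 * (lo + hi)
        D[:, j] = np.clip(d + scale * eps, 0.0, 2.0)
        realized[j] = _r2(scale)
    return DosageMatrix(dosages.sample_ids, dosages.snp_ids, D), realized


def simulate_phenotypes(
    dosages: DosageMatrix,
    config: SimulationConfig,
    seed: int | np.random.SeedSequence,
    site: np.ndarray | None = None,
    ancestry: np.ndarray | None = None,
) -> pd.DataFrame:
    """Bernoulli case labels from the logistic two-locus risk model.

    logit P(case) = b0 + b1*dA + b2*dB + b3*dA*dB + site offset
                    + ancestry_effect . a

    ``site``/``ancestry`` may be supplied (e.g. when the same latent
    ancestry already shaped the genotypes); otherwise they are drawn here.
    Returns a sample table with status, site and the true ancestry
    coordinates.
    """
    rng = np.random.default_rng(seed)
    n = dosages.n_samples
    snp_a, snp_b = config.planted_snp_ids()
    for s in (snp_a, snp_b):
        if s not in dosages.snp_ids:
            raise ConfigurationError(f"planted SNP {s!r} missing from dosage matrix")
    if site is None:
        site = rng.integers(0, config.site_count, size=n)
    if ancestry is None:
        ancestry = rng.standard_normal((n, 2))
    dA = dosages.column(snp_a)
    dB = dosages.column(snp_b)
    eta = (
        config.beta0
        + config.beta1 * dA
        + config.beta2 * dB
        + config.beta3 * dA * dB
        + np.asarray(config.site_effects)[site]
        + ancestry @ np.asarray(config.ancestry_effect)
    )
    prob = 1.0 / (1.0 + np.exp(-eta))
    status = rng.random(n) < prob
    return pd.DataFrame(
        {
            "sample_id": dosages.sample_ids,
            "status": status.astype(int),
            "site": [f"site{k}" for k in site],
            "a1": ancestry[:, 0],
            "a2": ancestry[:, 1],
        }
    )


def _gene_layout(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Per-SNP layout (id, gene, chrom, pos, target MAF, duplicate links)."""
    rows = []
    for gene in [config.index_gene] + config.partner_genes:
        ids = gene.snp_ids()
        mafs = rng.uniform(gene.maf_low, gene.maf_high, size=gene.n_snps)
        dup = [""] * gene.n_snps
        for src, dst in gene.duplicate_pairs:
            dup[dst] = ids[src]
            mafs[dst] = mafs[src]
        for i, sid in enumerate(ids):
            rows.append(
                {
                    "snp_id": sid,
                    "gene": gene.name,
                    "chrom": gene.chrom,
                    "pos": gene.start + i * gene.spacing,
                    "target_maf": mafs[i],
                    "duplicate_of": dup[i],
                    "ancestry_shift": gene.ancestry_shift,
                    "block_size": gene.block_size,
                }
            )
    return pd.DataFrame(rows)


def _simulate_cohort(
    config: SimulationConfig,
    layout: pd.DataFrame,
    pools: dict[str, HaplotypePool],
    bg_freqs: np.ndarray,
    bg_informative: np.ndarray,
    n_cases: int,
    n_controls: int,
    seq: np.random.SeedSequence,
    cohort_tag: str,
) -> Cohort:
    rng = np.random.default_rng(seq)
    gene_names = [config.index_gene.name] + [g.name for g in config.partner_genes]
    specs = {g.name: g for g in [config.index_gene] + config.partner_genes}
    n_bg = config.n_background_snps

    kept_rows: list[np.ndarray] = []
    kept_samples: list[pd.DataFrame] = []
    need_cases, need_controls = n_cases, n_controls
    batch = max(1024, 2 * (n_cases + n_controls))
    for _round in range(80):
        if need_cases <= 0 and need_controls <= 0:
            break
        site = rng.integers(0, config.site_count, size=batch)
        ancestry = rng.standard_normal((batch, 2))
        blocks_g = []
        for gname in gene_names:
            spec = specs[gname]
            sub = layout[layout["gene"] == gname]
            if spec.ancestry_shift == 0.0:
                pool = pools[gname]
                idx = rng.integers(0, pool.n_haplotypes, size=(batch, 2))
                G = (pool.haplotypes[idx[:, 0]] + pool.haplotypes[idx[:, 1]]).astype(
                    np.float64
                )
            else:
                f = sub["target_maf"].to_numpy()[None, :] + spec.ancestry_shift * ancestry[
                    :, [0]
                ]
                f = np.clip(f, 0.02, 0.98)
                G = rng.binomial(2, f).astype(np.float64)
            blocks_g.append(G)
        if n_bg > 0:
            f = np.broadcast_to(bg_freqs[None, :], (batch, n_bg)).copy()
            f[:, bg_informative] = np.clip(
                bg_freqs[bg_informative][None, :]
                + config.background_shift * ancestry[:, [0]],
                0.02,
                0.98,
            )
            blocks_g.append(rng.binomial(2, f).astype(np.float64))
        G_all = np.concatenate(blocks_g, axis=1)

        snp_ids = layout["snp_id"].tolist() + [f"bg_s{i:04d}" for i in range(n_bg)]
        dm = DosageMatrix(
            [f"tmp{i}" for i in range(batch)], snp_ids, G_all
        )
        pheno = simulate_phenotypes(
            dm, config, rng.integers(2**31), site=site, ancestry=ancestry
        )
        y = pheno["status"].to_numpy()
        take_case = np.nonzero(y == 1)[0][: max(need_cases, 0)]
        take_ctrl = np.nonzero(y == 0)[0][: max(need_controls, 0)]
        take = np.concatenate([take_case, take_ctrl])
        kept_rows.append(G_all[take])
        kept_samples.append(pheno.iloc[take])
        need_cases -= take_case.size
        need_controls -= take_ctrl.size
    if need_cases > 0 or need_controls > 0:
        raise ConfigurationError(
            "could not reach case/control quotas; baseline risk too extreme"
        )

    G = np.concatenate(kept_rows, axis=0)
    samples = pd.concat(kept_samples, ignore_index=True)
    order = rng.permutation(len(samples))
    G = G[order]
    samples = samples.iloc[order].reset_index(drop=True)
    sample_ids = [f"{cohort_tag}{i:05d}" for i in range(len(samples))]
    samples = samples.assign(sample_id=sample_ids)

    snp_ids = layout["snp_id"].tolist() + [
        f"bg_s{i:04d}" for i in range(n_bg)
    ]
    dm = DosageMatrix(sample_ids, snp_ids, G)

    # imputation noise on every SNP
    targets = np.random.default_rng(seq.spawn(1)[0]).uniform(
        config.imputation_r2_low, config.imputation_r2_high, size=dm.n_snps
    )
    noisy, realized = add_imputation_noise(dm, targets, seq.spawn(2)[1])

    # fold to the minor allele on the delivered (noisy) dosages — the same
    # decision a loader makes, so save/load round-trips cleanly
    freqs = noisy.dosages.mean(axis=0) / 2.0
    flip = freqs > 0.5
    minor = np.where(flip, "G", "A").astype(object)
    major = np.where(flip, "A", "G").astype(object)
    if flip.any():
        noisy.dosages[:, flip] = 2.0 - noisy.dosages[:, flip]

    chroms = layout["chrom"].tolist() + ["99"] * n_bg
    positions = layout["pos"].tolist() + [
        1_000_000 + 10_000 * i for i in range(n_bg)
    ]
    snp_meta = pd.DataFrame(
        {
            "snp_id": snp_ids,
            "chrom": chroms,
            "pos": positions,
            "minor": minor,
            "major": major,
            "imputation_r2": realized,
        }
    )
    return Cohort(dosages=noisy, samples=samples, snps=snp_meta)


def simulate_study(
    config: SimulationConfig, seed: int | None = None
) -> CohortBundle:
    """Generate a full two-cohort study from one master seed.

    The master seed (argument, else ``config.seed``) deterministically
    derives child seeds for the haplotype pool, each cohort's genotype and
    phenotype draws, and the imputation noise, so identical configurations
    reproduce bit-identical bundles.
    """
    config.validate()
    master = np.random.SeedSequence(seed if seed is not None else config.seed)
    seq_layout, seq_pool, seq_disc, seq_rep = master.spawn(4)

    layout_rng = np.random.default_rng(seq_layout)
    layout = _gene_layout(config, layout_rng)
    bg_freqs = layout_rng.uniform(0.1, 0.5, size=config.n_background_snps)
    n_informative = int(
        round(config.background_informative_fraction * config.n_background_snps)
    )
    bg_informative = np.zeros(config.n_background_snps, dtype=bool)
    bg_informative[:n_informative] = True

    pools: dict[str, HaplotypePool] = {}
    pool_seqs = seq_pool.spawn(1 + len(config.partner_genes))
    for gene, gseq in zip([config.index_gene] + config.partner_genes, pool_seqs):
        sub = layout[layout["gene"] == gene.name][
            ["snp_id", "target_maf", "duplicate_of"]
        ].reset_index(drop=True)
        pools[gene.name] = simulate_haplotype_pool(
            config.n_haplotypes, sub, gene.block_size, gseq, rho=config.ld_rho
        )

    n_cases_rep = config.n_cases_replication or config.n_cases
    n_controls_rep = config.n_controls_replication or config.n_controls
    discovery = _simulate_cohort(
        config, layout, pools, bg_freqs, bg_informative,
        config.n_cases, config.n_controls, seq_disc, "D",
    )
    replication = _simulate_cohort(
        config, layout, pools, bg_freqs, bg_informative,
        n_cases_rep, n_controls_rep, seq_rep, "R",
    )

    regions = []
    for gene in [config.index_gene] + config.partner_genes:
        sub = layout[layout["gene"] == gene.name]
        regions.append(
            GeneRegion(
                gene=gene.name,
                chrom=gene.chrom,
                start=int(sub["pos"].min()) - 1,
                end=int(sub["pos"].max()),
                pad=10_000,
            )
        )
    return CohortBundle(
        discovery=discovery, replication=replication, regions=regions, truth=config
    )


def default_demo_config(seed: int = 0) -> SimulationConfig:
    """The packaged demonstration study.

    An ANK3-like index gene scanned against three partner genes, with the
    interaction planted between index SNP 2 and the first SNP of the
    KCNQ2-like partner, whose first two SNPs are in perfect LD — the
    structure the method is designed to detect.
    """
    return SimulationConfig(
        index_gene=GeneSpec(name="ANK3", chrom="10", n_snps=12, start=61_780_000),
        partner_genes=[
            GeneSpec(
                name="KCNQ2",
                chrom="20",
                n_snps=6,
                start=61_500_000,
                duplicate_pairs=[(0, 1)],
            ),
            GeneSpec(name="KCNQ3", chrom="8", n_snps=5, start=133_100_000),
            GeneSpec(name="SPTB", chrom="14", n_snps=5, start=64_200_000),
        ],
        n_cases=600,
        n_controls=600,
        beta1=0.1,
        beta2=0.1,
        beta3=float(np.log(2.2)),
        planted_pair=(("ANK3", 2), ("KCNQ2", 0)),
        n_background_snps=150,
        seed=seed,
    )
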