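"""End-to-end driver: simulate -> QC -> PCA -> scan -> permute -> replicate.

Chains the library stages exactly the way the analysis scripts do, writing
byte-stable TSVs (fixed float formats, deterministic orderings) so a fixed
master seed reproduces identical result files.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .core import gene_min_p, scan_gene_pair
from .gwasio import read_candidate_genes
from .permrep import (
    PermutationNull,
    build_null,
    cross_gene_rescan,
    replicate_pairs,
    significance_threshold,
    summarize_genes,
)
from .qc import QcThresholds, apply_qc, assign_snps_to_gene, select_candidate_genes
from .structure import build_covariates, eigenstrat_pca
from .synthdata import CohortBundle, SimulationConfig, simulate_study
from .types import CovariateMatrix, DosageMatrix, GeneRegion, ValidationError

_FLOAT_FMT = "%.10g"


@dataclass
class CohortAnalysis:
    """Post-QC view of one cohort ready for scanning."""

    dosages: DosageMatrix
    samples: pd.DataFrame
    snps: pd.DataFrame
    covariates: CovariateMatrix
    y: np.ndarray
    index_snps: list[str]
    gene_snp_lists: dict[str, list[str]]


@dataclass
class PipelineResult:
    bundle: CohortBundle
    scans: pd.DataFrame
    gene_summary: pd.DataFrame
    null: PermutationNull
    threshold: float
    significant_pairs: pd.DataFrame
    replication: pd.DataFrame
    rescan: pd.DataFrame


def prepare_cohort(
    dosages: DosageMatrix,
    samples: pd.DataFrame,
    snps: pd.DataFrame,
    regions: list[GeneRegion],
    index_gene: str,
    partner_genes: list[str],
    thresholds: QcThresholds | None = None,
    k_pcs: int = 2,
) -> CohortAnalysis:
    """QC a cohort, estimate ancestry PCs and collect per-gene SNP lists."""
    filtered, samples_out, stats, _report = apply_qc(
        dosages, samples, snp_meta=snps, thresholds=thresholds
    )
    pcs = eigenstrat_pca(filtered, k=k_pcs)
    covariates = build_covariates(samples_out, pcs, k=k_pcs)
    y = samples_out["status"].to_numpy(dtype=np.float64)

    by_gene = {r.gene: r for r in regions}
    if index_gene not in by_gene:
        raise ValidationError(f"index gene {index_gene!r} has no region")
    index_snps = assign_snps_to_gene(stats, by_gene[index_gene])
    if not index_snps:
        raise ValidationError(f"no post-QC SNPs in index gene {index_gene!r}")
    gene_snp_lists = {}
    for g in partner_genes:
        if g not in by_gene:
            continue
        snp_list = assign_snps_to_gene(stats, by_gene[g])
        if snp_list:
            gene_snp_lists[g] = snp_list
    return CohortAnalysis(
        dosages=filtered,
        samples=samples_out,
        snps=stats,
        covariates=covariates,
        y=y,
        index_snps=index_snps,
        gene_snp_lists=gene_snp_lists,
    )


def scan_all_genes(cohort: CohortAnalysis, index_gene: str) -> tuple[pd.DataFrame, dict[str, float]]:
    """Scan the index gene against every partner; gene-level minima."""
    frames = []
    observed: dict[str, float] = {}
    for gene, snps in cohort.gene_snp_lists.items():
        scan = scan_gene_pair(
            cohort.dosages,
            cohort.index_snps,
            snps,
            cohort.covariates,
            cohort.y,
            gene_index=index_gene,
            gene_partner=gene,
        )
        frames.append(scan.to_frame())
        try:
            observed[gene], _best = gene_min_p(scan)
        except ValidationError:
            observed[gene] = np.nan
    scans = pd.concat(frames, ignore_index=True)
    return scans, observed


def run_pipeline(
    config: SimulationConfig,
    master_seed: int,
    outdir: str | Path,
    B: int = 200,
    alpha: float = 0.05,
    k_pcs: int = 2,
    candidate_table: pd.DataFrame | None = None,
) -> PipelineResult:
    """Run the full study on synthetic cohorts and write result TSVs.

    Stages: candidate-gene selection (packaged STRING-derived table unless
    one is given), cohort simulation, per-cohort QC + PCA, the discovery
    interaction scan, the B-replicate permutation null with its rank
    threshold, pair selection, replication, and the driving-SNP rescan.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed_seq = np.random.SeedSequence(master_seed)
    sim_seed, perm_seed = (int(s.generate_state(1)[0] % 2**31) for s in seed_seq.spawn(2))

    candidates = select_candidate_genes(
        candidate_table if candidate_table is not None else read_candidate_genes()
    )
    bundle = simulate_study(config, sim_seed)
    bundle.save(outdir / "data")

    index_gene = config.index_gene.name
    simulated_partners = [g.name for g in config.partner_genes]
    partner_genes = [g for g in simulated_partners if g in set(candidates["gene"])]
    if not partner_genes:  # simulated genes outside the candidate table
        partner_genes = simulated_partners

    disc = prepare_cohort(
        bundle.discovery.dosages,
        bundle.discovery.samples,
        bundle.discovery.snps,
        bundle.regions,
        index_gene,
        partner_genes,
        k_pcs=k_pcs,
    )
    scans, observed = scan_all_genes(disc, index_gene)
    scans.to_csv(outdir / "scan.tsv", sep="\t", index=False, float_format=_FLOAT_FMT)

    null = build_null(
        disc.dosages,
        disc.y,
        disc.covariates,
        disc.index_snps,
        disc.gene_snp_lists,
        B=B,
        master_seed=perm_seed,
        alpha=alpha,
    )
    pd.DataFrame(
        {"replicate": np.arange(null.B), "seed": null.seeds, "min_p": null.null_min_p}
    ).to_csv(outdir / "null.tsv", sep="\t", index=False, float_format=_FLOAT_FMT)
    threshold = significance_threshold(null, alpha)

    gene_summary = summarize_genes(
        {g: p for g, p in observed.items() if np.isfinite(p)}, null, alpha
    )
    gene_summary.to_csv(
        outdir / "empirical.tsv", sep="\t", index=False, float_format=_FLOAT_FMT
    )

    ok = scans[(scans["status"] == "OK") & (scans["p"] <= threshold)]
    pairs = ok.sort_values(["p", "gene", "snp_a", "snp_b"], kind="mergesort").reset_index(
        drop=True
    )
    pairs.to_csv(outdir / "pairs.tsv", sep="\t", index=False, float_format=_FLOAT_FMT)

    rep = prepare_cohort(
        bundle.replication.dosages,
        bundle.replication.samples,
        bundle.replication.snps,
        bundle.regions,
        index_gene,
        partner_genes,
        k_pcs=k_pcs,
    )
    replication = replicate_pairs(pairs, rep.dosages, rep.covariates, rep.y, alpha=alpha)
    replication.to_csv(
        outdir / "replication.tsv", sep="\t", index=False, float_format=_FLOAT_FMT
    )

    driving = sorted(set(pairs["snp_b"]))
    if driving:
        rescan = cross_gene_rescan(
            [s for s in driving if s in set(rep.dosages.snp_ids)],
            rep.index_snps,
            rep.dosages,
            rep.covariates,
            rep.y,
            alpha=alpha,
        )
    else:
        rescan = pd.DataFrame(
            columns=[
                "driving_snp", "partner_snp", "beta3", "se3", "p",
                "status", "significant",
            ]
        )
    rescan.to_csv(outdir / "rescan.tsv", sep="\t", index=False, float_format=_FLOAT_FMT)

    manifest = {
        "version": __version__,
        "master_seed": int(master_seed),
        "simulation_seed": int(sim_seed),
        "permutation_seed": int(perm_seed),
        "B": int(B),
        "alpha": float(alpha),
        "k_pcs": int(k_pcs),
        "threshold": float(threshold),
        "index_gene": index_gene,
        "partner_genes": partner_genes,
        "n_candidate_genes": int(len(candidates)),
    }
    with open(outdir / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)

    return PipelineResult(
        bundle=bundle,
        scans=scans,
        gene_summary=gene_summary,
        null=null,
        threshold=threshold,
        significant_pairs=pairs,
        replication=replication,
        rescan=rescan,
    )
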