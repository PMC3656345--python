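"""Readers and writers for the pipeline's on-disk formats.

Supported inputs:

* genotype dosages as VCF v4.2+ with a per-genotype ``DS`` FORMAT field
  (falling back to hard GT calls) and an optional per-SNP imputation-quality
  INFO key (default ``R2``) — parsed with cyvcf2;
* a bit-exact dosage-TSV dialect (one row per SNP, missing = ``.``) with a
  companion SNP-metadata TSV;
* sample TSV (sample_id, status 1=case/0=control, site, optional extra
  columns), BED gene regions, and a candidate-gene TSV (gene, chrom, score).

At load time every SNP is normalized to count the dataset-minor allele:
when the alternate-allele frequency exceeds 0.5 the dosages are flipped
(d -> 2 - d), the allele labels swapped, and the flip recorded in the
returned metadata.
"""

from __future__ import annotations

import importlib.resources
from pathlib import Path

import numpy as np
import pandas as pd

from .types import DosageMatrix, GeneRegion, ValidationError, validate_sample_table

DOSAGE_DECIMALS = 4
MISSING_TOKEN = "."


def _flip_to_minor(dm: DosageMatrix, meta: pd.DataFrame) -> tuple[DosageMatrix, pd.DataFrame]:
    """Flip SNPs whose counted-allele frequency exceeds 0.5; record flips."""
    D = dm.dosages
    with np.errstate(invalid="ignore"):
        freq = np.nanmean(D, axis=0) / 2.0
    flip = np.isfinite(freq) & (freq > 0.5)
    if flip.any():
        D = D.copy()
        D[:, flip] = 2.0 - D[:, flip]
        dm = DosageMatrix(dm.sample_ids, dm.snp_ids, D)
    meta = meta.copy()
    meta["flipped"] = flip
    if flip.any():
        minor = meta["minor"].to_numpy(dtype=object)
        major = meta["major"].to_numpy(dtype=object)
        minor[flip], major[flip] = major[flip].copy(), minor[flip].copy()
        meta["minor"] = minor
        meta["major"] = major
    return dm, meta


def read_dosages(
    path: str | Path,
    format: str = "vcf",
    meta_path: str | Path | None = None,
    r2_key: str = "R2",
) -> tuple[DosageMatrix, pd.DataFrame]:
    """Load a dosage matrix plus a SNP-metadata skeleton.

    Returns ``(DosageMatrix, meta)`` where ``meta`` has columns snp_id,
    chrom, pos (1-based), minor, major, imputation_r2 and flipped.  For the
    TSV dialect ``meta_path`` defaults to the dosage path with a
    ``.snps.tsv`` suffix.
    """
    if format == "vcf":
        return _read_vcf(path, r2_key)
    if format == "tsv":
        return _read_tsv(path, meta_path)
    raise ValidationError(f"unknown dosage format {format!r}")


def _read_vcf(path: str | Path, r2_key: str) -> tuple[DosageMatrix, pd.DataFrame]:
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)  # gt_types: 0/1/2 ALT copies, 3 unknown
    sample_ids = list(vcf.samples)
    snp_ids: list[str] = []
    rows: list[np.ndarray] = []
    meta_rows: list[dict] = []
    for i, var in enumerate(vcf):
        if len(var.ALT) != 1:
            raise ValidationError(
                f"multi-allelic record at {var.CHROM}:{var.POS} (record {i + 1})"
            )
        ds = None
        try:
            ds = var.format("DS")
        except KeyError:
            ds = None
        if ds is not None:
            d = np.asarray(ds, dtype=np.float64).reshape(-1)
            d[~np.isfinite(d) | (d < -1.0)] = np.nan
        else:
            # hard genotypes: 0/1/2 copies of ALT, 3 = unknown
            gt = np.asarray(var.gt_types, dtype=np.float64)
            d = np.where(gt == 3, np.nan, np.where(gt == 2, 2.0, gt))
        finite = d[np.isfinite(d)]
        if finite.size and (finite.min() < 0 or finite.max() > 2):
            raise ValidationError(
                f"dosage outside [0,2] at {var.CHROM}:{var.POS} (record {i + 1})"
            )
        sid = var.ID if var.ID not in (None, ".") else f"{var.CHROM}:{var.POS}"
        snp_ids.append(sid)
        rows.append(d)
        r2 = var.INFO.get(r2_key)
        meta_rows.append(
            {
                "snp_id": sid,
                "chrom": var.CHROM,
                "pos": var.POS,
                "minor": var.ALT[0],
                "major": var.REF,
                "imputation_r2": float(r2) if r2 is not None else np.nan,
            }
        )
    dm = DosageMatrix(
        sample_ids,
        snp_ids,
        np.array(rows).T if rows else np.empty((len(sample_ids), 0)),
    )
    meta = pd.DataFrame(
        meta_rows,
        columns=["snp_id", "chrom", "pos", "minor", "major", "imputation_r2"],
    )
    return _flip_to_minor(dm, meta)


def _default_meta_path(path: str | Path) -> Path:
    p = Path(path)
    return p.with_suffix(p.suffix + ".snps.tsv") if p.suffix != ".tsv" else Path(
        str(p)[: -len(".tsv")] + ".snps.tsv"
    )


def _read_tsv(
    path: str | Path, meta_path: str | Path | None
) -> tuple[DosageMatrix, pd.DataFrame]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.columns[0] != "snp_id":
        raise ValidationError(f"{path}: first dosage-TSV column must be 'snp_id'")
    snp_ids = df["snp_id"].tolist()
    sample_ids = list(df.columns[1:])
    body = df.iloc[:, 1:].replace(MISSING_TOKEN, np.nan)
    try:
        values = body.to_numpy(dtype=np.float64)
    except ValueError as exc:
        raise ValidationError(f"{path}: malformed dosage value ({exc})") from None
    dm = DosageMatrix(sample_ids, snp_ids, values.T)

    mp = Path(meta_path) if meta_path is not None else _default_meta_path(path)
    if mp.exists():
        meta = pd.read_csv(mp, sep="\t")
        required = {"snp_id", "chrom", "pos", "minor", "major", "imputation_r2"}
        if not required <= set(meta.columns):
            raise ValidationError(f"{mp}: SNP metadata needs columns {sorted(required)}")
        meta = meta.set_index("snp_id").loc[snp_ids].reset_index()
    else:
        meta = pd.DataFrame(
            {
                "snp_id": snp_ids,
                "chrom": "NA",
                "pos": np.arange(1, len(snp_ids) + 1),
                "minor": "A",
                "major": "G",
                "imputation_r2": np.nan,
            }
        )
    return _flip_to_minor(dm, meta)


def write_dosages_tsv(
    path: str | Path,
    dm: DosageMatrix,
    meta: pd.DataFrame | None = None,
    meta_path: str | Path | None = None,
    decimals: int = DOSAGE_DECIMALS,
) -> None:
    """Write the dosage-TSV dialect (and companion metadata when given)."""
    with open(path, "w") as fh:
        fh.write("snp_id\t" + "\t".join(dm.sample_ids) + "\n")
        for j, sid in enumerate(dm.snp_ids):
            vals = [
                MISSING_TOKEN if not np.isfinite(v) else f"{v:.{decimals}f}"
                for v in dm.dosages[:, j]
            ]
            fh.write(sid + "\t" + "\t".join(vals) + "\n")
    if meta is not None:
        mp = Path(meta_path) if meta_path is not None else _default_meta_path(path)
        cols = ["snp_id", "chrom", "pos", "minor", "major", "imputation_r2"]
        meta[cols].to_csv(mp, sep="\t", index=False, float_format="%.6g")


def write_dosages_vcf(
    path: str | Path,
    dm: DosageMatrix,
    meta: pd.DataFrame,
    r2_key: str = "R2",
    decimals: int = DOSAGE_DECIMALS,
) -> None:
    """Serialize dosages as VCF v4.2 with a DS FORMAT field.

    The minor allele is written as ALT so that DS equals the stored
    minor-allele dosage; hard GT calls are derived by rounding for
    consumers without DS support.
    """
    meta = meta.set_index("snp_id")
    key = pd.DataFrame(
        {
            "chrom": [str(meta.loc[s, "chrom"]) for s in dm.snp_ids],
            "pos": [int(meta.loc[s, "pos"]) for s in dm.snp_ids],
            "col": np.arange(len(dm.snp_ids)),
        }
    )
    order = key.sort_values(["chrom", "pos"], kind="mergesort")["col"].tolist()
    chroms = []
    for s in dm.snp_ids:
        c = str(meta.loc[s, "chrom"])
        if c not in chroms:
            chroms.append(c)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f'##INFO=<ID={r2_key},Number=1,Type=Float,Description="Imputation r-squared">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Minor allele dosage">\n')
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(dm.sample_ids)
            + "\n"
        )
        for j in order:
            sid = dm.snp_ids[int(j)]
            row = meta.loc[sid]
            r2 = row["imputation_r2"]
            info = f"{r2_key}={float(r2):.4f}" if np.isfinite(float(r2)) else "."
            fields = [
                str(row["chrom"]),
                str(int(row["pos"])),
                sid,
                str(row["major"]),
                str(row["minor"]),
                ".",
                "PASS",
                info,
                "GT:DS",
            ]
            for v in dm.dosages[:, int(j)]:
                if not np.isfinite(v):
                    fields.append("./.:.")
                else:
                    g = int(np.clip(np.floor(v + 0.5), 0, 2))
                    gt = ["0/0", "0/1", "1/1"][g]
                    fields.append(f"{gt}:{v:.{decimals}f}")
            fh.write("\t".join(fields) + "\n")


def read_samples_tsv(path: str | Path) -> pd.DataFrame:
    samples = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "site": str})
    return validate_sample_table(samples)


def write_samples_tsv(path: str | Path, samples: pd.DataFrame) -> None:
    validate_sample_table(samples).to_csv(
        path, sep="\t", index=False, float_format="%.6f"
    )


def read_gene_regions_bed(path: str | Path, pad: int = 10_000) -> list[GeneRegion]:
    """BED4 (chrom, start, end, gene) -> padded gene regions."""
    regions = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValidationError(f"{path}:{ln}: BED needs 4 columns")
            regions.append(
                GeneRegion(
                    gene=parts[3],
                    chrom=parts[0],
                    start=int(parts[1]),
                    end=int(parts[2]),
                    pad=pad,
                )
            )
    return regions


def write_gene_regions_bed(path: str | Path, regions: list[GeneRegion]) -> None:
    with open(path, "w") as fh:
        for r in regions:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.gene}\n")


def read_candidate_genes(path: str | Path | None = None) -> pd.DataFrame:
    """Candidate-partner-gene table (gene, chrom, score).

    With no path, loads the packaged STRING-derived ANK3 interactor table.
    """
    if path is None:
        ref = importlib.resources.files("episcan.data") / "string_candidates.tsv"
        with importlib.resources.as_file(ref) as p:
            table = pd.read_csv(p, sep="\t", comment="#")
    else:
        table = pd.read_csv(path, sep="\t", comment="#")
    required = {"gene", "chrom", "score"}
    if not required <= set(table.columns):
        raise ValidationError(f"candidate table needs columns {sorted(required)}")
    return table
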