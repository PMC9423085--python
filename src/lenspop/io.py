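"""Readers and writers for the pipeline's standard formats.

VCF (v4.2, GT-only) is read through cyvcf2/htslib; the writer emits minimal
GT-only records for round-tripping synthetic datasets.  Depth matrices,
population maps and interval sets travel as TSV/BED.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeMatrix


class VcfParseError(ValueError):
    """Malformed VCF input, with the first offending line when locatable."""


def _locate_bad_line(path) -> str:
    """Best-effort scan for the first structurally broken VCF data line."""
    n_cols = None
    with open(path, "rt", errors="replace") as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("##"):
                continue
            fields = line.rstrip("\n").split("\t")
            if line.startswith("#CHROM"):
                n_cols = len(fields)
                continue
            if n_cols is None:
                return f"line {lineno}: data before #CHROM header"
            if len(fields) != n_cols:
                return f"line {lineno}: {len(fields)} columns, expected {n_cols}"
            try:
                int(fields[1])
            except ValueError:
                return f"line {lineno}: non-integer POS {fields[1]!r}"
    return "location unknown"


def read_vcf(path) -> GenotypeMatrix:
    """Read a VCF with GT fields into a :class:`GenotypeMatrix`.

    Multiallelic records are retained with ``biallelic=False``; any ALT
    dosage >= 1 counts toward the alt code there.  Missing GT becomes -1.
    Sample order follows the VCF header.
    """
    from cyvcf2 import VCF

    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    try:
        vcf = VCF(path, gts012=True)
    except Exception as exc:  # htslib raises bare exceptions on bad input
        raise VcfParseError(f"cannot parse VCF {path} ({_locate_bad_line(path)})") from exc
    samples = list(vcf.samples)
    chroms: list[str] = []
    poss: list[int] = []
    refs: list[str] = []
    alts: list[str] = []
    quals: list[float] = []
    depths: list[float] = []
    bial: list[bool] = []
    geno_cols: list[np.ndarray] = []
    try:
        for var in vcf:
            chroms.append(var.CHROM)
            poss.append(var.POS)
            refs.append(var.REF)
            alts.append(",".join(var.ALT) if var.ALT else ".")
            quals.append(var.QUAL if var.QUAL is not None else np.nan)
            dp = var.INFO.get("DP")
            depths.append(float(dp) / len(samples) if dp is not None else np.nan)
            bial.append(len(var.ALT) == 1)
            # gts012: 0/1/2 = alt dosage, 3 = unknown
            g = np.asarray(var.gt_types, dtype=np.int8)
            g[g == 3] = MISSING
            geno_cols.append(g)
    except Exception as exc:
        raise VcfParseError(f"cannot parse VCF {path} ({_locate_bad_line(path)})") from exc
    sites = pd.DataFrame(
        {
            "chrom": chroms,
            "pos": np.asarray(poss, dtype=np.int64),
            "ref": refs,
            "alt": alts,
            "qual": np.asarray(quals, dtype=float),
            "mean_depth": np.asarray(depths, dtype=float),
            "biallelic": np.asarray(bial, dtype=bool),
        }
    )
    geno = (
        np.stack(geno_cols, axis=1)
        if geno_cols
        else np.empty((len(samples), 0), dtype=np.int8)
    )
    return GenotypeMatrix(samples=samples, sites=sites, geno=geno)


_GT_CODE = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(gm: GenotypeMatrix, path, force: bool = False) -> None:
    """Write a GT-only VCFv4.2 file (positions 1-based, per the standard)."""
    path = Path(path)
    if path.exists() and not force:
        raise FileExistsError(f"{path} exists (pass force=True to overwrite)")
    with open(path, "wt") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=DP,Number=1,Type=Integer,Description="Total depth">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in dict.fromkeys(gm.sites["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gm.samples)
            + "\n"
        )
        quals = gm.sites["qual"].to_numpy()
        depths = gm.sites["mean_depth"].to_numpy()
        for j in range(gm.n_sites):
            row = gm.sites.iloc[j]
            qual = "." if np.isnan(quals[j]) else f"{quals[j]:g}"
            if np.isnan(depths[j]):
                info = "."
            else:
                info = f"DP={int(round(depths[j] * gm.n_samples))}"
            gts = "\t".join(_GT_CODE[int(g)] for g in gm.geno[:, j])
            fh.write(
                f"{row['chrom']}\t{row['pos']}\t.\t{row['ref']}\t{row['alt']}\t"
                f"{qual}\tPASS\t{info}\tGT\t{gts}\n"
            )


# -- depth matrix TSV --------------------------------------------------------

def write_depth_tsv(targets: pd.DataFrame, samples: list[str], depth: np.ndarray,
                    path, force: bool = False) -> None:
    """Depth TSV: rows = targets (chrom/start/end), columns = samples."""
    path = Path(path)
    if path.exists() and not force:
        raise FileExistsError(f"{path} exists (pass force=True to overwrite)")
    df = targets[["chrom", "start", "end"]].copy()
    for i, s in enumerate(samples):
        df[s] = depth[i]
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_depth_tsv(path):
    """Read a depth TSV back into (targets DataFrame, samples, depth array)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    targets = df[["chrom", "start", "end"]].copy()
    samples = [c for c in df.columns if c not in ("chrom", "start", "end")]
    depth = df[samples].to_numpy(dtype=float).T
    return targets, samples, depth


# -- BED ---------------------------------------------------------------------

def read_bed(path, names: list[str] | None = None) -> pd.DataFrame:
    """Read a headerless BED3+ file; extra columns named by ``names``."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype={0: str})
    cols = ["chrom", "start", "end"] + (names or [])
    extra = df.shape[1] - len(cols)
    if extra > 0:
        cols += [f"col{i}" for i in range(len(cols), df.shape[1])]
    df.columns = cols[: df.shape[1]]
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    return df


def write_bed(df: pd.DataFrame, path, columns: list[str] | None = None,
              force: bool = False) -> None:
    path = Path(path)
    if path.exists() and not force:
        raise FileExistsError(f"{path} exists (pass force=True to overwrite)")
    cols = columns or list(df.columns)
    df[cols].to_csv(path, sep="\t", header=False, index=False)
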