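"""Readers and writers for study tables, results and configuration.

The native input is a tab-delimited study table with one row per sample:
mandatory columns ``sample``, ``D``, ``T`` (both binary) and one column per
SNP holding genotype codes 0/1/2 (count of the allele coded 'a') or ``NA``
for missing.  A convenience reader extracts the same codes from the GT field
of an uncompressed, diploid, biallelic VCF.
"""

from __future__ import annotations

import hashlib
import logging
import warnings
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exact import GenotypeCounts
from .likelihood import BlockCounts, TestResult

__all__ = [
    "read_study_table",
    "blocks_from_table",
    "write_results",
    "read_results",
    "read_vcf_genotypes",
    "log_run_context",
]

logger = logging.getLogger(__name__)

_META_COLUMNS = ("sample", "D", "T")
RESULT_COLUMNS = ("snp", "method", "statistic", "p_value", "converged", "flags")


def read_study_table(path: str | Path) -> pd.DataFrame:
    """Validated per-sample study table; every non-meta column is a SNP."""
    tbl = pd.read_csv(path, sep="\t", dtype={"sample": str}, na_values=["NA", ""])
    missing = [c for c in _META_COLUMNS if c not in tbl.columns]
    if missing:
        raise ValueError(f"study table lacks mandatory column(s) {missing}")
    if len(tbl) == 0:
        raise ValueError("no samples in study table")
    for col in ("D", "T"):
        bad = tbl.index[~tbl[col].isin([0, 1])]
        if len(bad):
            raise ValueError(
                f"non-binary {col} value at row {int(bad[0]) + 2} of {path}"
            )
    snps = [c for c in tbl.columns if c not in _META_COLUMNS]
    if not snps:
        raise ValueError("study table has no SNP columns")
    for col in snps:
        vals = tbl[col].dropna()
        bad = vals.index[~vals.isin([0, 1, 2])]
        if len(bad):
            raise ValueError(
                f"unknown genotype code {tbl[col][bad[0]]!r} in column {col} "
                f"at row {int(bad[0]) + 2}"
            )
        n_miss = int(tbl[col].isna().sum())
        if n_miss:
            logger.info("column %s: %d missing genotype(s) excluded", col, n_miss)
    return tbl


def blocks_from_table(tbl: pd.DataFrame, snp: str) -> BlockCounts:
    """Four-stratum genotype counts for one SNP (missing genotypes dropped)."""
    if snp not in tbl.columns:
        raise ValueError(f"SNP column {snp!r} not in table")
    sub = tbl[["T", "D", snp]].dropna(subset=[snp])
    g = sub[snp].to_numpy(dtype=np.int64)
    t = sub["T"].to_numpy(dtype=np.int64)
    d = sub["D"].to_numpy(dtype=np.int64)
    arr = np.zeros((4, 3), dtype=np.int64)
    for b, (ti, dj) in enumerate(((0, 0), (1, 0), (0, 1), (1, 1))):
        arr[b] = np.bincount(g[(t == ti) & (d == dj)], minlength=3)
    return BlockCounts.from_array(arr)


def write_results(
    results: Sequence[tuple[str, TestResult]], path: str | Path
) -> None:
    """Write test results as TSV with a fixed column order.

    Floats are serialized with full precision (well above the six decimals
    used in reporting) so a read back reproduces them exactly.
    """
    if not results:
        raise ValueError("no results to write")
    rows = []
    for snp, r in results:
        rows.append(
            {
                "snp": snp,
                "method": r.method,
                "statistic": "" if r.statistic is None else repr(float(r.statistic)),
                "p_value": "" if r.pvalue is None else repr(float(r.pvalue)),
                "converged": int(r.converged),
                "flags": ";".join(r.flags),
            }
        )
    pd.DataFrame(rows, columns=list(RESULT_COLUMNS)).to_csv(
        path, sep="\t", index=False
    )


def read_results(path: str | Path) -> pd.DataFrame:
    """Read a results TSV written by :func:`write_results`."""
    return pd.read_csv(
        path, sep="\t", dtype={"snp": str, "method": str, "flags": str}
    )


def read_vcf_genotypes(path: str | Path) -> pd.DataFrame:
    """Extract 0/1/2 genotype codes from the GT field of a plain-text VCF.

    Only diploid biallelic records are used; multiallelic records and
    half-calls are skipped with a warning.  Returns samples x SNPs codes
    (NaN for missing), with SNP ids from the ID column (or chrom:pos).
    """
    samples: list[str] = []
    snp_ids: list[str] = []
    rows: list[np.ndarray] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("##") or not line:
                continue
            fields = line.split("\t")
            if line.startswith("#CHROM"):
                samples = fields[9:]
                continue
            if not samples:
                raise ValueError("VCF has no #CHROM header line")
            chrom, pos, vid, _ref, alt = fields[:5]
            if "," in alt:
                warnings.warn(f"skipping multiallelic record {chrom}:{pos}")
                continue
            fmt = fields[8].split(":")
            try:
                gt_idx = fmt.index("GT")
            except ValueError:
                warnings.warn(f"record {chrom}:{pos} has no GT field; skipped")
                continue
            codes = np.full(len(samples), np.nan)
            for s, cell in enumerate(fields[9:]):
                gt = cell.split(":")[gt_idx].replace("|", "/")
                alleles = gt.split("/")
                if len(alleles) != 2 or "." in alleles:
                    if gt not in ("./.",):
                        warnings.warn(
                            f"half-call or non-diploid GT {gt!r} at {chrom}:{pos}"
                        )
                    continue
                codes[s] = sum(int(a) for a in alleles)
            snp_ids.append(vid if vid not in (".", "") else f"{chrom}:{pos}")
            rows.append(codes)
    if not rows:
        raise ValueError("no usable records in VCF")
    return pd.DataFrame(np.column_stack(rows), index=samples, columns=snp_ids)


def _checksum(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def log_run_context(
    seed: int | None,
    config: dict | None = None,
    inputs: Iterable[str | Path] = (),
) -> None:
    """Log versions, seed, config hash and input checksums for provenance."""
    import hwematch

    logger.info(
        "hwematch %s | numpy %s | pandas %s",
        hwematch.__version__,
        np.__version__,
        pd.__version__,
    )
    logger.info("seed=%s", seed)
    if config is not None:
        digest = hashlib.sha256(repr(sorted(config.items())).encode()).hexdigest()[:16]
        logger.info("config hash=%s", digest)
    for p in inputs:
        logger.info("input %s sha256=%s", p, _checksum(p))
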