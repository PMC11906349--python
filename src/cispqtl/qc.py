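"""Per-genotype and per-variant sequencing-quality filters.

A genotype call is set to missing when sum(LAD) < 8 (local allele depth)
or GQ < 10; both thresholds are strict.  Variants with missingness > 10%
after call filtering are dropped.  MAC/MAF are recomputed on the filtered
matrix, and missing dosages are mean-imputed only at regression time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class QCResult:
    dosages: np.ndarray  # (n_samples, n_variants) float, NaN = missing
    variants: pd.DataFrame  # with refreshed mac/maf/missingness
    n_calls_masked: int
    n_variants_dropped: int


def read_vcf(path: str) -> tuple[pd.DataFrame, np.ndarray, np.ndarray | None,
                                 np.ndarray | None, list[str]]:
    """Read a (plain-text) VCF via cyvcf2.

    Returns ``(variants, dosages, lad_sum, gq, sample_ids)``; dosages are
    float with NaN for missing calls, half-calls and phased genotypes are
    unphased on read.  ``lad_sum``/``gq`` are None when the FORMAT lacks
    AD/GQ.
    """
    from cyvcf2 import VCF

    vcf = VCF(path, gts012=True)
    samples = list(vcf.samples)
    rows = []
    dos_cols, lad_cols, gq_cols = [], [], []
    has_ad = has_gq = True
    for rec in vcf:
        alt = rec.ALT[0] if rec.ALT else "."
        rows.append(
            {
                "vid": f"{rec.CHROM}:{rec.POS}:{rec.REF}:{alt}",
                "chrom": rec.CHROM,
                "pos": rec.POS,
                "ref": rec.REF,
                "alt": alt,
            }
        )
        gt = rec.gt_types.astype(float)  # 0/1/2, 3 = unknown
        gt[gt == 3] = np.nan
        dos_cols.append(gt)
        if has_ad:
            try:
                ad = rec.format("AD")
                lad_cols.append(np.where(ad < 0, 0, ad).sum(axis=1))
            except (TypeError, KeyError):
                has_ad = False
        if has_gq:
            try:
                gq = rec.format("GQ")
                gq_cols.append(np.asarray(gq).reshape(-1))
            except (TypeError, KeyError):
                has_gq = False
    variants = pd.DataFrame(rows)
    dosages = np.column_stack(dos_cols) if dos_cols else np.empty((len(samples), 0))
    lad = np.column_stack(lad_cols) if has_ad and lad_cols else None
    gq = np.column_stack(gq_cols) if has_gq and gq_cols else None
    return variants, dosages, lad, gq, samples


def apply_call_filters(
    dosages: np.ndarray,
    lad_sum: np.ndarray | None,
    gq: np.ndarray | None,
    min_depth: int = 8,
    min_gq: int = 10,
) -> tuple[np.ndarray, int]:
    """Mask calls with sum(LAD) < min_depth or GQ < min_gq to missing.

    Returns the masked dosage matrix (float, NaN missing) and the number of
    newly masked calls.  Malformed (negative) FORMAT values trigger a
    warning and mask the call.
    """
    out = np.asarray(dosages, dtype=float).copy()
    bad = np.zeros(out.shape, dtype=bool)
    if lad_sum is not None:
        lad_sum = np.asarray(lad_sum, dtype=float)
        if (lad_sum < 0).any():
            warnings.warn("negative LAD values; affected calls set to missing")
            bad |= lad_sum < 0
        bad |= lad_sum < min_depth
    if gq is not None:
        gq = np.asarray(gq, dtype=float)
        if (gq < 0).any():
            warnings.warn("negative GQ values; affected calls set to missing")
            bad |= gq < 0
        bad |= gq < min_gq
    n_new = int((bad & ~np.isnan(out)).sum())
    out[bad] = np.nan
    return out, n_new


def variant_frequencies(dosages: np.ndarray) -> pd.DataFrame:
    """Per-variant MAC / MAF / missingness from a NaN-masked dosage matrix."""
    n = dosages.shape[0]
    miss = np.isnan(dosages)
    n_called = (~miss).sum(axis=0)
    alt = np.nansum(dosages, axis=0).astype(np.int64)
    total = 2 * n_called
    with np.errstate(invalid="ignore", divide="ignore"):
        mac = np.minimum(alt, total - alt)
        maf = np.where(total > 0, mac / np.maximum(total, 1), 0.0)
    return pd.DataFrame(
        {
            "mac": mac,
            "maf": maf,
            "missingness": miss.sum(axis=0) / n,
            "n_called": n_called,
        }
    )


def filter_missingness(
    dosages: np.ndarray,
    variants: pd.DataFrame,
    max_missing: float = 0.10,
) -> QCResult:
    """Drop variants with missingness strictly above ``max_missing``."""
    freq = variant_frequencies(dosages)
    keep = freq["missingness"].to_numpy() <= max_missing
    out_variants = variants.reset_index(drop=True).copy()
    for col in freq.columns:
        out_variants[col] = freq[col].to_numpy()
    out_variants = out_variants.loc[keep].reset_index(drop=True)
    return QCResult(
        dosages=dosages[:, keep],
        variants=out_variants,
        n_calls_masked=int(np.isnan(dosages).sum()),
        n_variants_dropped=int((~keep).sum()),
    )


def run_genotype_qc(
    dosages: np.ndarray,
    variants: pd.DataFrame,
    lad_sum: np.ndarray | None = None,
    gq: np.ndarray | None = None,
    min_depth: int = 8,
    min_gq: int = 10,
    max_missing: float = 0.10,
) -> QCResult:
    """Call-level filters followed by the variant missingness filter."""
    masked, _ = apply_call_filters(dosages, lad_sum, gq, min_depth, min_gq)
    return filter_missingness(masked, variants, max_missing)


def mean_impute(dosages: np.ndarray) -> np.ndarray:
    """Replace missing dosages by the per-variant mean (for regression)."""
    out = np.asarray(dosages, dtype=float).copy()
    col_mean = np.nanmean(np.where(np.isnan(out), np.nan, out), axis=0)
    col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
    idx = np.where(np.isnan(out))
    out[idx] = col_mean[idx[1]]
    return out
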