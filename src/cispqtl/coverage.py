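"""Coverage-based locus QC and problematic-region enrichment.

A base "passes" when strictly more than 90% of assessed samples have depth
strictly above 8 reads; a protein passes coverage QC when strictly more
than 99.5% of bases pass over both the UTR-to-UTR gene span and the full
cis-window.  A second filter drops proteins whose largest
marginal-vs-joint effect discrepancy lies beyond the empirical 90th
percentile across proteins (an indicator of an uncalled causal variant).
Excluded proteins are then tested for enrichment of overlaps with
problematic-region tracks (segmental duplications etc.) in a logistic
model adjusting for cis-window length.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class CoverageProfile:
    chrom: str
    start: int  # 0-based half-open interval the profile covers
    end: int
    pass_per_base: np.ndarray  # count of samples with depth > threshold
    n_samples_assessed: int
    sample_frac: float = 0.90
    depth_threshold: int = 8

    def __post_init__(self) -> None:
        if len(self.pass_per_base) != self.end - self.start:
            raise ValueError("pass-count track length mismatch")
        if (self.pass_per_base > self.n_samples_assessed).any():
            raise ValueError("per-base count exceeds samples assessed")

    @property
    def fraction_bases_passing(self) -> float:
        """Share of bases where > sample_frac of samples exceed the depth."""
        passing = self.pass_per_base > self.sample_frac * self.n_samples_assessed
        return float(passing.mean())


@dataclass
class ProteinQCVerdict:
    protein_id: str
    gene_coverage_frac: float
    region_coverage_frac: float
    passes_coverage: bool
    max_abs_beta_discrepancy: float = np.nan
    passes_discrepancy: bool | None = None


def compute_coverage(
    pass_counts: np.ndarray,
    track_start: int,
    interval: tuple[str, int, int],
    n_samples_assessed: int,
    sample_frac: float = 0.90,
    depth_threshold: int = 8,
) -> CoverageProfile:
    """Coverage profile of ``interval`` from a per-base pass-count track.

    ``pass_counts[i]`` is the number of samples with depth strictly above
    ``depth_threshold`` at genomic base ``track_start + i`` (0-based).
    """
    chrom, start, end = interval
    lo, hi = start - track_start, end - track_start
    if lo < 0 or hi > len(pass_counts) or hi <= lo:
        raise ValueError("interval outside depth track")
    return CoverageProfile(
        chrom, start, end, np.asarray(pass_counts[lo:hi]),
        n_samples_assessed, sample_frac, depth_threshold,
    )


def coverage_filter(
    protein_id: str,
    gene_profile: CoverageProfile,
    region_profile: CoverageProfile,
    threshold: float = 0.995,
) -> ProteinQCVerdict:
    """Pass iff BOTH gene and cis-region base fractions strictly exceed
    the threshold (99.5% by default)."""
    gf = gene_profile.fraction_bases_passing
    rf = region_profile.fraction_bases_passing
    return ProteinQCVerdict(
        protein_id, gf, rf, passes_coverage=(gf > threshold and rf > threshold)
    )


def discrepancy_filter(
    discrepancies: pd.Series | dict[str, float],
    percentile: float = 90.0,
) -> set[str]:
    """Proteins whose max |beta_marginal - beta_joint| lies strictly beyond
    the empirical percentile across proteins.

    Uses the linear-interpolation quantile definition; identical
    discrepancies therefore exclude nothing.  Needs at least 2 proteins.
    """
    if isinstance(discrepancies, dict):
        discrepancies = pd.Series(discrepancies)
    if len(discrepancies) < 2:
        raise ValueError("percentile undefined for fewer than 2 proteins")
    cut = float(np.quantile(discrepancies.to_numpy(dtype=float),
                            percentile / 100.0))
    return set(discrepancies.index[discrepancies > cut])


def overlap_counts(
    intervals: pd.DataFrame,
    window: tuple[str, int, int],
    gene_span: tuple[int, int] | None = None,
) -> dict[str, int]:
    """Per-type count of problematic regions overlapping (>= 1 bp) the
    cis-window or the gene span."""
    chrom, w0, w1 = window
    df = intervals[intervals["chrom"] == chrom]
    out: dict[str, int] = {}
    for _, row in df.iterrows():
        s, e = int(row["start"]), int(row["end"])
        hit = s < w1 and w0 < e
        if not hit and gene_span is not None:
            hit = s < gene_span[1] and gene_span[0] < e
        if hit:
            out[row["type"]] = out.get(row["type"], 0) + 1
    return out


def problematic_region_enrichment(
    excluded: pd.Series,
    counts: pd.DataFrame,
    window_length: pd.Series,
) -> pd.DataFrame:
    """Logistic enrichment of problematic-region overlap in excluded loci.

    ``excluded``: boolean per protein; ``counts``: per-protein overlap count
    per region type (one column per type); ``window_length``: total
    cis-window length per protein (adjusted for, since it scales with gene
    size).  Returns per-type OR with 95% CI and P.  Perfect separation is
    flagged and refit with an L2-penalised likelihood.
    """
    import statsmodels.api as sm

    y = excluded.astype(int)
    if len(y) < 20:
        raise ValueError("need at least 20 proteins for the logistic model")
    if y.nunique() < 2:
        raise ValueError("both excluded and retained proteins are required")
    rows = []
    wl_std = float(window_length.std())
    has_wl = wl_std > 1e-8 * max(abs(float(window_length.mean())), 1.0)
    wl = ((window_length - window_length.mean()) / wl_std) if has_wl else None
    for rtype in counts.columns:
        cols = {"count": counts[rtype].astype(float)}
        if has_wl:  # constant window lengths carry no information
            cols["window_len"] = wl
        X = sm.add_constant(pd.DataFrame(cols))
        flagged = False
        try:
            fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
            if not np.isfinite(fit.bse["count"]) or fit.bse["count"] > 50:
                raise np.linalg.LinAlgError
            beta, se = fit.params["count"], fit.bse["count"]
            pval = fit.pvalues["count"]
        except Exception:
            flagged = True
            fit = sm.Logit(y, X).fit_regularized(disp=0, alpha=1.0, L1_wt=0.0)
            beta = fit.params["count"]
            se, pval = np.nan, np.nan
        rows.append(
            {
                "region_type": rtype,
                "odds_ratio": float(np.exp(beta)),
                "ci_low": float(np.exp(beta - 1.96 * se)) if np.isfinite(se) else np.nan,
                "ci_high": float(np.exp(beta + 1.96 * se)) if np.isfinite(se) else np.nan,
                "p": float(pval) if np.isfinite(pval) else np.nan,
                "separation_flagged": flagged,
            }
        )
    return pd.DataFrame(rows)
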