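"""Consequence enrichment, bootstrap regulatory enrichment and empirical
significance thresholds.

* Fisher's exact two-sided test compares lead-variant consequence
  proportions with the tested background (Bonferroni at 0.05 / number of
  categories).
* Bootstrap enrichment samples, in each of n_sim simulations, as many
  elements from the tested pool as there are independent signals, and
  compares the stratum overlap distribution with the observed overlap; the
  empirical P uses the plus-one rule so it is never zero.
* Study-wide thresholds are the minimum P observed when the full scan is
  run on 20 independent standard-normal (null) traits.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class FisherResult:
    category: str
    a: int  # leads in category
    b: int  # leads not in category
    c: int  # background in category (non-lead)
    d: int  # background not in category
    odds_ratio: float
    p: float
    significant: bool
    haldane_corrected: bool = False


def fisher_enrichment(
    lead_counts: dict[str, int],
    background_counts: dict[str, int],
    n_categories: int | None = None,
) -> list[FisherResult]:
    """Two-sided Fisher's exact enrichment per consequence category.

    ``background_counts`` must contain the lead universe (counts include
    leads); the 2x2 table per category compares leads vs non-lead
    background in/out of the category.  Zero margins get a Haldane
    (+0.5) corrected OR and a flag.
    """
    n_lead = sum(lead_counts.values())
    n_bg = sum(background_counts.values())
    cats = sorted(background_counts)
    n_categories = n_categories or len(cats)
    alpha = 0.05 / n_categories
    out = []
    for cat in cats:
        a = int(lead_counts.get(cat, 0))
        bg_in = int(background_counts[cat])
        if a > bg_in:
            raise ValueError(f"lead count exceeds background in {cat!r}")
        b = n_lead - a
        c = bg_in - a
        d = (n_bg - bg_in) - b
        if min(a, b, c, d) < 0:
            raise ValueError(f"inconsistent counts for {cat!r}")
        orr, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
        haldane = False
        if not np.isfinite(orr) or (a * d == 0 or b * c == 0):
            orr = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
            haldane = True
        out.append(
            FisherResult(cat, a, b, c, d, float(orr), float(p), p < alpha,
                         haldane)
        )
    return out


@dataclass
class EnrichmentResult:
    stratum: str
    observed_overlap: int
    null_overlaps: np.ndarray
    empirical_p: float

    @property
    def null_mean(self) -> float:
        return float(self.null_overlaps.mean())

    @property
    def null_sd(self) -> float:
        return float(self.null_overlaps.std())


def bootstrap_region_enrichment(
    signal_is_overlapping: dict[str, np.ndarray],
    signal_idx: np.ndarray,
    pool_size: int,
    n_sim: int = 10_000,
    seed: int = 0,
    with_replacement: bool = False,
) -> list[EnrichmentResult]:
    """Empirical enrichment of signals in regulatory strata.

    ``signal_is_overlapping`` maps stratum name -> boolean vector over the
    candidate pool (True where pool element overlaps a region of that
    stratum; for aggregates this is any-overlap).  ``signal_idx`` indexes
    the observed independent signals within the pool.  Each simulation
    draws ``len(signal_idx)`` pool elements (without replacement by
    default) and counts stratum overlaps; the empirical P is
    ``(1 + #{sims >= observed}) / (1 + n_sim)``.
    """
    signal_idx = np.asarray(signal_idx, int)
    k = len(signal_idx)
    if k == 0 or pool_size == 0:
        raise ValueError("empty signal set or candidate pool")
    if k > pool_size and not with_replacement:
        raise ValueError("more signals than pool elements")
    rng = np.random.default_rng(seed)
    draws = np.empty((n_sim, k), dtype=np.int64)
    for s in range(n_sim):
        draws[s] = rng.choice(pool_size, size=k, replace=with_replacement)
    out = []
    for stratum, flags in signal_is_overlapping.items():
        flags = np.asarray(flags, bool)
        if len(flags) != pool_size:
            raise ValueError(f"overlap vector length mismatch for {stratum!r}")
        observed = int(flags[signal_idx].sum())
        null = flags[draws].sum(axis=1)
        p = (1 + int((null >= observed).sum())) / (1 + n_sim)
        out.append(EnrichmentResult(stratum, observed, null, p))
    return out


def region_overlap_flags(
    positions_or_intervals: pd.DataFrame,
    regions: pd.DataFrame,
    by: tuple[str, ...] = ("feature", "tissue_group"),
    active_only: bool = True,
) -> dict[str, np.ndarray]:
    """Boolean any-overlap vectors per regulatory stratum.

    ``positions_or_intervals`` needs ``start``/``end`` columns (a single
    position is a length-1 interval).  ``regions`` is a BED-like frame with
    the stratum columns in ``by`` and an optional ``active`` flag; only
    active regions contribute.
    """
    reg = regions
    if active_only and "active" in reg.columns:
        reg = reg[reg["active"].astype(bool)]
    s = positions_or_intervals["start"].to_numpy()
    e = positions_or_intervals["end"].to_numpy()
    out: dict[str, np.ndarray] = {}
    groups = [("all", reg)] + [
        ("|".join(map(str, key if isinstance(key, tuple) else (key,))), g)
        for key, g in reg.groupby(list(by))
    ]
    for name, g in groups:
        rs = g["start"].to_numpy()
        re_ = g["end"].to_numpy()
        flags = np.zeros(len(s), dtype=bool)
        for a, b in zip(rs, re_):
            flags |= (s < b) & (a < e)
        out[name] = flags
    return out


# ---------------------------------------------------------------------------
# empirical thresholds


def empirical_thresholds(
    scan_min_p: Callable[[np.ndarray], tuple[float, float]],
    n_samples: int,
    n_traits: int = 20,
    seed: int = 0,
) -> tuple[float, float]:
    """Minimum-P thresholds from scans of random normal traits.

    ``scan_min_p(y)`` must run the single-variant and aggregate scans on a
    phenotype vector and return ``(min_single_p, min_aggregate_p)``; this
    function feeds it ``n_traits`` independent standard-normal traits and
    returns the class-wise minima across traits (the two thresholds are
    treated independently).
    """
    if n_traits < 1:
        raise ValueError("n_traits must be at least 1")
    rng = np.random.default_rng(seed)
    min_single, min_agg = 1.0, 1.0
    for _ in range(n_traits):
        y = rng.standard_normal(n_samples)
        ps, pa = scan_min_p(y)
        min_single = min(min_single, float(ps))
        min_agg = min(min_agg, float(pa))
    return min_single, min_agg
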