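"""Regulatory-region enrichment of discovered signals and the empirical
significance thresholds.

Part 1: bootstrap enrichment (10,000 simulations) of planted regulatory
signals against the tested rare-noncoding pool, per feature/tissue stratum.
Part 2: the 20-null-trait minimum-P procedure defining the study-wide
single-variant and aggregate thresholds on this cohort.  Writes
results/regulatory_enrichment.tsv and results/empirical_thresholds.tsv.
"""

import os

import numpy as np
import pandas as pd

from cispqtl import enrich, pipeline, simulate

HERE = os.path.dirname(__file__)
RESULTS = os.path.join(HERE, "..", "results")


def regulatory_enrichment(seed: int = 11) -> None:
    cfg = simulate.LocusConfig(
        n_samples=500, window_length=200_000, n_variants=3_000,
        gene_span=20_000, regulatory_region_density=8.0, seed=seed,
    )
    loc = simulate.simulate_locus(cfg)
    rng = np.random.default_rng(seed)
    v = loc.variants
    pool = np.flatnonzero((v["maf"] < 0.01).to_numpy())
    pool_df = pd.DataFrame({"start": v["pos"].to_numpy()[pool] - 1,
                            "end": v["pos"].to_numpy()[pool]})
    flags = enrich.region_overlap_flags(pool_df, loc.regulatory)
    # plant signals preferentially inside regulatory regions (2/3 inside)
    inside = np.flatnonzero(flags["all"])
    outside = np.flatnonzero(~flags["all"])
    sig = np.concatenate([rng.choice(inside, 40, replace=False),
                          rng.choice(outside, 20, replace=False)])
    res = enrich.bootstrap_region_enrichment(flags, sig, len(pool),
                                             n_sim=10_000, seed=seed)
    out = pd.DataFrame([{
        "stratum": r.stratum, "observed": r.observed_overlap,
        "null_mean": r.null_mean, "null_sd": r.null_sd,
        "empirical_p": r.empirical_p,
    } for r in res]).sort_values("empirical_p")
    out.to_csv(os.path.join(RESULTS, "regulatory_enrichment.tsv"), sep="\t",
               index=False, float_format="%.6g")
    print("top enrichment strata:")
    print(out.head(8).to_string(index=False))


def thresholds(seed: int = 12) -> None:
    cfg = simulate.LocusConfig(
        n_samples=3_000, window_length=40_000, n_variants=400,
        gene_span=10_000, seed=seed,
    )
    loc = simulate.simulate_locus(cfg)
    rng = np.random.default_rng(seed)
    cov = simulate.simulate_covariates(cfg.n_samples, loc.sample_ids, rng)
    fx = simulate.Fixture(loc, covariates=cov)
    scan = pipeline.scan_min_p_factory(fx)
    s, a = enrich.empirical_thresholds(scan, cfg.n_samples, n_traits=20,
                                       seed=seed)
    out = pd.DataFrame([
        {"class": "single_variant", "min_p_threshold": s},
        {"class": "aggregate", "min_p_threshold": a},
    ])
    out.to_csv(os.path.join(RESULTS, "empirical_thresholds.tsv"), sep="\t",
               index=False, float_format="%.6g")
    print(out.to_string(index=False))
    print("Study-scale analogues (46k samples, 128M tests) give "
          "2.95e-10 / 8.71e-9; this cohort's totals are far smaller, so "
          "its minima are correspondingly larger.")


def main() -> None:
    os.makedirs(RESULTS, exist_ok=True)
    regulatory_enrichment()
    thresholds()


if __name__ == "__main__":
    main()
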