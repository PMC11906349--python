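"""End-to-end orchestration of the cis-pQTL discovery procedure.

Stage order: genotype QC -> annotation & masks -> single-variant scan ->
conditional-joint selection -> coverage / discrepancy QC -> aggregate tests
under step-(1) conditioning -> forward stepwise aggregate independence ->
regulatory enrichment.  Every output table carries the configuration hash
in a leading comment line, and an identical config + inputs + seed yields
byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from cispqtl import aggregate as agg
from cispqtl import annotate, coverage, enrich, qc, simulate, single


@dataclass
class RunConfig:
    single_p: float = 2.95e-10
    aggregate_p: float = 8.71e-9
    min_mac: int = 5
    rare_max_maf: float = 0.001
    conditioning_maf: float = 0.001
    max_missing: float = 0.10
    min_depth: int = 8
    min_gq: int = 10
    coverage_base_frac: float = 0.995
    coverage_sample_frac: float = 0.90
    coverage_depth: int = 8
    transcript_mode: str = "union"
    proximal_flank: int = 5_000
    enrichment_n_sim: int = 1_000
    seed: int = 0
    stages: tuple[str, ...] = (
        "qc", "annotate", "single", "cojo", "coverage", "aggregate",
        "stepwise", "enrich",
    )

    def __post_init__(self) -> None:
        if not (0 < self.single_p < 1 and 0 < self.aggregate_p < 1):
            raise ValueError("significance thresholds must lie in (0, 1)")
        if not 0 < self.rare_max_maf <= 0.5:
            raise ValueError("rare_max_maf out of range")
        if not 0 <= self.max_missing < 1:
            raise ValueError("max_missing out of range")

    def hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True,
                             default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _write_tsv(df: pd.DataFrame, path: str, cfg_hash: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_hash={cfg_hash}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.10g")


def read_result_tsv(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def load_fixture_dir(directory: str) -> simulate.Fixture:
    """Load a written fixture back through the pipeline's file readers."""
    paths = {k: os.path.join(directory, f) for k, f in [
        ("vcf", "genotypes.vcf"), ("phenotype", "phenotype.tsv"),
        ("covariates", "covariates.tsv"), ("annotation", "annotation.tsv"),
        ("gene", "gene_model.gff3"), ("regulatory", "regulatory.bed"),
        ("problematic", "problematic.bed"), ("coverage", "coverage.bedgraph"),
        ("truth", "truth.tsv"),
    ]}
    variants, dosages, lad, gq, samples = qc.read_vcf(paths["vcf"])
    ann = pd.read_csv(paths["annotation"], sep="\t")
    variants = variants.merge(ann, on="vid", how="left")
    genes = annotate.read_gene_models(paths["gene"])
    regulatory = annotate.read_bed(
        paths["regulatory"],
        ["name", "feature", "tissue_group", "active"],
    )
    problematic = annotate.read_bed(paths["problematic"], ["type"])
    pos = variants["pos"].to_numpy()
    gs, ge = genes[0].span()
    w0 = min(int(pos.min()) - 1, gs)
    w1 = max(int(pos.max()), ge)
    cfg = simulate.LocusConfig(
        n_samples=len(samples),
        window_length=max(w1 - w0, ge - gs + 1, 2),
        n_variants=len(variants),
        gene_span=max(ge - gs, 1),
        chrom=str(variants["chrom"].iat[0]),
        window_start=w0,
    )
    locus = simulate.Locus(
        cfg, variants, dosages, genes[0], regulatory, problematic,
        samples, {},
    )
    raw = None
    if lad is not None and gq is not None:
        track = None
        if os.path.exists(paths["coverage"]):
            _, tstart, counts = simulate.read_pass_count_track(paths["coverage"])
        else:
            tstart, counts = w0, np.zeros(0, np.int32)
        raw = simulate.RawCalls(
            lad_ref=np.zeros_like(lad, dtype=np.int32),
            lad_alt=lad.astype(np.int32),  # only the sum is consumed downstream
            gq=gq.astype(np.int32),
            pass_counts=counts,
            track_start=tstart,
            n_samples_assessed=len(samples),
        )
    pheno = (pd.read_csv(paths["phenotype"], sep="\t")
             if os.path.exists(paths["phenotype"]) else None)
    covs = (pd.read_csv(paths["covariates"], sep="\t")
            if os.path.exists(paths["covariates"]) else None)
    truth = (pd.read_csv(paths["truth"], sep="\t")
             if os.path.exists(paths["truth"]) else None)
    return simulate.Fixture(locus, pheno, covs, truth, raw)


def build_units(
    locus: simulate.Locus,
    variants: pd.DataFrame,
    window: annotate.CisWindow,
    config: RunConfig,
) -> list[annotate.AggregateUnit]:
    units: list[annotate.AggregateUnit] = []
    units += annotate.build_gene_units(
        variants, locus.gene, transcript_mode=config.transcript_mode
    )
    units += annotate.build_regulatory_units(variants, locus.regulatory)
    units += annotate.build_sliding_windows(window, variants)
    return [u for u in units if u.testable]


def run_pipeline(
    fixture: simulate.Fixture,
    out_dir: str,
    config: RunConfig | None = None,
) -> dict:
    """Run the discovery procedure on one locus fixture.

    Writes result tables under ``out_dir`` and returns a manifest dict.  A
    stage failure raises :class:`PipelineStageError`; tables written before
    the failure are preserved.
    """
    config = config or RunConfig()
    os.makedirs(out_dir, exist_ok=True)
    h = config.hash()
    loc = fixture.locus
    manifest: dict = {
        "config": dataclasses.asdict(config),
        "config_hash": h,
        "n_samples": loc.config.n_samples,
        "n_variants_input": len(loc.variants),
        "stages": {},
    }
    t_all = time.time()

    def _stage(name: str):
        class _Ctx:
            def __enter__(self):
                self.t0 = time.time()
                return self

            def __exit__(self, exc_type, exc, tb):
                if exc is not None:
                    raise PipelineStageError(name, exc)
                manifest["stages"][name] = round(time.time() - self.t0, 3)

        return _Ctx()

    # ---- genotype QC
    with _stage("qc"):
        if fixture.raw is not None:
            lad_sum = fixture.raw.lad_sum
            gq = fixture.raw.gq
        else:
            lad_sum = gq = None
        qcr = qc.run_genotype_qc(
            loc.dosages.astype(float), loc.variants, lad_sum, gq,
            config.min_depth, config.min_gq, config.max_missing,
        )
        variants = qcr.variants
        dosages = qc.mean_impute(qcr.dosages)
        _write_tsv(
            variants[[c for c in variants.columns
                      if c not in ("freq_bin",)]].assign(retained=True),
            os.path.join(out_dir, "qc_report.tsv"), h,
        )
        manifest["n_variants_qc"] = len(variants)

    # ---- annotation, cis-window, masks
    with _stage("annotate"):
        window = annotate.define_cis_window(
            loc.gene, flank=1_000_000,
            chrom_length=loc.config.window_start + loc.config.window_length,
            transcript_mode=config.transcript_mode,
        )
        window = annotate.CisWindow(
            window.chrom, max(window.start, loc.config.window_start),
            window.end, window.gene_id,
        )
        variants = variants.copy()
        variants["classification"] = annotate.classify_variants(
            variants, [loc.gene], config.proximal_flank
        )
        units = build_units(loc, variants, window, config)
        manifest["n_units"] = len(units)

    # ---- single-variant scan (phenotype normalised at runtime)
    with _stage("single"):
        y_raw = fixture.phenotype["protein"].to_numpy(dtype=float)
        y = single.rank_inverse_normalize(y_raw)
        covs = fixture.covariates.drop(columns=["sample_id"])
        assoc = single.single_variant_assoc(
            dosages, y, covs, variants, min_mac=config.min_mac
        )
        _write_tsv(assoc, os.path.join(out_dir, "single_variant.tsv"), h)
        manifest["n_single_tests"] = len(assoc)

    # ---- conditional-joint selection
    with _stage("cojo"):
        signals = single.cojo_select(
            dosages, y, covs, variants,
            p_threshold=config.single_p, min_mac=config.min_mac,
        )
        _write_tsv(signals.table,
                   os.path.join(out_dir, "joint_signals.tsv"), h)
        manifest["n_joint_signals"] = len(signals)
        manifest["variance_explained"] = single.variance_explained(
            signals, dosages, y, covs
        )

    # ---- coverage QC
    with _stage("coverage"):
        gs, ge = loc.gene.span(config.transcript_mode)
        if fixture.raw is not None and len(fixture.raw.pass_counts):
            raw = fixture.raw
            gene_prof = coverage.compute_coverage(
                raw.pass_counts, raw.track_start, (loc.config.chrom, gs, ge),
                raw.n_samples_assessed, config.coverage_sample_frac,
                config.coverage_depth,
            )
            region_prof = coverage.compute_coverage(
                raw.pass_counts, raw.track_start, loc.window,
                raw.n_samples_assessed, config.coverage_sample_frac,
                config.coverage_depth,
            )
            verdict = coverage.coverage_filter(
                loc.gene.gene_id, gene_prof, region_prof,
                config.coverage_base_frac,
            )
        else:
            verdict = coverage.ProteinQCVerdict(loc.gene.gene_id, np.nan,
                                                np.nan, True)
        verdict.max_abs_beta_discrepancy = signals.max_abs_beta_discrepancy
        _write_tsv(
            pd.DataFrame([dataclasses.asdict(verdict)]),
            os.path.join(out_dir, "coverage_qc.tsv"), h,
        )
        manifest["passes_coverage"] = bool(verdict.passes_coverage)

    # ---- aggregate tests under step-(1) conditioning
    with _stage("aggregate"):
        cond = agg.build_conditioning_set(
            signals, variants, loc.gene.gene_id, config.conditioning_maf
        )
        tcfg = agg.TestConfig(max_maf=config.rare_max_maf)
        results = agg.run_aggregate_scan(
            dosages, variants, units, y, covs, cond, tcfg
        )
        _write_tsv(results, os.path.join(out_dir, "aggregate_results.tsv"), h)
        manifest["n_aggregate_tests"] = int(len(results))
        manifest["conditioning_set_size"] = int(len(cond))

    # ---- stepwise aggregate independence
    with _stage("stepwise"):
        independent = agg.stepwise_aggregate_conditioning(
            dosages, variants, units, y, covs, cond,
            threshold=config.aggregate_p, config=tcfg,
        )
        sig_single = assoc[assoc["p"] < config.single_p]
        independent = agg.flag_single_lead_aggregates(
            independent, units, signals.selected_idx,
            assoc["idx"].to_numpy()[assoc["p"].to_numpy() < config.single_p],
        ) if len(independent) else independent
        _write_tsv(independent,
                   os.path.join(out_dir, "independent_aggregates.tsv"), h)
        manifest["n_independent_aggregates"] = int(len(independent))
        manifest["n_study_wide_single"] = int(len(sig_single))

    # ---- enrichment of signals in regulatory regions
    with _stage("enrich"):
        rare_nc = (
            (variants["maf"].to_numpy() < 0.01)
            & ~variants["consequence"].isin(annotate.CODING_CONSEQUENCES)
        )
        pool = np.flatnonzero(rare_nc)
        rows = []
        sig_idx = assoc["idx"].to_numpy()[
            assoc["p"].to_numpy() < config.single_p
        ]
        sig_in_pool = np.flatnonzero(np.isin(pool, sig_idx))
        if len(sig_in_pool) and len(pool):
            pool_df = pd.DataFrame(
                {
                    "start": variants["pos"].to_numpy()[pool] - 1,
                    "end": variants["pos"].to_numpy()[pool],
                }
            )
            flags = enrich.region_overlap_flags(pool_df, loc.regulatory)
            res = enrich.bootstrap_region_enrichment(
                flags, sig_in_pool, len(pool),
                n_sim=config.enrichment_n_sim, seed=config.seed,
            )
            rows = [
                {
                    "stratum": r.stratum,
                    "observed_overlap": r.observed_overlap,
                    "null_mean": r.null_mean,
                    "null_sd": r.null_sd,
                    "empirical_p": r.empirical_p,
                }
                for r in res
            ]
        _write_tsv(pd.DataFrame(rows, columns=[
            "stratum", "observed_overlap", "null_mean", "null_sd",
            "empirical_p"]),
            os.path.join(out_dir, "enrichment.tsv"), h)

    manifest["elapsed_s"] = round(time.time() - t_all, 3)
    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=float)
    return manifest


def scan_min_p_factory(
    fixture: simulate.Fixture, config: RunConfig | None = None
):
    """Callable for :func:`cispqtl.enrich.empirical_thresholds`.

    Prepares QC'd dosages, masks and units once, then scans any phenotype
    vector, returning the class-wise minimum P values (single, aggregate).
    """
    config = config or RunConfig()
    loc = fixture.locus
    qcr = qc.run_genotype_qc(
        loc.dosages.astype(float), loc.variants,
        fixture.raw.lad_sum if fixture.raw else None,
        fixture.raw.gq if fixture.raw else None,
        config.min_depth, config.min_gq, config.max_missing,
    )
    variants = qcr.variants.copy()
    dosages = qc.mean_impute(qcr.dosages)
    window = annotate.CisWindow(*loc.window, loc.gene.gene_id)
    variants["classification"] = annotate.classify_variants(
        variants, [loc.gene], config.proximal_flank
    )
    units = build_units(loc, variants, window, config)
    covs = (fixture.covariates.drop(columns=["sample_id"])
            if fixture.covariates is not None else None)
    tcfg = agg.TestConfig(max_maf=config.rare_max_maf)

    def scan(y: np.ndarray) -> tuple[float, float]:
        yn = single.rank_inverse_normalize(y)
        assoc = single.single_variant_assoc(
            dosages, yn, covs, variants, min_mac=config.min_mac
        )
        min_single = float(assoc["p"].min()) if len(assoc) else 1.0
        res = agg.run_aggregate_scan(dosages, variants, units, yn, covs,
                                     None, tcfg)
        ok = res[~res["untestable"] & np.isfinite(res["p"])]
        min_agg = float(ok["p"].min()) if len(ok) else 1.0
        return min_single, min_agg

    return scan


def report(run_dir: str) -> dict:
    """Human-readable summary of a completed run (counts recomputable from
    the shipped tables)."""
    out: dict = {"warnings": []}
    paths = {
        "single": "single_variant.tsv",
        "joint": "joint_signals.tsv",
        "aggregate": "aggregate_results.tsv",
        "independent": "independent_aggregates.tsv",
        "coverage": "coverage_qc.tsv",
    }
    tables = {}
    for key, fname in paths.items():
        p = os.path.join(run_dir, fname)
        if os.path.exists(p):
            tables[key] = read_result_tsv(p)
        else:
            out["warnings"].append(f"missing table {fname}")
    if "single" in tables:
        out["n_single_tests"] = int(len(tables["single"]))
    if "joint" in tables:
        jt = tables["joint"]
        out["n_joint_signals"] = int(len(jt))
        if len(jt):
            out["n_decreasing"] = int((jt["beta_joint"] < 0).sum())
            out["n_increasing"] = int((jt["beta_joint"] > 0).sum())
    if "aggregate" in tables:
        ag = tables["aggregate"]
        out["n_aggregate_tests"] = int(len(ag))
        testable = ag[~ag["untestable"].astype(bool)]
        if len(testable):
            # which framework wins (smallest P) per unit x mask
            core = testable[testable["test"].isin(("BURDEN", "SKAT", "ACAT_V"))]
            if len(core):
                win = core.loc[
                    core.groupby(["unit_id", "mask"])["p"].idxmin()
                ]
                out["burden_win_fraction"] = float(
                    (win["test"] == "BURDEN").mean()
                )
    if "independent" in tables:
        out["n_independent_aggregates"] = int(len(tables["independent"]))
    if "coverage" in tables and len(tables["coverage"]):
        out["passes_coverage"] = bool(
            tables["coverage"]["passes_coverage"].iloc[0]
        )
    lines = [f"{k}: {v}" for k, v in out.items() if k != "warnings"]
    lines += [f"WARNING: {w}" for w in out["warnings"]]
    with open(os.path.join(run_dir, "report.txt"), "w") as fh:
        fh.write("\n".join(lines) + "\n")
    return out
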