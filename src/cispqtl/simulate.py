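"""Synthetic cis-locus generator with known ground truth.

Generates everything the discovery pipeline consumes: a variant set with a
realistic allele-frequency spectrum down to singletons, genotype dosages
under Hardy-Weinberg (optional block-LD mode), a two-transcript gene model
with UTRs/exons/introns, per-variant annotation scores, active regulatory
regions, per-genotype raw-call fields (allele depth, genotype quality) with
optional low-coverage segments, covariates, and protein phenotypes built
from common + rare coding + rare noncoding causal variants whose
effect-size and direction statistics follow the reported distributions for
circulating proteins (mean |beta| 1.15 s.d. and 65.2% level-decreasing for
rare noncoding causals; 86.3% decreasing for rare coding causals).

All randomness flows from a single integer seed through
``numpy.random.SeedSequence`` spawning; the sub-seeds used per component are
recorded on the generated objects.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from cispqtl.annotate import (
    CODING_CONSEQUENCES,
    LOF_CONSEQUENCES,
    GeneModel,
    Transcript,
    gene_model_to_gff3,
)

FREQ_BINS = ("singleton", "mac2_5", "maf_lt_0.1pct", "maf_0.1_1pct", "maf_gt_1pct")

TISSUE_SUPERGROUPS = [
    "adipose", "adrenal_gland", "blood", "blood_vessel", "bone", "brain",
    "breast", "embryonic", "epithelium", "eye", "heart", "intestine",
    "kidney", "liver", "lung", "muscle", "pancreas", "placenta", "skin",
    "spleen", "stomach", "thymus",
]

REGULATORY_FEATURES = ("promoter", "enhancer", "CTCF_binding", "TF_binding",
                      "open_chromatin")

_HALFNORM_MEAN = np.sqrt(2.0 / np.pi)  # E|N(0,1)|


@dataclass
class LocusConfig:
    """Knobs for one synthetic cis-locus (reduced-scale by default).

    ``maf_spectrum`` gives mixture weights over frequency bins
    (singleton, MAC 2-5, MAF < 0.1%, 0.1-1%, > 1%); defaults follow the
    singleton-heavy spectrum of deep population sequencing.
    """

    n_samples: int = 2_000
    window_length: int = 200_000
    n_variants: int = 3_000
    maf_spectrum: tuple[float, ...] = (0.30, 0.25, 0.15, 0.15, 0.15)
    gene_span: int = 20_000
    exon_count: int = 8
    proximal_flank: int = 5_000
    regulatory_region_density: float = 5.0  # regions per 100 kb
    problematic_region_density: float = 1.0
    ld_block_size: int | None = None  # variants per LD block (None = independent)
    ld_n_founders: int = 30
    chrom: str = "chr1"
    window_start: int = 1_000_000
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_samples", "window_length", "n_variants", "gene_span",
                     "exon_count"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        w = np.asarray(self.maf_spectrum, float)
        if len(w) != len(FREQ_BINS) or abs(w.sum() - 1.0) > 1e-9 or (w < 0).any():
            raise ValueError("maf_spectrum must be 5 nonnegative weights summing to 1")
        if self.n_variants > self.window_length:
            raise ValueError("cannot place n_variants unique positions in window")
        if self.gene_span >= self.window_length:
            raise ValueError("gene_span must be smaller than window_length")


@dataclass
class ArchitectureConfig:
    """Causal architecture for one protein phenotype.

    Effect magnitudes are half-normal, scaled so the mean |beta| matches the
    configured value (in phenotype s.d. units per allele); signs are negative
    (protein-decreasing) with the configured probability.
    """

    n_causal_common: int = 1
    n_causal_rare_coding: int = 1
    n_causal_rare_noncoding: int = 1
    mean_abs_beta_common: float = 0.15
    mean_abs_beta_coding: float = 1.55
    mean_abs_beta_noncoding: float = 1.15
    frac_decreasing_noncoding: float = 0.652
    frac_decreasing_coding: float = 0.863
    # each entry: dict(unit_id, start, end, mean_abs_beta, frac_decreasing,
    #                  causal_fraction) or with a fixed per-carrier "beta"
    causal_aggregate_units: list[dict] = field(default_factory=list)
    # each entry: dict(vid, beta, role) — planted verbatim
    explicit_causals: list[dict] = field(default_factory=list)
    covariate_effects: dict[str, float] | None = None
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.frac_decreasing_noncoding, self.frac_decreasing_coding):
            if not 0.0 <= p <= 1.0:
                raise ValueError("direction proportions must be in [0, 1]")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")


@dataclass
class DepthModel:
    """Sequencing-depth model for raw-call simulation.

    ``mean_depth`` matches typical 30x short-read WGS; ``gq_low_rate`` is the
    marginal probability that a call gets a low (< 10) genotype quality
    independent of depth.
    """

    mean_depth: float = 32.5
    gq_low_rate: float = 0.02
    depth_pass_threshold: int = 8

    def __post_init__(self) -> None:
        if self.mean_depth < 0 or not 0 <= self.gq_low_rate <= 1:
            raise ValueError("negative depth parameters")


@dataclass
class Locus:
    config: LocusConfig
    variants: pd.DataFrame  # vid, chrom, pos(1-based), ref, alt, freq_bin,
    #                         mac, maf, consequence, annotated_gene,
    #                         gerp, cadd, jarvis, spliceai, loftee_hc
    dosages: np.ndarray  # (n_samples, n_variants) int8
    gene: GeneModel
    regulatory: pd.DataFrame  # chrom start end name feature tissue_group active
    problematic: pd.DataFrame  # chrom start end type
    sample_ids: list[str]
    sub_seeds: dict[str, int] = field(default_factory=dict)

    @property
    def window(self) -> tuple[str, int, int]:
        c = self.config
        return (c.chrom, c.window_start, c.window_start + c.window_length)


@dataclass
class RawCalls:
    lad_ref: np.ndarray  # (n_samples, n_variants) int32
    lad_alt: np.ndarray
    gq: np.ndarray  # int32
    pass_counts: np.ndarray  # per-base count of samples with depth > threshold
    track_start: int  # 0-based genomic position of pass_counts[0]
    n_samples_assessed: int
    depth_threshold: int = 8

    @property
    def lad_sum(self) -> np.ndarray:
        return self.lad_ref + self.lad_alt


@dataclass
class Fixture:
    locus: Locus
    phenotype: pd.DataFrame | None = None  # sample_id, protein
    covariates: pd.DataFrame | None = None  # sample_id + covariate columns
    truth: pd.DataFrame | None = None  # vid, beta, role, unit_id
    raw: RawCalls | None = None


# ---------------------------------------------------------------------------
# locus


def _draw_mac(bin_name: str, n_samples: int, rng: np.random.Generator) -> int:
    """Target minor-allele count for a frequency bin."""
    two_n = 2 * n_samples
    if bin_name == "singleton":
        return 1
    if bin_name == "mac2_5":
        return int(rng.integers(2, 6))
    if bin_name == "maf_lt_0.1pct":
        # MAC > 5 where the sample size allows MAF < 0.1% at MAC > 5,
        # else the widest sub-singleton range below the cut
        hi = max(2, int(np.ceil(0.001 * two_n)) - 1)
        lo = 6 if hi >= 6 else 2
        return int(rng.integers(lo, hi + 1))
    if bin_name == "maf_0.1_1pct":
        maf = float(np.exp(rng.uniform(np.log(0.001), np.log(0.01))))
        return max(int(np.ceil(0.001 * two_n)), int(round(maf * two_n)))
    if bin_name == "maf_gt_1pct":
        maf = float(np.exp(rng.uniform(np.log(0.011), np.log(0.5))))
        return min(n_samples, max(int(np.ceil(0.01 * two_n)) + 1, int(round(maf * two_n))))
    raise ValueError(bin_name)


def _place_alleles(mac: int, n_samples: int, rng: np.random.Generator) -> np.ndarray:
    """Dosages with exactly ``mac`` alternate alleles among 2N chromosomes."""
    chroms = rng.choice(2 * n_samples, size=mac, replace=False)
    dos = np.zeros(n_samples, dtype=np.int8)
    np.add.at(dos, chroms // 2, 1)
    return dos


def _build_gene(cfg: LocusConfig) -> GeneModel:
    w0 = cfg.window_start
    gs = w0 + (cfg.window_length - cfg.gene_span) // 2
    ge = gs + cfg.gene_span
    utr5_len = max(20, min(200, cfg.gene_span // 10))
    utr3_len = max(30, min(500, cfg.gene_span // 6))
    # transcript 1: full span (the longest)
    n_ex = cfg.exon_count
    exon_len = max(80, min(300, cfg.gene_span // (2 * n_ex)))
    starts = np.linspace(gs, ge - exon_len, n_ex).astype(int)
    exons = [(int(s), int(s) + exon_len) for s in starts]
    exons[0] = (gs, max(gs + utr5_len + 50, exons[0][1]))
    exons[-1] = (min(ge - utr3_len - 50, exons[-1][0]), ge)
    # de-overlap defensively for tiny gene spans
    fixed = [exons[0]]
    for s, e in exons[1:]:
        s = max(s, fixed[-1][1] + 1)
        if s < e:
            fixed.append((s, e))
    exons = fixed
    t1 = Transcript("TX1", gs, ge, exons,
                    [(gs, gs + utr5_len)], [(ge - utr3_len, ge)])
    # transcript 2: shorter but with a more extreme 3' end (union != longest)
    ge2 = min(ge + cfg.gene_span // 10, w0 + cfg.window_length - 1)
    gs2 = gs + cfg.gene_span // 3
    ex2 = [(s, e) for s, e in exons if s >= gs2 and e <= ge2]
    if not ex2 or ex2[-1][1] < ge2:
        last_end = ex2[-1][1] if ex2 else gs2
        s2 = max(gs2, ge2 - exon_len, last_end + 1)
        if s2 < ge2:
            ex2 = ex2 + [(s2, ge2)]
    t2 = Transcript("TX2", gs2, ge2, ex2,
                    [(gs2, min(gs2 + utr5_len, ge2))],
                    [(max(gs2, ge2 - utr3_len), ge2)])
    return GeneModel("GENE1", cfg.chrom, "+", [t1, t2])


def _consequences_and_scores(
    positions0: np.ndarray, gene: GeneModel, regulatory: pd.DataFrame,
    cfg: LocusConfig, rng: np.random.Generator,
) -> pd.DataFrame:
    n = len(positions0)
    conseq = np.empty(n, dtype=object)
    annotated = np.empty(n, dtype=object)
    loftee = np.zeros(n, dtype=bool)

    exons = gene.exon_intervals()
    utrs: list[tuple[int, int, str]] = []
    tx_spans = []
    for tx in gene.transcripts:
        tx_spans.append((tx.start, tx.end))
        utrs += [(s, e, "5") for s, e in tx.utr5]
        utrs += [(s, e, "3") for s, e in tx.utr3]

    reg_iv = list(zip(regulatory["start"], regulatory["end"]))

    coding_choices = np.array(
        ["missense_variant", "synonymous_variant", "stop_gained",
         "frameshift_variant", "splice_donor_variant"]
    )
    coding_p = np.array([0.50, 0.28, 0.10, 0.07, 0.05])

    for i, p in enumerate(positions0):
        in_utr = next((u for u in utrs if u[0] <= p < u[1]), None)
        in_exon = any(s <= p < e for s, e in exons)
        in_tx = any(s <= p < e for s, e in tx_spans)
        near = any(s - cfg.proximal_flank <= p < e + cfg.proximal_flank
                   for s, e, _ in utrs)
        if in_utr is not None:
            conseq[i] = ("5_prime_UTR_variant" if in_utr[2] == "5"
                         else "3_prime_UTR_variant")
            annotated[i] = gene.gene_id
        elif in_exon:
            c = rng.choice(coding_choices, p=coding_p)
            conseq[i] = c
            annotated[i] = gene.gene_id
            if c in LOF_CONSEQUENCES:
                loftee[i] = rng.random() < 0.8
        elif in_tx:
            conseq[i] = "intron_variant"
            annotated[i] = gene.gene_id
        elif near:
            gs, _ = gene.span()
            conseq[i] = ("upstream_gene_variant" if p < gs
                         else "downstream_gene_variant")
            annotated[i] = gene.gene_id
        elif any(s <= p < e for s, e in reg_iv):
            conseq[i] = "regulatory_region_variant"
            annotated[i] = None
        else:
            conseq[i] = "intergenic_variant"
            annotated[i] = None

    is_coding = np.isin(conseq.astype(str), list(CODING_CONSEQUENCES))
    gerp = np.clip(rng.normal(0.0, 2.0, n) + 2.0 * is_coding, -12.3, 6.18)
    cadd = np.where(
        conseq == "missense_variant", rng.normal(22, 6, n),
        np.where(is_coding, rng.normal(12, 5, n), rng.normal(3, 3, n)),
    ).clip(0, 60)
    jarvis = rng.uniform(0, 1, n)
    spliceai = np.clip(rng.exponential(4.0, n), 0, 100)
    splicey = (conseq == "intron_variant") & (rng.random(n) < 0.03)
    spliceai = np.where(splicey, rng.uniform(20, 100, n), spliceai)

    return pd.DataFrame(
        {
            "consequence": conseq.astype(str),
            "annotated_gene": annotated,
            "gerp": np.round(gerp, 4),
            "cadd": np.round(cadd, 4),
            "jarvis": np.round(jarvis, 6),
            "spliceai": np.round(spliceai, 4),
            "loftee_hc": loftee,
        }
    )


def _simulate_regions(cfg: LocusConfig, rng: np.random.Generator) -> pd.DataFrame:
    w0, w1 = cfg.window_start, cfg.window_start + cfg.window_length
    n = int(round(cfg.regulatory_region_density * cfg.window_length / 100_000))
    starts = np.sort(rng.integers(w0, w1 - 200, size=n))
    lengths = rng.integers(200, 2_000, size=n)
    ends = np.minimum(starts + lengths, w1)
    return pd.DataFrame(
        {
            "chrom": cfg.chrom,
            "start": starts,
            "end": ends,
            "name": [f"ENSR{j:011d}" for j in range(n)],
            "feature": rng.choice(REGULATORY_FEATURES, size=n,
                                  p=[0.2, 0.35, 0.15, 0.15, 0.15]),
            "tissue_group": rng.choice(TISSUE_SUPERGROUPS, size=n),
            "active": rng.random(n) < 0.7,
        }
    )


def _simulate_problematic(cfg: LocusConfig, rng: np.random.Generator) -> pd.DataFrame:
    w0, w1 = cfg.window_start, cfg.window_start + cfg.window_length
    n = max(1, int(round(cfg.problematic_region_density * cfg.window_length / 100_000)))
    starts = np.sort(rng.integers(w0, w1 - 500, size=n))
    lengths = rng.integers(500, 5_000, size=n)
    types = rng.choice(
        ["segmental_duplication", "tandem_repeat", "homopolymer", "low_mappability"],
        size=n,
    )
    return pd.DataFrame(
        {"chrom": cfg.chrom, "start": starts,
         "end": np.minimum(starts + lengths, w1), "type": types}
    )


_BASES = np.array(list("ACGT"))


def simulate_locus(config: LocusConfig) -> Locus:
    """Generate a complete cis-locus fixture (deterministic given seed)."""
    ss = np.random.SeedSequence(config.seed)
    keys = ["positions", "genotypes", "annotation", "regions", "alleles"]
    children = ss.spawn(len(keys))
    rngs = {k: np.random.default_rng(c) for k, c in zip(keys, children)}
    sub_seeds = {k: int(c.generate_state(1)[0] % (2**31)) for k, c in zip(keys, children)}

    cfg = config
    w0 = cfg.window_start
    pos0 = np.sort(
        rngs["positions"].choice(cfg.window_length, size=cfg.n_variants, replace=False)
    ) + w0

    gene = _build_gene(cfg)
    regulatory = _simulate_regions(cfg, rngs["regions"])
    problematic = _simulate_problematic(cfg, rngs["regions"])

    grng = rngs["genotypes"]
    bins = grng.choice(len(FREQ_BINS), size=cfg.n_variants,
                       p=np.asarray(cfg.maf_spectrum, float))
    dosages = np.zeros((cfg.n_samples, cfg.n_variants), dtype=np.int8)
    macs = np.zeros(cfg.n_variants, dtype=np.int64)
    if cfg.ld_block_size is None:
        for j in range(cfg.n_variants):
            mac = _draw_mac(FREQ_BINS[bins[j]], cfg.n_samples, grng)
            dosages[:, j] = _place_alleles(mac, cfg.n_samples, grng)
            macs[j] = mac
    else:
        # block-LD: within a block, individuals draw both haplotypes from a
        # shared founder pool, inducing correlation between variants
        b = cfg.ld_block_size
        for lo in range(0, cfg.n_variants, b):
            hi = min(lo + b, cfg.n_variants)
            m = hi - lo
            mafs = np.array(
                [_draw_mac(FREQ_BINS[bins[j]], cfg.n_samples, grng)
                 for j in range(lo, hi)]
            ) / (2 * cfg.n_samples)
            founders = (grng.random((cfg.ld_n_founders, m)) < mafs[None, :]).astype(np.int8)
            pick = grng.integers(0, cfg.ld_n_founders, size=(cfg.n_samples, 2))
            dosages[:, lo:hi] = founders[pick[:, 0]] + founders[pick[:, 1]]
        alt = dosages.sum(axis=0)
        macs = np.minimum(alt, 2 * cfg.n_samples - alt)

    two_n = 2 * cfg.n_samples
    alt_count = dosages.astype(np.int64).sum(axis=0)
    macs = np.minimum(alt_count, two_n - alt_count)
    mafs = macs / two_n

    ann = _consequences_and_scores(pos0, gene, regulatory, cfg, rngs["annotation"])

    arng = rngs["alleles"]
    ref_i = arng.integers(0, 4, size=cfg.n_variants)
    alt_i = (ref_i + arng.integers(1, 4, size=cfg.n_variants)) % 4
    ref = _BASES[ref_i]
    alt = _BASES[alt_i]
    pos1 = pos0 + 1
    vids = [f"{cfg.chrom}:{p}:{r}:{a}" for p, r, a in zip(pos1, ref, alt)]

    variants = pd.DataFrame(
        {
            "vid": vids,
            "chrom": cfg.chrom,
            "pos": pos1,
            "ref": ref,
            "alt": alt,
            "freq_bin": [FREQ_BINS[b] for b in bins],
            "mac": macs,
            "maf": mafs,
        }
    )
    variants = pd.concat([variants, ann], axis=1)

    sample_ids = [f"S{i:06d}" for i in range(cfg.n_samples)]
    return Locus(cfg, variants, dosages, gene, regulatory, problematic,
                 sample_ids, sub_seeds)


# ---------------------------------------------------------------------------
# phenotype


DEFAULT_COVARIATE_EFFECTS = {
    "age": 0.10, "age2": 0.03, "sex": -0.10,
    "pc1": 0.05, "pc2": -0.05, "pc3": 0.04, "pc4": -0.04, "batch": 0.05,
}


def simulate_covariates(
    n_samples: int, sample_ids: list[str], rng: np.random.Generator
) -> pd.DataFrame:
    """Reduced covariate set: age, age^2, sex, 4 PC-like axes, one batch."""
    age = rng.uniform(37, 80, n_samples)
    agez = (age - age.mean()) / age.std()
    cov = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "age": np.round(agez, 6),
            "age2": np.round(agez**2 - 1.0, 6),
            "sex": rng.integers(0, 2, n_samples),
            "pc1": np.round(rng.normal(size=n_samples), 6),
            "pc2": np.round(rng.normal(size=n_samples), 6),
            "pc3": np.round(rng.normal(size=n_samples), 6),
            "pc4": np.round(rng.normal(size=n_samples), 6),
            "batch": rng.integers(0, 2, n_samples),
        }
    )
    return cov


def _draw_betas(
    n: int, mean_abs: float, frac_decreasing: float, rng: np.random.Generator
) -> np.ndarray:
    mags = np.abs(rng.normal(0.0, mean_abs / _HALFNORM_MEAN, n))
    signs = np.where(rng.random(n) < frac_decreasing, -1.0, 1.0)
    return mags * signs


def simulate_phenotype(
    locus: Locus,
    arch: ArchitectureConfig,
    covariates: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Protein levels from the configured causal architecture.

    Returns ``(phenotype, covariates, truth)``; phenotype is on a raw
    (log2-like) scale, to be rank-inverse normalised by the association
    stage.  Causal rare variants are sampled from the locus (coding /
    noncoding pools at MAF < 0.1%); aggregate-unit causals get per-variant
    effects for ``causal_fraction`` of the unit's rare noncoding members.
    """
    rng = np.random.default_rng(np.random.SeedSequence(arch.seed))
    v = locus.variants
    n = locus.config.n_samples
    if covariates is None:
        covariates = simulate_covariates(n, locus.sample_ids, rng)

    coding = v["consequence"].isin(CODING_CONSEQUENCES).to_numpy()
    # at reduced sample sizes the MAC <= 5 analogue keeps the rare pool
    # non-empty (a singleton at n = 500 has MAF exactly 0.1%)
    rare = (
        ((v["maf"].to_numpy() < 0.001) | (v["mac"].to_numpy() <= 5))
        & (v["mac"].to_numpy() >= 1)
    )
    common = v["maf"].to_numpy() > 0.01

    rows: list[dict] = []

    def _pick(pool: np.ndarray, k: int, label: str) -> np.ndarray:
        idx = np.flatnonzero(pool)
        if k > len(idx):
            raise ValueError(f"not enough {label} variants to plant {k} causals")
        return rng.choice(idx, size=k, replace=False)

    beta = np.zeros(len(v))
    if arch.n_causal_common:
        ci = _pick(common, arch.n_causal_common, "common")
        b = _draw_betas(len(ci), arch.mean_abs_beta_common, 0.5, rng)
        beta[ci] += b
        rows += [{"vid": v["vid"].iat[i], "beta": bb, "role": "common",
                  "unit_id": ""} for i, bb in zip(ci, b)]
    if arch.n_causal_rare_coding:
        ci = _pick(coding & rare, arch.n_causal_rare_coding, "rare coding")
        b = _draw_betas(len(ci), arch.mean_abs_beta_coding,
                        arch.frac_decreasing_coding, rng)
        beta[ci] += b
        rows += [{"vid": v["vid"].iat[i], "beta": bb, "role": "rare_coding",
                  "unit_id": ""} for i, bb in zip(ci, b)]
    if arch.n_causal_rare_noncoding:
        ci = _pick(~coding & rare, arch.n_causal_rare_noncoding, "rare noncoding")
        b = _draw_betas(len(ci), arch.mean_abs_beta_noncoding,
                        arch.frac_decreasing_noncoding, rng)
        beta[ci] += b
        rows += [{"vid": v["vid"].iat[i], "beta": bb, "role": "rare_noncoding",
                  "unit_id": ""} for i, bb in zip(ci, b)]

    vid_to_idx = {vid: i for i, vid in enumerate(v["vid"])}
    for spec_causal in arch.explicit_causals:
        try:
            i = vid_to_idx[spec_causal["vid"]]
        except KeyError:
            raise ValueError(
                f"explicit causal {spec_causal['vid']!r} not in locus"
            ) from None
        beta[i] += float(spec_causal["beta"])
        rows.append({"vid": spec_causal["vid"], "beta": spec_causal["beta"],
                     "role": spec_causal.get("role", "explicit"),
                     "unit_id": ""})

    pos0 = v["pos"].to_numpy() - 1
    for unit in arch.causal_aggregate_units:
        members = np.flatnonzero(
            ~coding & rare & (pos0 >= unit["start"]) & (pos0 < unit["end"])
        )
        if len(members) == 0:
            raise ValueError(
                f"causal aggregate unit {unit.get('unit_id', '?')} has no "
                "rare noncoding members"
            )
        k = max(1, int(round(unit.get("causal_fraction", 1.0) * len(members))))
        chosen = rng.choice(members, size=k, replace=False)
        if "beta" in unit:  # constant per-carrier effect
            b = np.full(k, float(unit["beta"]))
        else:
            b = _draw_betas(
                k,
                unit.get("mean_abs_beta", arch.mean_abs_beta_noncoding),
                unit.get("frac_decreasing", arch.frac_decreasing_noncoding),
                rng,
            )
        beta[chosen] += b
        rows += [{"vid": v["vid"].iat[i], "beta": bb, "role": "aggregate",
                  "unit_id": unit.get("unit_id", "")} for i, bb in zip(chosen, b)]

    effects = arch.covariate_effects
    if effects is None:
        effects = DEFAULT_COVARIATE_EFFECTS
    xterm = np.zeros(n)
    for name, g in effects.items():
        xterm += g * covariates[name].to_numpy(dtype=float)

    y = (
        locus.dosages.astype(float) @ beta
        + xterm
        + rng.normal(0.0, arch.noise_sd, n)
    )
    phenotype = pd.DataFrame({"sample_id": locus.sample_ids,
                              "protein": np.round(y, 10)})
    truth = pd.DataFrame(rows, columns=["vid", "beta", "role", "unit_id"])
    return phenotype, covariates, truth


# ---------------------------------------------------------------------------
# raw calls and depth


def simulate_raw_calls(
    locus: Locus,
    depth_model: DepthModel | None = None,
    low_coverage_segments: list[tuple[int, int]] | None = None,
    seed: int = 0,
    n_samples_assessed: int | None = None,
) -> RawCalls:
    """Per-genotype LAD/GQ and a per-base depth-pass-count track.

    ``low_coverage_segments`` are 0-based half-open genomic intervals where
    the depth rate drops to zero.  The per-base track records, at each base
    of the locus window, how many of the first ``n_samples_assessed``
    samples have depth strictly above the threshold; at variant sites it is
    consistent with the simulated per-genotype depths.
    """
    dm = depth_model or DepthModel()
    cfg = locus.config
    segs = sorted(low_coverage_segments or [])
    w0, w1 = cfg.window_start, cfg.window_start + cfg.window_length
    for s, e in segs:
        if s < w0 or e > w1 or e <= s:
            raise ValueError("low-coverage segment outside locus bounds")

    rng = np.random.default_rng(np.random.SeedSequence([seed, cfg.seed]))
    n = cfg.n_samples
    m = cfg.n_variants
    n_assessed = n if n_samples_assessed is None else min(n, n_samples_assessed)

    pos0 = locus.variants["pos"].to_numpy() - 1
    in_low = np.zeros(m, dtype=bool)
    for s, e in segs:
        in_low |= (pos0 >= s) & (pos0 < e)
    rate = np.where(in_low, 0.0, dm.mean_depth)

    depth = rng.poisson(np.broadcast_to(rate, (n, m))).astype(np.int32)
    dos = locus.dosages
    lad_alt = np.where(
        dos == 2, depth,
        np.where(dos == 1, rng.binomial(depth, 0.5), 0),
    ).astype(np.int32)
    lad_ref = depth - lad_alt
    gq = np.minimum(99, 20 + 2 * depth).astype(np.int32)
    low_flag = rng.random((n, m)) < dm.gq_low_rate
    gq = np.where(low_flag, rng.integers(0, 10, size=(n, m)), gq).astype(np.int32)

    # per-base track: binomial draw at the analytic per-base pass rate,
    # overwritten at variant sites by the realised genotype depths
    thr = dm.depth_pass_threshold
    p_pass = float(stats.poisson.sf(thr, dm.mean_depth)) if dm.mean_depth > 0 else 0.0
    counts = rng.binomial(n_assessed, p_pass, size=cfg.window_length).astype(np.int32)
    for s, e in segs:
        counts[s - w0: e - w0] = 0
    counts[pos0 - w0] = (depth[:n_assessed, :] > thr).sum(axis=0)
    return RawCalls(lad_ref, lad_alt, gq, counts, w0, n_assessed, thr)


# ---------------------------------------------------------------------------
# fixture I/O


def _dosage_to_gt(d: int) -> str:
    return {0: "0/0", 1: "0/1", 2: "1/1"}.get(int(d), "./.")


def write_fixture(fixture: Fixture, directory: str) -> dict[str, str]:
    """Serialise a fixture as VCF + TSV + BED + GFF3 files.

    Returns a mapping of logical names to file paths.  All files are plain
    text; the VCF carries ``GT:AD:GQ`` when raw calls are present, else
    ``GT``.
    """
    os.makedirs(directory, exist_ok=True)
    loc = fixture.locus
    cfg = loc.config
    paths = {k: os.path.join(directory, f)
             for k, f in [
                 ("vcf", "genotypes.vcf"), ("phenotype", "phenotype.tsv"),
                 ("covariates", "covariates.tsv"),
                 ("annotation", "annotation.tsv"), ("gene", "gene_model.gff3"),
                 ("regulatory", "regulatory.bed"),
                 ("problematic", "problematic.bed"),
                 ("coverage", "coverage.bedgraph"), ("truth", "truth.tsv"),
             ]}

    v = loc.variants
    with open(paths["vcf"], "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={cfg.chrom},length={cfg.window_start + cfg.window_length + 1_000_000}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if fixture.raw is not None:
            fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allele depths">\n')
            fh.write('##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(loc.sample_ids) + "\n")
        fmt = "GT:AD:GQ" if fixture.raw is not None else "GT"
        for j in range(len(v)):
            fields = [
                cfg.chrom, str(int(v["pos"].iat[j])), v["vid"].iat[j],
                v["ref"].iat[j], v["alt"].iat[j], ".", "PASS", ".", fmt,
            ]
            if fixture.raw is not None:
                r = fixture.raw
                cells = [
                    f"{_dosage_to_gt(loc.dosages[i, j])}:"
                    f"{r.lad_ref[i, j]},{r.lad_alt[i, j]}:{r.gq[i, j]}"
                    for i in range(cfg.n_samples)
                ]
            else:
                cells = [_dosage_to_gt(loc.dosages[i, j])
                         for i in range(cfg.n_samples)]
            fh.write("\t".join(fields + cells) + "\n")

    ann_cols = ["vid", "consequence", "annotated_gene", "gerp", "cadd",
                "jarvis", "spliceai", "loftee_hc"]
    v[ann_cols].to_csv(paths["annotation"], sep="\t", index=False)

    with open(paths["gene"], "w") as fh:
        fh.write(gene_model_to_gff3(loc.gene))

    loc.regulatory.to_csv(paths["regulatory"], sep="\t", index=False,
                          header=False)
    loc.problematic.to_csv(paths["problematic"], sep="\t", index=False,
                           header=False)

    if fixture.phenotype is not None:
        fixture.phenotype.to_csv(paths["phenotype"], sep="\t", index=False)
    if fixture.covariates is not None:
        fixture.covariates.to_csv(paths["covariates"], sep="\t", index=False)
    if fixture.truth is not None:
        fixture.truth.to_csv(paths["truth"], sep="\t", index=False)
    if fixture.raw is not None:
        _write_bedgraph(fixture.raw, cfg.chrom, paths["coverage"])
    return paths


def _write_bedgraph(raw: RawCalls, chrom: str, path: str) -> None:
    """Run-length encoded pass-count track (chrom, start0, end0, count)."""
    c = raw.pass_counts
    change = np.flatnonzero(np.diff(c)) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [len(c)]])
    with open(path, "w") as fh:
        for s, e in zip(starts, ends):
            fh.write(f"{chrom}\t{raw.track_start + s}\t{raw.track_start + e}\t{c[s]}\n")


def read_pass_count_track(path: str) -> tuple[str, int, np.ndarray]:
    """Inverse of the bedgraph writer: (chrom, track_start, per-base counts)."""
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["chrom", "start", "end", "count"])
    start = int(df["start"].min())
    length = int(df["end"].max()) - start
    out = np.zeros(length, dtype=np.int32)
    for _, row in df.iterrows():
        out[int(row["start"]) - start: int(row["end"]) - start] = int(row["count"])
    return str(df["chrom"].iat[0]), start, out
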