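"""Cis-window definition, variant classification and aggregate-unit masks.

All internal coordinates are 0-based half-open; VCF-style 1-based positions
are converted on read and write.  Strand is carried on gene models but plays
no role in window arithmetic (UTR coordinates are already genomic).
"""

from __future__ import annotations

import os
import tempfile
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

# VEP-style consequence vocabulary used throughout the package.
LOF_CONSEQUENCES = frozenset(
    {
        "stop_gained",
        "frameshift_variant",
        "splice_donor_variant",
        "splice_acceptor_variant",
        "start_lost",
        "stop_lost",
    }
)
CODING_CONSEQUENCES = LOF_CONSEQUENCES | {
    "missense_variant",
    "synonymous_variant",
    "inframe_deletion",
    "inframe_insertion",
}

CODING = "coding"
PROXIMAL = "proximal_regulatory"
INTERGENIC = "intergenic_regulatory"


@dataclass
class Transcript:
    transcript_id: str
    start: int  # 0-based half-open genomic span
    end: int
    exons: list[tuple[int, int]]
    utr5: list[tuple[int, int]]
    utr3: list[tuple[int, int]]

    def __post_init__(self) -> None:
        ex = sorted(self.exons)
        for (s0, e0), (s1, e1) in zip(ex, ex[1:]):
            if e0 > s1:
                raise ValueError(
                    f"overlapping exons in transcript {self.transcript_id}"
                )
        for s, e in list(self.utr5) + list(self.utr3):
            if s < self.start or e > self.end:
                raise ValueError(
                    f"UTR outside transcript span in {self.transcript_id}"
                )

    @property
    def utr_bounds(self) -> tuple[int, int]:
        """Outermost bounds over the 5'/3' UTRs (transcript span fallback)."""
        ivs = list(self.utr5) + list(self.utr3)
        if not ivs:
            return self.start, self.end
        return min(s for s, _ in ivs), max(e for _, e in ivs)

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class GeneModel:
    gene_id: str
    chrom: str
    strand: str
    transcripts: list[Transcript]

    def span(self, transcript_mode: str = "union") -> tuple[int, int]:
        """Outermost UTR-to-UTR bounds.

        ``union`` takes the most extreme bounds over all transcripts;
        ``longest`` uses the single longest transcript.
        """
        if not self.transcripts:
            raise ValueError(f"gene {self.gene_id} has no transcripts")
        if transcript_mode == "longest":
            tx = max(self.transcripts, key=lambda t: t.length)
            return tx.utr_bounds
        if transcript_mode == "union":
            bounds = [t.utr_bounds for t in self.transcripts]
            return min(s for s, _ in bounds), max(e for _, e in bounds)
        raise ValueError(f"unknown transcript_mode {transcript_mode!r}")

    def exon_intervals(self) -> list[tuple[int, int]]:
        out: list[tuple[int, int]] = []
        for t in self.transcripts:
            out.extend(t.exons)
        return sorted(out)


@dataclass(frozen=True)
class CisWindow:
    chrom: str
    start: int  # 0-based half-open
    end: int
    gene_id: str

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("cis-window end must exceed start")

    @property
    def length(self) -> int:
        return self.end - self.start


def define_cis_window(
    gene: GeneModel,
    flank: int = 1_000_000,
    chrom_length: int | None = None,
    transcript_mode: str = "union",
) -> CisWindow:
    """Cis-window: ``flank`` bp either side of the outermost UTR bounds.

    Clipped at the chromosome bounds (position 0 and ``chrom_length``).
    """
    s, e = gene.span(transcript_mode=transcript_mode)
    lo = max(0, s - flank)
    hi = e + flank
    if chrom_length is not None:
        hi = min(hi, chrom_length)
    return CisWindow(gene.chrom, lo, hi, gene.gene_id)


# ---------------------------------------------------------------------------
# classification


def _near_any(pos0: int, intervals: list[tuple[int, int]], pad: int) -> bool:
    return any(s - pad <= pos0 < e + pad for s, e in intervals)


def _in_any(pos0: int, intervals: list[tuple[int, int]]) -> bool:
    return any(s <= pos0 < e for s, e in intervals)


def classify_variant(
    consequence: str,
    pos: int,
    genes: list[GeneModel],
    proximal_flank: int = 5_000,
) -> str:
    """Three-way classification of a variant.

    ``coding`` if the consequence implies coding impact on any transcript
    (coding takes priority over everything else); ``proximal_regulatory`` if
    the variant sits within ``proximal_flank`` bp of any UTR, within the UTRs
    themselves, or in an intron of a gene; otherwise
    ``intergenic_regulatory``.  ``pos`` is 1-based.
    """
    if consequence in CODING_CONSEQUENCES:
        return CODING
    pos0 = pos - 1
    for gene in genes:
        for tx in gene.transcripts:
            utrs = list(tx.utr5) + list(tx.utr3)
            if _near_any(pos0, utrs, proximal_flank):
                return PROXIMAL
            if tx.start <= pos0 < tx.end:
                # inside the transcript but not coding => UTR/intron
                return PROXIMAL
    return INTERGENIC


def classify_variants(
    variants: pd.DataFrame,
    genes: list[GeneModel],
    proximal_flank: int = 5_000,
) -> pd.Series:
    """Vectorised :func:`classify_variant` over a variant table."""
    out = np.empty(len(variants), dtype=object)
    for i, (csq, pos) in enumerate(
        zip(variants["consequence"].to_numpy(), variants["pos"].to_numpy())
    ):
        out[i] = classify_variant(str(csq), int(pos), genes, proximal_flank)
    return pd.Series(out, index=variants.index, name="classification")


# ---------------------------------------------------------------------------
# masks

SCORE_FIELDS = ("gerp", "cadd", "jarvis", "spliceai")


@dataclass(frozen=True)
class MaskDefinition:
    """A pure predicate over variant annotation rows.

    ``score_gt`` maps score field -> strict lower bound (a missing score
    excludes the variant from the mask).  ``consequences`` restricts to a
    whitelist when given.  ``classifications`` restricts the three-way
    classification.  ``max_maf`` is the rare-variant cut (inclusive upper
    bound is exclusive: maf < max_maf).
    """

    name: str
    classifications: frozenset[str] = frozenset({PROXIMAL, INTERGENIC})
    consequences: frozenset[str] | None = None
    score_gt: tuple[tuple[str, float], ...] = ()
    require_loftee_hc: bool = False
    max_maf: float = 0.001

    def member_index(self, variants: pd.DataFrame) -> np.ndarray:
        keep = variants["maf"].to_numpy() < self.max_maf
        keep &= variants["classification"].isin(self.classifications).to_numpy()
        if self.consequences is not None:
            keep &= variants["consequence"].isin(self.consequences).to_numpy()
        if self.require_loftee_hc:
            keep &= variants["loftee_hc"].fillna(False).to_numpy().astype(bool)
        for fieldname, thr in self.score_gt:
            if fieldname not in variants.columns:
                raise KeyError(f"mask {self.name} requires score {fieldname}")
            vals = variants[fieldname].to_numpy(dtype=float)
            keep &= np.isfinite(vals) & (vals > thr)
        return np.flatnonzero(keep)


def default_mask_catalogue() -> dict[str, MaskDefinition]:
    """Masks named in the discovery procedure.

    Coding masks: LOFTEE high-confidence LoF, missense with CADD > 25, and
    all coding.  Noncoding masks: unrestricted ("all"), highly conserved
    (GERP > 2), highly constrained (JARVIS > 0.99) and predicted splice
    (SpliceAI > 50).  Score thresholds are strict.
    """
    coding = frozenset({CODING})
    noncoding = frozenset({PROXIMAL, INTERGENIC})
    masks = [
        MaskDefinition("lof_hc", coding, LOF_CONSEQUENCES, require_loftee_hc=True),
        MaskDefinition(
            "missense_cadd25",
            coding,
            frozenset({"missense_variant"}),
            score_gt=(("cadd", 25.0),),
        ),
        MaskDefinition("coding_all", coding, CODING_CONSEQUENCES),
        MaskDefinition("noncoding_all", noncoding),
        MaskDefinition("gerp2", noncoding, score_gt=(("gerp", 2.0),)),
        MaskDefinition("jarvis99", noncoding, score_gt=(("jarvis", 0.99),)),
        MaskDefinition("spliceai50", noncoding, score_gt=(("spliceai", 50.0),)),
    ]
    return {m.name: m for m in masks}

CODING_MASKS = frozenset({"lof_hc", "missense_cadd25", "coding_all"})
NONCODING_MASKS = frozenset({"noncoding_all", "gerp2", "jarvis99", "spliceai50"})


@dataclass
class AggregateUnit:
    """A named set of rare variants tested jointly."""

    unit_id: str
    unit_kind: str  # gene_coding | gene_proximal | regulatory_region |
    #                 constrained_window | conserved_window | sliding_window
    chrom: str
    start: int
    end: int
    mask: str
    member_idx: np.ndarray = field(default_factory=lambda: np.empty(0, int))

    @property
    def n_variants(self) -> int:
        return len(self.member_idx)

    @property
    def testable(self) -> bool:
        return self.n_variants > 0


def build_masks(
    variants: pd.DataFrame,
    definitions: dict[str, MaskDefinition] | None = None,
    names: list[str] | None = None,
) -> dict[str, np.ndarray]:
    """Mask name -> integer row indices of member variants."""
    definitions = definitions or default_mask_catalogue()
    names = names or list(definitions)
    out: dict[str, np.ndarray] = {}
    for name in names:
        if name not in definitions:
            raise KeyError(f"unknown mask {name!r}")
        out[name] = definitions[name].member_index(variants)
    return out


def _interval_members(
    variants: pd.DataFrame, start: int, end: int, base_idx: np.ndarray
) -> np.ndarray:
    pos0 = variants["pos"].to_numpy()[base_idx] - 1
    return base_idx[(pos0 >= start) & (pos0 < end)]


def build_gene_units(
    variants: pd.DataFrame,
    gene: GeneModel,
    definitions: dict[str, MaskDefinition] | None = None,
    transcript_mode: str = "union",
) -> list[AggregateUnit]:
    """Gene-centric units: one coding and one proximal unit per mask.

    Coding and proximal halves are kept as separate units so that coding and
    noncoding statistics are never combined by the all-mask step.
    """
    definitions = definitions or default_mask_catalogue()
    masks = build_masks(variants, definitions)
    s, e = gene.span(transcript_mode=transcript_mode)
    units = []
    gene_centric = variants["annotated_gene"].fillna("") == gene.gene_id
    for name, idx in masks.items():
        kind = "gene_coding" if name in CODING_MASKS else "gene_proximal"
        if kind == "gene_proximal":
            # gene-centric = annotated to the gene (UTR/intron/<=5kb flank)
            idx = idx[gene_centric.to_numpy()[idx]]
        else:
            idx = idx[gene_centric.to_numpy()[idx]]
        units.append(
            AggregateUnit(
                f"{gene.gene_id}:{'coding' if kind == 'gene_coding' else 'proximal'}",
                kind,
                gene.chrom,
                s,
                e,
                name,
                idx,
            )
        )
    return units


def build_regulatory_units(
    variants: pd.DataFrame,
    regions: pd.DataFrame,
    definitions: dict[str, MaskDefinition] | None = None,
    noncoding_masks: list[str] = ("noncoding_all", "gerp2", "jarvis99"),
) -> list[AggregateUnit]:
    """One unit per active regulatory region (ENSR-style) per noncoding mask.

    ``regions`` needs columns chrom/start/end/name and optionally ``active``.
    """
    definitions = definitions or default_mask_catalogue()
    masks = build_masks(variants, definitions, list(noncoding_masks))
    units = []
    use = regions
    if "active" in regions.columns:
        use = regions[regions["active"].astype(bool)]
    for _, row in use.iterrows():
        for mname, idx in masks.items():
            members = _interval_members(variants, row["start"], row["end"], idx)
            units.append(
                AggregateUnit(
                    f"{row['name']}",
                    "regulatory_region",
                    str(row["chrom"]),
                    int(row["start"]),
                    int(row["end"]),
                    mname,
                    members,
                )
            )
    return units


def build_sliding_windows(
    window: CisWindow,
    variants: pd.DataFrame,
    size: int = 2_000,
    step: int = 1_000,
    definitions: dict[str, MaskDefinition] | None = None,
) -> list[AggregateUnit]:
    """Overlapping sliding windows (2 kb, 1 kb overlap) of noncoding rares.

    Coding variants are excluded from membership.  Windows start every
    ``step`` bp from the window start; a trailing partial window (< ``size``)
    at the 3' edge is emitted so edge variants stay covered.  Empty windows
    are retained (flagged untestable via ``n_variants == 0``).
    """
    definitions = definitions or default_mask_catalogue()
    base = build_masks(variants, definitions, ["noncoding_all"])["noncoding_all"]
    units = []
    for start in range(window.start, window.end, step):
        end = min(start + size, window.end)
        members = _interval_members(variants, start, end, base)
        units.append(
            AggregateUnit(
                f"win:{window.chrom}:{start}-{end}",
                "sliding_window",
                window.chrom,
                start,
                end,
                "noncoding_all",
                members,
            )
        )
    return units


def build_score_windows(
    window: CisWindow,
    variants: pd.DataFrame,
    constraint_z: pd.DataFrame | None = None,
    phastcon_percentile: pd.DataFrame | None = None,
    exon_intervals: list[tuple[int, int]] | None = None,
    z_min: float = 4.0,
    percentile_min: float = 99.0,
    definitions: dict[str, MaskDefinition] | None = None,
) -> list[AggregateUnit]:
    """Constraint- and conservation-scored window units.

    ``constraint_z``: per-window track (start, end, z); windows with
    z >= 4 become ``constrained_window`` units.  ``phastcon_percentile``:
    (start, end, percentile); windows at or above the 99th percentile and
    overlapping no exon become ``conserved_window`` units.  Tracks must
    cover the cis-window.
    """
    definitions = definitions or default_mask_catalogue()
    base = build_masks(variants, definitions, ["noncoding_all"])["noncoding_all"]
    exon_intervals = exon_intervals or []
    units: list[AggregateUnit] = []

    def _check_cover(track: pd.DataFrame, label: str) -> None:
        if track["start"].min() > window.start or track["end"].max() < window.end:
            raise ValueError(f"{label} track does not cover the cis-window")

    if constraint_z is not None:
        _check_cover(constraint_z, "constraint")
        hit = constraint_z[constraint_z["z"] >= z_min]
        for _, row in hit.iterrows():
            members = _interval_members(variants, row["start"], row["end"], base)
            units.append(
                AggregateUnit(
                    f"zwin:{window.chrom}:{int(row['start'])}-{int(row['end'])}",
                    "constrained_window",
                    window.chrom,
                    int(row["start"]),
                    int(row["end"]),
                    "noncoding_all",
                    members,
                )
            )
    if phastcon_percentile is not None:
        _check_cover(phastcon_percentile, "phastCon")
        hit = phastcon_percentile[
            phastcon_percentile["percentile"] >= percentile_min
        ]
        for _, row in hit.iterrows():
            s, e = int(row["start"]), int(row["end"])
            if any(es < e and s < ee for es, ee in exon_intervals):
                continue  # any exon overlap (even 1 bp) excludes the window
            members = _interval_members(variants, s, e, base)
            units.append(
                AggregateUnit(
                    f"pwin:{window.chrom}:{s}-{e}",
                    "conserved_window",
                    window.chrom,
                    s,
                    e,
                    "noncoding_all",
                    members,
                )
            )
    return units


# ---------------------------------------------------------------------------
# GFF3 round trip (gffutils-backed reader)


def gene_model_to_gff3(gene: GeneModel) -> str:
    lines = ["##gff-version 3"]
    s, e = gene.span()

    def rec(kind: str, start0: int, end0: int, attrs: str) -> str:
        return "\t".join(
            [
                gene.chrom,
                "cispqtl",
                kind,
                str(start0 + 1),
                str(end0),
                ".",
                gene.strand,
                ".",
                attrs,
            ]
        )

    lines.append(rec("gene", s, e, f"ID={gene.gene_id}"))
    for tx in gene.transcripts:
        lines.append(
            rec(
                "mRNA",
                tx.start,
                tx.end,
                f"ID={tx.transcript_id};Parent={gene.gene_id}",
            )
        )
        for i, (xs, xe) in enumerate(tx.exons):
            lines.append(
                rec(
                    "exon",
                    xs,
                    xe,
                    f"ID={tx.transcript_id}.exon{i};Parent={tx.transcript_id}",
                )
            )
        for i, (us, ue) in enumerate(tx.utr5):
            lines.append(
                rec(
                    "five_prime_UTR",
                    us,
                    ue,
                    f"ID={tx.transcript_id}.utr5.{i};Parent={tx.transcript_id}",
                )
            )
        for i, (us, ue) in enumerate(tx.utr3):
            lines.append(
                rec(
                    "three_prime_UTR",
                    us,
                    ue,
                    f"ID={tx.transcript_id}.utr3.{i};Parent={tx.transcript_id}",
                )
            )
    return "\n".join(lines) + "\n"


def read_gene_models(gff3_path: str) -> list[GeneModel]:
    """Parse gene models from a GFF3 file via gffutils."""
    import gffutils

    db = gffutils.create_db(
        gff3_path,
        ":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    genes = []
    for g in db.features_of_type("gene"):
        transcripts = []
        for t in db.children(g, featuretype="mRNA"):
            exons = [
                (f.start - 1, f.end) for f in db.children(t, featuretype="exon")
            ]
            utr5 = [
                (f.start - 1, f.end)
                for f in db.children(t, featuretype="five_prime_UTR")
            ]
            utr3 = [
                (f.start - 1, f.end)
                for f in db.children(t, featuretype="three_prime_UTR")
            ]
            transcripts.append(
                Transcript(t.id, t.start - 1, t.end, sorted(exons), utr5, utr3)
            )
        genes.append(GeneModel(g.id, g.seqid, g.strand, transcripts))
    return genes


def read_bed(path: str, names: list[str] | None = None) -> pd.DataFrame:
    """Read a BED-like file (0-based half-open native coordinates)."""
    base_cols = ["chrom", "start", "end"] + list(names or [])
    if os.path.getsize(path) == 0:
        return pd.DataFrame(columns=base_cols)
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    base = ["chrom", "start", "end"]
    extra = names or [f"col{i}" for i in range(3, df.shape[1])]
    df.columns = base + list(extra[: df.shape[1] - 3])
    return df
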