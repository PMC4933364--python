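"""Regulatory-evidence scoring of fine-mapping candidate variants.

Candidate variants emerging from association testing are prioritised by the
amount of regulatory evidence overlapping their position: open chromatin
(DNase hypersensitivity), histone enhancer/promoter marks in cancer and
normal sources, transcription-factor binding (ChIP-seq), binding-motif
disruption (position-weight-matrix log-odds change between alleles),
vertebrate conservation, and tissue context (colorectal cancer cell lines or
normal colon/rectal tissue).

The a-priori score sums six +1 components and two +0.5 components, for a
maximum of 7 for a non-coding variant.  A coding variant predicted damaging
overrides the sum: "possibly damaging" scores 8, "probably damaging" 9;
benign/unknown coding variants are scored like regulatory variants.
Categories: 3-3.5 = weak, 4-4.5 = moderate, >= 5 = strong.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from intervaltree import IntervalTree

__all__ = [
    "CodingClass",
    "EvidenceRecord",
    "FunctionalScore",
    "GeneContext",
    "GeneModel",
    "TrackBundle",
    "ScoredCandidate",
    "evidence_from_tracks",
    "score_evidence",
    "categorize",
    "assign_gene_context",
    "score_candidate_table",
    "MOTIF_LOD_THRESHOLD",
]

#: |delta log-odds| must strictly exceed this for a motif to count as altered.
MOTIF_LOD_THRESHOLD = 5.0


class CodingClass(str, enum.Enum):
    NONCODING = "noncoding"
    BENIGN = "benign"
    UNKNOWN = "unknown"
    POSSIBLY_DAMAGING = "possibly_damaging"
    PROBABLY_DAMAGING = "probably_damaging"


@dataclass
class EvidenceRecord:
    """Boolean summary of the regulatory evidence at one variant.

    ``binding_in_context`` means protein binding co-located with open
    chromatin or a histone mark; it therefore requires ``protein_binding``.
    ``cancer_normal_differential`` flags a histone-mark pattern that differs
    between cancer-tagged and normal-tagged sources.
    """

    variant_id: str
    histone_mark: bool = False
    open_chromatin: bool = False
    protein_binding: bool = False
    binding_in_context: bool = False
    cancer_normal_differential: bool = False
    colorectal_evidence: bool = False
    motif_altered: bool = False
    conserved: bool = False
    coding_class: CodingClass = CodingClass.NONCODING

    def __post_init__(self) -> None:
        self.coding_class = CodingClass(self.coding_class)
        if self.binding_in_context and not self.protein_binding:
            raise ValueError(
                f"{self.variant_id}: binding_in_context requires protein_binding"
            )


@dataclass(frozen=True)
class FunctionalScore:
    variant_id: str
    score: float
    category: str  # none | weak | moderate | strong


def categorize(score: float) -> str:
    """Map a functional-evidence score to its strength category."""
    if score >= 5:
        return "strong"
    if 4 <= score <= 4.5:
        return "moderate"
    if 3 <= score <= 3.5:
        return "weak"
    return "none"


def score_evidence(record: EvidenceRecord) -> FunctionalScore:
    """Apply the a-priori evidence-summing algorithm to one variant.

    Damaging coding predictions override the regulatory sum (8 possibly,
    9 probably damaging); benign/unknown coding variants fall through to the
    regulatory sum, since a sequence can be exonic in one tissue and an
    enhancer in another.
    """
    if record.coding_class is CodingClass.POSSIBLY_DAMAGING:
        return FunctionalScore(record.variant_id, 8.0, categorize(8.0))
    if record.coding_class is CodingClass.PROBABLY_DAMAGING:
        return FunctionalScore(record.variant_id, 9.0, categorize(9.0))
    score = float(
        record.histone_mark
        + record.open_chromatin
        + record.protein_binding
        + record.binding_in_context
        + record.cancer_normal_differential
        + record.colorectal_evidence
    )
    score += 0.5 * record.motif_altered + 0.5 * record.conserved
    return FunctionalScore(record.variant_id, score, categorize(score))


# ---------------------------------------------------------------------------
# Track bundle -> evidence
# ---------------------------------------------------------------------------

#: assay labels used in the BED name field: assay|source|cancer/normal|crc-flag
ASSAY_OPEN = "open_chromatin"
ASSAY_HISTONE = "histone"
ASSAY_BINDING = "protein_binding"
ASSAY_CONSERVED = "conserved"

_ASSAY_ATTR = {
    ASSAY_OPEN: "open_chromatin_bed",
    ASSAY_HISTONE: "histone_bed",
    ASSAY_BINDING: "binding_bed",
    ASSAY_CONSERVED: "conserved_bed",
}


@dataclass
class TrackBundle:
    """Paths to the local annotation evidence files.

    BED name fields encode ``source|cancer_status|colorectal_flag`` where
    cancer_status is ``cancer`` or ``normal`` and colorectal_flag is ``crc``
    or ``other``.  The motif TSV has columns variant_id, ref_lod, alt_lod;
    the PolyPhen TSV has variant_id, class.
    """

    open_chromatin_bed: Path | None = None
    histone_bed: Path | None = None
    binding_bed: Path | None = None
    conserved_bed: Path | None = None
    motif_tsv: Path | None = None
    polyphen_tsv: Path | None = None

    _trees: dict = field(default_factory=dict, repr=False)
    _motifs: dict | None = field(default=None, repr=False)
    _polyphen: dict | None = field(default=None, repr=False)

    def tree(self, which: str) -> Mapping[str, IntervalTree]:
        if which not in self._trees:
            path = getattr(self, _ASSAY_ATTR[which])
            self._trees[which] = _read_bed_tracks(path) if path else {}
        return self._trees[which]

    def motifs(self) -> Mapping[str, float]:
        if self._motifs is None:
            self._motifs = {}
            if self.motif_tsv and Path(self.motif_tsv).exists():
                df = pd.read_csv(self.motif_tsv, sep="\t")
                for row in df.itertuples(index=False):
                    self._motifs[str(row.variant_id)] = abs(
                        float(row.ref_lod) - float(row.alt_lod)
                    )
        return self._motifs

    def polyphen(self) -> Mapping[str, CodingClass]:
        if self._polyphen is None:
            self._polyphen = {}
            if self.polyphen_tsv and Path(self.polyphen_tsv).exists():
                df = pd.read_csv(self.polyphen_tsv, sep="\t")
                for vid, cls in zip(df["variant_id"], df["class"]):
                    self._polyphen[str(vid)] = CodingClass(cls)
        return self._polyphen


def _read_bed_tracks(path: Path | str) -> dict[str, IntervalTree]:
    """Parse a BED file (0-based half-open) into per-chromosome trees.

    The interval payload is the parsed name field tuple
    (source, cancer_status, colorectal_flag).
    """
    trees: dict[str, IntervalTree] = {}
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: malformed BED line: {line!r}")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer BED coordinates") from exc
            if end <= start:
                raise ValueError(f"{path}:{lineno}: empty/inverted BED interval")
            name = fields[3] if len(fields) > 3 else "unknown|normal|other"
            parts = (name.split("|") + ["normal", "other"])[:3]
            trees.setdefault(chrom, IntervalTree()).addi(start, end, tuple(parts))
    return trees


def _overlaps(trees: Mapping[str, IntervalTree], chrom: str, pos: int):
    """Intervals overlapping a 1-based point position."""
    tree = trees.get(chrom)
    if tree is None:
        return []
    return sorted(tree[pos - 1])  # 1-based point -> 0-based coordinate


def evidence_from_tracks(variant, tracks: TrackBundle) -> EvidenceRecord:
    """Assemble the evidence record for one variant from local track files.

    ``variant`` needs ``variant_id``, ``chrom`` and ``pos`` (1-based)
    attributes.  Booleans are set by point-in-interval overlap; the
    cancer/normal differential fires when histone overlap status disagrees
    between cancer-tagged and normal-tagged sources; a motif is altered when
    the absolute log-odds change strictly exceeds 5.
    """
    vid = str(variant.variant_id)
    chrom, pos = str(variant.chrom), int(variant.pos)

    missing = [
        which
        for which in (ASSAY_OPEN, ASSAY_HISTONE, ASSAY_BINDING, ASSAY_CONSERVED)
        if getattr(tracks, _ASSAY_ATTR[which]) is None
    ]
    if missing:
        warnings.warn(
            f"track bundle missing {missing}; corresponding evidence defaults to False",
            stacklevel=2,
        )

    open_hits = _overlaps(tracks.tree(ASSAY_OPEN), chrom, pos)
    histone_hits = _overlaps(tracks.tree(ASSAY_HISTONE), chrom, pos)
    binding_hits = _overlaps(tracks.tree(ASSAY_BINDING), chrom, pos)
    conserved_hits = _overlaps(tracks.tree(ASSAY_CONSERVED), chrom, pos)

    open_chromatin = bool(open_hits)
    histone_mark = bool(histone_hits)
    protein_binding = bool(binding_hits)
    cancer_histone = any(iv.data[1] == "cancer" for iv in histone_hits)
    normal_histone = any(iv.data[1] == "normal" for iv in histone_hits)
    colorectal = any(
        iv.data[2] == "crc" for iv in open_hits + histone_hits + binding_hits
    )
    delta_lod = tracks.motifs().get(vid, 0.0)
    coding = tracks.polyphen().get(vid, CodingClass.NONCODING)

    return EvidenceRecord(
        variant_id=vid,
        histone_mark=histone_mark,
        open_chromatin=open_chromatin,
        protein_binding=protein_binding,
        binding_in_context=protein_binding and (open_chromatin or histone_mark),
        cancer_normal_differential=cancer_histone != normal_histone,
        colorectal_evidence=colorectal,
        motif_altered=delta_lod > MOTIF_LOD_THRESHOLD,
        conserved=bool(conserved_hits),
        coding_class=coding,
    )


# ---------------------------------------------------------------------------
# Gene context
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneModel:
    name: str
    chrom: str
    start: int  # 1-based inclusive
    end: int
    strand: str  # '+' or '-'
    exons: tuple = ()  # (start, end) 1-based inclusive pairs


@dataclass(frozen=True)
class GeneContext:
    variant_id: str
    location_class: str  # intronic | exonic | intergenic | no_gene
    predicted_gene: str | None
    orientation: str | None  # within | upstream_5prime | downstream_3prime


def assign_gene_context(variant, gene_models: Sequence[GeneModel]) -> GeneContext:
    """Predict the regulated gene by proximity and 5'/3' orientation.

    A variant inside a gene body is assigned that gene (exonic if it overlaps
    an exon, else intronic).  An intergenic variant is assigned the gene with
    the nearest transcript end; the orientation is 5' or 3' relative to that
    gene's strand.
    """
    vid = str(variant.variant_id)
    chrom, pos = str(variant.chrom), int(variant.pos)
    on_chrom = [g for g in gene_models if g.chrom == chrom]
    if not on_chrom:
        return GeneContext(vid, "no_gene", None, None)

    for gene in on_chrom:
        if gene.start <= pos <= gene.end:
            exonic = any(s <= pos <= e for s, e in gene.exons)
            return GeneContext(vid, "exonic" if exonic else "intronic", gene.name, "within")

    # nearest transcript end wins; ties broken by gene name for determinism
    best = min(
        on_chrom,
        key=lambda g: (min(abs(pos - g.start), abs(pos - g.end)), g.name),
    )
    before = pos < best.start  # variant on the low-coordinate side
    if best.strand == "+":
        orientation = "upstream_5prime" if before else "downstream_3prime"
    else:
        orientation = "downstream_3prime" if before else "upstream_5prime"
    return GeneContext(vid, "intergenic", best.name, orientation)


# ---------------------------------------------------------------------------
# Candidate-table summary
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ScoredCandidate:
    variant_id: str
    locus: str
    index_snp: str
    record: EvidenceRecord
    score: FunctionalScore
    location_class: str | None = None


def score_candidate_table(candidates: Iterable[ScoredCandidate]) -> dict:
    """Tabulate a scored candidate set.

    Returns counts by category, by genomic location, the number of
    motif-altering candidates, the distinct loci carrying a strong candidate,
    and the loci where the index SNP itself is a strong candidate.
    """
    candidates = list(candidates)
    by_category: dict[str, int] = {"none": 0, "weak": 0, "moderate": 0, "strong": 0}
    by_location: dict[str, int] = {}
    motif_altered = 0
    strong_loci: set[str] = set()
    index_strong_loci: set[str] = set()
    for cand in candidates:
        by_category[cand.score.category] += 1
        if cand.location_class:
            by_location[cand.location_class] = by_location.get(cand.location_class, 0) + 1
        if cand.record.motif_altered:
            motif_altered += 1
        if cand.score.category == "strong":
            strong_loci.add(cand.locus)
            if cand.variant_id == cand.index_snp:
                index_strong_loci.add(cand.locus)
    return {
        "n_candidates": len(candidates),
        "by_category": by_category,
        "by_location": by_location,
        "n_motif_altered": motif_altered,
        "strong_loci": sorted(strong_loci),
        "n_strong_loci": len(strong_loci),
        "index_strong_loci": sorted(index_strong_loci),
        "n_index_strong_loci": len(index_strong_loci),
    }
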