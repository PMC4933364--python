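"""Region construction, top-SNP identification, conditional scans, and
annotation-candidate selection.

A fine-mapping region spans 250 kb up- and downstream of an index SNP
(500 kb total).  Within a region the "top SNP" is the variant with the
smallest meta-analysis P-value.  Independent-signal search re-tests every
other variant with the top SNP as an additional covariate (two variants per
model) against a per-region Bonferroni threshold of 0.05 divided by the
number of SNPs in the region.

The annotation candidate set follows four rules plus the conditional rule:
1) the top SNP, 2) the index SNP, 3) any of the region's ten smallest-P
variants with r2 > 0.5 to the index SNP, 4) any variant in perfect LD
(r2 = 1) with a variant from rules 1-3; and any variant with conditional
meta P <= 5e-5 together with its perfect proxies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .association import run_region_scan
from .ld_reference import MonomorphicVariantError, perfect_proxies, r2_haplotypes
from .meta_analysis import MetaResult, ivw_fixed, meta_by_variant

__all__ = [
    "Region",
    "CandidateSet",
    "ConditionalResult",
    "build_region",
    "find_top_snp",
    "unify_top_snps",
    "conditional_scan",
    "select_annotation_set",
    "DEFAULT_FLANK",
    "CONDITIONAL_P_THRESHOLD",
]

DEFAULT_FLANK = 250_000
CONDITIONAL_P_THRESHOLD = 5e-5
TOP_K = 10
R2_INDEX_THRESHOLD = 0.5


@dataclass(frozen=True)
class Region:
    """A 500-kb fine-mapping window centred on an index SNP."""

    index_snp: str
    chrom: str
    start: int  # 1-based inclusive
    end: int
    variants: tuple  # variant ids, genome order
    truncated: bool = False

    @property
    def n_snps(self) -> int:
        return len(self.variants)

    @property
    def alpha_region(self) -> float:
        return 0.05 / self.n_snps


@dataclass(frozen=True)
class ConditionalResult:
    variant_id: str
    beta_cond: float
    se_cond: float
    p_cond: float
    alpha_region: float
    significant: bool
    estimable: bool = True
    note: str = ""


@dataclass(frozen=True)
class CandidateSet:
    region_id: str
    index_snp: str
    top_snp: str
    rule3_members: frozenset  # top-10 variants with r2 > 0.5 to the index
    rule4_members: frozenset  # perfect proxies of rules 1-3
    conditional_members: frozenset  # conditional P <= 5e-5 plus proxies
    index_in_scan: bool = True

    @property
    def members(self) -> frozenset:
        return (
            frozenset({self.top_snp, self.index_snp})
            | self.rule3_members
            | self.rule4_members
            | self.conditional_members
        )


def build_region(
    index_variant,
    variants: Sequence,
    flank: int = DEFAULT_FLANK,
    chrom_length: int | None = None,
) -> Region:
    """Collect all variants within ``flank`` bp of the index SNP.

    ``variants`` is a genome-ordered sequence of objects with ``variant_id``,
    ``chrom`` and ``pos``; the index SNP must be among them.  Regions
    touching a chromosome end are clipped (start at 1, end at the chromosome
    length) and flagged truncated rather than rejected.
    """
    idx = None
    for v in variants:
        if v.variant_id == index_variant.variant_id:
            idx = v
            break
    if idx is None:
        raise KeyError(f"index SNP {index_variant.variant_id!r} not in variant list")
    start = idx.pos - flank
    end = idx.pos + flank
    truncated = False
    if start < 1:
        start, truncated = 1, True
    if chrom_length is not None and end > chrom_length:
        end, truncated = chrom_length, True
    members = tuple(
        v.variant_id
        for v in variants
        if v.chrom == idx.chrom and start <= v.pos <= end
    )
    return Region(
        index_snp=idx.variant_id,
        chrom=idx.chrom,
        start=start,
        end=end,
        variants=members,
        truncated=truncated,
    )


def find_top_snp(
    meta_results: Sequence[MetaResult],
    positions: Mapping[str, int] | None = None,
) -> str:
    """Variant with the smallest meta-analysis P-value.

    Ties break deterministically: smallest P, then largest |beta|, then
    smallest genomic position (then variant id, should positions be absent).
    """
    usable = [m for m in meta_results if np.isfinite(m.p_meta)]
    if not usable:
        raise ValueError("no converged meta results to rank")
    pos = positions or {}

    def key(m: MetaResult):
        return (m.p_meta, -abs(m.beta_meta), pos.get(m.variant_id, 0), m.variant_id)

    return min(usable, key=key).variant_id


def unify_top_snps(region_tops: Iterable[tuple]) -> list[dict]:
    """Collapse overlapping regions that share a top SNP.

    ``region_tops`` yields (index_snp, top_snp) or (index_snp, top_snp,
    locus) tuples, one per region.  Returns one entry per unique top SNP
    with all its index SNPs attached, in first-seen order.
    """
    order: list[str] = []
    grouped: dict[str, dict] = {}
    for item in region_tops:
        index_snp, top_snp = item[0], item[1]
        locus = item[2] if len(item) > 2 else None
        if top_snp not in grouped:
            grouped[top_snp] = {"top_snp": top_snp, "index_snps": [], "loci": []}
            order.append(top_snp)
        grouped[top_snp]["index_snps"].append(index_snp)
        if locus is not None and locus not in grouped[top_snp]["loci"]:
            grouped[top_snp]["loci"].append(locus)
    return [grouped[t] for t in order]


def conditional_scan(
    study_data: Sequence,
    region: Region,
    top: str,
    alpha_region: float | None = None,
) -> list[ConditionalResult]:
    """Per-variant association conditioned on the region's top SNP.

    For every non-top variant, each study is refitted with the top-SNP
    dosage appended to the covariates (two variants per model); the
    per-study conditional estimates are then meta-analysed.  Variants in
    perfect LD with the top SNP are flagged non-estimable rather than
    silently dropped.  Significance uses the per-region Bonferroni level
    0.05 / n_snps.
    """
    if region.n_snps < 2:
        raise ValueError("conditional scan needs a region with >= 2 variants")
    if top not in region.variants:
        raise KeyError(f"top SNP {top!r} not in region")
    alpha = alpha_region if alpha_region is not None else region.alpha_region

    others = [v for v in region.variants if v != top]
    per_study: list[list] = []
    collinear = set()
    for study in study_data:
        index = {v: i for i, v in enumerate(study.variant_ids)}
        if top not in index:
            continue
        top_dos = study.dosages[:, index[top]]
        for vid in others:
            if vid in index and np.ptp(study.dosages[:, index[vid]]) > 0:
                c = np.corrcoef(study.dosages[:, index[vid]], top_dos)[0, 1]
                if abs(c) > 0.99999:
                    collinear.add(vid)
        per_study.append(
            run_region_scan(study, variant_ids=others, extra_covariate=top_dos)
        )

    results = []
    metas = {m.variant_id: m for m in meta_by_variant(per_study)} if per_study else {}
    for vid in others:
        if vid in collinear or vid not in metas:
            results.append(
                ConditionalResult(
                    variant_id=vid,
                    beta_cond=float("nan"),
                    se_cond=float("nan"),
                    p_cond=float("nan"),
                    alpha_region=alpha,
                    significant=False,
                    estimable=False,
                    note="collinear_with_top" if vid in collinear else "no_converged_fit",
                )
            )
            continue
        m = metas[vid]
        results.append(
            ConditionalResult(
                variant_id=vid,
                beta_cond=m.beta_meta,
                se_cond=m.se_meta,
                p_cond=m.p_meta,
                alpha_region=alpha,
                significant=bool(m.p_meta <= alpha),
            )
        )
    return results


def select_annotation_set(
    region: Region,
    meta_results: Sequence[MetaResult],
    panel,
    conditional_results: Sequence[ConditionalResult] = (),
    positions: Mapping[str, int] | None = None,
    top_k: int = TOP_K,
    r2_threshold: float = R2_INDEX_THRESHOLD,
    conditional_p: float = CONDITIONAL_P_THRESHOLD,
) -> CandidateSet:
    """Assemble the annotation candidate set for one region.

    Rules 1-4 plus the conditional rule (see module docstring).  The index
    SNP is always a member even if QC removed it from the scan (flagged via
    ``index_in_scan``).  Rule-4 closure is applied once; r2 = 1 is an
    equivalence relation on a fixed panel, so proxies of proxies add
    nothing further.
    """
    if not meta_results:
        raise ValueError("meta_results must be nonempty")
    usable = [m for m in meta_results if np.isfinite(m.p_meta)]
    top = find_top_snp(usable, positions)
    scanned = {m.variant_id for m in usable}
    index_in_scan = region.index_snp in scanned

    # rule 3: among the 10 smallest-P variants, those with r2 > 0.5 to the index
    ranked = sorted(
        usable,
        key=lambda m: (m.p_meta, -abs(m.beta_meta), (positions or {}).get(m.variant_id, 0)),
    )
    top10 = [m.variant_id for m in ranked[:top_k]]
    rule3 = set()
    if region.index_snp in panel._index and not panel.monomorphic[panel._index[region.index_snp]]:
        index_col = panel.column(region.index_snp)
        for vid in top10:
            if vid == region.index_snp or vid not in panel._index:
                continue
            try:
                r2 = r2_haplotypes(index_col, panel.column(vid))
            except MonomorphicVariantError:
                continue
            if r2 > r2_threshold:
                rule3.add(vid)

    # conditional rule: meta-analysed conditional P <= 5e-5
    conditional = {
        c.variant_id
        for c in conditional_results
        if c.estimable and np.isfinite(c.p_cond) and c.p_cond <= conditional_p
    }

    # rule 4: perfect proxies (within the region) of every member so far
    seeds = {top, region.index_snp} | rule3
    in_region = set(region.variants)

    def proxies_of(members):
        out = set()
        for vid in sorted(members):
            if vid not in panel._index or panel.monomorphic[panel._index[vid]]:
                continue
            out |= perfect_proxies(vid, panel, candidates=in_region)
        return out

    rule4 = proxies_of(seeds) - seeds
    cond_proxies = proxies_of(conditional) - conditional if conditional else set()
    conditional = conditional | cond_proxies

    return CandidateSet(
        region_id=f"{region.chrom}:{region.start}-{region.end}",
        index_snp=region.index_snp,
        top_snp=top,
        rule3_members=frozenset(rule3),
        rule4_members=frozenset(rule4),
        conditional_members=frozenset(conditional),
        index_in_scan=index_in_scan,
    )
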