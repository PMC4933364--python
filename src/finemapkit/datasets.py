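"""Curated worked-example tables from a published colorectal-cancer
fine-mapping analysis, shipped as small TSVs.

Two tables are provided: per-region bookkeeping for 31 fine-mapped
GWAS regions (index SNP, number of SNPs in the 500-kb window, the region's
top SNP and its r2 with the index SNP), and the evidence profile of the 21
candidate variants reported with strong regulatory evidence at 12 loci.
They serve as demonstration inputs and as validation fixtures for the
bucketing and scoring code.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .functional_scoring import (
    EvidenceRecord,
    ScoredCandidate,
    score_evidence,
)

__all__ = [
    "load_region_top_snps",
    "load_strong_candidate_evidence",
    "evidence_records_from_candidates",
    "scored_candidates",
]


def _data_path(name: str):
    return resources.files("finemapkit.data").joinpath(name)


def load_region_top_snps() -> pd.DataFrame:
    """31 fine-mapped regions: index SNP, region SNP count, top SNP, r2.

    The ``r2_with_index`` column keeps values below the reporting floor as
    the string ``"<0.2"``; ``r2_value`` carries the parsed representation
    (float, or an (lo, hi) interval tuple for floored entries) accepted by
    :func:`finemapkit.ld_reference.bucket_r2`.
    """
    with resources.as_file(_data_path("region_top_snps.tsv")) as path:
        df = pd.read_csv(path, sep="\t", dtype={"r2_with_index": str})
    df["r2_value"] = [
        (0.0, 0.2) if v.strip() == "<0.2" else float(v) for v in df["r2_with_index"]
    ]
    return df


def load_strong_candidate_evidence() -> pd.DataFrame:
    """Evidence columns for the 21 strong regulatory candidates at 12 loci."""
    with resources.as_file(_data_path("strong_candidate_evidence.tsv")) as path:
        return pd.read_csv(path, sep="\t")


def evidence_records_from_candidates(df: pd.DataFrame) -> list[EvidenceRecord]:
    """Translate the printed evidence columns into EvidenceRecords.

    Histone marks count from any source (cancer cell lines, normal cell
    lines, or normal colorectal tissue); colorectal evidence is any assay in
    a colorectal cancer cell line or normal colon/rectal tissue.  The
    published table reports no per-variant cancer-vs-normal differential
    indicator, so that component is left unset here: the scores below are
    computed from the printed columns only.
    """
    records = []
    for row in df.itertuples(index=False):
        histone = (
            row.n_histone_cancer_cell_lines
            + row.n_histone_normal_cell_lines
            + row.n_histone_colorectal_tissues
        ) > 0
        open_chromatin = row.n_open_chromatin_cell_lines > 0
        protein = bool(str(row.proteins_bound).strip()) and str(row.proteins_bound) != "-"
        colorectal = bool(
            row.open_in_crc_cell_line
            or row.binding_in_crc_cell_line
            or row.n_histone_colorectal_tissues > 0
        )
        records.append(
            EvidenceRecord(
                variant_id=row.variant_id,
                histone_mark=bool(histone),
                open_chromatin=bool(open_chromatin),
                protein_binding=protein,
                binding_in_context=protein and (open_chromatin or histone),
                cancer_normal_differential=False,
                colorectal_evidence=colorectal,
                motif_altered=bool(row.motif_altered),
                conserved=bool(row.conserved),
            )
        )
    return records


def scored_candidates() -> list[ScoredCandidate]:
    """The curated candidate table, scored with the a-priori algorithm."""
    df = load_strong_candidate_evidence()
    records = evidence_records_from_candidates(df)
    out = []
    for row, rec in zip(df.itertuples(index=False), records):
        out.append(
            ScoredCandidate(
                variant_id=row.variant_id,
                locus=row.locus,
                index_snp=row.index_snp,
                record=rec,
                score=score_evidence(rec),
                location_class=row.location,
            )
        )
    return out
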