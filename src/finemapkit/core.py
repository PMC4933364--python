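"""Shared lightweight domain types."""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class Variant:
    """A biallelic variant: identity, coordinate, alleles, and QC metadata."""

    variant_id: str
    chrom: str
    pos: int  # 1-based
    ref: str = "A"
    alt: str = "G"
    maf: float | None = None
    rsq: float | None = None
    source: str = "genotyped"  # genotyped | imputed
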