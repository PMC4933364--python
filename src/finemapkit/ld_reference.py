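"""Pairwise linkage disequilibrium (r-squared) from a phased haplotype panel.

r2 here is the squared correlation of allelic indicators counted directly on
phased haplotypes, the quantity candidate-selection rules threshold on
(r2 > 0.5 with the index SNP; r2 = 1 for perfect proxies).
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "MonomorphicVariantError",
    "r2_haplotypes",
    "r2_matrix",
    "perfect_proxies",
    "bucket_r2",
    "R2_BUCKET_EDGES",
]

R2_BUCKET_EDGES = (0.2, 0.4, 0.6, 0.8)


class MonomorphicVariantError(ValueError):
    """LD is undefined for a monomorphic variant (zero variance)."""


def _as_binary(h) -> np.ndarray:
    arr = np.asarray(h)
    if not np.isin(arr, (0, 1)).all():
        raise ValueError("haplotype vectors must be 0/1")
    return arr.astype(float)


def r2_haplotypes(h_a: Sequence[int], h_b: Sequence[int]) -> float:
    """Haplotype r2 between two phased 0/1 vectors.

    r2 = (p_AB - p_A p_B)^2 / (p_A(1-p_A) p_B(1-p_B)) with haplotype
    frequencies counted directly.  Raises MonomorphicVariantError when either
    vector is constant, where LD is undefined (not zero).
    """
    a, b = _as_binary(h_a), _as_binary(h_b)
    if a.shape != b.shape:
        raise ValueError("haplotype vectors must have equal length")
    if a.size < 4:
        raise ValueError("need at least 4 haplotypes")
    p_a, p_b = a.mean(), b.mean()
    if p_a in (0.0, 1.0) or p_b in (0.0, 1.0):
        raise MonomorphicVariantError("r2 undefined for a monomorphic variant")
    p_ab = (a * b).mean()
    d = p_ab - p_a * p_b
    return float(d * d / (p_a * (1 - p_a) * p_b * (1 - p_b)))


def r2_matrix(haplotypes: np.ndarray) -> np.ndarray:
    """All-pairs r2 for a (n_hap x n_variants) 0/1 matrix.

    Monomorphic columns yield NaN rows/columns rather than an error, so the
    matrix form stays usable on raw panels.
    """
    h = np.asarray(haplotypes, dtype=float)
    p = h.mean(axis=0)
    centred = h - p
    denom = np.sqrt((centred**2).sum(axis=0))
    poly = denom > 0
    corr = np.full((h.shape[1], h.shape[1]), np.nan)
    if poly.any():
        unit = centred[:, poly] / denom[poly]
        sub = unit.T @ unit
        corr[np.ix_(poly, poly)] = sub**2
    return corr


def perfect_proxies(
    variant_id: str,
    panel,
    candidates: Iterable[str] | None = None,
) -> set[str]:
    """Candidates in perfect LD (r2 = 1) with ``variant_id`` on the panel.

    On a phased 0/1 panel, r2 = 1 holds exactly when a candidate's haplotype
    column equals the query column or its complement; the query variant
    itself is excluded.
    """
    col = panel.column(variant_id).astype(np.uint8)
    if col.min() == col.max():
        raise MonomorphicVariantError(f"{variant_id} is monomorphic in the panel")
    comp = 1 - col
    if candidates is None:
        candidates = panel.variant_ids
    out = set()
    for cand in candidates:
        if cand == variant_id:
            continue
        other = panel.column(cand).astype(np.uint8)
        if np.array_equal(other, col) or np.array_equal(other, comp):
            out.add(cand)
    return out


def bucket_r2(values: Iterable, edges: Sequence[float] = R2_BUCKET_EDGES) -> list[int]:
    """Count r2 values into left-closed bins [<e0, e0-e1, ..., >=e_last].

    With the default edges the bins are [0,0.2), [0.2,0.4), [0.4,0.6),
    [0.6,0.8), [0.8,1].  A value may also be an (lo, hi) interval — e.g. a
    published "r2 < 0.2" entry — provided the whole interval [lo, hi) sits in
    a single bin.
    """
    edges = np.asarray(edges, dtype=float)
    counts = [0] * (len(edges) + 1)
    for v in values:
        if isinstance(v, tuple):
            lo, hi = float(v[0]), float(v[1])
            b_lo = int(np.searchsorted(edges, lo, side="right"))
            # hi is an exclusive bound, so classify the last value just below it
            b_hi = int(np.searchsorted(edges, np.nextafter(hi, lo), side="right"))
            if b_lo != b_hi:
                raise ValueError(f"interval {v} spans multiple r2 bins")
            counts[b_lo] += 1
        else:
            v = float(v)
            if not 0 <= v <= 1:
                raise ValueError(f"r2 value {v} outside [0,1]")
            counts[int(np.searchsorted(edges, v, side="right"))] += 1
    return counts
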