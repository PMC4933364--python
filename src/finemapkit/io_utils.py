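"""Readers and writers for the pipeline's exchange formats.

Study genotype data travel as VCF with per-sample GT and DS (dosage) fields
and per-variant INFO keys for allele frequency and imputation quality;
phenotypes/covariates as headered TSV; association and meta-analysis results
as TSVs whose column names match what LocusZoom expects.
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "write_study_vcf",
    "read_dosage_vcf",
    "write_phenotype_tsv",
    "read_phenotype_tsv",
    "write_assoc_tsv",
    "write_meta_tsv",
    "sha256_of",
]

ASSOC_COLUMNS = ["CHR", "POS", "SNP", "REF", "ALT", "BETA", "SE", "P", "N_CASES", "N_CONTROLS"]


def write_study_vcf(study, panel, path) -> Path:
    """Write one study's dosages as a VCF with GT and DS per sample.

    GT is the hard call (rounded dosage); DS preserves the fractional
    dosage.  INFO carries AF (panel alternate-allele frequency), RSQ
    (empirical imputation quality) and TYPED for directly genotyped
    variants.
    """
    path = Path(path)
    meta = study.variant_meta
    rsq = dict(zip(meta["variant_id"], meta["rsq"])) if meta is not None else {}
    source = dict(zip(meta["variant_id"], meta["source"])) if meta is not None else {}
    af = panel.allele_freq()
    samples = study.subject_ids or [f"s{i + 1}" for i in range(len(study.phenotype))]
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={panel.chrom}>\n")
        fh.write('##INFO=<ID=AF,Number=1,Type=Float,Description="Alternate allele frequency">\n')
        fh.write('##INFO=<ID=RSQ,Number=1,Type=Float,Description="Imputation quality">\n')
        fh.write('##INFO=<ID=TYPED,Number=0,Type=Flag,Description="Directly genotyped">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Dosage">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples) + "\n")
        for j, vid in enumerate(study.variant_ids):
            pj = panel._index[vid]
            ref, alt = panel.alleles[pj]
            info = f"AF={af[pj]:.6g};RSQ={rsq.get(vid, 1.0):.6g}"
            if source.get(vid, "genotyped") == "genotyped":
                info += ";TYPED"
            dos = study.dosages[:, j]
            hard = np.rint(dos).astype(int)
            cells = "\t".join(
                f"{'0/0' if h == 0 else ('0/1' if h == 1 else '1/1')}:{d:.3f}"
                for h, d in zip(hard, dos)
            )
            fh.write(
                f"{panel.chrom}\t{panel.positions[pj]}\t{vid}\t{ref}\t{alt}\t.\tPASS\t{info}\tGT:DS\t{cells}\n"
            )
    return path


def read_dosage_vcf(path, rsq_key: str = "RSQ"):
    """Read a dosage VCF back: (variant table, dosage matrix, sample ids).

    Uses pysam; the imputation-quality INFO key is configurable since
    imputation tools differ in what they call it.
    """
    import pysam

    variants = []
    dosages = []
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        for rec in vcf:
            info = dict(rec.info)
            variants.append(
                {
                    "variant_id": rec.id,
                    "chrom": rec.chrom,
                    "pos": rec.pos,
                    "ref": rec.ref,
                    "alt": rec.alts[0] if rec.alts else ".",
                    "af": float(info.get("AF", np.nan)),
                    "rsq": float(info.get(rsq_key, np.nan)),
                    "source": "genotyped" if info.get("TYPED", False) else "imputed",
                }
            )
            dosages.append([rec.samples[s]["DS"] for s in samples])
    table = pd.DataFrame(variants)
    return table, np.asarray(dosages, dtype=float).T, samples


def write_phenotype_tsv(study, path) -> Path:
    path = Path(path)
    cov = study.covariates
    df = pd.DataFrame(
        {
            "study_id": study.study_id,
            "subject_id": study.subject_ids,
            "status": study.phenotype,
        }
    )
    for i, name in enumerate(study.covariate_names):
        df[name] = cov[:, i] if cov is not None else np.nan
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
    return path


def read_phenotype_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def _result_rows(results, variant_info):
    for r in results:
        v = variant_info.get(r.variant_id, {})
        yield {
            "CHR": v.get("chrom", "."),
            "POS": v.get("pos", 0),
            "SNP": r.variant_id,
            "REF": v.get("ref", "."),
            "ALT": v.get("alt", "."),
        }


def write_assoc_tsv(results, variant_info, path) -> Path:
    """Per-study association results, LocusZoom-compatible columns."""
    rows = []
    for base, r in zip(_result_rows(results, variant_info), results):
        base.update(
            BETA=r.beta,
            SE=r.se,
            P=r.p,
            N_CASES=r.n_cases,
            N_CONTROLS=r.n_controls,
            CONVERGED=int(r.converged),
        )
        rows.append(base)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.6g")
    return Path(path)


def write_meta_tsv(results, variant_info, path) -> Path:
    """Meta-analysis TSV: association columns plus Q, P_HET, K."""
    rows = []
    for base, m in zip(_result_rows(results, variant_info), results):
        lo, hi = m.ci()
        base.update(
            BETA=m.beta_meta,
            SE=m.se_meta,
            OR=m.odds_ratio,
            CI_LOW=lo,
            CI_HIGH=hi,
            P=m.p_meta,
            Q=m.q,
            P_HET=m.p_het,
            K=m.k,
        )
        rows.append(base)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.6g")
    return Path(path)


def sha256_of(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()
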