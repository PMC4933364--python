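"""End-to-end orchestration: simulate -> qc -> assoc -> meta -> finemap ->
annotate -> score -> power.

Every stage reads its inputs from files written by the previous stage
(VCF/TSV/BED), writes its own outputs into the run directory, and reruns
byte-identically under the same config and seed.  The manifest records, per
stage, the output paths, the variant counts surviving, and file checksums.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io_utils
from .association import AssocResult, fit_logistic_dosage
from .core import Variant
from .fine_mapping import build_region, conditional_scan, find_top_snp, select_annotation_set
from .functional_scoring import EvidenceRecord, TrackBundle, evidence_from_tracks, score_evidence
from .meta_analysis import ivw_fixed
from .power import power_curve
from .quality_control import filter_genotyped, filter_imputed, VariantQCStats
from .synthetic_data import (
    HaplotypePanel,
    SimulationDesign,
    StudyDataset,
    simulate_annotation_tracks,
    simulate_case_control,
    simulate_haplotype_panel,
)

__all__ = ["PipelineConfig", "run_pipeline", "STAGES"]

STAGES = ("simulate", "qc", "assoc", "meta", "finemap", "annotate", "score", "power")


@dataclass
class PipelineConfig:
    """Knobs for a full demo-scale pipeline run."""

    seed: int = 0
    # simulation
    n_studies: int = 3
    cases_per_study: int = 300
    controls_per_study: int = 300
    n_hap: int = 400
    n_variants: int = 120
    region_length: int = 480_000
    pos_offset: int = 1_000_000
    recombination_rate: float = 2e-5
    maf_floor: float = 0.05
    n_founders: int = 8
    causal_variant: str = "auto"  # "auto" = variant closest to the window centre
    index_snp: str = "auto"  # "auto" = the causal variant
    causal_or: float = 1.3
    baseline_prevalence: float = 0.1
    target_rsq: float = 0.95
    background_rate: float = 0.1
    # qc
    call_rate_min: float = 0.98
    hwe_alpha: float = 1e-4
    maf_min: float = 0.005
    rsq_info_key: str = "RSQ"
    # fine-mapping / candidate selection
    flank: int = 250_000
    top_k: int = 10
    r2_threshold: float = 0.5
    conditional_p: float = 5e-5
    # power grid
    power_mafs: tuple = (0.01, 0.05, 0.1, 0.2, 0.3, 0.5)
    power_ors: tuple = (1.05, 1.1, 1.12, 1.2, 1.3, 1.5)
    power_alpha: float = 5e-8

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["power_mafs"] = list(self.power_mafs)
        d["power_ors"] = list(self.power_ors)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline halted in stage {stage!r}: {cause}")
        self.stage = stage


# ---------------------------------------------------------------------------
# helpers shared by stages
# ---------------------------------------------------------------------------


def _panel_path(outdir: Path) -> Path:
    return outdir / "reference_panel.vcf"


def _write_panel_vcf(panel: HaplotypePanel, path: Path) -> Path:
    """Phased reference panel as a VCF (pairs of haplotypes per sample)."""
    n_samp = panel.n_hap // 2
    samples = [f"ref{i + 1:04d}" for i in range(n_samp)]
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={panel.chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Phased genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples) + "\n")
        for j, vid in enumerate(panel.variant_ids):
            ref, alt = panel.alleles[j]
            col = panel.haplotypes[:, j]
            cells = "\t".join(f"{col[2 * i]}|{col[2 * i + 1]}" for i in range(n_samp))
            fh.write(f"{panel.chrom}\t{panel.positions[j]}\t{vid}\t{ref}\t{alt}\t.\tPASS\t.\tGT\t{cells}\n")
    return path


def _read_panel_vcf(path) -> HaplotypePanel:
    import pysam

    ids, positions, alleles, rows = [], [], [], []
    chrom = "1"
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        for rec in vcf:
            chrom = rec.chrom
            ids.append(rec.id)
            positions.append(rec.pos)
            alleles.append((rec.ref, rec.alts[0]))
            row = []
            for s in samples:
                row.extend(rec.samples[s]["GT"])
            rows.append(row)
    haps = np.asarray(rows, dtype=np.uint8).T
    return HaplotypePanel(haps, np.asarray(positions), ids, alleles, chrom=chrom)


def _study_ids(cfg: PipelineConfig) -> list[str]:
    return [f"study{i + 1:02d}" for i in range(cfg.n_studies)]


def _load_study(outdir: Path, study_id: str, rsq_key: str) -> tuple[StudyDataset, pd.DataFrame]:
    table, dosages, samples = io_utils.read_dosage_vcf(outdir / f"{study_id}.vcf", rsq_key=rsq_key)
    pheno = io_utils.read_phenotype_tsv(outdir / f"{study_id}.pheno.tsv")
    pheno = pheno.set_index("subject_id").loc[samples].reset_index()
    cov_names = ("age", "sex", "pc1", "pc2", "pc3")
    meta = pd.DataFrame(
        {"variant_id": table["variant_id"], "maf": np.minimum(table["af"], 1 - table["af"]),
         "rsq": table["rsq"], "source": table["source"]}
    )
    study = StudyDataset(
        study_id=study_id,
        phenotype=pheno["status"].to_numpy(),
        dosages=np.clip(dosages, 0, 2),
        covariates=pheno.loc[:, list(cov_names)].to_numpy(dtype=float),
        variant_ids=list(table["variant_id"]),
        covariate_names=cov_names,
        variant_meta=meta,
        subject_ids=list(pheno["subject_id"]),
    )
    return study, table


def _variant_info(table: pd.DataFrame) -> dict:
    return {
        row.variant_id: {"chrom": row.chrom, "pos": int(row.pos), "ref": row.ref, "alt": row.alt}
        for row in table.itertuples(index=False)
    }


def _kept_variants(outdir: Path) -> list[str]:
    qc = pd.read_csv(outdir / "qc_report.tsv", sep="\t")
    return list(qc.loc[qc["keep"] == 1, "variant_id"])


def _tracks_bundle(outdir: Path) -> TrackBundle:
    t = outdir / "tracks"
    return TrackBundle(
        open_chromatin_bed=t / "open_chromatin.bed",
        histone_bed=t / "histone.bed",
        binding_bed=t / "protein_binding.bed",
        conserved_bed=t / "conserved.bed",
        motif_tsv=t / "motifs.tsv",
        polyphen_tsv=t / "polyphen.tsv",
    )


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------


def stage_simulate(cfg: PipelineConfig, outdir: Path) -> dict:
    panel = simulate_haplotype_panel(
        n_hap=cfg.n_hap,
        n_variants=cfg.n_variants,
        region_length=cfg.region_length,
        recombination_rate=cfg.recombination_rate,
        maf_floor=cfg.maf_floor,
        seed=cfg.seed,
        n_founders=cfg.n_founders,
    )
    panel.positions = panel.positions + cfg.pos_offset

    if cfg.causal_variant == "auto":
        centre = panel.positions[0] + (panel.positions[-1] - panel.positions[0]) // 2
        causal = panel.variant_ids[int(np.argmin(np.abs(panel.positions - centre)))]
    else:
        causal = cfg.causal_variant
    index_snp = causal if cfg.index_snp == "auto" else cfg.index_snp

    design = SimulationDesign(
        n_studies=cfg.n_studies,
        cases_per_study=cfg.cases_per_study,
        controls_per_study=cfg.controls_per_study,
        causal_variant_id=causal,
        causal_or=cfg.causal_or,
        baseline_prevalence=cfg.baseline_prevalence,
        target_rsq=cfg.target_rsq,
        seed=cfg.seed + 1,
    )
    studies = simulate_case_control(panel, design)

    planted = {
        causal: EvidenceRecord(
            variant_id=causal,
            histone_mark=True,
            open_chromatin=True,
            protein_binding=True,
            binding_in_context=True,
            cancer_normal_differential=True,
            colorectal_evidence=True,
            motif_altered=True,
            conserved=True,
        )
    }
    simulate_annotation_tracks(
        panel, planted, outdir / "tracks", seed=cfg.seed + 2, background_rate=cfg.background_rate
    )

    _write_panel_vcf(panel, _panel_path(outdir))
    outputs = [str(_panel_path(outdir))] + [str(outdir / "tracks")]
    for study in studies:
        io_utils.write_study_vcf(study, panel, outdir / f"{study.study_id}.vcf")
        io_utils.write_phenotype_tsv(study, outdir / f"{study.study_id}.pheno.tsv")
        outputs.append(str(outdir / f"{study.study_id}.vcf"))
        outputs.append(str(outdir / f"{study.study_id}.pheno.tsv"))
    truth = {"causal_variant": causal, "index_snp": index_snp, "causal_or": cfg.causal_or}
    (outdir / "truth.json").write_text(json.dumps(truth, indent=1))
    return {"n_variants": panel.n_variants, "n_studies": len(studies), "outputs": outputs}


def stage_qc(cfg: PipelineConfig, outdir: Path) -> dict:
    tables = []
    for sid in _study_ids(cfg):
        table, _, _ = io_utils.read_dosage_vcf(outdir / f"{sid}.vcf", rsq_key=cfg.rsq_info_key)
        tables.append(table)
    # variant metadata is shared; average the per-study empirical Rsq
    base = tables[0]
    rsq = np.mean([t["rsq"].to_numpy() for t in tables], axis=0)
    maf = np.minimum(base["af"], 1 - base["af"]).to_numpy()
    rows = []
    for i, row in enumerate(base.itertuples(index=False)):
        if row.source == "genotyped":
            stats_ = VariantQCStats(row.variant_id, maf=float(maf[i]), source="genotyped")
            dec = filter_genotyped(
                stats_, call_rate_min=cfg.call_rate_min, hwe_alpha=cfg.hwe_alpha, maf_min=cfg.maf_min
            )
        else:
            dec = filter_imputed(float(maf[i]), float(rsq[i]))
        rows.append(
            {
                "variant_id": row.variant_id,
                "maf": maf[i],
                "rsq": rsq[i],
                "source": row.source,
                "keep": int(dec.keep),
                "reasons": ",".join(dec.reasons),
            }
        )
    report = pd.DataFrame(rows)
    report.to_csv(outdir / "qc_report.tsv", sep="\t", index=False, float_format="%.6g")
    return {
        "n_in": len(report),
        "n_out": int(report["keep"].sum()),
        "outputs": [str(outdir / "qc_report.tsv")],
    }


def stage_assoc(cfg: PipelineConfig, outdir: Path) -> dict:
    kept = _kept_variants(outdir)
    outputs = []
    n_fits = 0
    for sid in _study_ids(cfg):
        study, table = _load_study(outdir, sid, cfg.rsq_info_key)
        info = _variant_info(table)
        index = {v: i for i, v in enumerate(study.variant_ids)}
        results = [
            fit_logistic_dosage(
                study.phenotype,
                study.dosages[:, index[vid]],
                covariates=study.covariates,
                variant_id=vid,
                study_id=sid,
            )
            for vid in kept
            if vid in index
        ]
        n_fits += len(results)
        outputs.append(str(io_utils.write_assoc_tsv(results, info, outdir / f"assoc_{sid}.tsv")))
    return {"n_in": len(kept), "n_out": n_fits, "outputs": outputs}


def stage_meta(cfg: PipelineConfig, outdir: Path) -> dict:
    frames = [
        pd.read_csv(outdir / f"assoc_{sid}.tsv", sep="\t") for sid in _study_ids(cfg)
    ]
    by_variant: dict[str, list] = {}
    info = {}
    for frame in frames:
        for row in frame.itertuples(index=False):
            info[row.SNP] = {"chrom": row.CHR, "pos": int(row.POS), "ref": row.REF, "alt": row.ALT}
            if row.CONVERGED and np.isfinite(row.SE) and row.SE > 0:
                by_variant.setdefault(row.SNP, []).append((row.BETA, row.SE))
    metas = [
        ivw_fixed(units, variant_id=vid) for vid, units in by_variant.items() if units
    ]
    path = io_utils.write_meta_tsv(metas, info, outdir / "meta.tsv")
    return {"n_in": len(by_variant), "n_out": len(metas), "outputs": [str(path)]}


def stage_finemap(cfg: PipelineConfig, outdir: Path) -> dict:
    panel = _read_panel_vcf(_panel_path(outdir))
    truth = json.loads((outdir / "truth.json").read_text())
    meta_df = pd.read_csv(outdir / "meta.tsv", sep="\t")
    metas = [
        ivw_fixed([(row.BETA, row.SE)], variant_id=row.SNP)
        for row in meta_df.itertuples(index=False)
    ]
    positions = dict(zip(meta_df["SNP"], meta_df["POS"].astype(int)))

    variants = [
        Variant(vid, panel.chrom, int(panel.positions[j]))
        for j, vid in enumerate(panel.variant_ids)
        if vid in positions  # QC-passing variants only
    ]
    index_variant = Variant(
        truth["index_snp"], panel.chrom, panel.position_of(truth["index_snp"])
    )
    region = build_region(index_variant, variants, flank=cfg.flank)
    top = find_top_snp(metas, positions)

    studies = [
        _load_study(outdir, sid, cfg.rsq_info_key)[0] for sid in _study_ids(cfg)
    ]
    conditionals = conditional_scan(studies, region, top)
    cands = select_annotation_set(
        region,
        metas,
        panel,
        conditional_results=conditionals,
        positions=positions,
        top_k=cfg.top_k,
        r2_threshold=cfg.r2_threshold,
        conditional_p=cfg.conditional_p,
    )

    pd.DataFrame(
        [
            {
                "locus": f"{region.chrom}:{region.start}-{region.end}",
                "index_snp": region.index_snp,
                "chrom": region.chrom,
                "start": region.start,
                "end": region.end,
                "n_snps": region.n_snps,
                "alpha_region": region.alpha_region,
                "truncated": int(region.truncated),
                "top_snp": top,
            }
        ]
    ).to_csv(outdir / "region.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            {
                "variant_id": c.variant_id,
                "beta_cond": c.beta_cond,
                "se_cond": c.se_cond,
                "p_cond": c.p_cond,
                "alpha_region": c.alpha_region,
                "significant": int(c.significant),
                "estimable": int(c.estimable),
                "note": c.note,
            }
            for c in conditionals
        ]
    ).to_csv(outdir / "conditional.tsv", sep="\t", index=False, float_format="%.6g")
    rows = [{"variant_id": cands.top_snp, "rule": "rule1_top_snp"},
            {"variant_id": cands.index_snp, "rule": "rule2_index_snp"}]
    rows += [{"variant_id": v, "rule": "rule3_top10_r2"} for v in sorted(cands.rule3_members)]
    rows += [{"variant_id": v, "rule": "rule4_perfect_proxy"} for v in sorted(cands.rule4_members)]
    rows += [{"variant_id": v, "rule": "conditional"} for v in sorted(cands.conditional_members)]
    pd.DataFrame(rows).to_csv(outdir / "candidates.tsv", sep="\t", index=False)
    outputs = [str(outdir / n) for n in ("region.tsv", "conditional.tsv", "candidates.tsv")]
    return {
        "n_in": region.n_snps,
        "n_out": len(cands.members),
        "top_snp": top,
        "n_conditional_significant": int(sum(c.significant for c in conditionals)),
        "outputs": outputs,
    }


def stage_annotate(cfg: PipelineConfig, outdir: Path) -> dict:
    panel = _read_panel_vcf(_panel_path(outdir))
    cand = pd.read_csv(outdir / "candidates.tsv", sep="\t")
    bundle = _tracks_bundle(outdir)
    rows = []
    for vid in sorted(set(cand["variant_id"])):
        v = Variant(vid, panel.chrom, panel.position_of(vid))
        rec = evidence_from_tracks(v, bundle)
        d = {k: (int(v_) if isinstance(v_, bool) else v_) for k, v_ in rec.__dict__.items()}
        d["coding_class"] = rec.coding_class.value
        rows.append(d)
    pd.DataFrame(rows).to_csv(outdir / "evidence.tsv", sep="\t", index=False)
    return {"n_in": len(set(cand["variant_id"])), "n_out": len(rows), "outputs": [str(outdir / "evidence.tsv")]}


def stage_score(cfg: PipelineConfig, outdir: Path) -> dict:
    ev = pd.read_csv(outdir / "evidence.tsv", sep="\t")
    bool_cols = [
        "histone_mark", "open_chromatin", "protein_binding", "binding_in_context",
        "cancer_normal_differential", "colorectal_evidence", "motif_altered", "conserved",
    ]
    rows = []
    for row in ev.itertuples(index=False):
        rec = EvidenceRecord(
            variant_id=row.variant_id,
            **{c: bool(getattr(row, c)) for c in bool_cols},
            coding_class=row.coding_class,
        )
        fs = score_evidence(rec)
        rows.append({"variant_id": fs.variant_id, "score": fs.score, "category": fs.category})
    scores = pd.DataFrame(rows)
    scores.to_csv(outdir / "scores.tsv", sep="\t", index=False)
    return {
        "n_in": len(ev),
        "n_out": len(scores),
        "n_strong": int((scores["category"] == "strong").sum()),
        "outputs": [str(outdir / "scores.tsv")],
    }


def stage_power(cfg: PipelineConfig, outdir: Path) -> dict:
    rows = power_curve(
        cfg.n_studies * cfg.cases_per_study,
        cfg.n_studies * cfg.controls_per_study,
        cfg.power_mafs,
        cfg.power_ors,
        alpha=cfg.power_alpha,
    )
    pd.DataFrame(rows).to_csv(outdir / "power_curve.tsv", sep="\t", index=False, float_format="%.6g")
    return {"n_in": len(rows), "n_out": len(rows), "outputs": [str(outdir / "power_curve.tsv")]}


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "qc": stage_qc,
    "assoc": stage_assoc,
    "meta": stage_meta,
    "finemap": stage_finemap,
    "annotate": stage_annotate,
    "score": stage_score,
    "power": stage_power,
}


def run_stage(stage: str, cfg: PipelineConfig, outdir) -> dict:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    try:
        return _STAGE_FUNCS[stage](cfg, outdir)
    except Exception as exc:  # halt with stage name; partial outputs stay on disk
        raise StageError(stage, exc) from exc


def run_pipeline(cfg: PipelineConfig, outdir) -> dict:
    """Run every stage in order and write a run manifest.

    Returns the manifest dict (also written to ``manifest.json``): per stage
    the input/output counts, elapsed seconds, output paths and sha256
    checksums of every file output.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(outdir / "config.yaml")
    manifest = {"config": asdict(cfg), "stages": {}}
    for stage in STAGES:
        t0 = time.perf_counter()
        result = run_stage(stage, cfg, outdir)
        result["elapsed_s"] = round(time.perf_counter() - t0, 3)
        checksums = {}
        for out in result.get("outputs", []):
            p = Path(out)
            if p.is_file():
                checksums[p.name] = io_utils.sha256_of(p)
            elif p.is_dir():
                for f in sorted(p.rglob("*")):
                    if f.is_file():
                        checksums[str(f.relative_to(outdir))] = io_utils.sha256_of(f)
        result["checksums"] = checksums
        manifest["stages"][stage] = result
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
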