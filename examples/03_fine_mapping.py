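"""Region scan, top SNP, conditional analysis, and candidate selection.

Scans a fine-mapping region for association, picks the top SNP, re-tests
every other variant conditioned on it (per-region Bonferroni threshold
0.05 / n_snps), and assembles the annotation candidate set from the
selection rules (top SNP, index SNP, correlated top-10 variants, perfect
proxies, conditional hits).
"""

from finemapkit import (
    SimulationDesign,
    Variant,
    build_region,
    conditional_scan,
    find_top_snp,
    meta_by_variant,
    run_region_scan,
    select_annotation_set,
    simulate_case_control,
    simulate_haplotype_panel,
)

panel = simulate_haplotype_panel(
    n_hap=400, n_variants=60, recombination_rate=5e-6, n_founders=4, seed=3
)
panel.positions = panel.positions + 1_000_000
causal = panel.variant_ids[30]

design = SimulationDesign(
    n_studies=2, cases_per_study=1000, controls_per_study=1000,
    causal_variant_id=causal, causal_or=1.5, seed=4,
)
studies = simulate_case_control(panel, design)

variants = [Variant(v, panel.chrom, int(p)) for v, p in zip(panel.variant_ids, panel.positions)]
region = build_region(variants[30], variants)  # 250-kb flank each side
print(f"region {region.chrom}:{region.start}-{region.end}: {region.n_snps} SNPs, "
      f"alpha_region = {region.alpha_region:.2e}")

metas = meta_by_variant([run_region_scan(s, region=region) for s in studies])
positions = dict(zip(panel.variant_ids, panel.positions))
top = find_top_snp(metas, positions)
best = min(m.p_meta for m in metas)
print(f"top SNP: {top} (P = {best:.2e}); planted causal: {causal}")

conditionals = conditional_scan(studies, region, top)
n_sig = sum(c.significant for c in conditionals)
print(f"conditional scan: {n_sig} variants significant after conditioning "
      f"(expected 0 - there is a single planted signal)")

cands = select_annotation_set(region, metas, panel, conditional_results=conditionals,
                              positions=positions)
print(f"candidate set ({len(cands.members)} variants): "
      f"top={cands.top_snp}, index={cands.index_snp}, "
      f"rule3={sorted(cands.rule3_members)}, rule4={sorted(cands.rule4_members)}")
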