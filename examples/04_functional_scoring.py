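"""Score the curated table of published strong regulatory candidates.

Encodes the printed evidence columns of 21 candidate variants at 12
colorectal-cancer GWAS loci as EvidenceRecords, applies the a-priori scoring
algorithm (+1 components for histone marks, open chromatin, protein binding,
binding in regulatory context, cancer/normal differential, colorectal
evidence; +0.5 for altered motifs and conservation), and tabulates the
result.
"""

from finemapkit import score_candidate_table
from finemapkit.datasets import scored_candidates

cands = scored_candidates()
for c in cands[:5]:
    print(f"{c.locus:9s} {c.variant_id:12s} score {c.score.score:.1f} ({c.score.category})")
print("...")

summary = score_candidate_table(cands)
print(f"\n{summary['by_category']['strong']} strong candidates "
      f"in {summary['n_strong_loci']} loci")
print(f"locations: {summary['by_location']}")
print(f"motif-altering: {summary['n_motif_altered']}")
print(f"loci where the index SNP itself is strong: {summary['n_index_strong_loci']} "
      f"({', '.join(summary['index_strong_loci'])})")

# All 21 curated rows reach score >= 5 ("strong"), spread over 12 loci;
# 15 are intronic, 6 intergenic, 15 disrupt a binding motif, and at 4 loci
# the GWAS index SNP itself carries the strongest functional evidence.
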