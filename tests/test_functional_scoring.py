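import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from finemapkit import (
    EvidenceRecord,
    GeneModel,
    Variant,
    assign_gene_context,
    categorize,
    score_candidate_table,
    score_evidence,
)
from finemapkit.datasets import (
    evidence_records_from_candidates,
    load_strong_candidate_evidence,
    scored_candidates,
)
from finemapkit.functional_scoring import ScoredCandidate, TrackBundle, evidence_from_tracks

PLUS_ONE = (
    "histone_mark",
    "open_chromatin",
    "protein_binding",
    "binding_in_context",
    "cancer_normal_differential",
    "colorectal_evidence",
)
PLUS_HALF = ("motif_altered", "conserved")


def make_record(on=(), coding="noncoding"):
    kw = {k: True for k in on}
    if "binding_in_context" in kw:
        kw["protein_binding"] = True
    return EvidenceRecord("v", coding_class=coding, **kw)


class TestScoreAlgebra:
    def test_empty_record_scores_zero(self):
        fs = score_evidence(EvidenceRecord("v"))
        assert fs.score == 0.0 and fs.category == "none"

    def test_maximum_noncoding_score_is_seven(self):
        fs = score_evidence(make_record(PLUS_ONE + PLUS_HALF))
        assert fs.score == 7.0 and fs.category == "strong"

    def test_coding_overrides(self):
        assert score_evidence(make_record((), "possibly_damaging")).score == 8.0
        assert score_evidence(make_record((), "probably_damaging")).score == 9.0

    def test_benign_and_unknown_score_like_regulatory(self):
        on = ("histone_mark", "open_chromatin", "protein_binding", "binding_in_context")
        for coding in ("benign", "unknown"):
            fs = score_evidence(make_record(on, coding))
            assert fs.score == 4.0 and fs.category == "moderate"

    def test_context_without_binding_is_invalid(self):
        with pytest.raises(ValueError):
            EvidenceRecord("v", binding_in_context=True)

    def test_all_attainable_scores_and_categories(self):
        """Noncoding scores live on {0, 0.5, ..., 7}; the weak/moderate/strong
        edges partition them with no gaps."""
        seen = set()
        for k in range(len(PLUS_ONE) + 1):
            for halves in range(3):
                on = PLUS_ONE[:k] + PLUS_HALF[:halves]
                seen.add(score_evidence(make_record(on)).score)
        assert seen == {0.5 * i for i in range(15)}  # 0 .. 7 in halves
        # explicit category map over the full half-integer grid
        for s in np.arange(0, 7.5, 0.5):
            expected = (
                "strong" if s >= 5 else "moderate" if s >= 4 else "weak" if s >= 3 else "none"
            )
            assert categorize(float(s)) == expected
        assert categorize(8.0) == "strong" and categorize(9.0) == "strong"

    @given(
        flags=st.lists(st.booleans(), min_size=8, max_size=8),
        idx=st.integers(0, 7),
    )
    @settings(max_examples=200, derandomize=True)
    def test_monotone_in_every_component(self, flags, idx):
        names = PLUS_ONE + PLUS_HALF
        base = {n: f for n, f in zip(names, flags)}
        if base["binding_in_context"]:
            base["protein_binding"] = True
        raised = dict(base)
        raised[names[idx]] = True
        if raised["binding_in_context"]:
            raised["protein_binding"] = True
        s0 = score_evidence(EvidenceRecord("v", **base)).score
        s1 = score_evidence(EvidenceRecord("v", **raised)).score
        assert s1 >= s0


class TestMotifThreshold:
    def test_strictly_greater_than_five(self, tmp_path):
        motif = tmp_path / "motifs.tsv"
        motif.write_text(
            "variant_id\tref_lod\talt_lod\nv_at\t10.0\t5.0\nv_above\t10.0\t4.99\nv_neg\t2.0\t7.01\n"
        )
        for name in ("open_chromatin", "histone", "binding", "conserved"):
            (tmp_path / f"{name}.bed").write_text("")
        bundle = TrackBundle(
            open_chromatin_bed=tmp_path / "open_chromatin.bed",
            histone_bed=tmp_path / "histone.bed",
            binding_bed=tmp_path / "binding.bed",
            conserved_bed=tmp_path / "conserved.bed",
            motif_tsv=motif,
        )
        recs = {
            vid: evidence_from_tracks(Variant(vid, "1", 100), bundle)
            for vid in ("v_at", "v_above", "v_neg")
        }
        assert not recs["v_at"].motif_altered  # delta exactly 5 does not count
        assert recs["v_above"].motif_altered
        assert recs["v_neg"].motif_altered  # sign of the change is ignored


class TestEvidenceFromTracks:
    def _bundle(self, tmp_path, open_lines=(), histone_lines=(), binding_lines=()):
        paths = {}
        for name, lines in (
            ("open_chromatin", open_lines),
            ("histone", histone_lines),
            ("binding", binding_lines),
            ("conserved", ()),
        ):
            p = tmp_path / f"{name}.bed"
            p.write_text("\n".join(lines) + ("\n" if lines else ""))
            paths[name] = p
        return TrackBundle(
            open_chromatin_bed=paths["open_chromatin"],
            histone_bed=paths["histone"],
            binding_bed=paths["binding"],
            conserved_bed=paths["conserved"],
        )

    def test_dnase_only(self, tmp_path):
        b = self._bundle(tmp_path, open_lines=("1\t99\t100\tDNase_K562|cancer|other",))
        rec = evidence_from_tracks(Variant("v", "1", 100), b)
        assert rec.open_chromatin and not rec.histone_mark and not rec.protein_binding
        assert not rec.binding_in_context and not rec.colorectal_evidence

    def test_binding_plus_histone_sets_context(self, tmp_path):
        b = self._bundle(
            tmp_path,
            histone_lines=("1\t90\t110\tH3K27ac_HCT116|cancer|crc",),
            binding_lines=("1\t95\t105\tTCF4|cancer|other",),
        )
        rec = evidence_from_tracks(Variant("v", "1", 100), b)
        assert rec.protein_binding and rec.binding_in_context
        assert rec.cancer_normal_differential  # cancer histone, no normal histone
        assert rec.colorectal_evidence

    def test_cancer_and_normal_histone_is_not_differential(self, tmp_path):
        b = self._bundle(
            tmp_path,
            histone_lines=(
                "1\t90\t110\tH3K27ac_HepG2|cancer|other",
                "1\t90\t110\tH3K4me1_NHEK|normal|other",
            ),
        )
        rec = evidence_from_tracks(Variant("v", "1", 100), b)
        assert rec.histone_mark and not rec.cancer_normal_differential

    def test_malformed_bed_names_file_and_line(self, tmp_path):
        bad = tmp_path / "open_chromatin.bed"
        bad.write_text("1\t100\n")
        b = TrackBundle(open_chromatin_bed=bad)
        with pytest.raises(ValueError, match="open_chromatin.bed:1"):
            with pytest.warns(UserWarning):
                evidence_from_tracks(Variant("v", "1", 100), b)

    def test_missing_tracks_default_false_with_warning(self, tmp_path):
        b = TrackBundle()
        with pytest.warns(UserWarning, match="missing"):
            rec = evidence_from_tracks(Variant("v", "1", 100), b)
        assert score_evidence(rec).score == 0.0


class TestGeneContext:
    GENES = [
        GeneModel("PLUS", "1", 10_000, 20_000, "+", exons=((10_000, 10_500), (19_000, 20_000))),
        GeneModel("MINUS", "1", 100_000, 120_000, "-"),
    ]

    def test_intronic(self):
        ctx = assign_gene_context(Variant("v", "1", 15_000), self.GENES)
        assert (ctx.location_class, ctx.predicted_gene, ctx.orientation) == ("intronic", "PLUS", "within")

    def test_exonic(self):
        ctx = assign_gene_context(Variant("v", "1", 10_250), self.GENES)
        assert ctx.location_class == "exonic"

    def test_upstream_five_prime_plus_strand(self):
        ctx = assign_gene_context(Variant("v", "1", 9_000), self.GENES)
        assert (ctx.location_class, ctx.predicted_gene, ctx.orientation) == (
            "intergenic", "PLUS", "upstream_5prime",
        )

    def test_strand_aware_orientation_minus(self):
        # low-coordinate side of a minus-strand gene is its 3' end
        ctx = assign_gene_context(Variant("v", "1", 95_000), self.GENES)
        assert (ctx.predicted_gene, ctx.orientation) == ("MINUS", "downstream_3prime")

    def test_no_gene_on_chromosome(self):
        ctx = assign_gene_context(Variant("v", "2", 100), self.GENES)
        assert ctx.location_class == "no_gene" and ctx.predicted_gene is None

    def test_matches_bruteforce_nearest_end(self, rng):
        """Random layouts: nearest-transcript-end assignment agrees with an
        exhaustive distance search."""
        for _ in range(50):
            n_genes = rng.integers(1, 6)
            genes = []
            for g in range(n_genes):
                start = int(rng.integers(1, 900_000))
                genes.append(
                    GeneModel(f"G{g}", "1", start, start + int(rng.integers(500, 50_000)),
                              "+" if rng.random() < 0.5 else "-")
                )
            pos = int(rng.integers(1, 1_000_000))
            ctx = assign_gene_context(Variant("v", "1", pos), genes)
            inside = [g for g in genes if g.start <= pos <= g.end]
            if inside:
                assert ctx.orientation == "within"
                assert ctx.predicted_gene in {g.name for g in inside}
            else:
                dists = {g.name: min(abs(pos - g.start), abs(pos - g.end)) for g in genes}
                best = min(dists.values())
                assert dists[ctx.predicted_gene] == best


class TestCuratedCandidateTable:
    def test_twenty_one_strong_in_twelve_loci(self):
        summary = score_candidate_table(scored_candidates())
        assert summary["by_category"]["strong"] == 21
        assert summary["n_strong_loci"] == 12

    def test_locations_and_motifs(self):
        summary = score_candidate_table(scored_candidates())
        assert summary["by_location"] == {"intronic": 15, "intergenic": 6}
        assert summary["n_motif_altered"] == 15
        assert summary["n_index_strong_loci"] == 4

    def test_published_worked_example_row(self):
        """rs3217827: open chromatin in one cell line, histone marks in
        normal colorectal tissue, RAD21/CTCF binding in context, colorectal
        tissue evidence, no motif change, not conserved -> score 5."""
        df = load_strong_candidate_evidence()
        recs = {r.variant_id: r for r in evidence_records_from_candidates(df)}
        fs = score_evidence(recs["rs3217827"])
        assert fs.score == 5.0 and fs.category == "strong"

    def test_empty_and_singleton_summaries(self):
        assert score_candidate_table([])["n_candidates"] == 0
        one = scored_candidates()[:1]
        s = score_candidate_table(one)
        assert s["by_category"]["strong"] == 1 and s["n_strong_loci"] == 1
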