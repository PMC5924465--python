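"""ORF scanning, homology labelling, boundary selection, TM prediction,
URF calling and the tRNA false-positive filter."""

import numpy as np
import pytest

from ctenomito import MOLD, GenomeSpec, extract_feature_sequence, generate_genome, translate
from ctenomito.annotate import (
    KYTE_DOOLITTLE,
    TrnaCandidate,
    annotate_genome,
    annotate_urfs,
    enumerate_start_variants,
    filter_trna_candidates,
    find_orfs,
    homology_scan,
    pairwise_similarity,
    predict_tm,
    select_boundaries,
)
from ctenomito.io import AnnotationSet, GeneFeature, MitoGenome
from ctenomito.simulate import SMALL_GENE_MODELS


class TestFindOrfs:
    def test_minimal_orf(self):
        g = MitoGenome("g", "ATGAAATAA", False)
        (orf,) = find_orfs(g, MOLD, min_len=9)
        assert (orf.start, orf.end, orf.protein, orf.stop_kind) == (0, 9, "MK", "TAA")

    def test_no_start_codon(self):
        g = MitoGenome("g", "CCCCCCCCCCCCTAACCC", False)
        assert find_orfs(g, MOLD, min_len=3) == []

    def test_origin_spanning_orf_recovered_exactly(self, small_genome, small_refs):
        genome, ann, _ = small_genome
        from ctenomito.io import rotate_genome

        cox1 = ann.by_label("cox1")
        # rotate so cox1 crosses the new origin
        mid = cox1.start + cox1.length // 2
        g2, a2 = rotate_genome(genome, ann, shift=mid)
        target = a2.by_label("cox1")
        assert target.end > g2.length
        orfs = find_orfs(g2, MOLD, min_len=100)
        spans = {(o.start % g2.length, o.end - o.start) for o in orfs}
        # the planted gene's stop bounds some maximal ORF ending at the same place
        assert any(
            (s + ln) % g2.length == target.end % g2.length for s, ln in spans
        )

    def test_n_bases_rejected(self):
        g = MitoGenome("g", "ATGNNNTAA", False)
        with pytest.raises(ValueError, match="N bases"):
            find_orfs(g, MOLD, min_len=3)


class TestHomology:
    def test_identity_scores_one(self):
        prot = "MKLIVFWSTAYHQDE"
        g = MitoGenome("g", "ATG" + "AAA" * 20 + "TAA", False)
        (orf,) = find_orfs(g, MOLD, min_len=9)
        (hit,) = homology_scan([orf], {"ref": orf.protein})
        assert hit is not None and hit.score == pytest.approx(1.0)

    def test_below_floor_dropped(self):
        g = MitoGenome("g", "ATG" + "AAA" * 20 + "TAA", False)
        (orf,) = find_orfs(g, MOLD, min_len=9)
        (hit,) = homology_scan([orf], {"ref": "WWWWCCCWWW"})
        assert hit is None

    def test_point_mutated_protein_recovers_label(self):
        rng = np.random.default_rng(7)
        aas = "ACDEFGHIKLMNPQRSTVWY"
        ref = "".join(rng.choice(list(aas), size=100))
        mutant = list(ref)
        for i in rng.choice(100, size=10, replace=False):  # 10% substitutions
            mutant[i] = aas[(aas.index(mutant[i]) + 1) % 20]
        mutant = "".join(mutant)
        # independent check: edit distance equals the number of substitutions
        import edlib

        assert edlib.align(ref, mutant)["editDistance"] == 10
        score = pairwise_similarity(mutant, ref)
        assert 0.8 < score < 1.0


class TestBoundaries:
    def _genome_with_two_starts(self):
        # gene body: start .. stop in one frame with two candidate starts
        body = "ATG" + "GGT" * 10 + "ATG" + "GGT" * 20 + "TAA"
        seq = "CCTCC" + body + "CCTCC"
        return MitoGenome("g", seq, False), 5, 5 + len(body)

    def test_overlap_minimization_wins(self):
        g, s0, e0 = self._genome_with_two_starts()
        starts = [s0, s0 + 33]
        ref = translate(g.sequence[s0 : e0 - 3], MOLD)
        # neighbour overlapping the first 40 bp => early start overlaps it
        neighbor = GeneFeature("cob", 0, s0 + 20)
        s, e, kind = select_boundaries(starts, [(e0, "TAA")], [neighbor], g, MOLD, ref)
        assert s == s0 + 33 and kind == "TAA"

    def test_similarity_breaks_zero_overlap_tie(self):
        g, s0, e0 = self._genome_with_two_starts()
        starts = [s0, s0 + 33]
        ref = translate(g.sequence[s0 : e0 - 3], MOLD)  # matches the long variant
        s, _, _ = select_boundaries(starts, [(e0, "TAA")], [], g, MOLD, ref)
        assert s == s0
        ref_short = translate(g.sequence[s0 + 33 : e0 - 3], MOLD)
        s, _, _ = select_boundaries(starts, [(e0, "TAA")], [], g, MOLD, ref_short)
        assert s == s0 + 33

    def test_single_candidate_returned(self):
        g, s0, e0 = self._genome_with_two_starts()
        s, e, kind = select_boundaries([s0], [(e0, "TAA")], [], g, MOLD, "M")
        assert (s, e) == (s0, e0)

    def test_no_candidate_start_raises(self):
        g, s0, e0 = self._genome_with_two_starts()
        with pytest.raises(ValueError):
            select_boundaries([], [(e0, "TAA")], [], g, MOLD, "M")

    def test_selected_overlap_is_minimal_over_all_candidates(self, small_genome, small_refs):
        # exhaustive check of the lexicographic contract on one real gene
        genome, ann, _ = small_genome
        prot_refs, _ = small_refs
        orfs = find_orfs(genome, MOLD, min_len=100)
        hits = homology_scan(orfs, prot_refs)
        from ctenomito.annotate import _circ_overlap

        for orf, hit in zip(orfs, hits):
            if hit is None or hit.query_label != "nad5":
                continue
            neighbors = [f for f in ann if f.label != "nad5"]
            starts = enumerate_start_variants(orf, genome, MOLD)
            s, e, _ = select_boundaries(
                starts, [(orf.end, orf.stop_kind)], neighbors, genome, MOLD,
                prot_refs["nad5"],
            )
            chosen = sum(
                _circ_overlap((s, e), (n.start, n.end), genome.length) for n in neighbors
            )
            for cand in starts:
                other = sum(
                    _circ_overlap((cand, orf.end), (n.start, n.end), genome.length)
                    for n in neighbors
                )
                assert chosen <= other


class TestTransmembrane:
    def test_single_leucine_window(self):
        assert predict_tm("L" * 19) == 1

    def test_all_glycine_zero(self):
        assert predict_tm("G" * 40) == 0

    def test_two_stretches_with_charged_linker(self):
        prot = "L" * 19 + "KRKDEKRKDEKR" + "L" * 19
        assert predict_tm(prot) == 2
        # oracle: direct window-mean computation, greedy non-overlap
        vals = [KYTE_DOOLITTLE.get(a, 0.0) for a in prot]
        count, i = 0, 0
        while i + 19 <= len(vals):
            if sum(vals[i : i + 19]) / 19 > 1.6:
                count += 1
                i += 19
            else:
                i += 1
        assert count == 2

    def test_unknown_residue_warns(self):
        with pytest.warns(UserWarning):
            predict_tm("X" * 25)


class TestUrfs:
    def _orf(self, genome, start, n_aa, hydrophobic):
        body = ("TTA" if hydrophobic else "AAA") * n_aa
        from ctenomito.annotate import OrfCandidate

        return OrfCandidate(start, start + 3 + 3 * n_aa + 3, 0, "+",
                            ("L" if hydrophobic else "K") * (n_aa + 1), "TAA")

    def test_short_orf_excluded(self):
        orfs = [self._orf(None, 0, 28, True)]  # 90 bp < 100
        assert annotate_urfs(orfs, min_len=100) == []

    def test_hydrophilic_orf_excluded(self):
        orfs = [self._orf(None, 0, 98, False)]  # 300 bp all-lysine
        assert annotate_urfs(orfs, min_len=100) == []

    def test_hydrophobic_orf_included_and_labelled_in_order(self):
        orfs = [self._orf(None, 500, 98, True), self._orf(None, 10, 98, True)]
        urfs = annotate_urfs(orfs, min_len=100)
        assert [u.label for u in urfs] == ["urf1", "urf2"]
        assert urfs[0].start == 10 and urfs[1].start == 500


class TestTrnaFilter:
    @pytest.fixture()
    def ann(self):
        return AnnotationSet(
            "g",
            [
                GeneFeature("cox1", 100, 400),
                GeneFeature("rnl", 500, 900, kind="rRNA"),
            ],
        )

    def test_noncanonical_inside_orf_rejected(self, ann):
        kept, rejected = filter_trna_candidates(
            [TrnaCandidate(150, 220, canonical_structure=False)], ann, 1000
        )
        assert kept == [] and len(rejected) == 1

    def test_canonical_in_gap_kept_unflagged(self, ann):
        kept, rejected = filter_trna_candidates(
            [TrnaCandidate(420, 480, canonical_structure=True)], ann, 1000
        )
        assert rejected == [] and kept[0][1] is False

    def test_canonical_inside_rrna_kept_with_flag(self, ann):
        kept, rejected = filter_trna_candidates(
            [TrnaCandidate(600, 670, canonical_structure=True)], ann, 1000
        )
        assert rejected == [] and kept[0][1] is True


class TestAnnotateGenome:
    def test_planted_annotation_recovered(self, small_genome, small_refs):
        genome, ann, _ = small_genome
        prot_refs, rrna_refs = small_refs
        out = annotate_genome(genome, prot_refs, rrna_refs, MOLD)
        truth = {f.label: (f.start, f.end) for f in ann if f.kind != "URF"}
        got = {f.label: (f.start, f.end) for f in out}
        assert all(got.get(l) == span for l, span in truth.items())

    def test_planted_urf_found(self, small_genome, small_refs):
        genome, ann, _ = small_genome
        prot_refs, rrna_refs = small_refs
        out = annotate_genome(genome, prot_refs, rrna_refs, MOLD)
        planted = [f for f in ann if f.kind == "URF"]
        found = [f for f in out if f.kind == "URF"]
        from ctenomito.annotate import _circ_overlap

        for p in planted:
            assert any(
                _circ_overlap((p.start, p.end), (f.start, f.end), genome.length)
                >= 0.8 * p.length
                for f in found
            )
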