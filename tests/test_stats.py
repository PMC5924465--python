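"""Composition, codon usage, non-coding accounting, correlation and repeats."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from ctenomito import MOLD, GenomeSpec, generate_genome
from ctenomito.io import AnnotationSet, GeneFeature, MitoGenome
from ctenomito.stats import (
    codon_usage,
    composition,
    dinucleotide_entropy,
    find_perfect_repeats,
    format_percent,
    nc_percent,
    size_nc_correlation,
    summarize_noncoding,
)


class TestComposition:
    def test_all_at(self):
        assert composition(MitoGenome("g", "ATAT", False)).at_percent == 100.0

    def test_uniform(self):
        prof = composition(MitoGenome("g", "ACGT", False))
        assert all(v == 25.0 for v in prof.percent.values())

    def test_generator_hits_target_within_tolerance(self):
        g, _, _ = generate_genome(GenomeSpec(seed=2))
        assert composition(g).at_percent == pytest.approx(84.0, abs=1.5)

    def test_percentages_sum_to_100(self):
        prof = composition(MitoGenome("g", "ACGTTGCAATTC", False))
        assert sum(prof.percent.values()) == pytest.approx(100.0)


class TestCodonUsage:
    def test_single_gene_tally(self):
        g = MitoGenome("g", "ATGAAATAA", False)
        ann = AnnotationSet("g", [GeneFeature("cox1", 0, 9)])
        usage = codon_usage(ann, g, MOLD)
        assert usage.start_counts == {"ATG": 1}
        assert usage.stop_counts == {"TAA": 1}
        assert usage.percent("AAA") == 100.0

    def test_percentages_sum_to_100_over_genes(self):
        g = MitoGenome("g", "ATGAAATTTTAA" + "ATTGGTCCTTAG", False)
        ann = AnnotationSet(
            "g", [GeneFeature("cox1", 0, 12), GeneFeature("cox2", 12, 24)]
        )
        usage = codon_usage(ann, g, MOLD)
        assert sum(usage.percentages().values()) == pytest.approx(100.0)

    def test_total_codons_identity(self, small_genome):
        genome, ann, _ = small_genome
        usage = codon_usage(ann, genome, MOLD, include_urfs=True)
        expected = sum(f.length // 3 for f in ann if f.kind != "rRNA")
        assert usage.total_codons == expected

    def test_generator_codon_frequencies_recovered(self, small_genome):
        # TTT should dominate in an AT-rich genome, as observed in real data
        genome, ann, _ = small_genome
        usage = codon_usage(ann, genome, MOLD)
        top = max(usage.codon_counts, key=usage.codon_counts.get)
        assert set(top) <= {"A", "T"}


class TestNonCoding:
    def test_toy_layout_with_and_without_urfs(self):
        # 1000 bp circle: genes cover 900, one 60 bp URF inside the 100 bp gap
        seq = "".join("ACGT"[(i * 3 + 1) % 4] for i in range(1000))
        g = MitoGenome("g", seq, True)
        ann = AnnotationSet(
            "g",
            [
                GeneFeature("cox1", 0, 500),
                GeneFeature("cox2", 500, 900),
                GeneFeature("urf1", 920, 980, kind="URF"),
            ],
        )
        prof = summarize_noncoding(ann, g)
        assert prof.nc_without_urfs == 40
        assert prof.nc_with_urfs == 100

    def test_wall_to_wall_zero(self):
        g = MitoGenome("g", "ACGT" * 25, True)
        ann = AnnotationSet("g", [GeneFeature("cox1", 0, 60), GeneFeature("cox2", 60, 100)])
        prof = summarize_noncoding(ann, g)
        assert prof.nc_with_urfs == 0 and prof.nc_without_urfs == 0

    def test_single_feature_wrapping_complement(self):
        g = MitoGenome("g", "ACGT" * 25, True)
        ann = AnnotationSet("g", [GeneFeature("cox1", 40, 60)])
        prof = summarize_noncoding(ann, g)
        assert prof.nc_with_urfs == 80
        assert prof.longest_nc_with == (80, ("cox1", "cox1"))

    def test_origin_spanning_feature_counted_once(self):
        g = MitoGenome("g", "ACGT" * 25, True)
        ann = AnnotationSet("g", [GeneFeature("cox1", 90, 110), GeneFeature("cox2", 30, 50)])
        prof = summarize_noncoding(ann, g)
        assert prof.nc_with_urfs == 100 - 40

    def test_ledger_conservation_on_synthetic(self, small_genome):
        genome, ann, ledger = small_genome
        prof = summarize_noncoding(ann, genome)
        urf_bp = sum(f.length for f in ann if f.kind == "URF")
        assert prof.nc_with_urfs == prof.nc_without_urfs + urf_bp
        assert prof.nc_without_urfs == sum(t["length"] for t in ledger.nc_tracts)


class TestNcPercent:
    @pytest.mark.parametrize(
        "nc,total,expected",
        [(930, 11574, 8.0), (429, 11016, 3.9), (0, 100, 0.0), (908, 11551, 7.9)],
    )
    def test_published_rows(self, nc, total, expected):
        assert nc_percent(nc, total) == expected

    def test_display_drops_trailing_zero(self):
        assert format_percent(8.0) == "8" and format_percent(7.9) == "7.9"

    def test_bounds_checked(self):
        with pytest.raises(ValueError):
            nc_percent(10, 5)


class TestCorrelation:
    ROWS = [(11574, 930), (11551, 908), (9961, 119), (10326, 406), (11016, 755)]

    def test_five_genome_rows(self):
        r = size_nc_correlation(self.ROWS)
        assert 0.98 <= r <= 0.99

    def test_matches_textbook_two_pass_formula(self):
        rng = np.random.default_rng(0)
        rows = [(float(x), float(y)) for x, y in rng.integers(1, 100, size=(4, 2))]
        x = np.array([r[0] for r in rows])
        y = np.array([r[1] for r in rows])
        manual = ((x - x.mean()) * (y - y.mean())).sum() / np.sqrt(
            ((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum()
        )
        assert size_nc_correlation(rows) == pytest.approx(manual)

    def test_perfectly_linear(self):
        assert size_nc_correlation([(1, 2), (2, 4), (3, 6)]) == pytest.approx(1.0)

    @given(
        st.floats(0.1, 10), st.floats(-5, 5),
        st.lists(st.tuples(st.integers(0, 1000), st.integers(0, 1000)),
                 min_size=4, max_size=8, unique=True),
    )
    def test_affine_invariance(self, a, b, rows):
        xs = {r[0] for r in rows}
        ys = {r[1] for r in rows}
        if len(xs) < 2 or len(ys) < 2:
            return
        r1 = size_nc_correlation(rows)
        r2 = size_nc_correlation([(a * x + b, y) for x, y in rows])
        assert r1 == pytest.approx(r2, abs=1e-9)

    def test_constant_column_rejected(self):
        with pytest.raises(ValueError):
            size_nc_correlation([(5, 1), (5, 2), (5, 3)])


def oracle_repeats(seq: str, min_unit: int):
    """Quadratic all-pairs maximal-match enumeration, grouped by unit string."""
    n = len(seq)
    by_unit: dict[str, set[int]] = {}
    for p in range(n):
        for q in range(p + 1, n):
            if seq[p] != seq[q]:
                continue
            if p > 0 and q > 0 and seq[p - 1] == seq[q - 1]:
                continue  # not left-maximal
            ln = 0
            while q + ln < n and seq[p + ln] == seq[q + ln]:
                ln += 1
            if ln >= min_unit:
                by_unit.setdefault(seq[p : p + ln], set()).update((p, q))
    return {u: tuple(sorted(pos)) for u, pos in by_unit.items()}


class TestRepeats:
    def test_poly_a_filtered_as_low_complexity(self):
        g = MitoGenome("g", "A" * 100, False)
        assert find_perfect_repeats(g, 20, filter_low_complexity=True) == []
        hits = find_perfect_repeats(g, 20, filter_low_complexity=False)
        assert hits and all(h.low_complexity for h in hits)

    def test_no_repeats_in_unique_string(self):
        seq = "ACGTAGCTTGCAATCCGGATTGACCTGA"
        g = MitoGenome("g", seq, False)
        assert find_perfect_repeats(g, 10) == []

    def test_planted_repeat_on_circle(self):
        rng = np.random.default_rng(3)
        unit = "".join(rng.choice(list("ACGT"), size=30))
        filler1 = "".join(rng.choice(list("ACGT"), size=200))
        filler2 = "".join(rng.choice(list("ACGT"), size=150))
        g = MitoGenome("g", unit + filler1 + unit + filler2, True)
        hits = find_perfect_repeats(g, 21)
        assert hits and hits[0].unit_length >= 30
        assert {0, 230} <= set(hits[0].positions)

    def test_planted_84bp_repeat_in_synthetic_genome(self):
        g, _, ledger = generate_genome(GenomeSpec(seed=8, planted_repeat=(84, 8200)))
        hits = find_perfect_repeats(g, 21, filter_low_complexity=True)
        assert hits and hits[0].unit_length == 84
        assert list(hits[0].positions) == ledger.repeat["positions"]

    def test_min_unit_above_length_empty(self):
        g = MitoGenome("g", "ACGT", False)
        assert find_perfect_repeats(g, 10) == []

    @given(st.text(alphabet="AT", min_size=20, max_size=120))
    def test_matches_quadratic_oracle_on_linear_strings(self, seq):
        g = MitoGenome("g", seq, False)
        got = {
            h.unit: h.positions for h in find_perfect_repeats(g, 5)
        }
        assert got == oracle_repeats(seq, 5)

    def test_entropy_flags(self):
        assert dinucleotide_entropy("T" * 40) < 1.5
        assert dinucleotide_entropy("ACGTAGCTTGCAATCCGGAT") > 1.5
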