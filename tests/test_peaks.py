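"""Stand-in peak caller, retention filters, overlaps, genomic distribution."""

import dataclasses

import numpy as np
import pytest

from conftest import make_sample
from ervchip import (
    FilterRules,
    GeneRecord,
    GenomeModel,
    Peak,
    call_candidate_peaks,
    cross_annotate_called_against,
    filter_peaks,
    genomic_distribution,
    intersect_peaks,
    venn_counts,
)


def peak(chrom="chr1", start=0, end=100, summit=None, fg=30, fg_tpm=5.0,
         bg=(10, 50), bg_tpm=(1.0, 2.0), called=("b1", "b2")):
    return Peak(
        chrom, start, end, summit if summit is not None else start,
        fg, fg_tpm,
        {"b1": bg[0], "b2": bg[1]}, {"b1": bg_tpm[0], "b2": bg_tpm[1]},
        frozenset(called),
    )


# The six-peak fixture spans every rule's pass/fail boundary; the expected
# retained subset was derived by hand-applying the four rules.
SIX_PEAKS = [
    peak(start=0, end=100),                                   # boundary pass
    peak(start=200, end=300, fg=29),                          # fails fg count (29 < 30)
    peak(start=400, end=500, bg=(10, 51)),                    # fails bg count (51 > 50)
    peak(start=600, end=700, fg_tpm=4.98),                    # ratio 2.49 < 2.5
    peak(start=800, end=900, called=("b1",)),                 # missing second background
    peak(start=1000, end=1100, fg=100, fg_tpm=50.0, bg=(0, 0), bg_tpm=(0.5, 1.0)),
]
HAND_RETAINED = {0, 5}


class TestFilterPeaks:
    def test_six_peak_fixture_matches_hand_derivation(self):
        retained = filter_peaks(SIX_PEAKS, FilterRules())
        assert {SIX_PEAKS.index(p) for p in retained} == HAND_RETAINED

    def test_boundary_peak_retained_exactly_at_thresholds(self):
        assert filter_peaks([SIX_PEAKS[0]], FilterRules()) == [SIX_PEAKS[0]]

    def test_monotone_under_random_tightenings(self):
        """Tightening any rule never adds a peak (100 seeded tightenings)."""
        baseline = set(map(id, filter_peaks(SIX_PEAKS, FilterRules())))
        rng = np.random.default_rng(17)
        for _ in range(100):
            rules = FilterRules(
                min_fg_reads=int(rng.integers(30, 200)),
                max_bg_reads=int(rng.integers(0, 51)),
                min_fold=float(2.5 + rng.random() * 5),
            )
            tightened = set(map(id, filter_peaks(SIX_PEAKS, rules)))
            assert tightened <= baseline

    def test_broad_mode_applies_only_fold_rule(self):
        # fails every count rule but exceeds threefold against one background
        p = peak(fg=5, fg_tpm=9.0, bg=(100, 100), bg_tpm=(3.0, 4.0))
        assert filter_peaks([p], FilterRules(broad_mode=True)) == [p]
        weak = peak(fg=5, fg_tpm=8.0, bg=(100, 100), bg_tpm=(3.0, 4.0))
        # 8/3 < 3 against either background -> rejected
        assert filter_peaks([weak], FilterRules(broad_mode=True)) == []

    def test_single_background_mode(self):
        p = peak(called=("b1",))
        assert filter_peaks([p], FilterRules(require_both_backgrounds=False)) == [p]

    def test_missing_background_entry_error_names_peak(self):
        bad = dataclasses.replace(SIX_PEAKS[0], bg_tpm={"b1": 1.0})
        with pytest.raises(ValueError, match="missing background"):
            filter_peaks([bad], FilterRules())


class TestCallCandidatePeaks:
    def _uniform(self, n, seed, sid="s", size=10_000):
        rng = np.random.default_rng(seed)
        return make_sample(
            [(f"chr1", int(rng.integers(0, size - 51)), "+") for _ in range(n)],
            sample_id=sid,
        )

    def test_fg_equal_bg_yields_zero_peaks(self):
        genome = GenomeModel({"chr1": 10_000})
        fg = self._uniform(500, 1)
        bg = make_sample(fg.placements, sample_id="bg")
        runs = call_candidate_peaks(fg, {"bg": bg}, genome)
        assert runs["bg"] == []

    def test_enriched_region_gives_one_covering_peak(self):
        genome = GenomeModel({"chr1": 10_000})
        rng = np.random.default_rng(2)
        enriched = [("chr1", int(rng.integers(1_000, 1_500)), "+") for _ in range(100)]
        scatter = [("chr1", int(rng.integers(0, 9_949)), "+") for _ in range(100)]
        fg = make_sample(enriched + scatter)
        bg = make_sample(
            [("chr1", 1_200, "+")] + [("chr1", int(rng.integers(0, 9_949)), "+")
                                      for _ in range(199)], sample_id="bg")
        runs = call_candidate_peaks(fg, {"bg": bg}, genome)
        assert len(runs["bg"]) == 1
        p = runs["bg"][0]
        assert p.start <= 1_000 and p.end >= 1_500
        assert p.start <= p.summit < p.end
        assert p.fg_effective_reads > p.bg_effective_reads["bg"]

    def test_nearby_windows_merge(self):
        genome = GenomeModel({"chr1": 10_000})
        fg = make_sample([("chr1", 1_100, "+")] * 60 + [("chr1", 1_450, "+")] * 60)
        bg = make_sample([("chr1", int(p), "+") for p in
                          np.random.default_rng(5).integers(0, 9_949, 120)],
                         sample_id="bg")
        runs = call_candidate_peaks(fg, {"bg": bg}, genome)
        assert len(runs["bg"]) == 1  # 200 bp apart = gap -> merged

    def test_zero_depth_background_error(self):
        genome = GenomeModel({"chr1": 10_000})
        with pytest.raises(ValueError, match="zero depth"):
            call_candidate_peaks(self._uniform(10, 1), {"bg": make_sample([])}, genome)

    def test_cross_annotation_marks_both_backgrounds(self):
        genome = GenomeModel({"chr1": 10_000})
        fg = make_sample([("chr1", 1_100, "+")] * 80)
        bg1 = self._uniform(80, 3, "bg1")
        bg2 = self._uniform(80, 4, "bg2")
        runs = call_candidate_peaks(fg, {"bg1": bg1, "bg2": bg2}, genome)
        annotated = cross_annotate_called_against(runs, "bg1")
        assert all(p.called_against == {"bg1", "bg2"} for p in annotated)


def brute_force_overlaps(set_a, set_b):
    """Quadratic all-pairs overlap scan."""
    out = []
    for a in set_a:
        if any(a.chrom == b.chrom and a.start < b.end and b.start < a.end
               for b in set_b):
            out.append(a)
    return out


def random_peak_set(rng, n=30, size=50_000):
    peaks = []
    for _ in range(n):
        start = int(rng.integers(0, size - 600))
        end = start + int(rng.integers(50, 600))
        peaks.append(Peak("chr1", start, end, start, 0, 0.0, {}, {}, frozenset()))
    return peaks


class TestOverlaps:
    def test_identical_sets(self):
        a = random_peak_set(np.random.default_rng(0))
        assert intersect_peaks(a, a) == a
        counts = venn_counts(a, a, a)
        assert counts["ABC"] == len(a)
        assert sum(v for k, v in counts.items() if k != "ABC") == 0

    def test_disjoint_sets(self):
        a = [Peak("chr1", 0, 100, 0, 0, 0.0, {}, {}, frozenset())]
        b = [Peak("chr1", 200, 300, 200, 0, 0.0, {}, {}, frozenset())]
        assert intersect_peaks(a, b) == []

    def test_reference_set_semantics(self):
        # two A peaks overlap one B peak: A-side count is 2, B-side count 1
        a = [Peak("chr1", 0, 100, 0, 0, 0.0, {}, {}, frozenset()),
             Peak("chr1", 150, 250, 150, 0, 0.0, {}, {}, frozenset())]
        b = [Peak("chr1", 50, 200, 50, 0, 0.0, {}, {}, frozenset())]
        assert len(intersect_peaks(a, b)) == 2
        assert len(intersect_peaks(b, a)) == 1

    @pytest.mark.parametrize("seed", range(10))
    def test_intersection_matches_quadratic_oracle(self, seed):
        rng = np.random.default_rng(seed)
        a, b = random_peak_set(rng), random_peak_set(rng)
        assert intersect_peaks(a, b) == brute_force_overlaps(a, b)

    @pytest.mark.parametrize("seed", range(10))
    def test_venn_counts_match_quadratic_oracle(self, seed):
        rng = np.random.default_rng(100 + seed)
        a, b, c = (random_peak_set(rng, n=20) for _ in range(3))
        counts = venn_counts(a, b, c)
        in_b = set(map(id, brute_force_overlaps(a, b)))
        in_c = set(map(id, brute_force_overlaps(a, c)))
        expected = {
            "A_only": sum(1 for p in a if id(p) not in in_b and id(p) not in in_c),
            "AB": sum(1 for p in a if id(p) in in_b and id(p) not in in_c),
            "AC": sum(1 for p in a if id(p) not in in_b and id(p) in in_c),
            "ABC": sum(1 for p in a if id(p) in in_b and id(p) in in_c),
        }
        b_not_a = [p for p in b if p not in brute_force_overlaps(b, a)]
        expected["B_only"] = len([p for p in b_not_a
                                  if p not in brute_force_overlaps(b_not_a, c)])
        expected["BC"] = len(b_not_a) - expected["B_only"]
        c_rest = [p for p in c if p not in brute_force_overlaps(c, a)
                  and p not in brute_force_overlaps(c, b)]
        expected["C_only"] = len(c_rest)
        assert counts == expected


def annotation_genome():
    genes = [
        GeneRecord("chr1", 5_000, 8_999, "+",
                   exons=((5_000, 5_300), (6_000, 6_300), (7_000, 7_300)), name="gplus"),
        GeneRecord("chr1", 30_000, 25_001, "-",
                   exons=((25_001, 25_400), (29_500, 30_001)), name="gminus"),
    ]
    return GenomeModel({"chr1": 50_000, "chr9": 10_000}, genes=genes)


def classify_point_oracle(genome, chrom, pos, tss_up=300, tes_flank=500):
    """Brute-force point-in-interval lookup, priority TSS>TES>exon>intron."""
    for g in genome.genes:
        if g.chrom != chrom:
            continue
        window = (range(g.tss - tss_up, g.tss + 1) if g.strand == "+"
                  else range(g.tss, g.tss + tss_up + 1))
        if pos in window:
            return "TSS"
    for g in genome.genes:
        if g.chrom == chrom and g.tes - tes_flank <= pos <= g.tes + tes_flank:
            return "TES"
    for g in genome.genes:
        if g.chrom == chrom and any(lo <= pos < hi for lo, hi in g.exons):
            return "exon"
    for g in genome.genes:
        lo, hi = g.body
        if g.chrom == chrom and lo <= pos < hi:
            return "intron"
    return "intergenic"


def point_peak(chrom, pos):
    return Peak(chrom, pos, pos + 200, pos, 0, 0.0, {}, {}, frozenset())


class TestGenomicDistribution:
    @pytest.mark.parametrize(
        "chrom,pos,expected",
        [
            ("chr1", 4_900, "TSS"),        # 100 bp upstream of + TSS
            ("chr1", 5_000, "TSS"),        # the TSS base itself, beats exon
            ("chr1", 30_200, "TSS"),       # upstream of the minus-strand gene
            ("chr1", 8_600, "TES"),        # within +-500 of TES
            ("chr1", 6_100, "exon"),
            ("chr1", 6_500, "intron"),
            ("chr1", 20_000, "intergenic"),
            ("chr9", 100, "intergenic"),   # gene-free chromosome
        ],
    )
    def test_hand_classified_positions(self, chrom, pos, expected):
        genome = annotation_genome()
        fractions = genomic_distribution([point_peak(chrom, pos)], genome)
        assert fractions[expected] == 1.0
        assert classify_point_oracle(genome, chrom, pos) == expected

    def test_random_peaks_match_bruteforce_oracle(self):
        genome = annotation_genome()
        rng = np.random.default_rng(23)
        peaks = [point_peak("chr1", int(p)) for p in rng.integers(0, 49_000, 100)]
        fractions = genomic_distribution(peaks, genome)
        labels = [classify_point_oracle(genome, p.chrom, p.start) for p in peaks]
        for cat in fractions:
            assert fractions[cat] == pytest.approx(labels.count(cat) / 100)
        assert abs(sum(fractions.values()) - 1.0) < 1e-12

    def test_invariant_to_gene_list_order(self):
        genome = annotation_genome()
        reversed_genome = GenomeModel(genome.chrom_sizes, genes=genome.genes[::-1])
        rng = np.random.default_rng(31)
        peaks = [point_peak("chr1", int(p)) for p in rng.integers(0, 49_000, 50)]
        assert genomic_distribution(peaks, genome) == genomic_distribution(
            peaks, reversed_genome)

    def test_empty_peak_list_error(self):
        with pytest.raises(ValueError):
            genomic_distribution([], annotation_genome())
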