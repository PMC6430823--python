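"""Candidate-peak calling (stand-in), retention filters, overlaps and
genomic-distribution annotation.

The window caller here is a clearly labelled stand-in for MACS v1.4 /
SICER 1.1 so synthetic data can flow end-to-end: fixed windows are scored
by a Poisson upper tail of the foreground count given the depth-scaled
background count, significant windows within a gap are merged, and the
summit is the maximum-pileup base. The scientifically load-bearing part is
the *filtering*: peaks are retained only with enough effective foreground
reads, few enough background reads, a minimum TPM fold increase over the
maximum background, and — when two backgrounds exist — a call against both.
Externally produced peak tables can be filtered identically via the readers
in :mod:`ervchip.io`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from intervaltree import IntervalTree
from scipy.stats import poisson

from .genome import GenomeModel
from .signal import tpm
from .simdata import AlignedSample


@dataclass
class Peak:
    chrom: str
    start: int
    end: int
    summit: int
    fg_effective_reads: int
    fg_tpm: float
    bg_effective_reads: dict[str, int] = field(default_factory=dict)
    bg_tpm: dict[str, float] = field(default_factory=dict)
    called_against: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"peak [{self.start}, {self.end}) is degenerate")
        if not self.start <= self.summit < self.end:
            raise ValueError(f"summit {self.summit} outside [{self.start}, {self.end})")


@dataclass(frozen=True)
class FilterRules:
    """The peak-retention thresholds.

    Defaults: >= 30 effective foreground reads, <= 50 effective reads in
    every background, >= 2.5-fold TPM increase over the *maximum*
    background TPM, and a call against all backgrounds when two are
    available. ``broad_mode`` (for broad histone-mark domains) disables the
    count thresholds and applies only a >= 3-fold TPM criterion, satisfied
    against either background.
    """

    min_fg_reads: int = 30
    max_bg_reads: int = 50
    min_fold: float = 2.5
    broad_mode: bool = False
    broad_min_fold: float = 3.0
    require_both_backgrounds: bool = True

    def __post_init__(self) -> None:
        if self.min_fold <= 1 or self.broad_min_fold <= 1:
            raise ValueError("fold thresholds must be > 1")


def call_candidate_peaks(
    fg: AlignedSample,
    bgs: dict[str, AlignedSample],
    genome: GenomeModel,
    window: int = 200,
    gap: int = 200,
    fragment: int = 51,
    p_threshold: float = 1e-5,
) -> dict[str, list[Peak]]:
    """STAND-IN window caller: one peak list per background.

    Windows of ``window`` bp are scored per background by the Poisson upper
    tail of the foreground count given the depth-scaled background count
    (floored at the genome-wide foreground rate, so an empty background
    cannot make a single read significant). Windows with p < ``p_threshold``
    lying within ``gap`` bp are merged; the summit is the maximum-pileup
    position (leftmost on ties) of fragment-length foreground reads. Every
    peak is annotated with effective counts and TPMs against *all*
    backgrounds. Deterministic.
    """
    for bg_id, bg in bgs.items():
        if bg.total_mapped < 1:
            raise ValueError(f"background {bg_id!r} has zero depth")
    if fg.total_mapped < 1:
        raise ValueError("foreground has zero depth")

    genome_len = genome.total_length()
    fg_rate = fg.total_mapped * window / genome_len  # genome-wide window floor

    def window_counts(sample: AlignedSample) -> dict[str, np.ndarray]:
        counts = {
            c: np.zeros(size // window + 1, dtype=np.int64)
            for c, size in genome.chrom_sizes.items()
        }
        for p in sample.placements:
            counts[p.chrom][p.start // window] += 1
        return counts

    fg_counts = window_counts(fg)
    results: dict[str, list[Peak]] = {}
    for bg_id, bg in bgs.items():
        bg_counts = window_counts(bg)
        depth_scale = fg.total_mapped / bg.total_mapped
        peaks: list[Peak] = []
        for chrom in genome.chrom_sizes:
            fgc, bgc = fg_counts[chrom], bg_counts[chrom]
            lam = np.maximum(bgc * depth_scale, fg_rate)
            with np.errstate(divide="ignore"):
                pvals = poisson.sf(fgc - 1, lam)
            sig = np.flatnonzero((pvals < p_threshold) & (fgc > 0))
            for w_start, w_end in _merge_windows(sig, window, gap, genome.chrom_sizes[chrom]):
                summit = _max_pileup(fg, chrom, w_start, w_end, fragment)
                peaks.append(
                    _annotate(
                        Peak(chrom, w_start, w_end, summit, 0, 0.0,
                             called_against=frozenset({bg_id})),
                        fg, bgs,
                    )
                )
        results[bg_id] = peaks
    return results


def _merge_windows(sig_idx: np.ndarray, window: int, gap: int, chrom_len: int):
    """Merge significant window indices whose gaps are <= gap bp."""
    merged: list[tuple[int, int]] = []
    for i in sig_idx:
        start, end = i * window, min((i + 1) * window, chrom_len)
        if merged and start - merged[-1][1] <= gap:
            merged[-1] = (merged[-1][0], end)
        else:
            merged.append((start, end))
    return merged


def _max_pileup(sample: AlignedSample, chrom: str, start: int, end: int, fragment: int) -> int:
    diff = np.zeros(end - start + 1)
    any_read = False
    for p in sample.placements:
        if p.chrom != chrom:
            continue
        lo, hi = max(p.start, start), min(p.start + fragment, end)
        if lo < hi:
            diff[lo - start] += 1
            diff[hi - start] -= 1
            any_read = True
    if not any_read:
        return start
    pileup = np.cumsum(diff[:-1])
    return start + int(np.argmax(pileup))  # argmax -> leftmost tie


def _annotate(peak: Peak, fg: AlignedSample, bgs: dict[str, AlignedSample]) -> Peak:
    def count_in(sample: AlignedSample) -> int:
        return sum(
            1 for p in sample.placements
            if p.chrom == peak.chrom and peak.start <= p.start < peak.end
        )

    fg_n = count_in(fg)
    bg_n = {bid: count_in(bg) for bid, bg in bgs.items()}
    return replace(
        peak,
        fg_effective_reads=fg_n,
        fg_tpm=tpm(fg_n, fg.total_mapped),
        bg_effective_reads=bg_n,
        bg_tpm={bid: tpm(n, bgs[bid].total_mapped) for bid, n in bg_n.items()},
    )


def cross_annotate_called_against(runs: dict[str, list[Peak]], reference: str) -> list[Peak]:
    """Mark each reference-run peak with every background it was called
    against, by >= 1 bp overlap with that background's run."""
    if reference not in runs:
        raise ValueError(f"reference run {reference!r} not among runs")
    trees = {
        bid: _build_tree(peaks) for bid, peaks in runs.items() if bid != reference
    }
    out = []
    for peak in runs[reference]:
        called = {reference}
        for bid, tree in trees.items():
            if tree.get(peak.chrom) is not None and tree[peak.chrom].overlap(peak.start, peak.end):
                called.add(bid)
        out.append(replace(peak, called_against=frozenset(called)))
    return out


def filter_peaks(peaks: list[Peak], rules: FilterRules) -> list[Peak]:
    """Apply the retention rules; returns the retained subset in order."""
    retained = []
    for i, p in enumerate(peaks):
        if set(p.bg_effective_reads) != set(p.bg_tpm):
            missing = set(p.bg_effective_reads) ^ set(p.bg_tpm)
            raise ValueError(
                f"peak {i} ({p.chrom}:{p.start}-{p.end}) missing background entry "
                f"{sorted(missing)}"
            )
        if not p.bg_tpm:
            raise ValueError(f"peak {i} ({p.chrom}:{p.start}-{p.end}) has no backgrounds")
        if rules.broad_mode:
            # broad domains: fold criterion only, satisfied against either bg
            folds = [
                p.fg_tpm / bg if bg > 0 else float("inf") for bg in p.bg_tpm.values()
            ]
            if max(folds) >= rules.broad_min_fold:
                retained.append(p)
            continue
        if p.fg_effective_reads < rules.min_fg_reads:
            continue
        if any(n > rules.max_bg_reads for n in p.bg_effective_reads.values()):
            continue
        max_bg_tpm = max(p.bg_tpm.values())
        fold = p.fg_tpm / max_bg_tpm if max_bg_tpm > 0 else float("inf")
        if fold < rules.min_fold:
            continue
        if rules.require_both_backgrounds and not p.called_against >= set(p.bg_tpm):
            continue
        retained.append(p)
    return retained


# -- overlaps ---------------------------------------------------------------

def _build_tree(peaks: list[Peak]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for p in peaks:
        trees.setdefault(p.chrom, IntervalTree()).addi(p.start, p.end)
    return trees


class _ChromTrees(dict):
    def overlaps(self, peak: Peak) -> bool:
        tree = self.get(peak.chrom)
        return bool(tree and tree.overlap(peak.start, peak.end))


def _trees(peaks: list[Peak]) -> _ChromTrees:
    return _ChromTrees(_build_tree(peaks))


def intersect_peaks(set_a: list[Peak], set_b: list[Peak]) -> list[Peak]:
    """A-side reference semantics: the peaks of set A that overlap (>= 1 bp)
    any peak of set B. Coordinates and summits reported are A's."""
    trees = _trees(set_b)
    return [p for p in set_a if trees.overlaps(p)]


def venn_counts(
    set_a: list[Peak], set_b: list[Peak], set_c: list[Peak]
) -> dict[str, int]:
    """Seven exclusive membership counts with reference-set semantics.

    Regions involving A count A's peaks (classified by which other sets
    they overlap); regions among B and C excluding A count B's peaks for
    "B_only"/"BC" and C's peaks for "C_only". The unit is therefore a peak
    of the region's reference set, matching pairwise reference-set overlap
    reporting.
    """
    ta, tb, tc = _trees(set_a), _trees(set_b), _trees(set_c)
    counts = dict.fromkeys(["A_only", "B_only", "C_only", "AB", "AC", "BC", "ABC"], 0)
    for p in set_a:
        in_b, in_c = tb.overlaps(p), tc.overlaps(p)
        key = "ABC" if in_b and in_c else "AB" if in_b else "AC" if in_c else "A_only"
        counts[key] += 1
    for p in set_b:
        if ta.overlaps(p):
            continue  # counted from A's side
        counts["BC" if tc.overlaps(p) else "B_only"] += 1
    for p in set_c:
        if ta.overlaps(p) or tb.overlaps(p):
            continue
        counts["C_only"] += 1
    return counts


# -- genomic distribution ---------------------------------------------------

CATEGORIES = ("TSS", "TES", "exon", "intron", "intergenic")


def genomic_distribution(
    peaks: list[Peak],
    genome: GenomeModel,
    tss_upstream: int = 300,
    tes_flank: int = 500,
) -> dict[str, float]:
    """Classify each peak's leftmost position; return category fractions.

    The TSS window is one-sided upstream of the gene (strand-aware,
    ``tss_upstream`` bp plus the TSS base itself); the TES window is
    two-sided (+-``tes_flank``). Priority on overlap: TSS > TES > exon >
    intron > intergenic. Fractions sum to 1.
    """
    if not peaks:
        raise ValueError("no peaks to classify")
    trees: dict[str, dict[str, IntervalTree]] = {
        cat: {} for cat in ("TSS", "TES", "exon", "intron")
    }

    def add(cat: str, chrom: str, lo: int, hi: int) -> None:
        lo, hi = max(lo, 0), min(hi, genome.chrom_sizes[chrom])
        if lo < hi:
            trees[cat].setdefault(chrom, IntervalTree()).addi(lo, hi)

    for g in genome.genes:
        if g.strand == "+":
            add("TSS", g.chrom, g.tss - tss_upstream, g.tss + 1)
        else:
            add("TSS", g.chrom, g.tss, g.tss + tss_upstream + 1)
        add("TES", g.chrom, g.tes - tes_flank, g.tes + tes_flank + 1)
        for lo, hi in g.exons:
            add("exon", g.chrom, lo, hi)
        add("intron", g.chrom, *g.body)

    counts = dict.fromkeys(CATEGORIES, 0)
    for p in peaks:
        pos = p.start  # leftmost position
        for cat in ("TSS", "TES", "exon", "intron"):
            tree = trees[cat].get(p.chrom)
            if tree is not None and tree.overlaps_point(pos):
                counts[cat] += 1
                break
        else:
            counts["intergenic"] += 1
    total = len(peaks)
    return {cat: counts[cat] / total for cat in CATEGORIES}
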