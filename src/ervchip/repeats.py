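"""Repeat-space quantification: padded library, best-hit read assignment,
per-element enrichment over input, category box statistics and per-class
sample correlation.

Repeat copies are short relative to reads that straddle their edges, so
each copy is padded by one read length (51 bp by default) on both sides
before assignment. A read is compatible with an element when its full
interval lies within the padded element ("best hit" in coordinate space);
a read compatible with several elements is assigned to exactly one of them,
chosen uniformly with seeded pseudo-randomness — mirroring a single-best-hit
aligner's arbitrary choice among equally good hits. Per-element TPM and
log2 fold-change over the input channel follow, with a small count-space
floor keeping zero-count elements finite.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml
from intervaltree import IntervalTree
from scipy.stats import spearmanr

from .genome import GenomeModel
from .signal import tpm
from .simdata import AlignedSample

DEFAULT_PAD = 51
DEFAULT_FLOOR = 0.5  # reads, added to both channels


@dataclass(frozen=True)
class PaddedElement:
    element_id: str
    chrom: str
    padded_start: int
    padded_end: int
    strand: str
    rep_name: str
    rep_class: str
    rep_family: str
    category: str


@dataclass
class PaddedRepeatLibrary:
    elements: list[PaddedElement]
    pad: int

    def __post_init__(self) -> None:
        ids = [e.element_id for e in self.elements]
        if len(set(ids)) != len(ids):
            raise ValueError("element_ids are not unique")


class CategoryMap:
    """Maps (repName, repClass) to a summary category.

    Resolution order: exact repName, repName prefix, repClass, fallback
    (the repName itself). The default map keeps the major IAP subfamilies
    and L1Md_F as their own categories, pools remaining IAP* copies into
    "IAP other", and pools the rest of LINE.
    """

    def __init__(self, named: dict[str, str], prefix: dict[str, str],
                 by_class: dict[str, str], fallback: str = "repName"):
        self.named = named
        self.prefix = prefix
        self.by_class = by_class
        self.fallback = fallback

    @classmethod
    def default(cls) -> "CategoryMap":
        text = (importlib.resources.files("ervchip") / "data/category_map.yaml").read_text()
        return cls.from_dict(yaml.safe_load(text))

    @classmethod
    def from_dict(cls, d: dict) -> "CategoryMap":
        return cls(d.get("named", {}), d.get("prefix", {}), d.get("class", {}),
                   d.get("fallback", "repName"))

    def __call__(self, rep_name: str, rep_class: str) -> str:
        if rep_name in self.named:
            return self.named[rep_name]
        for pre, cat in self.prefix.items():
            if rep_name.startswith(pre):
                return cat
        if rep_class in self.by_class:
            return self.by_class[rep_class]
        return rep_name if self.fallback == "repName" else self.fallback


def build_padded_library(
    genome: GenomeModel,
    pad: int = DEFAULT_PAD,
    drop_sex_chroms: bool = False,
    category_map: CategoryMap | None = None,
) -> PaddedRepeatLibrary:
    """Pad every repeat copy by ``pad`` bp each side, clipped to the
    chromosome; optionally drop sex-chromosome copies (for sex-mismatched
    sample comparisons)."""
    cmap = category_map or CategoryMap.default()
    elements = []
    for i, r in enumerate(genome.repeats):
        if r.chrom not in genome.chrom_sizes:
            raise ValueError(f"repeat {r.rep_name} on unknown chromosome {r.chrom!r}")
        if drop_sex_chroms and r.chrom in genome.sex_chrom_names:
            continue
        elements.append(
            PaddedElement(
                element_id=f"{r.rep_name}|{r.chrom}:{r.start}-{r.end}|{i}",
                chrom=r.chrom,
                padded_start=max(0, r.start - pad),
                padded_end=min(genome.chrom_sizes[r.chrom], r.end + pad),
                strand=r.strand,
                rep_name=r.rep_name,
                rep_class=r.rep_class,
                rep_family=r.rep_family,
                category=cmap(r.rep_name, r.rep_class),
            )
        )
    return PaddedRepeatLibrary(elements, pad)


def assign_reads(
    sample: AlignedSample, library: PaddedRepeatLibrary, seed: int = 0
) -> tuple[dict[str, int], int]:
    """Best-hit assignment: element_id -> read count, plus unassigned count.

    A read is compatible with an element iff fully contained in the padded
    interval; ties among compatible elements are broken uniformly at random
    (seeded). Conservation: sum(counts) + unassigned == sample size.
    """
    rng = np.random.default_rng(seed)
    trees: dict[str, IntervalTree] = {}
    for idx, e in enumerate(library.elements):
        trees.setdefault(e.chrom, IntervalTree()).addi(e.padded_start, e.padded_end, idx)

    counts = {e.element_id: 0 for e in library.elements}
    unassigned = 0
    for p in sample.placements:
        tree = trees.get(p.chrom)
        hits = []
        if tree is not None:
            # containment: element interval must cover the whole read
            hits = [
                iv.data for iv in tree.overlap(p.start, p.end)
                if iv.begin <= p.start and p.end <= iv.end
            ]
        if not hits:
            unassigned += 1
            continue
        hits.sort()  # determinism of the tie-break given the seed
        chosen = hits[0] if len(hits) == 1 else hits[int(rng.integers(len(hits)))]
        counts[library.elements[chosen].element_id] += 1
    return counts, unassigned


def element_enrichment(
    chip_counts: dict[str, int],
    input_counts: dict[str, int],
    chip_depth: int,
    input_depth: int,
    library: PaddedRepeatLibrary,
    floor_reads: float = DEFAULT_FLOOR,
) -> pd.DataFrame:
    """Per-element TPM and log2 fold-change over input.

    The floor is added in count space to both channels before the ratio, so
    log2fc is finite for zero-count elements; the raw TPM columns are
    floor-free. Depth here is the channel's effective mapped-read total.
    """
    if chip_depth < 1 or input_depth < 1:
        raise ValueError("channel depth must be >= 1")
    rows = []
    for e in library.elements:
        c = chip_counts.get(e.element_id, 0)
        i = input_counts.get(e.element_id, 0)
        chip_f = tpm(c + floor_reads, chip_depth)
        input_f = tpm(i + floor_reads, input_depth)
        rows.append(
            {
                "element_id": e.element_id,
                "repName": e.rep_name,
                "repClass": e.rep_class,
                "repFamily": e.rep_family,
                "category": e.category,
                "chip_count": c,
                "input_count": i,
                "chip_tpm": tpm(c, chip_depth),
                "input_tpm": tpm(i, input_depth),
                "log2fc": float(np.log2(chip_f / input_f)),
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class CategorySummary:
    """Tukey box statistics under the 1.5 x IQR whisker convention:
    whiskers sit on the most extreme data points within the fences, not on
    the fences themselves."""

    category: str
    n: int
    median: float
    q1: float
    q3: float
    whisker_low: float
    whisker_high: float
    outliers: tuple[float, ...]


def category_summary(signals: pd.DataFrame, category: str,
                     value_col: str = "log2fc") -> CategorySummary:
    values = np.sort(signals.loc[signals["category"] == category, value_col].to_numpy())
    if values.size == 0:
        raise ValueError(f"category {category!r} is empty")
    q1, med, q3 = np.percentile(values, [25, 50, 75])  # linear interpolation
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = values[(values >= lo_fence) & (values <= hi_fence)]
    outliers = values[(values < lo_fence) | (values > hi_fence)]
    return CategorySummary(
        category, int(values.size), float(med), float(q1), float(q3),
        float(inside.min()), float(inside.max()), tuple(float(v) for v in outliers),
    )


def summarize_categories(signals: pd.DataFrame, value_col: str = "log2fc") -> pd.DataFrame:
    rows = []
    for cat in sorted(signals["category"].unique()):
        s = category_summary(signals, cat, value_col)
        rows.append(
            {"category": cat, "n": s.n, "median": s.median, "q1": s.q1, "q3": s.q3,
             "whisker_low": s.whisker_low, "whisker_high": s.whisker_high,
             "n_outliers": len(s.outliers)}
        )
    return pd.DataFrame(rows)


def class_correlation(
    signals_a: pd.DataFrame, signals_b: pd.DataFrame,
    group_by: str = "repClass", value_col: str = "log2fc", min_elements: int = 3,
) -> pd.DataFrame:
    """Spearman rho between two samples' per-element values, per repeat
    class (average-rank ties), on elements present in both."""
    merged = signals_a.merge(
        signals_b[["element_id", value_col]], on="element_id", suffixes=("_a", "_b")
    )
    rows = []
    for cls, grp in merged.groupby(group_by, sort=True):
        if len(grp) < min_elements:
            continue
        rho, _ = spearmanr(grp[f"{value_col}_a"], grp[f"{value_col}_b"])
        rows.append({group_by: cls, "n": len(grp), "spearman_rho": float(rho)})
    return pd.DataFrame(rows)


def repname_medians(signals: pd.DataFrame, value_col: str = "log2fc") -> pd.DataFrame:
    """Median signal per repName (scatter-plot export)."""
    out = (
        signals.groupby(["repName", "repClass"], sort=True)[value_col]
        .median().reset_index().rename(columns={value_col: f"median_{value_col}"})
    )
    return out
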