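"""Synthetic ChIP-seq data with known (planted) truth.

Generates toy genomes carrying repeat families and gene models, and
strand-aware single-end read sets for ChIP / input / antibody-control
channels. Reads are drawn from a mixture of a uniform background over all
valid start positions and repeat-family components whose probability mass is
multiplied by a per-family fold factor; PCR duplicates are modelled by
re-emitting already-sampled placements (identical position and strand) at a
configurable rate. Everything is seeded and deterministic, so every
downstream stage of the toolkit can be tested without external data.

No sequence-level simulation is attempted: placements only, no bases and no
sequencing-error model.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .genome import GeneRecord, GenomeModel, RepeatRecord

DEFAULT_READ_LENGTH = 51


@dataclass(frozen=True, order=True)
class Placement:
    chrom: str
    start: int
    strand: str
    length: int = DEFAULT_READ_LENGTH

    @property
    def end(self) -> int:
        return self.start + self.length


@dataclass
class AlignedSample:
    """One sequencing channel as strand-aware read placements.

    ``total_mapped`` equals the number of placements before de-duplication;
    the dedup stage produces a new sample whose ``total_mapped`` is the
    retained ("effective") read count.
    """

    sample_id: str
    role: str  # chip | input | antibody_control
    placements: list[Placement]
    total_mapped: int

    ROLES = ("chip", "input", "antibody_control")

    def __post_init__(self) -> None:
        if self.role not in self.ROLES:
            raise ValueError(f"role must be one of {self.ROLES}, got {self.role!r}")
        if self.total_mapped != len(self.placements):
            raise ValueError(
                f"total_mapped={self.total_mapped} != {len(self.placements)} placements"
            )

    def arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """(chrom, start, strand, length) as parallel numpy arrays."""
        chrom = np.array([p.chrom for p in self.placements], dtype=object)
        start = np.array([p.start for p in self.placements], dtype=np.int64)
        strand = np.array([p.strand for p in self.placements], dtype=object)
        length = np.array([p.length for p in self.placements], dtype=np.int64)
        return chrom, start, strand, length

    def validate_against(self, genome: GenomeModel) -> None:
        for p in self.placements:
            if p.chrom not in genome.chrom_sizes:
                raise ValueError(f"placement on unknown chromosome {p.chrom!r}")
            if p.start < 0 or p.end > genome.chrom_sizes[p.chrom]:
                raise ValueError(
                    f"placement {p.chrom}:{p.start} (len {p.length}) out of bounds"
                )


@dataclass
class RepeatFamilySpec:
    """How many copies of one repeat family to plant, and how long each is."""

    rep_name: str
    rep_class: str
    rep_family: str
    n_copies: int
    length: int


@dataclass
class ToyGenomeConfig:
    chrom_sizes: dict[str, int]
    repeat_families: list[RepeatFamilySpec] = field(default_factory=list)
    n_genes: int = 0
    gene_length: int = 4000
    exons_per_gene: int = 3
    exon_length: int = 300
    seed: int = 0
    min_gap: int = 100  # between planted features


@dataclass
class EnrichmentSpec:
    """Planted enrichment for one simulated channel.

    ``factors`` maps repName -> fold enrichment of read density inside the
    family's copies relative to the uniform background. A factor of 1 leaves
    the family at background density.
    """

    n_reads: int
    factors: dict[str, float] = field(default_factory=dict)
    background_weight: float = 1.0
    read_length: int = DEFAULT_READ_LENGTH
    duplicate_rate: float = 0.05
    seed: int = 0
    sample_id: str = "sample"
    role: str = "chip"

    def __post_init__(self) -> None:
        if self.n_reads < 1:
            raise ValueError("n_reads must be >= 1")
        if not 0 <= self.duplicate_rate < 1:
            raise ValueError("duplicate_rate must be in [0, 1)")
        if self.background_weight <= 0:
            raise ValueError("background_weight must be > 0")
        for name, f in self.factors.items():
            if f <= 0:
                raise ValueError(f"fold factor for {name} must be > 0, got {f}")


def build_toy_genome(config: ToyGenomeConfig) -> GenomeModel:
    """Plant the requested repeat copies and genes on a toy genome.

    Placement is uniform-random but rejection-sampled so features do not
    overlap (separated by ``config.min_gap``); deterministic for a given
    seed. Raises a configuration error when a repeat cannot fit on any
    chromosome.
    """
    rng = np.random.default_rng(config.seed)
    chroms = list(config.chrom_sizes)
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}

    def place(length: int, what: str) -> tuple[str, int]:
        fitting = [c for c in chroms if config.chrom_sizes[c] >= length]
        if not fitting:
            raise ValueError(f"{what}: length {length} exceeds every chromosome")
        sizes = np.array([config.chrom_sizes[c] - length + 1 for c in fitting], float)
        for _ in range(10_000):
            c = fitting[int(rng.choice(len(fitting), p=sizes / sizes.sum()))]
            s = int(rng.integers(0, config.chrom_sizes[c] - length + 1))
            pad = config.min_gap
            if all(s >= e + pad or s + length + pad <= b for b, e in occupied[c]):
                occupied[c].append((s, s + length))
                return c, s
        raise ValueError(f"{what}: could not place without overlap (genome too full)")

    repeats: list[RepeatRecord] = []
    for fam in config.repeat_families:
        for i in range(fam.n_copies):
            chrom, start = place(fam.length, f"repeat {fam.rep_name}")
            strand = "+" if rng.random() < 0.5 else "-"
            repeats.append(
                RepeatRecord(chrom, start, start + fam.length, strand,
                             fam.rep_name, fam.rep_class, fam.rep_family)
            )

    genes: list[GeneRecord] = []
    for i in range(config.n_genes):
        chrom, start = place(config.gene_length, "gene")
        strand = "+" if rng.random() < 0.5 else "-"
        end = start + config.gene_length
        # evenly spaced exons inside the gene body
        step = config.gene_length // config.exons_per_gene
        exons = tuple(
            (start + j * step, min(start + j * step + config.exon_length, end))
            for j in range(config.exons_per_gene)
        )
        tss, tes = (start, end - 1) if strand == "+" else (end - 1, start)
        genes.append(GeneRecord(chrom, tss, tes, strand, exons, name=f"gene{i}"))

    repeats.sort(key=lambda r: (r.chrom, r.start))
    genes.sort(key=lambda g: (g.chrom, min(g.tss, g.tes)))
    return GenomeModel(dict(config.chrom_sizes), repeats, genes)


def default_toy_config(seed: int = 0, scale: float = 1.0) -> ToyGenomeConfig:
    """The study-condition toy genome: mouse ERV/LINE families on ~1 Mb.

    Family lengths are order-of-magnitude realistic (IAP internal segments
    are kb-scale, LTRs a few hundred bp); copy numbers are chosen so each
    category holds enough copies for a stable median while repeats stay a
    small fraction of the genome.
    """
    def n(k: int) -> int:
        return max(2, int(round(k * scale)))

    return ToyGenomeConfig(
        chrom_sizes={"chr1": 600_000, "chr2": 400_000, "chrX": 120_000, "chrY": 60_000},
        repeat_families=[
            RepeatFamilySpec("IAPEz-int", "LTR", "ERVK", n(15), 1200),
            RepeatFamilySpec("IAPLTR1a", "LTR", "ERVK", n(15), 340),
            RepeatFamilySpec("IAPA_MM-int", "LTR", "ERVK", n(10), 1000),
            RepeatFamilySpec("IAPLTR2_Mm", "LTR", "ERVK", n(8), 330),
            RepeatFamilySpec("VL30", "LTR", "ERV1", n(12), 900),
            RepeatFamilySpec("MMERVK10C-int", "LTR", "ERVK", n(10), 1100),
            RepeatFamilySpec("MERVL-int", "LTR", "ERVL", n(10), 900),
            RepeatFamilySpec("L1Md_F", "LINE", "L1", n(12), 1500),
            RepeatFamilySpec("L1_Mus", "LINE", "L1", n(15), 1300),
        ],
        n_genes=8,
        seed=seed,
    )


def _weighted_segments(
    genome: GenomeModel, spec: EnrichmentSpec
) -> tuple[list[tuple[str, int, int]], np.ndarray]:
    """Decompose valid start positions into constant-weight segments.

    Returns ([(chrom, start, end)], weights) where weight applies per start
    position; overlapping repeats contribute the max factor.
    """
    known = {r.rep_name for r in genome.repeats}
    for name in spec.factors:
        if name not in known:
            raise ValueError(f"fold factor given for repeat family {name!r} absent from genome")

    segments: list[tuple[str, int, int]] = []
    weights: list[float] = []
    for chrom, size in genome.chrom_sizes.items():
        n_valid = size - spec.read_length + 1
        if n_valid <= 0:
            continue
        # boundary sweep over repeat copies with a factor
        events: list[tuple[int, int, float]] = []
        for r in genome.repeats:
            if r.chrom != chrom or r.rep_name not in spec.factors:
                continue
            lo = max(0, r.start)
            hi = min(n_valid, r.end)  # reads *starting* inside the repeat
            if lo < hi:
                events.append((lo, hi, spec.factors[r.rep_name]))
        cuts = sorted({0, n_valid, *(e[0] for e in events), *(e[1] for e in events)})
        for a, b in zip(cuts[:-1], cuts[1:]):
            factor = max((f for lo, hi, f in events if lo <= a and b <= hi), default=1.0)
            segments.append((chrom, a, b))
            weights.append(spec.background_weight * factor * (b - a))
    if not segments:
        raise ValueError("genome has no valid start positions for this read length")
    return segments, np.asarray(weights, float)


def expected_family_fractions(genome: GenomeModel, spec: EnrichmentSpec) -> dict[str, float]:
    """Analytic mixture weight: expected fraction of reads starting inside
    each family with a declared factor (before duplication, which preserves
    expectations)."""
    segments, weights = _weighted_segments(genome, spec)
    total = weights.sum()
    out: dict[str, float] = {}
    for name, factor in spec.factors.items():
        mass = 0.0
        for r in genome.repeats:
            if r.rep_name != name:
                continue
            n_valid = genome.chrom_sizes[r.chrom] - spec.read_length + 1
            span = max(0, min(n_valid, r.end) - max(0, r.start))
            mass += spec.background_weight * factor * span
        out[name] = mass / total
    return out


def simulate_chip_experiment(genome: GenomeModel, spec: EnrichmentSpec) -> AlignedSample:
    """Draw ``spec.n_reads`` seeded placements from the planted mixture.

    Duplicates re-emit a uniformly chosen earlier placement, so a duplicate
    is positionally identical to its template — the phenomenon the binomial
    de-duplication targets.
    """
    rng = np.random.default_rng(spec.seed)
    segments, weights = _weighted_segments(genome, spec)
    probs = weights / weights.sum()
    n = spec.n_reads

    is_dup = rng.random(n) < spec.duplicate_rate
    is_dup[0] = False  # nothing to duplicate yet
    n_fresh = int((~is_dup).sum())

    seg_idx = rng.choice(len(segments), size=n_fresh, p=probs)
    offsets = rng.random(n_fresh)
    strands = rng.integers(0, 2, size=n_fresh)

    placements: list[Placement] = [None] * n  # type: ignore[list-item]
    fresh_i = 0
    for i in range(n):
        if is_dup[i]:
            j = int(rng.integers(0, i))
            placements[i] = placements[j]
        else:
            chrom, a, b = segments[seg_idx[fresh_i]]
            pos = a + int(offsets[fresh_i] * (b - a))
            placements[i] = Placement(
                chrom, pos, "+" if strands[fresh_i] == 0 else "-", spec.read_length
            )
            fresh_i += 1
    return AlignedSample(spec.sample_id, spec.role, placements, n)


def write_fixture_set(
    genome: GenomeModel,
    samples: list[AlignedSample],
    outdir: str | Path,
    truth: dict | None = None,
) -> dict[str, str]:
    """Write a complete on-disk fixture: chrom.sizes, repeat and gene tables,
    one BED6 per sample, and a JSON truth file. Returns the file manifest."""
    from . import io as eio

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, str] = {}
    try:
        eio.write_chrom_sizes(genome.chrom_sizes, out / "chrom.sizes")
        manifest["chrom_sizes"] = str(out / "chrom.sizes")
        eio.write_repeat_table(genome.repeats, out / "repeats.tsv")
        manifest["repeats"] = str(out / "repeats.tsv")
        eio.write_gene_table(genome.genes, out / "genes.bed")
        manifest["genes"] = str(out / "genes.bed")
        for s in samples:
            path = out / f"{s.sample_id}.bed"
            eio.write_reads_bed(s, path)
            manifest[f"reads:{s.sample_id}"] = str(path)
        truth_path = out / "truth.json"
        truth_path.write_text(json.dumps(_jsonable(truth or {}), indent=2, sort_keys=True))
        manifest["truth"] = str(truth_path)
    except OSError as err:
        raise OSError(f"writing fixture set under {out}: {err}") from err
    return manifest


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj
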