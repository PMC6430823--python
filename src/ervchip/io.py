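"""Readers and writers for the plain-text formats the toolkit exchanges.

chrom.sizes (UCSC two-column), BED6 read placements, RepeatMasker-style
repeat tables, BED12-like gene tables, BED6+ peak tables, narrowPeak, and
Cq tables for qPCR. All on-disk coordinates are BED-dialect 0-based
half-open, matching the in-memory convention, so readers and writers are
exact inverses.
"""

from __future__ import annotations

import csv
from pathlib import Path

import pandas as pd

from .genome import GeneRecord, GenomeModel, RepeatRecord
from .simdata import AlignedSample, Placement

REPEAT_COLUMNS = ["genoName", "genoStart", "genoEnd", "strand", "repName", "repClass", "repFamily"]


# -- chrom.sizes ------------------------------------------------------------

def write_chrom_sizes(chrom_sizes: dict[str, int], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, size in chrom_sizes.items():
            fh.write(f"{name}\t{size}\n")


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            name, size = line.split()[:2]
            if name in sizes:
                raise ValueError(f"{path}: duplicate chromosome {name!r}")
            sizes[name] = int(size)
    return sizes


# -- reads (BED6) -----------------------------------------------------------

def write_reads_bed(sample: AlignedSample, path: str | Path) -> None:
    with open(path, "w") as fh:
        for i, p in enumerate(sample.placements):
            fh.write(f"{p.chrom}\t{p.start}\t{p.end}\t{sample.sample_id}_{i}\t0\t{p.strand}\n")


def read_reads_bed(path: str | Path, sample_id: str | None = None, role: str = "chip") -> AlignedSample:
    placements: list[Placement] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("track", "browser", "#")):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 6:
                raise ValueError(f"{path}:{ln}: expected BED6, got {len(parts)} fields")
            chrom, start, end, _name, _score, strand = parts[:6]
            placements.append(Placement(chrom, int(start), strand, int(end) - int(start)))
    sid = sample_id if sample_id is not None else Path(path).stem
    return AlignedSample(sid, role, placements, len(placements))


# -- repeat annotation ------------------------------------------------------

def write_repeat_table(repeats: list[RepeatRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(REPEAT_COLUMNS) + "\n")
        for r in repeats:
            fh.write(
                f"{r.chrom}\t{r.start}\t{r.end}\t{r.strand}\t{r.rep_name}\t{r.rep_class}\t{r.rep_family}\n"
            )


def read_repeat_table(path: str | Path) -> list[RepeatRecord]:
    """UCSC RepeatMasker column dialect; extra columns are ignored."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in REPEAT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing repeat-table columns {missing}")
    return [
        RepeatRecord(
            str(row.genoName), int(row.genoStart), int(row.genoEnd), str(row.strand),
            str(row.repName), str(row.repClass), str(row.repFamily),
        )
        for row in df.itertuples(index=False)
    ]


# -- genes (BED12-like) -----------------------------------------------------

def write_gene_table(genes: list[GeneRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            lo, hi = g.body
            starts = sorted(s for s, _ in g.exons)
            sizes = [e - s for s, e in sorted(g.exons)]
            fh.write(
                "\t".join(
                    map(str, [
                        g.chrom, lo, hi, g.name or ".", 0, g.strand, lo, hi, "0",
                        len(g.exons),
                        ",".join(map(str, sizes)) + ("," if sizes else ""),
                        ",".join(str(s - lo) for s in starts) + ("," if starts else ""),
                    ])
                ) + "\n"
            )


def read_gene_table(path: str | Path) -> list[GeneRecord]:
    genes: list[GeneRecord] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("track", "#")):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 12:
                raise ValueError(f"{path}:{ln}: expected 12 BED12 fields")
            chrom, start, end, name, _score, strand = parts[:6]
            start, end = int(start), int(end)
            n_blocks = int(parts[9])
            sizes = [int(x) for x in parts[10].rstrip(",").split(",") if x] if n_blocks else []
            offs = [int(x) for x in parts[11].rstrip(",").split(",") if x] if n_blocks else []
            exons = tuple((start + o, start + o + s) for o, s in zip(offs, sizes))
            tss, tes = (start, end - 1) if strand == "+" else (end - 1, start)
            genes.append(GeneRecord(chrom, tss, tes, strand, exons, name=name))
    return genes


def read_genome(chrom_sizes_path, repeats_path=None, genes_path=None) -> GenomeModel:
    return GenomeModel(
        read_chrom_sizes(chrom_sizes_path),
        read_repeat_table(repeats_path) if repeats_path else [],
        read_gene_table(genes_path) if genes_path else [],
    )


# -- peaks ------------------------------------------------------------------

PEAK_COLUMNS = [
    "chrom", "start", "end", "name", "score", "strand", "summit",
    "fg_effective_reads", "fg_tpm", "bg_effective_reads", "bg_tpm", "called_against",
]


def write_peak_table(peaks, path: str | Path) -> None:
    """BED6+ dialect: per-background counts/TPMs encoded as `id:value` lists."""
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(PEAK_COLUMNS) + "\n")
        for i, p in enumerate(peaks):
            bg_counts = ",".join(f"{k}:{v}" for k, v in sorted(p.bg_effective_reads.items()))
            bg_tpms = ",".join(f"{k}:{v:.6g}" for k, v in sorted(p.bg_tpm.items()))
            called = ",".join(sorted(p.called_against))
            fh.write(
                f"{p.chrom}\t{p.start}\t{p.end}\tpeak_{i}\t0\t.\t{p.summit}\t"
                f"{p.fg_effective_reads}\t{p.fg_tpm:.6g}\t{bg_counts or '.'}\t"
                f"{bg_tpms or '.'}\t{called or '.'}\n"
            )


def read_peak_table(path: str | Path):
    from .peaks import Peak

    def parse_map(s: str, cast):
        if s == ".":
            return {}
        return {k: cast(v) for k, v in (item.split(":") for item in s.split(","))}

    peaks = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            peaks.append(
                Peak(
                    chrom=f[0], start=int(f[1]), end=int(f[2]), summit=int(f[6]),
                    fg_effective_reads=int(f[7]), fg_tpm=float(f[8]),
                    bg_effective_reads=parse_map(f[9], int), bg_tpm=parse_map(f[10], float),
                    called_against=frozenset() if f[11] == "." else frozenset(f[11].split(",")),
                )
            )
    return peaks


def read_narrowpeak(path: str | Path):
    """ENCODE narrowPeak: summit taken from column 10 (peak offset), or the
    interval midpoint when the offset is -1. Counts/TPMs are left empty — a
    narrowPeak carries neither — and must be annotated before filtering."""
    from .peaks import Peak

    peaks = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("track", "#")):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 10:
                raise ValueError(f"{path}:{ln}: expected 10 narrowPeak fields")
            start, end, offset = int(f[1]), int(f[2]), int(f[9])
            summit = start + offset if offset >= 0 else (start + end) // 2
            peaks.append(Peak(f[0], start, end, summit, 0, 0.0, {}, {}, frozenset()))
    return peaks


# -- qPCR Cq tables ---------------------------------------------------------

def read_cq_table(path: str | Path) -> pd.DataFrame:
    """TSV with columns: sample, target, role, replicate, Cq, input_fraction."""
    df = pd.read_csv(path, sep="\t")
    required = {"sample", "target", "role", "replicate", "Cq"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing Cq-table columns {sorted(missing)}")
    if "input_fraction" not in df.columns:
        df["input_fraction"] = 1.0
    return df


# -- generic tables ---------------------------------------------------------

def write_tsv(df: pd.DataFrame, path: str | Path, float_format: str = "%.10g") -> None:
    df.to_csv(path, sep="\t", index=False, float_format=float_format,
              quoting=csv.QUOTE_NONE, lineterminator="\n")
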