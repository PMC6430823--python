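"""TPM normalization, summit-centered profiles and heatmap matrices.

Signal is per-base coverage of *extended* reads: each read is lengthened by
a fixed amount upstream and downstream of itself (defaults 200 bp upstream,
350 bp downstream), which slightly smooths single-end pileups. Extension is
read-strand-aware: upstream for a minus-strand read points right-ward in
genome coordinates. Coverage is expressed in TPM (tag per million) units —
each read contributes 1e6 / total_mapped to every base it covers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genome import GenomeModel
from .simdata import AlignedSample

DEFAULT_EXT_UP = 200
DEFAULT_EXT_DOWN = 350


def tpm(count: float, total_mapped: int) -> float:
    """Tag-per-million normalization: count / total_mapped * 1e6."""
    if total_mapped < 1:
        raise ValueError("total_mapped must be >= 1")
    return count / total_mapped * 1e6


@dataclass
class SignalTrack:
    """Per-chromosome extended-read coverage in TPM units."""

    coverage: dict[str, np.ndarray]
    ext_up: int
    ext_down: int
    total_mapped: int

    def value(self, chrom: str, pos: int) -> float:
        arr = self.coverage.get(chrom)
        if arr is None or not 0 <= pos < len(arr):
            return 0.0
        return float(arr[pos])

    def write_bedgraph(self, path) -> None:
        with open(path, "w") as fh:
            for chrom in sorted(self.coverage):
                arr = self.coverage[chrom]
                # run-length encode constant stretches
                change = np.flatnonzero(np.diff(arr)) + 1
                bounds = np.concatenate(([0], change, [len(arr)]))
                for a, b in zip(bounds[:-1], bounds[1:]):
                    if arr[a] != 0:
                        fh.write(f"{chrom}\t{a}\t{b}\t{arr[a]:.6g}\n")


def coverage_track(
    sample: AlignedSample,
    genome: GenomeModel,
    ext_up: int = DEFAULT_EXT_UP,
    ext_down: int = DEFAULT_EXT_DOWN,
) -> SignalTrack:
    """Extended-read TPM coverage via a difference-array accumulation."""
    if ext_up < 0 or ext_down < 0:
        raise ValueError("extensions must be >= 0")
    if sample.total_mapped < 1:
        raise ValueError("sample has no reads")
    weight = 1e6 / sample.total_mapped
    diff = {c: np.zeros(size + 1) for c, size in genome.chrom_sizes.items()}
    for p in sample.placements:
        if p.strand == "+":
            lo, hi = p.start - ext_up, p.end + ext_down
        else:
            lo, hi = p.start - ext_down, p.end + ext_up
        size = genome.chrom_sizes[p.chrom]
        lo, hi = max(lo, 0), min(hi, size)
        if lo < hi:
            diff[p.chrom][lo] += weight
            diff[p.chrom][hi] -= weight
    return SignalTrack(
        {c: np.cumsum(d[:-1]) for c, d in diff.items()}, ext_up, ext_down,
        sample.total_mapped,
    )


def average_profile(
    summits: list[tuple[str, int]],
    sample: AlignedSample,
    genome: GenomeModel,
    half_window: int = 2000,
    ext_up: int = DEFAULT_EXT_UP,
    ext_down: int = DEFAULT_EXT_DOWN,
    track: SignalTrack | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Mean TPM at every offset in [-half_window, +half_window] around summits.

    Summed extended-read TPM across summits divided by the number of
    summits; positions falling off a chromosome contribute zero. Returns
    (offsets, mean_tpm).
    """
    if not summits:
        raise ValueError("average_profile requires at least one summit")
    if track is None:
        track = coverage_track(sample, genome, ext_up, ext_down)
    offsets = np.arange(-half_window, half_window + 1)
    total = np.zeros(len(offsets))
    for chrom, pos in summits:
        arr = track.coverage.get(chrom)
        if arr is None:
            continue
        lo, hi = pos - half_window, pos + half_window + 1
        a, b = max(lo, 0), min(hi, len(arr))
        if a < b:
            total[a - lo : b - lo] += arr[a:b]
    return offsets, total / len(summits)


@dataclass
class ProfileMatrix:
    """Summit-centered signal matrices on a shared row ordering and cap.

    ``matrices[sample_id]`` has one row per peak (in ``row_order`` of the
    input peak list) and one column per position of the window; values are
    clipped to [0, cap], the cap being a percentile of the reference
    sample's matrix.
    """

    matrices: dict[str, np.ndarray]
    row_order: np.ndarray
    cap: float
    cap_reference: str
    window: int


def heatmap_matrix(
    summits: list[tuple[str, int]],
    samples: dict[str, AlignedSample],
    genome: GenomeModel,
    cap_reference: str,
    window: int = 10_000,
    cap_percentile: float = 98.0,
    ext_up: int = DEFAULT_EXT_UP,
    ext_down: int = DEFAULT_EXT_DOWN,
    sort_rows: bool = True,
) -> ProfileMatrix:
    """Per-sample summit-centered matrices, cap-referenced and co-ordered.

    Rows span ``window`` bp centered on each summit (offsets
    [-window/2, window/2)). All samples share one row order — descending
    total intensity of the reference sample's rows — and one cap, the
    ``cap_percentile`` (linear-interpolation) of the reference matrix.
    """
    if window % 2:
        raise ValueError("window must be even")
    if cap_reference not in samples:
        raise ValueError(f"cap_reference {cap_reference!r} not among samples")
    if not summits:
        raise ValueError("heatmap_matrix requires at least one summit")

    half = window // 2
    raw: dict[str, np.ndarray] = {}
    for sid, sample in samples.items():
        track = coverage_track(sample, genome, ext_up, ext_down)
        mat = np.zeros((len(summits), window))
        for i, (chrom, pos) in enumerate(summits):
            arr = track.coverage.get(chrom)
            if arr is None:
                continue
            lo, hi = pos - half, pos + half
            a, b = max(lo, 0), min(hi, len(arr))
            if a < b:
                mat[i, a - lo : b - lo] = arr[a:b]
        raw[sid] = mat

    ref = raw[cap_reference]
    order = (
        np.argsort(-ref.sum(axis=1), kind="stable")
        if sort_rows
        else np.arange(len(summits))
    )
    cap = float(np.percentile(ref, cap_percentile))  # linear interpolation (type 7)
    matrices = {sid: np.clip(mat[order], 0.0, cap) for sid, mat in raw.items()}
    return ProfileMatrix(matrices, order, cap, cap_reference, window)


def write_matrix_tsv(matrix: np.ndarray, path, row_ids=None) -> None:
    """Matrix as TSV with offset column headers and row identifiers."""
    n_rows, n_cols = matrix.shape
    half = n_cols // 2
    with open(path, "w") as fh:
        fh.write("row\t" + "\t".join(str(o) for o in range(-half, n_cols - half)) + "\n")
        ids = row_ids if row_ids is not None else range(n_rows)
        for rid, row in zip(ids, matrix):
            fh.write(str(rid) + "\t" + "\t".join(f"{v:.6g}" for v in row) + "\n")
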