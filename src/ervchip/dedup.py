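"""Effective-read de-duplication under a binomial null.

With N mapped reads falling uniformly on P distinct (position, strand)
start sites, the multiplicity of one site is X ~ Binomial(N, 1/P). Some
exact-duplicate placements are then expected by chance, and removing all of
them would bias deep libraries. Instead, each site's multiplicity is capped
at c*, the largest count the null still expects to produce somewhere in the
genome: the largest c >= 1 with

    P * Pr(X >= c) >= 1.

Reads above the cap at a site are treated as PCR duplicates and dropped;
everything retained constitutes the "effective reads" used downstream. The
cap is global and the excess is dropped in stable input order, which makes
the operation deterministic and idempotent.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy.stats import binom, poisson

from .genome import GenomeModel
from .simdata import AlignedSample

# above this many sites the Poisson(N/P) tail is numerically indistinguishable
# from the exact binomial and much cheaper
POISSON_THRESHOLD = 10_000


@dataclass(frozen=True)
class DedupModel:
    """The calibrated null for one sample."""

    n_reads: int
    n_sites: int
    cap: int

    @property
    def rate(self) -> float:
        """Mean reads per site, lambda = N/P."""
        return self.n_reads / self.n_sites


def duplicate_cap(n_reads: int, n_sites: int) -> int:
    """Largest per-site multiplicity still expected >= once under the null.

    Exact binomial tail for small site counts, Poisson approximation above
    ``POISSON_THRESHOLD`` sites. Always >= 1: a single read is never a
    duplicate of itself.
    """
    if n_reads < 1:
        raise ValueError("no reads to de-duplicate (N = 0)")
    if n_sites < 1:
        raise ValueError("need at least one start site (P = 0)")

    def expected_sites_at_least(c: int) -> float:
        if n_sites > POISSON_THRESHOLD:
            tail = poisson.sf(c - 1, n_reads / n_sites)
        else:
            tail = binom.sf(c - 1, n_reads, 1.0 / n_sites)
        return n_sites * tail

    c = 1
    while expected_sites_at_least(c + 1) >= 1.0:
        c += 1
        if c > n_reads:  # cap cannot exceed the library size
            break
    return min(c, n_reads)


def deduplicate(
    sample: AlignedSample,
    genome: GenomeModel,
    read_length: int | None = None,
) -> tuple[AlignedSample, DedupModel]:
    """Cap per-(chrom, start, strand) multiplicity at the calibrated c*.

    Returns the effective-read sample (total_mapped = retained count) and
    the fitted model. Sites are 5' start + strand; excess reads at a site
    are dropped in stable input order.
    """
    sample.validate_against(genome)
    if read_length is None:
        read_length = sample.placements[0].length if sample.placements else 51
    n_sites = genome.n_start_sites(read_length)
    if n_sites < 1:
        raise ValueError("genome has no valid start sites at this read length")
    model = DedupModel(sample.total_mapped, n_sites, duplicate_cap(sample.total_mapped, n_sites))

    seen: dict[tuple[str, int, str], int] = {}
    kept = []
    for p in sample.placements:
        key = (p.chrom, p.start, p.strand)
        count = seen.get(key, 0)
        if count < model.cap:
            kept.append(p)
            seen[key] = count + 1
    effective = AlignedSample(sample.sample_id, sample.role, kept, len(kept))
    return effective, model
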