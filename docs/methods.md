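# Methods

This note documents the models, defaults and design decisions behind
`ervchip`, and what the synthetic tests do and do not establish about real
data.

## Coordinates and formats

All coordinates are 0-based half-open (BED convention) in memory and on
disk; reads are fixed-length single-end placements (default 51 bp,
matching 50-nt single-read sequencing with the padding convention below).
Sites, summits and TSS/TES anchors are single-base positions. Readers and
writers (chrom.sizes, BED6 reads, RepeatMasker-style repeat tables,
BED12-like genes, BED6+ peak tables, narrowPeak, Cq TSVs) are exact
inverses, so fixtures round-trip losslessly.

## Synthetic-data generator

The generator emulates the *structure* of a repeat-directed ChIP-seq
experiment, not its sequences. A toy genome (~1.2 Mb over chr1, chr2,
chrX, chrY by default) carries planted copies of named mouse repeat
families — IAPEz-int, IAPLTR1a, IAPA_MM-int, IAPLTR2_Mm, VL30,
MMERVK10C-int, MERVL-int, L1Md_F, L1_Mus — with kb-scale internal segments
and few-hundred-bp LTRs, plus a handful of exon-bearing genes. Reads are
drawn from a position-weighted mixture: every valid start position has
background weight 1, positions inside a family's copies are multiplied by
that family's fold factor. PCR duplicates are re-emissions of
already-sampled placements (identical position and strand) at a
configurable rate — the phenomenon the de-duplication step targets — with
default rate 0.05, a fixture choice for a typical low-duplication library.
All randomness flows from explicit seeds; identical config + seed gives
byte-identical outputs.

What the generator does *not* model: sequence content and mappability
(reads are placements, not bases), paired ends, fragment-size variation,
chromatin accessibility bias, and copy-to-copy divergence within a family.
Passing tests therefore establish the correctness of the downstream
arithmetic and the recoverability of planted enrichment under idealized
mapping — not alignment behaviour on real repeat sequence.

Two systematic offsets are expected and visible in the recovered medians:
(i) enriching one family dilutes the rest of the channel (total reads are
fixed), lowering all log2FC values by log2 of the total mixture weight
(~0.15–0.2 here); (ii) the ±51 bp padding admits background reads at the
element flanks, slightly compressing ratios for short elements. Both are
properties of the measurement design, and both stay well inside the ±0.4
recovery tolerance used in the tests.

## De-duplication to effective reads

Rather than collapsing every duplicate to one read, the library is reduced
to the duplicate level a uniform null *expects*. With `N` mapped reads and
`P` available (position, strand) start sites, per-site multiplicity is
`X ~ Binomial(N, 1/P)`; the retained cap is the largest `c ≥ 1` with
`P·Pr(X ≥ c) ≥ 1`, i.e. the deepest site the null still expects to produce
at least once genome-wide. The exact binomial tail is used for
`P ≤ 10 000`, the Poisson(λ = N/P) tail above (indistinguishable there,
much cheaper). Excess reads at a site are dropped in stable input order —
reads at one site are interchangeable, and determinism buys idempotence.
Sites are defined by 5′ start + strand (single-end data; no fragment
midpoint exists). An alternative reading of the procedure — thinning
globally to an expected duplicate total rather than capping per site — is
noted but not implemented.

## TPM and signal

TPM (tag per million) is `count / total_mapped × 1e6`, with `total_mapped`
the *effective* read count of the channel. For profiles and heatmaps each
read is extended 200 bp upstream and 350 bp downstream of itself before
pileup, which smooths single-end coverage. Extension is read-strand-aware
(upstream of a minus-strand read points right-ward in genome coordinates);
the convention is the natural reading of "upstream", and the choice is
configurable. The average profile is the summed extended-read TPM at each
offset in ±2000 bp around peak summits, divided by the number of summits.
Heatmap matrices span 10 000 bp around each summit; all samples share one
row order (descending row intensity of a designated reference sample) and
one cap, the 98th percentile of the reference matrix under the
linear-interpolation (type 7) quantile definition — recorded because
percentile conventions differ across tools. Values are clipped to
[0, cap].

## Peak calling stand-in and filtering

MACS v1.4 / SICER are not re-implemented. The stand-in caller exists so
synthetic data can flow end-to-end: fixed 200 bp windows are scored by the
Poisson upper-tail probability of the foreground count given the
depth-scaled background count, floored at the genome-wide foreground rate
per window so an empty background window cannot make a single read
significant; windows with p < 1e-5 within 200 bp are merged and the
maximum-pileup base (leftmost on ties) becomes the summit. The caller is
deterministic and labelled a stand-in in the CLI help.

The retention filter is the scientifically load-bearing step: a peak is
kept iff it has ≥ 30 effective foreground reads, no background with > 50
effective reads, TPM fold `fg / max(bg)` ≥ 2.5, and — when both an input
and an antibody control exist — was called against both (implemented as
≥ 1 bp overlap between the per-background call runs). Broad-mark mode
(H3K9me3-style domains) disables the count rules and keeps peaks at
≥ 3-fold TPM against either background; "either" is read as satisfiable
against at least one background, the laxer of the two possible readings,
and is configurable. The filter is monotone: tightening any threshold can
only remove peaks.

Peak-set intersection uses reference-set (A-side) semantics: the
"overlapping peaks" between A and B are the peaks *of A* with ≥ 1 bp
intersection in B, so counts are not symmetric; three-way venn counts
follow the same convention with A taking precedence, then B. The unit of
counting for a region is always a peak of that region's reference set.

Genomic distribution classifies each peak's *leftmost* position with
priority TSS > TES > exon > intron > intergenic (priority chosen here;
configurable windows). The TSS window is one-sided upstream (300 bp plus
the TSS base, strand-aware); the TES window is two-sided ±500 bp.

## Repeat-space quantification

Repeat copies are padded ±51 bp (one read length) so reads straddling an
element edge still count. "Best hit" in this coordinate world is full
containment of the read in the padded interval; a read compatible with
several (e.g. nested) elements is assigned to exactly one, chosen
uniformly with a seeded generator — mirroring a single-best-hit aligner's
arbitrary choice among equally good placements. Whether edge-overhanging
reads would have been counted by a sequence aligner is
alignment-dependent; containment is the conservative choice. Assignment
conserves reads: assigned + unassigned = total.

Per element, `log2FC = log2(TPM(c_chip + 0.5) / TPM(c_input + 0.5))`, the
0.5-read floor applied in count space to both channels keeping zero-count
elements finite with minimal bias (configurable). Category box statistics
follow the Tukey convention: median, quartiles (linear interpolation),
whiskers at the most extreme data points within 1.5×IQR of the hinges —
on the data, not the fences — and everything beyond as outliers. The
category map is shipped data (`data/category_map.yaml`): the major IAP
subfamilies and L1Md_F are their own categories, remaining IAP* pool into
"IAP other", remaining LINE into "LINE", and other names fall back to
their repName. Cross-sample agreement is summarized per repeat class with
Spearman's ρ (average ranks on ties). Sex-chromosome elements can be
dropped for sex-mismatched comparisons.

## qPCR arithmetic

Amplification efficiency is fixed at 2.0 per cycle (configurable);
percent input corrects the input Cq by log2 of the dilution factor and is
`100 × 2^(adjusted input Cq − IP Cq)`. Re-ChIP enrichment is the same
formula against the *first* ChIP's input. Ratios (e.g. a histone mark over
total H3) carry first-order delta-method standard errors propagated from
the replicate Cq spread; SEM of technical replicates is the default and SD
is selectable, since error-bar conventions vary. ΔΔCq normalizes the
target Cq to the arithmetic mean of the housekeeping Cqs (the geometric
mean of their quantities) per condition; fold change is
`2^(ΔCq_ctrl − ΔCq_kd)`. The paired two-tailed t-test is computed from the
textbook formula on the paired differences and errors out on
zero-variance differences rather than returning a degenerate statistic.

## Pipeline and problem sizes

The orchestrator chains simulate → dedup → call/filter → signal → repeats
from one YAML config validated by a typed schema; all stage seeds derive
deterministically from one root seed, and the manifest records the config
hash (location-independent), per-stage counts and sha256 checksums of
every result table, making byte-level reproducibility checkable.

Default analysis sizes — a ~1.2 Mb toy genome, 200 000 reads per channel
for enrichment recovery, 20 000–60 000 reads for pipeline-level checks —
are chosen so every planted category holds enough copies and reads for
stable medians while the complete test suite and the acceptance script
run in well under a minute each; they are desk-scale stand-ins, three
orders of magnitude below a real mouse ChIP-seq experiment.

## Known limitations

No sequence-level simulation or alignment; no paired-end support; no
mappability model for repeat space (a real aligner resolves only ~78 % of
repeat-space placements uniquely — unmodelled here); the stand-in caller
approximates neither MACS's local-lambda machinery nor SICER's island
statistics; qPCR efficiencies are assumed, not estimated from standard
curves.
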