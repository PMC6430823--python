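# ervchip

Downstream ChIP-seq analysis for repeat-element (ERV/IAP) enrichment in
mouse embryonic stem cells — the computational path from aligned read
placements to the statements "this factor is bound at class I/II ERVs" and
"these peaks co-occur with H3K9me3/KAP1":

* **Effective-read de-duplication** under a binomial null, keeping the
  duplicate multiplicity a uniform library is *expected* to produce.
* **Peak filtering** against one or two background channels (input and
  antibody control) with count and TPM-fold thresholds.
* **Summit-centered signal**: average TPM metaprofiles and
  percentile-capped heatmap matrices.
* **Genomic-distribution annotation** (TSS / TES / exon / intron /
  intergenic) of peak positions.
* **Repeat-space quantification**: padded RepeatMasker elements, best-hit
  read assignment, per-element log2 fold-change over input, custom
  category box statistics and per-class Spearman correlation.
* **ChIP-qPCR / expression arithmetic**: percent input, fold over H3 with
  error propagation, re-ChIP enrichment, ΔΔCq, paired t-tests.

A built-in synthetic-data generator plants known fold-enrichments for
named repeat families (IAPEz-int, IAPLTR1a, VL30, MMERVK10C, L1Md_F, …) on
a toy genome, so the whole pipeline runs and is tested end-to-end offline.
The peak *caller* included here is a clearly labelled stand-in window
caller (fixed 200 bp windows, Poisson-scored against the depth-scaled
background); externally called peaks can be filtered identically through
the table readers.

## The model in brief

**De-duplication.** With `N` mapped reads on `P` distinct (position,
strand) start sites, a site's multiplicity under uniform placement is
`X ~ Binomial(N, 1/P)`. The retained per-site cap is the largest `c ≥ 1`
with

```
P · Pr(X ≥ c) ≥ 1
```

(Poisson(λ = N/P) tail for large `P`). Reads above the cap at a site are
dropped in stable order; survivors are the *effective reads* (TPM = tag
per million effective mapped reads).

**Peak retention.** A peak survives iff it has ≥ 30 effective foreground
reads, ≤ 50 effective reads in every background, a TPM ratio
`fg / max(bg)` ≥ 2.5, and (with two backgrounds) was called against both.
Broad marks (H3K9me3) use a ≥ 3-fold TPM rule only.

**Repeat enrichment.** Each repeat copy is padded ±51 bp (one read
length); a read maps to an element when fully contained in the padded
interval, ties among elements broken uniformly at random (seeded), like a
single-best-hit aligner. Per element,
`log2FC = log2(TPM_ChIP+f / TPM_input+f)` with a 0.5-read floor `f` in
both channels.

## Worked example

```python
import ervchip as ec
from ervchip import EnrichmentSpec, deduplicate

genome = ec.build_toy_genome(ec.default_toy_config(seed=0))
chip = ec.simulate_chip_experiment(genome, EnrichmentSpec(
    n_reads=200_000, factors={"IAPEz-int": 8.0, "VL30": 4.0},
    duplicate_rate=0.05, seed=1, sample_id="chip"))
inp = ec.simulate_chip_experiment(genome, EnrichmentSpec(
    n_reads=200_000, factors={}, duplicate_rate=0.05, seed=2,
    sample_id="input", role="input"))

chip_eff, model = deduplicate(chip, genome, 51)
inp_eff, _ = deduplicate(inp, genome, 51)
print(f"dedup: N={model.n_reads} P={model.n_sites} lambda={model.rate:.3f} "
      f"cap={model.cap} retained={chip_eff.total_mapped}")

lib = ec.build_padded_library(genome, pad=51)
chip_counts, _ = ec.assign_reads(chip_eff, lib, seed=3)
input_counts, _ = ec.assign_reads(inp_eff, lib, seed=4)
signals = ec.element_enrichment(chip_counts, input_counts,
                                chip_eff.total_mapped, inp_eff.total_mapped, lib)
print(signals.groupby("category")["log2fc"].median().round(2))
```

prints

```
dedup: N=200000 P=2359600 lambda=0.085 cap=4 retained=199890
category
IAP other       -0.12
IAPA_MM-int     -0.18
IAPEz-int        2.78
IAPLTR1a        -0.15
L1Md_F          -0.20
LINE            -0.27
MERVL-int       -0.13
MMERVK10C-int   -0.15
VL30             1.73
Name: log2fc, dtype: float64
```

At λ ≈ 0.085 the binomial null still expects sites with 4 coincident reads
somewhere in a 2.36 M-site genome, so the cap is 4 and almost nothing is
removed. The category medians recover the planted mixture: the 8× IAPEz-int
family sits near log2(8) = 3 (slightly below, because ChIP enrichment
inside repeats dilutes the rest of the channel), the 4× VL30 near log2(4),
and unenriched families near 0.

The same workflow is available from the shell:

```bash
ervchip simulate --outdir fix --seed 3
ervchip dedup --reads fix/chip.bed --chrom-sizes fix/chrom.sizes --out chip.eff.bed
ervchip run --config run.yaml       # full pipeline with manifest + checksums
```

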