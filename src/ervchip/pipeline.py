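"""End-to-end orchestration: simulate -> dedup -> call/filter -> signal ->
repeats -> report, driven by one validated YAML config and one root seed.

Every stage's randomness derives deterministically from the root seed, and
the run manifest records the config hash, per-stage input/output counts and
a sha256 checksum of every result table, so two runs with the same config
and seed are byte-identical and verifiably so.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import yaml
from pydantic import BaseModel, Field

from . import __version__, io as eio
from .dedup import deduplicate
from .peaks import FilterRules, call_candidate_peaks, cross_annotate_called_against, filter_peaks
from .repeats import (build_padded_library, assign_reads, element_enrichment,
                      summarize_categories)
from .signal import average_profile, heatmap_matrix, write_matrix_tsv
from .simdata import (EnrichmentSpec, build_toy_genome, default_toy_config,
                      write_fixture_set)

log = logging.getLogger("ervchip.pipeline")


class SimulateConfig(BaseModel):
    genome_scale: float = 1.0
    n_reads: int = Field(200_000, ge=1)
    duplicate_rate: float = Field(0.05, ge=0.0, lt=1.0)
    read_length: int = Field(51, ge=1)
    chip_factors: dict[str, float] = {"IAPEz-int": 8.0, "IAPLTR1a": 8.0, "VL30": 4.0}
    control_factors: dict[str, float] = {}
    with_antibody_control: bool = True


class FilterConfig(BaseModel):
    min_fg_reads: int = 30
    max_bg_reads: int = 50
    min_fold: float = 2.5
    broad_mode: bool = False
    broad_min_fold: float = 3.0
    require_both_backgrounds: bool = True

    def rules(self) -> FilterRules:
        return FilterRules(**self.model_dump())


class SignalConfig(BaseModel):
    ext_up: int = 200
    ext_down: int = 350
    profile_half_window: int = 2000
    heatmap_window: int = 10_000
    cap_percentile: float = 98.0


class RepeatConfig(BaseModel):
    pad: int = 51
    drop_sex_chroms: bool = False
    floor_reads: float = 0.5


class RunConfig(BaseModel):
    outdir: str
    seed: int = 0
    simulate: SimulateConfig = SimulateConfig()
    filter: FilterConfig = FilterConfig()
    signal: SignalConfig = SignalConfig()
    repeats: RepeatConfig = RepeatConfig()

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.model_validate(yaml.safe_load(fh))


def _stage_seed(root: int, k: int) -> int:
    return (root * 1_000_003 + k) % (2**31)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Run the whole workflow; returns (and writes) the run manifest."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "tool_version": __version__,
        # outdir excluded: the hash identifies the analysis, not its location
        "config_hash": hashlib.sha256(
            json.dumps(config.model_dump(exclude={"outdir"}), sort_keys=True).encode()
        ).hexdigest(),
        "seed": config.seed,
        "stages": {},
        "checksums": {},
    }
    stage = "setup"
    try:
        # -- simulate -------------------------------------------------------
        stage = "simulate"
        sim = config.simulate
        genome = build_toy_genome(default_toy_config(seed=_stage_seed(config.seed, 0),
                                                     scale=sim.genome_scale))
        common = dict(n_reads=sim.n_reads, duplicate_rate=sim.duplicate_rate,
                      read_length=sim.read_length)
        chip = EnrichmentSpec(factors=sim.chip_factors, sample_id="chip", role="chip",
                              seed=_stage_seed(config.seed, 1), **common)
        inp = EnrichmentSpec(factors={}, sample_id="input", role="input",
                             seed=_stage_seed(config.seed, 2), **common)
        specs = {"chip": chip, "input": inp}
        if sim.with_antibody_control:
            specs["control"] = EnrichmentSpec(
                factors=sim.control_factors, sample_id="control",
                role="antibody_control", seed=_stage_seed(config.seed, 3), **common)
        from .simdata import simulate_chip_experiment
        samples = {sid: simulate_chip_experiment(genome, s) for sid, s in specs.items()}
        write_fixture_set(genome, list(samples.values()), out / "fixtures",
                          truth={sid: s for sid, s in specs.items()})
        manifest["stages"]["simulate"] = {
            sid: {"n_reads": s.total_mapped} for sid, s in samples.items()
        }
        log.info("simulate: %s", manifest["stages"]["simulate"])

        # -- dedup ----------------------------------------------------------
        stage = "dedup"
        effective = {}
        dd_stats = {}
        for sid, s in samples.items():
            eff, model = deduplicate(s, genome, sim.read_length)
            effective[sid] = eff
            dd_stats[sid] = {
                "reads_in": s.total_mapped, "reads_out": eff.total_mapped,
                "n_sites": model.n_sites, "lambda": model.rate, "cap": model.cap,
            }
            eio.write_reads_bed(eff, out / f"{sid}.effective.bed")
        manifest["stages"]["dedup"] = dd_stats
        log.info("dedup: %s", dd_stats)

        # -- call + filter ---------------------------------------------------
        stage = "peaks"
        bgs = {sid: eff for sid, eff in effective.items() if sid != "chip"}
        runs = call_candidate_peaks(effective["chip"], bgs, genome)
        reference_bg = sorted(runs)[0]
        candidates = cross_annotate_called_against(runs, reference_bg)
        retained = filter_peaks(candidates, config.filter.rules())
        eio.write_peak_table(candidates, out / "peaks_candidates.tsv")
        eio.write_peak_table(retained, out / "peaks_retained.tsv")
        manifest["stages"]["peaks"] = {
            "per_background_called": {bid: len(pk) for bid, pk in runs.items()},
            "candidates": len(candidates), "retained": len(retained),
        }
        log.info("peaks: %s", manifest["stages"]["peaks"])

        # -- signal ----------------------------------------------------------
        stage = "signal"
        sg = config.signal
        summits = [(p.chrom, p.summit) for p in retained]
        if summits:
            offsets, prof = average_profile(
                summits, effective["chip"], genome, sg.profile_half_window,
                sg.ext_up, sg.ext_down)
            with open(out / "average_profile.tsv", "w") as fh:
                fh.write("offset\tmean_tpm\n")
                for o, v in zip(offsets, prof):
                    fh.write(f"{o}\t{v:.6g}\n")
            pm = heatmap_matrix(summits, effective, genome, cap_reference="chip",
                                window=sg.heatmap_window,
                                cap_percentile=sg.cap_percentile,
                                ext_up=sg.ext_up, ext_down=sg.ext_down)
            for sid, mat in pm.matrices.items():
                write_matrix_tsv(mat, out / f"heatmap_{sid}.tsv",
                                 row_ids=pm.row_order)
            manifest["stages"]["signal"] = {"n_summits": len(summits),
                                            "heatmap_cap": pm.cap}
        else:
            manifest["stages"]["signal"] = {"n_summits": 0}
        log.info("signal: %s", manifest["stages"]["signal"])

        # -- repeats ---------------------------------------------------------
        stage = "repeats"
        rp = config.repeats
        library = build_padded_library(genome, rp.pad, rp.drop_sex_chroms)
        chip_counts, chip_un = assign_reads(effective["chip"], library,
                                            seed=_stage_seed(config.seed, 4))
        input_counts, input_un = assign_reads(effective["input"], library,
                                              seed=_stage_seed(config.seed, 5))
        signals = element_enrichment(
            chip_counts, input_counts, effective["chip"].total_mapped,
            effective["input"].total_mapped, library, rp.floor_reads)
        eio.write_tsv(signals, out / "repeat_signals.tsv")
        eio.write_tsv(summarize_categories(signals), out / "category_summary.tsv")
        manifest["stages"]["repeats"] = {
            "elements": len(library.elements),
            "chip_unassigned": chip_un, "input_unassigned": input_un,
        }
        log.info("repeats: %s", manifest["stages"]["repeats"])
    except Exception as err:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err

    for path in sorted(out.rglob("*")):
        if path.is_file() and path.name != "manifest.json":
            manifest["checksums"][str(path.relative_to(out))] = _sha256(path)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
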