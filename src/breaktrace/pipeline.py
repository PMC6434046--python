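"""End-to-end orchestration: preprocess -> align -> call -> dedup ->
quantify -> hotspots, with per-stage accounting and deterministic
outputs."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

from . import io as btio
from .align import ToyAligner
from .config import CallParams, DedupParams, RunConfig
from .dedup import DedupReport, dedupe
from .genome import Genome
from .hotspots import (
    Hotspot,
    PeakParams,
    call_enriched_regions,
    filter_and_merge,
    hotspot_intensity,
)
from .junctions import BaitConfig, JunctionCall, call_junction, classify, group_alignments, split_translocations
from .preprocess import AdapterSpec, RawReadPair, preprocess_pairs
from .quantify import LibraryStats, editing_efficiency, junction_profile, resection_fraction, tabulate

__all__ = ["LibraryResult", "RunResult", "process_library", "run_pipeline"]


@dataclass
class LibraryResult:
    label: str
    stats: LibraryStats
    unique_calls: list[JunctionCall]
    counts: dict[str, int]
    dedup_report: DedupReport

    def translocation_junctions(self) -> list[tuple[str, int, str]]:
        return [
            (c.prey.chrom, c.prey.coord, c.prey.strand)
            for c in self.unique_calls
            if c.category == "translocation" and c.prey is not None
        ]


@dataclass
class RunResult:
    sample_reps: list[LibraryResult]
    control: Optional[LibraryResult]
    sample_stats: LibraryStats
    hotspots: list[Hotspot]
    efficiency: Optional[object]
    resection: float
    translocation_split: dict[str, int]


def process_library(
    pairs: Sequence[RawReadPair],
    aligner: ToyAligner,
    bait: BaitConfig,
    adapter: AdapterSpec,
    label: str = "sample",
    dedup_params: DedupParams = DedupParams(),
    call_params: CallParams = CallParams(),
    sam_path: Optional[str | Path] = None,
) -> LibraryResult:
    """Run one library through preprocess, alignment, junction calling
    and deduplication.

    With ``sam_path`` set, alignments are round-tripped through a SAM
    file (exercising the standard-format interface); otherwise they stay
    in memory.
    """
    clean, counts = preprocess_pairs(pairs, adapter, sample_id=label)
    aligned = [(m.read_id, m.rmb, aligner.align(m.insert_seq), m.insert_seq) for m in clean]
    if sam_path is not None:
        btio.write_sam(sam_path, aligner.genome.sizes, aligned)
        records = btio.read_sam_groups(sam_path)
    else:
        records = ((mid, rmb, segs) for mid, rmb, segs, _ in aligned)
    groups, n_multi = group_alignments(records, min_mapq=call_params.min_mapq)
    counts["multimapped"] = n_multi
    calls: list[JunctionCall] = []
    n_baitless = 0
    for mol_id, rmb, segs in groups:
        call = call_junction(
            segs,
            bait,
            rmb=rmb,
            molecule_id=mol_id,
            min_prey_len=call_params.min_prey_len,
            max_prey_edit_rate=call_params.max_prey_edit_rate,
        )
        if call is None:
            n_baitless += 1
            continue
        calls.append(
            classify(
                call,
                bait,
                indel_window=call_params.indel_window,
                proximal_span=call_params.proximal_span,
            )
        )
    counts["baitless"] = n_baitless
    counts["called"] = len(calls)
    unique, report = dedupe(
        calls,
        bait.chrom,
        bait.strand,
        max_edit=dedup_params.max_edit,
        pos_tolerance=dedup_params.pos_tolerance,
        metric=dedup_params.metric,
    )
    counts["unique_molecules"] = len(unique)
    return LibraryResult(label, tabulate(unique, label=label), unique, counts, report)


def _pool_stats(results: Sequence[LibraryResult], label: str) -> LibraryStats:
    calls = [c for r in results for c in r.unique_calls]
    return tabulate(calls, label=label)


def run_pipeline(config: RunConfig, write_outputs: bool = True) -> RunResult:
    """Execute the full analysis described by a run configuration."""
    config.validate_paths()
    genome = Genome.from_fasta(config.genome_fasta)
    aligner = ToyAligner(genome)
    outdir = Path(config.output_dir)
    if write_outputs:
        outdir.mkdir(parents=True, exist_ok=True)

    def load_and_process(paths: dict[str, str], label: str) -> LibraryResult:
        pairs = list(btio.read_fastq_pairs(paths["r1"], paths["r2"]))
        sam = outdir / f"{label}.sam" if write_outputs else None
        res = process_library(
            pairs,
            aligner,
            config.bait,
            config.adapter,
            label=label,
            dedup_params=config.dedup,
            call_params=config.call,
            sam_path=sam,
        )
        if write_outputs:
            btio.write_junction_bedpe(
                res.unique_calls, outdir / f"junctions_{label}.bedpe", config.bait.chrom, config.bait.strand
            )
        return res

    sample_reps = [
        load_and_process(rep, f"sample_rep{i + 1}")
        for i, rep in enumerate(config.sample_replicates)
    ]
    control = load_and_process(config.control, "control") if config.control else None
    sample_stats = _pool_stats(sample_reps, "sample")

    require_reps = not config.allow_single_replicate and len(sample_reps) >= config.peaks.min_replicates
    junctions_per_rep = [r.translocation_junctions() for r in sample_reps]
    cands_per_rep = [
        call_enriched_regions(j, genome.sizes, config.peaks, bait=config.bait)
        for j in junctions_per_rep
    ]
    hotspots = filter_and_merge(
        cands_per_rep,
        junctions_per_rep,
        genome,
        config.bait.guide_seq,
        config.peaks,
        require_replicates=require_reps,
    )
    control_stats = control.stats if control else LibraryStats(G=1, I=0, T=0, label="null-control")
    for h in hotspots:
        try:
            h.intensity = hotspot_intensity(h.junction_count, sample_stats, control_stats)
        except ValueError:
            h.intensity = None

    pooled_calls = [c for r in sample_reps for c in r.unique_calls]
    split = split_translocations(
        pooled_calls, [(h.chrom, h.presumed_cut) for h in hotspots], window=config.peaks.count_window
    )
    efficiency = None
    if control is not None:
        efficiency = editing_efficiency(sample_stats, control.stats, config.te)
    resection = (
        resection_fraction(sample_stats, pooled_calls, config.bait)
        if sample_stats.editing_events
        else 0.0
    )
    result = RunResult(
        sample_reps=sample_reps,
        control=control,
        sample_stats=sample_stats,
        hotspots=hotspots,
        efficiency=efficiency,
        resection=resection,
        translocation_split=split,
    )
    if write_outputs:
        _write_outputs(config, result, outdir)
    return result


def _write_outputs(config: RunConfig, result: RunResult, outdir: Path) -> None:
    libs = result.sample_reps + ([result.control] if result.control else [])
    with open(outdir / "stats.tsv", "w") as fh:
        fh.write("library\tG\tI\tT\ttotal\traw_editing_fraction\n")
        for r in libs:
            s = r.stats
            frac = s.raw_editing_fraction() if s.total else 0.0
            fh.write(f"{r.label}\t{s.G}\t{s.I}\t{s.T}\t{s.total}\t{frac:.6f}\n")
    summary = {
        "sample": {
            "G": result.sample_stats.G,
            "I": result.sample_stats.I,
            "T": result.sample_stats.T,
            "subcounts": result.sample_stats.subcounts,
        },
        "translocation_split": result.translocation_split,
        "resection_fraction": result.resection,
        "n_hotspots": len(result.hotspots),
    }
    if result.efficiency is not None:
        summary["efficiency"] = {
            "efficiency": result.efficiency.efficiency,
            "raw_sample_fraction": result.efficiency.raw_sample_fraction,
            "raw_control_fraction": result.efficiency.raw_control_fraction,
            "te": result.efficiency.te,
        }
    btio.write_json(summary, outdir / "stats.json")
    with open(outdir / "hotspots.bed", "w") as fh:
        for h in result.hotspots:
            score = f"{h.intensity:.4f}" if h.intensity is not None else "."
            fh.write(f"{h.chrom}\t{h.start}\t{h.end}\t{h.match.matched_seq}\t{score}\t{h.match.strand}\n")
    with open(outdir / "hotspots.tsv", "w") as fh:
        fh.write(
            "chrom\tstart\tend\tpresumed_cut\tjunction_count\tmatched_seq\tmismatches\t"
            "pam_ok\treplicate_support\tbalance_p\tintensity\n"
        )
        for h in result.hotspots:
            fh.write(
                f"{h.chrom}\t{h.start}\t{h.end}\t{h.presumed_cut}\t{h.junction_count}\t"
                f"{h.match.matched_seq}\t{h.match.mismatches}\t{int(h.match.pam_ok)}\t"
                f"{h.replicate_support}\t{h.balance_p:.6g}\t"
                f"{h.intensity if h.intensity is None else f'{h.intensity:.4f}'}\n"
            )
    pooled = [c for r in result.sample_reps for c in r.unique_calls]
    prof_junctions = [
        (c.junction_pos, c.prey.strand if c.prey else config.bait.strand)
        for c in pooled
        if c.category != "germline"
        and (c.prey is None or c.prey.chrom == config.bait.chrom)
    ]
    tracks = junction_profile(
        prof_junctions, config.bait.cut_pos, config.profile_window, config.profile_binsize
    )
    with open(outdir / "profile.tsv", "w") as fh:
        fh.write("bin_start\torientation\tcount\n")
        start = config.bait.cut_pos - config.profile_window
        for orient in sorted(tracks):
            for b, count in enumerate(tracks[orient]):
                fh.write(f"{start + b * config.profile_binsize}\t{orient}\t{count}\n")
    counts: dict[str, int] = {}
    for r in libs:
        for key, value in r.counts.items():
            counts[f"{r.label}.{key}"] = value
    btio.write_counts_tsv(counts, outdir / "counts.tsv")
    with open(outdir / "run_log.txt", "w") as fh:
        fh.write("breaktrace run\n==============\n\nconfig:\n")
        import json

        fh.write(json.dumps(config.echo(), indent=2, sort_keys=True) + "\n\nstage counts:\n")
        for key in sorted(counts):
            fh.write(f"  {key}: {counts[key]}\n")
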