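"""End-to-end orchestration: reference -> simulate -> scan -> call -> evaluate.

``build_reference`` materializes the synthetic genome/annotation/whitelist,
parses gene models, enumerates whitelisted junction contigs and builds the
full chimeric fusion transcripts.  ``run_sample`` simulates one sample from
that reference and pushes it through the scanner and caller; ``run_cohort``
scores a list of samples into the reported/discarded/missed taxonomy.

The wildtype spliced transcripts of the fusion partners are always passed to
the scanner as counter-evidence, so reads that merely cross a wildtype exon
boundary are not mistaken for breakpoint-spanning evidence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

from .caller import CallerParams, FusionCall, call_fusions, write_calls
from .evaluation import SampleOutcome, CohortSummary, evaluate_sample, summarize_cohort
from .junction_reference import (
    GeneModel,
    Junction,
    KnownFusionList,
    enumerate_known_junctions,
    parse_gene_models,
    write_junction_fasta,
)
from .scanner import (
    FragmentSupport,
    JunctionHit,
    ScanParams,
    ScanStats,
    compute_fragment_support,
    scan_fastq,
)
from .simulator import (
    SimulatedSample,
    SimulationConfig,
    build_fusion_transcript,
    simulate_sample,
)
from .synthetic import background_transcripts, write_synthetic_reference

DEFAULT_FLANK_TARGET = 200  # 2 x read length: any read placement fits the contig
DEFAULT_READ_LENGTH = 100


@dataclass
class Reference:
    """Everything derived from genome + annotation + whitelist."""

    models: dict[str, GeneModel]
    junctions: list[Junction]
    whitelist: KnownFusionList
    fusion_transcripts: dict[tuple[int, int], tuple[str, int]]
    background: dict[str, str]
    target_pair: tuple[str, str]

    @property
    def wildtype_transcripts(self) -> dict[str, str]:
        return {name: m.spliced_seq for name, m in self.models.items()}

    def fusion_junction(self, variant: tuple[int, int]) -> Junction:
        gene5, gene3 = self.target_pair
        jid = f"{gene5}:{gene3}|e{variant[0]}:e{variant[1]}"
        for j in self.junctions:
            if j.junction_id == jid:
                return j
        raise KeyError(jid)


def build_reference(
    workdir: str | Path,
    seed: int = 1042,
    flank_target: int = DEFAULT_FLANK_TARGET,
    n_background: int = 20,
) -> Reference:
    """Write the synthetic reference files into ``workdir`` and load them
    back through the regular parsing path."""
    paths = write_synthetic_reference(workdir, seed=seed)
    whitelist = KnownFusionList.from_tsv(paths.whitelist_tsv)
    gene_names = whitelist.gene_names()
    models = {
        m.gene_name: m
        for m in parse_gene_models(paths.annotation_gtf, paths.genome_fasta, gene_names)
    }
    junctions = enumerate_known_junctions(whitelist, models, flank_target)
    fusion_transcripts = {}
    target_pair: Optional[tuple[str, str]] = None
    for entry in whitelist.entries:
        for exon5, exon3 in entry.variants:
            fusion_transcripts[(exon5, exon3)] = build_fusion_transcript(
                models[entry.gene5], exon5, models[entry.gene3], exon3
            )
            target_pair = (entry.gene5, entry.gene3)
    if target_pair is None:
        raise ValueError("whitelist defines no junction variants")
    write_junction_fasta(junctions, Path(workdir) / "junctions.fa")
    return Reference(
        models=models,
        junctions=junctions,
        whitelist=whitelist,
        fusion_transcripts=fusion_transcripts,
        background=background_transcripts(seed + 1, n=n_background),
        target_pair=target_pair,
    )


def sample_config(
    ref: Reference,
    n_fragments: int,
    fusion_fraction: float,
    seed: int,
    variant: tuple[int, int] = (16, 9),
    read_length: int = DEFAULT_READ_LENGTH,
    fragment_length_mean: float = 250.0,
    fragment_length_sd: float = 30.0,
    error_rate: float = 0.001,
) -> SimulationConfig:
    """Study-condition simulation config: wildtype partner transcripts plus
    random background, with the chimeric transcript mixed in at
    ``fusion_fraction`` (fusion-positive samples only)."""
    transcripts = dict(ref.wildtype_transcripts)
    transcripts.update(ref.background)
    fusion_name = None
    breakpoint = None
    if fusion_fraction > 0:
        seq, breakpoint = ref.fusion_transcripts[variant]
        gene5, gene3 = ref.target_pair
        fusion_name = f"{gene5}:{gene3}|e{variant[0]}:e{variant[1]}"
        transcripts[fusion_name] = seq
    return SimulationConfig(
        transcripts=transcripts,
        n_fragments=n_fragments,
        fusion_name=fusion_name,
        fusion_breakpoint=breakpoint,
        fusion_fraction=fusion_fraction,
        read_length=read_length,
        fragment_length_mean=fragment_length_mean,
        fragment_length_sd=fragment_length_sd,
        error_rate=error_rate,
        seed=seed,
    )


@dataclass
class SampleResult:
    sample_id: str
    sample: SimulatedSample
    hits: list[JunctionHit]
    stats: ScanStats
    supports: list[FragmentSupport]
    calls: list[FusionCall]


def run_sample(
    ref: Reference,
    outdir: str | Path,
    sample_id: str,
    seed: int,
    n_fragments: int,
    fusion_fraction: float,
    variant: tuple[int, int] = (16, 9),
    scan_params: Optional[ScanParams] = None,
    caller_params: Optional[CallerParams] = None,
    error_rate: float = 0.001,
    gzip_output: bool = False,
    write_outputs: bool = False,
) -> SampleResult:
    """Simulate one sample and analyze it end to end."""
    outdir = Path(outdir)
    cfg = sample_config(
        ref, n_fragments, fusion_fraction, seed, variant=variant, error_rate=error_rate
    )
    sim = simulate_sample(cfg, outdir / sample_id, gzip_output=gzip_output)
    hits, stats = scan_fastq(
        sim.fastq1_path,
        sim.fastq2_path,
        ref.junctions,
        scan_params,
        decoys=list(ref.wildtype_transcripts.values()),
    )
    supports = compute_fragment_support(hits, [j.junction_id for j in ref.junctions])
    calls = call_fusions(
        ref.junctions,
        supports,
        caller_params or CallerParams(whitelist=ref.whitelist),
    )
    if write_outputs:
        write_calls(calls, outdir / f"{sample_id}.calls.tsv")
        stats.to_json(outdir / f"{sample_id}.scanstats.json")
    return SampleResult(sample_id, sim, hits, stats, supports, calls)


@dataclass(frozen=True)
class SampleSpec:
    sample_id: str
    seed: int
    fusion_fraction: float
    truth_positive: bool
    variant: tuple[int, int] = (16, 9)


def run_cohort(
    ref: Reference,
    outdir: str | Path,
    specs: Sequence[SampleSpec],
    n_fragments: int,
    scan_params: Optional[ScanParams] = None,
    caller_params: Optional[CallerParams] = None,
    error_rate: float = 0.001,
    keep_fastq: bool = False,
) -> tuple[list[SampleOutcome], CohortSummary]:
    """Run a cohort of simulated samples and summarize detection outcomes.

    Simulated FASTQ files are deleted after analysis unless ``keep_fastq``
    (a 50-sample cohort otherwise leaves ~2 GB of reads behind).
    """
    outdir = Path(outdir)
    outcomes = []
    for spec in specs:
        result = run_sample(
            ref,
            outdir,
            spec.sample_id,
            seed=spec.seed,
            n_fragments=n_fragments,
            fusion_fraction=spec.fusion_fraction,
            variant=spec.variant,
            scan_params=scan_params,
            caller_params=caller_params,
            error_rate=error_rate,
        )
        outcomes.append(
            evaluate_sample(
                result.calls,
                truth_positive=spec.truth_positive,
                target_pair=ref.target_pair,
                sample_id=spec.sample_id,
            )
        )
        if not keep_fastq:
            for path in (result.sample.fastq1_path, result.sample.fastq2_path):
                Path(path).unlink(missing_ok=True)
    return outcomes, summarize_cohort(outcomes)
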