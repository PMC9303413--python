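"""The cycle engine: seed -> search -> select -> (fragment) -> assemble ->
contig-select -> (polish) -> repeat.

Cycle 1 queries the read store with the seed sequences (translated search
when the seeds are protein); later cycles query with the surviving contigs.
Contig selection always re-queries the ORIGINAL seeds against the new
contigs, and only matching contigs advance.  Per-cycle contig FASTAs, a
TSV trajectory report and a plain-text call log are written; a run is fully
deterministic for a fixed configuration.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import yaml

from .assemble import (
    AssemblerParams,
    Contig,
    ExternalAssembler,
    assemble_with,
    write_layout,
)
from .polish import polish
from .recruit import (
    ManualCountsExhausted,
    SelectionPolicy,
    fragment_reads,
    select_reads,
)
from .search import (
    NUCLEOTIDE_SCHEME,
    PROTEIN_SCHEME,
    align_local,
    search_store,
)
from .seqio import ReadStore, SeqRecord, read_fasta, write_fasta

logger = logging.getLogger("seedasm")


@dataclass
class PipelineConfig:
    """Everything a run needs, loadable from a YAML key-value file.

    ``evalue_initial`` gates the seed-vs-reads search of cycle 1;
    ``evalue_cycle`` is the tightened threshold for later cycles and for
    contig selection.  ``minprogress`` stalls the run when the longest
    matching contig changes by less than this many bases between cycles
    (0 disables).  ``seed`` drives every source of randomness.
    """

    seeds: Optional[str] = None
    store: Optional[str] = None
    seed_alphabet: str = "nucleotide"  # nucleotide | protein
    evalue_initial: float = 1e-10
    evalue_cycle: float = 1e-20
    max_hits: int = 10000
    selection: SelectionPolicy = field(default_factory=SelectionPolicy)
    frag_mode: str = "off"  # off | single | double
    frag_len: int = 600
    frag_len2: int = 490
    include_mates: bool = False
    assembler: str = "builtin"
    assembler_params: AssemblerParams = field(default_factory=AssemblerParams)
    external: Optional[ExternalAssembler] = None
    polish_iterations: int = 0
    polish_min_depth: int = 2
    max_cycles: int = 21
    minprogress: int = 100
    outdir: Optional[str] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.evalue_initial <= 0 or self.evalue_cycle <= 0:
            raise ValueError("e-value cutoffs must be positive")
        if self.max_cycles < 1:
            raise ValueError("max_cycles must be >= 1")
        if self.minprogress < 0:
            raise ValueError("minprogress must be >= 0")
        if self.seed_alphabet not in ("nucleotide", "protein"):
            raise ValueError("seed_alphabet must be nucleotide or protein")

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sel = SelectionPolicy(
            mode=raw.pop("mode", "increment"),
            bitscore_min=float(raw.pop("bitscore_min", 0.0)),
            # "extincrement" kept as the historical configuration key
            increment=int(raw.pop("extincrement", raw.pop("increment", 10))),
            manual_counts=list(raw.pop("manual_counts", [])),
        )
        asm_kwargs = {
            k: raw.pop(k)
            for k in ("min_overlap", "min_identity", "keep_singletons")
            if k in raw
        }
        params = AssemblerParams(**asm_kwargs)
        frag = raw.pop("frag", "off")
        known = {f.name for f in dataclasses.fields(cls)}
        cfg = {k: v for k, v in raw.items() if k in known}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(selection=sel, assembler_params=params, frag_mode=frag, **cfg)


@dataclass
class CycleReport:
    """Per-cycle bookkeeping: the trajectory record."""

    cycle: int
    n_reads_selected: int = 0
    n_contigs_all: int = 0
    n_contigs_matching: int = 0
    longest_all: int = 0
    longest_matching: int = 0
    mean_len_all: float = 0.0
    mean_len_matching: float = 0.0
    stop_reason: Optional[str] = None


class _CallLog:
    """Plain-text log of every search/assembly/polish call with parameters."""

    def __init__(self) -> None:
        self.lines: list[str] = []

    def add(self, line: str) -> None:
        self.lines.append(line)
        logger.debug(line)

    def write(self, path: Path) -> None:
        path.write_text("".join(l + "\n" for l in self.lines))


@dataclass
class PipelineState:
    seeds: list[SeqRecord]
    store: ReadStore
    queries: list[SeqRecord] = field(default_factory=list)
    previous_ids: set[str] = field(default_factory=set)
    reports: list[CycleReport] = field(default_factory=list)
    contigs: list[Contig] = field(default_factory=list)
    prepolish: list[Contig] = field(default_factory=list)
    log: _CallLog = field(default_factory=_CallLog)


def _contig_lengths(contigs: Sequence[Contig]) -> tuple[int, float]:
    if not contigs:
        return 0, 0.0
    lengths = [len(c) for c in contigs]
    return max(lengths), sum(lengths) / len(lengths)


def matching_contigs(
    seeds: Sequence[SeqRecord],
    contigs: Sequence[Contig],
    evalue: float,
    protein_seeds: bool,
) -> list[Contig]:
    """Contigs the ORIGINAL seeds hit at the given e-value (carry-forward rule)."""
    scheme = PROTEIN_SCHEME if protein_seeds else NUCLEOTIDE_SCHEME
    db_len = max(sum(len(c) for c in contigs), 1)
    kept = []
    for contig in contigs:
        rec = contig.to_record()
        for seed in seeds:
            hits = align_local(seed, rec, scheme=scheme, db_len=db_len)
            if hits and hits[0].evalue <= evalue:
                kept.append(contig)
                break
    return kept


def run_cycle(state: PipelineState, config: PipelineConfig) -> tuple[list[Contig], CycleReport]:
    """One retrieval-assembly-selection cycle; appends its report to state."""
    cycle = len(state.reports) + 1
    report = CycleReport(cycle=cycle)
    first = cycle == 1
    queries = state.seeds if first else state.queries
    protein_query = first and config.seed_alphabet == "protein"
    scheme = PROTEIN_SCHEME if protein_query else NUCLEOTIDE_SCHEME
    cutoff = config.evalue_initial if first else config.evalue_cycle

    if len(state.store) == 0:
        raise RuntimeError("read store is empty")
    state.log.add(
        f"cycle {cycle}: search_store n_queries={len(queries)} "
        f"evalue={cutoff:g} max_hits={config.max_hits} "
        f"scheme={'protein' if protein_query else 'nucleotide'}"
    )
    hits = search_store(queries, state.store, cutoff, config.max_hits, scheme)
    if not hits:
        report.stop_reason = "no_matching_reads"
        state.reports.append(report)
        return [], report

    ranked = [(h.subject_id, h.bitscore) for h in hits]
    try:
        selected = select_reads(ranked, config.selection, cycle, state.previous_ids)
    except ManualCountsExhausted:
        report.stop_reason = "manual_exhausted"
        state.reports.append(report)
        return [], report
    state.log.add(
        f"cycle {cycle}: select_reads mode={config.selection.mode} "
        f"-> {len(selected)} of {len(ranked)} ranked"
    )
    if config.include_mates:
        mates = [
            state.store[rid].mate_of
            for rid in selected
            if state.store[rid].mate_of and state.store[rid].mate_of in state.store
        ]
        selected += [m for m in mates if m not in set(selected)]
    if not selected:
        report.stop_reason = "no_matching_reads"
        state.reports.append(report)
        return [], report
    report.n_reads_selected = len(selected)

    reads = [state.store[rid] for rid in selected]
    assembly_input = fragment_reads(reads, config.frag_mode, config.frag_len, config.frag_len2)
    if config.frag_mode != "off":
        state.log.add(
            f"cycle {cycle}: fragment mode={config.frag_mode} "
            f"L={config.frag_len}/{config.frag_len2} -> {len(assembly_input)} pieces"
        )

    state.log.add(
        f"cycle {cycle}: assemble n_reads={len(assembly_input)} "
        f"assembler={config.assembler} min_overlap={config.assembler_params.min_overlap} "
        f"min_identity={config.assembler_params.min_identity}"
    )
    contigs = assemble_with(
        assembly_input,
        config.assembler_params,
        config.external if config.assembler != "builtin" else None,
    )
    report.n_contigs_all = len(contigs)
    report.longest_all, report.mean_len_all = _contig_lengths(contigs)
    if not contigs:
        report.stop_reason = "no_contigs"
        state.reports.append(report)
        return [], report

    protein_seeds = config.seed_alphabet == "protein"
    survivors = matching_contigs(state.seeds, contigs, config.evalue_cycle, protein_seeds)
    state.log.add(
        f"cycle {cycle}: contig selection vs original seeds "
        f"evalue={config.evalue_cycle:g} -> {len(survivors)}/{len(contigs)} match"
    )
    report.n_contigs_matching = len(survivors)
    report.longest_matching, report.mean_len_matching = _contig_lengths(survivors)
    if not survivors:
        report.stop_reason = "no_matching_contigs"
        state.reports.append(report)
        return [], report

    state.prepolish = survivors
    if config.polish_iterations > 0:
        state.log.add(
            f"cycle {cycle}: polish n_contigs={len(survivors)} "
            f"iterations={config.polish_iterations} min_depth={config.polish_min_depth}"
        )
        survivors = [
            polish(c, reads, config.polish_iterations, config.polish_min_depth)
            for c in survivors
        ]

    state.previous_ids = set(selected)
    state.queries = [c.to_record() for c in survivors]
    state.contigs = survivors
    state.reports.append(report)
    return survivors, report


def should_stop(reports: Sequence[CycleReport], config: PipelineConfig) -> Optional[str]:
    """Stopping rule applied after each cycle; None means continue."""
    if not reports:
        raise ValueError("no reports")
    last = reports[-1]
    if last.stop_reason:
        return last.stop_reason
    if last.cycle >= config.max_cycles:
        return "max_cycles_reached"
    if config.minprogress > 0 and len(reports) >= 2:
        delta = abs(last.longest_matching - reports[-2].longest_matching)
        if delta < config.minprogress:
            return "minprogress_stalled"
    return None


def write_report(reports: Sequence[CycleReport], path: Path) -> None:
    cols = (
        "cycle n_reads_selected n_contigs_all n_contigs_matching "
        "longest_all longest_matching mean_len_all mean_len_matching stop_reason"
    ).split()
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for r in reports:
            fh.write(
                f"{r.cycle}\t{r.n_reads_selected}\t{r.n_contigs_all}\t"
                f"{r.n_contigs_matching}\t{r.longest_all}\t{r.longest_matching}\t"
                f"{r.mean_len_all:.1f}\t{r.mean_len_matching:.1f}\t"
                f"{r.stop_reason or ''}\n"
            )


def run(
    config: PipelineConfig,
    seeds: Optional[Sequence[SeqRecord]] = None,
    store: Optional[ReadStore] = None,
) -> list[CycleReport]:
    """Iterate cycles until a stopping criterion fires; write all outputs.

    ``seeds``/``store`` may be passed in memory; otherwise they load from
    the configured paths.  Outputs under ``outdir``: ``cycle_<N>.fasta``
    (matching contigs), ``cycle_<N>.polished.fasta`` when polishing,
    ``report.tsv``, ``layout_<N>.tsv`` and ``log.txt``.
    """
    if seeds is None:
        if not config.seeds:
            raise ValueError("no seeds given")
        seeds = read_fasta(config.seeds, alphabet=config.seed_alphabet)
    if store is None:
        if not config.store:
            raise ValueError("no read store given")
        p = Path(config.store)
        store = ReadStore.load(p) if p.is_dir() else ReadStore.from_files([p])
    outdir = Path(config.outdir) if config.outdir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)

    state = PipelineState(seeds=list(seeds), store=store)
    state.log.add(
        f"run: {len(state.seeds)} seeds, {len(store)} reads "
        f"({store.total_bases} bases), seed_alphabet={config.seed_alphabet}, "
        f"rng_seed={config.seed}"
    )
    while True:
        try:
            contigs, report = run_cycle(state, config)
        except Exception:
            state.log.add(f"cycle {len(state.reports) + 1}: fatal error")
            if outdir:
                state.log.write(outdir / "log.txt")
            raise
        if outdir and contigs:
            write_fasta(
                [c.to_record() for c in state.prepolish],
                outdir / f"cycle_{report.cycle}.fasta",
            )
            if config.polish_iterations > 0:
                write_fasta(
                    [c.to_record() for c in contigs],
                    outdir / f"cycle_{report.cycle}.polished.fasta",
                )
            write_layout(contigs, str(outdir / f"layout_{report.cycle}.tsv"))
        reason = should_stop(state.reports, config)
        if reason:
            state.reports[-1].stop_reason = reason
            state.log.add(f"stop: {reason}")
            break
    if outdir:
        write_report(state.reports, outdir / "report.tsv")
        state.log.write(outdir / "log.txt")
    return state.reports
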