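"""Four-step pipeline orchestration.

Per query sequence: (i) guide discovery, (ii) variant generation and exact
genome mapping, (iii) scoring, (iv) guide-to-variant alignment and report
writing.  Multiple query records run concurrently (process pool across
records); each record owns an independent result tree, so outputs are
byte-identical regardless of worker count.
"""

from __future__ import annotations

import logging
from concurrent.futures import ProcessPoolExecutor
from dataclasses import dataclass
from pathlib import Path

from Bio import SeqIO

from . import variants as vs
from .discovery import Guide, find_guides
from .mapping import (ReferenceGenome, build_index, count_hits, map_variants)
from .reporting import ResultTree, prepare_result_tree, write_outputs
from .scoring import load_tables, score_guide
from .variants import NRG_PAMS, SCHEMES, VariantSpaceSpec

log = logging.getLogger(__name__)

NGG_ONLY = ("AGG", "TGG", "GGG", "CGG")


@dataclass(frozen=True)
class RunConfig:
    """Everything one pipeline invocation needs."""

    genome: str
    inputs: tuple[str, ...]
    outdir: str
    r_max: int = 4
    schemes: tuple[str, ...] = SCHEMES
    pam_set: tuple[str, ...] = NRG_PAMS
    seed_filter: bool = False
    workers: int = 1
    seed: int = 0
    overwrite: bool = False
    batch_size: int = 200_000

    def __post_init__(self) -> None:
        if self.workers < 1:
            raise ValueError("workers must be >= 1")
        if not 1 <= self.r_max <= 20:
            raise ValueError("r_max must be in 1..20")
        if self.r_max > 4:
            log.warning("r_max=%d exceeds the designed range 1..4", self.r_max)
        VariantSpaceSpec(r=min(self.r_max, 20), schemes=self.schemes,
                         pam_set=self.pam_set)


def load_config_file(path: str | Path) -> dict[str, object]:
    """Parse a flat key=value config file ('#' comments, blank lines ok)."""
    out: dict[str, object] = {}
    for raw in Path(path).read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"bad config line: {raw!r}")
        key, value = (s.strip() for s in line.split("=", 1))
        if key in {"r_max", "workers", "seed", "batch_size"}:
            out[key] = int(value)
        elif key in {"seed_filter", "overwrite"}:
            out[key] = value.lower() in {"1", "true", "yes", "on"}
        elif key in {"schemes", "pam_set", "inputs"}:
            out[key] = tuple(v.strip() for v in value.split(",") if v.strip())
        else:
            out[key] = value
    return out


def _variant_stream(guide: Guide, config: RunConfig):
    """Deterministic stream of PAM-expanded variants for one guide."""
    for scheme in SCHEMES:  # fixed scheme order, independent of config order
        if scheme not in config.schemes:
            continue
        stream = vs.enumerate_scheme(scheme, guide.sequence, config.r_max,
                                     parent=guide.name)
        if config.seed_filter and scheme == vs.SUBSTITUTION:
            stream = vs.seed_region_filter(stream)
        yield from vs.expand_pams(stream, config.pam_set)


def process_sequence(record_id: str, seq: str, config: RunConfig,
                     genome: ReferenceGenome | None = None) -> ResultTree:
    """Run the four pipeline steps for one query sequence."""
    if genome is None:
        genome = ReferenceGenome.from_fasta(config.genome)
    outroot = Path(config.outdir) / record_id
    tree = prepare_result_tree(outroot, overwrite=config.overwrite)

    handler = logging.FileHandler(tree.log_file, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    run_log = logging.getLogger(f"guidescout.run.{record_id}")
    run_log.setLevel(logging.INFO)
    run_log.addHandler(handler)
    try:
        run_log.info("step 1/4: guide discovery on %s (%d nt)", record_id, len(seq))
        guides = find_guides(seq)
        run_log.info("found %d guides (%d forward, %d reverse)", len(guides),
                     sum(g.strand == "+" for g in guides),
                     sum(g.strand == "-" for g in guides))

        index = build_index(genome)
        tables = load_tables()
        rows, hits_by_guide = [], {}
        for guide in guides:
            run_log.info("step 2/4: mapping variants of %s (r<=%d, schemes=%s)",
                         guide.name, config.r_max, ",".join(config.schemes))
            hits = map_variants(_variant_stream(guide, config), index,
                                batch_size=config.batch_size)
            counts = count_hits(hits)
            if counts.on_target == 0:
                run_log.warning("%s: design locus not found in the genome "
                                "(on-target count 0)", guide.name)
            run_log.info("step 3/4: scoring %s (%d hits)", guide.name, len(hits))
            rows.append(score_guide(guide, hits, counts, tables))
            hits_by_guide[guide.name] = hits
        run_log.info("step 4/4: writing alignments and reports")
        write_outputs(tree, guides, rows, hits_by_guide, genome)
        run_log.info("done: %d guides reported", len(guides))
    finally:
        run_log.removeHandler(handler)
        handler.close()
    return tree


def _worker(args: tuple[str, str, RunConfig]) -> tuple[str, str | None]:
    record_id, seq, config = args
    try:
        process_sequence(record_id, seq, config)
        return record_id, None
    except Exception as exc:  # noqa: BLE001 - isolate per-record failures
        return record_id, f"{type(exc).__name__}: {exc}"


def run_pipeline(config: RunConfig) -> dict[str, ResultTree]:
    """Process every record of every input FASTA; failures are isolated.

    Returns the result trees of the records that succeeded; failed records
    are logged and skipped without aborting their siblings.
    """
    genome_path = Path(config.genome)
    if not genome_path.exists():
        raise FileNotFoundError(f"reference genome not found: {genome_path}")
    records: list[tuple[str, str]] = []
    for inp in config.inputs:
        if not Path(inp).exists():
            raise FileNotFoundError(f"input FASTA not found: {inp}")
        for rec in SeqIO.parse(str(inp), "fasta"):
            records.append((rec.id, str(rec.seq)))
    if not records:
        raise ValueError("no query records found in the input FASTA(s)")

    results: dict[str, ResultTree] = {}
    failures: dict[str, str] = {}
    if config.workers == 1 or len(records) == 1:
        genome = ReferenceGenome.from_fasta(config.genome)
        for record_id, seq in records:
            try:
                results[record_id] = process_sequence(record_id, seq, config,
                                                      genome=genome)
            except Exception as exc:  # noqa: BLE001
                failures[record_id] = f"{type(exc).__name__}: {exc}"
    else:
        # warm the FASTA index in the parent so workers never race on it
        ReferenceGenome.from_fasta(config.genome)
        jobs = [(rid, seq, config) for rid, seq in records]
        with ProcessPoolExecutor(max_workers=config.workers) as pool:
            for record_id, error in pool.map(_worker, jobs):
                if error is None:
                    results[record_id] = ResultTree(
                        Path(config.outdir) / record_id)
                else:
                    failures[record_id] = error
    for record_id, error in failures.items():
        log.error("record %s failed: %s", record_id, error)
    if not results and failures:
        raise RuntimeError(f"all {len(failures)} record(s) failed")
    return results
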