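"""Off-target (Hsu/MIT, CFD) and on-target (Rule Set 1) guide scoring.

All scores are reported on a 0-100 scale.  Per-pair scores apply to the
substitution scheme only — both systems are positional and require the
guide and the off-site to have equal length; indel hits enter the report
through their map counts instead.

Per-guide aggregates follow the specificity-score convention
``100 * 100 / (100 + sum of single scores)``: a guide with no off-target
hits scores 100, and every additional hit with positive single score
strictly lowers it.  The formula is isolated here so an alternative
aggregate can be swapped in.

The Hsu score has no PAM factor; NAG-PAM hits are attenuated only under
CFD.  This asymmetry is inherent to the two published systems.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

from .discovery import Guide
from .mapping import MapCounts, MappedHit
from .variants import SUBSTITUTION


@dataclass(frozen=True)
class ScoringTables:
    """Bundled scoring constants (see data/PROVENANCE.md).

    hsu_weights: W[1..20] stored 0-indexed, 5'->3', index 19 adjacent to
    the PAM.  cfd_mismatch maps (position 1..20, RNA base, DNA base) to a
    factor in [0,1]; cfd_pam maps the two bases after N to a factor.
    """

    hsu_weights: tuple[float, ...]
    cfd_mismatch: dict[tuple[int, str, str], float]
    cfd_pam: dict[str, float]
    doench_intercept: float
    doench_gc_low: float
    doench_gc_high: float
    doench_weights: tuple[tuple[int, str, float], ...]


def load_tables(data_dir: str | Path | None = None) -> ScoringTables:
    """Load the bundled constant files (or same-layout replacements)."""
    if data_dir is None:
        root = resources.files("guidescout") / "data"
    else:
        root = Path(data_dir)

    def read(name: str) -> dict:
        return json.loads((root / name).read_text())

    hsu = read("hsu_weights.json")["weights"]
    mm_raw = read("cfd_mismatch_synthetic.json")["mismatch"]
    mismatch = {}
    for key, values in mm_raw.items():
        rna, dna = key[1], key[4]  # "rA:dC" -> ("A", "C")
        for pos0, factor in enumerate(values):
            mismatch[(pos0 + 1, rna, dna)] = factor
    pam = read("cfd_pam.json")["pam"]
    rs1 = read("doench_rs1_synthetic.json")
    return ScoringTables(
        hsu_weights=tuple(hsu),
        cfd_mismatch=mismatch,
        cfd_pam=dict(pam),
        doench_intercept=rs1["intercept"],
        doench_gc_low=rs1["gc_low"],
        doench_gc_high=rs1["gc_high"],
        doench_weights=tuple((p, s, w) for p, s, w in rs1["weights"]),
    )


def _mismatch_positions(guide: str, offsite: str) -> list[int]:
    if len(guide) != len(offsite):
        raise ValueError(
            f"guide ({len(guide)} nt) and off-site ({len(offsite)} nt) "
            "must have equal length")
    return [i for i, (a, b) in enumerate(zip(guide.upper(), offsite.upper()))
            if a != b]


def hsu_single(guide: str, offsite: str, tables: ScoringTables) -> float:
    """Hsu/MIT score for one guide/off-site pair, 0-100.

    With mismatch positions M (|M| = m) and mean pairwise distance d among
    them: 100 * prod_{p in M}(1 - W[p]) * 1/(((19-d)/19)*4 + 1) * 1/m^2.
    d is defined as 19 when m <= 1, neutralising the proximity penalty;
    m = 0 scores 100.
    """
    mm = _mismatch_positions(guide, offsite)
    m = len(mm)
    if m == 0:
        return 100.0
    score = 1.0
    for p in mm:
        score *= 1.0 - tables.hsu_weights[p]
    if m < 2:
        d = 19.0
    else:
        pairs = [(a, b) for i, a in enumerate(mm) for b in mm[i + 1:]]
        d = sum(b - a for a, b in pairs) / len(pairs)
    score *= 1.0 / (((19.0 - d) / 19.0) * 4.0 + 1.0)
    score *= 1.0 / (m * m)
    return 100.0 * score


def cfd_single(guide: str, offsite: str, pam: str,
               tables: ScoringTables) -> float:
    """CFD score for one guide/off-site pair including its PAM, 0-100.

    Product over mismatch positions of the empirical (position, RNA base,
    DNA base) factor, times the PAM factor.  The guide is read as RNA
    (T -> U) and the DNA base recorded in the table is the template-strand
    base the RNA actually pairs with, i.e. the complement of the off-site
    protospacer base (rA:dT is the Watson-Crick match, not a table entry).
    """
    if len(pam) != 3:
        raise ValueError(f"PAM must be 3 nt, got {pam!r}")
    mm = _mismatch_positions(guide, offsite)
    guide = guide.upper()
    offsite = offsite.upper()
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    score = 1.0
    for p in mm:
        key = (p + 1, "U" if guide[p] == "T" else guide[p], comp[offsite[p]])
        try:
            score *= tables.cfd_mismatch[key]
        except KeyError:
            raise KeyError(
                f"no CFD mismatch factor for position {p + 1}, "
                f"guide base {guide[p]}, off-site base {offsite[p]}") from None
    pam_key = pam.upper()[1:]
    try:
        score *= tables.cfd_pam[pam_key]
    except KeyError:
        raise KeyError(f"no CFD PAM factor for N{pam_key}") from None
    return 100.0 * score


def aggregate(single_scores: Iterable[float]) -> float:
    """Specificity aggregate 100*100/(100 + sum), 0-100; empty input -> 100."""
    total = sum(single_scores)
    return 100.0 * 100.0 / (100.0 + total)


# spec'd aliases: Hsu and CFD share the aggregate convention
hsu_aggregate = aggregate
cfd_aggregate = aggregate


def doench_ontarget(context30: str, tables: ScoringTables) -> float | None:
    """Rule-Set-1 on-target score from the 30-mer context, 0-100.

    Logistic model: intercept + GC-count penalty over the spacer
    (positions 5-24 of the context) + position-specific sequence weights.
    Contexts padded with 'N' (guide at a query edge) score as missing
    (None).
    """
    s = context30.upper()
    if len(s) != 30:
        raise ValueError(f"context must be 30 nt, got {len(s)}")
    if "N" in s:
        return None
    x = tables.doench_intercept
    gc = s[4:24].count("G") + s[4:24].count("C")
    if gc < 10:
        x += tables.doench_gc_low * (10 - gc)
    elif gc > 10:
        x += tables.doench_gc_high * (gc - 10)
    for pos, sub, w in tables.doench_weights:
        if s[pos : pos + len(sub)] == sub:
            x += w
    return 100.0 / (1.0 + math.exp(-x))


@dataclass(frozen=True)
class ScoreRow:
    """One line of the per-guide report."""

    name: str
    strand: str
    start: int
    end: int
    sequence: str
    pam: str
    gc_percent: float
    doench: float | None
    counts: MapCounts
    hsu_aggregate: float
    cfd_aggregate: float

    @property
    def on_target_count(self) -> int:
        return self.counts.on_target


def score_guide(guide: Guide, hits: Sequence[MappedHit], counts: MapCounts,
                tables: ScoringTables) -> ScoreRow:
    """Assemble the per-guide report line.

    Hsu/CFD aggregates run over substitution-scheme off-target loci only
    (on-target loci excluded; indel hits enter via counts).  Each distinct
    (contig, pos, strand) locus contributes exactly one guide/off-site
    pair, matching the locus-based counting convention.
    """
    seen: set[tuple[str, int, str]] = set()
    hsu_scores: list[float] = []
    cfd_scores: list[float] = []
    for h in hits:
        if h.is_on_target or h.variant.scheme != SUBSTITUTION:
            continue
        key = (h.contig, h.pos, h.strand)
        if key in seen:
            continue
        seen.add(key)
        hsu_scores.append(hsu_single(guide.sequence, h.variant.sequence, tables))
        cfd_scores.append(cfd_single(guide.sequence, h.variant.sequence,
                                     h.variant.pam, tables))
    doench = doench_ontarget(guide.context30, tables)
    return ScoreRow(
        name=guide.name, strand=guide.strand, start=guide.start,
        end=guide.end, sequence=guide.sequence, pam=guide.pam,
        gc_percent=guide.gc_percent, doench=doench, counts=counts,
        hsu_aggregate=aggregate(hsu_scores),
        cfd_aggregate=aggregate(cfd_scores),
    )
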