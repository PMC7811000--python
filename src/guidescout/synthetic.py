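"""Deterministic synthetic genomes with planted guide-variant sites.

Every pipeline stage is testable without downloads: a uniform-random
background is seeded, known variant full-sites are planted at chosen loci,
and a machine-readable truth table records the hits mapping must recover.
The generator rejects backgrounds that contain accidental exact copies of
any planted full-site (or the background copy of a site overlapping a
plant), so the truth table is exhaustive by construction.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from Bio.Seq import reverse_complement

from .variants import VariantRecord, apply_edits

_BASES = "ACGT"


@dataclass(frozen=True)
class PlantSpec:
    """One site to plant: a guide variant, its PAM, and its locus."""

    guide: str
    scheme: str
    edits: tuple[tuple[str, int, str], ...]
    pam: str
    contig: str
    position: int
    strand: str = "+"
    parent: str = "f1"

    def variant(self) -> VariantRecord:
        seq = apply_edits(self.guide, self.edits)
        dist = (sum(1 for k, _, _ in self.edits if k == "S")
                if self.scheme == "substitution" else None)
        return VariantRecord(self.parent, self.scheme, seq, tuple(self.edits),
                             pam=self.pam, hamming_distance=dist)

    @property
    def full_site(self) -> str:
        return self.variant().full_site


@dataclass(frozen=True)
class TruthRow:
    """Expected mapping outcome for one planted site."""

    contig: str
    pos: int
    strand: str
    scheme: str
    full_site: str


def make_synthetic_genome(
    seed: int,
    length: int,
    plants: Sequence[PlantSpec],
    contigs: Iterable[str] = ("chr1",),
    max_attempts: int = 50,
) -> tuple[dict[str, str], list[TruthRow]]:
    """Build contigs of ``length`` nt each with ``plants`` embedded.

    The background is uniform ACGT from ``seed``.  Planted sites must not
    overlap; a forward plant writes full_site at [position, position+len),
    a reverse plant writes its reverse complement there (so mapping reports
    it on strand '-').  If the finished genome contains any planted
    full_site more often than the truth table demands, the background is
    re-sampled (fresh sub-seed) up to ``max_attempts`` times.
    """
    contigs = list(contigs)
    spans: dict[str, list[tuple[int, int]]] = {c: [] for c in contigs}
    for p in plants:
        if p.contig not in spans:
            raise ValueError(f"plant references unknown contig {p.contig!r}")
        site = p.full_site
        lo, hi = p.position, p.position + len(site)
        if hi > length:
            raise ValueError(f"plant at {p.contig}:{p.position} exceeds contig")
        for a, b in spans[p.contig]:
            if lo < b and a < hi:
                raise ValueError("planted sites overlap")
        spans[p.contig].append((lo, hi))

    expected: dict[str, int] = {}
    for p in plants:
        expected[p.full_site] = expected.get(p.full_site, 0) + 1

    for attempt in range(max_attempts):
        rng = random.Random((seed * 1_000_003 + attempt) & 0x7FFFFFFF)
        genome: dict[str, str] = {}
        for c in contigs:
            bg = rng.choices(_BASES, k=length)
            for p in plants:
                if p.contig != c:
                    continue
                site = p.full_site
                if p.strand == "-":
                    site = reverse_complement(site)
                bg[p.position : p.position + len(site)] = list(site)
            genome[c] = "".join(bg)
        if _clean(genome, expected):
            truth = [TruthRow(p.contig, p.position, p.strand, p.scheme,
                              p.full_site) for p in plants]
            truth.sort(key=lambda t: (t.contig, t.pos, t.strand))
            return genome, truth
    raise RuntimeError(
        f"no accident-free background found in {max_attempts} attempts")


def _count_occurrences(seq: str, pattern: str) -> int:
    n, start = 0, 0
    while (i := seq.find(pattern, start)) != -1:
        n += 1
        start = i + 1
    return n


def _clean(genome: dict[str, str], expected: dict[str, int]) -> bool:
    """True when each planted full_site occurs exactly as often as planted."""
    for site, want in expected.items():
        got = 0
        for seq in genome.values():
            got += _count_occurrences(seq, site)
            got += _count_occurrences(seq, reverse_complement(site))
        if got != want:
            return False
    return True


def write_fasta(genome: dict[str, str], path: str | Path,
                width: int = 70) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
    return path


def write_truth_table(truth: Sequence[TruthRow], path: str | Path) -> Path:
    path = Path(path)
    lines = ["contig\tpos\tstrand\tscheme\tfull_site"]
    lines += [f"{t.contig}\t{t.pos}\t{t.strand}\t{t.scheme}\t{t.full_site}"
              for t in truth]
    path.write_text("\n".join(lines) + "\n")
    return path
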