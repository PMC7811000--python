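"""Variant-space enumeration for a 20-nt guide.

Off-target search here is exhaustive by construction: instead of aligning
the guide with tolerated mismatches, every sequence the guide could pair
with under <= ``r`` edits is materialised and later matched *exactly*
against the genome.  Three edit schemes model the three DNA:RNA
heteroduplex defects:

* substitution  — mismatched base pairs (the Hamming ball of radius r),
* deletion      — DNA bulges (the genomic site is shorter than the guide),
* insertion     — RNA bulges (the genomic site is longer than the guide).

Closed-form counters give the scheme sizes; the enumerators generate the
actual deduplicated sequences.  Counts from the counters are exact for
substitutions and upper bounds for the indel schemes, whose unique counts
are sequence-dependent (repeats collapse under deduplication).

Conventions shared by both indel schemes: the 5'-most position never
participates (deleting it would just shorten the guide into its own
suffix), and the gap between the spacer 3' end and the PAM is a valid
insertion site, giving 19 deletable positions and 20 insertion sites.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace
from math import comb
from typing import Iterable, Iterator

SUBSTITUTION = "substitution"
DELETION = "deletion"
INSERTION = "insertion"
SCHEMES = (SUBSTITUTION, DELETION, INSERTION)

#: The eight NRG PAMs tolerated by SpCas9 (NGG strongly, NAG weakly),
#: in canonical order.
NRG_PAMS = ("AGG", "TGG", "GGG", "CGG", "AAG", "TAG", "GAG", "CAG")
NGG_PAMS = frozenset(p for p in NRG_PAMS if p[1:] == "GG")

_BASES = "ACGT"


@dataclass(frozen=True, slots=True)
class VariantSpaceSpec:
    """Parameters of one guide's variant space."""

    n: int = 20
    r: int = 4
    schemes: tuple[str, ...] = SCHEMES
    pam_set: tuple[str, ...] = NRG_PAMS

    def __post_init__(self) -> None:
        _check_nr(self.n, self.r)
        unknown = set(self.schemes) - set(SCHEMES)
        if unknown:
            raise ValueError(f"unknown scheme(s): {sorted(unknown)}")
        if not self.pam_set:
            raise ValueError("pam_set must not be empty")


@dataclass(frozen=True, slots=True)
class VariantRecord:
    """One edited spacer, optionally with a PAM appended.

    ``edits`` is a canonical tuple of (kind, position, base) triples with
    0-based positions: ("S", p, b) substitutes position p with b;
    ("D", p, "") deletes position p; ("I", g, b) inserts b after original
    position g (g == n puts the base between spacer and PAM).
    ``hamming_distance`` is defined for the substitution scheme only.
    """

    parent: str
    scheme: str
    sequence: str
    edits: tuple[tuple[str, int, str], ...]
    pam: str = ""
    hamming_distance: int | None = None

    @property
    def full_site(self) -> str:
        if not self.pam:
            raise ValueError("variant has no PAM assigned")
        return self.sequence + self.pam

    @property
    def edit_label(self) -> str:
        if not self.edits:
            return "center"
        return ";".join(f"{k}{p + 1}{('>' + b) if b else ''}"
                        for k, p, b in self.edits)

    @property
    def read_name(self) -> str:
        """Identifier used in SAM/FASTA artifacts."""
        return f"{self.parent}|{self.scheme[:3]}|{self.edit_label}|{self.pam or 'NA'}"


def _check_nr(n: int, r: int) -> None:
    if not 1 <= r <= n:
        raise ValueError(f"require 1 <= r <= n, got n={n}, r={r}")


def _check_guide(guide: str) -> str:
    guide = guide.upper()
    if set(guide) - set(_BASES):
        raise ValueError(f"guide must be ACGT only, got {guide!r}")
    return guide


# ---------------------------------------------------------------------------
# closed-form counters
# ---------------------------------------------------------------------------

def substitution_count(n: int, r: int, include_center: bool = False) -> int:
    """Size of the substitution scheme: sum_{i=1..r} 3^i C(n, i).

    With ``include_center`` the unedited guide itself is counted too, i.e.
    the full Hamming ball of radius r.  For n=20, r=4 the two readings are
    424,996 (ball) and 424,995 (proper variants only); the per-scheme total
    of 1,243,190 uses the latter.
    """
    _check_nr(n, r)
    total = sum(3**i * comb(n, i) for i in range(1, r + 1))
    return total + 1 if include_center else total


def deletion_count_max(n: int, r: int) -> int:
    """Upper bound on unique deletion variants: sum_{i=1..r} C(n-1, i).

    The 5'-most base is never deleted, leaving n-1 candidate positions.
    The realised unique count is sequence-dependent (repeats collapse) and
    can be far below this bound.
    """
    _check_nr(n, r)
    return sum(comb(n - 1, i) for i in range(1, r + 1))


def insertion_count_terms(n: int, r: int) -> tuple[int, ...]:
    """Per-edit-count terms of the insertion counter.

    Term i equals 1 + sum_{j=1..i} 3^j C(n-1+i, j); for n=20 these are
    61; 1,954; 43,726; 767,419 for i = 1..4.
    """
    _check_nr(n, r)
    return tuple(
        1 + sum(3**j * comb(n - 1 + i, j) for j in range(1, i + 1))
        for i in range(1, r + 1)
    )


def insertion_count(n: int, r: int) -> int:
    """Cumulative insertion counter: r + sum_i sum_{j<=i} 3^j C(n-1+i, j)."""
    return sum(insertion_count_terms(n, r))


def scheme_total(n: int = 20, r: int = 4) -> int:
    """Three-scheme total (center excluded): 1,243,190 for n=20, r=4."""
    return (substitution_count(n, r)
            + deletion_count_max(n, r)
            + insertion_count(n, r))


# ---------------------------------------------------------------------------
# enumerators
# ---------------------------------------------------------------------------

def enumerate_substitutions(guide: str, r: int,
                            parent: str = "guide") -> Iterator[VariantRecord]:
    """Yield the exact Hamming ball of radius ``r`` around ``guide``.

    The unedited center is yielded first with hamming_distance 0.  Every
    member is produced exactly once (distinct mismatch sets give distinct
    strings), in deterministic order: edit count, then positions, then
    bases.
    """
    guide = _check_guide(guide)
    n = len(guide)
    _check_nr(n, r)
    yield VariantRecord(parent, SUBSTITUTION, guide, (), hamming_distance=0)
    seq = list(guide)
    for i in range(1, r + 1):
        for positions in itertools.combinations(range(n), i):
            alt = [tuple(b for b in _BASES if b != guide[p]) for p in positions]
            for bases in itertools.product(*alt):
                for p, b in zip(positions, bases):
                    seq[p] = b
                edits = tuple(("S", p, b) for p, b in zip(positions, bases))
                yield VariantRecord(parent, SUBSTITUTION, "".join(seq),
                                    edits, hamming_distance=i)
                for p in positions:
                    seq[p] = guide[p]


def enumerate_deletions(guide: str, r: int,
                        parent: str = "guide") -> Iterator[VariantRecord]:
    """Yield unique deletion variants (1..r deletions of positions 2..n).

    Distinct position sets frequently produce the same shortened string
    (any repeat makes neighbouring deletions equivalent); duplicates are
    collapsed, keeping the first edit description in (edit count,
    positions) order, which is the lexicographically smallest.
    """
    guide = _check_guide(guide)
    n = len(guide)
    _check_nr(n, r)
    for i in range(1, r + 1):
        seen: set[str] = set()  # lengths differ across i; dedup within i
        for positions in itertools.combinations(range(1, n), i):
            drop = set(positions)
            s = "".join(c for p, c in enumerate(guide) if p not in drop)
            if s not in seen:
                seen.add(s)
                yield VariantRecord(parent, DELETION, s,
                                    tuple(("D", p, "") for p in positions))


def enumerate_insertions(guide: str, r: int,
                         parent: str = "guide") -> Iterator[VariantRecord]:
    """Yield unique insertion variants (1..r single-base insertions).

    The n insertion sites are the n-1 internal gaps plus the gap between
    the spacer 3' end and the PAM; the 5' gap is excluded, mirroring the
    deletion convention.  Each chosen site receives one of the four bases;
    duplicate strings are collapsed as in :func:`enumerate_deletions`.
    """
    guide = _check_guide(guide)
    n = len(guide)
    _check_nr(n, r)
    for i in range(1, r + 1):
        seen: set[str] = set()
        for gaps in itertools.combinations(range(1, n + 1), i):
            for bases in itertools.product(_BASES, repeat=i):
                parts: list[str] = []
                prev = 0
                for g, b in zip(gaps, bases):
                    parts.append(guide[prev:g])
                    parts.append(b)
                    prev = g
                parts.append(guide[prev:])
                s = "".join(parts)
                if s not in seen:
                    seen.add(s)
                    yield VariantRecord(
                        parent, INSERTION, s,
                        tuple(("I", g, b) for g, b in zip(gaps, bases)))


_ENUMERATORS = {
    SUBSTITUTION: enumerate_substitutions,
    DELETION: enumerate_deletions,
    INSERTION: enumerate_insertions,
}


def enumerate_scheme(scheme: str, guide: str, r: int,
                     parent: str = "guide") -> Iterator[VariantRecord]:
    """Dispatch to the enumerator for ``scheme``."""
    try:
        enum = _ENUMERATORS[scheme]
    except KeyError:
        raise ValueError(f"unknown scheme {scheme!r}") from None
    return enum(guide, r, parent=parent)


def apply_edits(guide: str, edits: Iterable[tuple[str, int, str]]) -> str:
    """Apply a canonical edit tuple to a guide (fixture construction aid)."""
    guide = _check_guide(guide)
    subs = [(p, b) for k, p, b in edits if k == "S"]
    dels = {p for k, p, _ in edits if k == "D"}
    ins = [(g, b) for k, g, b in edits if k == "I"]
    seq = list(guide)
    for p, b in subs:
        seq[p] = b
    out: list[str] = []
    ins_at = {g: b for g, b in ins}
    for p, c in enumerate(seq):
        if p not in dels:
            out.append(c)
        if p + 1 in ins_at:
            out.append(ins_at[p + 1])
    if 0 in ins_at:
        out.insert(0, ins_at[0])
    return "".join(out)


def expand_pams(variants: Iterable[VariantRecord],
                pam_set: tuple[str, ...] = NRG_PAMS) -> Iterator[VariantRecord]:
    """Cross every variant with every PAM; cardinality |variants| x |pam_set|."""
    if not pam_set:
        raise ValueError("pam_set must not be empty")
    for v in variants:
        for pam in pam_set:
            yield replace(v, pam=pam)


def seed_region_filter(variants: Iterable[VariantRecord],
                       n: int = 20) -> Iterator[VariantRecord]:
    """Keep substitution variants edited only in the PAM-distal half.

    Mismatches in the seed (the ~10 nt adjacent to the PAM) are poorly
    tolerated by Cas9, so restricting the search space to PAM-distal
    edits (positions 1..n/2 counting from the 5' end) is a cheap,
    biologically motivated reduction.  Off by default in the pipeline.
    """
    distal = n // 2  # 0-based positions 0..distal-1 are PAM-distal
    for v in variants:
        if v.scheme != SUBSTITUTION:
            raise ValueError(
                "seed_region_filter is defined for substitution variants only")
        if all(p < distal for _, p, _ in v.edits):
            yield v


def batched(iterable: Iterable, size: int) -> Iterator[list]:
    """Yield lists of up to ``size`` items (bounded working set for mapping)."""
    it = iter(iterable)
    while chunk := list(itertools.islice(it, size)):
        yield chunk
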