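"""Discovery of SpCas9 guide candidates in a query sequence.

A guide is any 20-nt protospacer immediately followed by an NGG PAM, on
either strand of the query.  Overlapping guides are all reported: the point
of the downstream variant-space analysis is to rank *every* candidate, so
no greedy masking is applied at discovery time.

Coordinates are 0-based half-open on the forward strand of the query
throughout; the 1-based convention appears only in SAM output.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from Bio.Seq import reverse_complement

log = logging.getLogger(__name__)

GUIDE_LEN = 20
PAM_LEN = 3
SITE_LEN = GUIDE_LEN + PAM_LEN

_ACGT = frozenset("ACGT")


@dataclass(frozen=True, slots=True)
class Guide:
    """One candidate protospacer.

    ``name`` is ``f<k>``/``r<k>`` with ``k`` assigned in ascending
    forward-strand start order per strand.  ``sequence`` is the 20-nt spacer
    read 5'->3' as the gRNA would be, ``pam`` the 3-nt NGG motif immediately
    3' of it on the same strand.  ``context30`` is the N4-guide-NGG-N3
    layout used for on-target scoring, 'N'-padded at query edges.
    """

    name: str
    sequence: str
    pam: str
    strand: str
    start: int
    end: int
    context30: str
    gc_percent: float

    def __post_init__(self) -> None:
        if len(self.sequence) != GUIDE_LEN:
            raise ValueError(f"guide {self.name}: spacer must be {GUIDE_LEN} nt")
        if len(self.pam) != PAM_LEN:
            raise ValueError(f"guide {self.name}: PAM must be {PAM_LEN} nt")
        if self.strand not in "+-":
            raise ValueError(f"guide {self.name}: strand must be + or -")
        if self.end - self.start != GUIDE_LEN:
            raise ValueError(f"guide {self.name}: start/end must span {GUIDE_LEN} nt")


def gc_content(sequence: str) -> float:
    """G+C percentage of a spacer, on a 0-100 scale."""
    bad = set(sequence.upper()) - _ACGT
    if bad:
        raise ValueError(
            f"non-ACGT base(s) {sorted(bad)} in sequence {sequence!r}"
        )
    s = sequence.upper()
    return 100.0 * (s.count("G") + s.count("C")) / len(s)


def context_30mer(seq: str, start: int, end: int, strand: str) -> str:
    """30-mer context (4 nt upstream + spacer + PAM + 3 nt downstream).

    Read on the guide's own strand; flanks that run off the query are
    padded with 'N'.  ``start``/``end`` are forward-strand protospacer
    coordinates.
    """
    seq = seq.upper()
    if strand == "+":
        lo, hi = start - 4, end + PAM_LEN + 3
        left_pad = max(0, -lo)
        right_pad = max(0, hi - len(seq))
        core = seq[max(lo, 0) : min(hi, len(seq))]
        return "N" * left_pad + core + "N" * right_pad
    # reverse strand: 4 nt upstream of the spacer on '-' lie at higher
    # forward coordinates
    lo, hi = start - PAM_LEN - 3, end + 4
    left_pad = max(0, -lo)
    right_pad = max(0, hi - len(seq))
    core = seq[max(lo, 0) : min(hi, len(seq))]
    return "N" * right_pad + reverse_complement(core) + "N" * left_pad


def _is_ngg(pam: str) -> bool:
    return pam[0] in _ACGT and pam[1] == "G" and pam[2] == "G"


def find_guides(seq: str) -> list[Guide]:
    """Scan both strands of ``seq`` for every 20-nt guide next to an NGG PAM.

    Guides whose 20-mer or PAM contains a non-ACGT character are skipped.
    Input shorter than 23 nt yields an empty list (logged, not an error).
    Forward guides are named f1..fF and reverse guides r1..rR, each in
    ascending forward-strand start order.
    """
    seq = seq.upper()
    if len(seq) < SITE_LEN:
        log.warning("input of %d nt is too short for a %d+%d guide+PAM site",
                    len(seq), GUIDE_LEN, PAM_LEN)
        return []

    guides: list[Guide] = []
    fwd: list[tuple[int, str, str]] = []
    rev: list[tuple[int, str, str]] = []
    for i in range(len(seq) - SITE_LEN + 1):
        window = seq[i : i + GUIDE_LEN]
        pam = seq[i + GUIDE_LEN : i + SITE_LEN]
        if _is_ngg(pam) and _ACGT.issuperset(window):
            fwd.append((i, window, pam))
        # a reverse-strand site at forward positions [i+3, i+23) shows as
        # CCN followed by 20 nt on the forward strand
        rc_pam = seq[i : i + PAM_LEN]
        rc_window = seq[i + PAM_LEN : i + SITE_LEN]
        if (rc_pam[0] == "C" and rc_pam[1] == "C" and rc_pam[2] in _ACGT
                and _ACGT.issuperset(rc_window)):
            rev.append((i + PAM_LEN, reverse_complement(rc_window),
                        reverse_complement(rc_pam)))

    for k, (start, spacer, pam) in enumerate(fwd, 1):
        guides.append(Guide(
            name=f"f{k}", sequence=spacer, pam=pam, strand="+",
            start=start, end=start + GUIDE_LEN,
            context30=context_30mer(seq, start, start + GUIDE_LEN, "+"),
            gc_percent=gc_content(spacer),
        ))
    for k, (start, spacer, pam) in enumerate(rev, 1):
        guides.append(Guide(
            name=f"r{k}", sequence=spacer, pam=pam, strand="-",
            start=start, end=start + GUIDE_LEN,
            context30=context_30mer(seq, start, start + GUIDE_LEN, "-"),
            gc_percent=gc_content(spacer),
        ))
    return guides
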