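"""Result-tree rendering: alignments, SAM maps, FASTA artifacts, score table.

One run over one query sequence produces four directories plus a log:

* ``align/``          guide-to-variant alignment blocks per guide
* ``ot_maps/``        one SAM file of mapped variants per guide
* ``single_guides/``  one single-record FASTA per guide (RNA-fold ready)
* ``outfiles/``       scores.tsv, raw.txt (30-mer contexts, one per line,
                      machine-learning scorer input), guides.fa

Everything under ``outfiles/`` is deterministic (no timestamps, fixed
ordering and formatting) so identical inputs give byte-identical files;
timestamps live only in the log.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .discovery import Guide
from .mapping import MappedHit, ReferenceGenome, write_sam
from .scoring import ScoreRow
from .variants import DELETION, INSERTION, SUBSTITUTION

SUBDIRS = ("align", "ot_maps", "single_guides", "outfiles")


@dataclass(frozen=True)
class ResultTree:
    root: Path

    @property
    def align(self) -> Path: return self.root / "align"
    @property
    def ot_maps(self) -> Path: return self.root / "ot_maps"
    @property
    def single_guides(self) -> Path: return self.root / "single_guides"
    @property
    def outfiles(self) -> Path: return self.root / "outfiles"
    @property
    def log_file(self) -> Path: return self.root / "guidescout.log"


def render_alignment(guide: Guide, hit: MappedHit) -> str:
    """Three-line alignment of the guide against one mapped variant.

    Marker line: '|' match, '*' mismatch, '-' gap.  Indel pairs are
    reconstructed from the variant's recorded edits: deletions gap the
    variant row, insertions gap the guide row.
    """
    v = hit.variant
    g = guide.sequence
    if v.scheme == SUBSTITUTION:
        top, bottom = g, v.sequence
        marks = "".join("|" if a == b else "*" for a, b in zip(top, bottom))
    elif v.scheme == DELETION:
        deleted = {p for _, p, _ in v.edits}
        top = g
        bottom = "".join("-" if p in deleted else c for p, c in enumerate(g))
        marks = "".join("-" if p in deleted else "|" for p in range(len(g)))
    elif v.scheme == INSERTION:
        gaps = sorted(gp for _, gp, _ in v.edits)
        top_parts, prev = [], 0
        for gp in gaps:
            top_parts.append(g[prev:gp])
            top_parts.append("-")
            prev = gp
        top_parts.append(g[prev:])
        top = "".join(top_parts)
        bottom = v.sequence
        marks = "".join("-" if a == "-" else "|" for a in top)
    else:  # pragma: no cover - schemes are closed
        raise ValueError(f"unknown scheme {v.scheme!r}")
    header = (f"> {v.read_name} {hit.contig}:{hit.pos + 1}:{hit.strand}"
              f" PAM={v.pam}{' on-target' if hit.is_on_target else ''}")
    return "\n".join((header, top, marks, bottom))


def _fmt(x: float | None, nd: int = 2) -> str:
    return "NA" if x is None else f"{x:.{nd}f}"


def scores_frame(rows: Sequence[ScoreRow]) -> pd.DataFrame:
    """Score table with one line per guide, report formatting applied."""
    return pd.DataFrame([{
        "guide": r.name, "strand": r.strand, "start": r.start, "end": r.end,
        "sequence": r.sequence, "pam": r.pam,
        "gc_percent": f"{r.gc_percent:.1f}",
        "doench": _fmt(r.doench),
        "subs": r.counts.subs, "dels": r.counts.dels, "ins": r.counts.ins,
        "hsu_aggregate": _fmt(r.hsu_aggregate),
        "cfd_aggregate": _fmt(r.cfd_aggregate),
        "on_target": r.counts.on_target,
    } for r in rows])


def prepare_result_tree(root: str | Path, overwrite: bool = False) -> ResultTree:
    """Create the four-directory tree; refuse a non-empty root unless told."""
    root = Path(root)
    if root.exists() and any(root.iterdir()) and not overwrite:
        raise FileExistsError(
            f"output directory {root} is not empty (use overwrite to proceed)")
    for sub in SUBDIRS:
        (root / sub).mkdir(parents=True, exist_ok=True)
    return ResultTree(root)


def write_outputs(tree: ResultTree,
                  guides: Sequence[Guide],
                  rows: Sequence[ScoreRow],
                  hits_by_guide: Mapping[str, Sequence[MappedHit]],
                  genome: ReferenceGenome) -> ResultTree:
    """Populate a prepared result tree for one query sequence."""
    guide_by_name = {g.name: g for g in guides}
    for name, hits in hits_by_guide.items():
        guide = guide_by_name[name]
        blocks = [render_alignment(guide, h) for h in hits]
        (tree.align / f"{name}.txt").write_text(
            "\n\n".join(blocks) + ("\n" if blocks else ""))
        write_sam(list(hits), genome, tree.ot_maps / f"{name}.sam")
    for g in guides:
        (tree.single_guides / f"{g.name}.fa").write_text(
            f">{g.name}\n{g.sequence}\n")
    frame = scores_frame(rows)
    frame.to_csv(tree.outfiles / "scores.tsv", sep="\t", index=False)
    (tree.outfiles / "raw.txt").write_text(
        "".join(g.context30 + "\n" for g in guides))
    (tree.outfiles / "guides.fa").write_text(
        "".join(f">{g.name}\n{g.sequence}\n" for g in guides))
    return tree
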