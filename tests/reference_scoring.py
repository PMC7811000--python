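"""Independent reference implementations of the three scoring systems.

Written directly from the published formulas as straight-line code, loading
the bundled constant files themselves (plain json, no package loader).
These exist solely as oracles for the package's scoring module; they share
the constants but none of the implementation path.
"""

import json
import math
from importlib import resources

_DATA = resources.files("guidescout") / "data"
_HSU_W = json.loads((_DATA / "hsu_weights.json").read_text())["weights"]
_CFD_MM = json.loads((_DATA / "cfd_mismatch_synthetic.json").read_text())["mismatch"]
_CFD_PAM = json.loads((_DATA / "cfd_pam.json").read_text())["pam"]
_RS1 = json.loads((_DATA / "doench_rs1_synthetic.json").read_text())


def ref_hsu(guide, offsite):
    positions = [p for p in range(20) if guide[p] != offsite[p]]
    if not positions:
        return 100.0
    t1 = 1.0
    for p in positions:
        t1 = t1 * (1 - _HSU_W[p])
    if len(positions) > 1:
        dsum, npairs = 0, 0
        for i in range(len(positions)):
            for j in range(i + 1, len(positions)):
                dsum += positions[j] - positions[i]
                npairs += 1
        dbar = dsum / npairs
    else:
        dbar = 19.0
    t2 = 1.0 / ((((19.0 - dbar) / 19.0) * 4.0) + 1.0)
    t3 = 1.0 / (len(positions) ** 2)
    return 100.0 * t1 * t2 * t3


def ref_cfd(guide, offsite, pam):
    # the table's dna base is the template-strand base paired with the RNA
    rna = guide.replace("T", "U")
    template = offsite.translate(str.maketrans("ACGT", "TGCA"))
    score = 1.0
    for p in range(20):
        if guide[p] != offsite[p]:
            score = score * _CFD_MM[f"r{rna[p]}:d{template[p]}"][p]
    score = score * _CFD_PAM[pam[1:]]
    return 100.0 * score


def ref_doench(context30):
    score = _RS1["intercept"]
    spacer = context30[4:24]
    gc = sum(1 for c in spacer if c in "GC")
    if gc < 10:
        score += _RS1["gc_low"] * (10 - gc)
    if gc > 10:
        score += _RS1["gc_high"] * (gc - 10)
    for pos, sub, w in _RS1["weights"]:
        if context30[pos : pos + len(sub)] == sub:
            score += w
    return 100.0 / (1.0 + math.exp(-score))
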