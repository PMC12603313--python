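"""Regenerate the packaged synthetic reference anchors.

The shipped fixtures (src/auxinmir/data/) are seeded random protein
backgrounds with the documented functional residues planted at their
documented 1-based positions; this script reproduces them byte-for-byte
and exists so the fixtures' provenance is auditable.  Running it is
never required at analysis time.
"""
from pathlib import Path

DATA = Path(__file__).resolve().parent.parent / "src" / "auxinmir" / "data"

import json
import numpy as np

AA = list("ACDEFGHIKLMNPQRSTVWY")
rng = np.random.default_rng(20240915)

def bg(n):
    return list(rng.choice(AA, size=n))

# --- TIR1-like reference, 600 aa -------------------------------------------
tir = bg(600)
def put(seq, pos1, aa):  # 1-based
    seq[pos1 - 1] = aa

orientation = [(410, "K"), (440, "S"), (441, "G"), (464, "A"), (465, "F")]
selectivity = [(405, "C"), (438, "S"), (439, "L"), (440, "S"), (462, "S"), (489, "R")]
ac = [(520, "N"), (544, "S"), (568, "R")]
for p, a in orientation + selectivity + ac:
    put(tir, p, a)
put(tir, 1, "M")
tir = "".join(tir)

# --- ARF-like reference, 640 aa --------------------------------------------
arf = bg(640)
put(arf, 1, "M")
# B3 motif S-x4-H-G-x2-S-x2-R at 120..132
for p, a in [(120, "S"), (125, "H"), (126, "G"), (129, "S"), (132, "R")]:
    put(arf, p, a)
# PB1 region 551..640: canonical K at 570, OPCA D-x-[DE]-x-D at 600..604
put(arf, 570, "K")
for p, a in [(600, "D"), (601, "A"), (602, "E"), (603, "A"), (604, "D")]:
    put(arf, p, a)
arf = "".join(arf)
pb1 = arf[550:640]  # standalone PB1 reference, 90 aa; K at rel 20, OPCA 50..54

# sanity: the planted B3 motif is the unique exact match
import re
hits = [m.start() for m in re.finditer(r"(?=S.{4}HG.{2}S.{2}R)", arf)]
assert hits == [119], hits
# no accidental second exact motif in tir
assert not re.search(r"S.{4}HG.{2}S.{2}R", tir)

with open(DATA / "synthetic_references.fasta", "w") as fh:
    fh.write(">SYN_TIR1_REF synthetic TIR1/AFB anchor (planted pocket/AC residues)\n")
    for i in range(0, len(tir), 60):
        fh.write(tir[i:i+60] + "\n")
    fh.write(">SYN_ARF_REF synthetic ARF anchor (planted B3 motif, PB1 K/OPCA)\n")
    for i in range(0, len(arf), 60):
        fh.write(arf[i:i+60] + "\n")
    fh.write(">SYN_PB1_REF synthetic PB1 domain anchor (slice of SYN_ARF_REF)\n")
    for i in range(0, len(pb1), 60):
        fh.write(pb1[i:i+60] + "\n")

anchors = {
    "tir1": {
        "ref_id": "SYN_TIR1_REF",
        "fbox_span": [10, 55],
        "lrr_span": [100, 580],
        "pocket_orientation": [[p, a] for p, a in orientation],
        "pocket_selectivity": [[p, a] for p, a in selectivity],
        "ac_positions": [[p, a] for p, a in ac],
    },
    "arf": {
        "ref_id": "SYN_ARF_REF",
        "dbd_span": [1, 350],
        "dd_span": [230, 330],
        "b3_motif_start": 120,
        "md_span": [351, 550],
        "pb1_span": [551, 640],
    },
    "pb1": {
        "ref_id": "SYN_PB1_REF",
        "canonical_k_pos": 20,
        "opca_span": [50, 54],
    },
}
with open(DATA / "anchors.json", "w") as fh:
    json.dump(anchors, fh, indent=2)
print("tir[409]=", tir[409], "arf[569]=", arf[569], "pb1[19]=", pb1[19], "opca=", pb1[49:54])
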