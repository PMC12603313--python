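"""Packaged reference anchors for domain-grammar classification.

The anchors are SYNTHETIC stand-ins: seeded random protein backgrounds
with the documented functional residues planted at their documented
1-based positions (auxin-pocket orientation/selectivity residues, the
AC-domain critical triad on the TIR1-like reference; the B3 DBD motif,
PB1 canonical lysine and OPCA acidic patch on the ARF-like reference).
They carry the residue *grammar* the classifier tests, not the biology
of any real accession, and are shipped as fixture data so that residue
numbering in reports is reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources

from .sequence_core import read_protein_fasta


@dataclass(frozen=True)
class Tir1Reference:
    ref_id: str
    seq: str
    fbox_span: tuple[int, int]          # 1-based inclusive
    lrr_span: tuple[int, int]
    pocket_orientation: tuple[tuple[int, str], ...]
    pocket_selectivity: tuple[tuple[int, str], ...]
    ac_positions: tuple[tuple[int, str], ...]


@dataclass(frozen=True)
class ArfReference:
    ref_id: str
    seq: str
    dbd_span: tuple[int, int]
    dd_span: tuple[int, int]
    b3_motif_start: int
    md_span: tuple[int, int]
    pb1_span: tuple[int, int]


@dataclass(frozen=True)
class Pb1Reference:
    ref_id: str
    seq: str
    canonical_k_pos: int                # 1-based within the PB1 reference
    opca_span: tuple[int, int]          # 1-based inclusive, 5 columns


def _data_path(name: str):
    return resources.files("auxinmir.data").joinpath(name)


def load_references() -> tuple[Tir1Reference, ArfReference, Pb1Reference]:
    seqs = read_protein_fasta(str(_data_path("synthetic_references.fasta")))
    meta = json.loads(_data_path("anchors.json").read_text())

    t = meta["tir1"]
    tir1 = Tir1Reference(
        ref_id=t["ref_id"], seq=seqs[t["ref_id"]],
        fbox_span=tuple(t["fbox_span"]), lrr_span=tuple(t["lrr_span"]),
        pocket_orientation=tuple((p, a) for p, a in t["pocket_orientation"]),
        pocket_selectivity=tuple((p, a) for p, a in t["pocket_selectivity"]),
        ac_positions=tuple((p, a) for p, a in t["ac_positions"]),
    )
    a = meta["arf"]
    arf = ArfReference(
        ref_id=a["ref_id"], seq=seqs[a["ref_id"]],
        dbd_span=tuple(a["dbd_span"]), dd_span=tuple(a["dd_span"]),
        b3_motif_start=a["b3_motif_start"], md_span=tuple(a["md_span"]),
        pb1_span=tuple(a["pb1_span"]),
    )
    p = meta["pb1"]
    pb1 = Pb1Reference(
        ref_id=p["ref_id"], seq=seqs[p["ref_id"]],
        canonical_k_pos=p["canonical_k_pos"], opca_span=tuple(p["opca_span"]),
    )
    # self-consistency: planted residues really sit where the metadata says
    for pos, aa in tir1.pocket_orientation + tir1.pocket_selectivity + tir1.ac_positions:
        if tir1.seq[pos - 1] != aa:
            raise ValueError(f"reference {tir1.ref_id}: expected {aa} at {pos}, "
                             f"found {tir1.seq[pos - 1]}")
    if pb1.seq[pb1.canonical_k_pos - 1] != "K":
        raise ValueError("PB1 reference: canonical lysine position mismatch")
    return tir1, arf, pb1
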