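"""Sequence primitives: FASTA I/O, ORF finding, global alignment, logos.

Conventions used throughout the package:

* nucleotide sequences are stored DNA-style (``U`` is normalised to ``T``
  on ingest and the normalisation is recorded on the record);
* coordinates are 0-based half-open internally and 1-based inclusive in
  user-facing reports;
* reverse-strand features are reported in the reverse strand's own
  coordinates together with a strand flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Align import substitution_matrices
from Bio.Data import CodonTable
from Bio.Seq import Seq

NUC_ALPHABET = set("ACGTN")
AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX")

_STANDARD_TABLE = CodonTable.unambiguous_dna_by_id[1]
CODON_TO_AA = dict(_STANDARD_TABLE.forward_table)
STOP_CODONS = set(_STANDARD_TABLE.stop_codons)
START_CODON = "ATG"


class FastaParseError(ValueError):
    """Raised when a FASTA record cannot be ingested."""


@dataclass
class Transcript:
    """A nucleotide record; ``had_u`` records the U->T normalisation."""

    id: str
    seq: str
    annotation: str = ""
    had_u: bool = False

    def __post_init__(self) -> None:
        raw = self.seq.upper()
        if "U" in raw:
            self.had_u = True
            raw = raw.replace("U", "T")
        bad = set(raw) - NUC_ALPHABET
        if bad:
            raise FastaParseError(
                f"transcript {self.id!r}: non-nucleotide symbols {sorted(bad)}")
        if not raw:
            raise FastaParseError(f"transcript {self.id!r}: empty sequence")
        self.seq = raw


@dataclass
class OrfProtein:
    """A complete open reading frame and its translation.

    ``cds_start``/``cds_end`` are 0-based half-open on the stored strand
    (``strand='-'`` means coordinates on the reverse complement).  The
    stop codon is inside the CDS but not in ``aa_seq``.
    """

    transcript_id: str
    frame: int
    strand: str
    cds_start: int
    cds_end: int
    aa_seq: str
    complete: bool = True

    @property
    def n_aa(self) -> int:
        return len(self.aa_seq)


@dataclass
class AlignmentAnchor:
    """Column trace of a pairwise global alignment.

    ``pairs`` holds one tuple per alignment column: (ref_pos, query_pos),
    1-based, ``None`` for a gap.  ``identity`` is computed over columns
    where neither side is a gap.
    """

    ref_id: str
    query_id: str
    pairs: list[tuple[int | None, int | None]]
    score: float
    identity: float

    def query_at_ref(self, ref_pos: int) -> int | None:
        """Query position (1-based) aligned to ``ref_pos``; None if gapped."""
        for r, q in self.pairs:
            if r == ref_pos:
                return q
        raise KeyError(f"reference position {ref_pos} not in alignment")


@dataclass
class PositionFrequencyMatrix:
    alphabet: str
    counts: np.ndarray  # positions x symbols
    n_seqs: int

    @property
    def frequencies(self) -> np.ndarray:
        return self.counts / self.n_seqs


# ---------------------------------------------------------------------------
# FASTA I/O
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[Transcript]:
    """Read nucleotide FASTA into :class:`Transcript` records.

    The description after the first whitespace of the header becomes the
    annotation; ``U`` is normalised to ``T``.
    """
    out: list[Transcript] = []
    for idx, rec in enumerate(SeqIO.parse(str(path), "fasta")):
        seq = str(rec.seq)
        if not seq:
            raise FastaParseError(f"record {idx} ({rec.id!r}): empty sequence")
        annotation = rec.description[len(rec.id):].strip() if rec.description else ""
        try:
            out.append(Transcript(id=rec.id, seq=seq, annotation=annotation))
        except FastaParseError as exc:
            raise FastaParseError(f"record {idx}: {exc}") from exc
    return out


def read_protein_fasta(path: str | Path) -> dict[str, str]:
    """Read a protein FASTA as an id -> sequence mapping."""
    out: dict[str, str] = {}
    for idx, rec in enumerate(SeqIO.parse(str(path), "fasta")):
        seq = str(rec.seq).upper()
        bad = set(seq) - AA_ALPHABET
        if bad:
            raise FastaParseError(
                f"record {idx} ({rec.id!r}): non-amino-acid symbols {sorted(bad)}")
        out[rec.id] = seq
    return out


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# ORF finding
# ---------------------------------------------------------------------------

def translate_cds(cds: str) -> str:
    """Translate a CDS (without requiring a trailing stop); N codons -> X."""
    aas = []
    for i in range(0, len(cds) - len(cds) % 3, 3):
        codon = cds[i:i + 3]
        if codon in STOP_CODONS:
            aas.append("*")
        else:
            aas.append(CODON_TO_AA.get(codon, "X"))
    return "".join(aas)


def _orfs_one_strand(seq: str, transcript_id: str, strand: str, min_aa: int) -> list[OrfProtein]:
    n = len(seq)
    found: list[OrfProtein] = []
    for frame in range(3):
        open_starts: list[int] = []
        for pos in range(frame, n - 2, 3):
            codon = seq[pos:pos + 3]
            # codons containing N are neither start nor stop
            if codon == START_CODON:
                open_starts.append(pos)
            if codon in STOP_CODONS:
                for start in open_starts:
                    n_aa = (pos - start) // 3  # stop codon excluded
                    if n_aa >= min_aa:
                        cds = seq[start:pos]
                        found.append(OrfProtein(
                            transcript_id=transcript_id, frame=frame,
                            strand=strand, cds_start=start, cds_end=pos + 3,
                            aa_seq=translate_cds(cds), complete=True))
                open_starts = []
    return found


def find_complete_orfs(t: Transcript, min_aa: int = 50) -> list[OrfProtein]:
    """All complete ORFs (ATG..stop) on both strands and three frames.

    Returned sorted by residue count descending, then (strand, frame,
    start) for determinism.  ORFs shorter than ``min_aa`` residues are
    dropped.
    """
    if min_aa < 1:
        raise ValueError("min_aa must be >= 1")
    rc = str(Seq(t.seq).reverse_complement())
    orfs = (_orfs_one_strand(t.seq, t.id, "+", min_aa)
            + _orfs_one_strand(rc, t.id, "-", min_aa))
    orfs.sort(key=lambda o: (-o.n_aa, o.strand, o.frame, o.cds_start))
    return orfs


def principal_orf(orfs: list[OrfProtein]) -> OrfProtein | None:
    """The longest mRNA-sense (+ strand) ORF, falling back to the longest
    overall; transcripts are assumed to be oriented mRNAs."""
    if not orfs:
        return None
    forward = [o for o in orfs if o.strand == "+"]
    return forward[0] if forward else orfs[0]


# ---------------------------------------------------------------------------
# Global alignment (Needleman-Wunsch / Gotoh, affine gaps)
# ---------------------------------------------------------------------------

def _load_matrix(name: str):
    return substitution_matrices.load(name)


def global_align(a: str, b: str, matrix: str = "BLOSUM62",
                 gap_open: float = 10.0, gap_extend: float = 1.0,
                 ref_id: str = "ref", query_id: str = "query") -> AlignmentAnchor:
    """Optimal global alignment of protein ``a`` (reference) vs ``b`` (query).

    Affine gap model: a gap of length L costs ``gap_open + (L-1)*gap_extend``.
    Tie-breaking in the traceback is deterministic: diagonal, then up
    (gap in query), then left (gap in reference).
    """
    if not a or not b:
        raise ValueError("both sequences must be non-empty")
    sub = _load_matrix(matrix)
    valid = set(sub.alphabet) - {"*"}
    for label, s in (("reference", a), ("query", b)):
        bad = set(s) - valid
        if bad:
            raise ValueError(f"{label} contains symbols outside the "
                             f"substitution alphabet: {sorted(bad)}")

    n, m = len(a), len(b)
    NEG = float("-inf")
    M = np.full((n + 1, m + 1), NEG)
    Ix = np.full((n + 1, m + 1), NEG)  # gap in query (consumes a)
    Iy = np.full((n + 1, m + 1), NEG)  # gap in reference (consumes b)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        Ix[i, 0] = -(gap_open + (i - 1) * gap_extend)
    for j in range(1, m + 1):
        Iy[0, j] = -(gap_open + (j - 1) * gap_extend)
    # row-vectorised fill: M and Ix depend only on the previous row; the
    # in-row Iy recurrence collapses to a running-max transform
    alpha_index = {sym: k for k, sym in enumerate(sub.alphabet)}
    sub_arr = np.asarray(sub)
    b_idx = np.array([alpha_index[c] for c in b])
    jj = np.arange(m + 1, dtype=float)
    for i in range(1, n + 1):
        srow = sub_arr[alpha_index[a[i - 1]], b_idx]
        prev_best = np.maximum(np.maximum(M[i - 1], Ix[i - 1]), Iy[i - 1])
        M[i, 1:] = prev_best[:-1] + srow
        Ix[i] = np.maximum(M[i - 1] - gap_open, Ix[i - 1] - gap_extend)
        Ix[i, 0] = -(gap_open + (i - 1) * gap_extend)
        # Iy[i, j] = max_{j' < j} M[i, j'] - gap_open - (j - j' - 1) * gap_extend
        t = M[i] + gap_extend * jj
        Iy[i, 1:] = (np.maximum.accumulate(t[:-1]) - gap_open
                     - gap_extend * (jj[1:] - 1.0))
        Iy[i, 0] = NEG

    # traceback; state preference encodes diagonal > up > left
    i, j = n, m
    score = max(M[i, j], Ix[i, j], Iy[i, j])
    if M[i, j] == score:
        state = "M"
    elif Ix[i, j] == score:
        state = "Ix"
    else:
        state = "Iy"
    pairs: list[tuple[int | None, int | None]] = []
    while i > 0 or j > 0:
        if state == "M":
            if i == 0 or j == 0:  # boundary: only gap states reach here
                state = "Ix" if i > 0 else "Iy"
                continue
            pairs.append((i, j))
            s = sub[a[i - 1], b[j - 1]]
            prev = M[i, j] - s
            i, j = i - 1, j - 1
            if M[i, j] == prev:
                state = "M"
            elif Ix[i, j] == prev:
                state = "Ix"
            else:
                state = "Iy"
        elif state == "Ix":
            pairs.append((i, None))
            val = Ix[i, j]
            i -= 1
            if i >= 0 and M[i, j] - gap_open == val:
                state = "M"
            else:
                state = "Ix"
        else:  # Iy
            pairs.append((None, j))
            val = Iy[i, j]
            j -= 1
            if j >= 0 and M[i, j] - gap_open == val:
                state = "M"
            else:
                state = "Iy"
    pairs.reverse()

    aligned = [(r, q) for r, q in pairs if r is not None and q is not None]
    ident = (sum(1 for r, q in aligned if a[r - 1] == b[q - 1]) / len(aligned)
             if aligned else 0.0)
    return AlignmentAnchor(ref_id=ref_id, query_id=query_id, pairs=pairs,
                           score=float(score), identity=ident)


# ---------------------------------------------------------------------------
# Position-frequency matrices (sequence logos as data)
# ---------------------------------------------------------------------------

def build_pfm(seqs: Sequence[str], alphabet: str) -> PositionFrequencyMatrix:
    """Column counts for equal-length sequences over ``alphabet``."""
    if not seqs:
        raise ValueError("need at least one sequence")
    length = len(seqs[0])
    if any(len(s) != length for s in seqs):
        raise ValueError("sequences must all have the same length")
    index = {sym: k for k, sym in enumerate(alphabet)}
    counts = np.zeros((length, len(alphabet)), dtype=int)
    for s in seqs:
        for pos, sym in enumerate(s):
            if sym not in index:
                raise ValueError(f"symbol {sym!r} not in alphabet {alphabet!r}")
            counts[pos, index[sym]] += 1
    return PositionFrequencyMatrix(alphabet=alphabet, counts=counts, n_seqs=len(seqs))


def pfm_to_tsv(pfm: PositionFrequencyMatrix, path: str | Path) -> None:
    """Export as TSV: rows = 1-based positions, columns = alphabet symbols."""
    with open(path, "w") as fh:
        fh.write("position\t" + "\t".join(pfm.alphabet) + "\n")
        for pos in range(pfm.counts.shape[0]):
            row = "\t".join(str(int(c)) for c in pfm.counts[pos])
            fh.write(f"{pos + 1}\t{row}\n")


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())
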