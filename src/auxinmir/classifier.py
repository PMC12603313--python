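"""Rule-based functional curation of TIR1/AFB receptors and ARF factors.

The classifier replaces profile-HMM domain scans with identity-threshold
global alignment to packaged reference anchors, then interrogates single
residue columns:

* TIR1/AFB: F-box presence (identity over the reference F-box span), LRR
  ring closure (aligned coverage of the LRR region), the eleven
  auxin-pocket residues (five ligand-orientation, six ligand-selectivity
  positions) and the three AC-domain critical positions (first expected
  asparagine).  A pocket or AC substitution is *reported*, it does not
  revoke receptor status; an LRR ring that does not close (low coverage,
  e.g. a C-terminal truncation) yields the ``incomplete`` verdict.
* ARF: B3 DBD presence plus the SxxxxHGxxSxxR AuxRE-recognition motif
  (tolerant scan that records substitutions such as the H->G variant
  characteristic of ARF17/18), DD dimerisation-span coverage, middle
  domain (MD) amino-acid-composition typing into activator (Q/S/L-rich)
  vs repressor (S/L/P/G-rich), and PB1 typing from the canonical-lysine
  (motif I) and acidic OPCA (motif II) faces.  Domain-architecture calls
  map to functional roles (AuxRE masking for DBD-only proteins,
  polymerisation modulation for PB1-only proteins, auxin-independent
  action for PB1-less ARFs).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from .config import PipelineConfig
from .references import ArfReference, Pb1Reference, Tir1Reference
from .sequence_core import AlignmentAnchor, OrfProtein, global_align

AA20 = "ACDEFGHIKLMNPQRSTVWY"

# roles a checked residue can play
ROLE_ORIENTATION = "orientation"
ROLE_SELECTIVITY = "selectivity"
ROLE_AC = "ac_critical"


class ReferenceConfigError(ValueError):
    """Anchor metadata disagrees with the reference sequence."""


@dataclass
class ResidueCheck:
    ref_name: str
    ref_pos: int                # 1-based on the reference
    ref_aa: str
    query_aa: str               # "-" for a gap
    conserved: bool
    role: str


@dataclass
class DbdMotifMatch:
    start: int                  # 1-based position of the motif in the protein
    window: str
    n_mismatch: int
    substitutions: list[tuple[str, int, str]]  # (expected, motif offset 1-based, observed)


@dataclass
class Pb1Evidence:
    present: bool
    identity: float
    motif_i_lysine: bool
    motif_ii_opca: bool
    lysine_observed: str = "-"
    opca_observed: str = ""

    @property
    def pb1_type(self) -> str:
        if not self.present:
            return "absent"
        if self.motif_i_lysine and self.motif_ii_opca:
            return "full"
        if self.motif_ii_opca:
            return "typeI_OPCA_only"       # OPCA face without the canonical K
        if self.motif_i_lysine:
            return "typeII_lysine_only"
        return "absent_motifs"


@dataclass
class TirAfbReport:
    protein_id: str
    has_fbox: bool
    fbox_quality: float
    lrr_coverage: float
    pocket_checks: list[ResidueCheck]
    ac_checks: list[ResidueCheck]
    verdict: str                # receptor | incomplete | rejected
    reason: str = ""

    @property
    def n_pocket_conserved(self) -> int:
        return sum(1 for c in self.pocket_checks if c.conserved)


@dataclass
class ArfReport:
    protein_id: str
    has_dbd: bool
    dbd_identity: float
    dbd_motif: DbdMotifMatch | None
    has_dd: bool
    dd_coverage: float
    md_span: tuple[int, int] | None     # 0-based half-open on the query
    md_composition: dict[str, float] | None
    md_call: str                        # activator | repressor | unclassified | none
    pb1: Pb1Evidence
    architecture: str = ""
    role_note: str = ""


# ---------------------------------------------------------------------------
# candidate ORF selection
# ---------------------------------------------------------------------------

def select_candidate_orf(orfs: list[OrfProtein], ref_seqs: list[str],
                         k: int = 4, top: int = 10) -> OrfProtein | None:
    """Pick the ORF most likely to encode the annotated protein.

    Transcripts often carry several complete ORFs (nested starts,
    frame-shifted readthroughs); all are emitted upstream and the
    classifier selects here by shared k-mer content with the reference
    sequences — a cheap proxy for alignment identity.  Considers the
    ``top`` longest mRNA-sense ORFs, falls back to the overall longest;
    ties resolve to the longer ORF.
    """
    if not orfs:
        return None
    forward = [o for o in orfs if o.strand == "+"][:top] or orfs[:top]
    ref_kmers = set()
    for ref in ref_seqs:
        ref_kmers |= {ref[i:i + k] for i in range(len(ref) - k + 1)}

    def shared(o: OrfProtein) -> int:
        return sum(1 for i in range(len(o.aa_seq) - k + 1)
                   if o.aa_seq[i:i + k] in ref_kmers)

    return max(forward, key=lambda o: (shared(o), o.n_aa))


# ---------------------------------------------------------------------------
# residue anchoring
# ---------------------------------------------------------------------------

def anchor_residues(query_aa: str, ref_seq: str,
                    positions: list[tuple[int, str, str]],
                    cfg: PipelineConfig | None = None,
                    ref_name: str = "ref", query_id: str = "query",
                    anchor: AlignmentAnchor | None = None) -> list[ResidueCheck]:
    """Check the query residues aligned to reference columns.

    ``positions`` lists (ref_pos 1-based, expected ref_aa, role).  The
    expected residue must match the reference sequence itself; a mismatch
    means the anchor metadata has drifted and is a configuration error,
    not a biological finding.  A gap in the query is non-conserved.
    """
    cfg = cfg or PipelineConfig()
    for pos, aa, _role in positions:
        if not 1 <= pos <= len(ref_seq):
            raise ReferenceConfigError(f"{ref_name}: position {pos} outside reference")
        if ref_seq[pos - 1] != aa:
            raise ReferenceConfigError(
                f"{ref_name}: metadata says {aa} at {pos}, sequence has {ref_seq[pos - 1]}")
    if anchor is None:
        anchor = global_align(ref_seq, query_aa, matrix=cfg.matrix,
                              gap_open=cfg.gap_open, gap_extend=cfg.gap_extend,
                              ref_id=ref_name, query_id=query_id)
    ref_to_query = {r: q for r, q in anchor.pairs if r is not None}
    checks = []
    for pos, aa, role in positions:
        qpos = ref_to_query.get(pos)
        qaa = query_aa[qpos - 1] if qpos is not None else "-"
        checks.append(ResidueCheck(ref_name=ref_name, ref_pos=pos, ref_aa=aa,
                                   query_aa=qaa, conserved=(qaa == aa), role=role))
    return checks


def _span_identity(anchor: AlignmentAnchor, ref_seq: str, query_aa: str,
                   span: tuple[int, int]) -> float:
    """Fraction of reference span columns aligned to the identical residue."""
    lo, hi = span
    ref_to_query = {r: q for r, q in anchor.pairs if r is not None}
    n_match = 0
    for pos in range(lo, hi + 1):
        q = ref_to_query.get(pos)
        if q is not None and query_aa[q - 1] == ref_seq[pos - 1]:
            n_match += 1
    return n_match / (hi - lo + 1)


def _span_coverage(anchor: AlignmentAnchor, span: tuple[int, int]) -> float:
    """Fraction of reference span columns aligned to any query residue."""
    lo, hi = span
    ref_to_query = {r: q for r, q in anchor.pairs if r is not None}
    covered = sum(1 for pos in range(lo, hi + 1) if ref_to_query.get(pos) is not None)
    return covered / (hi - lo + 1)


# ---------------------------------------------------------------------------
# TIR1/AFB receptors
# ---------------------------------------------------------------------------

def classify_tir_afb(p: OrfProtein, ref: Tir1Reference,
                     cfg: PipelineConfig | None = None) -> TirAfbReport:
    """Curate one translated ORF as a candidate auxin receptor."""
    cfg = cfg or PipelineConfig()
    if not p.complete:
        return TirAfbReport(protein_id=p.transcript_id, has_fbox=False,
                            fbox_quality=0.0, lrr_coverage=0.0,
                            pocket_checks=[], ac_checks=[],
                            verdict="rejected", reason="incomplete ORF")
    anchor = global_align(ref.seq, p.aa_seq, matrix=cfg.matrix,
                          gap_open=cfg.gap_open, gap_extend=cfg.gap_extend,
                          ref_id=ref.ref_id, query_id=p.transcript_id)
    fbox_quality = _span_identity(anchor, ref.seq, p.aa_seq, ref.fbox_span)
    has_fbox = fbox_quality >= cfg.fbox_min_identity
    lrr_coverage = _span_coverage(anchor, ref.lrr_span)

    pocket_positions = ([(pos, aa, ROLE_ORIENTATION) for pos, aa in ref.pocket_orientation]
                        + [(pos, aa, ROLE_SELECTIVITY) for pos, aa in ref.pocket_selectivity])
    pocket = anchor_residues(p.aa_seq, ref.seq, pocket_positions, cfg,
                             ref_name=ref.ref_id, query_id=p.transcript_id,
                             anchor=anchor)
    ac = anchor_residues(p.aa_seq, ref.seq,
                         [(pos, aa, ROLE_AC) for pos, aa in ref.ac_positions],
                         cfg, ref_name=ref.ref_id, query_id=p.transcript_id,
                         anchor=anchor)

    if lrr_coverage < cfg.lrr_coverage_threshold:
        verdict, reason = "incomplete", "LRR ring does not close (low coverage)"
    elif has_fbox:
        verdict, reason = "receptor", ""
    else:
        verdict, reason = "rejected", "no high-quality F-box domain"
    return TirAfbReport(protein_id=p.transcript_id, has_fbox=has_fbox,
                        fbox_quality=fbox_quality, lrr_coverage=lrr_coverage,
                        pocket_checks=pocket, ac_checks=ac,
                        verdict=verdict, reason=reason)


# ---------------------------------------------------------------------------
# ARF domain grammar
# ---------------------------------------------------------------------------

_MOTIF_LEN = 13
_MOTIF_LITERALS = ((0, "S"), (5, "H"), (6, "G"), (9, "S"), (12, "R"))


def scan_dbd_motif(aa_seq: str, max_mismatch: int = 1) -> DbdMotifMatch | None:
    """Best window matching S-x4-H-G-x2-S-x2-R with tolerated substitutions.

    Returns the leftmost window with the fewest mismatches at the five
    literal positions, or None if even the best window exceeds
    ``max_mismatch``.
    """
    best: DbdMotifMatch | None = None
    for start in range(len(aa_seq) - _MOTIF_LEN + 1):
        window = aa_seq[start:start + _MOTIF_LEN]
        subs = [(exp, off + 1, window[off])
                for off, exp in _MOTIF_LITERALS if window[off] != exp]
        if len(subs) > max_mismatch:
            continue
        if best is None or len(subs) < best.n_mismatch:
            best = DbdMotifMatch(start=start + 1, window=window,
                                 n_mismatch=len(subs), substitutions=subs)
            if best.n_mismatch == 0:
                break
    return best


def type_pb1(aa_seq: str, pb1_ref: Pb1Reference,
             cfg: PipelineConfig | None = None) -> Pb1Evidence:
    """Type the PB1 interaction domain from its two faces.

    Motif I = canonical lysine at the basic face; motif II = the acidic
    OPCA patch D-x-[DE]-x-D (at most one mismatch at the three literal
    columns).  The domain itself is called present when the identity to
    the packaged PB1 reference reaches ``pb1_min_identity`` over a
    compact region (aligned query extent at most ``pb1_max_stretch``
    reference lengths — a real domain hit is contiguous, while spurious
    threading of the short reference through a long unrelated query is
    not).
    """
    cfg = cfg or PipelineConfig()
    anchor = global_align(pb1_ref.seq, aa_seq, matrix=cfg.matrix,
                          gap_open=cfg.gap_open, gap_extend=cfg.gap_extend,
                          ref_id=pb1_ref.ref_id, query_id="query")
    span = (1, len(pb1_ref.seq))
    identity = _span_identity(anchor, pb1_ref.seq, aa_seq, span)
    ref_to_query = {r: q for r, q in anchor.pairs if r is not None}
    qpos = [q for q in ref_to_query.values() if q is not None]
    stretch = ((max(qpos) - min(qpos) + 1) / len(pb1_ref.seq)) if qpos else float("inf")
    if identity < cfg.pb1_min_identity or stretch > cfg.pb1_max_stretch:
        return Pb1Evidence(present=False, identity=identity,
                           motif_i_lysine=False, motif_ii_opca=False)

    kq = ref_to_query.get(pb1_ref.canonical_k_pos)
    k_obs = aa_seq[kq - 1] if kq is not None else "-"
    motif_i = k_obs == "K"

    lo, hi = pb1_ref.opca_span
    opca_obs = "".join(
        aa_seq[ref_to_query[pos] - 1] if ref_to_query.get(pos) is not None else "-"
        for pos in range(lo, hi + 1))
    # literal columns of D-x-[DE]-x-D are offsets 0, 2, 4
    mismatches = 0
    if len(opca_obs) == 5:
        if opca_obs[0] != "D":
            mismatches += 1
        if opca_obs[2] not in "DE":
            mismatches += 1
        if opca_obs[4] != "D":
            mismatches += 1
    else:  # defensive; span is fixed width
        mismatches = 3
    motif_ii = mismatches <= 1
    return Pb1Evidence(present=True, identity=identity, motif_i_lysine=motif_i,
                       motif_ii_opca=motif_ii, lysine_observed=k_obs,
                       opca_observed=opca_obs)


def classify_md(aa_seq: str, md_span: tuple[int, int] | None,
                cfg: PipelineConfig | None = None) -> tuple[str, dict[str, float] | None]:
    """Activator/repressor call from middle-domain amino-acid composition.

    Activator: Gln frequency >= ``q_min`` and Q, S, L all within the
    ``top_k`` most frequent residues.  Repressor: Pro+Gly frequency >=
    ``pg_min`` with Gln below ``q_min``.  Anything else is reported as
    ``unclassified`` rather than coerced.
    """
    cfg = cfg or PipelineConfig()
    if md_span is None:
        return "none", None
    start, end = md_span
    if not 0 <= start < end <= len(aa_seq):
        raise ValueError(f"invalid MD span {md_span} for length {len(aa_seq)}")
    span = aa_seq[start:end]
    if len(span) < cfg.md_min_len:
        return "none", None
    counts = Counter(span)
    total = len(span)
    comp = {aa: counts.get(aa, 0) / total for aa in AA20}
    # deterministic ranking: frequency desc, then alphabetical
    ranked = sorted(AA20, key=lambda aa: (-comp[aa], aa))
    top = set(ranked[:cfg.top_k])
    if comp["Q"] >= cfg.q_min and {"Q", "S", "L"} <= top:
        return "activator", comp
    if comp["P"] + comp["G"] >= cfg.pg_min and comp["Q"] < cfg.q_min:
        return "repressor", comp
    return "unclassified", comp


def assign_architecture(has_dbd: bool, has_md: bool, pb1_present: bool) -> tuple[str, str]:
    """Map domain presence to an architecture class and functional role."""
    if has_dbd and has_md and pb1_present:
        return "full_arf", "canonical auxin-responsive transcription factor"
    if has_dbd and has_md:
        return "no_pb1", "auxin-independent action (ARF17/18-like, no Aux/IAA contact)"
    if has_dbd:
        return "dbd_only", "AuxRE masking (competes for TGTCNN sites)"
    if pb1_present and not has_md:
        return "pb1_only", "modulates ARF-Aux/IAA polymerisation dynamics"
    return "no_dbd", "no DNA contact; protein-protein interactions only"


def _query_md_span(anchor: AlignmentAnchor, ref_md: tuple[int, int],
                   min_cols: int) -> tuple[int, int] | None:
    """Query extent (0-based half-open) aligned inside the reference MD block."""
    lo, hi = ref_md
    qpos = [q for r, q in anchor.pairs
            if r is not None and q is not None and lo <= r <= hi]
    if len(qpos) < min_cols:
        return None
    return min(qpos) - 1, max(qpos)


def classify_arf(p: OrfProtein, arf_ref: ArfReference, pb1_ref: Pb1Reference,
                 cfg: PipelineConfig | None = None) -> ArfReport:
    """Full ARF domain-grammar report for one translated ORF."""
    cfg = cfg or PipelineConfig()
    anchor = global_align(arf_ref.seq, p.aa_seq, matrix=cfg.matrix,
                          gap_open=cfg.gap_open, gap_extend=cfg.gap_extend,
                          ref_id=arf_ref.ref_id, query_id=p.transcript_id)
    dbd_identity = _span_identity(anchor, arf_ref.seq, p.aa_seq, arf_ref.dbd_span)
    has_dbd = dbd_identity >= cfg.dbd_min_identity
    dd_coverage = _span_coverage(anchor, arf_ref.dd_span)
    has_dd = has_dbd and dd_coverage >= cfg.dd_min_coverage
    dbd_motif = scan_dbd_motif(p.aa_seq, cfg.dbd_max_mismatch) if has_dbd else None

    md_span = _query_md_span(anchor, arf_ref.md_span, cfg.md_min_len)
    md_call, md_comp = classify_md(p.aa_seq, md_span, cfg)
    if md_call == "none":
        md_span = None

    pb1 = type_pb1(p.aa_seq, pb1_ref, cfg)
    architecture, role = assign_architecture(has_dbd, md_span is not None, pb1.present)
    return ArfReport(protein_id=p.transcript_id, has_dbd=has_dbd,
                     dbd_identity=dbd_identity, dbd_motif=dbd_motif,
                     has_dd=has_dd, dd_coverage=dd_coverage,
                     md_span=md_span, md_composition=md_comp, md_call=md_call,
                     pb1=pb1, architecture=architecture, role_note=role)
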