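"""Seeded synthetic-data generator with recorded ground truth.

Produces every input the pipeline consumes — a transcriptome with
planted receptor/ARF ORFs among decoys, mature miRNAs, precursor
transcripts with stem- or loop-planted miRNAs, degradome tag tables,
expression matrices with controlled Spearman correlation, and qPCR Ct
tables with planted fold changes — together with a ``GroundTruth``
record of what was planted where.  Identical (config, seed) regenerates
byte-identical files.

Design notes for the hairpin constructs: stems are random G/C arms
(the 3' arm the reverse complement of the 5' arm); loops and flanks are
poly-A.  With no U/T anywhere, A cannot pair at all, and since every
admissible pair consumes exactly one G and one C and the arms hold
equal numbers of each, every maximum-pairing structure must pair all
arm bases — and the unique nested perfect matching between the two arm
blocks is the designed rainbow stem (an intra-arm pair would need a
fully base-paired interior, which the minimum-loop rule forbids).
Stem/loop membership of planted miRNAs is therefore guaranteed by
construction, not by re-running the folder: arm-planted miRNAs are
fully paired; loop-planted miRNAs carry at most 5 C residues (the rest
A), capping their pairable fraction at 5/21, far below the in-stem
threshold.  The restricted alphabets trade base-composition realism for
provable structural ground truth.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .config import PipelineConfig
from .references import load_references
from .sequence_core import Transcript, reverse_complement, write_fasta

AA20 = "ACDEFGHIKLMNPQRSTVWY"

# fixed codon per amino acid: keeps back-translation deterministic
BACK_CODON = {
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT",
    "G": "GGT", "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTT",
    "M": "ATG", "N": "AAT", "P": "CCT", "Q": "CAA", "R": "CGT",
    "S": "TCT", "T": "ACT", "V": "GTT", "W": "TGG", "Y": "TAT",
}
_NON_STOP_CODONS = sorted(set(BACK_CODON.values()))
_COMP = {"A": "T", "T": "A", "C": "G", "G": "C"}

SEED_LO, SEED_HI = 2, 13        # doubled-cost miRNA positions (kept in sync
GAP = 2.0                       # with the scoring module by a unit test)


@dataclass
class SynthConfig:
    """Counts and noise levels defining the emulated study conditions."""

    # transcriptome
    n_decoys: int = 30
    decoy_aa_range: tuple[int, int] = (120, 300)
    n_tir_receptor: int = 3         # intact receptors (LlTIR1a/b, LlAFB2-like)
    n_tir_ac_variant: int = 1       # AC first-position Asn->Asp (LlAFB3-like)
    n_tir_truncated: int = 1        # C-terminal loss, LRR ring does not close
    n_arf_full: int = 2             # DBD+MD+PB1 (ARF6-like)
    n_arf_no_pb1: int = 2           # DBD+MD, H->G motif variant (ARF17/18-like)
    n_arf_pb1_only: int = 2         # PB1 only (ARF8-like)
    n_arf_dbd_only: int = 1
    n_arf_no_dbd: int = 1           # MD+PB1
    protein_mut_rate: float = 0.02  # background substitutions outside anchors
    truncate_frac: float = 0.60     # fraction of the receptor kept when truncating
    utr5_len: int = 30
    utr3_len: int = 80

    # precursors
    n_stem_precursors: int = 50
    n_loop_decoys: int = 50
    arm_len: int = 30
    loop_pad: int = 5
    hairpin_flank: int = 60
    mirna_len: int = 21

    # target sites / degradome
    hot_penalties: tuple[float, ...] = (0.0, 0.5, 1.0, 1.5, 2.0, 2.5, 3.0,
                                        3.5, 4.0, 4.5, 1.0, 2.0)
    cold_penalties: tuple[float, ...] = (6.0, 6.5, 7.0, 5.0, 5.5, 6.0, 7.0, 8.0)
    signal_reads: int = 50
    n_noise_positions: int = 5
    noise_max: int = 3

    # expression
    n_samples: int = 8
    pass_rhos: tuple[float, ...] = (0.55, 0.6, 0.7, 0.75, 0.8, 0.85, 0.9, 0.95, 1.0)
    fail_rhos: tuple[float, ...] = (0.5, 0.4, 0.3, 0.2, 0.0, -0.3)
    n_decoy_pairs: int = 20

    # qPCR
    qpcr_folds: tuple[float, ...] = (0.5, 1.0, 2.0, 4.0)
    ct_noise_sd: float = 0.1
    n_bio: int = 3
    n_tech: int = 3
    ref_ct: float = 18.0
    base_dct: float = 4.0


@dataclass
class GroundTruth:
    """Everything planted, keyed the way the pipeline reports it."""

    master_seed: int
    proteins: dict = field(default_factory=dict)     # transcript_id -> class record
    precursors: dict = field(default_factory=dict)   # transcript_id -> placement record
    target_sites: list = field(default_factory=list)
    degradome: dict = field(default_factory=dict)    # "mirna|transcript" -> expected category
    correlations: list = field(default_factory=list)
    qpcr: dict = field(default_factory=dict)         # gene -> planted fold

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, sort_keys=True))


def back_translate(aa_seq: str) -> str:
    return "".join(BACK_CODON[a] for a in aa_seq)


def _random_seq(rng: np.random.Generator, alphabet: str, n: int) -> str:
    return "".join(alphabet[i] for i in rng.integers(0, len(alphabet), size=n))


def _wrap_orf(rng: np.random.Generator, aa_seq: str, utr5: int, utr3: int) -> str:
    """UTRs + ATG + CDS + stop; the protein's own M supplies the start."""
    if not aa_seq.startswith("M"):
        aa_seq = "M" + aa_seq
    cds = back_translate(aa_seq) + "TAA"
    return _random_seq(rng, "ACGT", utr5) + cds + _random_seq(rng, "ACGT", utr3)


def _mutate_protein(rng: np.random.Generator, aa_seq: str, rate: float,
                    protected: set[int]) -> str:
    """Background substitutions at ``rate``, skipping protected 1-based sites."""
    out = list(aa_seq)
    for i in range(len(out)):
        if (i + 1) in protected or out[i] == "M" and i == 0:
            continue
        if rng.random() < rate:
            choices = [a for a in AA20 if a != out[i]]
            out[i] = choices[rng.integers(0, len(choices))]
    return "".join(out)


# ---------------------------------------------------------------------------
# transcriptome with planted protein architectures
# ---------------------------------------------------------------------------

def gen_transcriptome(cfg: SynthConfig, seed: int,
                      ) -> tuple[list[Transcript], dict]:
    rng = np.random.default_rng(np.random.SeedSequence([seed, 1]))
    tir1, arf, pb1 = load_references()
    truth: dict[str, dict] = {}
    transcripts: list[Transcript] = []

    tir_protected = {p for p, _ in (tir1.pocket_orientation + tir1.pocket_selectivity
                                    + tir1.ac_positions)}
    tir_protected |= set(range(tir1.fbox_span[0], tir1.fbox_span[1] + 1))
    b3 = arf.b3_motif_start
    arf_protected = {b3, b3 + 5, b3 + 6, b3 + 9, b3 + 12}
    k_abs = arf.pb1_span[0] - 1 + 20                      # canonical K, ARF coords
    arf_protected |= {k_abs} | set(range(arf.pb1_span[0] - 1 + 50,
                                         arf.pb1_span[0] - 1 + 55))

    def add(name: str, aa: str, annotation: str, record: dict) -> None:
        seq = _wrap_orf(rng, aa, cfg.utr5_len, cfg.utr3_len)
        transcripts.append(Transcript(id=name, seq=seq, annotation=annotation))
        truth[name] = record

    for i in range(cfg.n_tir_receptor):
        aa = _mutate_protein(rng, tir1.seq, cfg.protein_mut_rate, tir_protected)
        add(f"TIR_RCPT_{i}", aa, "TIR1",
            {"class": "tir_receptor", "verdict": "receptor", "edits": []})
    for i in range(cfg.n_tir_ac_variant):
        aa = list(_mutate_protein(rng, tir1.seq, cfg.protein_mut_rate, tir_protected))
        pos, _asn = tir1.ac_positions[0]
        aa[pos - 1] = "D"                                  # Asn -> Asp at AC position 1
        add(f"TIR_ACVAR_{i}", "".join(aa), "AFB",
            {"class": "tir_ac_variant", "verdict": "receptor",
             "edits": [["ac", pos, "N", "D"]]})
    for i in range(cfg.n_tir_truncated):
        keep = int(len(tir1.seq) * cfg.truncate_frac)
        aa = _mutate_protein(rng, tir1.seq[:keep], cfg.protein_mut_rate, tir_protected)
        add(f"TIR_TRUNC_{i}", aa, "AFB",
            {"class": "tir_truncated", "verdict": "incomplete", "edits": ["truncated"]})

    dbd_end, md_lo, md_hi, pb1_lo = arf.dbd_span[1], arf.md_span[0], arf.md_span[1], arf.pb1_span[0]
    pieces = {
        "arf_full": (arf.seq, "full_arf", cfg.n_arf_full, []),
        "arf_no_pb1": (arf.seq[:md_hi], "no_pb1", cfg.n_arf_no_pb1, ["H2G"]),
        "arf_pb1_only": (arf.seq[pb1_lo - 1:], "pb1_only", cfg.n_arf_pb1_only, []),
        "arf_dbd_only": (arf.seq[:dbd_end], "dbd_only", cfg.n_arf_dbd_only, []),
        "arf_no_dbd": (arf.seq[md_lo - 1:], "no_dbd", cfg.n_arf_no_dbd, []),
    }
    for cls, (base, arch, count, edits) in pieces.items():
        offset = 0 if not cls.endswith(("pb1_only", "no_dbd")) else (
            pb1_lo - 1 if cls == "arf_pb1_only" else md_lo - 1)
        protected = {p - offset for p in arf_protected if 0 < p - offset <= len(base)}
        for i in range(count):
            aa = _mutate_protein(rng, base, cfg.protein_mut_rate, protected)
            if "H2G" in edits:      # ARF17/18-like AuxRE-motif variant
                aa = list(aa)
                aa[b3 + 5 - 1 - offset] = "G"
                aa = "".join(aa)
            add(f"{cls.upper()}_{i}", aa, "ARF",
                {"class": cls, "architecture": arch, "edits": list(edits)})

    for i in range(cfg.n_decoys):
        n_aa = int(rng.integers(cfg.decoy_aa_range[0], cfg.decoy_aa_range[1]))
        aa = "M" + _random_seq(rng, AA20, n_aa - 1)
        add(f"DECOY_{i}", aa, "unknown", {"class": "decoy"})

    return transcripts, truth


# ---------------------------------------------------------------------------
# precursor hairpins
# ---------------------------------------------------------------------------

def _hairpin(rng: np.random.Generator, cfg: SynthConfig, placement: str,
             ) -> tuple[str, str, tuple[int, int], str]:
    """One designed hairpin transcript.

    Returns (transcript_seq, mirna_seq, mirna_span, arm_label).  The 5'
    arm is random {G,C}, the 3' arm its reverse complement, loop filler
    and flanks are poly-A (inert under WC+wobble pairing: no U/T in the
    transcript).
    """
    arm5 = _random_seq(rng, "GC", cfg.arm_len)
    arm3 = reverse_complement(arm5)
    flank = "A" * cfg.hairpin_flank
    m = cfg.mirna_len

    if placement in ("5p", "3p"):
        loop = "A" * (cfg.loop_pad + 4)
        arm = arm5 if placement == "5p" else arm3
        lo = int(rng.integers(0, cfg.arm_len - m + 1))
        mirna = arm[lo:lo + m]
        arm_off = len(flank) if placement == "5p" else len(flank) + len(arm5) + len(loop)
        span = (arm_off + lo, arm_off + lo + m)
    elif placement == "loop":
        # at most 5 C's: caps the pairable fraction at 5/21 < threshold
        mirna_arr = np.full(m, "A")
        c_pos = rng.choice(m, size=5, replace=False)
        mirna_arr[c_pos] = "C"
        mirna = "".join(mirna_arr)
        loop = "A" * cfg.loop_pad + mirna + "A" * cfg.loop_pad
        lo = len(flank) + len(arm5) + cfg.loop_pad
        span = (lo, lo + m)
    elif placement == "junction":
        # half in the 5' arm, half in the loop: paired fraction ~ 0.5
        loop = "A" * (m // 2 + cfg.loop_pad + 4)
        lo = len(flank) + cfg.arm_len - (m - m // 2)
        seq_tmp = flank + arm5 + loop + arm3 + flank
        mirna = seq_tmp[lo:lo + m]
        span = (lo, lo + m)
    else:
        raise ValueError(f"unknown placement {placement!r}")
    seq = flank + arm5 + loop + arm3 + flank
    assert seq[span[0]:span[1]] == mirna
    return seq, mirna, span, placement


def gen_precursors(cfg: SynthConfig, seed: int,
                   ) -> tuple[list[Transcript], dict[str, str], dict]:
    """Stem-planted precursors and loop-planted decoys.

    Returns (transcripts, mirna sequences by id, truth records).
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 2]))
    transcripts: list[Transcript] = []
    mirnas: dict[str, str] = {}
    truth: dict[str, dict] = {}
    plan = ([("5p" if i % 2 == 0 else "3p") for i in range(cfg.n_stem_precursors)]
            + ["loop"] * cfg.n_loop_decoys)
    for i, placement in enumerate(plan):
        seq, mirna, span, arm = _hairpin(rng, cfg, placement)
        tid = f"PREC_{placement.upper()}_{i}"
        mid = f"syn-miR-{i}"
        transcripts.append(Transcript(id=tid, seq=seq, annotation="precursor-candidate"))
        mirnas[mid] = mirna
        truth[tid] = {"mirna_id": mid, "span": list(span), "placement": placement,
                      "in_stem": placement in ("5p", "3p"), "arm": arm}
    return transcripts, mirnas, truth


# ---------------------------------------------------------------------------
# target sites and degradome evidence
# ---------------------------------------------------------------------------

def _weight(pos: int) -> float:
    return 2.0 if SEED_LO <= pos <= SEED_HI else 1.0


def _site_for_penalty(rng: np.random.Generator, mirna: str, penalty: float,
                      ) -> tuple[str, float]:
    """A target window whose gapless duplex penalty equals ``penalty``.

    Edits are placed in the non-critical tail (positions 14..len) plus
    position 1, so single substitutions cost 1.0 (mismatch) or 0.5
    (G:U); the achieved penalty is returned for the record.
    """
    mirna = mirna.upper().replace("U", "T")
    n = len(mirna)
    paired = [_COMP[b] for b in mirna]          # target 3'->5' == miRNA order
    tail = [p for p in range(SEED_HI + 1, n + 1)] + [1]
    seed_pos = [p for p in range(SEED_LO, SEED_HI + 1)]
    remaining = penalty
    used: set[int] = set()
    # 0.5 fraction first: one tail G:U (miRNA G or T position)
    if remaining % 1.0 == 0.5:
        gu_ok = [p for p in tail if mirna[p - 1] in "GT"]
        if gu_ok:
            p = gu_ok[0]
            paired[p - 1] = "T" if mirna[p - 1] == "G" else "G"
            used.add(p)
            remaining -= 0.5
        else:       # no wobble-capable tail base: round up with a mismatch
            remaining += 0.5
    for p in tail:
        if remaining < 1.0:
            break
        if p in used:
            continue
        options = [b for b in "ACGT"
                   if b != _COMP[mirna[p - 1]] and (mirna[p - 1], b) not in
                   (("G", "T"), ("T", "G"))]
        paired[p - 1] = options[rng.integers(0, len(options))]
        used.add(p)
        remaining -= 1.0
    for p in seed_pos:          # large penalties spill into the doubled region
        if remaining < 2.0:
            break
        options = [b for b in "ACGT"
                   if b != _COMP[mirna[p - 1]] and (mirna[p - 1], b) not in
                   (("G", "T"), ("T", "G"))]
        paired[p - 1] = options[rng.integers(0, len(options))]
        remaining -= 2.0
    achieved = penalty - remaining
    window = "".join(reversed(paired))          # transcript 5'->3'
    return window, achieved


def gen_target_sites(cfg: SynthConfig, seed: int,
                     transcripts: list[Transcript], protein_truth: dict,
                     ) -> tuple[dict[str, str], list[dict]]:
    """Plant miRNA target sites; module edges on classified transcripts,
    a penalty ladder on dedicated decoy targets.

    Mutates the passed transcript list in place (site insertion into the
    3' UTR) and appends ladder decoy transcripts.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 3]))
    mirnas = {
        "syn-miR393": _random_seq(rng, "ACGT", cfg.mirna_len),
        "syn-miR167": _random_seq(rng, "ACGT", cfg.mirna_len),
        "syn-miR160": _random_seq(rng, "ACGT", cfg.mirna_len),
    }
    family_targets = {
        "syn-miR393": ("tir_receptor", "tir_ac_variant"),
        "syn-miR167": ("arf_full", "arf_pb1_only"),
        "syn-miR160": ("arf_no_pb1",),
    }
    sites: list[dict] = []
    by_id = {t.id: t for t in transcripts}
    for mid, classes in family_targets.items():
        for tid, rec in protein_truth.items():
            if rec["class"] not in classes:
                continue
            t = by_id[tid]
            window = "".join(reversed([_COMP[b] for b in mirnas[mid]]))
            start = len(t.seq) - cfg.utr3_len + 10
            t.seq = t.seq[:start] + window + t.seq[start + len(window):]
            sites.append({"mirna_id": mid, "transcript_id": tid,
                          "start": start, "end": start + len(window),
                          "penalty": 0.0, "cleavage_pos": start + len(window) - 9,
                          "confirmed": True, "module_edge": True})

    threshold = PipelineConfig().max_penalty
    ladder = list(cfg.hot_penalties) + list(cfg.cold_penalties)
    for i, pen in enumerate(ladder):
        mid = f"syn-miR-ladder{i}"
        mirnas[mid] = _random_seq(rng, "ACGT", cfg.mirna_len)
        window, achieved = _site_for_penalty(rng, mirnas[mid], pen)
        hot = achieved <= threshold
        flank5 = _random_seq(rng, "ACGT", 150)
        flank3 = _random_seq(rng, "ACGT", 150)
        tid = f"TARGETLADDER_{i}"
        seq = flank5 + window + flank3
        transcripts.append(Transcript(id=tid, seq=seq, annotation="unknown"))
        start = len(flank5)
        sites.append({"mirna_id": mid, "transcript_id": tid,
                      "start": start, "end": start + len(window),
                      "penalty": achieved, "cleavage_pos": start + len(window) - 9,
                      "confirmed": hot, "module_edge": False})
    return mirnas, sites


def expected_category(counts: dict[int, int], pos: int) -> int | None:
    """Literal transcription of the degradome category ladder."""
    r = counts.get(pos, 0)
    if r == 0:
        return None
    if r == 1:
        return 4
    values = sorted(counts.values())
    vmax = values[-1]
    if r == vmax:
        return 0 if values.count(vmax) == 1 else 1
    mid = len(values) // 2
    median = (values[mid] if len(values) % 2 == 1
              else (values[mid - 1] + values[mid]) / 2)
    return 2 if r > median else 3


def gen_degradome(cfg: SynthConfig, seed: int, sites: list[dict],
                  transcripts: list[Transcript],
                  ) -> tuple[dict[str, dict[int, int]], dict[str, int | None]]:
    """Tag profiles: signal at confirmed cleavage sites, uniform noise."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 4]))
    lengths = {t.id: len(t.seq) for t in transcripts}
    profiles: dict[str, dict[int, int]] = {}
    for site in sites:
        if not site["confirmed"]:
            continue
        tid = site["transcript_id"]
        prof = profiles.setdefault(tid, {})
        prof[site["cleavage_pos"]] = prof.get(site["cleavage_pos"], 0) + cfg.signal_reads
    for tid, prof in sorted(profiles.items()):
        n = lengths[tid]
        for _ in range(cfg.n_noise_positions):
            pos = int(rng.integers(1, n + 1))
            if pos in prof:
                continue
            prof[pos] = int(rng.integers(1, cfg.noise_max + 1))
    expected: dict[str, int | None] = {}
    for site in sites:
        if not site["confirmed"]:
            continue
        key = f"{site['mirna_id']}|{site['transcript_id']}"
        expected[key] = expected_category(profiles[site["transcript_id"]],
                                          site["cleavage_pos"])
    return profiles, expected


# ---------------------------------------------------------------------------
# expression matrices and qPCR tables
# ---------------------------------------------------------------------------

_PERM_CACHE: dict[int, tuple[np.ndarray, np.ndarray]] = {}


def _rank_permutations(n: int) -> tuple[np.ndarray, np.ndarray]:
    """All rank permutations of size n and their exact Spearman rho."""
    if n not in _PERM_CACHE:
        perms = np.array(list(itertools.permutations(range(n))), dtype=float)
        d2 = ((perms - np.arange(n)) ** 2).sum(axis=1)
        rho = 1.0 - 6.0 * d2 / (n * (n * n - 1))
        _PERM_CACHE[n] = (perms.astype(int), rho)
    return _PERM_CACHE[n]


def nearest_rho_permutation(target: float, n: int) -> tuple[np.ndarray, float]:
    """Rank permutation whose exact Spearman rho is closest to ``target``."""
    perms, rhos = _rank_permutations(n)
    idx = int(np.argmin(np.abs(rhos - target)))
    return perms[idx], float(rhos[idx])


def gen_expression(cfg: SynthConfig, seed: int, precursor_truth: dict,
                   ) -> tuple[dict[str, list[float]], dict[str, list[float]], list[dict]]:
    """Paired miRNA RPM / precursor FPKM vectors with controlled rho.

    Stem-planted precursor pairs receive target rhos from
    ``cfg.pass_rhos`` and ``cfg.fail_rhos`` round-robin; decoy pairs are
    independent draws.  The achieved (exactly realised) rho is recorded
    for every constructed pair.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 5]))
    n = cfg.n_samples
    mirna_expr: dict[str, list[float]] = {}
    transcript_expr: dict[str, list[float]] = {}
    records: list[dict] = []

    targets = list(cfg.pass_rhos) + list(cfg.fail_rhos)
    stem_items = [(tid, rec) for tid, rec in sorted(precursor_truth.items())
                  if rec["in_stem"]]
    for i, (tid, rec) in enumerate(stem_items):
        target = targets[i % len(targets)]
        perm, achieved = nearest_rho_permutation(target, n)
        base = np.sort(rng.uniform(1.0, 100.0, size=n))
        other = np.sort(rng.uniform(1.0, 100.0, size=n))
        x = base                                  # miRNA vector, ranks 0..n-1
        y = other[np.argsort(perm)]               # y's ranks follow perm
        mirna_expr[rec["mirna_id"]] = [round(float(v), 4) for v in x]
        transcript_expr[tid] = [round(float(v), 4) for v in y]
        records.append({"mirna_id": rec["mirna_id"], "transcript_id": tid,
                        "target_rho": target, "achieved_rho": achieved,
                        "expected_pass": achieved > 0.5, "kind": "constructed"})

    loop_items = [(tid, rec) for tid, rec in sorted(precursor_truth.items())
                  if not rec["in_stem"]][:cfg.n_decoy_pairs]
    for tid, rec in loop_items:
        x = rng.uniform(1.0, 100.0, size=n)
        y = rng.uniform(1.0, 100.0, size=n)
        mirna_expr[rec["mirna_id"]] = [round(float(v), 4) for v in x]
        transcript_expr[tid] = [round(float(v), 4) for v in y]
        records.append({"mirna_id": rec["mirna_id"], "transcript_id": tid,
                        "target_rho": None, "achieved_rho": None,
                        "expected_pass": None, "kind": "decoy"})
    return mirna_expr, transcript_expr, records


def gen_qpcr(cfg: SynthConfig, seed: int) -> tuple[list[dict], dict[str, float]]:
    """Ct table with planted fold changes (treated vs control calibrator)."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 6]))
    rows: list[dict] = []
    folds: dict[str, float] = {}
    genes = [(f"GENE_F{str(f).replace('.', '_')}", f) for f in cfg.qpcr_folds]
    for group in ("control", "treated"):
        for bio in range(1, cfg.n_bio + 1):
            for tech in range(1, cfg.n_tech + 1):
                ref = cfg.ref_ct + rng.normal(0.0, cfg.ct_noise_sd)
                rows.append({"gene": "LlActin", "group": group, "bio_rep": bio,
                             "tech_rep": tech, "ct": round(ref, 4)})
            for gene, fold in genes:
                folds[gene] = fold
                shift = -np.log2(fold) if group == "treated" else 0.0
                for tech in range(1, cfg.n_tech + 1):
                    ct = (cfg.ref_ct + cfg.base_dct + shift
                          + rng.normal(0.0, cfg.ct_noise_sd))
                    rows.append({"gene": gene, "group": group, "bio_rep": bio,
                                 "tech_rep": tech, "ct": round(ct, 4)})
    return rows, folds


# ---------------------------------------------------------------------------
# full bundle
# ---------------------------------------------------------------------------

def gen_bundle(cfg: SynthConfig, seed: int, outdir: str | Path) -> GroundTruth:
    """Write every pipeline input plus ground_truth.json to ``outdir``."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)

    transcripts, protein_truth = gen_transcriptome(cfg, seed)
    prec_transcripts, prec_mirnas, prec_truth = gen_precursors(cfg, seed)
    target_mirnas, sites = gen_target_sites(cfg, seed, transcripts, protein_truth)
    all_transcripts = transcripts + prec_transcripts
    profiles, expected_cat = gen_degradome(cfg, seed, sites, all_transcripts)
    mirna_expr, transcript_expr, corr_records = gen_expression(cfg, seed, prec_truth)
    qpcr_rows, folds = gen_qpcr(cfg, seed)

    write_fasta([(f"{t.id} {t.annotation}", t.seq) for t in all_transcripts],
                out / "transcripts.fasta")
    all_mirnas = {**prec_mirnas, **target_mirnas}
    write_fasta(sorted(all_mirnas.items()), out / "mirnas.fasta")

    with open(out / "degradome.tsv", "w") as fh:
        fh.write("transcript_id\tposition\tcount\n")
        for tid in sorted(profiles):
            for pos in sorted(profiles[tid]):
                fh.write(f"{tid}\t{pos}\t{profiles[tid][pos]}\n")

    samples = [f"S{i + 1}" for i in range(cfg.n_samples)]
    for fname, table in (("mirna_rpm.tsv", mirna_expr),
                         ("transcript_fpkm.tsv", transcript_expr)):
        with open(out / fname, "w") as fh:
            fh.write("feature_id\t" + "\t".join(samples) + "\n")
            for fid in sorted(table):
                fh.write(fid + "\t" + "\t".join(f"{v:.4f}" for v in table[fid]) + "\n")

    with open(out / "qpcr.tsv", "w") as fh:
        fh.write("gene\tgroup\tbio_rep\ttech_rep\tct\n")
        for row in qpcr_rows:
            fh.write(f"{row['gene']}\t{row['group']}\t{row['bio_rep']}\t"
                     f"{row['tech_rep']}\t{row['ct']}\n")

    truth = GroundTruth(master_seed=seed, proteins=protein_truth,
                        precursors=prec_truth, target_sites=sites,
                        degradome=expected_cat, correlations=corr_records,
                        qpcr=folds)
    truth.to_json(out / "ground_truth.json")
    return truth
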