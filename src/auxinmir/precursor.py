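"""miRNA precursor identification.

A transcript is a precursor candidate when (i) it contains the mature
miRNA, (ii) the locus folds into a stem-loop with the miRNA inside the
stem (its pair partners all on the opposite arm of one hairpin), and
(iii) the precursor/miRNA expression profiles co-vary (Spearman rho
strictly above the threshold).

Folding is maximum base pairing (Nussinov dynamic programming) over
Watson-Crick plus G:U wobble pairs with a minimum hairpin loop, rather
than thermodynamic energy minimisation: it is self-contained, exactly
checkable against exhaustive enumeration, and the stem/loop membership
question it answers is robust to the scoring model for designed stems.
An external folder can be substituted via the ``structure`` argument of
:func:`assess_stem_membership`; outputs record which engine produced the
structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .config import PipelineConfig
from .sequence_core import Transcript

# stored DNA-style; G:T below is the G:U wobble
_CANONICAL = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C"), ("G", "T"), ("T", "G")}


def can_pair(x: str, y: str) -> bool:
    return (x, y) in _CANONICAL


@dataclass
class FoldResult:
    seq: str
    structure: str                      # dot-bracket
    pairs: set[tuple[int, int]]         # 0-based, i < j
    engine: str = "nussinov-max-pairing"

    @property
    def energy_proxy(self) -> int:
        return len(self.pairs)

    def partner_map(self) -> dict[int, int]:
        out: dict[int, int] = {}
        for i, j in self.pairs:
            out[i] = j
            out[j] = i
        return out


@dataclass
class PrecursorCandidate:
    transcript_id: str
    mirna_id: str
    mirna_start: int                    # 0-based half-open on the transcript
    mirna_end: int
    window_start: int                   # folded window, transcript coords
    window_end: int
    fold: FoldResult
    in_stem: bool
    paired_fraction: float
    arm: str                            # 5p | 3p | spanning | unpaired
    star_span: tuple[int, int] | None   # transcript coords, 0-based half-open


@dataclass
class CorrelationRecord:
    mirna_id: str
    transcript_id: str
    rho: float                          # nan when undefined
    n_samples: int
    passes: bool
    flagged: str = ""


# ---------------------------------------------------------------------------
# mature miRNA search
# ---------------------------------------------------------------------------

def locate_mature(t: Transcript, mirna: str, max_mismatch: int = 0) -> list[tuple[int, int]]:
    """All occurrences of the mature miRNA on the transcript (+ strand).

    U/T equivalent; exact by default, Hamming distance <= ``max_mismatch``
    otherwise.  An empty result means the transcript is discarded as a
    precursor candidate upstream.
    """
    query = mirna.upper().replace("U", "T")
    n, m = len(t.seq), len(query)
    spans = []
    for start in range(n - m + 1):
        window = t.seq[start:start + m]
        if max_mismatch == 0:
            if window == query:
                spans.append((start, start + m))
        else:
            mism = sum(1 for a, b in zip(window, query) if a != b)
            if mism <= max_mismatch:
                spans.append((start, start + m))
    return spans


# ---------------------------------------------------------------------------
# folding
# ---------------------------------------------------------------------------

def fold_window(seq: str, min_loop: int = 3, max_window: int = 400,
                ) -> FoldResult:
    """Maximum-cardinality nested pairing with hairpin loops >= ``min_loop``.

    Deterministic traceback: at each interval prefer leaving the left
    base unpaired when that already achieves the optimum, otherwise pair
    it with the smallest admissible partner.
    """
    s = seq.upper().replace("U", "T")
    n = len(s)
    if n > max_window:
        raise ValueError(f"window of {n} nt exceeds max_window={max_window}; "
                         "raise max_window to fold longer loci")
    if min_loop < 3:
        raise ValueError("min_loop must be >= 3")
    # pairability matrix for the inner maximisation (vectorised over k)
    code = np.frombuffer(s.encode(), dtype=np.uint8)
    pairable = np.zeros((n, n), dtype=bool)
    for x, y in _CANONICAL:
        pairable |= (code[:, None] == ord(x)) & (code[None, :] == ord(y))

    dp = np.zeros((n + 1, n + 1), dtype=np.int32)  # dp[i][j], j exclusive
    # interval length increasing
    for span in range(min_loop + 2, n + 1):
        for i in range(0, n - span + 1):
            j = i + span
            best = dp[i + 1, j]
            ks = np.nonzero(pairable[i, i + min_loop + 1:j])[0] + i + min_loop + 1
            if ks.size:
                cand = 1 + dp[i + 1, ks] + dp[ks + 1, j]
                best = max(best, int(cand.max()))
            dp[i, j] = best

    pairs: set[tuple[int, int]] = set()
    stack = [(0, n)]
    while stack:
        i, j = stack.pop()
        if j - i < min_loop + 2:
            continue
        if dp[i, j] == dp[i + 1, j]:
            stack.append((i + 1, j))
            continue
        for k in range(i + min_loop + 1, j):
            if can_pair(s[i], s[k]) and dp[i, j] == 1 + dp[i + 1, k] + dp[k + 1, j]:
                pairs.add((i, k))
                stack.append((i + 1, k))
                stack.append((k + 1, j))
                break
    structure = ["."] * n
    for i, j in pairs:
        structure[i] = "("
        structure[j] = ")"
    return FoldResult(seq=s, structure="".join(structure), pairs=pairs)


# ---------------------------------------------------------------------------
# stem membership
# ---------------------------------------------------------------------------

def assess_stem_membership(t: Transcript, mirna_id: str,
                           span: tuple[int, int],
                           cfg: PipelineConfig | None = None,
                           structure: FoldResult | None = None,
                           ) -> PrecursorCandidate:
    """Fold the locus around the miRNA and decide stem membership.

    The window is the miRNA span plus ``cfg.flank`` nt context each side.
    ``in_stem`` requires the paired fraction of miRNA bases to reach
    ``cfg.min_paired_frac`` with every pair partner on one side of the
    miRNA (the opposite arm of a single hairpin).  ``star_span`` is the
    partner extent with the conventional 2-nt offset for the Dicer
    3'-overhang, clipped to the folded window.
    """
    cfg = cfg or PipelineConfig()
    s, e = span
    if not 0 <= s < e <= len(t.seq):
        raise ValueError(f"miRNA span {span} outside transcript {t.id!r}")
    w_start = max(0, s - cfg.flank)
    w_end = min(len(t.seq), e + cfg.flank)
    window = t.seq[w_start:w_end]
    fold = structure if structure is not None else fold_window(
        window, min_loop=cfg.min_loop, max_window=cfg.max_window)
    partner = fold.partner_map()

    local = range(s - w_start, e - w_start)      # miRNA positions in window coords
    partners = [partner[i] for i in local if i in partner]
    paired_fraction = len(partners) / (e - s)

    lo, hi = s - w_start, e - w_start - 1
    if not partners:
        arm = "unpaired"
    elif all(p > hi for p in partners):
        arm = "5p"
    elif all(p < lo for p in partners):
        arm = "3p"
    else:
        arm = "spanning"
    in_stem = paired_fraction >= cfg.min_paired_frac and arm in ("5p", "3p")

    star_span = None
    if partners:
        pmin, pmax = min(partners), max(partners)
        if arm == "5p":      # star on the 3p arm; its 3' end gains the 2-nt offset
            raw = (pmin, pmax + 3)
        elif arm == "3p":    # star on the 5p arm; 3' end is the low-coordinate side
            raw = (pmin - 2, pmax + 1)
        else:
            raw = (pmin, pmax + 1)
        star_span = (max(0, raw[0]) + w_start, min(len(window), raw[1]) + w_start)

    return PrecursorCandidate(transcript_id=t.id, mirna_id=mirna_id,
                              mirna_start=s, mirna_end=e,
                              window_start=w_start, window_end=w_end,
                              fold=fold, in_stem=in_stem,
                              paired_fraction=paired_fraction,
                              arm=arm, star_span=star_span)


# ---------------------------------------------------------------------------
# expression correlation filter
# ---------------------------------------------------------------------------

def correlate_expression(mirna_rpm, precursor_fpkm, mirna_id: str = "",
                         transcript_id: str = "",
                         rho_threshold: float = 0.5) -> CorrelationRecord:
    """Spearman correlation between miRNA and precursor expression.

    Average ranks for ties; the filter is a strict ``rho > threshold``.
    Zero variance in either vector leaves rho undefined (NaN, fails,
    flagged).
    """
    x = np.asarray(mirna_rpm, dtype=float)
    y = np.asarray(precursor_fpkm, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("expression vectors must be 1-D and paired")
    if x.size < 3:
        raise ValueError("need at least 3 paired samples")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return CorrelationRecord(mirna_id=mirna_id, transcript_id=transcript_id,
                                 rho=float("nan"), n_samples=x.size,
                                 passes=False, flagged="zero variance")
    rho = float(stats.spearmanr(x, y).statistic)
    # strict ">": a rho equal to the threshold fails.  The 1e-9 guard
    # absorbs float error in the rank correlation (the spacing between
    # achievable rho values is ~6/(n^3-n), orders of magnitude larger).
    return CorrelationRecord(mirna_id=mirna_id, transcript_id=transcript_id,
                             rho=rho, n_samples=x.size,
                             passes=bool(rho > rho_threshold + 1e-9))
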