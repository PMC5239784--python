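"""Consecutive-run alignment scoring and ungapped germline placement.

The alignment score of a match/mismatch pattern is the sum of squared
lengths of consecutively matched runs minus the sum of squared lengths of
consecutively mismatched runs:

    Score = sum_i C_i^2  -  sum_j M_j^2

A mismatch-leniency rule lets isolated point mutations (mismatch runs of
length exactly 1) be "forgiven": the forgiven position contributes zero
length but fuses its two flanking match runs into one squared term.
Runs of two or more consecutive mismatches are never forgiven.  Because
somatic hypermutation hits the 5' end of short amplicons more often,
forgiveness is spent greedily from the 5' end.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

_ENCODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _ENCODE[_b] = _i

NO_ALIGNMENT_SCORE = -math.inf


def encode(seq: str) -> np.ndarray:
    """Encode a nucleotide string as uint8 (A,C,G,T -> 0..3, N/other -> 4)."""
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@dataclass(frozen=True)
class LeniencyPolicy:
    """Budget of forgivable isolated mismatches.

    Either a fixed count, or a fraction of the aligned overlap length
    (rounded up) — the V segment uses fraction 0.15, while D and J reuse
    the mutation fraction observed on the V segment of the same read.
    """

    fixed: Optional[int] = None
    fraction: Optional[float] = None

    def budget(self, overlap_len: int) -> int:
        if self.fixed is not None:
            return self.fixed
        if self.fraction is not None:
            return math.ceil(self.fraction * overlap_len)
        return 0


NO_LENIENCY = LeniencyPolicy(fixed=0)


@dataclass(frozen=True)
class MatchPattern:
    """Boolean match vector over an aligned overlap (True = match).

    ``read_span`` and ``gene_span`` are 1-based inclusive intervals of the
    overlap within the read and the germline gene.
    """

    pattern: np.ndarray
    read_span: tuple[int, int]
    gene_span: tuple[int, int]

    def __post_init__(self):
        n = len(self.pattern)
        if n != self.read_span[1] - self.read_span[0] + 1:
            raise ValueError("pattern length does not match read_span")
        if n != self.gene_span[1] - self.gene_span[0] + 1:
            raise ValueError("pattern length does not match gene_span")


def score_match_pattern(pattern, max_forgiven: int = 0,
                        forgivable: Optional[Sequence[bool]] = None) -> int:
    """Score a match/mismatch pattern with 5'-greedy mismatch leniency.

    ``pattern`` is a boolean sequence (True = match).  Up to
    ``max_forgiven`` isolated mismatches are forgiven left to right; a
    forgiven position contributes 0 to the fused match run.  ``forgivable``
    optionally marks positions that may never be forgiven (ambiguous read
    characters score as hard mismatches).
    """
    pat = np.asarray(pattern, dtype=bool)
    if pat.size == 0:
        raise ValueError("empty match pattern")
    if forgivable is None:
        forgivable = np.ones(pat.size, dtype=bool)
    else:
        forgivable = np.asarray(forgivable, dtype=bool)

    n = pat.size
    change = np.flatnonzero(pat[1:] != pat[:-1]) + 1
    starts = np.concatenate(([0], change))
    lengths = np.diff(np.concatenate((starts, [n])))

    score = 0
    fused = 0          # length of the current (possibly fused) match run
    budget = max_forgiven
    for start, run in zip(starts, lengths):
        if pat[start]:
            fused += run
        elif run == 1 and budget > 0 and forgivable[start]:
            budget -= 1          # forgive: flanking runs keep fusing
        else:
            score += fused * fused
            fused = 0
            score -= run * run
    score += fused * fused
    return int(score)


@dataclass(frozen=True)
class AlignmentResult:
    """Best ungapped placement of one germline gene against a read."""

    gene_name: str
    score: float
    pattern: Optional[MatchPattern]
    n_mismatch: int
    overlap: int

    @property
    def mutation_fraction(self) -> float:
        return self.n_mismatch / self.overlap if self.overlap else 0.0

    @property
    def aligned(self) -> bool:
        return self.pattern is not None

    @classmethod
    def no_alignment(cls, gene_name: str = "") -> "AlignmentResult":
        return cls(gene_name=gene_name, score=NO_ALIGNMENT_SCORE,
                   pattern=None, n_mismatch=0, overlap=0)


def _best_extent(pat: np.ndarray, forgivable: np.ndarray, budget_fn,
                 min_overlap: int):
    """Best contiguous aligned extent of one ungapped placement.

    Terminal mismatch runs are removed, then end blocks (the outermost
    match run together with the mismatch run separating it from the rest)
    are greedily dropped from either end while that strictly increases the
    score.  Germline gene ends deleted during recombination would
    otherwise be forced into the segment as mismatch-laden flanks.
    Returns ``(score, start, end)`` in pattern coordinates, or None if no
    extent of at least ``min_overlap`` exists.
    """
    nz = np.flatnonzero(pat)
    if nz.size == 0:
        return None
    a, b = int(nz[0]), int(nz[-1]) + 1

    def sc(x: int, y: int) -> int:
        return score_match_pattern(pat[x:y], budget_fn(y - x), forgivable[x:y])

    if b - a < min_overlap:
        return None
    cur = sc(a, b)
    while True:
        sub = pat[a:b]
        change = np.flatnonzero(sub[1:] != sub[:-1]) + 1
        if change.size < 2:          # a single match run: nothing to drop
            break
        starts = np.concatenate(([0], change))
        ends = np.concatenate((change, [b - a]))
        cands = []
        la = a + int(starts[2])      # drop leading match run + mismatch run
        if b - la >= min_overlap:
            cands.append((sc(la, b), b - la, 1, la, b))
        rb = a + int(ends[-3])       # drop trailing mismatch run + match run
        if rb - a >= min_overlap:
            cands.append((sc(a, rb), rb - a, 0, a, rb))
        if not cands:
            break
        best = max(cands)
        if best[0] <= cur:
            break
        cur, a, b = best[0], best[3], best[4]
    return cur, a, b


def _match_counts(r_enc: np.ndarray, g_enc: np.ndarray) -> np.ndarray:
    """Match counts for every ungapped shift via one-hot cross-correlation.

    Entry ``j`` corresponds to shift ``s = j - (len(g) - 1)``, where the
    gene is placed so its first base aligns to window position ``s``.
    """
    out = np.zeros(len(r_enc) + len(g_enc) - 1)
    for b in range(4):
        out += np.correlate((r_enc == b).astype(float),
                            (g_enc == b).astype(float), mode="full")
    return np.rint(out).astype(int)


def best_ungapped_alignment(read: str, gene, leniency: LeniencyPolicy,
                            read_window: Optional[tuple[int, int]] = None,
                            min_overlap: int = 1,
                            score_floor: float = NO_ALIGNMENT_SCORE,
                            counts: Optional[np.ndarray] = None
                            ) -> AlignmentResult:
    """Best ungapped placement of ``gene`` within a window of ``read``.

    All offsets are evaluated (partial overhangs allowed at the window
    edges); each offset is scored on its best contiguous aligned extent
    (see :func:`_best_extent`) and the offset maximizing the run-squared
    score under ``leniency`` wins, with ties broken by longer overlap
    then smaller offset.  An overlap below ``min_overlap`` yields a
    no-alignment sentinel with score -inf.

    Exactness note: an offset with ``m`` matching positions can never score
    above ``m**2``, so offsets are visited in decreasing match count and
    pruned once the bound falls below the best exact score found (or below
    ``score_floor``, which callers scanning many genes may set to the best
    score seen so far; pruning is strict, so ties at the floor survive).
    """
    if read_window is None:
        read_window = (1, len(read))
    ws, we = read_window
    if ws < 1 or we > len(read) or ws > we:
        return AlignmentResult.no_alignment(gene.name)
    r = encode(read)[ws - 1:we]
    g = encode(gene.sequence)
    w, gl = len(r), len(g)
    if min(w, gl) < min_overlap:
        return AlignmentResult.no_alignment(gene.name)

    if counts is None:
        counts = _match_counts(r, g)
    shifts = np.arange(len(counts)) - (gl - 1)
    order = np.lexsort((shifts, -counts))

    best = None           # (score, overlap, -shift, pattern-args)
    best_score = NO_ALIGNMENT_SCORE
    for idx in order:
        s = int(shifts[idx])
        a = max(0, s)
        b = min(w, gl + s)
        olen = b - a
        if olen < min_overlap:
            continue
        m = int(counts[idx])
        bound = max(best_score, score_floor)
        if m * m < bound and bound > NO_ALIGNMENT_SCORE:
            break        # no remaining offset can beat or tie the best
        pat = r[a:b] == g[a - s:b - s]
        forgivable = r[a:b] != 4
        extent = _best_extent(pat, forgivable, leniency.budget, min_overlap)
        if extent is None:
            continue
        score, ea, eb = extent
        a, b = a + ea, a + eb
        olen = b - a
        key = (score, olen, -s)
        if best is None or key > best[0]:
            best = (key, s, a, b, pat[ea:eb])
            best_score = score
    if best is None:
        return AlignmentResult.no_alignment(gene.name)
    _, s, a, b, pat = best
    mp = MatchPattern(pattern=pat,
                      read_span=(ws + a, ws + b - 1),
                      gene_span=(a - s + 1, b - s))
    return AlignmentResult(gene_name=gene.name, score=best_score, pattern=mp,
                           n_mismatch=int((~pat).sum()), overlap=b - a)


def correct_v_indels(read: str, v_result: AlignmentResult, v_gene,
                     leniency: LeniencyPolicy, margin: float = 4.0,
                     max_edits: int = 2,
                     read_window_tail: int = 9) -> tuple[str, list[tuple[int, str]]]:
    """Repair suspected sequencing indels in the V framework.

    Only the read region aligned strictly 5' of the germline 104Cys anchor
    is edited — indels in the CDR3 can be genuine recombination events and
    are left alone.  Up to ``max_edits`` single-nucleotide edits (deleting
    a read base, or inserting the germline base) are applied, each only if
    it raises the alignment score by more than ``margin``.  Returns the
    (possibly edited) read and a log of ``(1-based position, "ins"|"del")``.
    """
    log: list[tuple[int, str]] = []
    if v_gene.anchor_pos is None or not v_result.aligned:
        return read, log
    current = v_result
    for _ in range(max_edits):
        mp = current.pattern
        if mp is None:
            break
        # read position (0-based) aligned to the base before the anchor
        anchor_read0 = (mp.read_span[0] - 1) + (v_gene.anchor_pos - mp.gene_span[0])
        lo = mp.read_span[0] - 1
        hi = min(anchor_read0, mp.read_span[1])  # exclusive
        best_gain, best_read, best_entry = 0.0, None, None
        for p in range(lo, hi):
            candidates = [(read[:p] + read[p + 1:], "del")]
            # the base lost to a sequencing deletion is recovered by trying
            # each nucleotide; the alignment score arbitrates
            candidates += [(read[:p] + nt + read[p:], "ins")
                           for nt in "ACGT"]
            for cand, kind in candidates:
                res = best_ungapped_alignment(
                    cand, v_gene, leniency,
                    read_window=(1, max(1, len(cand) - read_window_tail)),
                    min_overlap=min(10, len(cand)))
                gain = res.score - current.score
                # a true indel repair realigns a whole misaligned tail, so
                # it must reduce mismatches; merely extending the overlap
                # with germline bases does not qualify
                if gain > best_gain and res.n_mismatch < current.n_mismatch:
                    best_gain, best_read, best_entry, best_res = gain, cand, (p + 1, kind), res
        if best_read is None or best_gain <= margin:
            break
        read = best_read
        current = best_res
        log.append(best_entry)
    return read, log
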