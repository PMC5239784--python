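"""Benchmarking and SHM-analysis statistics.

Gene calls are scored either as exact allele-name matches or as
degenerate matches, where the called allele's germline sequence is at
least 98% identical to the truth allele's sequence over the best
ungapped placement of the shorter within the longer.  SHM calls in the
CDR3 are scored per position as a confusion matrix (accuracy and
positive prediction rate), substitution behaviour is summarized as a
12-entry propensity matrix of row-normalized X0 -> X1 frequencies
counted over parent-child sequence pairs (inherited mutations are not
double-counted), and V-vs-DJ consistency is measured by the Pearson
correlation and regression slope over those 12 frequencies.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from scipy import stats

NUCLEOTIDES = ("A", "C", "G", "T")


# ---------------------------------------------------------------------------
# Gene matching
# ---------------------------------------------------------------------------

def sequence_identity(a: str, b: str) -> float:
    """Best containment identity of the shorter sequence within the longer."""
    short, long_ = (a, b) if len(a) <= len(b) else (b, a)
    best = 0
    for off in range(len(long_) - len(short) + 1):
        m = sum(x == y for x, y in zip(short, long_[off:off + len(short)]))
        best = max(best, m)
    return best / len(short)


def gene_match(predicted: str, truth: str, db, mode: str = "exact",
               identity_threshold: float = 0.98) -> bool:
    """Is a predicted gene call correct, exactly or degenerately?"""
    if predicted not in db or truth not in db:
        raise KeyError(f"unknown gene name: {predicted!r} or {truth!r}")
    if mode == "exact":
        return predicted == truth
    if mode != "degenerate":
        raise ValueError(f"unknown mode {mode!r}")
    if predicted == truth:
        return True
    return sequence_identity(db[predicted].sequence,
                             db[truth].sequence) >= identity_threshold


# ---------------------------------------------------------------------------
# SHM confusion metrics
# ---------------------------------------------------------------------------

@dataclass
class ConfusionCounts:
    tp: int = 0
    tn: int = 0
    fp: int = 0
    fn: int = 0

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.tp + other.tp, self.tn + other.tn,
                               self.fp + other.fp, self.fn + other.fn)

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def shm_confusion(called_positions: Iterable[int],
                  true_positions: Iterable[int],
                  region: tuple[int, int]) -> ConfusionCounts:
    """Per-position mutation-call confusion over a 1-based inclusive region."""
    called = set(called_positions)
    true = set(true_positions)
    c = ConfusionCounts()
    for p in range(region[0], region[1] + 1):
        if p in true:
            if p in called:
                c.tp += 1
            else:
                c.fn += 1
        else:
            if p in called:
                c.fp += 1
            else:
                c.tn += 1
    return c


def accuracy_ppr(c: ConfusionCounts) -> tuple[float, float]:
    """Accuracy and positive prediction rate of mutation calls.

    ACC = (TP+TN)/(TP+TN+FP+FN); PPR = TP/(TP+FP), defined as 0 when no
    positives were called.
    """
    if c.total == 0:
        raise ValueError("empty confusion counts")
    acc = (c.tp + c.tn) / c.total
    ppr = c.tp / (c.tp + c.fp) if (c.tp + c.fp) else 0.0
    return acc, ppr


# ---------------------------------------------------------------------------
# SHM propensities
# ---------------------------------------------------------------------------

@dataclass
class PropensityMatrix:
    """Counts and row-normalized frequencies of the 12 X0 -> X1 mutations."""

    counts: pd.DataFrame      # 4x4, diagonal zero
    scope: str = "all"

    @property
    def frequencies(self) -> pd.DataFrame:
        freq = self.counts.astype(float).copy()
        for nt in NUCLEOTIDES:
            row_sum = freq.loc[nt].sum()
            if row_sum > 0:
                freq.loc[nt] /= row_sum
        return freq

    @property
    def is_empty(self) -> bool:
        return int(self.counts.values.sum()) == 0

    def vector(self) -> pd.Series:
        """The 12 off-diagonal normalized frequencies, in fixed order."""
        freq = self.frequencies
        idx, vals = [], []
        for x0 in NUCLEOTIDES:
            for x1 in NUCLEOTIDES:
                if x0 != x1:
                    idx.append(f"{x0}>{x1}")
                    vals.append(freq.loc[x0, x1])
        return pd.Series(vals, index=idx)


def _empty_counts() -> pd.DataFrame:
    return pd.DataFrame(0, index=list(NUCLEOTIDES), columns=list(NUCLEOTIDES))


def propensity_matrix(pairs: Iterable[tuple[str, str, Iterable[tuple[int, int]]]],
                      scope: str = "all") -> PropensityMatrix:
    """Count X0 -> X1 substitutions over parent-child sequence pairs.

    Each pair is ``(parent_seq, child_seq, spans)`` where ``spans`` are the
    1-based inclusive intervals to scan (V segment, D and J segments, ...)
    — N regions are excluded by simply not listing them.  The parent
    strand provides X0; a position mutated in an earlier generation counts
    again only if it re-mutates on this edge.
    """
    counts = _empty_counts()
    for parent, child, spans in pairs:
        for lo, hi in spans:
            for p in range(lo - 1, hi):
                if p < len(parent) and p < len(child) and parent[p] != child[p]:
                    if parent[p] in counts.index and child[p] in counts.columns:
                        counts.loc[parent[p], child[p]] += 1
    return PropensityMatrix(counts=counts, scope=scope)


@dataclass
class CorrelationSummary:
    r_corr: float
    slope: float


def v_dj_correlation(v: PropensityMatrix, dj: PropensityMatrix) -> CorrelationSummary:
    """Pearson r and regression slope of DJ propensities on V propensities."""
    if v.is_empty or dj.is_empty:
        raise ValueError("propensity matrix is empty")
    x = v.vector().to_numpy()
    y = dj.vector().to_numpy()
    if np.allclose(x, x[0]) or np.allclose(y, y[0]):
        raise ValueError("zero variance in propensity frequencies")
    r, _ = stats.pearsonr(x, y)
    slope = float(np.polyfit(x, y, 1)[0])
    return CorrelationSummary(r_corr=float(r), slope=slope)


# ---------------------------------------------------------------------------
# Hot-spot context profiles
# ---------------------------------------------------------------------------

def hotspot_profile(pairs: Iterable[tuple[str, str, Iterable[tuple[int, int]]]],
                    k: int = 3) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Nucleotide composition around mutated versus all positions.

    Returns two (2k+1) x 4 tables of parent-strand composition fractions:
    the first centered on mutated positions only, the second on every
    scanned position regardless of mutation — the background against
    which motif enrichment (e.g. WGC) must be judged.  Centers within k
    of a read end contribute only their defined offsets.
    """
    offsets = list(range(-k, k + 1))
    mut = pd.DataFrame(0, index=offsets, columns=list(NUCLEOTIDES))
    allpos = pd.DataFrame(0, index=offsets, columns=list(NUCLEOTIDES))
    for parent, child, spans in pairs:
        for lo, hi in spans:
            for p in range(lo - 1, hi):
                tables = [allpos]
                if parent[p] != child[p]:
                    tables.append(mut)
                for off in offsets:
                    q = p + off
                    if 0 <= q < len(parent) and parent[q] in NUCLEOTIDES:
                        for t in tables:
                            t.loc[off, parent[q]] += 1
    def norm(t):
        sums = t.sum(axis=1)
        return t.div(sums.replace(0, np.nan), axis=0)
    return norm(mut), norm(allpos)


# ---------------------------------------------------------------------------
# Usage frequencies and Vframe-vs-CDR3 mutation loads
# ---------------------------------------------------------------------------

def usage_frequencies(annotations) -> dict:
    """Family-level gene usage and VD/DJ pair frequency tables.

    Inverted D genes keep their ``r`` prefix and tally as separate
    families.  All tables are normalized to sum to 1.
    """
    from .germline import parse_family
    v, d, j, vd, dj = {}, {}, {}, {}, {}
    n = 0
    for ann in annotations:
        if ann.v_name is None or ann.j_name is None:
            continue
        n += 1
        fv = parse_family(ann.v_name)
        fj = parse_family(ann.j_name)
        fd = parse_family(ann.d_name) if ann.d_name else "none"
        v[fv] = v.get(fv, 0) + 1
        d[fd] = d.get(fd, 0) + 1
        j[fj] = j.get(fj, 0) + 1
        vd[(fv, fd)] = vd.get((fv, fd), 0) + 1
        dj[(fd, fj)] = dj.get((fd, fj), 0) + 1
    def series(c):
        s = pd.Series(c, dtype=float).sort_index()
        return s / s.sum() if s.sum() else s
    return {"V": series(v), "D": series(d), "J": series(j),
            "VD": series(vd), "DJ": series(dj), "n": n}


def vframe_vs_cdr3(clusters) -> tuple[pd.DataFrame, Optional[float]]:
    """Per-sequence (Vframe, CDR3) mutation counts against cluster germlines.

    Returns the count table and the Pearson correlation, or None (flagged)
    when either count has zero variance (e.g. an all-germline repertoire).
    """
    rows = []
    for cluster in clusters:
        ann = cluster.annotation
        if ann is None or ann.cdr3_span is None:
            continue
        cdr3_start = ann.cdr3_span.start
        for mid, mism in cluster.member_mismatches.items():
            flat = [p for v in mism.values() for p in v]
            vframe = sum(1 for p in flat if p < cdr3_start)
            cdr3 = sum(1 for p in flat if p >= cdr3_start)
            rows.append({"id": mid, "vframe_mutations": vframe,
                         "cdr3_mutations": cdr3})
    table = pd.DataFrame(rows)
    if table.empty:
        return table, None
    x = table["vframe_mutations"].to_numpy(float)
    y = table["cdr3_mutations"].to_numpy(float)
    if np.allclose(x, x[0]) or np.allclose(y, y[0]):
        return table, None
    return table, float(stats.pearsonr(x, y)[0])


def pairs_from_truth(seqs, scope: str = "all"):
    """Parent-child pairs with truth segment spans from simulator output."""
    by_id = {s.id: s for s in seqs}
    out = []
    for s in seqs:
        if s.parent_id is None:
            continue
        parent = by_id[s.parent_id]
        spans = []
        if scope in ("V", "all"):
            spans.append((1, s.v_end))
        if scope in ("DJ", "all"):
            spans.append((s.d_start, s.d_end))
            spans.append((s.j_start, len(s.sequence)))
        out.append((parent.sequence, s.sequence, spans))
    return out


def pairs_from_clusters(clusters, scope: str = "all"):
    """Parent-child pairs with unified segment spans from lineage trees."""
    out = []
    for cluster in clusters:
        ann = cluster.annotation
        if ann is None:
            continue
        spans = []
        if scope in ("V", "all") and ann.v_span is not None:
            spans.append((ann.v_span.start, ann.v_span.end))
        if scope in ("DJ", "all"):
            if ann.d_span is not None and ann.d_span.length:
                spans.append((ann.d_span.start, ann.d_span.end))
            if ann.j_span is not None:
                spans.append((ann.j_span.start, ann.j_span.end))
        for child, (parent, _) in cluster.tree.parent.items():
            out.append((cluster.member(parent).sequence,
                        cluster.member(child).sequence, spans))
    return out
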