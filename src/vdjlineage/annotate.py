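"""Read segmentation into V / N_VD / D / N_DJ / J and CDR3 location.

Matching order follows the nucleotide-preservation scheme that prevents
"no D" calls on short CDR3-focused amplicons: the V gene is matched first
against all but the last 9 nt of the read, 3 nt to the right of the V
segment are then reserved before matching the J gene, and every remaining
nucleotide between V and J is offered to the D match.  Unassigned
junction nucleotides become the N_VD and N_DJ regions.

All public coordinates are 1-based inclusive; an empty interval is
represented with ``end = start - 1``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .align import (AlignmentResult, LeniencyPolicy,
                    best_ungapped_alignment)
from .germline import STOP_CODONS, GermlineDatabase


@dataclass(frozen=True)
class Span:
    """1-based inclusive interval; ``end < start`` means empty."""

    start: int
    end: int

    @property
    def length(self) -> int:
        return max(0, self.end - self.start + 1)

    def extract(self, seq: str) -> str:
        return seq[self.start - 1:self.end]

    def contains(self, pos: int) -> bool:
        return self.start <= pos <= self.end


@dataclass(frozen=True)
class NRegion:
    sequence: str
    side: str  # "VD" or "DJ"


@dataclass
class AnnotationConfig:
    """Tunable knobs of the annotation stage."""

    v_leniency_fraction: float = 0.15
    min_overlap_v: int = 10
    min_overlap_j: int = 10
    min_overlap_d: int = 3
    v_preserve: int = 9        # 3' nt reserved from the V match for D and J
    j_reserve: int = 3         # nt reserved right of V before the J match
    allow_inverted_d: bool = True
    indel_margin: float = 4.0
    indel_max_edits: int = 2
    indel_trigger_fraction: float = 0.25  # only search indels when V misaligns structurally


@dataclass
class Annotation:
    """Per-read VDJ segmentation.

    The five spans tile the read end to end (N spans may be empty);
    ``mismatches`` maps segment label (V/D/J) to sorted 1-based read
    positions that differ from the chosen germline.  ``status`` is ``ok``
    or a failure reason (``no_v``, ``no_j``, ``too_short``, ...); failed
    reads keep their row in the output but are excluded from clustering.
    """

    read_id: str
    sequence: str
    status: str = "ok"
    v_name: Optional[str] = None
    d_name: Optional[str] = None
    j_name: Optional[str] = None
    v_span: Optional[Span] = None
    nvd_span: Optional[Span] = None
    d_span: Optional[Span] = None
    ndj_span: Optional[Span] = None
    j_span: Optional[Span] = None
    v_gene_span: Optional[tuple[int, int]] = None
    d_gene_span: Optional[tuple[int, int]] = None
    j_gene_span: Optional[tuple[int, int]] = None
    n_vd: Optional[NRegion] = None
    n_dj: Optional[NRegion] = None
    cdr3_span: Optional[Span] = None
    cdr3_seq: Optional[str] = None
    productive: bool = False
    mismatches: dict = field(default_factory=dict)
    tied: dict = field(default_factory=dict)
    v_score: float = 0.0
    d_score: float = 0.0
    j_score: float = 0.0
    v_mutation_fraction: float = 0.0
    indel_log: list = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return self.status == "ok"

    @property
    def total_score(self) -> float:
        return self.v_score + self.d_score + self.j_score

    def segment_span(self, label: str) -> Optional[Span]:
        return {"V": self.v_span, "D": self.d_span, "J": self.j_span,
                "NVD": self.nvd_span, "NDJ": self.ndj_span}[label]


def _best_over_genes(read: str, genes, leniency, window, min_overlap):
    """Best alignment across genes; ties on score keep the full tied list.

    The primary gene is chosen by (overlap, smaller offset, name); if the
    tied list mixes functional genes and pseudogenes, pseudogene
    suggestions are removed.
    """
    from .align import _match_counts, encode
    r_enc = encode(read)[window[0] - 1:window[1]]
    # visit genes in decreasing best-possible-score order so the running
    # floor prunes hopeless genes after their first offset
    all_counts = [_match_counts(r_enc, encode(g.sequence)) for g in genes]
    bounds = [int(c.max()) if c.size else 0 for c in all_counts]
    order = sorted(range(len(genes)), key=lambda i: (-bounds[i], genes[i].name))

    results = []
    floor = float("-inf")
    for i in order:
        g = genes[i]
        if bounds[i] * bounds[i] < floor:
            continue
        res = best_ungapped_alignment(read, g, leniency, read_window=window,
                                      min_overlap=min_overlap, score_floor=floor,
                                      counts=all_counts[i])
        if res.aligned:
            results.append((res, g))
            floor = max(floor, res.score)
    if not results:
        return None, []
    top = max(r.score for r, _ in results)
    tied = [(r, g) for r, g in results if r.score == top]
    if len(tied) > 1 and any(not g.is_pseudogene for _, g in tied):
        tied = [(r, g) for r, g in tied if not g.is_pseudogene]
    tied.sort(key=lambda t: (-t[0].overlap, t[0].pattern.read_span[0],
                             t[0].gene_name))
    return tied[0], [r.gene_name for r, _ in tied]


def annotate_v(read: str, db: GermlineDatabase, cfg: AnnotationConfig,
               leniency: Optional[LeniencyPolicy] = None):
    """Best V gene with the last ``v_preserve`` nt excluded from matching."""
    window_end = len(read) - cfg.v_preserve
    if window_end < cfg.min_overlap_v:
        return None, []
    leniency = leniency or LeniencyPolicy(fraction=cfg.v_leniency_fraction)
    return _best_over_genes(read, db.genes("V"), leniency,
                            (1, window_end), cfg.min_overlap_v)


def annotate_j(read: str, db: GermlineDatabase, v_end: int,
               leniency: LeniencyPolicy, cfg: AnnotationConfig):
    """Best J gene over the read right of V, honouring the 3-nt reservation."""
    start = v_end + cfg.j_reserve + 1
    if len(read) - start + 1 < cfg.min_overlap_j:
        return None, []
    return _best_over_genes(read, db.genes("J"), leniency,
                            (start, len(read)), cfg.min_overlap_j)


def annotate_d(read: str, db: GermlineDatabase, v_end: int, j_start: int,
               leniency: LeniencyPolicy, cfg: AnnotationConfig,
               allow_inverted: Optional[bool] = None):
    """Best D gene (inverted copies included by default) between V and J."""
    if allow_inverted is None:
        allow_inverted = cfg.allow_inverted_d
    window = (v_end + 1, j_start - 1)
    if window[1] - window[0] + 1 < cfg.min_overlap_d:
        return None, []
    genes = [g for g in db.genes("D") if allow_inverted or not g.is_inverted]
    return _best_over_genes(read, genes, leniency, window, cfg.min_overlap_d)


def assign_n_regions(read: str, v_end: int, d_span: Optional[Span],
                     j_start: int) -> tuple[NRegion, NRegion, Span, Span]:
    """N regions between the assigned segments (empty regions allowed)."""
    if d_span is not None and d_span.length:
        nvd = Span(v_end + 1, d_span.start - 1)
        ndj = Span(d_span.end + 1, j_start - 1)
    else:
        nvd = Span(v_end + 1, j_start - 1)
        ndj = Span(j_start, j_start - 1)
    return (NRegion(nvd.extract(read), "VD"), NRegion(ndj.extract(read), "DJ"),
            nvd, ndj)


def locate_cdr3(ann: Annotation, db: GermlineDatabase) -> Annotation:
    """Map the germline anchors into read coordinates and screen the frame.

    The CDR3 runs from the first base of the 104Cys codon to the last base
    of the 118Trp codon.  Productive means: anchors in a common reading
    frame (junction length divisible by 3) and no stop codon in that frame
    across the junction.
    """
    if ann.v_name is None or ann.j_name is None:
        return ann
    vg, jg = db[ann.v_name], db[ann.j_name]
    if vg.anchor_pos is None or jg.anchor_pos is None:
        return ann
    av = ann.v_span.start + (vg.anchor_pos - ann.v_gene_span[0])
    aj = ann.j_span.start + (jg.anchor_pos - ann.j_gene_span[0])
    if av < 1 or aj + 2 > len(ann.sequence) or av > aj:
        ann.cdr3_span = None
        ann.productive = False
        return ann
    ann.cdr3_span = Span(av, aj + 2)
    ann.cdr3_seq = ann.cdr3_span.extract(ann.sequence)
    in_frame = (aj + 2 - av + 1) % 3 == 0
    stop_free = True
    if in_frame:
        for p in range(av - 1, aj + 2, 3):
            if ann.sequence[p:p + 3] in STOP_CODONS:
                stop_free = False
                break
    ann.productive = in_frame and stop_free
    return ann


def _segment_mismatches(pattern, span: Span) -> list[int]:
    return [span.start + i for i, m in enumerate(pattern.pattern) if not m]


def annotate_sequence(read_id: str, read: str, db: GermlineDatabase,
                      cfg: Optional[AnnotationConfig] = None) -> Annotation:
    """Full Step-1 segmentation of one read.

    Pipeline: V match -> V indel correction (re-align once if edited) ->
    J match -> D match -> N-region assignment -> CDR3 location, recording
    per-segment mismatch positions against the chosen germlines.
    """
    cfg = cfg or AnnotationConfig()
    ann = Annotation(read_id=read_id, sequence=read)
    if not read:
        ann.status = "empty"
        return ann
    if set(read) - set("ACGTN"):
        ann.status = "ambiguous_chars"
        return ann

    v_pick, v_tied = annotate_v(read, db, cfg)
    if v_pick is None:
        ann.status = "no_v"
        return ann
    v_res, v_gene = v_pick

    if (v_res.mutation_fraction > cfg.indel_trigger_fraction
            and cfg.indel_max_edits > 0):
        from .align import correct_v_indels
        edited, log = correct_v_indels(
            read, v_res, v_gene, LeniencyPolicy(fraction=cfg.v_leniency_fraction),
            margin=cfg.indel_margin, max_edits=cfg.indel_max_edits,
            read_window_tail=cfg.v_preserve)
        if log:
            read = edited
            ann.sequence = read
            ann.indel_log = log
            v_pick, v_tied = annotate_v(read, db, cfg)
            if v_pick is None:
                ann.status = "no_v"
                return ann
            v_res, v_gene = v_pick

    ann.v_name = v_res.gene_name
    ann.tied["V"] = v_tied
    ann.v_score = v_res.score
    ann.v_mutation_fraction = v_res.mutation_fraction
    v_end = v_res.pattern.read_span[1]
    ann.v_span = Span(1, v_end)  # V segment owns the read start through its match
    # shift the gene span so it maps from read position 1
    gs, ge = v_res.pattern.gene_span
    ann.v_gene_span = (gs - (v_res.pattern.read_span[0] - 1), ge)
    ann.mismatches["V"] = _segment_mismatches(v_res.pattern, Span(*v_res.pattern.read_span))

    dj_leniency = LeniencyPolicy(fraction=v_res.mutation_fraction)
    j_pick, j_tied = annotate_j(read, db, v_end, dj_leniency, cfg)
    if j_pick is None:
        ann.status = "no_j"
        return ann
    j_res, _ = j_pick
    ann.j_name = j_res.gene_name
    ann.tied["J"] = j_tied
    ann.j_score = j_res.score
    ann.j_gene_span = j_res.pattern.gene_span
    j_start = j_res.pattern.read_span[0]
    ann.j_span = Span(j_start, len(read))
    ann.mismatches["J"] = _segment_mismatches(j_res.pattern, Span(*j_res.pattern.read_span))

    d_pick, d_tied = annotate_d(read, db, v_end, j_start, dj_leniency, cfg)
    if d_pick is not None:
        d_res, _ = d_pick
        ann.d_name = d_res.gene_name
        ann.tied["D"] = d_tied
        ann.d_score = d_res.score
        ann.d_gene_span = d_res.pattern.gene_span
        ann.d_span = Span(*d_res.pattern.read_span)
        ann.mismatches["D"] = _segment_mismatches(d_res.pattern, ann.d_span)
    else:
        # rare: window below the minimum D overlap — flagged via d_name=None
        ann.d_span = None

    ann.n_vd, ann.n_dj, ann.nvd_span, ann.ndj_span = assign_n_regions(
        read, v_end, ann.d_span, j_start)
    if ann.d_span is None:
        ann.d_span = Span(ann.nvd_span.end + 1, ann.nvd_span.end)
    return locate_cdr3(ann, db)


def trim_constant_region(read: str, db: GermlineDatabase,
                         cfg: Optional[AnnotationConfig] = None) -> str:
    """Remove any 3' overhang past the best J gene match (constant region)."""
    cfg = cfg or AnnotationConfig()
    pick, _ = _best_over_genes(read, db.genes("J"),
                               LeniencyPolicy(fraction=cfg.v_leniency_fraction),
                               (1, len(read)), cfg.min_overlap_j)
    if pick is None:
        return read
    res, gene = pick
    j_read_end = res.pattern.read_span[1]
    # trim only what lies beyond the end of the germline J
    gene_tail = len(gene.sequence) - res.pattern.gene_span[1]
    cut = j_read_end + gene_tail
    return read[:cut] if cut < len(read) else read


def germline_read(ann: Annotation, db: GermlineDatabase) -> str:
    """Predicted unmutated sequence underlying an annotated read.

    V/D/J spans take the germline nucleotides at the aligned offsets; the
    N regions (non-templated by definition) keep the read's own bases.
    """
    out = list(ann.sequence)
    for label, span, gspan, name in (("V", ann.v_span, ann.v_gene_span, ann.v_name),
                                     ("D", ann.d_span, ann.d_gene_span, ann.d_name),
                                     ("J", ann.j_span, ann.j_gene_span, ann.j_name)):
        if span is None or name is None or gspan is None or span.length == 0:
            continue
        gene = db[name].sequence
        for i in range(span.length):
            gpos = gspan[0] - 1 + i
            rpos = span.start - 1 + i
            if 0 <= gpos < len(gene) and 0 <= rpos < len(out):
                out[rpos] = gene[gpos]
    return "".join(out)


def recount_mismatches(ann: Annotation, germline: str) -> dict:
    """Per-segment mismatch positions of a read against a germline guess.

    Positions are in germline (cluster root) coordinates.  A member whose
    read length differs from the root's (after an indel correction) is
    compared 3'-anchored, since all reads end on the 118Trp codon.
    """
    shift = len(germline) - len(ann.sequence)
    out = {}
    for label in ("V", "D", "J"):
        span = ann.segment_span(label)
        if span is None or span.length == 0:
            out[label] = []
            continue
        mism = []
        for p in range(span.start, span.end + 1):
            q = p - shift
            if 1 <= q <= len(ann.sequence) and 1 <= p <= len(germline):
                if ann.sequence[q - 1] != germline[p - 1]:
                    mism.append(p)
        out[label] = mism
    return out
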