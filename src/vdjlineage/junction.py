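"""Cluster-level junction refinement: TDT scoring, D re-annotation, N edges.

Terminal deoxynucleotidyl transferase (TDT) inserts non-templated
nucleotides with a strong G/A bias on the strand it elongates.  The
probability that an N region was created by TDT rather than uniform
insertion is

    P_TDT = prod_j P_X(j) / (0.25^L + prod_j P_X(j))

with per-nucleotide insertion probabilities P_A=0.25, P_C=0.08, P_G=0.60,
P_T=0.07 (estimated once from healthy mouse repertoires).  Because TDT
may act on either DNA strand, P_TDT is evaluated on the sequence and its
element-wise (non-reversed) complement and the larger value kept.  The
squared length-weighted score Nscore = (P_TDT * L)^2 rewards long,
TDT-plausible N regions.

Step 3 revisits the D gene whenever a cluster shows consensus mismatches
confined to the CDR3 (a consensus mismatch in the V framework instead
indicates genuine shared SHM); an alternative D is accepted only if the
summed VDJ alignment scores plus both Nscores strictly increase.  Step 4
re-demarcates segment edges abutting N regions: edge runs of three or
more consensus mismatches move into the N region unconditionally, and
otherwise edge nucleotides are trimmed into the N region only when the
TDT model supports it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .align import LeniencyPolicy, best_ungapped_alignment
from .annotate import Annotation, NRegion, Span
from .germline import GermlineDatabase
from .lineage import CloneCluster, unify_annotations

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass(frozen=True)
class TDTModel:
    """Nucleotide insertion probabilities of TDT plus the uniform baseline."""

    p_insert: tuple = (("A", 0.25), ("C", 0.08), ("G", 0.60), ("T", 0.07))
    baseline: float = 0.25

    def __post_init__(self):
        total = sum(p for _, p in self.p_insert)
        if abs(total - 1.0) > 1e-9:
            raise ValueError("insertion probabilities must sum to 1")
        if any(not 0 < p < 1 for _, p in self.p_insert):
            raise ValueError("insertion probabilities must lie in (0,1)")

    @property
    def probs(self) -> dict:
        return dict(self.p_insert)


DEFAULT_TDT = TDTModel()


def _p_tdt_one_strand(seq: str, model: TDTModel) -> float:
    prod = 1.0
    for nt in seq:
        prod *= model.probs[nt]
    return prod / (model.baseline ** len(seq) + prod)


def p_tdt(n_seq: str, model: TDTModel = DEFAULT_TDT) -> float:
    """P_TDT of an N region, maximized over the two strands.

    The complement is element-wise without reversal.  An empty region is
    neutral by convention and returns 0.5.
    """
    if not n_seq:
        return 0.5
    comp = "".join(_COMP[nt] for nt in n_seq)
    return max(_p_tdt_one_strand(n_seq, model), _p_tdt_one_strand(comp, model))


def nscore(n_seq: str, model: TDTModel = DEFAULT_TDT) -> float:
    """Length-weighted TDT likelihood score; empty regions score 0."""
    if not n_seq:
        return 0.0
    return (p_tdt(n_seq, model) * len(n_seq)) ** 2


@dataclass(frozen=True)
class ConsensusMismatch:
    """A position where every cluster member mismatches the germline guess."""

    position: int      # 1-based read coordinate
    region: str        # "Vframe" or "CDR3"


def find_consensus_mismatches(cluster: CloneCluster) -> list[ConsensusMismatch]:
    """Positions mismatching the unified germline in 100% of members."""
    if not cluster.member_mismatches:
        return []
    sets = [set(p for v in mm.values() for p in v)
            for mm in cluster.member_mismatches.values()]
    common = sorted(set.intersection(*sets))
    ann = cluster.annotation
    out = []
    for pos in common:
        if ann.cdr3_span is not None and ann.cdr3_span.contains(pos):
            region = "CDR3"
        elif ann.v_span is not None and ann.v_span.contains(pos):
            region = "Vframe"
        else:
            region = "CDR3"
        out.append(ConsensusMismatch(position=pos, region=region))
    return out


@dataclass
class RefineConfig:
    min_d_len: int = 3
    edge_scan: int = 4         # nt inspected at each segment tip for trims
    run_tip_slack: int = 2     # a >=3 mismatch run must start this close to the tip
    max_passes: int = 2


def _objective(ann: Annotation, model: TDTModel) -> float:
    n_vd = ann.n_vd.sequence if ann.n_vd else ""
    n_dj = ann.n_dj.sequence if ann.n_dj else ""
    return ann.total_score + nscore(n_vd, model) + nscore(n_dj, model)


def refine_d_gene(cluster: CloneCluster, db: GermlineDatabase,
                  model: TDTModel = DEFAULT_TDT,
                  allow_inverted: bool = True,
                  cfg: Optional[RefineConfig] = None) -> CloneCluster:
    """Re-annotate the root's D gene if TDT evidence supports it.

    Gate: at least one CDR3 consensus mismatch and none in the V
    framework.  Every D gene and placement inside the junction window is
    tried on the root; a candidate replaces the current D only if the sum
    of VDJ alignment scores and both Nscores strictly increases.
    """
    cfg = cfg or RefineConfig()
    cons = find_consensus_mismatches(cluster)
    if not any(c.region == "CDR3" for c in cons):
        return cluster
    if any(c.region == "Vframe" for c in cons):
        return cluster
    ann = cluster.annotation
    if ann.v_span is None or ann.j_span is None:
        return cluster
    read = ann.sequence
    v_end, j_start = ann.v_span.end, ann.j_span.start
    window = (v_end + 1, j_start - 1)
    if window[1] < window[0]:
        return cluster
    leniency = LeniencyPolicy(fraction=ann.v_mutation_fraction)
    current = _objective(ann, model)
    member_seqs = [cluster.member(mid).sequence for mid in cluster.ids]

    def consensus_in_d(d_span: Span, gene_seq: str, gene_start: int) -> int:
        n = 0
        for i in range(d_span.length):
            gbase = gene_seq[gene_start - 1 + i]
            p = d_span.start - 1 + i
            if all(s[p] != gbase for s in member_seqs):
                n += 1
        return n

    cur_cons = (consensus_in_d(ann.d_span, db[ann.d_name].sequence,
                               ann.d_gene_span[0])
                if ann.d_name and ann.d_span and ann.d_span.length else 0)
    if cur_cons == 0:
        # the current D explains the junction without consensus mismatches;
        # re-annotation exists only to remove them
        return cluster
    best = None
    for gene in db.genes("D"):
        if gene.is_inverted and not allow_inverted:
            continue
        res = best_ungapped_alignment(read, gene, leniency, read_window=window,
                                      min_overlap=cfg.min_d_len)
        if not res.aligned:
            continue
        d_span = Span(*res.pattern.read_span)
        # only candidates that strictly reduce the consensus mismatches
        # inside the D segment qualify
        if consensus_in_d(d_span, gene.sequence,
                          res.pattern.gene_span[0]) >= cur_cons:
            continue
        if res.score <= ann.d_score:
            # both the alignment-score sum and the TDT evidence must
            # improve; otherwise trading D nucleotides for a longer N
            # region could pay for itself through the length term of the
            # Nscore alone
            continue
        n_vd = read[v_end:d_span.start - 1]
        n_dj = read[d_span.end:j_start - 1]
        obj = (ann.v_score + ann.j_score + res.score
               + nscore(n_vd, model) + nscore(n_dj, model))
        key = (obj, res.overlap, -d_span.start, gene.name)
        if best is None or key > best[0]:
            best = (key, res, gene)
    if best is None or best[0][0] <= current:
        return cluster
    _, res, gene = best
    ann.d_name = gene.name
    ann.d_score = res.score
    ann.d_span = Span(*res.pattern.read_span)
    ann.d_gene_span = res.pattern.gene_span
    ann.nvd_span = Span(v_end + 1, ann.d_span.start - 1)
    ann.ndj_span = Span(ann.d_span.end + 1, j_start - 1)
    ann.n_vd = NRegion(ann.nvd_span.extract(read), "VD")
    ann.n_dj = NRegion(ann.ndj_span.extract(read), "DJ")
    return unify_annotations(cluster, db)


def _edge_trim(seq_slice: str, mism_offsets: set,
               n_region: str, n_after: bool, model: TDTModel,
               cfg: RefineConfig) -> int:
    """Number of nt to shave off one segment edge, by rules A then B/C.

    ``seq_slice`` is the whole segment ordered from interior to tip;
    ``mism_offsets`` indexes consensus mismatches within it; ``n_after``
    says whether the existing N region sits tip-ward of the slice in
    read order (P_TDT is composition-based, so the order only documents
    the geometry).

    Rule A scans the full segment: a run of three or more consecutive
    consensus mismatches with at most ``run_tip_slack`` germline-matching
    nucleotides between it and the tip moves into the N region
    unconditionally, carrying those matching nucleotides along.  Rules
    B/C consider only the ``edge_scan`` tip-most nucleotides: with no N
    region present, the innermost-mismatch-through-tip piece is trimmed
    iff its P_TDT exceeds 0.5; with an N region present, iff combining
    the piece with the N region raises P_TDT above the piece alone.
    """
    k = len(seq_slice)
    if not mism_offsets:
        return 0
    offs = sorted(mism_offsets)
    runs = []
    start = prev = offs[0]
    for o in offs[1:] + [None]:
        if o is None or o != prev + 1:
            runs.append((start, prev))
            if o is not None:
                start = o
        prev = o if o is not None else prev
    for a, b in runs:
        if b - a + 1 >= 3 and (k - 1 - b) <= cfg.run_tip_slack:
            return k - a                       # from the run through the tip
    window_offs = [o for o in offs if o >= k - cfg.edge_scan]
    if not window_offs:
        return 0
    cut = k - window_offs[0]
    candidate = seq_slice[window_offs[0]:]
    if not n_region:
        return cut if p_tdt(candidate, model) > 0.5 else 0
    combined = candidate + n_region if n_after else n_region + candidate
    return cut if p_tdt(combined, model) > p_tdt(candidate, model) else 0


def refine_n_edges(cluster: CloneCluster, model: TDTModel = DEFAULT_TDT,
                   cfg: Optional[RefineConfig] = None,
                   db: Optional[GermlineDatabase] = None) -> CloneCluster:
    """Re-demarcate segment edges abutting the N regions (Step 4).

    Edges are processed in the order V3', D5', D3', J5'; each applies
    rule A (unconditional move of a >=3 consensus-mismatch run at the
    tip), else rule B (create an N region if the trimmed nucleotides look
    TDT-made, P_TDT > 0.5), else rule C (extend an existing N region only
    if the combination raises P_TDT over the trimmed piece alone).  One
    pass, then one re-unification.
    """
    cfg = cfg or RefineConfig()
    cons = {c.position for c in find_consensus_mismatches(cluster)}
    if not cons:
        return cluster
    ann = cluster.annotation
    if ann.v_span is None or ann.j_span is None or ann.d_span is None:
        return cluster
    read = ann.sequence
    v_end = ann.v_span.end
    d_start, d_end = ann.d_span.start, ann.d_span.end
    j_start = ann.j_span.start
    d_len = ann.d_span.length

    def slice_and_offsets(lo: int, hi: int, tip_high: bool):
        """Edge window [lo, hi] with mismatch offsets, interior->tip order."""
        positions = list(range(lo, hi + 1))
        if not tip_high:
            positions = positions[::-1]
        s = "".join(read[p - 1] for p in positions)
        offs = {i for i, p in enumerate(positions) if p in cons}
        return s, offs, positions

    # --- V 3' edge (abuts N_VD; trimmed nts go in front of N_VD)
    lo = ann.v_span.start
    if lo <= v_end:
        s, offs, _ = slice_and_offsets(lo, v_end, tip_high=True)
        n_vd = read[v_end:d_start - 1]
        cut = _edge_trim(s, offs, n_vd, n_after=True, model=model, cfg=cfg)
        cut = min(cut, v_end - ann.v_span.start)   # keep at least 1 nt of V
        v_end -= cut

    # --- D 5' edge (abuts N_VD; trimmed nts append after N_VD)
    hi = d_end
    if d_start <= hi and d_len > cfg.min_d_len:
        s, offs, positions = slice_and_offsets(d_start, hi, tip_high=False)
        n_vd = read[v_end:d_start - 1]
        cut = _edge_trim(s, offs, n_vd, n_after=False, model=model, cfg=cfg)
        cut = min(cut, d_len - cfg.min_d_len)
        d_start += cut
        d_len = d_end - d_start + 1

    # --- D 3' edge (abuts N_DJ; trimmed nts go in front of N_DJ)
    lo = d_start
    if lo <= d_end and d_len > cfg.min_d_len:
        s, offs, _ = slice_and_offsets(lo, d_end, tip_high=True)
        n_dj = read[d_end:j_start - 1]
        cut = _edge_trim(s, offs, n_dj, n_after=True, model=model, cfg=cfg)
        cut = min(cut, d_len - cfg.min_d_len)
        d_end -= cut

    # --- J 5' edge (abuts N_DJ; trimmed nts append after N_DJ)
    hi = ann.j_span.end - 1
    if j_start <= hi:
        s, offs, _ = slice_and_offsets(j_start, hi, tip_high=False)
        n_dj = read[d_end:j_start - 1]
        cut = _edge_trim(s, offs, n_dj, n_after=False, model=model, cfg=cfg)
        cut = min(cut, ann.j_span.end - j_start)
        j_start += cut

    changed = (v_end != ann.v_span.end or d_start != ann.d_span.start
               or d_end != ann.d_span.end or j_start != ann.j_span.start)
    if not changed:
        return cluster
    shift_v = ann.v_span.end - v_end
    shift_d5 = d_start - ann.d_span.start
    shift_d3 = ann.d_span.end - d_end
    shift_j = j_start - ann.j_span.start
    ann.v_span = Span(ann.v_span.start, v_end)
    if ann.v_gene_span:
        ann.v_gene_span = (ann.v_gene_span[0], ann.v_gene_span[1] - shift_v)
    ann.d_span = Span(d_start, d_end)
    if ann.d_gene_span:
        ann.d_gene_span = (ann.d_gene_span[0] + shift_d5,
                           ann.d_gene_span[1] - shift_d3)
    ann.j_span = Span(j_start, ann.j_span.end)
    if ann.j_gene_span:
        ann.j_gene_span = (ann.j_gene_span[0] + shift_j, ann.j_gene_span[1])
    ann.nvd_span = Span(v_end + 1, d_start - 1)
    ann.ndj_span = Span(d_end + 1, j_start - 1)
    ann.n_vd = NRegion(ann.nvd_span.extract(read), "VD")
    ann.n_dj = NRegion(ann.ndj_span.extract(read), "DJ")
    if db is not None:
        return unify_annotations(cluster, db)
    return cluster


def refine_cluster(cluster: CloneCluster, db: GermlineDatabase,
                   model: TDTModel = DEFAULT_TDT, allow_inverted: bool = True,
                   cfg: Optional[RefineConfig] = None) -> CloneCluster:
    """Run the Step3 -> Step4 refinement pair, at most ``max_passes`` times."""
    cfg = cfg or RefineConfig()
    for _ in range(cfg.max_passes):
        before = find_consensus_mismatches(cluster)
        cluster = refine_d_gene(cluster, db, model, allow_inverted, cfg)
        cluster = refine_n_edges(cluster, model, cfg, db=db)
        after = find_consensus_mismatches(cluster)
        if [c.position for c in after] == [c.position for c in before]:
            break
    return cluster
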