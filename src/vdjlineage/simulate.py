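"""Truth-annotated synthetic BCR repertoires for benchmarking.

Each germline sequence is an independent recombination event: V, D, and J
genes are drawn uniformly (gene-usage realism is deliberately not a
goal — uniform sampling exercises more VDJ combinations), gene edges are
nibbled back by exonuclease-style deletions (truncated-geometric, so most
ends lose only a few nucleotides), and TDT-biased N regions are inserted
at both joints.  The assembled sequence is trimmed to a fixed
read length keeping the conserved 118Trp codon as the final three
nucleotides, mimicking CDR3-focused short-amplicon sequencing.  Only
productive junctions (in frame, stop-free) are emitted.

Somatic hypermutation is simulated as a chain: each of ``n_rounds``
descendants mutates the previous round's sequence at
``mutations_per_descendant`` fresh, never-before-mutated positions, so a
generation-g sequence carries exactly g x mutations_per_descendant
mismatches to its germline ancestor.  The default substitution biases
mirror AID (dominant C>T / G>A) and strand-biased adenosine mutation
(A mutated more than T, with A>G the most common A substitution).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .germline import STOP_CODONS, GermlineDatabase
from .junction import DEFAULT_TDT, TDTModel

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}

DEFAULT_SUBSTITUTION = {
    "C": {"T": 0.6, "A": 0.2, "G": 0.2},
    "G": {"A": 0.6, "T": 0.2, "C": 0.2},
    "A": {"G": 0.5, "T": 0.3, "C": 0.2},
    "T": {"C": 0.5, "A": 0.25, "G": 0.25},
}


@dataclass
class SimConfig:
    """Study conditions for the benchmark repertoire."""

    n_germline: int = 1000
    n_rounds: int = 5
    mutations_per_descendant: int = 5
    read_length: int = 125
    max_deletion: int = 5          # hard cap per gene end
    deletion_decay: float = 0.55   # P(d) ~ decay**d, truncated at the cap
    max_n_length: int = 8          # per N region, uniform 0..max
    min_d_remnant: int = 3         # D-less junctions are out of scope
    strand_flip_prob: float = 0.5
    substitution_model: dict = field(default_factory=lambda: {
        k: dict(v) for k, v in DEFAULT_SUBSTITUTION.items()})
    tdt: TDTModel = field(default_factory=lambda: DEFAULT_TDT)
    seed: int = 0

    def __post_init__(self):
        for row in self.substitution_model.values():
            if abs(sum(row.values()) - 1.0) > 1e-9:
                raise ValueError("substitution rows must sum to 1")


def _sample_deletion(rng: np.random.Generator, cap: int, decay: float) -> int:
    """Truncated-geometric deletion length: most gene ends lose 0-2 nt."""
    probs = np.array([decay ** d for d in range(cap + 1)])
    probs /= probs.sum()
    return int(rng.choice(cap + 1, p=probs))


@dataclass
class SimulatedSequence:
    """A simulated read with its generating truth."""

    id: str
    sequence: str
    generation: int                # 0 = germline
    germline_id: str
    parent_id: Optional[str]
    v_name: str
    d_name: str
    j_name: str
    v_end: int                     # 1-based read coordinates
    d_start: int
    d_end: int
    j_start: int
    n_vd: str
    n_dj: str
    cdr3_start: int                # first base of the 104Cys codon
    mutations: list = field(default_factory=list)   # this round: (pos, frm, to)
    lineage_mutated: set = field(default_factory=set)

    @property
    def cdr3_length(self) -> int:
        return len(self.sequence) - self.cdr3_start + 1


def synthesize_n_region(length: int, model: TDTModel,
                        rng: np.random.Generator,
                        strand_flip_prob: float = 0.5) -> str:
    """Draw an N region from the TDT insertion bias.

    Nucleotides are i.i.d. from the insertion probabilities; with
    probability ``strand_flip_prob`` the whole region is complemented
    element-wise, modelling TDT elongating either strand.
    """
    if length == 0:
        return ""
    nts, probs = zip(*model.p_insert)
    seq = "".join(rng.choice(nts, size=length, p=probs))
    if rng.random() < strand_flip_prob:
        seq = "".join(_COMP[c] for c in seq)
    return seq


def sample_recombination_event(db: GermlineDatabase, config: SimConfig,
                               rng: np.random.Generator,
                               index: int = 0) -> SimulatedSequence:
    """One productive germline (generation 0) recombination event."""
    vs = sorted((g for g in db.genes("V") if g.anchor_pos is not None),
                key=lambda g: g.name)
    ds = sorted((g for g in db.genes("D") if not g.is_inverted),
                key=lambda g: g.name)
    js = sorted((g for g in db.genes("J") if g.anchor_pos is not None),
                key=lambda g: g.name)
    if not vs or not ds or not js:
        raise ValueError("database lacks usable V/D/J genes with anchors")
    L = config.read_length
    for _ in range(1000):
        v = vs[rng.integers(len(vs))]
        d = ds[rng.integers(len(ds))]
        j = js[rng.integers(len(js))]
        del_v = _sample_deletion(rng, config.max_deletion, config.deletion_decay)
        max_d_del = len(d.sequence) - config.min_d_remnant
        del_d5 = _sample_deletion(rng, min(config.max_deletion, max_d_del),
                                  config.deletion_decay)
        del_d3 = _sample_deletion(rng, min(config.max_deletion,
                                           max_d_del - del_d5),
                                  config.deletion_decay)
        del_j = _sample_deletion(rng, config.max_deletion, config.deletion_decay)
        # never delete into the V 104Cys or past the J 118Trp
        if len(v.sequence) - del_v < v.anchor_pos + 2:
            continue
        if j.anchor_pos - 1 - del_j < 0:
            continue
        n_vd = synthesize_n_region(int(rng.integers(0, config.max_n_length + 1)),
                                   config.tdt, rng, config.strand_flip_prob)
        n_dj = synthesize_n_region(int(rng.integers(0, config.max_n_length + 1)),
                                   config.tdt, rng, config.strand_flip_prob)
        vpart = v.sequence[:len(v.sequence) - del_v]
        dpart = d.sequence[del_d5:len(d.sequence) - del_d3]
        jpart = j.sequence[del_j:j.anchor_pos + 2]   # ends at the 118Trp codon
        full = vpart + n_vd + dpart + n_dj + jpart
        if len(full) < L:
            continue
        off = len(full) - L                       # 0-based read start in full
        read = full[off:]
        anchor_v0 = v.anchor_pos - 1 - off        # 0-based in read
        if anchor_v0 < 10:                        # anchor (plus context) must survive
            continue
        if (L - anchor_v0) % 3 != 0:
            continue
        if any(read[p:p + 3] in STOP_CODONS for p in range(anchor_v0, L, 3)):
            continue
        return SimulatedSequence(
            id=f"G{index:04d}", sequence=read, generation=0,
            germline_id=f"G{index:04d}", parent_id=None,
            v_name=v.name, d_name=d.name, j_name=j.name,
            v_end=len(vpart) - off,
            d_start=len(vpart) + len(n_vd) + 1 - off,
            d_end=len(vpart) + len(n_vd) + len(dpart) - off,
            j_start=len(vpart) + len(n_vd) + len(dpart) + len(n_dj) + 1 - off,
            n_vd=n_vd, n_dj=n_dj, cdr3_start=anchor_v0 + 1)
    raise RuntimeError("could not generate a productive junction in 1000 tries")


def apply_shm_round(parent: SimulatedSequence, config: SimConfig,
                    rng: np.random.Generator,
                    round_index: int) -> SimulatedSequence:
    """Mutate ``mutations_per_descendant`` fresh positions of the parent."""
    n = config.mutations_per_descendant
    fresh = [p for p in range(len(parent.sequence))
             if p not in parent.lineage_mutated]
    if len(fresh) < n:
        raise ValueError("not enough unmutated positions left in the lineage")
    picks = sorted(rng.choice(len(fresh), size=n, replace=False))
    positions = [fresh[i] for i in picks]
    seq = list(parent.sequence)
    mutations = []
    for p in positions:
        frm = seq[p]
        row = config.substitution_model[frm]
        tos, probs = zip(*sorted(row.items()))
        to = str(rng.choice(tos, p=probs))
        seq[p] = to
        mutations.append((p + 1, frm, to))
    return SimulatedSequence(
        id=f"{parent.germline_id}R{round_index}", sequence="".join(seq),
        generation=round_index, germline_id=parent.germline_id,
        parent_id=parent.id, v_name=parent.v_name, d_name=parent.d_name,
        j_name=parent.j_name, v_end=parent.v_end, d_start=parent.d_start,
        d_end=parent.d_end, j_start=parent.j_start, n_vd=parent.n_vd,
        n_dj=parent.n_dj, cdr3_start=parent.cdr3_start,
        mutations=mutations,
        lineage_mutated=parent.lineage_mutated | {p - 1 for p, _, _ in mutations})


def simulate_repertoire(db: GermlineDatabase,
                        config: Optional[SimConfig] = None
                        ) -> tuple[list[SimulatedSequence], pd.DataFrame]:
    """Full benchmark repertoire: germlines plus their descendant chains.

    Returns the sequences (germlines first, then each germline's chain in
    round order) and a truth table with one row per sequence.
    """
    config = config or SimConfig()
    rng = np.random.default_rng(config.seed)
    seqs: list[SimulatedSequence] = []
    for i in range(config.n_germline):
        g = sample_recombination_event(db, config, rng, index=i)
        chain = [g]
        for r in range(1, config.n_rounds + 1):
            chain.append(apply_shm_round(chain[-1], config, rng, r))
        seqs.extend(chain)
    return seqs, truth_table(seqs)


def truth_table(seqs: list[SimulatedSequence]) -> pd.DataFrame:
    rows = []
    for s in seqs:
        rows.append({
            "id": s.id, "generation": s.generation, "parent_id": s.parent_id or "",
            "sequence": s.sequence, "v_name": s.v_name, "d_name": s.d_name,
            "j_name": s.j_name, "v_end": s.v_end, "d_start": s.d_start,
            "d_end": s.d_end, "j_start": s.j_start, "n_vd": s.n_vd,
            "n_dj": s.n_dj, "cdr3_start": s.cdr3_start,
            "mutated_positions": ";".join(f"{p}:{f}>{t}" for p, f, t in s.mutations),
        })
    return pd.DataFrame(rows)


def write_fasta(seqs: list[SimulatedSequence], path) -> None:
    with open(path, "w") as fh:
        for s in seqs:
            fh.write(f">{s.id}\n{s.sequence}\n")
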