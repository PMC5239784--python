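"""Germline V/D/J gene databases.

Loads IMGT-style germline FASTA files, filters them by mouse strain,
synthesizes reverse-complement ("inverted") D genes, and locates the
conserved CDR3 anchor codons: the 104Cys (TGT/TGC) near the 3' end of V
genes and the 118Trp (TGG) of J genes.  All coordinates exposed here are
1-based and inclusive.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
from Bio import SeqIO

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

STOP_CODONS = {"TAA", "TAG", "TGA"}


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


_FAMILY_RE = re.compile(r"^(r?)(IG[HKL][VDJ]\d+)")


def parse_family(name: str) -> str:
    """Gene family from an allele name, e.g. ``IGHV1-2*01`` -> ``IGHV1``.

    Inverted D genes keep their ``r`` prefix so they tally separately.
    """
    m = _FAMILY_RE.match(name)
    if m is None:
        return name.split("-")[0].split("*")[0]
    return m.group(1) + m.group(2)


def family_number(name: str) -> Optional[int]:
    m = re.search(r"\d+", parse_family(name).lstrip("r"))
    return int(m.group(0)) if m else None


@dataclass(frozen=True)
class GermlineGene:
    """One germline V, D, or J allele.

    ``anchor_pos`` is the 1-based position of the first nucleotide of the
    conserved 104Cys codon (V genes) or 118Trp codon (J genes); ``frame``
    is the 1-based reading-frame offset annotated in the database (codons
    start at positions frame, frame+3, ...).
    """

    name: str
    segment_class: str
    sequence: str
    strain: Optional[str] = None
    is_pseudogene: bool = False
    is_inverted: bool = False
    anchor_pos: Optional[int] = None
    frame: int = 1

    def __post_init__(self):
        if self.segment_class not in ("V", "D", "J"):
            raise ValueError(f"bad segment_class {self.segment_class!r}")
        if not self.sequence:
            raise ValueError(f"gene {self.name}: empty sequence")
        if set(self.sequence) - set("ACGT"):
            raise ValueError(f"gene {self.name}: non-ACGT characters")
        if self.is_inverted and (self.segment_class != "D" or not self.name.startswith("r")):
            raise ValueError(f"gene {self.name}: inverted genes must be D with 'r' prefix")
        if self.anchor_pos is not None and not (1 <= self.anchor_pos <= len(self.sequence) - 2):
            raise ValueError(f"gene {self.name}: anchor_pos {self.anchor_pos} out of range")

    @property
    def family(self) -> str:
        return parse_family(self.name)

    @property
    def family_number(self) -> Optional[int]:
        return family_number(self.name)

    def __len__(self) -> int:
        return len(self.sequence)


class GermlineDatabase:
    """V/D/J gene collections indexed by name and segment class."""

    def __init__(self, genes: Iterable[GermlineGene], species: str = "",
                 strain_filter: Optional[str] = None):
        self.species = species
        self.strain_filter = strain_filter
        self._by_name: dict[str, GermlineGene] = {}
        self._by_class: dict[str, list[GermlineGene]] = {"V": [], "D": [], "J": []}
        for g in genes:
            if g.name in self._by_name:
                raise ValueError(f"duplicate gene name {g.name!r}")
            self._by_name[g.name] = g
            self._by_class[g.segment_class].append(g)

    def genes(self, segment_class: Optional[str] = None) -> list[GermlineGene]:
        if segment_class is None:
            return list(self._by_name.values())
        return list(self._by_class[segment_class])

    def __getitem__(self, name: str) -> GermlineGene:
        return self._by_name[name]

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    def __len__(self) -> int:
        return len(self._by_name)

    def replace_genes(self, genes: Iterable[GermlineGene]) -> "GermlineDatabase":
        return GermlineDatabase(genes, species=self.species,
                                strain_filter=self.strain_filter)


def _parse_header(description: str) -> tuple[str, Optional[str], bool]:
    """Parse an IMGT-style FASTA description into (name, strain, pseudogene).

    Two dialects are accepted: the full IMGT header, where the allele name
    sits in the second ``|``-separated field and the functionality token in
    the fourth, and a simplified ``NAME|STRAIN|FUNCTIONALITY`` fixture
    dialect where the allele name comes first.
    """
    fields = [f.strip() for f in description.split("|")]
    if _FAMILY_RE.match(fields[0]):
        name = fields[0]
        strain = fields[1] if len(fields) > 1 and fields[1] else None
        func = fields[2] if len(fields) > 2 else ""
    else:
        if len(fields) < 2 or not fields[1]:
            raise ValueError(f"malformed FASTA header: {description!r}")
        name = fields[1]
        species_field = fields[2] if len(fields) > 2 else ""
        strain = species_field.split("_", 1)[1] if "_" in species_field else None
        func = fields[3] if len(fields) > 3 else ""
    is_pseudo = "P" in func.replace("ORF", "").upper()
    return name, strain, is_pseudo


def load_germline_fasta(path, segment_class: str) -> list[GermlineGene]:
    """Load one segment class of germline genes from an IMGT-style FASTA.

    Sequences are uppercased and IMGT gap characters (``.``) removed;
    pseudogene status is parsed from the functionality token.  Anchors are
    not assigned here (see :func:`find_anchor_positions`).
    """
    path = Path(path)
    genes = []
    for rec in SeqIO.parse(str(path), "fasta"):
        try:
            name, strain, is_pseudo = _parse_header(rec.description)
        except ValueError as e:
            raise ValueError(f"record {rec.id!r}: {e}") from e
        seq = str(rec.seq).upper().replace(".", "")
        if not seq:
            raise ValueError(f"record {name!r}: empty sequence")
        if set(seq) - set("ACGT"):
            raise ValueError(f"record {name!r}: non-ACGT characters after cleaning")
        genes.append(GermlineGene(name=name, segment_class=segment_class,
                                  sequence=seq, strain=strain,
                                  is_pseudogene=is_pseudo))
    if not genes:
        raise ValueError(f"no FASTA records in {path}")
    return genes


def filter_by_strain(db: GermlineDatabase, strain: str,
                     keep_unannotated: bool = True) -> GermlineDatabase:
    """Keep only genes from one mouse strain.

    Genes lacking a strain annotation are kept by default (set
    ``keep_unannotated=False`` to drop them).  Raises if the filter would
    empty the V, D, or J set, since annotation is then impossible.
    """
    if not strain:
        raise ValueError("strain must be non-empty")
    kept = [g for g in db.genes()
            if g.strain == strain or (g.strain is None and keep_unannotated)]
    out = GermlineDatabase(kept, species=db.species, strain_filter=strain)
    for cls in "VDJ":
        if db.genes(cls) and not out.genes(cls):
            raise ValueError(f"strain filter {strain!r} removed all {cls} genes")
    return out


def make_inverted_d(genes: Iterable[GermlineGene]) -> list[GermlineGene]:
    """Augment a D-gene collection with reverse-complement copies.

    Each copy is named with an ``r`` prefix (e.g. ``rIGHD1-1*01``) and has
    its anchor cleared.  Idempotent: genes that are already inverted, or
    whose inverted counterpart is present, are not duplicated.
    """
    genes = list(genes)
    names = {g.name for g in genes}
    out = list(genes)
    for g in genes:
        if g.segment_class != "D":
            raise ValueError(f"{g.name} is not a D gene")
        if g.is_inverted or ("r" + g.name) in names:
            continue
        out.append(GermlineGene(name="r" + g.name, segment_class="D",
                                sequence=reverse_complement(g.sequence),
                                strain=g.strain, is_pseudogene=g.is_pseudogene,
                                is_inverted=True))
    return out


def find_anchor_positions(gene: GermlineGene) -> GermlineGene:
    """Locate the conserved CDR3 anchor codon of a V or J gene.

    V genes: the in-frame Cys codon (TGT/TGC) nearest the 3' end.
    J genes: the first in-frame Trp codon (TGG).
    Genes with no in-frame anchor keep ``anchor_pos=None`` and are thereby
    flagged unusable for CDR3 calls, but are not dropped.
    """
    if gene.segment_class not in ("V", "J"):
        raise ValueError("anchors are defined for V and J genes only")
    seq = gene.sequence
    targets = ("TGT", "TGC") if gene.segment_class == "V" else ("TGG",)
    hits = [p for p in range(gene.frame - 1, len(seq) - 2, 3)
            if seq[p:p + 3] in targets]
    if not hits:
        return replace(gene, anchor_pos=None)
    pos = hits[-1] if gene.segment_class == "V" else hits[0]
    return replace(gene, anchor_pos=pos + 1)


# ---------------------------------------------------------------------------
# Synthetic fixture database
# ---------------------------------------------------------------------------

def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))


def _min_pairwise_diff(seqs: list[str], tail: int) -> int:
    best = 10 ** 9
    for i in range(len(seqs)):
        for j in range(i + 1, len(seqs)):
            a, b = seqs[i][-tail:], seqs[j][-tail:]
            n = min(len(a), len(b))
            best = min(best, sum(x != y for x, y in zip(a[-n:], b[-n:])))
    return best


def synthetic_germline_database(seed: int = 0, n_v: int = 20, n_d: int = 12,
                                n_j: int = 5, strain: str = "C57BL/6",
                                include_inverted_d: bool = True) -> GermlineDatabase:
    """Deterministic synthetic germline database for tests and simulation.

    Emulates the shape of a mouse heavy-chain locus: V genes ~290 nt ending
    in a 104Cys codon plus two trailing codons, D genes 9-18 nt (the mouse
    D length range), and J genes ~48 nt with a unique in-frame 118Trp
    codon.  Genes are mutually distinct by at least 2 nt over the portion
    visible in a 125-bp read, and carry IMGT-like names and strain tags.
    """
    rng = np.random.default_rng(seed)

    def make_v(idx: int) -> GermlineGene:
        while True:
            body = _random_seq(rng, 282)
            tail_codons = []
            while len(tail_codons) < 2:
                c = _random_seq(rng, 3)
                if c not in STOP_CODONS and c not in ("TGT", "TGC", "TGG"):
                    tail_codons.append(c)
            seq = body + "TGT" + "".join(tail_codons)
            # keep the synthetic 104Cys the 3'-most in-frame Cys codon
            later = [p for p in range(0, len(seq) - 2, 3)
                     if seq[p:p + 3] in ("TGT", "TGC") and p + 1 > 283]
            if later:
                continue
            g = GermlineGene(name=f"IGHV{idx + 1}-1*01", segment_class="V",
                             sequence=seq, strain=strain)
            return find_anchor_positions(g)

    def make_j(idx: int) -> GermlineGene:
        while True:
            lead = []
            for _ in range(12):
                c = _random_seq(rng, 3)
                if c in STOP_CODONS or c == "TGG":
                    break
                lead.append(c)
            if len(lead) != 12:
                continue
            seq = "".join(lead) + "TGG" + _random_seq(rng, 9)
            g = GermlineGene(name=f"IGHJ{idx + 1}*01", segment_class="J",
                             sequence=seq, strain=strain)
            return find_anchor_positions(g)

    vs, js, ds = [], [], []
    while len(vs) < n_v:
        vs.append(make_v(len(vs)))
        if _min_pairwise_diff([g.sequence for g in vs], tail=125) < 2:
            vs.pop()
    while len(js) < n_j:
        js.append(make_j(len(js)))
        if _min_pairwise_diff([g.sequence for g in js], tail=48) < 2:
            js.pop()
    while len(ds) < n_d:
        seq = _random_seq(rng, int(rng.integers(9, 19)))
        cand = [g.sequence for g in ds] + [reverse_complement(g.sequence) for g in ds]
        if any(_min_pairwise_diff([seq, s], tail=18) < 2 for s in cand):
            continue
        ds.append(GermlineGene(name=f"IGHD{len(ds) + 1}-1*01", segment_class="D",
                               sequence=seq, strain=strain))
    if include_inverted_d:
        ds = make_inverted_d(ds)
    return GermlineDatabase(vs + ds + js, species="Mus musculus",
                            strain_filter=strain)


def write_germline_fasta(genes: Iterable[GermlineGene], path) -> None:
    """Write genes in the simplified ``>NAME|STRAIN|FUNCTIONALITY`` dialect."""
    with open(path, "w") as fh:
        for g in genes:
            func = "P" if g.is_pseudogene else "F"
            fh.write(f">{g.name}|{g.strain or ''}|{func}\n{g.sequence}\n")
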