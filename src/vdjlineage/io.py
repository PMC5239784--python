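"""Sequence readers, the annotation table writer, and tree export."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

from .lineage import CloneCluster, LineageTree, Member


@dataclass(frozen=True)
class SequenceRecord:
    id: str
    sequence: str
    template_count: int = 1

    def __post_init__(self):
        if not self.sequence:
            raise ValueError(f"record {self.id!r}: empty sequence")
        if self.template_count < 1:
            raise ValueError(f"record {self.id!r}: template_count must be >= 1")


def read_sequences(path, fmt: Optional[str] = None
                   ) -> tuple[list[SequenceRecord], list[str]]:
    """Read BCR reads from FASTA/FASTQ or a delimited table.

    Tabular inputs need columns ``id`` and ``sequence`` (optional
    ``template_count``).  Sequences are uppercased; FASTQ qualities are
    ignored.  Records with characters outside ACGTN are rejected and
    listed in the returned log; duplicate ids raise.
    """
    path = Path(path)
    if fmt is None:
        fmt = {".fa": "fasta", ".fasta": "fasta", ".fq": "fastq",
               ".fastq": "fastq", ".csv": "csv", ".tsv": "tsv"}.get(
                   path.suffix.lower(), "fasta")
    raw: list[tuple[str, str, int]] = []
    if fmt in ("fasta", "fastq"):
        for rec in SeqIO.parse(str(path), fmt):
            raw.append((rec.id, str(rec.seq).upper(), 1))
    elif fmt in ("csv", "tsv"):
        df = pd.read_csv(path, sep="," if fmt == "csv" else "\t")
        tc = df["template_count"] if "template_count" in df.columns else [1] * len(df)
        for rid, seq, t in zip(df["id"], df["sequence"], tc):
            raw.append((str(rid), str(seq).upper(), int(t)))
    else:
        raise ValueError(f"unknown format {fmt!r}")

    ids = [r[0] for r in raw]
    dupes = sorted({i for i in ids if ids.count(i) > 1})
    if dupes:
        raise ValueError(f"duplicate sequence ids: {', '.join(dupes)}")
    records, rejected = [], []
    for rid, seq, t in raw:
        if set(seq) - set("ACGTN"):
            rejected.append(rid)
            continue
        records.append(SequenceRecord(id=rid, sequence=seq, template_count=t))
    return records, rejected


def _translate(nt: str) -> str:
    if len(nt) < 3:
        return ""
    trimmed = nt[:len(nt) - len(nt) % 3]
    return str(Seq(trimmed).translate())


def annotation_table(annotations, clusters) -> pd.DataFrame:
    """One output row per input sequence, failures included with a status."""
    cluster_of, parent_of, dist_of, ndesc = {}, {}, {}, {}
    tcount = {}
    for ci, cluster in enumerate(clusters):
        for mid in cluster.ids:
            cluster_of[mid] = ci
            tcount[mid] = cluster.member(mid).template_count
            ndesc[mid] = cluster.tree.n_descendants(mid)
        for child, (parent, dist) in cluster.tree.parent.items():
            parent_of[child] = parent
            dist_of[child] = dist
    rows = []
    for ann in annotations:
        span_cols = {}
        for label, span in (("v", ann.v_span), ("nvd", ann.nvd_span),
                            ("d", ann.d_span), ("ndj", ann.ndj_span),
                            ("j", ann.j_span)):
            span_cols[f"{label}_start"] = span.start if span else ""
            span_cols[f"{label}_end"] = span.end if span else ""
        flat = [p for v in ann.mismatches.values() for p in v]
        cdr3_start = ann.cdr3_span.start if ann.cdr3_span else None
        rows.append({
            "id": ann.read_id,
            "template_count": tcount.get(ann.read_id, 1),
            "cluster_id": cluster_of.get(ann.read_id, ""),
            "parent_id": parent_of.get(ann.read_id, ""),
            "shm_distance_to_parent": dist_of.get(ann.read_id, ""),
            "n_descendants": ndesc.get(ann.read_id, 0),
            "v_name": ann.v_name or "", "d_name": ann.d_name or "",
            "j_name": ann.j_name or "",
            "tied_alleles": ";".join(",".join(v) for v in ann.tied.values()),
            **span_cols,
            "n_vd": ann.n_vd.sequence if ann.n_vd else "",
            "n_dj": ann.n_dj.sequence if ann.n_dj else "",
            "cdr3_nt": ann.cdr3_seq or "",
            "cdr3_aa": _translate(ann.cdr3_seq) if ann.cdr3_seq else "",
            "shm_count_vframe": sum(1 for p in flat
                                    if cdr3_start and p < cdr3_start),
            "shm_count_cdr3": sum(1 for p in flat
                                  if cdr3_start and p >= cdr3_start),
            "productive": ann.productive,
            "status": ann.status,
        })
    return pd.DataFrame(rows)


def write_annotation_table(annotations, clusters, path) -> None:
    annotation_table(annotations, clusters).to_csv(path, sep="\t", index=False)


def tree_to_newick(tree: LineageTree) -> str:
    """Newick string with SHM distances as branch lengths, ids as labels."""
    def fmt(node: str) -> str:
        kids = tree.children(node)
        label = node
        if not kids:
            return label
        return "(" + ",".join(
            f"{fmt(c)}:{tree.parent[c][1]:g}" for c in kids) + ")" + label
    return fmt(tree.root) + ";"


def tree_to_table(cluster: CloneCluster) -> pd.DataFrame:
    rows = []
    for mid in cluster.ids:
        parent, dist = cluster.tree.parent.get(mid, ("", ""))
        ann = cluster.member(mid).annotation
        rows.append({"child_id": mid, "parent_id": parent, "distance": dist,
                     "template_count": cluster.member(mid).template_count,
                     "cdr3": ann.cdr3_seq or ""})
    return pd.DataFrame(rows)


def export_tree(cluster: CloneCluster, fmt: str = "newick"):
    if fmt == "newick":
        return tree_to_newick(cluster.tree)
    if fmt == "tabular":
        return tree_to_table(cluster)
    raise ValueError(f"unknown tree format {fmt!r}")


def tree_from_table(table: pd.DataFrame) -> LineageTree:
    """Rebuild a bare lineage tree from the tabular export (round-trip)."""
    from .annotate import Annotation
    members = {}
    parent = {}
    root = None
    for _, row in table.iterrows():
        mid = str(row["child_id"])
        members[mid] = Member(id=mid,
                              annotation=Annotation(read_id=mid, sequence="N"),
                              template_count=int(row["template_count"]))
        if row["parent_id"] in ("", None) or pd.isna(row["parent_id"]):
            root = mid
        else:
            parent[mid] = (str(row["parent_id"]), float(row["distance"]))
    return LineageTree(members=members, root=root, parent=parent)
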