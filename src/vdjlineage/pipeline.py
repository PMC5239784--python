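"""End-to-end pipeline: annotate reads, cluster, build trees, refine."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .annotate import Annotation, AnnotationConfig, annotate_sequence
from .germline import GermlineDatabase
from .junction import DEFAULT_TDT, RefineConfig, TDTModel, refine_cluster
from .lineage import (DEFAULT_SHM_PARAMS, CloneCluster, Member,
                      ShmDistanceParams, build_forest, coarse_group,
                      merge_clusters, reroot_cluster, unify_annotations)


@dataclass
class PipelineConfig:
    annotation: AnnotationConfig = field(default_factory=AnnotationConfig)
    shm_params: ShmDistanceParams = field(default_factory=lambda: DEFAULT_SHM_PARAMS)
    tdt: TDTModel = field(default_factory=lambda: DEFAULT_TDT)
    refine: RefineConfig = field(default_factory=RefineConfig)
    cutoff_fraction: float = 0.03
    run_refinement: bool = True


@dataclass
class PipelineResult:
    annotations: list          # every input, failures included
    clusters: list             # CloneCluster per final tree

    @property
    def ok_annotations(self) -> list:
        return [a for a in self.annotations if a.ok]


def run_pipeline(records, db: GermlineDatabase,
                 config: Optional[PipelineConfig] = None) -> PipelineResult:
    """Annotate, cluster, assemble lineage trees, and refine junctions.

    ``records`` is an iterable of objects with ``id``, ``sequence`` and
    optionally ``template_count``.  Reads failing V or J annotation stay
    in the output with a status and are excluded from clustering.
    """
    config = config or PipelineConfig()
    annotations: list[Annotation] = []
    members: list[Member] = []
    for rec in records:
        ann = annotate_sequence(rec.id, rec.sequence, db, config.annotation)
        annotations.append(ann)
        if ann.ok and ann.cdr3_span is not None:
            members.append(Member(id=rec.id, annotation=ann,
                                  template_count=getattr(rec, "template_count", 1)))

    trees = []
    for key, group in sorted(coarse_group(members).items(),
                             key=lambda kv: str(kv[0])):
        if key is None:
            # reads without a CDR3 call: singletons, never clustered
            for m in group:
                trees.extend(build_forest([m], config.shm_params))
            continue
        trees.extend(build_forest(group, config.shm_params))
    trees = merge_clusters(trees, config.cutoff_fraction, config.shm_params)

    clusters = []
    for tree in trees:
        cluster = unify_annotations(CloneCluster(tree=tree), db)
        cluster = reroot_cluster(cluster, db)
        if config.run_refinement:
            cluster = refine_cluster(
                cluster, db, config.tdt,
                allow_inverted=config.annotation.allow_inverted_d,
                cfg=config.refine)
        clusters.append(cluster)
    clusters.sort(key=lambda c: c.root)
    return PipelineResult(annotations=annotations, clusters=clusters)
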