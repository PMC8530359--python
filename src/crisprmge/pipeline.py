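"""End-to-end orchestration of the discovery pipeline.

Contigs + reads in; deduplicated terminally redundant (TR) records with
metrics, host calls and PAM profiles out.  Each stage is the
corresponding module function with its default thresholds; all
parameters can be overridden through ``PipelineParams``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from . import clustering, crispr, hostpam, metrics, protospacer, targets
from .seqcore import SeqRecord


@dataclass
class PipelineParams:
    min_copies: int = 3
    repeat_len: tuple[int, int] = (23, 55)
    spacer_len: tuple[int, int] = (20, 60)
    min_dr_match_len: int = 18
    read_mask_mismatch: int = 1
    map_min_identity: float = 0.93
    mask_flank: int = 60
    flank_ratio_cutoff: float = 0.5
    locus_cluster_gap: int = 50_000
    mcl_inflation: float = 4.0
    mcl_pre_inflation: float = 0.4
    cluster_min_size: int = 10
    cluster_min_gcc: float = 0.5
    region_min_fraction: float = 0.30
    region_join_gap: int = 1000
    min_tr: int = 20
    max_tr_fraction: float = 0.5
    dedup_min_identity: float = 0.95
    dedup_min_coverage: float = 0.95


@dataclass
class PipelineResult:
    arrays: list[crispr.CrisprArray]
    drs: list[crispr.DirectRepeat]
    spacers: list[crispr.Spacer]
    loci: list[protospacer.ProtospacerLocus]          # all candidates
    masked: protospacer.MaskedContigSet
    locus_clusters: list[clustering.LocusCluster]
    spacer_clusters: list[clustering.SpacerCluster]
    regions: list[targets.TargetRegion]
    tr_records: list[targets.TRRecord]                 # deduplicated
    linear_records: list[SeqRecord]
    record_metrics: dict[str, metrics.RecordMetrics] = field(default_factory=dict)

    @property
    def validated_loci(self) -> list[protospacer.ProtospacerLocus]:
        return [l for l in self.loci if l.validated]


def run_pipeline(contigs: list[SeqRecord], reads: list[SeqRecord],
                 params: PipelineParams | None = None,
                 compute_metrics: bool = True) -> PipelineResult:
    p = params or PipelineParams()

    arrays = [a for c in contigs
              for a in crispr.detect_arrays(c, p.min_copies, p.repeat_len,
                                            p.spacer_len)]
    drs = crispr.collect_drs(arrays)
    spacers = crispr.extract_all_spacers(reads, drs, p.min_dr_match_len,
                                         p.read_mask_mismatch, p.spacer_len)

    loci, masked = protospacer.find_protospacers(
        spacers, contigs, drs, p.map_min_identity, p.mask_flank,
        p.flank_ratio_cutoff)
    validated = [l for l in loci if l.validated]

    locus_clusters = clustering.cluster_loci(validated, p.locus_cluster_gap)
    graph = clustering.build_graph(locus_clusters)
    partition = clustering.markov_cluster(graph, p.mcl_inflation,
                                          p.mcl_pre_inflation)
    spacer_clusters = clustering.filter_clusters(
        partition, graph, locus_clusters, p.cluster_min_size, p.cluster_min_gcc)

    regions: list[targets.TargetRegion] = []
    for sc in spacer_clusters:
        marked = targets.mark_regions(sc, validated, p.region_min_fraction)
        regions.extend(targets.join_regions(marked, p.region_join_gap))

    tr_records, linear = targets.make_tr_records(
        regions, contigs, validated, p.min_tr, p.max_tr_fraction)
    tr_records = targets.dedup_circular(tr_records, p.dedup_min_identity,
                                        p.dedup_min_coverage)

    result = PipelineResult(
        arrays=arrays, drs=drs, spacers=spacers, loci=loci, masked=masked,
        locus_clusters=locus_clusters, spacer_clusters=spacer_clusters,
        regions=regions, tr_records=tr_records, linear_records=linear)
    if compute_metrics:
        for rec in tr_records:
            result.record_metrics[rec.tr_id] = metrics.compute_metrics(
                rec.tr_id, rec.circular_seq)
    return result


def record_loci(result: PipelineResult, record: targets.TRRecord,
                ) -> list[protospacer.ProtospacerLocus]:
    """Validated loci lying within a TR record's source region."""
    iv = record.source
    return [l for l in result.validated_loci
            if l.interval.contig_id == iv.contig_id
            and l.interval.start >= iv.start and l.interval.end <= iv.end]


def call_hosts(result: PipelineResult, ref_genomes: list[SeqRecord],
               lineages: dict[str, hostpam.Lineage], rank: str = "phylum",
               min_identity: float = 0.9) -> dict[str, hostpam.HostCall]:
    """Targeting-host call per deduplicated TR record at one rank."""
    taxonomies = hostpam.assign_dr_taxonomy(result.drs, ref_genomes,
                                            lineages, min_identity)
    return {rec.tr_id: hostpam.call_host(rec.tr_id, record_loci(result, rec),
                                         taxonomies, rank)
            for rec in result.tr_records}


def infer_pams(result: PipelineResult, contigs: list[SeqRecord],
               ) -> dict[str, tuple[hostpam.PamProfile, hostpam.PamProfile]]:
    seqs = {c.id: c.seq for c in contigs}
    return {rec.tr_id: hostpam.infer_pam(rec.tr_id,
                                         record_loci(result, rec), seqs)
            for rec in result.tr_records}
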