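"""End-to-end orchestration: read filtering, anchoring, clustering, calling.

``run_search`` is the full caller on an in-memory read stream; it is
deterministic for fixed inputs and configuration.  ``run_benchmark``
reproduces the synthetic-insertion sensitivity experiment end to end:
generate a reference, plant inverted-template insertions, simulate
paired-end reads, run the search and score recall against the truth
manifest.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable

from .align import AnchoredRead, ReferenceIndex, align_read, split_and_anchor
from .call import (
    MMBTICall,
    SearchConfig,
    classify_event,
    extract_variant,
    find_template,
    flag_clonality,
)
from .cluster import Cluster, ConsensusContig, build_consensus, cluster_anchored, merge_LR
from .compare import EvaluationResult, score_against_truth
from .io import ReadRecord, ReferenceGenome, passes_dust
from .junction import junctions_for_call
from .simulate import (
    SimConfig,
    TruthRecord,
    make_random_reference,
    plant_insertions,
    simulate_reads,
)

logger = logging.getLogger("mmbti")


@dataclass(slots=True)
class StageCounts:
    reads_in: int = 0
    too_short: int = 0
    dust_filtered: int = 0
    mapped: int = 0
    unmapped: int = 0
    anchored: int = 0
    anchor_both_mapped: int = 0
    anchor_none_mapped: int = 0
    anchor_ambiguous: int = 0
    clusters: int = 0
    clusters_below_min: int = 0
    clusters_accepted: int = 0
    calls: int = 0
    calls_by_class: dict = field(default_factory=dict)

    def check_conservation(self) -> None:
        assert (
            self.reads_in
            == self.too_short + self.dust_filtered + self.mapped + self.unmapped
        ), "read accounting broken"
        assert self.anchored <= self.unmapped, "anchors exceed unmapped reads"


@dataclass(slots=True)
class SearchResult:
    calls: list[MMBTICall]
    counts: StageCounts
    clusters: list[Cluster]
    contigs: list[ConsensusContig]


def _calls_from_cluster(
    cluster: Cluster,
    ref: ReferenceGenome,
    cfg: SearchConfig,
    avg_coverage: float,
) -> tuple[list[MMBTICall], list[ConsensusContig]]:
    contigs: list[ConsensusContig] = []
    candidates: list[ConsensusContig] = []
    if cluster.pattern == "LR":
        left = build_consensus(cluster, "L")
        right = build_consensus(cluster, "R")
        if left is None or right is None:
            return [], []
        contigs.extend([left, right])
        merged = merge_LR(left, right)
        if merged is not None:
            contigs.append(merged)
            candidates.append(merged)
        else:  # unmerged breakpoint pair: report each side
            candidates.extend([left, right])
    elif cluster.pattern in ("L_only", "R_only"):
        side = cluster.pattern[0]
        contig = build_consensus(cluster, side)
        if contig is None:
            return [], []
        contigs.append(contig)
        candidates.append(contig)
    else:
        return [], []

    calls: list[MMBTICall] = []
    for cand in candidates:
        extracted = extract_variant(
            cand, ref, cluster.contig, cfg.min_len, cfg.template_window
        )
        if extracted is None:
            continue
        left_bp, right_bp, ins, one_sided = extracted
        call = MMBTICall(
            contig=cluster.contig,
            left_bp=left_bp,
            right_bp=right_bp,
            ins_seq=ins,
            support=cluster.size,
            one_sided=one_sided,
        )
        find_template(call, ref, cfg)
        call.event_class = classify_event(call, ref)
        call.junctions = junctions_for_call(call, ref)
        call.subclonal = flag_clonality(
            call.support, avg_coverage, cfg.subclonal_fraction
        )
        calls.append(call)
    return calls, contigs


def run_search(
    reads: Iterable[ReadRecord],
    ref: ReferenceGenome,
    cfg: SearchConfig | None = None,
) -> SearchResult:
    """Run the full templated-insertion search over a read stream."""
    cfg = cfg or SearchConfig()
    counts = StageCounts()
    index = ReferenceIndex(ref)
    min_read_len = 2 * index.seed_len

    unmapped: list[ReadRecord] = []
    total_bases = 0
    for read in reads:
        counts.reads_in += 1
        total_bases += len(read.seq)
        if len(read.seq) < min_read_len:
            counts.too_short += 1
            continue
        if not passes_dust(read.seq, cfg.dust_threshold):
            counts.dust_filtered += 1
            continue
        aln = align_read(read, index, cfg.max_err, fast=True)
        if aln is not None:
            counts.mapped += 1
        else:
            counts.unmapped += 1
            unmapped.append(read)
    logger.info(
        "reads: %d in, %d short, %d dust-filtered, %d mapped, %d unmapped",
        counts.reads_in, counts.too_short, counts.dust_filtered,
        counts.mapped, counts.unmapped,
    )

    anchors: list[AnchoredRead] = []
    read_len = 0
    for read in unmapped:
        read_len = max(read_len, len(read.seq))
        anchored, reason = split_and_anchor(read, index, cfg.max_err)
        if anchored is not None:
            anchors.append(anchored)
            counts.anchored += 1
        elif reason == "both_mapped":
            counts.anchor_both_mapped += 1
        elif reason == "none_mapped":
            counts.anchor_none_mapped += 1
        else:
            counts.anchor_ambiguous += 1
    logger.info("anchored %d of %d unmapped reads", counts.anchored, counts.unmapped)

    genome_len = sum(ref.lengths.values())
    avg_coverage = cfg.avg_coverage or (total_bases / genome_len if genome_len else 1.0)

    clusters, below = cluster_anchored(
        anchors, cfg.min_cluster_size, link_dist=read_len or 125
    )
    counts.clusters = len(clusters) + below
    counts.clusters_below_min = below
    counts.clusters_accepted = sum(1 for c in clusters if c.pattern != "rejected")

    calls: list[MMBTICall] = []
    all_contigs: list[ConsensusContig] = []
    for cluster in clusters:
        if cluster.pattern == "rejected":
            continue
        cluster_calls, contigs = _calls_from_cluster(cluster, ref, cfg, avg_coverage)
        calls.extend(cluster_calls)
        all_contigs.extend(contigs)
    calls.sort(key=lambda c: (c.contig, c.left_bp, c.right_bp, c.ins_seq))
    counts.calls = len(calls)
    for c in calls:
        counts.calls_by_class[c.event_class] = (
            counts.calls_by_class.get(c.event_class, 0) + 1
        )
    counts.check_conservation()
    logger.info("%d clusters accepted, %d calls: %s",
                counts.clusters_accepted, counts.calls, counts.calls_by_class)
    return SearchResult(calls, counts, clusters, all_contigs)


# ---------------------------------------------------------------------------
# Self-contained sensitivity benchmark
# ---------------------------------------------------------------------------

@dataclass(slots=True)
class BenchmarkConfig:
    """Synthetic-insertion sensitivity benchmark (desk-scale defaults)."""

    ref_length: int = 2_000_000
    n_insertions: int = 50
    size_range: tuple[int, int] = (20, 50)
    mode: str = "append"
    template_offset: int = 80
    gc: float = 0.41
    seed: int = 1
    sim: SimConfig = None  # defaults derived from seed when None
    search: SearchConfig = None

    def __post_init__(self) -> None:
        if self.sim is None:
            self.sim = SimConfig(seed=self.seed)
        if self.search is None:
            # benchmark regime: minimum event length 6, cluster of >= 3 reads
            self.search = SearchConfig(min_len=6, min_cluster_size=3)


@dataclass(slots=True)
class BenchmarkResult:
    evaluation: EvaluationResult
    truth: list[TruthRecord]
    search: SearchResult
    total_reads: int


def run_benchmark(cfg: BenchmarkConfig | None = None) -> BenchmarkResult:
    """Generate, plant, simulate, search and score; fully seeded."""
    cfg = cfg or BenchmarkConfig()
    ref = make_random_reference(cfg.ref_length, cfg.gc, seed=cfg.seed)
    mutated, truth = plant_insertions(
        ref,
        cfg.n_insertions,
        cfg.size_range,
        mode=cfg.mode,
        template_offset=cfg.template_offset,
        seed=cfg.seed + 1,
    )
    if cfg.search.avg_coverage is None:
        cfg.search.avg_coverage = cfg.sim.depth
    reads = simulate_reads(mutated, cfg.sim)
    result = run_search(reads, ref, cfg.search)
    evaluation = score_against_truth(result.calls, truth)
    return BenchmarkResult(
        evaluation=evaluation,
        truth=truth,
        search=result,
        total_reads=result.counts.reads_in,
    )
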