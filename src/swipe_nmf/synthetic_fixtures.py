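"""Synthetic genomes and evidence with planted latent structure.

The generator emulates the shape of the real inputs — six segment types on
a chromosome tiled by TADs, with binary pairwise evidence from four sources
— while planting a known low-rank structure: every segment carries a latent
cluster label correlated with its TAD, and evidence between two segments is
emitted with a probability set by their cluster pair (block-diagonal
affinity by default), then flipped with a symmetric noise rate.  Evidence is
only emitted between segments within ``max_pair_distance`` of each other, so
planted pairs are always co-resident in at least one sliding window.

Statistic columns are drawn so that the load-time significance filters
retain exactly the emitted rows at default thresholds (e.g. Hi-C q-values
are sampled strictly below 1e-3).

What the generator does *not* emulate: genomic distance decay of contact
probability, segment length heterogeneity of real annotations, and
unbalanced cluster sizes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .core_model import (
    FusionProblem,
    GenomicSegment,
    RelationKind,
    RelationMatrix,
    SegmentCatalog,
    SegmentType,
    assemble_block_problem,
)
from .io_formats import EvidenceTable, StatKind
from .windowed_pipeline import TissueInputs

E = SegmentType.ENHANCER
P = SegmentType.PROMOTER
ANCHOR = SegmentType.HIC_ANCHOR
SNP = SegmentType.EQTL_SNP
DHS = SegmentType.DHS
TAD = SegmentType.TAD


@dataclass
class PlantedModel:
    """Parameters of the planted-structure generator.

    Defaults describe a desk-scale tissue: one 10 Mb chromosome, six TADs,
    three latent clusters, 200 enhancers and 100 promoters, 10% evidence
    noise.  ``tad_cluster_fidelity`` is the probability a segment adopts its
    TAD's cluster rather than a random one, tying latent structure to
    genomic domains.
    """

    chrom: str = "chr1"
    chrom_length: int = 10_000_000
    n_tads: int = 6
    n_clusters: int = 3
    n_enhancers: int = 200
    n_promoters: int = 100
    n_anchors: int = 60
    n_snps: int = 120
    n_dhs: int = 120
    enhancer_length: int = 1_000
    promoter_length: int = 1_500
    anchor_length: int = 40_000
    dhs_length: int = 300
    p_within: float = 0.3
    p_between: float = 0.0
    noise: float = 0.1
    tad_cluster_fidelity: float = 0.9
    snp_in_enhancer: float = 0.7
    dhs_on_enhancer: float = 0.7
    max_pair_distance: int = 2_000_000
    seed: int = 0

    def affinity(self, c_a: int, c_b: int) -> float:
        return self.p_within if c_a == c_b else self.p_between


ClusterLabels = Dict[Tuple[SegmentType, str], int]


def _place(
    rng: np.random.Generator, model: PlantedModel, n: int, length: int,
    seg_type: SegmentType, prefix: str,
) -> List[GenomicSegment]:
    starts = rng.integers(0, model.chrom_length - length, size=n)
    return [
        GenomicSegment(model.chrom, int(s), int(s) + length, seg_type, f"{prefix}{i:05d}")
        for i, s in enumerate(np.sort(starts))
    ]


def generate_genome(model: PlantedModel) -> Tuple[SegmentCatalog, ClusterLabels]:
    """Segment catalog (TADs included) plus the planted cluster label of
    every segment.

    TADs tile the chromosome in equal non-overlapping intervals and carry
    cluster labels in round-robin order; other segments land uniformly and
    adopt their TAD's cluster with probability ``tad_cluster_fidelity``.
    SNPs and DHS sites are preferentially co-located with enhancers (a SNP
    inside / a DHS overlapping a host enhancer inherits its cluster),
    mirroring cis-variants and open chromatin at regulatory elements.
    """
    rng = np.random.default_rng(model.seed)
    labels: ClusterLabels = {}
    segments: List[GenomicSegment] = []

    bounds = np.linspace(0, model.chrom_length, model.n_tads + 1).astype(int)
    tad_cluster = {}
    for t in range(model.n_tads):
        seg = GenomicSegment(model.chrom, int(bounds[t]), int(bounds[t + 1]), TAD, f"TAD{t:03d}")
        segments.append(seg)
        tad_cluster[t] = t % model.n_clusters
        labels[(TAD, seg.id)] = tad_cluster[t]

    def tad_of(pos: float) -> int:
        return min(int(pos * model.n_tads // model.chrom_length), model.n_tads - 1)

    def assign_cluster(seg: GenomicSegment) -> int:
        base = tad_cluster[tad_of(seg.midpoint)]
        if rng.random() < model.tad_cluster_fidelity:
            return base
        return int(rng.integers(model.n_clusters))

    enhancers = _place(rng, model, model.n_enhancers, model.enhancer_length, E, "E")
    promoters = _place(rng, model, model.n_promoters, model.promoter_length, P, "Pr")
    anchors = _place(rng, model, model.n_anchors, model.anchor_length, ANCHOR, "A")
    for group in (enhancers, promoters, anchors):
        for seg in group:
            labels[(seg.type, seg.id)] = assign_cluster(seg)
        segments.extend(group)

    # SNPs: mostly inside enhancers (inheriting the host's cluster)
    for i in range(model.n_snps):
        if enhancers and rng.random() < model.snp_in_enhancer:
            host = enhancers[int(rng.integers(len(enhancers)))]
            pos = int(rng.integers(host.start, host.end))
            seg = GenomicSegment(model.chrom, pos, pos + 1, SNP, f"S{i:05d}")
            labels[(SNP, seg.id)] = labels[(E, host.id)]
        else:
            pos = int(rng.integers(0, model.chrom_length - 1))
            seg = GenomicSegment(model.chrom, pos, pos + 1, SNP, f"S{i:05d}")
            labels[(SNP, seg.id)] = assign_cluster(seg)
        segments.append(seg)

    # DHS sites: mostly overlapping enhancers
    for i in range(model.n_dhs):
        if enhancers and rng.random() < model.dhs_on_enhancer:
            host = enhancers[int(rng.integers(len(enhancers)))]
            start = int(rng.integers(host.start, host.end))
            seg = GenomicSegment(
                model.chrom, start, start + model.dhs_length, DHS, f"D{i:05d}"
            )
            labels[(DHS, seg.id)] = labels[(E, host.id)]
        else:
            start = int(rng.integers(0, model.chrom_length - model.dhs_length))
            seg = GenomicSegment(
                model.chrom, start, start + model.dhs_length, DHS, f"D{i:05d}"
            )
            labels[(DHS, seg.id)] = assign_cluster(seg)
        segments.append(seg)

    return SegmentCatalog("synthetic", segments), labels


def _emit_pairs(
    rng: np.random.Generator,
    model: PlantedModel,
    segs_a: Sequence[GenomicSegment],
    segs_b: Sequence[GenomicSegment],
    labels: ClusterLabels,
    same_type: bool,
) -> List[Tuple[GenomicSegment, GenomicSegment]]:
    """Bernoulli emission by cluster affinity, then symmetric noise flips,
    restricted to pairs within ``max_pair_distance``."""
    out = []
    for ia, a in enumerate(segs_a):
        b_iter = segs_b[ia + 1:] if same_type else segs_b
        for b in b_iter:
            if abs(a.midpoint - b.midpoint) > model.max_pair_distance:
                continue
            p = model.affinity(labels[(a.type, a.id)], labels[(b.type, b.id)])
            present = rng.random() < p
            if rng.random() < model.noise:
                present = not present
            if present:
                out.append((a, b))
    return out


def _table(
    source_kind: str,
    stat_kind: StatKind,
    pairs: Sequence[Tuple[GenomicSegment, GenomicSegment]],
    stats: Optional[np.ndarray],
) -> EvidenceTable:
    rows = pd.DataFrame(
        {
            "chrom_a": [a.chrom for a, _ in pairs],
            "start_a": [a.start for a, _ in pairs],
            "end_a": [a.end for a, _ in pairs],
            "chrom_b": [b.chrom for _, b in pairs],
            "start_b": [b.start for _, b in pairs],
            "end_b": [b.end for _, b in pairs],
            "stat": stats if stats is not None else np.full(len(pairs), np.nan),
        }
    )
    return EvidenceTable(source_kind=source_kind, stat_kind=stat_kind, rows=rows)


def generate_evidence(
    model: PlantedModel, catalog: SegmentCatalog, labels: ClusterLabels
) -> Dict[str, EvidenceTable]:
    """Evidence tables for the four sources, driven by the planted clusters.

    Statistic columns pass the default load-time thresholds for every
    emitted row (strictly inside the significant range).
    """
    rng = np.random.default_rng([model.seed, 1])
    enh = catalog.segments_of(E)
    pro = catalog.segments_of(P)
    anchors = catalog.segments_of(ANCHOR)
    snps = catalog.segments_of(SNP)
    dhs = catalog.segments_of(DHS)

    coact = _emit_pairs(rng, model, enh, pro, labels, same_type=False)
    hic = _emit_pairs(rng, model, anchors, anchors, labels, same_type=True)
    eqtl = _emit_pairs(rng, model, snps, pro, labels, same_type=False)
    dhsc = _emit_pairs(rng, model, dhs, pro, labels, same_type=False)

    return {
        "coactivity": _table("coactivity", StatKind.NONE, coact, None),
        "hic": _table(
            "hic", StatKind.QVALUE, hic, 10.0 ** rng.uniform(-6, -3.05, len(hic))
        ),
        "eqtl": _table(
            "eqtl", StatKind.PVALUE, eqtl, 10.0 ** rng.uniform(-8, -5.05, len(eqtl))
        ),
        "dhs_corr": _table(
            "dhs_corr", StatKind.SCORE, dhsc, rng.uniform(0.905, 0.999, len(dhsc))
        ),
    }


def make_noise_evidence(
    model: PlantedModel,
    catalog: SegmentCatalog,
    density: float = 0.03,
    seed: Optional[int] = None,
    window_size: int = 5_000_000,
    step: int = 2_500_000,
    exclude: Optional[set] = None,
) -> EvidenceTable:
    """A pure-noise E-P source: uniform pairs independent of the clusters.

    Pairs are drawn uniformly from the co-window frame (both segments share
    at least one sliding window) — the same frame negative pairs are sampled
    from in evaluation — minus any pair in ``exclude`` (typically the pairs
    touched by the informative sources).  Held-out-null evaluation then
    compares two samples from one exchangeable frame, which is the property
    that makes it a null: a noise source with a different distance
    composition, or one overlapping real evidence, would confound the
    calibration with the score-vs-distance profile or with genuine
    cross-source redundancy.
    """
    from .windowed_pipeline import make_windows

    rng = np.random.default_rng([model.seed if seed is None else seed, 99])
    windows = make_windows({model.chrom: model.chrom_length}, window_size, step)
    cowindow = set()
    for w in windows:
        wcat = catalog.restrict_to_window(w)
        for a in wcat.segments_of(E):
            for b in wcat.segments_of(P):
                cowindow.add((a.id, b.id))
    if exclude:
        cowindow -= set(exclude)
    pairs = [
        (catalog.get(E, ia), catalog.get(P, ib))
        for ia, ib in sorted(cowindow)
        if rng.random() < density
    ]
    return _table("noise", StatKind.NONE, pairs, None)


def make_inputs(
    model: PlantedModel, extra_sources: Optional[Dict[str, EvidenceTable]] = None
) -> Tuple[TissueInputs, ClusterLabels]:
    """Convenience: genome + evidence bundled as pipeline-ready inputs."""
    catalog, labels = generate_genome(model)
    evidence = generate_evidence(model, catalog, labels)
    if extra_sources:
        evidence.update(extra_sources)
    inputs = TissueInputs(
        catalog=catalog,
        evidence=evidence,
        chrom_lengths={model.chrom: model.chrom_length},
    )
    return inputs, labels


def random_problem(
    seed: int,
    n_per_type: Tuple[int, ...] = (30, 20),
    density: float = 0.15,
    with_theta: bool = True,
) -> FusionProblem:
    """A random binary block system for solver stress tests.

    Types are taken in enum order; every ordered distinct type pair gets a
    random sparse binary R block, and the first two types get random
    attractive Theta blocks when ``with_theta``.
    """
    rng = np.random.default_rng(seed)
    types = list(SegmentType)[: len(n_per_type)]
    segments = []
    for t, n in zip(types, n_per_type):
        for i in range(n):
            start = 1000 * i
            segments.append(
                GenomicSegment("chrZ", start, start + 500, t, f"{t.short}{i:04d}")
            )
    catalog = SegmentCatalog("random", segments)
    relations = []
    for ai, a in enumerate(types):
        for b in types[ai + 1:]:
            data = (rng.random((catalog.count(a), catalog.count(b))) < density).astype(float)
            relations.append(
                RelationMatrix(type_i=a, type_j=b, data=data, kind=RelationKind.INTERACTION)
            )
    constraints = []
    if with_theta:
        import scipy.sparse as sp

        for t in types[:2]:
            n = catalog.count(t)
            mask = rng.random((n, n)) < 0.05
            theta = sp.csr_matrix(-mask.astype(float))
            from .core_model import ConstraintMatrix

            constraints.append(ConstraintMatrix(seg_type=t, data=theta))
    return assemble_block_problem(catalog, relations, constraints)


def planted_partition_problem(
    n_rows: int = 20,
    n_cols: int = 15,
    n_clusters: int = 3,
    seed: int = 12345,
) -> Tuple[FusionProblem, np.ndarray, np.ndarray]:
    """An exactly tri-factorizable two-type problem.

    Rows and columns are partitioned into ``n_clusters`` groups and
    R = Z_r Z_c^T for the indicator matrices, i.e. a block matrix of ones —
    binary and exactly factorizable at rank ``n_clusters`` with S = I.
    Returns (problem, row labels, column labels).
    """
    rng = np.random.default_rng(seed)
    row_labels = np.sort(rng.integers(0, n_clusters, size=n_rows))
    col_labels = np.sort(rng.integers(0, n_clusters, size=n_cols))
    # guarantee every cluster occupied on both sides
    row_labels[:n_clusters] = np.arange(n_clusters)
    col_labels[:n_clusters] = np.arange(n_clusters)
    r = (row_labels[:, None] == col_labels[None, :]).astype(float)
    segments = [
        GenomicSegment("chrZ", 1000 * i, 1000 * i + 500, E, f"e{i:04d}")
        for i in range(n_rows)
    ] + [
        GenomicSegment("chrZ", 1000 * j, 1000 * j + 500, P, f"p{j:04d}")
        for j in range(n_cols)
    ]
    catalog = SegmentCatalog("planted", segments)
    rel = RelationMatrix(type_i=E, type_j=P, data=r, kind=RelationKind.INTERACTION)
    return assemble_block_problem(catalog, [rel]), row_labels, col_labels


def golden_small_problem() -> Tuple[FusionProblem, np.ndarray, np.ndarray]:
    """The fixed 20 x 15 rank-3 exactly factorizable regression problem."""
    return planted_partition_problem(n_rows=20, n_cols=15, n_clusters=3, seed=12345)
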