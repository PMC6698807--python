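"""Comparison predictors sharing the factorization pipeline's inputs.

Four baselines: (1) concatenation — the mean of per-source normalized 0/1
evidence over the enhancer-promoter pair grid; (2) nearest-promoter
assignment; (3) coactivity links alone; (4) similarity network fusion (SNF)
over the unified enhancer+promoter node set, run without any local
neighborhood restriction.  All emit the same :class:`ScoredNetwork` shape
consumed by the evaluation protocols.
"""

from __future__ import annotations

import logging
import warnings
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np

from .core_model import NetworkKind, ScoredNetwork, SegmentCatalog, SegmentType
from .io_formats import EvidenceTable
from .network_builder import _evidence_pairs
from .windowed_pipeline import TissueInputs

logger = logging.getLogger(__name__)

E = SegmentType.ENHANCER
P = SegmentType.PROMOTER

#: sources whose rows can be mapped to an enhancer on one side and a
#: promoter on the other (directly or through the segment the row touches).
EP_MAPPABLE = ("coactivity", "hic", "eqtl", "dhs_corr")


def _ep_pair_set(
    evidence: EvidenceTable, catalog: SegmentCatalog
) -> Set[Tuple[int, int]]:
    return _evidence_pairs(evidence, catalog, E, P)


def baseline_concatenation(
    inputs: TissueInputs, sources: Sequence[str] = EP_MAPPABLE
) -> ScoredNetwork:
    """Mean of per-source 0/1 indicators on the E-P pair grid.

    Binary indicators are already min-max normalized, so the score of a pair
    is (number of sources containing it) / (number of sources used).
    """
    used = [s for s in sources if s in inputs.evidence]
    if not used:
        raise ValueError("no mappable evidence sources available")
    cat = inputs.catalog
    counts: Dict[Tuple[int, int], int] = {}
    for s in used:
        for pair in _ep_pair_set(inputs.evidence[s], cat):
            counts[pair] = counts.get(pair, 0) + 1
    enh = cat.segments_of(E)
    pro = cat.segments_of(P)
    edges = [
        (enh[p].id, pro[q].id, c / len(used)) for (p, q), c in sorted(counts.items())
    ]
    return ScoredNetwork(NetworkKind.EP, cat.tissue_id, edges, catalog=cat)


def baseline_nearest_promoter(catalog: SegmentCatalog) -> ScoredNetwork:
    """Link each enhancer to its nearest same-chromosome promoter (score 1).

    Distance is between interval midpoints; ties break to the promoter with
    the smaller catalog ordinal.  Enhancers on chromosomes without a promoter
    are left unlinked (logged).
    """
    promoters = catalog.segments_of(P)
    by_chrom: Dict[str, List[Tuple[float, int]]] = {}
    for q, seg in enumerate(promoters):
        by_chrom.setdefault(seg.chrom, []).append((seg.midpoint, q))
    edges = []
    n_unlinked = 0
    for enh in catalog.segments_of(E):
        cands = by_chrom.get(enh.chrom)
        if not cands:
            n_unlinked += 1
            continue
        best_q = min(cands, key=lambda c: (abs(c[0] - enh.midpoint), c[1]))[1]
        edges.append((enh.id, promoters[best_q].id, 1.0))
    if n_unlinked:
        logger.info("%d enhancers on promoter-less chromosomes left unlinked", n_unlinked)
    return ScoredNetwork(NetworkKind.EP, catalog.tissue_id, edges, catalog=catalog)


def baseline_coactivity(inputs: TissueInputs) -> ScoredNetwork:
    """The enhancer-promoter coactivity links alone, each with score 1."""
    if "coactivity" not in inputs.evidence:
        raise ValueError("no coactivity evidence available")
    cat = inputs.catalog
    enh = cat.segments_of(E)
    pro = cat.segments_of(P)
    edges = [
        (enh[p].id, pro[q].id, 1.0)
        for p, q in sorted(_ep_pair_set(inputs.evidence["coactivity"], cat))
    ]
    return ScoredNetwork(NetworkKind.EP, cat.tissue_id, edges, catalog=cat)


def snf_normalize(mat: np.ndarray) -> np.ndarray:
    """Row normalization of one similarity matrix.

    Off-diagonal entries become P(x,y) / (2 * sum_{k != x} P(x,k)); the
    diagonal is fixed at 1/2.  A row with zero off-diagonal mass is left as
    diagonal-only (warned about once per call).
    """
    n = mat.shape[0]
    off = mat.copy()
    np.fill_diagonal(off, 0.0)
    row_sums = off.sum(axis=1)
    out = np.zeros_like(mat, dtype=float)
    zero_rows = row_sums == 0
    safe = np.where(zero_rows, 1.0, row_sums)
    out = off / (2.0 * safe[:, None])
    np.fill_diagonal(out, 0.5)
    if zero_rows.any():
        warnings.warn(
            f"{int(zero_rows.sum())} nodes have no neighbors; "
            "their rows stay diagonal-only"
        )
    return out


def _unified_adjacency(
    evidence: EvidenceTable, catalog: SegmentCatalog
) -> np.ndarray:
    """Symmetric 0/1 adjacency on the enhancer+promoter node set implied by
    one source: every row joins all enhancer/promoter segments overlapping
    its two sides (nodes of other types are projected through overlap)."""
    n_e = catalog.count(E)
    n_p = catalog.count(P)
    n = n_e + n_p
    adj = np.zeros((n, n))

    def nodes(pairs_ep, off_i, off_j):
        for p, q in pairs_ep:
            adj[off_i + p, off_j + q] = 1.0
            adj[off_j + q, off_i + p] = 1.0

    nodes(_evidence_pairs(evidence, catalog, E, P), 0, n_e)
    nodes(_evidence_pairs(evidence, catalog, E, E), 0, 0)
    nodes(_evidence_pairs(evidence, catalog, P, P), n_e, n_e)
    np.fill_diagonal(adj, 0.0)
    return adj


def baseline_snf(
    inputs: TissueInputs,
    sources: Sequence[str] = EP_MAPPABLE,
    iterations: int = 20,
) -> ScoredNetwork:
    """Similarity network fusion over enhancer+promoter nodes.

    Each source's network is normalized, then cross-diffused for ``iterations``
    steps: P_i <- P_i x (mean of the other matrices) x P_i^T, re-normalizing
    after every step.  The fused output is the mean of the final matrices,
    restricted to enhancer-promoter pairs.
    """
    used = [s for s in sources if s in inputs.evidence]
    if len(used) < 2:
        raise ValueError("similarity network fusion needs at least 2 sources")
    cat = inputs.catalog
    mats = [snf_normalize(_unified_adjacency(inputs.evidence[s], cat)) for s in used]
    m = len(mats)
    for _t in range(iterations):
        total = np.sum(mats, axis=0)
        new = []
        for i, p_i in enumerate(mats):
            others = (total - p_i) / (m - 1)
            new.append(p_i @ others @ p_i.T)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # isolated nodes already reported
            mats = [snf_normalize(p) for p in new]
    fused = np.sum(mats, axis=0) / m
    # row normalization breaks exact symmetry; a pair has one score, so
    # average the two orientations
    fused = 0.5 * (fused + fused.T)
    n_e = cat.count(E)
    enh = cat.segments_of(E)
    pro = cat.segments_of(P)
    ep = fused[:n_e, n_e:]
    edges = [
        (enh[p].id, pro[q].id, float(ep[p, q]))
        for p in range(len(enh))
        for q in range(len(pro))
        if ep[p, q] > 0
    ]
    return ScoredNetwork(NetworkKind.EP, cat.tissue_id, edges, catalog=cat)
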