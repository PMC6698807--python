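"""Validation protocols for fused interaction networks.

Three protocols mirror how an unsupervised fusion method can be judged
without a gold standard: (1) k-fold cross-validation on the coactivity
links — a fold of links is removed from the inputs and the pipeline must
rank them above an equal number of sampled non-interacting pairs; (2)
leave-one-dataset-out — an entire evidence source is dropped and used as
ground truth; (3) a TAD contrast — with TAD blocks excluded from the
inputs, scores of intra-TAD pairs should still exceed inter-TAD scores.

Negative pairs are sampled uniformly from enhancer-promoter pairs that are
co-resident in at least one window and absent from every input evidence
source.  AUROC is rank-based with mean-rank tie handling (identical to the
Mann-Whitney U statistic divided by n+ * n-).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy.stats import ranksums
from sklearn.metrics import roc_auc_score

from .core_model import GenomicSegment, NetworkKind, ScoredNetwork, SegmentCatalog, SegmentType
from .io_formats import EvidenceTable
from .network_builder import (
    MatrixSchema,
    _evidence_pairs,
    _evidence_row_pairs,
    default_schema,
)
from .windowed_pipeline import (
    PipelineConfig,
    TissueInputs,
    make_windows,
    run_pipeline,
)

E = SegmentType.ENHANCER
P = SegmentType.PROMOTER
TAD = SegmentType.TAD

Pair = Tuple[str, str]  # (enhancer id, promoter id)


@dataclass
class EvalSplit:
    """One fold: held-out positive pairs and matched sampled negatives."""

    fold_id: int
    held_out_positives: List[Pair]
    sampled_negatives: List[Pair]
    seed: int

    def __post_init__(self) -> None:
        if len(self.sampled_negatives) != len(self.held_out_positives):
            raise ValueError("negatives must balance positives")
        if set(self.held_out_positives) & set(self.sampled_negatives):
            raise ValueError("positives and negatives overlap")


def auroc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Rank-based AUROC; both classes must be present."""
    labels = np.asarray(labels)
    if labels.min() == labels.max():
        raise ValueError("AUROC needs both positive and negative examples")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def distance_filter(network: ScoredNetwork, min_bp: int = 5000) -> ScoredNetwork:
    """Retain pairs whose midpoint distance strictly exceeds ``min_bp``."""
    if network.catalog is None:
        raise ValueError("network needs a catalog to compute distances")
    cat = network.catalog
    kept = []
    for a, b, s in network.edges:
        sa = cat.get(network.type_a, a)
        sb = cat.get(network.type_b, b)
        if sa.chrom == sb.chrom and abs(sa.midpoint - sb.midpoint) > min_bp:
            kept.append((a, b, s))
    return ScoredNetwork(network.network_kind, network.tissue_id, kept, cat)


def cowindow_ep_pairs(inputs: TissueInputs, config: PipelineConfig) -> List[Pair]:
    """All E-P id pairs co-resident in at least one sliding window."""
    windows = make_windows(inputs.chrom_lengths, config.window_size, config.step)
    pairs: Set[Pair] = set()
    for w in windows:
        wcat = inputs.catalog.restrict_to_window(w)
        e_ids = [s.id for s in wcat.segments_of(E)]
        p_ids = [s.id for s in wcat.segments_of(P)]
        pairs.update((e, p) for e in e_ids for p in p_ids)
    return sorted(pairs)


def evidence_ep_pairs(
    inputs: TissueInputs, sources: Optional[Sequence[str]] = None
) -> Set[Pair]:
    """E-P pairs touched by any evidence source, mapped by interval overlap."""
    cat = inputs.catalog
    enh = cat.segments_of(E)
    pro = cat.segments_of(P)
    out: Set[Pair] = set()
    for name, table in inputs.evidence.items():
        if sources is not None and name not in sources:
            continue
        for p, q in _evidence_pairs(table, cat, E, P):
            out.add((enh[p].id, pro[q].id))
    return out


def make_cv_splits(
    positives: Sequence[Pair],
    negative_pool: Sequence[Pair],
    n_folds: int = 5,
    seed: int = 0,
) -> List[EvalSplit]:
    """Partition positives into ``n_folds`` disjoint folds with balanced,
    non-overlapping negatives sampled from ``negative_pool``."""
    positives = list(positives)
    if len(positives) < n_folds:
        raise ValueError(f"need >= {n_folds} positives, got {len(positives)}")
    pool = [p for p in negative_pool if p not in set(positives)]
    if len(pool) < len(positives):
        raise ValueError(
            f"negative pool too small: need {len(positives)}, have {len(pool)} "
            f"(deficit {len(positives) - len(pool)})"
        )
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(positives))
    neg_order = rng.permutation(len(pool))
    folds = np.array_split(order, n_folds)
    splits: List[EvalSplit] = []
    neg_cursor = 0
    for fold_id, idx in enumerate(folds):
        pos = [positives[i] for i in idx]
        neg = [pool[neg_order[neg_cursor + j]] for j in range(len(pos))]
        neg_cursor += len(pos)
        splits.append(
            EvalSplit(
                fold_id=fold_id, held_out_positives=pos,
                sampled_negatives=neg, seed=seed,
            )
        )
    return splits


def _drop_pairs_from_source(
    inputs: TissueInputs, source: str, pairs: Set[Pair]
) -> TissueInputs:
    """Inputs with every ``source`` row mapping to a held-out pair removed."""
    cat = inputs.catalog
    enh = cat.segments_of(E)
    pro = cat.segments_of(P)
    table = inputs.evidence[source]
    row_pairs = _evidence_row_pairs(table, cat, E, P)
    keep_rows = [
        ridx
        for ridx, mapped in enumerate(row_pairs)
        if not ({(enh[p].id, pro[q].id) for p, q in mapped} & pairs)
    ]
    new_table = EvidenceTable(
        table.source_kind, table.stat_kind, table.rows.iloc[keep_rows]
    )
    evidence = dict(inputs.evidence)
    evidence[source] = new_table
    return TissueInputs(cat, evidence, dict(inputs.chrom_lengths))


def _score_pairs(network: ScoredNetwork, pairs: Sequence[Pair]) -> np.ndarray:
    smap = network.score_map()
    return np.array([smap.get(p, 0.0) for p in pairs])


def assert_no_leakage(inputs: TissueInputs, held_out: Sequence[Pair]) -> None:
    """Structural check: no held-out pair is present in any input evidence."""
    leaked = evidence_ep_pairs(inputs) & set(held_out)
    if leaked:
        raise AssertionError(f"{len(leaked)} held-out pairs leak into the inputs")


def cross_validate(
    inputs: TissueInputs,
    config: Optional[PipelineConfig] = None,
    seed: int = 0,
    n_folds: int = 5,
    folds_to_run: Optional[int] = None,
    schema: Optional[MatrixSchema] = None,
) -> dict:
    """K-fold cross-validation on the coactivity links.

    Per fold, held-out links are removed from the coactivity table, the
    pipeline re-run, and AUROC computed on held-out positives vs balanced
    sampled negatives.
    """
    config = config or PipelineConfig()
    cat = inputs.catalog
    enh = cat.segments_of(E)
    pro = cat.segments_of(P)
    coact = inputs.evidence["coactivity"]
    positives = sorted(
        {(enh[p].id, pro[q].id) for p, q in _evidence_pairs(coact, cat, E, P)}
    )
    pool = sorted(set(cowindow_ep_pairs(inputs, config)) - evidence_ep_pairs(inputs))
    splits = make_cv_splits(positives, pool, n_folds=n_folds, seed=seed)
    if folds_to_run is not None:
        splits = splits[:folds_to_run]
    fold_auc = []
    for split in splits:
        held = set(split.held_out_positives)
        fold_inputs = _drop_pairs_from_source(inputs, "coactivity", held)
        assert_no_leakage(
            TissueInputs(cat, {"coactivity": fold_inputs.evidence["coactivity"]},
                         inputs.chrom_lengths),
            split.held_out_positives,
        )
        result = run_pipeline(
            fold_inputs, config, seed=seed + split.fold_id,
            schema=schema, calibrate=False,
        )
        pairs = split.held_out_positives + split.sampled_negatives
        labels = [1] * len(split.held_out_positives) + [0] * len(split.sampled_negatives)
        fold_auc.append(auroc(_score_pairs(result.ep, pairs), labels))
    return {
        "protocol": "cv",
        "n_folds": n_folds,
        "folds_run": len(splits),
        "seed": seed,
        "fold_auroc": fold_auc,
        "mean_auroc": float(np.mean(fold_auc)),
    }


def leave_dataset_out(
    inputs: TissueInputs,
    held_out_source: str,
    config: Optional[PipelineConfig] = None,
    seed: int = 0,
    schema: Optional[MatrixSchema] = None,
) -> dict:
    """Drop an entire evidence source, use it as ground truth.

    The pipeline runs without every block the source contributes; its rows
    are mapped to E-P pairs by overlap and scored against balanced sampled
    negatives (pairs with no evidence in any source, held-out included).
    """
    config = config or PipelineConfig()
    if held_out_source not in inputs.evidence:
        raise ValueError(f"source {held_out_source!r} not among inputs")
    cat = inputs.catalog
    enh = cat.segments_of(E)
    pro = cat.segments_of(P)
    truth_pairs = sorted(
        {
            (enh[p].id, pro[q].id)
            for p, q in _evidence_pairs(inputs.evidence[held_out_source], cat, E, P)
        }
    )
    if not truth_pairs:
        raise ValueError(f"source {held_out_source!r} maps to no E-P pairs")
    reduced = inputs.without_source(held_out_source)
    run_schema = (schema or default_schema()).without_source(held_out_source)
    pool = sorted(set(cowindow_ep_pairs(inputs, config)) - evidence_ep_pairs(inputs))
    rng = np.random.default_rng(seed)
    truth_set = set(truth_pairs)
    pool = [p for p in pool if p not in truth_set]
    if len(pool) < len(truth_pairs):
        raise ValueError("negative pool too small for leave-one-dataset-out")
    neg_idx = rng.choice(len(pool), size=len(truth_pairs), replace=False)
    negatives = [pool[i] for i in sorted(neg_idx)]
    result = run_pipeline(reduced, config, seed=seed, schema=run_schema, calibrate=False)
    pairs = truth_pairs + negatives
    labels = [1] * len(truth_pairs) + [0] * len(negatives)
    value = auroc(_score_pairs(result.ep, pairs), labels)
    return {
        "protocol": "ldo",
        "held_out": held_out_source,
        "seed": seed,
        "n_positives": len(truth_pairs),
        "auroc": value,
    }


def tad_score_contrast(
    ep_network: ScoredNetwork, tads: Sequence[GenomicSegment]
) -> Tuple[np.ndarray, np.ndarray, float]:
    """Split scored pairs into intra-TAD vs inter-TAD and test the shift.

    A pair is intra-TAD when both members overlap one common TAD.  Returns
    (intra scores, inter scores, two-sided Wilcoxon rank-sum p-value).
    """
    if ep_network.catalog is None:
        raise ValueError("network needs a catalog for TAD labeling")
    cat = ep_network.catalog
    intra, inter = [], []
    for a, b, s in ep_network.edges:
        sa = cat.get(ep_network.type_a, a)
        sb = cat.get(ep_network.type_b, b)
        shared = any(
            sa.overlaps(t.chrom, t.start, t.end) and sb.overlaps(t.chrom, t.start, t.end)
            for t in tads
        )
        (intra if shared else inter).append(s)
    if not intra or not inter:
        raise ValueError("both intra- and inter-TAD classes must be non-empty")
    stat = ranksums(intra, inter)
    return np.array(intra), np.array(inter), float(stat.pvalue)
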