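"""Assemble the per-window block system from catalogs and evidence tables.

The default schema mirrors the method's 17-matrix input layout for one
tissue: 4 interaction blocks (E-P coactivity, Hi-C anchor-anchor, SNP-P
eQTL, DHS-P correlation), 11 incidence blocks (segment-overlap indicators),
and 2 signed constraint blocks Theta_EE and Theta_PP built from Hi-C contact
pairs and shared-TAD membership.  The exact set of blocks is configurable;
each block records which evidence source it depends on so that
leave-one-dataset-out runs can drop everything a source contributes.

Overlap semantics everywhere: >= 1 bp, strand-agnostic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np
import scipy.sparse as sp
from intervaltree import IntervalTree

from .core_model import (
    ConstraintMatrix,
    FusionProblem,
    GenomeWindow,
    RelationKind,
    RelationMatrix,
    SegmentCatalog,
    SegmentType,
    assemble_block_problem,
)
from .io_formats import EvidenceTable

E = SegmentType.ENHANCER
P = SegmentType.PROMOTER
ANCHOR = SegmentType.HIC_ANCHOR
SNP = SegmentType.EQTL_SNP
DHS = SegmentType.DHS
TAD = SegmentType.TAD

#: which evidence source owns each non-E/P segment type (the segments
#: themselves come from that assay, so leaving the source out drops them).
_TYPE_SOURCE = {ANCHOR: "hic", SNP: "eqtl", DHS: "dhs_corr", TAD: "tad"}


class _OverlapIndex:
    """Per-chromosome interval tree over one segment type of a catalog."""

    def __init__(self, catalog: SegmentCatalog, seg_type: SegmentType):
        self._trees: Dict[str, IntervalTree] = {}
        for ordinal, seg in enumerate(catalog.segments_of(seg_type)):
            self._trees.setdefault(seg.chrom, IntervalTree()).addi(
                seg.start, seg.end, ordinal
            )

    def query(self, chrom: str, start: int, end: int) -> List[int]:
        tree = self._trees.get(chrom)
        if tree is None or start >= end:
            return []
        return sorted(iv.data for iv in tree.overlap(start, end))


@dataclass(frozen=True)
class RelationSpec:
    """Declaration of one R block in the schema."""

    type_i: SegmentType
    type_j: SegmentType
    kind: RelationKind
    source: Optional[str] = None  # evidence table feeding an interaction block

    @property
    def requires(self) -> FrozenSet[str]:
        """Evidence sources this block cannot exist without."""
        needs: Set[str] = set()
        if self.source is not None:
            needs.add(self.source)
        for t in (self.type_i, self.type_j):
            if t in _TYPE_SOURCE:
                needs.add(_TYPE_SOURCE[t])
        return frozenset(needs)


@dataclass(frozen=True)
class ThetaSpec:
    """Declaration of one signed constraint block."""

    seg_type: SegmentType
    sources: Tuple[str, ...] = ("hic", "tad")


@dataclass
class MatrixSchema:
    """The set of blocks to build for each window."""

    relations: List[RelationSpec]
    thetas: List[ThetaSpec]

    def n_declared(self) -> int:
        return len(self.relations) + len(self.thetas)

    def without_source(self, source: str) -> "MatrixSchema":
        """Schema with every block contributed by ``source`` removed.

        Constraint blocks keep their remaining ingredients; a constraint
        losing all its sources is dropped.
        """
        rels = [r for r in self.relations if source not in r.requires]
        thetas = []
        for th in self.thetas:
            remaining = tuple(s for s in th.sources if s != source)
            if remaining:
                thetas.append(ThetaSpec(th.seg_type, remaining))
        return MatrixSchema(relations=rels, thetas=thetas)


def default_schema() -> MatrixSchema:
    """The default 17-block schema (15 R blocks + 2 Theta blocks)."""
    inter = RelationKind.INTERACTION
    inc = RelationKind.INCIDENCE
    relations = [
        RelationSpec(E, P, inter, "coactivity"),
        RelationSpec(ANCHOR, ANCHOR, inter, "hic"),
        RelationSpec(SNP, P, inter, "eqtl"),
        RelationSpec(DHS, P, inter, "dhs_corr"),
        RelationSpec(ANCHOR, E, inc),
        RelationSpec(ANCHOR, P, inc),
        RelationSpec(SNP, E, inc),
        RelationSpec(DHS, E, inc),
        RelationSpec(TAD, E, inc),
        RelationSpec(TAD, P, inc),
        RelationSpec(TAD, ANCHOR, inc),
        RelationSpec(TAD, SNP, inc),
        RelationSpec(TAD, DHS, inc),
        RelationSpec(SNP, ANCHOR, inc),
        RelationSpec(DHS, ANCHOR, inc),
    ]
    thetas = [ThetaSpec(E), ThetaSpec(P)]
    return MatrixSchema(relations=relations, thetas=thetas)


def _window_rows(rows, window: Optional[GenomeWindow]):
    """Evidence rows with both anchors overlapping the window."""
    if window is None:
        return rows
    keep_a = (
        (rows["chrom_a"] == window.chrom)
        & (rows["start_a"] < window.end)
        & (rows["end_a"] > window.start)
    )
    keep_b = (
        (rows["chrom_b"] == window.chrom)
        & (rows["start_b"] < window.end)
        & (rows["end_b"] > window.start)
    )
    return rows.loc[keep_a & keep_b]


def _evidence_row_pairs(
    evidence: EvidenceTable,
    catalog: SegmentCatalog,
    type_i: SegmentType,
    type_j: SegmentType,
    window: Optional[GenomeWindow] = None,
) -> List[Set[Tuple[int, int]]]:
    """Per-row ordinal pairs (p, q), both orientations tried, aligned with
    the (window-filtered) row order of the evidence table."""
    idx_i = _OverlapIndex(catalog, type_i)
    idx_j = _OverlapIndex(catalog, type_j) if type_j != type_i else idx_i
    out: List[Set[Tuple[int, int]]] = []
    rows = _window_rows(evidence.rows, window)
    for r in rows.itertuples(index=False):
        a = (r.chrom_a, int(r.start_a), int(r.end_a))
        b = (r.chrom_b, int(r.start_b), int(r.end_b))
        pairs: Set[Tuple[int, int]] = set()
        for side_i, side_j in ((a, b), (b, a)):
            for p in idx_i.query(*side_i):
                for q in idx_j.query(*side_j):
                    if type_i == type_j and p == q:
                        continue
                    pairs.add((p, q))
        out.append(pairs)
    return out


def _evidence_pairs(
    evidence: EvidenceTable,
    catalog: SegmentCatalog,
    type_i: SegmentType,
    type_j: SegmentType,
    window: Optional[GenomeWindow] = None,
) -> Set[Tuple[int, int]]:
    """Ordinal pairs (p, q) linked by evidence rows, both orientations tried."""
    pairs: Set[Tuple[int, int]] = set()
    for row_pairs in _evidence_row_pairs(evidence, catalog, type_i, type_j, window):
        pairs |= row_pairs
    return pairs


def build_interaction_matrix(
    evidence: EvidenceTable,
    catalog: SegmentCatalog,
    type_i: SegmentType,
    type_j: SegmentType,
    window: Optional[GenomeWindow] = None,
) -> RelationMatrix:
    """Binary matrix with a 1 wherever an evidence row joins two segments.

    Each evidence row's two anchors are mapped by >=1 bp interval overlap to
    segments of ``type_i`` and ``type_j`` (either orientation); rows mapping
    to no segment contribute nothing.  For same-type blocks the matrix is
    symmetrized and the diagonal left empty.
    """
    pairs = _evidence_pairs(evidence, catalog, type_i, type_j, window)
    if type_i == type_j:
        pairs |= {(q, p) for p, q in pairs}
    n_i, n_j = catalog.count(type_i), catalog.count(type_j)
    if pairs:
        rows, cols = zip(*sorted(pairs))
        data = sp.csr_matrix(
            (np.ones(len(rows)), (rows, cols)), shape=(n_i, n_j)
        )
    else:
        data = sp.csr_matrix((n_i, n_j))
    return RelationMatrix(type_i=type_i, type_j=type_j, data=data,
                          kind=RelationKind.INTERACTION)


def build_incidence_matrix(
    catalog: SegmentCatalog,
    container_type: SegmentType,
    member_type: SegmentType,
) -> RelationMatrix:
    """Binary matrix: entry (p, q) = 1 iff member q overlaps container p."""
    idx = _OverlapIndex(catalog, member_type)
    rows: List[int] = []
    cols: List[int] = []
    for p, seg in enumerate(catalog.segments_of(container_type)):
        for q in idx.query(seg.chrom, seg.start, seg.end):
            rows.append(p)
            cols.append(q)
    n_i, n_j = catalog.count(container_type), catalog.count(member_type)
    data = sp.csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(n_i, n_j))
    return RelationMatrix(type_i=container_type, type_j=member_type, data=data,
                          kind=RelationKind.INCIDENCE)


def build_theta(
    catalog: SegmentCatalog,
    seg_type: SegmentType,
    hic_evidence: Optional[EvidenceTable] = None,
    use_tads: bool = True,
    window: Optional[GenomeWindow] = None,
    lambda_theta: float = 1.0,
) -> ConstraintMatrix:
    """Signed same-type prior: -lambda for pairs joined by a Hi-C contact or
    sharing a TAD, 0 otherwise.  Symmetric with a zero diagonal.

    Only the negative (interacting) entries are populated; the method's prior
    is attractive (physical contact and TAD co-residence both argue for
    co-clustering).
    """
    if seg_type not in (E, P):
        raise ValueError("constraint blocks are defined for enhancers and promoters")
    pairs: Set[Tuple[int, int]] = set()
    if hic_evidence is not None:
        pairs |= _evidence_pairs(hic_evidence, catalog, seg_type, seg_type, window)
    if use_tads:
        idx = _OverlapIndex(catalog, seg_type)
        for tad in catalog.segments_of(TAD):
            members = idx.query(tad.chrom, tad.start, tad.end)
            for a_i, p in enumerate(members):
                for q in members[a_i + 1:]:
                    pairs.add((p, q))
    pairs = {(p, q) for p, q in pairs if p != q}
    pairs |= {(q, p) for p, q in pairs}
    n = catalog.count(seg_type)
    if pairs:
        rows, cols = zip(*sorted(pairs))
        data = sp.csr_matrix(
            (np.full(len(rows), -lambda_theta), (rows, cols)), shape=(n, n)
        )
    else:
        data = sp.csr_matrix((n, n))
    return ConstraintMatrix(seg_type=seg_type, data=data)


def build_problem_for_window(
    catalog: SegmentCatalog,
    evidence: Dict[str, EvidenceTable],
    window: GenomeWindow,
    schema: Optional[MatrixSchema] = None,
    lambda_theta: float = 1.0,
) -> FusionProblem:
    """Build the full window-restricted :class:`FusionProblem`.

    Blocks whose segment types have no segments in the window, or whose
    evidence source is unavailable, are recorded as absent (never as zero
    matrices of the wrong provenance).
    """
    if schema is None:
        schema = default_schema()
    wcat = catalog.restrict_to_window(window)
    relations: List[RelationMatrix] = []
    for spec in schema.relations:
        if wcat.count(spec.type_i) == 0 or wcat.count(spec.type_j) == 0:
            continue
        if spec.kind is RelationKind.INTERACTION:
            if spec.source not in evidence:
                continue
            relations.append(
                build_interaction_matrix(
                    evidence[spec.source], wcat, spec.type_i, spec.type_j, window
                )
            )
        else:
            relations.append(build_incidence_matrix(wcat, spec.type_i, spec.type_j))
    constraints: List[ConstraintMatrix] = []
    for th in schema.thetas:
        if wcat.count(th.seg_type) == 0:
            continue
        hic = evidence.get("hic") if "hic" in th.sources else None
        use_tads = "tad" in th.sources and wcat.count(TAD) > 0
        if hic is None and not use_tads:
            continue
        constraints.append(
            build_theta(
                wcat, th.seg_type, hic_evidence=hic, use_tads=use_tads,
                window=window, lambda_theta=lambda_theta,
            )
        )
    return assemble_block_problem(wcat, relations, constraints)
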