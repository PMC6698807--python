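"""Core domain types for heterogeneous regulatory-network fusion.

The method operates on six kinds of genomic segments (enhancers, promoters,
Hi-C anchors, eQTL SNPs, DHS sites and TADs).  Pairwise evidence between
segment types is held in sparse binary relation matrices ``R_ij``; same-type
prior knowledge (physical contact, shared TAD membership) is held in signed
constraint matrices ``Theta_ii``.  Together with a per-tissue segment catalog
these form a :class:`FusionProblem`, the unit of work consumed by the
factorization engine.

Coordinates follow the BED convention: 0-based, half-open.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import scipy.sparse as sp


class SegmentType(enum.IntEnum):
    """The six genomic segment types handled by the model.

    Integer codes are stable: enhancer=1 and promoter=2 so that ``G_1`` is
    always the enhancer factor and ``G_2`` the promoter factor.
    """

    ENHANCER = 1
    PROMOTER = 2
    HIC_ANCHOR = 3
    EQTL_SNP = 4
    DHS = 5
    TAD = 6

    @property
    def short(self) -> str:
        return self.name.lower()


class StructuralError(ValueError):
    """A block does not fit the catalog it is declared against."""


@dataclass(frozen=True, order=True)
class GenomicSegment:
    """A typed genomic interval, 0-based half-open.

    SNP segments are single-base: ``end == start + 1``.
    """

    chrom: str
    start: int
    end: int
    type: SegmentType
    id: str

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start for segment {self.id!r}")
        if not self.start < self.end:
            raise ValueError(
                f"segment {self.id!r} must satisfy start < end "
                f"(got [{self.start}, {self.end}))"
            )

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.start + self.end)

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        return self.chrom == chrom and self.start < end and self.end > start


def _sort_key(seg: GenomicSegment) -> Tuple[str, int, int, str]:
    return (seg.chrom, seg.start, seg.end, seg.id)


class SegmentCatalog:
    """Deterministically ordered per-tissue universe of genomic segments.

    Segments are grouped by type and sorted by (chrom, start, end, id) within
    each type, so the ordinal of a segment — its row/column index in every
    matrix — is reproducible across runs.
    """

    def __init__(self, tissue_id: str, segments: Iterable[GenomicSegment]):
        self.tissue_id = tissue_id
        by_type: Dict[SegmentType, List[GenomicSegment]] = {t: [] for t in SegmentType}
        for seg in segments:
            by_type[seg.type].append(seg)
        self._by_type: Dict[SegmentType, List[GenomicSegment]] = {}
        self._index: Dict[Tuple[SegmentType, str], int] = {}
        for t, segs in by_type.items():
            segs.sort(key=_sort_key)
            self._by_type[t] = segs
            for i, seg in enumerate(segs):
                key = (t, seg.id)
                if key in self._index:
                    raise ValueError(f"duplicate segment id {seg.id!r} for type {t.name}")
                self._index[key] = i

    def count(self, seg_type: SegmentType) -> int:
        return len(self._by_type[seg_type])

    def segments_of(self, seg_type: SegmentType) -> List[GenomicSegment]:
        return self._by_type[seg_type]

    def all_segments(self) -> List[GenomicSegment]:
        out: List[GenomicSegment] = []
        for t in SegmentType:
            out.extend(self._by_type[t])
        return out

    def ordinal(self, seg_type: SegmentType, seg_id: str) -> int:
        return self._index[(seg_type, seg_id)]

    def get(self, seg_type: SegmentType, seg_id: str) -> GenomicSegment:
        return self._by_type[seg_type][self.ordinal(seg_type, seg_id)]

    def restrict_to_window(self, window: "GenomeWindow", clip: bool = True) -> "SegmentCatalog":
        """Catalog of segments overlapping ``window`` (>= 1 bp).

        Intervals larger than the window (typically TADs) are clipped to the
        window bounds when ``clip`` is true so incidence computations stay
        window-local; ids are preserved.
        """
        kept: List[GenomicSegment] = []
        for seg in self.all_segments():
            if not seg.overlaps(window.chrom, window.start, window.end):
                continue
            if clip and (seg.start < window.start or seg.end > window.end):
                kept.append(
                    GenomicSegment(
                        chrom=seg.chrom,
                        start=max(seg.start, window.start),
                        end=min(seg.end, window.end),
                        type=seg.type,
                        id=seg.id,
                    )
                )
            else:
                kept.append(seg)
        return SegmentCatalog(self.tissue_id, kept)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SegmentCatalog):
            return NotImplemented
        return self.tissue_id == other.tissue_id and all(
            self._by_type[t] == other._by_type[t] for t in SegmentType
        )


class RelationKind(str, enum.Enum):
    INTERACTION = "interaction"
    INCIDENCE = "incidence"


@dataclass
class RelationMatrix:
    """Sparse binary matrix of observed associations between two segment types.

    ``kind`` distinguishes experimentally supported interactions from purely
    positional incidence (one segment overlapping another).  Same-type blocks
    (``type_i == type_j``, e.g. Hi-C anchor pairs) are allowed for
    interactions only.
    """

    type_i: SegmentType
    type_j: SegmentType
    data: sp.csr_matrix
    kind: RelationKind = RelationKind.INTERACTION

    def __post_init__(self) -> None:
        self.kind = RelationKind(self.kind)
        if self.type_i == self.type_j and self.kind is not RelationKind.INTERACTION:
            raise StructuralError(
                f"incidence block must relate two distinct types, got {self.type_i.name}"
            )
        self.data = sp.csr_matrix(self.data, dtype=np.float64)
        if self.data.nnz and not np.all(self.data.data == 1.0):
            raise ValueError(
                f"relation matrix ({self.type_i.name}, {self.type_j.name}) "
                "must have all stored entries equal to 1"
            )

    @property
    def shape(self) -> Tuple[int, int]:
        return self.data.shape


@dataclass
class ConstraintMatrix:
    """Signed same-type matrix Theta_ii entering the objective as tr(G'ΘG).

    Negative entries mark segment pairs known to interact (co-clustering is
    rewarded); positive entries mark pairs known not to interact.  The matrix
    is symmetrized on construction with the min rule: if either orientation
    marks a pair as interacting the symmetric entry is the negative weight.
    The diagonal is zeroed.
    """

    seg_type: SegmentType
    data: sp.csr_matrix

    def __post_init__(self) -> None:
        m = sp.csr_matrix(self.data, dtype=np.float64)
        if m.shape[0] != m.shape[1]:
            raise StructuralError(
                f"constraint matrix for {self.seg_type.name} must be square, got {m.shape}"
            )
        m = m.minimum(m.T.tocsr())
        m.setdiag(0.0)
        m.eliminate_zeros()
        self.data = m

    @property
    def shape(self) -> Tuple[int, int]:
        return self.data.shape


@dataclass
class FusionProblem:
    """One tissue's (windowed) block system: catalog + R blocks + Theta blocks.

    Any relation block may be missing; a missing block is absent from
    ``relations``, never stored as a zero matrix.
    """

    catalog: SegmentCatalog
    relations: Dict[Tuple[SegmentType, SegmentType], RelationMatrix]
    constraints: Dict[SegmentType, ConstraintMatrix]

    def types_present(self) -> List[SegmentType]:
        """Types that participate in at least one block."""
        seen = set()
        for (i, j) in self.relations:
            seen.add(i)
            seen.add(j)
        seen.update(self.constraints)
        return sorted(seen)

    def n_blocks(self) -> int:
        return len(self.relations) + len(self.constraints)


def assemble_block_problem(
    catalog: SegmentCatalog,
    relations: Sequence[RelationMatrix],
    constraints: Sequence[ConstraintMatrix] = (),
) -> FusionProblem:
    """Validate blocks against the catalog and assemble a :class:`FusionProblem`.

    Raises :class:`StructuralError` naming the offending block on any
    dimension mismatch or duplicate block declaration.
    """
    rel_map: Dict[Tuple[SegmentType, SegmentType], RelationMatrix] = {}
    for rel in relations:
        key = (rel.type_i, rel.type_j)
        if key in rel_map:
            raise StructuralError(
                f"duplicate relation block ({rel.type_i.name}, {rel.type_j.name})"
            )
        expect = (catalog.count(rel.type_i), catalog.count(rel.type_j))
        if rel.shape != expect:
            raise StructuralError(
                f"relation block ({rel.type_i.name}, {rel.type_j.name}) has shape "
                f"{rel.shape}, catalog implies {expect}"
            )
        rel_map[key] = rel
    con_map: Dict[SegmentType, ConstraintMatrix] = {}
    for con in constraints:
        if con.seg_type in con_map:
            raise StructuralError(f"duplicate constraint block for {con.seg_type.name}")
        n = catalog.count(con.seg_type)
        if con.shape != (n, n):
            raise StructuralError(
                f"constraint block for {con.seg_type.name} has shape {con.shape}, "
                f"catalog implies ({n}, {n})"
            )
        con_map[con.seg_type] = con
    return FusionProblem(catalog=catalog, relations=rel_map, constraints=con_map)


@dataclass
class FactorSet:
    """Factors of one penalized tri-factorization run.

    ``G[i]`` is the non-negative n_i x k_i membership matrix of segment type
    ``i``; ``S[(i, j)]`` couples the latent clusters of types ``i`` and ``j``.
    ``objective_trace`` holds the objective value after each iteration;
    ``initial_objective`` is its value at the initialization.
    """

    G: Dict[SegmentType, np.ndarray]
    S: Dict[Tuple[SegmentType, SegmentType], np.ndarray]
    ranks: Dict[SegmentType, int]
    objective_trace: List[float] = field(default_factory=list)
    initial_objective: float = float("nan")

    def copy(self) -> "FactorSet":
        return FactorSet(
            G={t: g.copy() for t, g in self.G.items()},
            S={k: s.copy() for k, s in self.S.items()},
            ranks=dict(self.ranks),
            objective_trace=list(self.objective_trace),
            initial_objective=self.initial_objective,
        )


DEFAULT_WINDOW_SIZE = 5_000_000
DEFAULT_WINDOW_STEP = 2_500_000


@dataclass(frozen=True)
class GenomeWindow:
    """One sliding-window region (default 5 Mb windows, 2.5 Mb step)."""

    chrom: str
    start: int
    end: int
    window_size: int = DEFAULT_WINDOW_SIZE
    step: int = DEFAULT_WINDOW_STEP

    def __post_init__(self) -> None:
        if self.end - self.start > self.window_size:
            raise ValueError("window span exceeds window_size")
        if not (0 < self.step <= self.window_size):
            raise ValueError("step must be in (0, window_size]")


class NetworkKind(str, enum.Enum):
    EP = "EP"
    EE = "EE"
    PP = "PP"


_KIND_TYPES = {
    NetworkKind.EP: (SegmentType.ENHANCER, SegmentType.PROMOTER),
    NetworkKind.EE: (SegmentType.ENHANCER, SegmentType.ENHANCER),
    NetworkKind.PP: (SegmentType.PROMOTER, SegmentType.PROMOTER),
}


@dataclass
class ScoredNetwork:
    """Weighted segment-pair edge list (E-P, E-E or P-P) for one tissue.

    Edges are (id_a, id_b, score) with finite non-negative scores and no
    duplicate unordered pairs.  Same-type networks store each pair once with
    id_a < id_b in catalog order.
    """

    network_kind: NetworkKind
    tissue_id: str
    edges: List[Tuple[str, str, float]]
    catalog: Optional[SegmentCatalog] = None

    def __post_init__(self) -> None:
        self.network_kind = NetworkKind(self.network_kind)
        seen = set()
        for a, b, s in self.edges:
            if not np.isfinite(s) or s < 0:
                raise ValueError(f"edge ({a}, {b}) has invalid score {s!r}")
            key = frozenset((a, b)) if self.type_a is self.type_b else (a, b)
            if key in seen:
                raise ValueError(f"duplicate edge ({a}, {b})")
            seen.add(key)

    @property
    def type_a(self) -> SegmentType:
        return _KIND_TYPES[self.network_kind][0]

    @property
    def type_b(self) -> SegmentType:
        return _KIND_TYPES[self.network_kind][1]

    def __len__(self) -> int:
        return len(self.edges)

    def score_map(self) -> Dict[Tuple[str, str], float]:
        return {(a, b): s for a, b, s in self.edges}

    def filtered(self, cutoff: float) -> "ScoredNetwork":
        """Edges with score >= cutoff."""
        return ScoredNetwork(
            network_kind=self.network_kind,
            tissue_id=self.tissue_id,
            edges=[(a, b, s) for a, b, s in self.edges if s >= cutoff],
            catalog=self.catalog,
        )
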