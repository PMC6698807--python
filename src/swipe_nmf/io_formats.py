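"""Readers and writers for segment catalogs, pairwise evidence and networks.

Segments come in as BED3/BED4 (optional 4th column = id).  Pairwise evidence
comes in as BEDPE-like tab-separated files (six coordinate columns, optional
statistic in column 7).  Each evidence source carries the significance filter
used when the original association calls were made: Hi-C pairs are kept at
q-value < 1e-3, eQTL links at P < 1e-5, DHS-promoter correlations at
score > 0.9, and coactivity links are used as published, with no filter.
Inequalities are strict; boundary values are excluded.
"""

from __future__ import annotations

import enum
import json
import os
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .core_model import (
    ConstraintMatrix,
    FusionProblem,
    GenomicSegment,
    NetworkKind,
    RelationKind,
    RelationMatrix,
    ScoredNetwork,
    SegmentCatalog,
    SegmentType,
    assemble_block_problem,
)


class ParseError(ValueError):
    pass


class StatKind(str, enum.Enum):
    QVALUE = "qvalue"
    PVALUE = "pvalue"
    SCORE = "score"
    NONE = "none"


#: source kind -> (stat kind, comparison, threshold); None = no filtering.
DEFAULT_THRESHOLDS: Dict[str, Optional[Tuple[StatKind, str, float]]] = {
    "coactivity": None,
    "hic": (StatKind.QVALUE, "<", 1e-3),
    "eqtl": (StatKind.PVALUE, "<", 1e-5),
    "dhs_corr": (StatKind.SCORE, ">", 0.9),
}

_EVIDENCE_COLUMNS = [
    "chrom_a", "start_a", "end_a", "chrom_b", "start_b", "end_b", "stat",
]


@dataclass
class EvidenceTable:
    """One source's pairwise association rows with its significance statistic."""

    source_kind: str
    stat_kind: StatKind
    rows: pd.DataFrame  # columns: chrom_a,start_a,end_a,chrom_b,start_b,end_b,stat

    def __post_init__(self) -> None:
        self.stat_kind = StatKind(self.stat_kind)
        missing = [c for c in _EVIDENCE_COLUMNS if c not in self.rows.columns]
        if missing:
            raise ValueError(f"evidence table missing columns {missing}")
        self.rows = self.rows.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.rows)


def _auto_id(seg_type: SegmentType, chrom: str, start: int, end: int) -> str:
    return f"{seg_type.short}:{chrom}:{start}-{end}"


def read_segments(path: str, seg_type: SegmentType) -> List[GenomicSegment]:
    """Read a BED3+ file into sorted :class:`GenomicSegment` records.

    The optional 4th column supplies segment ids; absent ids are generated as
    ``"{type}:{chrom}:{start}-{end}"``.  Malformed coordinates raise
    :class:`ParseError` with the 1-based line number.
    """
    segments: List[GenomicSegment] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: expected >= 3 tab-separated columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: malformed coordinate ({exc})") from exc
            seg_id = fields[3] if len(fields) > 3 and fields[3] else _auto_id(
                seg_type, chrom, start, end
            )
            try:
                segments.append(GenomicSegment(chrom, start, end, seg_type, seg_id))
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    segments.sort(key=lambda s: (s.chrom, s.start, s.end, s.id))
    return segments


def apply_threshold(
    rows: pd.DataFrame, rule: Optional[Tuple[StatKind, str, float]]
) -> pd.DataFrame:
    """Drop rows failing the (strict) significance rule; idempotent."""
    if rule is None:
        return rows
    _, op, value = rule
    stat = rows["stat"].astype(float)
    if stat.isna().any():
        raise ParseError("stat column required when a threshold is active")
    if op == "<":
        keep = stat < value
    elif op == ">":
        keep = stat > value
    else:  # pragma: no cover - config validation
        raise ValueError(f"unknown comparison {op!r}")
    return rows.loc[keep].reset_index(drop=True)


def read_evidence(
    path: str,
    source_kind: str,
    threshold_config: Optional[Dict[str, Optional[Tuple[StatKind, str, float]]]] = None,
) -> EvidenceTable:
    """Read a BEDPE-like evidence file, applying the source's load-time filter.

    ``threshold_config`` overrides/extends :data:`DEFAULT_THRESHOLDS`; an
    unknown ``source_kind`` (absent from both) is an error.
    """
    thresholds = dict(DEFAULT_THRESHOLDS)
    if threshold_config:
        thresholds.update(threshold_config)
    if source_kind not in thresholds:
        raise ValueError(f"unknown evidence source kind {source_kind!r}")
    rule = thresholds[source_kind]

    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    except pd.errors.EmptyDataError:
        df = pd.DataFrame(columns=range(7))
    if len(df) and df.shape[1] < 6:
        raise ParseError(f"{path}: BEDPE-like input needs >= 6 columns")
    if df.shape[1] < 7:
        df[6] = np.nan
    out = pd.DataFrame(
        {
            "chrom_a": df[0],
            "start_a": pd.to_numeric(df[1], errors="raise").astype(int) if len(df) else [],
            "end_a": pd.to_numeric(df[2], errors="raise").astype(int) if len(df) else [],
            "chrom_b": df[3],
            "start_b": pd.to_numeric(df[4], errors="raise").astype(int) if len(df) else [],
            "end_b": pd.to_numeric(df[5], errors="raise").astype(int) if len(df) else [],
            "stat": pd.to_numeric(df[6], errors="coerce") if len(df) else [],
        }
    )
    out = apply_threshold(out, rule)
    stat_kind = rule[0] if rule is not None else StatKind.NONE
    return EvidenceTable(source_kind=source_kind, stat_kind=stat_kind, rows=out)


_NETWORK_HEADER = [
    "chrom_a", "start_a", "end_a", "id_a",
    "chrom_b", "start_b", "end_b", "id_b", "score",
]


def write_scored_network(network: ScoredNetwork, path: str) -> None:
    """Write a network as TSV with full-precision scores.

    Rows are ordered by score descending, then by (id_a, id_b), so output is
    byte-deterministic.  Requires the network to carry its catalog for
    coordinates.
    """
    if network.catalog is None:
        raise ValueError("network has no catalog attached; coordinates unavailable")
    cat = network.catalog
    rows = sorted(network.edges, key=lambda e: (-e[2], e[0], e[1]))
    with open(path, "w") as fh:
        fh.write("\t".join(_NETWORK_HEADER) + "\n")
        for id_a, id_b, score in rows:
            a = cat.get(network.type_a, id_a)
            b = cat.get(network.type_b, id_b)
            fh.write(
                f"{a.chrom}\t{a.start}\t{a.end}\t{id_a}\t"
                f"{b.chrom}\t{b.start}\t{b.end}\t{id_b}\t{score!r}\n"
            )


def read_scored_network(
    path: str, network_kind: NetworkKind, tissue_id: str,
    catalog: Optional[SegmentCatalog] = None,
) -> ScoredNetwork:
    df = pd.read_csv(path, sep="\t")
    edges = [
        (str(r.id_a), str(r.id_b), float(r.score)) for r in df.itertuples(index=False)
    ]
    return ScoredNetwork(
        network_kind=network_kind, tissue_id=tissue_id, edges=edges, catalog=catalog
    )


# -- FusionProblem persistence (catalog TSV + MatrixMarket blocks + JSON meta) --

def save_problem(problem: FusionProblem, dirpath: str) -> None:
    os.makedirs(dirpath, exist_ok=True)
    cat = problem.catalog
    with open(os.path.join(dirpath, "catalog.tsv"), "w") as fh:
        fh.write("type\tchrom\tstart\tend\tid\n")
        for seg in cat.all_segments():
            fh.write(f"{seg.type.value}\t{seg.chrom}\t{seg.start}\t{seg.end}\t{seg.id}\n")
    meta = {"tissue_id": cat.tissue_id, "relations": [], "constraints": []}
    for (i, j), rel in sorted(problem.relations.items()):
        name = f"R_{i.value}_{j.value}.mtx"
        scipy.io.mmwrite(os.path.join(dirpath, name), rel.data)
        meta["relations"].append(
            {"type_i": i.value, "type_j": j.value, "kind": rel.kind.value, "file": name}
        )
    for i, con in sorted(problem.constraints.items()):
        name = f"Theta_{i.value}.mtx"
        scipy.io.mmwrite(os.path.join(dirpath, name), con.data)
        meta["constraints"].append({"type": i.value, "file": name})
    with open(os.path.join(dirpath, "problem.json"), "w") as fh:
        json.dump(meta, fh, indent=1, sort_keys=True)


def load_problem(dirpath: str) -> FusionProblem:
    with open(os.path.join(dirpath, "problem.json")) as fh:
        meta = json.load(fh)
    df = pd.read_csv(os.path.join(dirpath, "catalog.tsv"), sep="\t")
    segments = [
        GenomicSegment(str(r.chrom), int(r.start), int(r.end), SegmentType(int(r.type)), str(r.id))
        for r in df.itertuples(index=False)
    ]
    catalog = SegmentCatalog(meta["tissue_id"], segments)
    relations = [
        RelationMatrix(
            type_i=SegmentType(entry["type_i"]),
            type_j=SegmentType(entry["type_j"]),
            data=sp.csr_matrix(scipy.io.mmread(os.path.join(dirpath, entry["file"]))),
            kind=RelationKind(entry["kind"]),
        )
        for entry in meta["relations"]
    ]
    constraints = [
        ConstraintMatrix(
            seg_type=SegmentType(entry["type"]),
            data=sp.csr_matrix(scipy.io.mmread(os.path.join(dirpath, entry["file"]))),
        )
        for entry in meta["constraints"]
    ]
    return assemble_block_problem(catalog, relations, constraints)
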