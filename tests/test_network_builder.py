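import numpy as np
import pandas as pd
import pytest

from swipe_nmf.core_model import GenomeWindow, GenomicSegment, SegmentCatalog, SegmentType
from swipe_nmf.io_formats import EvidenceTable, StatKind
from swipe_nmf.network_builder import (
    build_incidence_matrix,
    build_interaction_matrix,
    build_problem_for_window,
    build_theta,
    default_schema,
)
from swipe_nmf.synthetic_fixtures import PlantedModel, generate_genome

E = SegmentType.ENHANCER
P = SegmentType.PROMOTER
TAD = SegmentType.TAD


def _table(pairs, source="coactivity"):
    rows = pd.DataFrame(
        {
            "chrom_a": [a[0] for a, b in pairs],
            "start_a": [a[1] for a, b in pairs],
            "end_a": [a[2] for a, b in pairs],
            "chrom_b": [b[0] for a, b in pairs],
            "start_b": [b[1] for a, b in pairs],
            "end_b": [b[2] for a, b in pairs],
            "stat": np.nan,
        }
    )
    return EvidenceTable(source, StatKind.NONE, rows)


class TestInteractionMatrix:
    def test_single_link_single_entry(self, small_catalog):
        ev = _table([(("chr1", 100, 600), ("chr1", 50_000, 51_500))])
        m = build_interaction_matrix(ev, small_catalog, E, P)
        assert m.data.nnz == 1
        assert m.data[small_catalog.ordinal(E, "e1"), small_catalog.ordinal(P, "p1")] == 1

    def test_multi_overlap_sets_multiple_entries(self, small_catalog):
        # side A spans e1 and e2
        ev = _table([(("chr1", 0, 12_000), ("chr1", 50_000, 51_500))])
        m = build_interaction_matrix(ev, small_catalog, E, P)
        # brute-force oracle over all enhancers
        expected = {
            small_catalog.ordinal(E, s.id)
            for s in small_catalog.segments_of(E)
            if s.start < 12_000 and s.end > 0
        }
        got = set(m.data.tocoo().row)
        assert got == expected == {0, 1}

    def test_swapped_orientation_mapped(self, small_catalog):
        ev = _table([(("chr1", 50_000, 51_500), ("chr1", 100, 600))])  # P side first
        m = build_interaction_matrix(ev, small_catalog, E, P)
        assert m.data.nnz == 1

    def test_out_of_window_anchor_excluded(self, small_catalog):
        ev = _table([(("chr1", 100, 600), ("chr1", 1_200_000, 1_201_500))])
        window = GenomeWindow("chr1", 0, 1_000_000)
        wcat = small_catalog.restrict_to_window(window)
        m = build_interaction_matrix(ev, wcat, E, P, window)
        assert m.data.nnz == 0


class TestIncidenceMatrix:
    def test_containment_and_disjoint(self, small_catalog):
        m = build_incidence_matrix(small_catalog, TAD, E)
        tadA = small_catalog.ordinal(TAD, "tadA")
        tadB = small_catalog.ordinal(TAD, "tadB")
        assert m.data[tadA, small_catalog.ordinal(E, "e1")] == 1
        assert m.data[tadA, small_catalog.ordinal(E, "e3")] == 0
        assert m.data[tadB, small_catalog.ordinal(E, "e3")] == 1

    def test_straddling_member_hits_both_containers(self):
        segs = [
            GenomicSegment("chr1", 0, 1000, TAD, "t1"),
            GenomicSegment("chr1", 1000, 2000, TAD, "t2"),
            GenomicSegment("chr1", 900, 1100, E, "e"),
        ]
        cat = SegmentCatalog("t", segs)
        m = build_incidence_matrix(cat, TAD, E)
        assert m.data.nnz == 2

    def test_matches_brute_force_on_random_segments(self):
        rng = np.random.default_rng(5)
        tads = [
            GenomicSegment("chr1", int(s), int(s) + 5000, TAD, f"t{i}")
            for i, s in enumerate(sorted(rng.integers(0, 90_000, 10) * 1))
        ]
        members = [
            GenomicSegment("chr1", int(s), int(s) + 800, E, f"e{i}")
            for i, s in enumerate(rng.integers(0, 99_000, 50))
        ]
        cat = SegmentCatalog("t", tads + members)
        m = build_incidence_matrix(cat, TAD, E).data.toarray()
        for p, t in enumerate(cat.segments_of(TAD)):
            for q, e in enumerate(cat.segments_of(E)):
                expected = 1.0 if (e.start < t.end and e.end > t.start) else 0.0
                assert m[p, q] == expected


class TestTheta:
    def test_shared_tad_pair_negative(self, small_catalog):
        theta = build_theta(small_catalog, E, hic_evidence=None, use_tads=True)
        i, j = small_catalog.ordinal(E, "e1"), small_catalog.ordinal(E, "e2")
        assert theta.data[i, j] == -1.0
        assert theta.data[j, i] == -1.0
        # cross-TAD pair untouched
        k = small_catalog.ordinal(E, "e3")
        assert theta.data[i, k] == 0.0

    def test_hic_pair_crossing_tads_negative(self, small_catalog):
        hic = _table([(("chr1", 40_000, 52_000), ("chr1", 1_199_000, 1_202_000))], "hic")
        theta = build_theta(small_catalog, P, hic_evidence=hic, use_tads=False)
        i, j = small_catalog.ordinal(P, "p1"), small_catalog.ordinal(P, "p2")
        assert theta.data[i, j] == -1.0

    def test_lambda_scales_entries(self, small_catalog):
        theta = build_theta(small_catalog, E, use_tads=True, lambda_theta=0.25)
        vals = set(np.unique(theta.data.toarray()))
        assert vals <= {0.0, -0.25}

    def test_matches_brute_force_pairwise_scan(self):
        rng = np.random.default_rng(11)
        tads = [
            GenomicSegment("chr1", 20_000 * i, 20_000 * (i + 1), TAD, f"t{i}")
            for i in range(5)
        ]
        enh = [
            GenomicSegment("chr1", int(s), int(s) + 500, E, f"e{i}")
            for i, s in enumerate(rng.integers(0, 99_000, 50))
        ]
        cat = SegmentCatalog("t", tads + enh)
        theta = build_theta(cat, E, use_tads=True).data.toarray()
        segs = cat.segments_of(E)
        for i in range(len(segs)):
            for j in range(len(segs)):
                share = i != j and any(
                    segs[i].start < t.end and segs[i].end > t.start
                    and segs[j].start < t.end and segs[j].end > t.start
                    for t in tads
                )
                assert theta[i, j] == (-1.0 if share else 0.0)


class TestWindowProblems:
    def test_default_schema_yields_17_matrices(self, planted):
        _model, inputs, _ = planted
        window = GenomeWindow("chr1", 0, 5_000_000)
        prob = build_problem_for_window(
            inputs.catalog, inputs.evidence, window, default_schema()
        )
        assert prob.n_blocks() == 17
        assert len(prob.relations) == 15 and len(prob.constraints) == 2

    def test_missing_source_blocks_absent_not_zero(self, planted):
        _model, inputs, _ = planted
        evidence = {k: v for k, v in inputs.evidence.items() if k != "eqtl"}
        window = GenomeWindow("chr1", 0, 5_000_000)
        schema = default_schema().without_source("eqtl")
        prob = build_problem_for_window(inputs.catalog, evidence, window, schema)
        snp = SegmentType.EQTL_SNP
        assert all(snp not in key for key in prob.relations)
        assert prob.n_blocks() == 17 - 4  # eQTL R, SNP-E/anchor inc, TAD-SNP inc

    def test_empty_window_all_blocks_absent(self, planted):
        _model, inputs, _ = planted
        window = GenomeWindow("chr9", 0, 5_000_000)
        prob = build_problem_for_window(inputs.catalog, inputs.evidence, window)
        assert prob.n_blocks() == 0

    def test_window_union_matches_whole_chromosome_build(self, planted):
        """Nonzeros of per-window E-P matrices, unioned, equal the nonzeros of
        one unwindowed build restricted to co-window pairs."""
        _model, inputs, _ = planted
        cat = inputs.catalog
        ev = inputs.evidence["coactivity"]
        windows = [
            GenomeWindow("chr1", s, min(s + 5_000_000, 10_000_000))
            for s in (0, 2_500_000, 5_000_000, 7_500_000)
        ]
        union = set()
        for w in windows:
            wcat = cat.restrict_to_window(w)
            m = build_interaction_matrix(ev, wcat, E, P, w).data.tocoo()
            e_ids = [s.id for s in wcat.segments_of(E)]
            p_ids = [s.id for s in wcat.segments_of(P)]
            union |= {(e_ids[r], p_ids[c]) for r, c in zip(m.row, m.col)}
        full = build_interaction_matrix(ev, cat, E, P).data.tocoo()
        e_ids = [s.id for s in cat.segments_of(E)]
        p_ids = [s.id for s in cat.segments_of(P)]
        cowindow = set()
        for w in windows:
            wcat = cat.restrict_to_window(w)
            we = {s.id for s in wcat.segments_of(E)}
            wp = {s.id for s in wcat.segments_of(P)}
            cowindow |= {(a, b) for a in we for b in wp}
        full_pairs = {
            (e_ids[r], p_ids[c]) for r, c in zip(full.row, full.col)
        } & cowindow
        assert union == full_pairs
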