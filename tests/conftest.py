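import numpy as np
import pytest

from swipe_nmf.core_model import GenomicSegment, SegmentCatalog, SegmentType
from swipe_nmf.synthetic_fixtures import PlantedModel, make_inputs

E = SegmentType.ENHANCER
P = SegmentType.PROMOTER
ANCHOR = SegmentType.HIC_ANCHOR
SNP = SegmentType.EQTL_SNP
DHS = SegmentType.DHS
TAD = SegmentType.TAD


@pytest.fixture
def small_catalog() -> SegmentCatalog:
    """A hand-laid catalog: two TADs, four enhancers, three promoters,
    two Hi-C anchors, two SNPs, two DHS sites on one chromosome."""
    segs = [
        GenomicSegment("chr1", 0, 1_000_000, TAD, "tadA"),
        GenomicSegment("chr1", 1_000_000, 2_000_000, TAD, "tadB"),
        GenomicSegment("chr1", 100, 600, E, "e1"),
        GenomicSegment("chr1", 10_000, 11_000, E, "e2"),
        GenomicSegment("chr1", 1_100_000, 1_101_000, E, "e3"),
        GenomicSegment("chr1", 1_500_000, 1_500_800, E, "e4"),
        GenomicSegment("chr1", 50_000, 51_500, P, "p1"),
        GenomicSegment("chr1", 1_200_000, 1_201_500, P, "p2"),
        GenomicSegment("chr1", 1_900_000, 1_901_500, P, "p3"),
        GenomicSegment("chr1", 9_000, 49_000, ANCHOR, "a1"),
        GenomicSegment("chr1", 1_099_000, 1_210_000, ANCHOR, "a2"),
        GenomicSegment("chr1", 200, 201, SNP, "s1"),
        GenomicSegment("chr1", 1_500_400, 1_500_401, SNP, "s2"),
        GenomicSegment("chr1", 300, 600, DHS, "d1"),
        GenomicSegment("chr1", 1_200_100, 1_200_400, DHS, "d2"),
    ]
    return SegmentCatalog("test-tissue", segs)


@pytest.fixture(scope="session")
def planted() -> tuple:
    """One default planted fixture shared by pipeline-level tests."""
    model = PlantedModel(seed=1)
    inputs, labels = make_inputs(model)
    return model, inputs, labels
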