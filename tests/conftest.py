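"""Shared fixtures: generated codes and libraries reused across test modules."""

import pytest

from smartscreen.barcode_design import BarcodeSet, CompositionRules, generate_barcodes
from smartscreen.synthetic_data import Construct, LibraryDesign, simulate_library

# permissive rules for hand-written toy sequences (AAAA etc.)
PERMISSIVE = CompositionRules(gc_min=0.0, gc_max=1.0, max_homopolymer=100)


@pytest.fixture(scope="session")
def default_code() -> BarcodeSet:
    """The screen-scale code: 70 barcodes, 20 nt, minimum distance 10."""
    return generate_barcodes(n=70, length=20, min_distance=10, seed=1)


@pytest.fixture(scope="session")
def default_library() -> LibraryDesign:
    """Full default library: 34 elements x 2 barcodes + duplicated controls."""
    return simulate_library(seed=1)


@pytest.fixture(scope="session")
def small_library() -> LibraryDesign:
    """A 6-element, 2-barcodes-per-construct library for fast pipeline tests."""
    return simulate_library(n_elements=6, barcodes_per_construct=2, seed=3)


@pytest.fixture()
def micro_library() -> LibraryDesign:
    """Hand-built 3-construct library with explicit barcodes for arithmetic tests."""
    bset = BarcodeSet(
        barcodes=["AAAACCCC", "GGGGTTTT", "ACACGTGT"],
        length=8,
        min_distance=4,
        constraints=PERMISSIVE,
        labels=["BC001", "BC002", "BC003"],
    )
    constructs = [
        Construct("E01", "enhancer", ["BC001"], 5000),
        Construct("Pro", "promoter_only", ["BC002"], 4800),
        Construct("EFS", "efs_control", ["BC003"], 5200),
    ]
    return LibraryDesign(
        constructs=constructs,
        anchor5="TTGACGTCA",
        anchor3="CATGCATGC",
        barcode_set=bset,
    )
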