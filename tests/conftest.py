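import numpy as np
import pandas as pd
import pytest

from mirscreen.library import GuideLibrary
from mirscreen.simulate import SimConfig, simulate_library, simulate_panel


def make_library_frame(rows):
    return pd.DataFrame(
        rows,
        columns=[
            "guide_id", "spacer", "gene_id", "guide_class",
            "chrom", "pos", "strand", "offtarget_count",
        ],
    )


@pytest.fixture
def toy_library():
    """1 miRNA gene (2 guides), 1 essential control, 1 intergenic, 1 non-targeting."""
    rows = [
        ("g1", "A" * 20, "MIR1", "mirna_targeting", "chr1", 100, "+", 0),
        ("g2", "C" * 20, "MIR1", "mirna_targeting", "chr1", 130, "-", 1),
        ("g3", "G" * 20, "RPL1", "essential_control", "chr1", 5000, "+", 0),
        ("g4", "T" * 20, "INTERGENIC_1", "intergenic_control", "chr2", 200, "+", 0),
        ("g5", "AC" * 10, "NT_1", "non_targeting", None, None, None, 0),
    ]
    return GuideLibrary(make_library_frame(rows))


@pytest.fixture(scope="session")
def small_sim():
    """Small but complete simulated panel shared across tests (read-only)."""
    cfg = SimConfig(
        n_genes=120,
        n_screens=4,
        n_replicates=2,
        n_common_essential=6,
        n_context_essential=12,
        n_intergenic=100,
        seed=42,
    )
    lib, truth = simulate_library(cfg)
    panel = simulate_panel(lib, truth, cfg)
    return cfg, lib, truth, panel
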