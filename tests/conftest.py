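import numpy as np
import pandas as pd
import pytest

from sigtome import synthetic_data as sd
from sigtome.annotations import PathwayAnnotation
from sigtome.io_formats import SignatureTable


@pytest.fixture
def small_config() -> sd.SimulationConfig:
    return sd.SimulationConfig(
        n_probes=800,
        signature_size=80,
        n_pathways=20,
        pathway_size_range=(5, 25),
        seed=11,
    )


@pytest.fixture
def small_study(small_config) -> sd.ExpressionStudy:
    return sd.generate_study(small_config)


@pytest.fixture
def toy_annotation() -> PathwayAnnotation:
    return PathwayAnnotation.from_sets({
        "apoptosis": ["g1", "g2", "g3", "g4", "g5"],
        "p53": ["g4", "g5", "g6", "g7"],
        "notch": ["g8", "g9"],
    })


def make_signature_table(genes, log2fc, p=None, background=None) -> SignatureTable:
    genes = list(genes)
    frame = pd.DataFrame({
        "probe_id": [f"pr_{g}" for g in genes],
        "gene_id": genes,
        "log2fc": np.asarray(log2fc, dtype=float),
        "p_value": np.asarray(p if p is not None else [0.01] * len(genes),
                              dtype=float),
    })
    return SignatureTable(frame=frame, background_size=background)


@pytest.fixture
def table_factory():
    return make_signature_table
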