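import numpy as np
import pandas as pd
import pytest

from mirnome import CountMatrix, MiRNAPanelDE, SimulationConfig, simulate_counts


def build_matrix(counts, code_classes=None, groups=None, fraction="cell_fraction", rins=None):
    """Small CountMatrix from a probe -> per-sample count mapping."""
    counts = {p: list(v) for p, v in counts.items()}
    n_samples = len(next(iter(counts.values())))
    sample_ids = [f"S{i + 1}" for i in range(n_samples)]
    code_classes = code_classes or {}
    ann = pd.DataFrame(
        {
            "code_class": [code_classes.get(p, "Endogenous") for p in counts],
            "accession": ["" for _ in counts],
        },
        index=pd.Index(list(counts), name="probe_id"),
    )
    frame = pd.DataFrame(counts, index=sample_ids).T.astype("int64")
    frame.index = ann.index
    samples = pd.DataFrame(
        {
            "group": groups or ["case"] * (n_samples // 2) + ["control"] * (n_samples - n_samples // 2),
            "fraction": [fraction] * n_samples,
            "rin": rins or [None] * n_samples,
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    return CountMatrix(counts=frame, annotations=ann, samples=samples)


@pytest.fixture(scope="session")
def small_panel():
    """A compact two-group cellular panel with planted effects."""
    cfg = SimulationConfig(
        n_endogenous=120, n_negative=6, n_spikein=6, n_case=10, n_control=10,
        n_de=8, fold_range=(2.0, 2.0), seed=42,
    )
    return simulate_counts(cfg)


@pytest.fixture(scope="session")
def small_fit(small_panel):
    matrix, truth = small_panel
    return MiRNAPanelDE(matrix).fit(), truth


@pytest.fixture(scope="session")
def null_panel_fit():
    """Full-size null panel (no planted effects) fitted once per session."""
    matrix, _ = simulate_counts(SimulationConfig(seed=0))
    return MiRNAPanelDE(matrix).fit()
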