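import numpy as np
import pytest

from clpnet import PanelDataset, generate_panel, make_paper_like_config


@pytest.fixture(scope="session")
def paper_panel_noclip() -> PanelDataset:
    """One study-sized dataset from the study-like generator, clipping off
    (the exact linear-Gaussian surface used for parameter recovery)."""
    return generate_panel(make_paper_like_config(seed=42, clip_mode="none"))


@pytest.fixture(scope="session")
def small_panel() -> PanelDataset:
    """Small clipped dataset for structural / IO tests."""
    return generate_panel(make_paper_like_config(seed=7, n_subjects=80))


def random_panel(n: int, seed: int, means=None) -> PanelDataset:
    """Independent-noise panel with optional per-wave mean shifts for one
    node (means: dict node_index -> (m1, m2, m3)); all scores ~ N(50, 8)."""
    rng = np.random.default_rng(seed)
    scores = {}
    for w, wave in enumerate(("T1", "T2", "T3")):
        m = rng.normal(50.0, 8.0, size=(n, 15))
        if means:
            for j, shifts in means.items():
                m[:, j] = rng.normal(shifts[w], 8.0, size=n)
        scores[wave] = np.clip(m, 0, 100)
    return PanelDataset(subject_ids=np.arange(n), scores=scores)
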