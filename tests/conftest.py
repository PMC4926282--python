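"""Shared fixtures: small seeded synthetic studies and helper writers."""

from __future__ import annotations

import pandas as pd
import pytest

from binflux import simulate as sim


@pytest.fixture(scope="session")
def small_dataset() -> sim.SyntheticDataset:
    """Compact noisy community (20 bins) for fast module tests."""
    community = sim.CommunitySpec(n_bins=20, n_responsive=8)
    return sim.generate_dataset(11, community=community)


@pytest.fixture(scope="session")
def zero_noise_dataset() -> sim.SyntheticDataset:
    """Default-size community with all noise switched off."""
    design = sim.DesignSpec(noise_cv=0.0)
    return sim.generate_dataset(23, design=design, process_noise=False)


@pytest.fixture()
def tiny_design() -> pd.DataFrame:
    """Two samples, one reactor, hand-written design rows."""
    return pd.DataFrame(
        {
            "sample_id": ["s1", "s2"],
            "experimental_set": ["non_acclimatized", "non_acclimatized"],
            "reactor_id": ["R1", "R1"],
            "replicate": [1, 1],
            "lcfa_dose": [2.0, 2.0],
            "period": ["I", "II"],
            "day": [2, 7],
            "aligned_reads": [100, 200],
        }
    )


def write_tsv(path, text: str) -> str:
    path.write_text(text, encoding="utf-8")
    return str(path)
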