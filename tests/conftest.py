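import numpy as np
import pandas as pd
import pytest

import hhdkit as hk


@pytest.fixture(scope="session")
def embryonic_sim():
    """Small population with a fully penetrant embryonic lethal (seeded)."""
    cfg = hk.SimConfig(
        seed=11, n_sires=20, daughters_per_sire=60, sons_per_sire=3,
        chrom_length_mb=10.0, markers_per_mb=30.0, q0=0.05,
        causal_pos_mb=5.0, lethality="embryonic", penetrance=1.0,
    )
    return hk.simulate_population(cfg)


@pytest.fixture(scope="session")
def neutral_sim():
    """Population without lethality, same structure (seeded)."""
    cfg = hk.SimConfig(
        seed=13, n_sires=15, daughters_per_sire=50, sons_per_sire=3,
        chrom_length_mb=8.0, markers_per_mb=25.0, q0=0.05,
        causal_pos_mb=4.0, lethality="none",
    )
    return hk.simulate_population(cfg)


@pytest.fixture(scope="session")
def scan_sim():
    """Medium population sized so the deficit scan has power at alpha = 1e-6."""
    cfg = hk.SimConfig(
        seed=17, n_sires=30, daughters_per_sire=150, sons_per_sire=3,
        chrom_length_mb=10.0, markers_per_mb=30.0, q0=0.05,
        causal_pos_mb=5.0, lethality="embryonic", penetrance=1.0,
    )
    return hk.simulate_population(cfg)


def make_marker_map(n: int, chrom: str = "1", spacing: int = 100_000) -> hk.MarkerMap:
    return hk.MarkerMap(
        pd.DataFrame(
            {
                "marker_id": [f"m{i}" for i in range(n)],
                "chrom": chrom,
                "pos_bp": np.arange(1, n + 1) * spacing,
            }
        )
    )


@pytest.fixture
def marker_map3():
    return make_marker_map(3)
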