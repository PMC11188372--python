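from pathlib import Path

import pytest

import toxregulon as tr

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def demo_dir() -> Path:
    return DATA_DIR / "demo"


@pytest.fixture(scope="session")
def golden_dir() -> Path:
    return DATA_DIR / "golden"


@pytest.fixture(scope="session")
def small_regulons():
    return tr.simulate_regulons(n_tfs=6, targets_per_tf=(8, 20), overlap_prob=0.2, seed=11)


@pytest.fixture(scope="session")
def small_design():
    chems = [
        tr.Chemical("pfas-a", "PFAS", (1.0, 10.0, 100.0)),
        tr.Chemical("pah-b", "PAH", (1.0, 10.0, 100.0)),
    ]
    return tr.StudyDesign(chems, n_treated=4, n_control=5, n_genes=150)


@pytest.fixture(scope="session")
def planted_study(small_design, small_regulons):
    """Study with an all-up TF001 regulon effect planted in males only."""
    effects = [
        tr.PlantedEffect(tf="TF001", direction="up", max_log2fc=2.0, sexes=("male",)),
    ]
    return tr.simulate_study(
        small_design, small_regulons, effects, noise_sd=0.3, mode="lognormal", seed=7
    )
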