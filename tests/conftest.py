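import numpy as np
import pytest

import oligodyn as od


@pytest.fixture(scope="session")
def toy_panel():
    """Two families, three variants each, <=3 segregating positions."""
    return od.generate_variant_panel(2, 3, 3, 130, seed=7)


@pytest.fixture(scope="session")
def toy_dataset(toy_panel, tmp_path_factory):
    """A small emitted dataset: 20 sampled days, depth 500, 0.1% error."""
    out = tmp_path_factory.mktemp("toy_dataset")
    specs = {e.name: od.DynamicsSpec(fluctuation_sd=0.3, ar1_coeff=0.9) for e in toy_panel}
    truth = od.simulate_trajectories(toy_panel, specs, 22, missing_days={5, 12}, seed=1)
    manifest, truth_path = od.emit_reads(truth, 500, 0.001, 130, out, seed=2)
    toy_panel.to_fasta(out / "panel.fasta")
    return {
        "dir": out,
        "panel": toy_panel,
        "truth": truth,
        "manifest": manifest,
        "truth_path": truth_path,
    }


def hamming(a: str, b: str) -> int:
    assert len(a) == len(b)
    return sum(x != y for x, y in zip(a, b))


@pytest.fixture
def rng():
    return np.random.default_rng(123)
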