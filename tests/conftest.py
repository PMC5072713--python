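from __future__ import annotations

import sys
from pathlib import Path
from types import SimpleNamespace

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))   # for the oracles module

from plastokit import synth


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=n)])


@pytest.fixture(scope="session")
def synth_bundle(tmp_path_factory):
    """The stock synthetic study: genome, features, truth, simulated reads."""
    config = synth.default_config(seed=1)
    genome, features, truth = synth.generate_plastome(config)
    sam = tmp_path_factory.mktemp("synth") / "reads.sam"
    read_truth = synth.simulate_reads(genome, features, truth, config, sam)
    return SimpleNamespace(config=config, genome=genome, features=features,
                           truth=truth, sam=sam, read_truth=read_truth)


@pytest.fixture()
def rng():
    return np.random.default_rng(20_240_101)
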