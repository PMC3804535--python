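import numpy as np
import pytest

from swaloop.config import RunConfig
from swaloop.fixtures import make_recovery_problem, make_scaffold
from swaloop.geometry import build_from_torsions


def helix_torsions(n, phi=-63.0, psi=-43.0):
    return {r: {"phi": phi, "psi": psi, "omega": 180.0} for r in range(1, n + 1)}


@pytest.fixture(scope="session")
def ala_helix():
    """16-residue helix with a few rotameric residues, frozen as scaffold."""
    seq = "AASLAAVAASAALAAA"
    conf = build_from_torsions(seq, helix_torsions(16))
    return conf.freeze_as_scaffold()


@pytest.fixture(scope="session")
def small_problem():
    """Length-4 recovery problem on a small helix-turn scaffold."""
    scaffold = make_scaffold(16, "helix_turn", seed=5)
    return make_recovery_problem(scaffold, (7, 10), seed=5)


@pytest.fixture()
def coarse_config():
    cfg = RunConfig.coarse()
    cfg.mode = "linear"
    return cfg


@pytest.fixture(scope="session")
def recovery_sweep():
    """Five planted-optimum recovery problems (length-4 loops) solved by the
    full pipeline at the 20-degree grid; shared across tests."""
    from swaloop.dag import run_pipeline

    results = {}
    for s in range(1, 6):
        scaffold = make_scaffold(16, "helix_turn", seed=s)
        prob = make_recovery_problem(scaffold, (7, 10), seed=s)
        cfg = RunConfig.coarse()
        cfg.mode = "linear"
        cfg.seed = s
        preds, report = run_pipeline(prob.problem, (7, 10), cfg)
        results[s] = (prob, preds, report)
    return results


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)
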