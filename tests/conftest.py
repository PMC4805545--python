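import pytest

from fostag.cassettes import load_registry
from fostag.read_simulator import simulate_plate
from fostag.synthetic import build_plate_scenario
from fostag.validator import ReferenceSet, validate_pools


@pytest.fixture(scope="session")
def registry():
    return load_registry()


@pytest.fixture(scope="session")
def cassette(registry):
    return registry["tags"]["sgfp_tag"]


@pytest.fixture(scope="session")
def pretag(registry):
    return registry["pretag"]


@pytest.fixture(scope="session")
def small_scenario():
    """8-clone plate with one arm substitution, one un-flipped clone and one
    junction deletion; reused across validator tests."""
    return build_plate_scenario(
        n_clones=8, seed=1,
        defect_assignment={1: "arm_sub", 3: "unflipped", 5: "junction_del2"})


@pytest.fixture(scope="session")
def small_run(small_scenario):
    """Simulated pools, reference set and verdicts for the small scenario."""
    sc = small_scenario
    by_pool = simulate_plate(sc.plate, sc.pools, sc.defective, depth=50,
                             seq_error_rate=0.005, dup_rate=0.2, seed=1)
    refs = ReferenceSet(sc.constructs, sc.cassette)
    verdicts = validate_pools(by_pool, refs, sc.pools)
    return {"scenario": sc, "by_pool": by_pool, "refs": refs,
            "verdicts": verdicts}
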