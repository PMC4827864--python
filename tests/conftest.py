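import hypothesis
import pytest

hypothesis.settings.register_profile(
    "deterministic", derandomize=True, max_examples=25, deadline=None
)
hypothesis.settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def barrel8():
    """A standard 8-hairpin synthetic barrel with ground truth."""
    from ompbarrel.simulate import BarrelSpec, make_ancestor

    rec, truth, model = make_ancestor(BarrelSpec(n_hairpins=8), seed=11)
    return rec, truth, model


@pytest.fixture(scope="session")
def small_family(barrel8):
    """Ten members at ~40% within-family identity."""
    from ompbarrel.simulate import FamilySpec, evolve_family

    _, _, model = barrel8
    return evolve_family(model, FamilySpec(10, 0.4, seed=21))
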