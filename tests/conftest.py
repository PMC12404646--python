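import pytest

from endodiff.model_core import REFERENCE_PARAMS, ModelSpec
from endodiff.synthetic_data import default_config, generate_study


@pytest.fixture(scope="session")
def ref_spec() -> ModelSpec:
    return ModelSpec.from_code("M1-gompertz-combined")


@pytest.fixture(scope="session")
def ref_theta(ref_spec):
    return {k: REFERENCE_PARAMS[k] for k in ref_spec.struct_param_names}


@pytest.fixture(scope="session")
def ref_xi():
    return {"a": REFERENCE_PARAMS["a"], "b": REFERENCE_PARAMS["b"]}


@pytest.fixture(scope="session")
def study():
    """One default synthetic study (6 replicates, days 0-5), with truth."""
    return generate_study(default_config(seed=2024))


def random_theta(rng, spec: ModelSpec) -> dict[str, float]:
    """Random structural parameters in a moderate, integrable range."""
    theta = {}
    for name in spec.struct_param_names:
        if name == "nmax":
            theta[name] = rng.uniform(300.0, 3000.0)
        elif name.startswith("p_"):
            theta[name] = rng.uniform(0.0, 1.0)
        elif name.startswith("beta"):
            theta[name] = rng.uniform(0.0, 5.0)
        else:
            theta[name] = rng.uniform(0.0, 2.0)
    return theta
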