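import numpy as np
import pytest

from nmfseg import PhantomSpec, generate_phantom, run_pipeline


@pytest.fixture(scope="session")
def default_phantom():
    """Default-spec phantom, seed 1; shared across the suite."""
    spec = PhantomSpec(seed=1)
    t2, flair, t1c, truth = generate_phantom(spec)
    return {"spec": spec, "t2": t2, "flair": flair, "t1c": t1c, "truth": truth}


@pytest.fixture(scope="session")
def pipeline_run(default_phantom):
    """One full default-config pipeline run on the default phantom."""
    label_map, results = run_pipeline(
        default_phantom["t2"],
        default_phantom["flair"],
        default_phantom["t1c"],
    )
    return {"label_map": label_map, "results": results}


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
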