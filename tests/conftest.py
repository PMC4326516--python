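import numpy as np
import pytest
from hypothesis import settings

from grasemap.fitting import fit_map
from grasemap.phantoms import PhantomSpec, generate_stack
from grasemap.protocols import preset

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def protocol_6ec():
    return preset("6Ec")


@pytest.fixture(scope="session")
def tube_phantom_fit(protocol_6ec):
    """Six-tube phantom at SNR 50 (optimized profile) with its MLE map.

    Session-scoped: the pixelwise ML fit of the full-matrix phantom is
    the most expensive single computation in the suite and several tests
    inspect the same result.
    """
    spec = PhantomSpec(kind="tubes", snr=50.0, seed=20150212)
    stack, truth = generate_stack(spec, protocol_6ec)
    result = fit_map(stack, mask=truth["label_map"] > 0, method="mle")
    return spec, stack, truth, result


def tube_medians(truth, result):
    """Per-tube median fitted T2, ordered by tube label."""
    labels = truth["label_map"]
    return {
        lab: float(np.median(result.t2_map[(labels == lab) & result.converged_mask]))
        for lab in sorted(truth["t2_values"])
    }
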