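import numpy as np
import pytest

from diolconf import synthetic_data as syn
from diolconf import trajectory_io as tio


@pytest.fixture(scope="session")
def small_run():
    """A small seeded synthetic run shared by the analysis-stage tests.

    6 molecules x 120 frames under the solution-like default model, built
    into coordinates in a 30 A cubic box.
    """
    rng = np.random.default_rng(1234)
    model = syn.TorsionChainModel.solution_like()
    sim = syn.simulate_labels(model, n_molecules=6, n_frames=120, seed=rng)
    frames = syn.build_coordinates(sim.quads, box=(30.0, 30.0, 30.0), seed=rng)
    topology = syn.default_topology(6)
    stream = tio.from_frames(frames, stride_ps=model.stride_ps)
    return {
        "model": model,
        "sim": sim,
        "frames": frames,
        "topology": topology,
        "stream": stream,
    }
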