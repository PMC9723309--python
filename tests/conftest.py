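import numpy as np
import pytest

from oscimap import montage, net, synth, topo


@pytest.fixture(scope="session")
def layout():
    return montage.standard_layout()


@pytest.fixture(scope="session")
def grid(layout):
    return topo.build_grid_assignment(layout)


@pytest.fixture(scope="session")
def short_recording(layout):
    """A 20 s healthy-control recording with all artifact sources on."""
    cfg = synth.SimulationConfig(duration_s=20.0)
    sig = synth.default_signatures(2.0)["HC"]
    return synth.generate_recording(sig, cfg, seed=7, layout=layout)


@pytest.fixture(scope="session")
def small_volumes(grid, short_recording):
    """Spectral volumes of the short recording's kept trials."""
    from oscimap import preprocess

    ts = preprocess.run_pipeline(short_recording)
    return topo.trials_to_volumes(ts.kept(), ts.rate, grid)


@pytest.fixture(scope="session")
def default_model():
    return net.build_model(net.ModelSpec(), seed=0)
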