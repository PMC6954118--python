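import pytest

from bbmnet import compile_network, CompileOptions
from bbmnet.fixtures import MotifConfig, modification_motif


@pytest.fixture
def phospho_cycle_model():
    """Modification motif with only the phosphocycle clamped on
    (syn/deg off), compiled without smoothing."""
    cfg = MotifConfig(syn=False, deg=False, fwd=True, rev=True,
                      init=(True, False))
    net = modification_motif(cfg)
    return compile_network(net, CompileOptions(smoothing=False))


def attractor_by_name(model, result):
    """Map a point attractor to {original target name: value}."""
    assert result.is_point
    final = result.attractor[0]
    return {t.name: final[i] for i, t in enumerate(model.targets)}
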