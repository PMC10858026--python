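import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from imcfiber.panel import default_panel

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def panel():
    return default_panel()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_panel_csv(tmp_path_factory):
    """A minimal valid 3-channel panel file."""
    p = tmp_path_factory.mktemp("panel") / "panel3.csv"
    p.write_text(
        "marker_name,metal_tag,channel_index,target_class\n"
        "Laminin,149Sm,0,fiber_marker\n"
        "CD68,159Tb,1,cell_marker\n"
        "DNA,191Ir,2,nuclei\n"
    )
    return p
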