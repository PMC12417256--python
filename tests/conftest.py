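import pytest

from atopt import bundled_config_path, load_config, load_default


@pytest.fixture(scope="session")
def lv_cfg():
    """Default Lotka-Volterra run configuration."""
    return load_default("lv")


@pytest.fixture(scope="session")
def lv_turnover_cfg():
    """LV variant with natural turnover d = 0.3 r_S and a smaller tumor."""
    return load_config(bundled_config_path("lv_turnover"))


@pytest.fixture(scope="session")
def wc_cfg():
    """Default waning-competition run configuration."""
    return load_default("wc")


@pytest.fixture(scope="session")
def sc_cfg():
    """Default stem-cell run configuration."""
    return load_default("sc")
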