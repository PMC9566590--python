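import pytest

from sensits import DEFAULT_CONFIG, PanelSpec, generate_panel


@pytest.fixture(scope="session")
def cfg():
    return DEFAULT_CONFIG


@pytest.fixture(scope="session")
def clean_panel():
    """Noise-free panel: no missingness, every score branch exercised."""
    return generate_panel(PanelSpec(n_chemicals=64, prevalence=0.7, seed=7))


@pytest.fixture()
def tiny_panel_path(tmp_path):
    from sensits import generate_assay_calls
    from sensits.io import write_panel

    panel = generate_panel(PanelSpec(n_chemicals=12, prevalence=0.5, seed=3))
    calls = generate_assay_calls(panel, seed=4)
    path = tmp_path / "panel.csv"
    write_panel(panel, path, assay_calls=calls)
    return path
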