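import warnings

import numpy as np
import pytest

import npscreen as nps


@pytest.fixture()
def example_record():
    """The worked fragment-selection example: 4 peaks, 2 above the 10% threshold."""
    return nps.SpectrumRecord(
        analyte_id="example",
        precursor_mz=377.2,
        retention_time=5.0,
        peaks=[(232.1126, 1000.0), (144.0444, 400.0), (116.0495, 90.0), (77.0386, 50.0)],
        class_label="JWH",
    )


@pytest.fixture(scope="session")
def separated_panel_matrix():
    """Balanced 9-class panel from the idealized (unimodal) templates."""
    panel = nps.generate_panel(nps.well_separated_templates(), 20, seed=11)
    return nps.build_matrix(panel.records, nl_reference="precursor")


@pytest.fixture(scope="session")
def fitted_models(separated_panel_matrix):
    """SIMCA models of the balanced panel (published-style configuration)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return nps.fit_all_classes(separated_panel_matrix, A_max=3)


@pytest.fixture()
def gaussian_class():
    """A single anisotropic Gaussian class for calibration-style checks."""
    rng = np.random.default_rng(123)
    return rng.normal(size=(200, 8)) @ np.diag([3, 2.5, 2, 1.5, 1, 0.8, 0.5, 0.3])
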