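import numpy as np
import pytest

from siderocalc.chem import load_model, packaged_model


@pytest.fixture(scope="session")
def minimal_pl_model():
    """P + L = PL with log K = 6 and a proton component for pH clamping."""
    return load_model(
        {
            "components": [
                {"name": "P", "role": "protein"},
                {"name": "L", "role": "ligand"},
                {"name": "H", "role": "proton"},
            ],
            "species": [
                {"label": "PL", "stoich": {"P": 1, "L": 1}, "log_beta": 6.0,
                 "provenance": "test"},
            ],
        }
    )


@pytest.fixture(scope="session")
def bare_plh_model():
    """Protein/ligand/proton components with no species (fit candidates supply them)."""
    return load_model(
        {
            "components": [
                {"name": "P", "role": "protein"},
                {"name": "L", "role": "ligand"},
                {"name": "H", "role": "proton"},
            ],
            "species": [],
        }
    )


@pytest.fixture(scope="session")
def dhba_model():
    return packaged_model("dhba23")


@pytest.fixture(scope="session")
def ga_model():
    return packaged_model("gentisate")


def quadratic_bound(p_total, l_total, k_assoc):
    """Closed-form 1:1 complex concentration (independent oracle)."""
    b = p_total + l_total + 1.0 / k_assoc
    return (b - np.sqrt(b * b - 4.0 * p_total * l_total)) / 2.0
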