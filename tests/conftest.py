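import numpy as np
import pytest

import sabrekit as sk


@pytest.fixture(scope="session")
def cpdtst_efficacy_groups():
    """Sharing structure that matches the CpdTst ground truth: balanced
    ligands share one efficacy across pathways, the biased one gets a
    pathway-specific value."""
    return {
        "CpdTst1": "eps1",
        "CpdTst3": "eps3",
        ("CpdTst2", "P1"): "eps2_P1",
        ("CpdTst2", "P2"): "eps2_P2",
    }


@pytest.fixture(scope="session")
def fig4_clean_panel():
    spec = sk.scenario_preset("fig4", noise_sigma=0.0, seed=0)
    return spec, sk.generate_panel(spec)


def make_hill_curve(ligand, pathway, log_ec50, e_max, hill=1.0, points=9, span=3.0):
    logc = np.linspace(log_ec50 - span, log_ec50 + span, points)
    y = sk.hill_response(logc, sk.HillParameters(log_ec50, e_max, hill))
    return sk.ResponseCurve(ligand, pathway, logc, y)
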