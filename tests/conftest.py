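import numpy as np
import pytest

from tdprisk import myocyte as myo
from tdprisk.biomarkers import FEATURE_NAMES
from tdprisk.classifier import RiskANNClassifier
from tdprisk.synthetic import gen_feature_table


@pytest.fixture(scope="session")
def surrogate_runs():
    """Paced 50-beat runs of the surrogate at graded IKr / ICaL block.

    Shared across electrophysiology tests; ~10 s total.
    """
    protocol = myo.PacingProtocol(n_beats=50)
    model = myo.surrogate_model()
    g0 = model.control_conductances()
    runs = {}
    for key, channel, frac in [
        ("control", None, 0.0),
        ("ikr25", "IKr", 0.25), ("ikr50", "IKr", 0.5),
        ("ical25", "ICaL", 0.25), ("ical50", "ICaL", 0.5),
    ]:
        g = dict(g0.g)
        if channel:
            g[channel] = g0[channel] * (1.0 - frac)
        from tdprisk.drug_block import ConductanceSet

        trace = myo.simulate_paced(model, ConductanceSet(g), protocol)
        runs[key] = (trace, myo.select_representative_beat(trace, 25))
    return runs


@pytest.fixture(scope="session")
def signal_tables():
    """Strongly class-separated drug-clustered feature tables."""
    return gen_feature_table(n_drugs_per_class=3, n_samples=60,
                             effect_size=3.0, seed=0)


@pytest.fixture(scope="session")
def trained_classifier(signal_tables):
    train, _ = signal_tables
    X = train[FEATURE_NAMES].to_numpy(float)
    y = train["risk"].to_numpy()
    return RiskANNClassifier(epochs=50, seed=0).fit(X, y)
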