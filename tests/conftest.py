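import numpy as np
import pandas as pd
import pytest
from hypothesis import settings, HealthCheck

from circaprot.quantify import ProteinAbundanceMatrix
from circaprot.simulate import make_design

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_design():
    return make_design()


@pytest.fixture(scope="session")
def default_meta(default_design):
    return default_design.sample_meta()


def matrix_from_raw(raw: pd.DataFrame, sample_meta: pd.DataFrame,
                    peptides_per_protein: int = 3) -> ProteinAbundanceMatrix:
    """Abundance matrix straight from raw intensities (ArcSinH, no
    normalization): the rhythm/detectability test surface."""
    values = np.arcsinh(raw)
    detected = raw > 0
    counts = detected.astype(int) * peptides_per_protein
    return ProteinAbundanceMatrix(values, detected, counts, sample_meta.copy())


@pytest.fixture(scope="session")
def small_simulated(default_design, default_meta):
    from circaprot.simulate import simulate_abundance, DropoutParams
    raw, truth = simulate_abundance(default_design, n_proteins=150,
                                    frac_rhythmic=0.2, noise_sd=0.2,
                                    dropout_params=DropoutParams(500.0, 1.5),
                                    seed=11)
    return raw, truth, matrix_from_raw(raw, default_meta)
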