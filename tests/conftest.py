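import numpy as np
import pytest

from qstratify import CentroidTable, Phenotype, QSTParameter, QSTProfile
from qstratify.profiles import PARAMETERS


@pytest.fixture(scope="session")
def centroids():
    return CentroidTable.load_default()


def make_table(mu_by_pheno, sigma_by_pheno=None):
    """Centroid table with one (mu, sigma) per phenotype, constant over parameters."""
    mu = {
        Phenotype(ph): {p: float(m) for p in PARAMETERS}
        for ph, m in mu_by_pheno.items()
    }
    sigma_by_pheno = sigma_by_pheno or {ph: 1.0 for ph in mu_by_pheno}
    sigma = {
        Phenotype(ph): {p: float(s) for p in PARAMETERS}
        for ph, s in sigma_by_pheno.items()
    }
    return CentroidTable(mu, sigma)


def profile_at(centroids, phenotype, subject_id="s", offset_sd=0.0, skip=()):
    """Profile sitting exactly at (or offset_sd SDs from) a phenotype centroid."""
    values = {}
    for p in PARAMETERS:
        if p in skip:
            continue
        values[p] = centroids.mu(phenotype, p) + offset_sd * centroids.sigma(
            phenotype, p
        )
    return QSTProfile(subject_id=subject_id, values=values, validate=False)


@pytest.fixture
def flat_table():
    """Well-separated constant-profile centroids for controllable probabilities."""
    return make_table(
        {"SL": -2.0, "TH": 2.0, "MH": 6.0},
        {"SL": 1.0, "TH": 1.0, "MH": 1.0},
    )
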