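import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_panel(rows: list[dict]) -> pd.DataFrame:
    """Canonical summary-statistics frame from terse row dicts."""
    defaults = {
        "chrom": "1",
        "pos": 1000,
        "effect_allele": "A",
        "other_allele": "G",
        "eaf": 0.3,
        "beta": 0.1,
        "se": 0.01,
        "pvalue": 1e-8,
        "n": 10_000,
    }
    out = []
    for i, row in enumerate(rows):
        rec = dict(defaults, variant_id=f"rs{i + 1}", pos=1000 + i * 10)
        rec.update(row)
        out.append(rec)
    return pd.DataFrame(out)


@pytest.fixture(scope="session")
def cis_fixture():
    from cismr.simulate import cis_instrument_fixture

    return cis_instrument_fixture()


@pytest.fixture(scope="session")
def il6r():
    from cismr.simulate import il6r_region

    return il6r_region()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_harmonised(rng, n=10, seed_offset=0):
    """A random harmonised instrument frame for estimator identities."""
    local = np.random.default_rng(rng.integers(2**31) + seed_offset)
    g = local.uniform(0.02, 0.12, n) * local.choice([-1, 1], n)
    return pd.DataFrame(
        {
            "variant_id": [f"rs{i}" for i in range(n)],
            "gamma": g,
            "se_gamma": local.uniform(0.005, 0.02, n),
            "beta_out": local.normal(0, 0.05, n),
            "se_out": local.uniform(0.005, 0.05, n),
        }
    )
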