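import numpy as np
import pandas as pd
import pytest

from mrcox.instruments import VariantRecord
from mrcox.simulate import SimulationConfig, simulate_cohort


def make_variant(vid="rs1", eaf=0.3, gamma=0.1, se=0.02, **kw):
    defaults = dict(
        variant_id=vid, chrom="1", pos=1000, effect_allele="A", other_allele="G",
        eaf=eaf, gamma_hat=gamma, se_gamma=se,
    )
    defaults.update(kw)
    return VariantRecord(**defaults)


@pytest.fixture(scope="session")
def small_cohort():
    """A modest cohort (n=1500, 12 variants) reused across read-only tests."""
    cfg = SimulationConfig(
        n_individuals=1500, n_variants=12, causal_effect_theta=0.3,
        n_substudies=2, seed=11,
    )
    cohort, genotypes, variants, true = simulate_cohort(cfg)
    return cfg, cohort, genotypes, variants, true


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def survival_frame(rng):
    """Minimal survival data with the stage-1 covariate columns present."""
    n = 600
    df = pd.DataFrame({"age": rng.uniform(50, 79, n)})
    for k in range(1, 11):
        df[f"pc{k}"] = rng.normal(size=n)
    df["x"] = rng.normal(size=n)
    lam = 0.05 * np.exp(0.5 * df["x"])
    t = rng.exponential(1 / lam)
    c = rng.uniform(5, 15, n)
    df["followup_years"] = np.minimum(t, c)
    df["event"] = (t <= c).astype(int)
    df["substudy"] = "S1"
    return df
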