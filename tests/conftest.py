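import numpy as np
import pytest

from hiscompage import ExpressionMatrix, HierarchyDesign, SurvivalPhenotype
from hiscompage.simulate import SimulationConfig, simulate_dataset


@pytest.fixture
def small_dataset():
    """Small simulated replicate with signal: I=40, K=12, two pathways of 6."""
    cfg = SimulationConfig(I=40, K=12, m_s=6, m_p=0.5, c_p=0.2, scenario=1)
    return simulate_dataset(cfg, rng=np.random.default_rng(42))


@pytest.fixture
def null_dataset():
    """Small replicate under the global null (no gene affects the hazard)."""
    cfg = SimulationConfig(I=40, K=12, m_s=6, c_p=0.2, null=True)
    return simulate_dataset(cfg, rng=np.random.default_rng(7))


def random_survival(rng, n, censor_frac=0.3):
    """Plain exponential survival data without any covariate effect."""
    time = rng.exponential(10.0, size=n)
    event = (rng.random(n) > censor_frac).astype(int)
    return np.maximum(time, 1e-3), event


@pytest.fixture
def toy_files(tmp_path):
    """Tiny on-disk expression/GMT/survival triple for IO and CLI tests."""
    rng = np.random.default_rng(0)
    cfg = SimulationConfig(I=30, K=12, m_s=4, m_p=0.5, c_p=0.2)
    ds = simulate_dataset(cfg, rng=rng)
    from hiscompage import write_expression, write_gmt, write_survival

    expr = tmp_path / "expr.tsv"
    gmt = tmp_path / "sets.gmt"
    surv = tmp_path / "surv.tsv"
    write_expression(ds.X, expr)
    write_gmt(ds.pathways, gmt)
    write_survival(ds.survival, surv)
    return {"expr": expr, "gmt": gmt, "surv": surv, "dataset": ds, "dir": tmp_path}
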