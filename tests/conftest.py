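import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from flowshock import RunConfig
from flowshock.gating import BinnedSeries
from flowshock.replay import run_replay

settings.register_profile(
    "ci", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_replay():
    """One full replay of the default experiment, shared across tests."""
    return run_replay(RunConfig(), seed=7)


@pytest.fixture(scope="session")
def replay_out_dirs(tmp_path_factory):
    """Two replays with identical (config, seed), written to disk."""
    d1 = tmp_path_factory.mktemp("replay_a")
    d2 = tmp_path_factory.mktemp("replay_b")
    r1 = run_replay(RunConfig(), seed=3, out_dir=d1)
    r2 = run_replay(RunConfig(), seed=3, out_dir=d2)
    return (d1, r1), (d2, r2)


def make_series(concentration, bin_width_s=60.0, start_min=0.0,
                mode="SG") -> BinnedSeries:
    """Minimal BinnedSeries around a concentration vector (test helper)."""
    conc = np.asarray(concentration, dtype=float)
    n = len(conc)
    counts = np.maximum(np.rint(conc * 7.0), 0).astype(int)  # 14 ul/min, x2
    zeros = np.zeros(n, dtype=int)
    return BinnedSeries(
        staining_mode=mode, bin_width_s=bin_width_s,
        bin_start_min=start_min + np.arange(n) * bin_width_s / 60.0,
        lna_count=counts, hna_count=zeros, background_count=zeros,
        concentration=conc,
        pct_lna=np.where(counts > 0, 100.0, np.nan),
        pct_hna=np.where(counts > 0, 0.0, np.nan),
        fingerprint_defined=counts > 0)
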