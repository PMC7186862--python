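import numpy as np
import pandas as pd
import pytest

from crossmr.sumstats_io import SUMSTAT_COLUMNS


def make_sumstats(rows: list[dict]) -> pd.DataFrame:
    """Build a canonical summary-stat frame from partial row dicts."""
    defaults = {"chrom": "1", "pos": 1000, "eaf": 0.3, "n": 10000,
                "trait": "trait", "pvalue": 0.5}
    full = []
    for r in rows:
        d = dict(defaults)
        d.update(r)
        full.append(d)
    return pd.DataFrame(full, columns=SUMSTAT_COLUMNS)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def hand_instruments():
    """Five hand-set instruments used across estimator oracle tests."""
    return pd.DataFrame({
        "snp_id": [f"rs{i}" for i in range(1, 6)],
        "beta_exp": [0.10, 0.08, -0.12, 0.15, 0.09],
        "se_exp": [0.010, 0.012, 0.011, 0.013, 0.010],
        "beta_out": [0.021, 0.015, -0.030, 0.028, 0.020],
        "se_out": [0.050, 0.040, 0.060, 0.045, 0.055],
    })


def raps_profile_root_by_grid(insts, lo=-2.0, hi=2.0, step=1e-6,
                              chunk=200_000):
    """Independent RAPS oracle: scan the l2 profile score over a fine
    grid of b and return the first sign-change point (midpoint of the
    bracketing step).  Chunked to bound memory."""
    bx = insts["beta_exp"].to_numpy()[:, None]
    sx = insts["se_exp"].to_numpy()[:, None]
    by = insts["beta_out"].to_numpy()[:, None]
    sy = insts["se_out"].to_numpy()[:, None]
    n_points = int(round((hi - lo) / step)) + 1
    prev_val = None
    prev_b = None
    for start in range(0, n_points, chunk):
        b = lo + step * np.arange(start, min(start + chunk, n_points))
        bb = b[None, :]
        s = np.sqrt(sy**2 + bb**2 * sx**2)
        r = by - bb * bx
        t = r / s
        dtdb = -(bx / s) - r * bb * sx**2 / s**3
        score = (t * dtdb).sum(axis=0)
        if prev_val is not None:
            score = np.concatenate([[prev_val], score])
            b = np.concatenate([[prev_b], b])
        sign = np.sign(score)
        idx = np.where(np.diff(sign) != 0)[0]
        if len(idx):
            return float(b[idx[0]] + step / 2)
        prev_val, prev_b = score[-1], b[-1]
    raise AssertionError("no sign change of the profile score on the grid")


def random_instruments(rng, n, true_beta=0.1, pleio_sd=0.0):
    """Quick random instrument frame for property tests."""
    bx = rng.normal(0.1, 0.03, n)
    sx = rng.uniform(0.005, 0.02, n)
    sy = rng.uniform(0.02, 0.08, n)
    alpha = rng.normal(0.0, pleio_sd, n) if pleio_sd else np.zeros(n)
    by = true_beta * bx + alpha + rng.normal(0.0, 1.0, n) * sy
    bx_obs = bx + rng.normal(0.0, 1.0, n) * sx
    return pd.DataFrame({
        "snp_id": [f"rs{i}" for i in range(n)],
        "beta_exp": bx_obs, "se_exp": sx, "beta_out": by, "se_out": sy,
    })
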