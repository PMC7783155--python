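import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def chemo_step_oracle(U, N, lam, c1dt, c2dt):
    """Brute-force 5-point-stencil update, coded independently of the package.

    Double loop over sites; neighbors outside the lattice read as zero
    (zero-Dirichlet boundary).
    """
    m, n = U.shape
    out = np.zeros_like(U, dtype=float)
    for i in range(m):
        for j in range(n):
            up = U[i - 1, j] if i > 0 else 0.0
            down = U[i + 1, j] if i < m - 1 else 0.0
            left = U[i, j - 1] if j > 0 else 0.0
            right = U[i, j + 1] if j < n - 1 else 0.0
            out[i, j] = (
                (1.0 - 4.0 * lam) * U[i, j]
                + lam * (up + down + left + right)
                + c1dt * N[i, j]
                - c2dt * U[i, j] * N[i, j]
            )
    return out


def ks_statistic_oracle(a, b):
    """Sup-distance between two ECDFs by direct enumeration."""
    a = np.sort(np.asarray(a, dtype=float))
    b = np.sort(np.asarray(b, dtype=float))
    grid = np.concatenate([a, b])
    fa = np.searchsorted(a, grid, side="right") / len(a)
    fb = np.searchsorted(b, grid, side="right") / len(b)
    return float(np.max(np.abs(fa - fb)))


def make_track_table(positions, times_s):
    """Track table from a dict {track_id: [(x, y), ...]} over shared times."""
    rows = []
    for tid, pos in positions.items():
        for t, (x, y) in zip(times_s, pos):
            rows.append((tid, t, x, y))
    return pd.DataFrame(rows, columns=["track_id", "time_s", "x_um", "y_um"])
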