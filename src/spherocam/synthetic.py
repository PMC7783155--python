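"""Synthetic inputs: Brownian reference tracks and drug-perturbation bands.

The Brownian generator emulates single glioblastoma cells migrating in a
low-density monolayer, the condition used to measure the cellular
diffusion coefficient (0.21 um^2/s for untreated U87 cells at a 10-minute
imaging cadence). Per step each cell takes an isotropic Gaussian jump
with total displacement variance 4*D*dt (2*D*dt per axis), the convention
under which the (1/4T) sum-of-squares estimator is unbiased.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: measured untreated cellular diffusion coefficient, um^2/s
DCELL_UM2_S = 0.21
#: MK-2206-treated diffusivity as a fraction of vehicle control, mean and SEM spread
DRUG_FRACTION = 0.40
DRUG_SPREAD = 0.15


@dataclass(frozen=True)
class BrownianSpec:
    """Parameters of a synthetic Brownian track cohort."""

    true_d_um2_s: float = DCELL_UM2_S
    n_cells: int = 100
    n_steps: int = 144
    dt_s: float = 600.0
    origin_radius_um: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.true_d_um2_s < 0:
            raise ValueError("diffusion coefficient must be nonnegative")
        if self.n_cells < 1 or self.n_steps < 1:
            raise ValueError("need at least one cell and one step")
        if self.dt_s <= 0:
            raise ValueError("sampling interval must be positive")
        if self.origin_radius_um < 0:
            raise ValueError("origin scatter radius must be nonnegative")


def brownian_tracks(spec: BrownianSpec) -> pd.DataFrame:
    """Generate a track table of independent 2-D Brownian walkers.

    Origins are scattered uniformly in a disk of ``origin_radius_um``
    (all at the origin when 0); each axis increment is N(0, 2*D*dt).
    Deterministic given the spec's seed.
    """
    rng = np.random.default_rng(spec.seed)
    n, k = spec.n_cells, spec.n_steps
    theta = rng.uniform(0, 2 * np.pi, size=n)
    rad = spec.origin_radius_um * np.sqrt(rng.uniform(0, 1, size=n))
    x0, y0 = rad * np.cos(theta), rad * np.sin(theta)

    sd = np.sqrt(2.0 * spec.true_d_um2_s * spec.dt_s)
    steps = rng.normal(0.0, sd, size=(2, n, k))
    x = np.concatenate([x0[:, None], x0[:, None] + steps[0].cumsum(axis=1)], axis=1)
    y = np.concatenate([y0[:, None], y0[:, None] + steps[1].cumsum(axis=1)], axis=1)

    times = np.arange(k + 1) * spec.dt_s
    return pd.DataFrame(
        {
            "track_id": np.repeat(np.arange(n), k + 1),
            "time_s": np.tile(times, n),
            "x_um": x.ravel(),
            "y_um": y.ravel(),
        }
    )


def drug_r_interval(
    fraction: float = DRUG_FRACTION, spread: float = DRUG_SPREAD
) -> tuple[float, float]:
    """Random-movement weight band modeling a migration-inhibitor treatment.

    A drug that reduces single-cell diffusivity to ``fraction +/- spread``
    of control maps directly onto the random weight r, because the
    lattice walker's effective diffusivity is linear in r. MK-2206 at
    40 +/- 15% of vehicle gives r in (0.25, 0.55).
    """
    lo, hi = fraction - spread, fraction + spread
    if not (0.0 < lo <= hi <= 1.0):
        raise ValueError(
            f"diffusivity fraction band ({lo:.3g}, {hi:.3g}) must lie in (0, 1]"
        )
    return lo, hi


def sample_drug_r(
    rng: np.random.Generator,
    fraction: float = DRUG_FRACTION,
    spread: float = DRUG_SPREAD,
) -> float:
    """Draw one spheroid's r uniformly from the drug band."""
    lo, hi = drug_r_interval(fraction, spread)
    return float(rng.uniform(lo, hi))
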