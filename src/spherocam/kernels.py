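"""The four biological actuators as kernel and field computations.

Each mechanism contributes a 3x3 nonnegative weight stencil over the moves
(di, dj) in {-1, 0, 1}^2:

* ``gaussian_kernel`` — isotropic random movement (zero center, sum 1);
* ``chemo_step`` / ``chemo_kernel`` — a self-generated chemoattractant
  field evolved by an explicit finite-difference scheme, sampled as a
  receptor-saturated gradient that puts mass on a single cardinal move;
* ``mechanical_kernel`` — attraction toward occupied neighbor sites,
  computed by convolving occupancy with an all-ones window and removing
  the focal cell's own contribution.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .params import CellState, ChemoScheme, SimulationParams

#: flattened 3x3 move offsets in row-major order; index 4 is the center
OFFSETS = [(di, dj) for di in (-1, 0, 1) for dj in (-1, 0, 1)]
CENTER = 4

# flat indices of the four cardinal moves
_NORTH, _WEST, _EAST, _SOUTH = 1, 3, 5, 7


def gaussian_kernel(sigma: float) -> np.ndarray:
    """3x3 Gaussian movement kernel with zero center, normalized to sum 1.

    Weights are proportional to exp(-(di^2 + dj^2) / (2 sigma^2)) at the
    eight neighbor offsets; zeroing the center enhances movement away from
    the current site.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    di, dj = np.meshgrid((-1, 0, 1), (-1, 0, 1), indexing="ij")
    g = np.exp(-(di**2 + dj**2) / (2.0 * sigma**2))
    g[1, 1] = 0.0
    return g / g.sum()


def chemo_step(
    U: np.ndarray,
    state: CellState | np.ndarray,
    params: SimulationParams,
    scheme: ChemoScheme | None = None,
) -> np.ndarray:
    """One explicit finite-difference update of the chemoattractant field.

    Realizes du/dt = D (u_xx + u_yy) + c1 n - c2 n u on the lattice:

        U'[i,j] = (1 - 4 lam) U[i,j] + lam (U[i±1,j] + U[i,j±1])
                  + c1 dt N[i,j] - c2 dt U[i,j] N[i,j]

    with lam = D dt / h^2 and zero-Dirichlet boundaries (the concentration
    outside the lattice is zero, so mass leaks across the edges).
    """
    N = state.occupancy if isinstance(state, CellState) else state
    if U.shape != N.shape:
        raise ValueError(f"field shape {U.shape} != occupancy shape {N.shape}")
    if not np.all(np.isfinite(U)):
        raise ValueError("chemical field contains non-finite values")
    if scheme is None:
        scheme = ChemoScheme.from_params(params)
    lam = scheme.lam
    occ = N.astype(np.float64, copy=False)

    out = scheme.delta * U
    out[1:, :] += lam * U[:-1, :]
    out[:-1, :] += lam * U[1:, :]
    out[:, 1:] += lam * U[:, :-1]
    out[:, :-1] += lam * U[:, 1:]
    out += params.c1 * params.dt * occ
    out -= params.c2 * params.dt * U * occ
    return out


def chemo_gradient(
    U: np.ndarray, site: tuple[int, int]
) -> tuple[float, float]:
    """Receptor-saturated chemical gradient sensed by a cell at ``site``.

    mu_x = (U[i,j+1] - U[i,j-1]) / (1 + 3 u)^2 and symmetrically for
    mu_y, where u is the concentration at the cell's own site. The
    denominator models saturation of membrane receptors: the same gradient
    drives the cell less when it sits in a high ambient concentration.
    Off-lattice neighbors read as zero (consistent with the field's
    zero-Dirichlet boundary).
    """
    i, j = site
    m, n = U.shape
    if not (0 <= i < m and 0 <= j < n):
        raise ValueError(f"site {site} outside the lattice")
    east = U[i, j + 1] if j + 1 < n else 0.0
    west = U[i, j - 1] if j - 1 >= 0 else 0.0
    south = U[i + 1, j] if i + 1 < m else 0.0
    north = U[i - 1, j] if i - 1 >= 0 else 0.0
    denom = (1.0 + 3.0 * U[i, j]) ** 2
    return (east - west) / denom, (south - north) / denom


def chemo_kernel(
    U: np.ndarray,
    site: tuple[int, int],
    params: SimulationParams,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Chemotaxis stencil C: all zero except |mu| at one cardinal move.

    The nonzero entry sits on the axis with the larger gradient modulus,
    pointing up-gradient (the sign of c_f in the composition later decides
    attraction versus repulsion). An exact modulus tie is broken uniformly
    at random; a locally uniform field yields the all-zero kernel.
    """
    mu_x, mu_y = chemo_gradient(U, site)
    C = np.zeros((3, 3))
    ax, ay = abs(mu_x), abs(mu_y)
    if ax == 0.0 and ay == 0.0:
        return C
    if ax == ay:
        use_x = (rng.random() < 0.5) if rng is not None else True
    else:
        use_x = ax > ay
    if use_x:
        C[1, 2 if mu_x > 0 else 0] = ax
    else:
        C[2 if mu_y > 0 else 0, 1] = ay
    return C


def occupancy_convolution(occupancy: np.ndarray, neighbor_order: int = 1) -> np.ndarray:
    """Occupancy convolved with the all-ones window of side 2*order + 1.

    Entry (i, j) counts occupied sites within the window centered at
    (i, j); sites outside the lattice count as empty. Computed once per
    step and sliced per cell by :func:`mechanical_kernel`.
    """
    if neighbor_order not in (1, 2):
        raise ValueError("neighbor_order must be 1 or 2")
    side = 2 * neighbor_order + 1
    return ndimage.convolve(
        occupancy.astype(np.float64),
        np.ones((side, side)),
        mode="constant",
        cval=0.0,
    )


def mechanical_kernel(
    state: CellState | np.ndarray,
    site: tuple[int, int],
    neighbor_order: int = 1,
    conv: np.ndarray | None = None,
) -> np.ndarray:
    """Mechanical-interaction stencil I for the cell at ``site``.

    The occupancy convolved with an all-ones window gives, at each of the
    3x3 candidate positions, the number of cells the mover would have
    within interaction range. Every candidate position's window covers the
    focal cell itself, so subtracting 1 everywhere removes
    self-interaction. The center is zeroed (the stencil is a pure movement
    bias) and the result normalized to sum 1; an isolated cell gets the
    all-zero kernel. Movement is always to adjacent sites even for
    ``neighbor_order=2``; the order only widens the sensing window.
    """
    occ = state.occupancy if isinstance(state, CellState) else state
    i, j = site
    if not occ[i, j]:
        raise ValueError(f"site {site} is not occupied")
    if conv is None:
        conv = occupancy_convolution(occ, neighbor_order)
    m, n = conv.shape
    if 1 <= i < m - 1 and 1 <= j < n - 1:
        # every candidate window covers the focal cell: subtract its count
        patch = conv[i - 1 : i + 2, j - 1 : j + 2] - 1.0
    else:  # lattice edge: off-lattice candidate positions carry no weight
        patch = np.zeros((3, 3))
        for a in range(3):
            for b in range(3):
                ii, jj = i + a - 1, j + b - 1
                if 0 <= ii < m and 0 <= jj < n:
                    patch[a, b] = conv[ii, jj] - 1.0
    patch[1, 1] = 0.0
    s = patch.sum()
    return patch / s if s > 0 else patch
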