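"""Simulation parameters, scheme constants, and initial conditions.

The model lives on an m x m square lattice whose sites are the size of one
cell (10 um for U87 glioblastoma cells). All engine math is dimensionless:
one length unit is one lattice site, one time unit is the full assay
duration (24 h), so the default time step of 7 minutes is dt = 7/1440.
Physical units (um, seconds, hours) appear only in the analysis and
synthetic-data layers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace

import numpy as np
import yaml

#: physical edge of one lattice site, um (average U87 cell size)
DEFAULT_CELL_SIZE_UM = 10.0
#: physical duration mapped onto one dimensionless time unit, hours
TIME_UNIT_H = 24.0
#: default physical time step, minutes
DEFAULT_STEP_MIN = 7.0


@dataclass(frozen=True)
class SimulationParams:
    """All model constants plus lattice/time bookkeeping.

    Parameters
    ----------
    D : dimensionless chemoattractant diffusion coefficient, the ratio
        D_chem / D_cell of chemical to cellular diffusivity.
    c1 : chemoattractant production rate per occupied site per time unit.
    c2 : chemoattractant degradation rate (degradation is proportional to
        both local cell occupancy and chemical concentration).
    c_f : chemotaxis coefficient; sign encodes attractant (> 0) versus
        repellent (< 0), magnitude the strength of gradient following.
    q : weight of the mechanical cell-cell interaction, in [0, 1].
    r : probability weight of the random-movement component, in [0, 1].
        Reducing r below 1 lowers the effective cellular diffusivity
        without rescaling any other parameter.
    alpha : probability per cell per step of a division event, in [0, 1].
    dt : dimensionless time step. Default 7 min / 24 h = 7/1440.
    h : lattice spacing (dimensionless; 1 by construction).
    m : lattice side length in sites.
    cell_size_um : physical site edge in micrometers.
    total_time_h : physical duration of one dimensionless time unit.
    sigma_G : standard deviation (in sites) of the Gaussian random-movement
        kernel.
    neighbor_order : 1 or 2; range of the mechanical interaction window
        (3x3 or 5x5 ones window in the occupancy convolution).
    seed : RNG seed used when a run does not receive an explicit generator.
    chemo_update_order : "after" (default) updates the chemical field once
        per step after all cells have acted; "before" updates it first.
    synchronous : if True, all cells sample their moves from the frozen
        start-of-step occupancy (conflicts resolved in random order);
        default False uses a sequential update in a freshly shuffled order.
    """

    D: float = 50.0
    c1: float = 0.035
    c2: float = 0.0175
    c_f: float = 20.0
    q: float = 0.3
    r: float = 1.0
    alpha: float = 0.0
    dt: float = DEFAULT_STEP_MIN / (TIME_UNIT_H * 60.0)
    h: float = 1.0
    m: int = 200
    cell_size_um: float = DEFAULT_CELL_SIZE_UM
    total_time_h: float = TIME_UNIT_H
    sigma_G: float = 2.0
    neighbor_order: int = 1
    seed: int = 0
    chemo_update_order: str = "after"
    synchronous: bool = False

    def __post_init__(self) -> None:
        for name in ("r", "q", "alpha"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} must lie in [0, 1]")
        for name in ("c1", "c2", "D"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.dt <= 0 or self.h <= 0:
            raise ValueError("dt and h must be positive")
        if self.m < 3:
            raise ValueError("lattice side m must be at least 3")
        if self.sigma_G <= 0:
            raise ValueError("sigma_G must be positive")
        if self.neighbor_order not in (1, 2):
            raise ValueError("neighbor_order must be 1 or 2")
        if self.chemo_update_order not in ("after", "before"):
            raise ValueError("chemo_update_order must be 'after' or 'before'")
        bound = self.h**2 / (2.0 * self.D) if self.D > 0 else math.inf
        if self.dt > bound:
            raise ValueError(
                f"explicit chemo scheme unstable: dt={self.dt:.6g} exceeds "
                f"h^2/(2 D)={bound:.6g} (lambda = D dt / h^2 = "
                f"{self.lam:.4g} > 1/2)"
            )
        if self.c2 * self.dt > 1.0:
            raise ValueError(
                f"degradation overshoots: c2*dt={self.c2 * self.dt:.4g} > 1"
            )

    @property
    def lam(self) -> float:
        """Scheme constant lambda = D dt / h^2."""
        return self.D * self.dt / self.h**2

    @property
    def delta(self) -> float:
        """Scheme constant Delta = 1 - 4 lambda."""
        return 1.0 - 4.0 * self.lam

    @property
    def step_min(self) -> float:
        """Physical duration of one step in minutes."""
        return self.dt * self.total_time_h * 60.0

    def with_overrides(self, **overrides) -> "SimulationParams":
        return replace(self, **overrides)


@dataclass(frozen=True)
class ChemoScheme:
    """Explicit finite-difference scheme constants for the chemo field."""

    lam: float
    delta: float
    boundary_mode: str = "dirichlet0"

    def __post_init__(self) -> None:
        if self.lam > 0.5:
            raise ValueError(f"lambda={self.lam:.4g} violates stability bound 1/2")
        if not math.isclose(self.delta, 1.0 - 4.0 * self.lam, abs_tol=1e-12):
            raise ValueError("delta must equal 1 - 4*lambda")
        if self.boundary_mode != "dirichlet0":
            raise ValueError("only zero-Dirichlet boundaries are supported")

    @classmethod
    def from_params(cls, params: SimulationParams) -> "ChemoScheme":
        return cls(lam=params.lam, delta=params.delta)


_FIELD_NAMES = {f.name for f in fields(SimulationParams)}


def make_params(**overrides) -> SimulationParams:
    """Build validated parameters from defaults plus named overrides.

    Defaults are the optimum parameter set for U87 spheroids (D=50,
    c1=0.035, c2=c1/2, c_f=20, q=0.3, r=1, alpha=0) on a 200-site lattice.
    If ``c1`` is overridden without ``c2``, the convention c2 = c1/2 is kept.
    """
    unknown = set(overrides) - _FIELD_NAMES
    if unknown:
        raise TypeError(f"unknown parameter(s): {sorted(unknown)}")
    if "c1" in overrides and "c2" not in overrides:
        overrides["c2"] = overrides["c1"] / 2.0
    return SimulationParams(**overrides)


def load_config(path) -> dict:
    """Read a YAML key: value config mirroring SimulationParams fields."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} must be a mapping of parameter names")
    return cfg


@dataclass
class CellState:
    """Binary occupancy lattice plus an identity-preserving cell list.

    ``occupancy`` is the m x m 0/1 matrix N; ``cells`` lists
    (cell_id, row, col) with stable unique ids so individual trajectories
    can be followed across steps.
    """

    occupancy: np.ndarray
    cells: list[tuple[int, int, int]]
    time_index: int = 0

    def validate(self) -> None:
        occ = self.occupancy
        if occ.ndim != 2 or occ.shape[0] != occ.shape[1]:
            raise ValueError("occupancy must be a square matrix")
        vals = np.unique(occ)
        if not np.all(np.isin(vals, (0, 1))):
            raise ValueError("occupancy entries must be 0 or 1")
        if int(occ.sum()) != len(self.cells):
            raise ValueError("occupancy sum must match the number of cells")
        sites = {(i, j) for _, i, j in self.cells}
        if len(sites) != len(self.cells):
            raise ValueError("two cells share a lattice site")
        ids = [cid for cid, _, _ in self.cells]
        if len(set(ids)) != len(ids):
            raise ValueError("cell ids must be unique")
        for _, i, j in self.cells:
            if not occ[i, j]:
                raise ValueError("cell list inconsistent with occupancy")

    def copy(self) -> "CellState":
        return CellState(self.occupancy.copy(), list(self.cells), self.time_index)

    @property
    def n_cells(self) -> int:
        return len(self.cells)


def init_spheroid(m: int, d: int) -> tuple[CellState, np.ndarray]:
    """Centered d x d cluster of cells on an empty m x m lattice.

    The block's upper-left corner sits at floor((m-d)/2) on both axes; cell
    ids are assigned row-major starting at 0. The chemical field starts at
    zero everywhere.
    """
    if d <= 0:
        raise ValueError("spheroid side d must be positive")
    if d >= m:
        raise ValueError(f"spheroid side d={d} must be smaller than lattice m={m}")
    occ = np.zeros((m, m), dtype=np.uint8)
    lo = (m - d) // 2
    occ[lo : lo + d, lo : lo + d] = 1
    cells = [
        (k, lo + k // d, lo + k % d)
        for k in range(d * d)
    ]
    field_u = np.zeros((m, m), dtype=np.float64)
    return CellState(occ, cells, 0), field_u


def n_steps_for(total_time_h: float, step_min: float) -> int:
    """Number of whole steps of ``step_min`` minutes within ``total_time_h``.

    The reference assay of 24 h at a 7-minute step gives 205 iterations.
    """
    if total_time_h <= 0 or step_min <= 0:
        raise ValueError("durations must be positive")
    return int(total_time_h * 60.0 // step_min)
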