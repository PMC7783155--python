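"""Per-cell probability composition and the simulation loop.

Each step, every cell gets a composed movement stencil
P' = r*G + c_f*C + q*I built from the mechanism kernels, clipped at zero
(a repellent c_f < 0 can drive entries negative) and normalized only when
the total weight exceeds 1; any deficit below 1 is the probability of
staying put, which is what makes the random weight r act as a true
probability of moving and lets the effective cellular diffusivity scale
linearly with r. A sampled move succeeds only if the target site is free
(volume exclusion). Division, when enabled, keeps the mother in place and
drops a daughter on a uniformly chosen free 8-neighbor site.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .kernels import (
    CENTER,
    OFFSETS,
    chemo_gradient,
    chemo_step,
    gaussian_kernel,
    mechanical_kernel,
    occupancy_convolution,
)
from .params import CellState, SimulationParams, init_spheroid

_NEIGH8 = [(di, dj) for di in (-1, 0, 1) for dj in (-1, 0, 1) if (di, dj) != (0, 0)]

# flat stencil indices of the cardinal moves (row-major 3x3)
_EAST, _WEST, _SOUTH, _NORTH = 5, 3, 7, 1


@dataclass(frozen=True)
class MechanismFlags:
    """Switches for the four mechanisms; ablations turn one off at a time."""

    random_on: bool = True
    chemo_on: bool = True
    mech_on: bool = True
    proliferation_on: bool = False

    @classmethod
    def all_on(cls) -> "MechanismFlags":
        return cls(True, True, True, True)

    @classmethod
    def random_only(cls) -> "MechanismFlags":
        return cls(True, False, False, False)


_MECHANISM_ATTR = {
    "random": "random_on",
    "chemotaxis": "chemo_on",
    "mechanics": "mech_on",
    "proliferation": "proliferation_on",
}


def ablate(flags: MechanismFlags, drop: str) -> MechanismFlags:
    """Copy of ``flags`` with one named mechanism switched off."""
    try:
        attr = _MECHANISM_ATTR[drop]
    except KeyError:
        raise ValueError(
            f"unknown mechanism {drop!r}; choose from {sorted(_MECHANISM_ATTR)}"
        ) from None
    return replace(flags, **{attr: False})


def compose_probability(
    G: np.ndarray,
    C: np.ndarray,
    I: np.ndarray,
    params: SimulationParams,
) -> np.ndarray:
    """Combine mechanism stencils into the per-cell movement stencil P.

    P' = r*G + c_f*C + q*I; negative entries (repellent chemotaxis) are
    clipped to zero. If the summed weight exceeds 1 the stencil is
    normalized; a total below 1 is left as is and the deficit is the
    probability of remaining in place. An all-zero stencil means the cell
    stays with probability 1.
    """
    for k in (G, C, I):
        if not np.all(np.isfinite(k)):
            raise ValueError("non-finite kernel entries")
    P = params.r * G + params.c_f * C + params.q * I
    np.clip(P, 0.0, None, out=P)
    s = P.sum()
    if s > 1.0:
        P /= s
    return P


@dataclass
class SimulationResult:
    """Recorded trajectory of one simulation.

    ``spots`` is an (n_rows, 4) integer array of (step, cell_id, row, col)
    covering every cell at every recorded step; division events are
    (step, mother_id, daughter_id) triples.
    """

    params: SimulationParams
    flags: MechanismFlags
    d: int
    n_steps: int
    spots: np.ndarray
    divisions: list[tuple[int, int, int]] = field(default_factory=list)
    snapshots: dict[int, tuple[np.ndarray, np.ndarray]] = field(default_factory=dict)

    def to_tracks(self) -> pd.DataFrame:
        """Trajectories as a track table in physical units.

        Columns: track_id, time_s, x_um, y_um. x maps to lattice columns
        and y to rows; positions are site centers, so site (i, j) sits at
        ((j + 0.5) s, (i + 0.5) s) for site edge s.
        """
        s_um = self.params.cell_size_um
        step_s = self.params.step_min * 60.0
        spots = self.spots
        return pd.DataFrame(
            {
                "track_id": spots[:, 1],
                "time_s": spots[:, 0] * step_s,
                "x_um": (spots[:, 3] + 0.5) * s_um,
                "y_um": (spots[:, 2] + 0.5) * s_um,
            }
        ).sort_values(["track_id", "time_s"], kind="stable", ignore_index=True)

    def initial_centroid_um(self) -> tuple[float, float]:
        """Centroid (x, y) in um of the cells at step 0."""
        first = self.spots[self.spots[:, 0] == 0]
        s_um = self.params.cell_size_um
        return (
            float((first[:, 3] + 0.5).mean() * s_um),
            float((first[:, 2] + 0.5).mean() * s_um),
        )

    def n_cells_at(self, step: int) -> int:
        return int((self.spots[:, 0] == step).sum())


def _sample_move(
    weights: np.ndarray, rng: np.random.Generator
) -> tuple[int, int] | None:
    """Draw a move offset from a flattened stencil; None means stay."""
    cum = np.cumsum(weights)
    total = cum[-1]
    u = rng.random()
    if u >= total:
        return None
    k = int(np.searchsorted(cum, u, side="right"))
    if k == CENTER:
        return None
    return OFFSETS[k]


def advance(
    state: CellState,
    U: np.ndarray,
    params: SimulationParams,
    flags: MechanismFlags,
    rng: np.random.Generator,
    division_log: list[tuple[int, int, int]] | None = None,
) -> tuple[CellState, np.ndarray]:
    """One time step of the automaton.

    Cells act in a freshly shuffled order. Each cell first draws
    proliferation (probability alpha when enabled): a divider stays put
    and places a daughter on a free 8-neighbor site if one exists.
    Otherwise it samples a move from its composed stencil; chemotaxis and
    mechanical kernels are computed from the frozen start-of-step fields,
    while the occupancy check for the actual move sees the live lattice
    (the one asymmetry sequential updating introduces; with
    ``params.synchronous`` moves are also *sampled* against the frozen
    occupancy and conflicts resolved in the shuffled order). The chemical
    field is updated once per step, by default after all cells have acted.
    """
    occ = state.occupancy.copy()
    cells = list(state.cells)
    m = params.m

    if flags.chemo_on and params.chemo_update_order == "before":
        U = chemo_step(U, occ, params)

    U0 = U
    occ0 = state.occupancy  # frozen start-of-step occupancy
    conv0 = (
        occupancy_convolution(occ0, params.neighbor_order) if flags.mech_on else None
    )
    base = (
        params.r * gaussian_kernel(params.sigma_G).ravel()
        if flags.random_on
        else np.zeros(9)
    )
    need_compose = flags.chemo_on or flags.mech_on
    base_cum = None if need_compose else np.cumsum(base)

    order = rng.permutation(len(cells))
    next_id = max((cid for cid, _, _ in cells), default=-1) + 1

    for idx in order:
        cid, i, j = cells[idx]

        if flags.proliferation_on and params.alpha > 0.0:
            if rng.random() < params.alpha:
                free = [
                    (i + di, j + dj)
                    for di, dj in _NEIGH8
                    if 0 <= i + di < m and 0 <= j + dj < m and not occ[i + di, j + dj]
                ]
                if free:
                    ni, nj = free[int(rng.integers(len(free)))]
                    occ[ni, nj] = 1
                    cells.append((next_id, ni, nj))
                    if division_log is not None:
                        division_log.append((state.time_index + 1, cid, next_id))
                    next_id += 1
                continue  # a proliferating cell does not move

        if need_compose:
            w = base.copy()
            if flags.chemo_on:
                mu_x, mu_y = chemo_gradient(U0, (i, j))
                ax, ay = abs(mu_x), abs(mu_y)
                if ax > 0.0 or ay > 0.0:
                    if ax == ay:
                        use_x = rng.random() < 0.5
                    else:
                        use_x = ax > ay
                    if use_x:
                        w[_EAST if mu_x > 0 else _WEST] += params.c_f * ax
                    else:
                        w[_SOUTH if mu_y > 0 else _NORTH] += params.c_f * ay
            if flags.mech_on:
                I = mechanical_kernel(
                    occ0, (i, j), params.neighbor_order, conv=conv0
                )
                w += params.q * I.ravel()
            np.clip(w, 0.0, None, out=w)
            s = w.sum()
            if s > 1.0:
                w = w / s
            cum = np.cumsum(w)
        else:
            cum = base_cum

        u_draw = rng.random()
        if u_draw >= cum[-1]:
            continue
        k = int(np.searchsorted(cum, u_draw, side="right"))
        if k == CENTER:
            continue
        di, dj = OFFSETS[k]
        ti, tj = i + di, j + dj
        if not (0 <= ti < m and 0 <= tj < m):
            continue  # moves off-lattice are cancelled
        blocked = occ0[ti, tj] if params.synchronous else occ[ti, tj]
        if blocked or occ[ti, tj]:
            continue  # volume exclusion: target taken, cell stays
        occ[i, j] = 0
        occ[ti, tj] = 1
        cells[idx] = (cid, ti, tj)

    if flags.chemo_on and params.chemo_update_order == "after":
        U = chemo_step(U, occ, params)

    return CellState(occ, cells, state.time_index + 1), U


def run(
    params: SimulationParams,
    d: int,
    flags: MechanismFlags | None = None,
    n_steps: int = 205,
    rng: np.random.Generator | None = None,
    snapshot_steps: tuple[int, ...] = (),
) -> SimulationResult:
    """Simulate a d x d spheroid for ``n_steps`` steps and record tracks.

    Deterministic given (params, flags, seed): with ``rng=None`` a fresh
    generator seeded from ``params.seed`` is used.
    """
    if n_steps < 1:
        raise ValueError("n_steps must be at least 1")
    if flags is None:
        flags = MechanismFlags()
    if rng is None:
        rng = np.random.default_rng(params.seed)

    state, U = init_spheroid(params.m, d)
    rows: list[np.ndarray] = []

    def record(step: int) -> None:
        arr = np.empty((len(state.cells), 4), dtype=np.int64)
        for k, (cid, i, j) in enumerate(state.cells):
            arr[k] = (step, cid, i, j)
        rows.append(arr)

    record(0)
    divisions: list[tuple[int, int, int]] = []
    snapshots: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    if 0 in snapshot_steps:
        snapshots[0] = (state.occupancy.copy(), U.copy())
    for step in range(1, n_steps + 1):
        state, U = advance(state, U, params, flags, rng, division_log=divisions)
        record(step)
        if step in snapshot_steps:
            snapshots[step] = (state.occupancy.copy(), U.copy())

    return SimulationResult(
        params=params,
        flags=flags,
        d=d,
        n_steps=n_steps,
        spots=np.concatenate(rows),
        divisions=divisions,
        snapshots=snapshots,
    )


def run_cohort(
    diameters_um,
    params: SimulationParams,
    flags: MechanismFlags | None = None,
    seeds=None,
    n_steps: int = 205,
) -> list[SimulationResult]:
    """One simulation per (diameter, seed) pair.

    Physical diameters (um) are mapped to lattice sides
    d = round(diameter / cell_size_um). ``seeds`` may be an iterable of
    seeds or an int count (seeds params.seed, params.seed+1, ...);
    ``None`` means one run per diameter at params.seed + index.
    """
    diameters_um = list(diameters_um)
    if not diameters_um:
        raise ValueError("no diameters given")
    if isinstance(seeds, int):
        seeds = [params.seed + k for k in range(seeds)]
    else:
        seeds = list(seeds)
        if not seeds:
            raise ValueError("no seeds given")

    results = []
    if seeds is None:
        for k, diam in enumerate(diameters_um):
            d = max(1, round(diam / params.cell_size_um))
            p = params.with_overrides(seed=params.seed + k)
            results.append(run(p, d, flags, n_steps))
    else:
        for diam in diameters_um:
            d = max(1, round(diam / params.cell_size_um))
            for s in seeds:
                p = params.with_overrides(seed=s)
                results.append(run(p, d, flags, n_steps))
    return results


def default_cohort_diameters(n: int = 24, low: float = 50.0, high: float = 160.0):
    """Evenly spaced spheroid diameters (um) spanning the assay's range."""
    return list(np.linspace(low, high, n))
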