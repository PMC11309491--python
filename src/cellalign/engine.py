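"""Population state, initialisation, neighbour search and time stepping.

The engine integrates the overdamped (first-order) equations of motion with
explicit Euler at a fixed step ``dt`` (default 0.01 non-dimensional time
units), evaluating all derivative terms at the pre-step state.  Positions
live in the periodic square ``[0, L)²``, orientations in ``[0, 2π)``;
contacts and junctions are recomputed from scratch every step (junctions are
stateless).  Trajectories are fully reproducible from ``(params, seed)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .geometry import EllipseSpec, intersect
from .junction_dynamics import Junction, find_junctions
from .shape_dynamics import axes_from_r

R_MIN, R_MAX = 1.0, 16.0     # aspect-ratio clamp of the shape module
_EVENT_NAMES = ("containment", "coincidence_jitter", "r_clamp_low", "r_clamp_high")


@dataclass
class ModelParams:
    """All non-dimensional model constants and run controls.

    Parameters
    ----------
    nu : self-propulsion speed relative to overlap avoidance (ν = wη√(π/A)·A/σ
        in dimensional terms: the ratio of the overlap-relaxation time Aη/σ to
        the time √(A/π)/w a cell needs to travel one reference length).
    gamma : shape-restoring strength γ = πg/(Aσ); only acts when ``shape_on``.
    rbar : preferred aspect ratio (default 2).
    kappa : junction spring strength κ = k/σ.
    mu : supracellular actin bending strength (non-dimensional group of m/σ).
    lam : junction range λ = l·√(π/A); endpoints closer than λ are joined.
    n_cells, box, dt, t_end, save_every, seed : run controls.
    shape_on / junctions_on : module toggles.  The two modules are mutually
        exclusive by default (aspect ratio is held constant while junctions
        are active); set ``allow_shape_with_junctions`` to override.
    r_init : initial (or fixed) aspect ratio; defaults to ``rbar``.
    rot_noise : rotational noise variance per unit time (extension point,
        default 0; off in all standard experiments).
    """

    nu: float = 0.5
    gamma: float = 0.0
    rbar: float = 2.0
    kappa: float = 0.0
    mu: float = 0.0
    lam: float = 0.0
    n_cells: int = 125
    box: float = 20.0
    dt: float = 0.01
    t_end: float = 400.0
    save_every: int = 10
    seed: int = 0
    shape_on: bool = False
    junctions_on: bool = False
    r_init: float | None = None
    rot_noise: float = 0.0
    allow_shape_with_junctions: bool = False

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.n_cells < 1 or self.box <= 0:
            raise ValueError("need n_cells >= 1 and box > 0")
        if self.rbar <= 1:
            raise ValueError("rbar must exceed 1")
        if min(self.nu, self.gamma, self.kappa, self.mu, self.lam) < 0:
            raise ValueError("nu, gamma, kappa, mu, lam must be non-negative")
        if self.r_init is None:
            self.r_init = self.rbar
        if self.shape_on and self.junctions_on and not self.allow_shape_with_junctions:
            raise ValueError(
                "aspect ratio is held constant while junctions are active; "
                "shape_on and junctions_on are mutually exclusive "
                "(set allow_shape_with_junctions=True to override)")
        # minimum-image validity at the run's aspect ratio
        if self.box <= 2 * (2 * np.sqrt(self.r_init)) + self.lam:
            raise ValueError(
                f"box L={self.box} too small for minimum-image pair geometry "
                f"at r={self.r_init} with junction range {self.lam}")
        if self.shape_on and self.box <= 2 * (2 * np.sqrt(R_MAX)):
            warnings.warn(
                "box may violate minimum-image validity if aspect ratios "
                f"grow towards the clamp {R_MAX}", stacklevel=2)
        if self.n_cells * np.pi > 1.2 * self.box ** 2:
            warnings.warn(
                f"total cell area {self.n_cells * np.pi:.1f} exceeds 1.2·L²; "
                "the population is strongly overcrowded", stacklevel=2)

    @property
    def n_steps(self) -> int:
        return int(round(self.t_end / self.dt))


@dataclass
class CellState:
    """One cell: centroid, orientation, aspect ratio (semi-axes derived)."""

    X: np.ndarray
    alpha: float
    r: float

    @property
    def a(self) -> float:
        return axes_from_r(self.r)[0]

    @property
    def b(self) -> float:
        return axes_from_r(self.r)[1]

    def ellipse(self) -> EllipseSpec:
        return EllipseSpec(self.X, self.alpha, self.a, self.b)


class Population:
    """Array-backed state of N cells in a periodic box."""

    def __init__(self, X: np.ndarray, alpha: np.ndarray, r: np.ndarray,
                 box: float):
        self.X = np.array(X, dtype=float)
        self.alpha = np.array(alpha, dtype=float) % (2 * np.pi)
        self.r = np.array(r, dtype=float)
        self.box = float(box)
        if self.X.shape != (self.n, 2):
            raise ValueError("X must be (N, 2)")
        if np.any(self.X < 0) or np.any(self.X >= self.box):
            raise ValueError("positions must lie in [0, L)")
        if np.any(self.r < 1):
            raise ValueError("aspect ratios must be >= 1")

    @property
    def n(self) -> int:
        return len(self.alpha)

    @property
    def a(self) -> np.ndarray:
        return np.sqrt(self.r)

    @property
    def b(self) -> np.ndarray:
        return 1.0 / np.sqrt(self.r)

    def cells(self) -> list[CellState]:
        return [CellState(self.X[i].copy(), float(self.alpha[i]),
                          float(self.r[i])) for i in range(self.n)]

    def copy(self) -> "Population":
        return Population(self.X.copy(), self.alpha.copy(), self.r.copy(),
                          self.box)

    def contact_lists(self, box_L: float | None = None) -> dict[int, list]:
        """Per-cell overlap contacts (each pair seen from both perspectives)."""
        L = self.box if box_L is None else box_L
        cells = self.cells()
        out: dict[int, list] = {i: [] for i in range(self.n)}
        for i, j in neighbor_candidates(self, L):
            ct = intersect(cells[i].ellipse(), cells[j].ellipse(), L,
                           cell_i_index=i, cell_j_index=j)
            if ct is not None:
                out[i].append(ct)
                out[j].append(intersect(cells[j].ellipse(),
                                        cells[i].ellipse(), L,
                                        cell_i_index=j, cell_j_index=i))
        return out


@dataclass
class Frame:
    time: float
    X: np.ndarray
    alpha: np.ndarray
    r: np.ndarray

    def population(self, box: float) -> Population:
        return Population(self.X, self.alpha, self.r, box)


@dataclass
class Trajectory:
    """Recorded run: frames, parameters and the event log."""

    frames: list[Frame]
    params: ModelParams
    events: dict = field(default_factory=dict)

    @property
    def times(self) -> np.ndarray:
        return np.array([f.time for f in self.frames])

    @property
    def final(self) -> Population:
        f = self.frames[-1]
        return f.population(self.params.box)

    def population_at(self, idx: int) -> Population:
        return self.frames[idx].population(self.params.box)

    def junctions_at(self, idx: int) -> list[Junction]:
        """Active junction set of a recorded frame (junctions are stateless,
        so they are derived from the frame rather than stored)."""
        return find_junctions(self.population_at(idx), self.params.lam,
                              self.params.box)

    def to_frames_dataframe(self):
        import pandas as pd
        rows = []
        for f in self.frames:
            for i in range(len(f.alpha)):
                rows.append((f.time, i, f.X[i, 0], f.X[i, 1],
                             f.alpha[i], f.r[i]))
        return pd.DataFrame(rows, columns=["t", "cell_id", "x", "y",
                                           "alpha", "r"])

    def to_junctions_dataframe(self):
        import pandas as pd
        rows = []
        for k, f in enumerate(self.frames):
            for jn in self.junctions_at(k):
                rows.append((f.time, jn.i, jn.end_i, jn.j, jn.end_j, jn.type))
        return pd.DataFrame(rows, columns=["t", "i", "end_i", "j", "end_j",
                                           "type"])


def initialize(params: ModelParams) -> Population:
    """Uniform random placement and orientation, reproducible from the seed."""
    rng = np.random.default_rng(params.seed)
    X = rng.uniform(0.0, params.box, size=(params.n_cells, 2))
    alpha = rng.uniform(0.0, 2 * np.pi, size=params.n_cells)
    r = np.full(params.n_cells, float(params.r_init))
    return Population(X, alpha, r, params.box)


def neighbor_candidates(population: Population,
                        box_L: float | None = None) -> list[tuple[int, int]]:
    """Broad phase: every pair whose minimum-image centroid distance is below
    the sum of semi-major axes (a superset of all overlapping pairs).

    Uses a uniform spatial grid for N > 64, the direct O(N²) test otherwise.
    """
    L = population.box if box_L is None else box_L
    N = population.n
    a = population.a
    if N <= 64:
        pairs = []
        for i in range(N):
            for j in range(i + 1, N):
                d = population.X[j] - population.X[i]
                d -= L * np.round(d / L)
                if d @ d < (a[i] + a[j]) ** 2:
                    pairs.append((i, j))
        return pairs
    cut = 2.0 * float(a.max())
    ncell = max(1, int(L // cut))
    size = L / ncell
    grid: dict[tuple[int, int], list[int]] = {}
    cell_of = (population.X // size).astype(int) % ncell
    for i in range(N):
        grid.setdefault((cell_of[i, 0], cell_of[i, 1]), []).append(i)
    pairs = []
    seen = set()
    for (cx, cy), members in grid.items():
        for dx in (-1, 0, 1):
            for dy in (-1, 0, 1):
                other = grid.get(((cx + dx) % ncell, (cy + dy) % ncell))
                if not other:
                    continue
                for i in members:
                    for j in other:
                        if i >= j or (i, j) in seen:
                            continue
                        d = population.X[j] - population.X[i]
                        d -= L * np.round(d / L)
                        if d @ d < (a[i] + a[j]) ** 2:
                            pairs.append((i, j))
                            seen.add((i, j))
    return sorted(pairs)


def _advance(pop: Population, params: ModelParams, n_steps: int,
             counters: np.ndarray, rng=None) -> int:
    """Advance the population in place by n_steps Euler steps."""
    if params.rot_noise > 0.0 and rng is not None:
        status = 0
        sd = np.sqrt(params.rot_noise * params.dt)
        for _ in range(n_steps):
            status = _kernels.run_steps(
                pop.X, pop.alpha, pop.r, 1, pop.box, params.dt, params.nu,
                params.gamma, params.rbar, params.kappa, params.mu,
                params.lam, params.shape_on, params.junctions_on, counters)
            if status:
                return status
            pop.alpha = (pop.alpha + rng.normal(0.0, sd, pop.n)) % (2 * np.pi)
        return status
    return _kernels.run_steps(
        pop.X, pop.alpha, pop.r, n_steps, pop.box, params.dt, params.nu,
        params.gamma, params.rbar, params.kappa, params.mu, params.lam,
        params.shape_on, params.junctions_on, counters)


def step(population: Population, params: ModelParams,
         counters: np.ndarray | None = None) -> Population:
    """One explicit-Euler update of all cells (derivatives at the pre-step
    state, simultaneous update); returns a new Population."""
    pop = population.copy()
    if counters is None:
        counters = np.zeros(4, dtype=np.int64)
    status = _advance(pop, params, 1, counters)
    if status:
        raise FloatingPointError("state became non-finite during step")
    return pop


def simulate(params: ModelParams,
             initial: Population | None = None) -> Trajectory:
    """Run the model to t_end, recording every ``save_every``-th frame plus
    frame 0; aborts with a diagnostic if the state becomes non-finite.

    ``initial`` overrides the seeded random initial population."""
    pop = initialize(params) if initial is None else initial.copy()
    counters = np.zeros(4, dtype=np.int64)
    rng = np.random.default_rng(params.seed + 2 ** 20) \
        if params.rot_noise > 0 else None
    frames = [Frame(0.0, pop.X.copy(), pop.alpha.copy(), pop.r.copy())]
    n_rec = params.n_steps // params.save_every
    for k in range(1, n_rec + 1):
        status = _advance(pop, params, params.save_every, counters, rng)
        if status:
            raise FloatingPointError(
                f"state became non-finite near t={k * params.save_every * params.dt:.3f} "
                f"(seed {params.seed})")
        frames.append(Frame(k * params.save_every * params.dt,
                            pop.X.copy(), pop.alpha.copy(), pop.r.copy()))
    leftover = params.n_steps - n_rec * params.save_every
    if leftover:
        _advance(pop, params, leftover, counters, rng)
    events = dict(zip(_EVENT_NAMES, counters.tolist()))
    return Trajectory(frames=frames, params=params, events=events)
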