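"""L-BFGS minimization of the folding energy in backbone torsion space.

The optimization variables are the 2L-2 defined backbone dihedrals in
radians.  Search directions come from the limited-memory BFGS two-loop
recursion (history m = 256); step sizes from Armijo backtracking line
search.  A folding run performs up to 10 restart rounds of at most 2000
quasi-Newton steps each -- the curvature history is cleared between
rounds while the conformation carries over -- and returns the
lowest-energy conformation seen at any accepted step.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

import numpy as np

from torsionfold import geometry as geom
from torsionfold.energy import EnergyModel, WeightVector

CURVATURE_EPS = 1e-12
ARMIJO_C = 1e-4
ARMIJO_BACKTRACK = 0.5
ARMIJO_MAX_TRIES = 30

INIT_MODES = ("provided", "extended", "ss_guess", "random")

#: Ramachandran basins used by random initialization: (phi, psi, half-width)
_BASINS = [
    (-63.0, -43.0, 20.0),   # alpha
    (-120.0, 130.0, 30.0),  # beta
    (-65.0, 145.0, 20.0),   # polyproline II
    (60.0, 20.0, 25.0),     # left-handed alpha (turns)
]


class NonDescentError(ValueError):
    """Line search called with a non-descent direction."""


class OptimizerError(RuntimeError):
    pass


@dataclass
class LbfgsState:
    """Curvature history and current iterate of one L-BFGS round."""

    m: int = 256
    s_list: deque = field(default_factory=deque)
    y_list: deque = field(default_factory=deque)
    rho_list: deque = field(default_factory=deque)

    def push(self, s: np.ndarray, y: np.ndarray) -> bool:
        """Store a curvature pair; rejects pairs with y.s below the guard."""
        ys = float(y @ s)
        if ys <= CURVATURE_EPS:
            return False
        if len(self.s_list) == self.m:
            self.s_list.popleft()
            self.y_list.popleft()
            self.rho_list.popleft()
        self.s_list.append(s)
        self.y_list.append(y)
        self.rho_list.append(1.0 / ys)
        return True

    def clear(self) -> None:
        self.s_list.clear()
        self.y_list.clear()
        self.rho_list.clear()


def lbfgs_direction(state: LbfgsState, grad: np.ndarray) -> np.ndarray:
    """Two-loop recursion: d = -H^{-1} g with implicit inverse Hessian.

    The initial inverse Hessian is gamma * I with the standard scaling
    gamma = s.y / y.y from the most recent pair (identity when the
    history is empty).  Falls back to steepest descent if the result is
    not a descent direction.
    """
    if not np.all(np.isfinite(grad)):
        raise OptimizerError("non-finite gradient")
    q = grad.copy()
    alphas = []
    for s, y, rho in zip(
        reversed(state.s_list), reversed(state.y_list), reversed(state.rho_list)
    ):
        a = rho * (s @ q)
        alphas.append(a)
        q -= a * y
    if state.s_list:
        s, y = state.s_list[-1], state.y_list[-1]
        gamma = (s @ y) / (y @ y)
    else:
        gamma = 1.0
    r = gamma * q
    for (s, y, rho), a in zip(
        zip(state.s_list, state.y_list, state.rho_list), reversed(alphas)
    ):
        b = rho * (y @ r)
        r += (a - b) * s
    d = -r
    if grad @ d >= 0.0:
        d = -grad
    return d


def armijo_line_search(energy_fn, x, d, grad, e0=None, alpha0: float = 1.0):
    """Backtracking line search enforcing sufficient decrease.

    Halves alpha from ``alpha0`` until
    E(x + alpha d) <= E(x) + c alpha g.d (c = 1e-4); returns
    (alpha, E(x + alpha d)).  alpha = 0 signals failure after 30
    backtracks.  Raises :class:`NonDescentError` if g.d >= 0.
    """
    slope = float(grad @ d)
    if slope >= 0.0:
        raise NonDescentError(f"gradient.direction = {slope:g} >= 0")
    if e0 is None:
        e0 = energy_fn(x)
    alpha = alpha0
    for _ in range(ARMIJO_MAX_TRIES):
        e_new = energy_fn(x + alpha * d)
        if e_new <= e0 + ARMIJO_C * alpha * slope:
            return alpha, e_new
        alpha *= ARMIJO_BACKTRACK
    return 0.0, e0


@dataclass
class FoldConfig:
    """Optimizer settings of one folding run."""

    weights: WeightVector = field(default_factory=WeightVector.default)
    rounds: int = 10
    steps_per_round: int = 2000
    memory: int = 256
    energy_tol: float = 1e-6
    grad_tol: float = 1e-6
    converged_steps: int = 5
    init_mode: str = "random"
    seed: int = 0
    ss_string: str | None = None
    init_torsions: tuple | None = None  # (phi, psi) degrees for "provided"


@dataclass
class FoldResult:
    """Outcome of a folding run."""

    model: geom.ProteinModel
    energy: float
    breakdown: object
    trajectory: list  # (round, step, energy, grad_inf, alpha)
    termination: str

    @property
    def n_steps(self) -> int:
        return len(self.trajectory)


def initialize_torsions(sequence: str, mode: str, seed: int = 0,
                        ss_string: str | None = None,
                        torsions: tuple | None = None):
    """Initial (phi, psi) in degrees for a folding run.

    ``provided`` passes stored torsions through; ``extended`` sets every
    residue to (-120, 120); ``ss_guess`` draws near helix/strand means
    under an H/E/C secondary-structure string; ``random`` draws a
    Ramachandran basin per residue.  All draws are seeded.
    """
    L = len(sequence)
    if mode not in INIT_MODES:
        raise ValueError(f"unknown init mode {mode!r}")
    rng = np.random.default_rng(seed)
    if mode == "provided":
        if torsions is None:
            raise ValueError("mode 'provided' needs torsions")
        phi, psi = (np.asarray(a, dtype=float).copy() for a in torsions)
        if len(phi) != L or len(psi) != L:
            raise ValueError(
                f"provided torsions have length {len(phi)}, sequence {L}"
            )
        return phi, psi
    if mode == "extended":
        return np.full(L, -120.0), np.full(L, 120.0)
    if mode == "ss_guess":
        ss = (ss_string or "C" * L).upper()
        if len(ss) != L:
            raise ValueError("secondary-structure string length mismatch")
        phi = np.empty(L)
        psi = np.empty(L)
        for i, s in enumerate(ss):
            if s == "H":
                mu = (-57.0, -47.0)
                phi[i] = mu[0] + rng.normal(0, 10.0)
                psi[i] = mu[1] + rng.normal(0, 10.0)
            elif s == "E":
                phi[i] = -120.0 + rng.normal(0, 15.0)
                psi[i] = 130.0 + rng.normal(0, 15.0)
            else:
                b = _BASINS[rng.integers(len(_BASINS))]
                phi[i] = b[0] + rng.uniform(-b[2], b[2])
                psi[i] = b[1] + rng.uniform(-b[2], b[2])
        return phi, psi
    # random: uniform within a random allowed basin per residue
    phi = np.empty(L)
    psi = np.empty(L)
    for i in range(L):
        b = _BASINS[rng.integers(len(_BASINS))]
        phi[i] = b[0] + rng.uniform(-b[2], b[2])
        psi[i] = b[1] + rng.uniform(-b[2], b[2])
    return phi, psi


def fold(sequence: str, potentials, config: FoldConfig) -> FoldResult:
    """Minimize the composite energy from a seeded initial conformation.

    Runs up to ``config.rounds`` rounds of at most
    ``config.steps_per_round`` L-BFGS steps.  A round converges when the
    energy change stays below ``energy_tol`` for ``converged_steps``
    consecutive accepted steps, when the gradient infinity norm falls
    below ``grad_tol``, or when the line search fails.  The whole run
    stops early once a round converges immediately.  Deterministic given
    the seed.
    """
    em = EnergyModel(sequence, potentials, config.weights)
    phi0, psi0 = initialize_torsions(
        sequence, config.init_mode, seed=config.seed,
        ss_string=config.ss_string, torsions=config.init_torsions,
    )
    x = geom.wrap_angles(geom.torsion_vector(np.asarray(phi0), np.asarray(psi0)))

    energy_only = em.energy
    e, g, bd = em.energy_and_grad(x)
    best_e, best_x, best_bd = e, x.copy(), bd
    trajectory = []
    termination = "max_rounds"

    for rnd in range(config.rounds):
        state = LbfgsState(m=config.memory)
        quiet = 0
        steps_in_round = 0
        round_term = None
        for step in range(config.steps_per_round):
            if np.abs(g).max() < config.grad_tol:
                round_term = "grad_tol"
                break
            d = lbfgs_direction(state, g)
            alpha, e_new = armijo_line_search(energy_only, x, d, g, e0=e)
            if alpha == 0.0:
                round_term = "line_search_failed"
                break
            s = alpha * d
            x = geom.wrap_angles(x + s)
            e_prev = e
            e, g_new, bd = em.energy_and_grad(x)
            state.push(s, g_new - g)
            g = g_new
            steps_in_round += 1
            trajectory.append((rnd, step, e, float(np.abs(g).max()), alpha))
            if e < best_e:
                best_e, best_x, best_bd = e, x.copy(), bd
            if abs(e_prev - e) < config.energy_tol:
                quiet += 1
                if quiet >= config.converged_steps:
                    round_term = "energy_tol"
                    break
            else:
                quiet = 0
        if round_term in ("grad_tol", "energy_tol", "line_search_failed") and (
            steps_in_round <= config.converged_steps
        ):
            termination = f"converged ({round_term})"
            break

    phi, psi = geom.torsions_from_vector(best_x)
    model = geom.build_coordinates(sequence, phi, psi)
    return FoldResult(
        model=model,
        energy=best_e,
        breakdown=best_bd,
        trajectory=trajectory,
        termination=termination,
    )
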