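"""Gillespie stochastic simulation baseline.

Direct-method SSA over the same truncated lattice boxes as the exact
solver: per-channel propensities are tabulated on the box once (with
conserving truncation, so trajectories never leave the box), and the jump
loop runs over flat state indices.  A numba-compiled kernel handles long
trajectories; a pure-Python loop with identical semantics and identical
random-number stream is used when numba is unavailable.

The state-occupancy distribution of a trajectory — the waiting-time
weighted fraction of time spent in each state — converges to the
stationary distribution for ergodic chains and is the quantity compared
against the exact steady state.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .fullgrid import LatticeBox, LatticeDistribution
from .models import ReactionNetwork

__all__ = [
    "SSATrajectory",
    "gillespie",
    "occupancy_distribution",
    "smooth_box3",
    "l2_error",
]

try:
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a declared dependency
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(fn):
            return fn

        if args and callable(args[0]):
            return args[0]
        return wrap


@dataclass
class SSATrajectory:
    """A single SSA realisation on a lattice box.

    ``states`` holds the visited states (n_jumps + 1 rows); ``waits`` the
    exponential holding time in each state except the last, whose residence
    is unobserved.
    """

    box: LatticeBox
    states: np.ndarray
    waits: np.ndarray
    seed: int
    absorbed: bool = False

    @property
    def n_steps(self) -> int:
        return self.waits.size

    def coordinate(self, k: int) -> np.ndarray:
        """The k-th (0-based) coordinate along the trajectory."""
        return self.states[:, k]


def _propensity_tables(network: ReactionNetwork, box: LatticeBox) -> tuple[np.ndarray, np.ndarray]:
    """Flat per-channel propensity tables with conserving truncation,
    plus the flat-index offset of each channel's jump."""
    coords = [g.ravel() for g in box.grid()]
    K = network.n_channels
    N = box.nstates
    tables = np.zeros((K, N))
    offsets = np.zeros(K, dtype=np.int64)
    strides = np.array(
        [int(np.prod(box.shape[k + 1 :])) for k in range(box.d)], dtype=np.int64
    )
    for i, ch in enumerate(network.channels):
        a = ch(*coords)
        if np.any(a < 0):
            raise ValueError(f"channel {ch.name!r} has a negative propensity on the box")
        inside = np.ones(N, dtype=bool)
        for k in range(box.d):
            t = coords[k] + ch.stoichiometry[k]
            inside &= (t >= box.lower[k]) & (t <= box.upper[k])
        tables[i] = np.where(inside, a, 0.0)
        offsets[i] = int(np.dot(ch.stoichiometry, strides))
    return tables, offsets


@njit(cache=True)
def _ssa_kernel(tables, offsets, start, n_steps, seed):  # pragma: no cover - compiled
    K = tables.shape[0]
    states = np.empty(n_steps + 1, dtype=np.int64)
    waits = np.empty(n_steps, dtype=np.float64)
    np.random.seed(seed)
    s = start
    states[0] = s
    done = n_steps
    for step in range(n_steps):
        a_total = 0.0
        for i in range(K):
            a_total += tables[i, s]
        if a_total <= 0.0:
            done = step
            break
        waits[step] = -np.log(np.random.random()) / a_total
        r = np.random.random() * a_total
        acc = 0.0
        chosen = K - 1
        for i in range(K):
            acc += tables[i, s]
            if r < acc:
                chosen = i
                break
        s = s + offsets[chosen]
        states[step + 1] = s
    return states, waits, done


def _ssa_python(tables, offsets, start, n_steps, seed):
    """Reference implementation of the jump loop (same RNG stream)."""
    np.random.seed(seed)
    K = tables.shape[0]
    states = np.empty(n_steps + 1, dtype=np.int64)
    waits = np.empty(n_steps, dtype=np.float64)
    s = start
    states[0] = s
    done = n_steps
    for step in range(n_steps):
        a_total = tables[:, s].sum()
        if a_total <= 0.0:
            done = step
            break
        waits[step] = -np.log(np.random.random()) / a_total
        r = np.random.random() * a_total
        acc = 0.0
        chosen = K - 1
        for i in range(K):
            acc += tables[i, s]
            if r < acc:
                chosen = i
                break
        s = s + offsets[chosen]
        states[step + 1] = s
    return states, waits, done


def gillespie(
    network: ReactionNetwork,
    x0,
    n_steps: int,
    seed: int,
    box: LatticeBox | None = None,
    use_numba: bool = _HAVE_NUMBA,
) -> SSATrajectory:
    """Direct-method SSA: exponential waiting times with rate sum(a_i),
    channel chosen with probability a_i / sum(a_i).

    The walk is confined to ``box`` (default: a cube sized generously from
    the start state) by the same conserving truncation as the exact
    generator.  If all propensities vanish the trajectory terminates early
    and is flagged as absorbed.
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    x0 = np.asarray(x0, dtype=int)
    if x0.shape != (network.d,):
        raise ValueError(f"x0 must have length {network.d}")
    if box is None:
        hi = max(300, int(4 * max(x0.max(), 1)))
        box = LatticeBox.cube(network.d, hi)
    if not box.contains(x0[None, :])[0]:
        raise ValueError("start state lies outside the box")

    tables, offsets = _propensity_tables(network, box)
    start = int(box.index(x0[None, :])[0])
    runner = _ssa_kernel if use_numba else _ssa_python
    flat_states, waits, done = runner(tables, offsets, start, int(n_steps), int(seed))
    absorbed = done < n_steps
    flat_states = flat_states[: done + 1]
    waits = waits[:done]
    states = box.state(flat_states)
    return SSATrajectory(box, states, waits, int(seed), absorbed)


def occupancy_distribution(
    traj: SSATrajectory,
    box: LatticeBox | None = None,
    time_weighted: bool = True,
) -> LatticeDistribution:
    """Normalized state-occupancy distribution of a trajectory.

    By default states are weighted by the waiting time spent in them (the
    ergodic estimator of the stationary law); ``time_weighted=False``
    counts raw visits instead.  States outside ``box`` contribute to the
    returned distribution's ``overflow_mass`` attribute; on-box mass plus
    overflow equals one.
    """
    if box is None:
        box = traj.box
    if traj.states.shape[0] == 0:
        raise ValueError("trajectory is empty")
    occupied = traj.states[:-1] if traj.waits.size else traj.states[:1]
    if traj.waits.size:
        weights = traj.waits if time_weighted else np.ones(traj.waits.size)
    else:
        occupied = traj.states[:1]
        weights = np.ones(1)
    inside = box.contains(occupied)
    vals = np.zeros(box.nstates)
    if inside.any():
        idx = box.index(occupied[inside])
        np.add.at(vals, idx, weights[inside])
    total = weights.sum()
    overflow = float(weights[~inside].sum() / total) if total > 0 else 0.0
    dist = LatticeDistribution(box, vals / total)
    dist.overflow_mass = overflow
    return dist


def smooth_box3(u: LatticeDistribution) -> LatticeDistribution:
    """Moving average over the 3^d neighbourhood, mass preserving.

    Windows are truncated and renormalized at box faces (a constant field
    stays constant); the result is rescaled to the input mass, which is
    otherwise changed only by boundary effects.
    """
    vals = u.grid_values()
    size = 3
    num = ndimage.uniform_filter(vals, size=size, mode="constant", cval=0.0)
    ones = np.ones_like(vals)
    den = ndimage.uniform_filter(ones, size=size, mode="constant", cval=0.0)
    sm = num / den
    m_in, m_out = vals.sum(), sm.sum()
    if m_out > 0 and m_in > 0:
        sm *= m_in / m_out
    return LatticeDistribution(u.box, sm.ravel())


def l2_error(u: LatticeDistribution, ref: LatticeDistribution) -> float:
    """Euclidean norm of the difference of two distributions on one box."""
    if u.box != ref.box:
        raise ValueError("distributions live on different boxes")
    return float(np.linalg.norm(u.values - ref.values))
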