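"""Gaussian radial-basis-function collocation.

The distribution is approximated as u~(x) = sum_i alpha_i phi_i(x) with
anisotropic Gaussians phi_i(x) = prod_k exp(-(x_k - c_ik)^2 / sigma_ik)
centred on an enumerated node set.  The interpolation matrix
A_ij = phi_j(x^i) maps coefficients to nodal values; its LU factorization
is reused for every operator build.

Coefficient-space operators: the shift along axis k is T~ = A^{-1} A1 with
(A1)_ij = phi_j(x^i - e_k) (the nodal values of the shifted interpolant,
re-expanded in the basis), and pointwise multiplication by a propensity a
is W~ = A^{-1} diag{a(x^i)} A.  The discretized CME generator is then the
channel sum L~ = sum_i (prod_k T~_k^{v_ik} - I) W~_{a_i}, and time stepping
is the action of exp(dt L~) on the coefficient vector.  In the limit where
the centres enumerate every lattice state and the Gaussians are sharply
peaked, these operators reduce to the exact lattice operators.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg as sla
import scipy.sparse.linalg as spla

from .models import ReactionNetwork

__all__ = [
    "BasisSystem",
    "CoefficientVector",
    "DiscretizedGenerator",
    "make_basis",
    "interpolate",
    "evaluate",
    "approx_shift",
    "approx_mult",
    "discretize_generator",
    "collocation_step",
    "ConditioningError",
]

#: default ratio between the Gaussian length scale and the centre grid
#: spacing: sigma = (SHAPE_C * grid_step)^2.  Nearest-neighbour overlap is
#: then exp(-1/SHAPE_C^2); the value balances coverage of the support
#: against the growth of cond(A) on large node sets.
SHAPE_C = 0.85

#: refuse to use interpolation matrices whose 1-norm condition estimate
#: exceeds this cap
COND_CAP = 1e12


class ConditioningError(RuntimeError):
    """Interpolation matrix is singular or too ill-conditioned to trust."""


def gaussian_design(points: np.ndarray, centres: np.ndarray, sigma: np.ndarray) -> np.ndarray:
    """Matrix of basis values: out[i, j] = phi_j(points[i])."""
    points = np.atleast_2d(np.asarray(points, dtype=float))
    n, d = centres.shape
    out = np.ones((points.shape[0], n))
    for k in range(d):
        diff = points[:, k, None] - centres[None, :, k]
        out *= np.exp(-(diff**2) / sigma[None, :, k])
    return out


@dataclass
class BasisSystem:
    """Gaussian RBF basis: centres, connectivity parameters and factorized A."""

    centres: np.ndarray
    sigma: np.ndarray
    A: np.ndarray
    lu: tuple
    condition_estimate: float

    @property
    def n(self) -> int:
        return self.centres.shape[0]

    @property
    def d(self) -> int:
        return self.centres.shape[1]

    def solve(self, rhs: np.ndarray) -> np.ndarray:
        """Apply A^{-1} to a vector or matrix of nodal values."""
        return sla.lu_solve(self.lu, rhs)


@dataclass
class CoefficientVector:
    """Expansion coefficients alpha of an interpolant in a basis."""

    basis: BasisSystem
    alpha: np.ndarray

    def __post_init__(self):
        self.alpha = np.asarray(self.alpha, dtype=float)
        if self.alpha.shape != (self.basis.n,):
            raise ValueError(
                f"alpha has length {self.alpha.shape}, basis has {self.basis.n} centres"
            )

    def nodal_values(self) -> np.ndarray:
        """Values of the interpolant at the basis centres (A @ alpha)."""
        return self.basis.A @ self.alpha


@dataclass
class DiscretizedGenerator:
    """Dense coefficient-space discretization of the CME generator."""

    basis: BasisSystem
    matrix: np.ndarray
    network_name: str = ""


def make_basis(
    centres: np.ndarray,
    sigma: float | np.ndarray | None = None,
    grid_step: float = 1.0,
    shape_c: float = SHAPE_C,
    cond_cap: float = COND_CAP,
) -> BasisSystem:
    """Build a basis from distinct centres and factorize its interpolation matrix.

    ``sigma`` may be a scalar or an (n, d) array of per-centre, per-axis
    length-squared parameters; if omitted, the default shape rule
    sigma = (shape_c * grid_step)^2 (isotropic) is applied.
    """
    centres = np.atleast_2d(np.asarray(centres, dtype=float))
    n, d = centres.shape
    if n < 1:
        raise ValueError("at least one centre is required")
    if sigma is None:
        sigma = (shape_c * grid_step) ** 2
    sigma = np.broadcast_to(np.asarray(sigma, dtype=float), (n, d)).copy()
    if np.any(sigma <= 0):
        raise ValueError("sigma must be positive")

    A = gaussian_design(centres, centres, sigma)
    try:
        lu = sla.lu_factor(A)
    except sla.LinAlgError as exc:
        raise ConditioningError(
            "interpolation matrix is singular; centres may coincide or the "
            "shape rule gives too much overlap"
        ) from exc

    norm1 = np.linalg.norm(A, 1)
    if n == 1:
        cond = 1.0
    else:
        inv_op = spla.LinearOperator(
            (n, n),
            matvec=lambda v: sla.lu_solve(lu, v),
            rmatvec=lambda v: sla.lu_solve(lu, v, trans=1),
        )
        try:
            inv_norm1 = spla.onenormest(inv_op)
        except Exception:
            inv_norm1 = np.inf
        cond = float(norm1 * inv_norm1)
    if not np.isfinite(cond) or cond > cond_cap:
        raise ConditioningError(
            f"interpolation matrix condition estimate {cond:.2e} exceeds cap "
            f"{cond_cap:.1e}; use a smaller shape parameter or coarser overlap"
        )
    return BasisSystem(centres, sigma, A, lu, cond)


def interpolate(basis: BasisSystem, nodal_values: np.ndarray) -> CoefficientVector:
    """Coefficients reproducing the given values at the basis centres."""
    nodal_values = np.asarray(nodal_values, dtype=float)
    if nodal_values.shape != (basis.n,):
        raise ValueError(
            f"expected {basis.n} nodal values, got shape {nodal_values.shape}"
        )
    return CoefficientVector(basis, basis.solve(nodal_values))


def evaluate(
    basis: BasisSystem,
    alpha: CoefficientVector | np.ndarray,
    points: np.ndarray,
    chunk: int = 8192,
) -> np.ndarray:
    """Evaluate the interpolant sum_j alpha_j phi_j at arbitrary points."""
    a = alpha.alpha if isinstance(alpha, CoefficientVector) else np.asarray(alpha, dtype=float)
    points = np.atleast_2d(np.asarray(points, dtype=float))
    out = np.empty(points.shape[0])
    for s in range(0, points.shape[0], chunk):
        block = points[s : s + chunk]
        out[s : s + block.shape[0]] = gaussian_design(block, basis.centres, basis.sigma) @ a
    return out


def _shift_matrix_once(basis: BasisSystem, k: int, direction: int) -> np.ndarray:
    """A^{-1} A1 for a unit lattice shift along 1-based axis k."""
    pts = basis.centres.copy()
    pts[:, k - 1] -= direction
    A1 = gaussian_design(pts, basis.centres, basis.sigma)
    return basis.solve(A1)


def approx_shift(basis: BasisSystem, k: int, n: int) -> np.ndarray:
    """Coefficient-space shift operator T~_k^n (|n|-fold composition)."""
    if not 1 <= k <= basis.d:
        raise ValueError(f"axis k must be in 1..{basis.d}")
    if n == 0:
        return np.eye(basis.n)
    step = _shift_matrix_once(basis, k, 1 if n > 0 else -1)
    out = step
    for _ in range(abs(n) - 1):
        out = step @ out
    return out


def approx_mult(basis: BasisSystem, a) -> np.ndarray:
    """Coefficient-space multiplication operator W~_a = A^{-1} diag{a(x^i)} A.

    ``a`` is either a propensity callable over d coordinate arrays or a
    vector of values at the centres.
    """
    if callable(a):
        vals = np.asarray(a(*(basis.centres[:, k] for k in range(basis.d))), dtype=float)
        vals = np.broadcast_to(vals, (basis.n,))
    else:
        vals = np.asarray(a, dtype=float)
        if vals.shape != (basis.n,):
            raise ValueError(f"expected {basis.n} values, got {vals.shape}")
    if not np.all(np.isfinite(vals)):
        raise ValueError("propensity is not finite at all centres")
    return basis.solve(vals[:, None] * basis.A)


def discretize_generator(basis: BasisSystem, network: ReactionNetwork) -> DiscretizedGenerator:
    """Assemble L~ = sum_i (prod_k T~_k^{v_ik} - I) W~_{a_i} channel by channel."""
    if network.d != basis.d:
        raise ValueError(f"network dimension {network.d} != basis dimension {basis.d}")
    n = basis.n
    eye = np.eye(n)
    shift_cache: dict[tuple[int, int], np.ndarray] = {}
    L = np.zeros((n, n))
    for ch in network.channels:
        W = approx_mult(basis, ch)
        T = eye
        for k in range(1, basis.d + 1):
            nu = ch.stoichiometry[k - 1]
            if nu == 0:
                continue
            key = (k, nu)
            if key not in shift_cache:
                shift_cache[key] = approx_shift(basis, k, nu)
            T = shift_cache[key] @ T
        L += (T - eye) @ W
    return DiscretizedGenerator(basis, L, network.name)


def collocation_step(
    gen: DiscretizedGenerator,
    alpha: CoefficientVector,
    dt: float,
) -> CoefficientVector:
    """Advance coefficients by alpha(t + dt) = exp(dt L~) alpha(t)."""
    if dt < 0:
        raise ValueError("dt must be non-negative")
    if alpha.basis is not gen.basis:
        raise ValueError("coefficient vector and generator use different bases")
    if dt == 0:
        return CoefficientVector(gen.basis, alpha.alpha.copy())
    out = spla.expm_multiply(gen.matrix * dt, alpha.alpha)
    if not np.all(np.isfinite(out)):
        raise FloatingPointError(
            "collocation step produced non-finite coefficients; reduce dt or "
            "improve the basis conditioning"
        )
    return CoefficientVector(gen.basis, out)
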