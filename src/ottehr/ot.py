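"""Discrete unbalanced entropy-regularized optimal transport.

Implements the regularized unbalanced 1-Wasserstein problem between two
discrete measures: minimize, over nonnegative couplings pi,

    Phi(pi) = <pi, d^p>  +  (1/lambda) * sum(pi log pi - pi)
              + rho * KL(pi_rows | mass_A) + rho * KL(pi_cols | mass_B)

where d is the pairwise Euclidean cost, lambda is the entropic
regularization parameter (larger lambda = weaker smoothing; the effective
Sinkhorn temperature is eps = 1/lambda), and the marginal constraints of
classical OT are relaxed into KL penalties with a single weight rho, so
mass can be created or destroyed when the two measures are unbalanced.
The entropy and KL terms use the standard unnormalized (generalized)
extensions, which reduce to the textbook forms on probability couplings
and make the zero-cost fixed point preserve total mass.

The solver runs Sinkhorn-type scaling iterations in the log domain for
numerical stability, and is fully deterministic.  A Gromov-Wasserstein
variant aligns supports living in different coordinate spaces by
comparing intra-domain distance structures.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist
from scipy.special import logsumexp, xlogy

logger = logging.getLogger(__name__)

__all__ = [
    "DiscreteMeasure",
    "OTConfig",
    "CostMatrix",
    "TransportPlan",
    "build_cost_matrix",
    "solve_unbalanced_ot",
    "solve_ugw",
    "barycentric_projection",
    "plan_unbalancedness",
    "write_plan",
    "read_plan",
]


@dataclass
class DiscreteMeasure:
    """A discrete measure: support points (rows) with nonnegative masses."""

    support: np.ndarray
    mass: np.ndarray

    def __post_init__(self) -> None:
        self.support = np.atleast_2d(np.asarray(self.support, dtype=float))
        self.mass = np.asarray(self.mass, dtype=float).ravel()
        if self.mass.shape[0] != self.support.shape[0]:
            raise ValueError(
                f"mass length {self.mass.shape[0]} does not match "
                f"{self.support.shape[0]} support points"
            )
        if np.any(self.mass < 0):
            raise ValueError("mass entries must be nonnegative")
        if self.mass.sum() <= 0:
            raise ValueError("total mass must be positive")

    @property
    def n_points(self) -> int:
        return self.support.shape[0]

    @property
    def dim(self) -> int:
        return self.support.shape[1]

    @classmethod
    def uniform(cls, support: np.ndarray) -> "DiscreteMeasure":
        """Uniform probability measure on the given support points."""
        support = np.atleast_2d(np.asarray(support, dtype=float))
        n = support.shape[0]
        return cls(support, np.full(n, 1.0 / n))


@dataclass
class OTConfig:
    """Hyperparameters for the unbalanced entropic OT solver.

    ``entropic_reg`` is lambda in the objective above: the entropy enters
    as -(1/lambda) H(pi), so the common "eps * H" convention corresponds
    to eps = 1/lambda.  ``mass_reg`` is the shared weight rho on both
    marginal KL penalties.
    """

    entropic_reg: float = 0.1
    mass_reg: float = 1.0
    p_exponent: int = 1
    cost_metric: str = "euclidean"
    max_iter: int = 5000
    tol: float = 1e-8
    mode: str = "unbalanced_entropic"

    def __post_init__(self) -> None:
        if self.entropic_reg <= 0:
            raise ValueError("entropic_reg must be positive")
        if self.mass_reg <= 0:
            raise ValueError("mass_reg must be positive")
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if self.p_exponent < 1:
            raise ValueError("p_exponent must be >= 1")
        if self.cost_metric != "euclidean":
            raise ValueError(f"unsupported cost metric: {self.cost_metric!r}")
        if self.mode not in ("unbalanced_entropic", "balanced_entropic"):
            raise ValueError(f"unknown mode: {self.mode!r}")


@dataclass
class CostMatrix:
    """Pairwise ground costs, rows indexed by A-points, columns by B-points."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < 0):
            raise ValueError("cost entries must be nonnegative")


@dataclass
class TransportPlan:
    """A coupling between two discrete measures and its diagnostics."""

    coupling: np.ndarray
    row_marginal: np.ndarray = field(init=False)
    col_marginal: np.ndarray = field(init=False)
    objective: float = np.nan
    transport_cost: float = np.nan
    converged: bool = True
    iterations: int = 0

    def __post_init__(self) -> None:
        self.coupling = np.asarray(self.coupling, dtype=float)
        self.row_marginal = self.coupling.sum(axis=1)
        self.col_marginal = self.coupling.sum(axis=0)


def build_cost_matrix(
    A: DiscreteMeasure, B: DiscreteMeasure, config: OTConfig | None = None
) -> CostMatrix:
    """Pairwise Euclidean distances between the supports of A and B."""
    if A.dim != B.dim:
        raise ValueError(
            f"support dimension mismatch: A has {A.dim} coordinates, B has {B.dim}"
        )
    return CostMatrix(cdist(A.support, B.support, metric="euclidean"))


def generalized_kl(alpha: np.ndarray, beta: np.ndarray) -> float:
    """Unnormalized KL divergence sum(a*log(a/b) - a + b); +inf off-support."""
    alpha = np.asarray(alpha, dtype=float)
    beta = np.asarray(beta, dtype=float)
    if np.any((beta == 0) & (alpha > 0)):
        return np.inf
    pos = beta > 0
    a, b = alpha[pos], beta[pos]
    return float(np.sum(xlogy(a, a) - xlogy(a, b) - a + b))


def _entropy_term(pi: np.ndarray) -> float:
    """sum(pi log pi - pi) with the 0 log 0 = 0 convention."""
    return float(np.sum(xlogy(pi, pi) - pi))


def evaluate_objective(
    pi: np.ndarray,
    cost_p: np.ndarray,
    mass_a: np.ndarray,
    mass_b: np.ndarray,
    config: OTConfig,
) -> tuple[float, float]:
    """Return (Phi(pi), transport cost <pi, d^p>) for a given coupling."""
    transport_cost = float(np.sum(pi * cost_p))
    lam, rho = config.entropic_reg, config.mass_reg
    obj = (
        transport_cost
        + _entropy_term(pi) / lam
        + rho * generalized_kl(pi.sum(axis=1), mass_a)
        + rho * generalized_kl(pi.sum(axis=0), mass_b)
    )
    return obj, transport_cost


def _sinkhorn_log(
    cost_p: np.ndarray,
    mass_a: np.ndarray,
    mass_b: np.ndarray,
    config: OTConfig,
) -> tuple[np.ndarray, bool, int]:
    """Log-domain scaling iterations; returns (coupling, converged, iters).

    The coupling is parameterized as pi = exp((f_i + g_j - C_ij) / eps)
    with eps = 1/lambda.  Unbalanced mode damps each potential update by
    rho/(rho + eps), the fixed point of the KL-relaxed marginal problem;
    balanced mode is classical Sinkhorn (hard marginals).
    """
    eps = 1.0 / config.entropic_reg
    rho = config.mass_reg
    damp = 1.0 if config.mode == "balanced_entropic" else rho / (rho + eps)

    with np.errstate(divide="ignore"):
        loga = np.log(mass_a)
        logb = np.log(mass_b)

    f = np.zeros_like(mass_a)
    g = np.zeros_like(mass_b)
    # zero-mass points carry no coupling mass; forced via -inf potential
    f[mass_a == 0] = -np.inf
    g[mass_b == 0] = -np.inf
    neg_c = -cost_p / eps

    converged = False
    it = 0
    for it in range(1, config.max_iter + 1):
        f_prev, g_prev = f, g
        with np.errstate(invalid="ignore"):
            f = damp * eps * (loga - logsumexp(neg_c + g_prev[None, :] / eps, axis=1))
            f = np.where(np.isneginf(loga), -np.inf, f)
            g = damp * eps * (logb - logsumexp(neg_c + f[:, None] / eps, axis=0))
            g = np.where(np.isneginf(logb), -np.inf, g)
        # convergence measured on the log scaling vectors f/eps, g/eps
        delta = 0.0
        for new, old in ((f, f_prev), (g, g_prev)):
            finite = np.isfinite(new) & np.isfinite(old)
            if finite.any():
                delta = max(delta, np.max(np.abs(new[finite] - old[finite])) / eps)
        if delta < config.tol:
            converged = True
            break

    with np.errstate(invalid="ignore"):
        log_pi = (f[:, None] + g[None, :] - cost_p) / eps
    log_pi = np.where(np.isneginf(f)[:, None] | np.isneginf(g)[None, :], -np.inf, log_pi)
    return np.exp(log_pi), converged, it


def solve_unbalanced_ot(
    A: DiscreteMeasure,
    B: DiscreteMeasure,
    cost: CostMatrix,
    config: OTConfig,
) -> TransportPlan:
    """Approximately minimize Phi(pi) by log-domain scaling iterations.

    In ``balanced_entropic`` mode the marginals are constrained to the
    input masses (which must then have equal totals); in the default
    ``unbalanced_entropic`` mode they are KL-penalized with weight rho.
    """
    if cost.values.shape != (A.n_points, B.n_points):
        raise ValueError(
            f"cost shape {cost.values.shape} inconsistent with measures "
            f"({A.n_points}, {B.n_points})"
        )
    if config.mode == "balanced_entropic":
        if abs(A.mass.sum() - B.mass.sum()) > 1e-9 * max(A.mass.sum(), B.mass.sum()):
            raise ValueError(
                "balanced mode requires equal total masses: "
                f"{A.mass.sum():g} vs {B.mass.sum():g}"
            )
    cost_p = cost.values if config.p_exponent == 1 else cost.values**config.p_exponent

    pi, converged, iters = _sinkhorn_log(cost_p, A.mass, B.mass, config)
    if not converged:
        logger.warning(
            "unbalanced OT did not converge in %d iterations (lambda=%g, rho=%g)",
            config.max_iter, config.entropic_reg, config.mass_reg,
        )
    obj, transport_cost = evaluate_objective(pi, cost_p, A.mass, B.mass, config)
    return TransportPlan(
        coupling=pi,
        objective=obj,
        transport_cost=transport_cost,
        converged=converged,
        iterations=iters,
    )


def _gw_tensor_cost(
    d_a: np.ndarray, d_b: np.ndarray, pi: np.ndarray
) -> np.ndarray:
    """Linearized Gromov cost M_ij = sum_kl (d_a[i,k] - d_b[j,l])^2 pi[k,l]."""
    r = pi.sum(axis=1)
    c = pi.sum(axis=0)
    return ((d_a**2) @ r)[:, None] + ((d_b**2) @ c)[None, :] - 2.0 * d_a @ pi @ d_b


def gw_discrepancy(d_a: np.ndarray, d_b: np.ndarray, pi: np.ndarray) -> float:
    """Quadratic Gromov term sum_ijkl (d_a[i,k] - d_b[j,l])^2 pi[i,j] pi[k,l]."""
    return float(np.sum(_gw_tensor_cost(d_a, d_b, pi) * pi))


def solve_ugw(
    A: DiscreteMeasure, B: DiscreteMeasure, config: OTConfig
) -> TransportPlan:
    """Regularized unbalanced Gromov-Wasserstein OT between heterogeneous spaces.

    The inner discrepancy is L(u, v) = (u - v)^2 on intra-domain Euclidean
    distances, so no cross-domain cost is needed and the supports may have
    different coordinate dimensions.  Solved by alternating linearization:
    starting from the independent product coupling, repeatedly form the
    linearized cost at the current coupling and re-solve the unbalanced
    entropic problem, until the coupling stabilizes.
    """
    if A.n_points < 2 or B.n_points < 2:
        raise ValueError(
            "Gromov-Wasserstein needs >= 2 points per side to define "
            f"intra-domain geometry (got {A.n_points} and {B.n_points})"
        )
    d_a = cdist(A.support, A.support, metric="euclidean")
    d_b = cdist(B.support, B.support, metric="euclidean")

    pi = np.outer(A.mass, B.mass)
    converged = False
    iters = 0
    inner_last = None
    for iters in range(1, config.max_iter + 1):
        m_cost = np.maximum(_gw_tensor_cost(d_a, d_b, pi), 0.0)
        inner_last = solve_unbalanced_ot(A, B, CostMatrix(m_cost), config)
        pi_new = inner_last.coupling
        if np.max(np.abs(pi_new - pi)) < config.tol:
            pi = pi_new
            converged = True
            break
        pi = pi_new
    if not converged:
        logger.warning("UGW alternation did not converge in %d sweeps", iters)

    lam, rho = config.entropic_reg, config.mass_reg
    gw_term = gw_discrepancy(d_a, d_b, pi)
    obj = (
        gw_term
        + _entropy_term(pi) / lam
        + rho * generalized_kl(pi.sum(axis=1), A.mass)
        + rho * generalized_kl(pi.sum(axis=0), B.mass)
    )
    return TransportPlan(
        coupling=pi,
        objective=obj,
        transport_cost=gw_term,
        converged=converged,
        iterations=iters,
    )


def barycentric_projection(
    plan: TransportPlan, B: DiscreteMeasure
) -> np.ndarray:
    """Map each A-point to the coupling-weighted mean of the B-support.

    Row i of the result is sum_j pi[i, j] * b_j / sum_j pi[i, j].  Rows of
    the plan with zero total mass have no defined image; they are returned
    as NaN rows and their count is logged, never silently imputed.
    """
    pi = plan.coupling
    if pi.shape[1] != B.n_points:
        raise ValueError(
            f"plan has {pi.shape[1]} columns but B has {B.n_points} points"
        )
    row_sums = pi.sum(axis=1)
    if not np.any(row_sums > 0):
        raise ValueError("empty transport: every plan row has zero mass")
    n_zero = int(np.sum(row_sums == 0))
    if n_zero:
        logger.warning("%d plan rows have zero mass; returned as missing", n_zero)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = (pi @ B.support) / row_sums[:, None]
    # a row coupled to a single source point maps to it exactly, with no
    # float round-trip through the weighted average
    single = (pi > 0).sum(axis=1) == 1
    if single.any():
        out[single] = B.support[np.argmax(pi[single] > 0, axis=1)]
    out[row_sums == 0] = np.nan
    return out


def plan_unbalancedness(plan: TransportPlan, target_mass: np.ndarray) -> float:
    """l1 gap between the plan's row marginals and the target mass.

    This is the "unbalancedness" term of the generalization bound: it
    vanishes exactly when the plan transports each target point's full
    mass, as hard marginal constraints would enforce.
    """
    target_mass = np.asarray(target_mass, dtype=float).ravel()
    if target_mass.shape[0] != plan.coupling.shape[0]:
        raise ValueError(
            f"target_mass length {target_mass.shape[0]} does not match "
            f"{plan.coupling.shape[0]} plan rows"
        )
    return float(np.sum(np.abs(plan.row_marginal - target_mass)))


def write_plan(plan: TransportPlan, config: OTConfig, path) -> None:
    """Export a coupling as delimited text with a one-line parameter header."""
    header = (
        f"lambda={config.entropic_reg} rho={config.mass_reg} "
        f"p={config.p_exponent} mode={config.mode}"
    )
    np.savetxt(path, plan.coupling, delimiter="\t", header=header)


def read_plan(path) -> tuple[np.ndarray, dict]:
    """Read a coupling written by :func:`write_plan`; returns (matrix, params)."""
    with open(path) as fh:
        first = fh.readline().lstrip("# ").strip()
    params: dict = {}
    for tok in first.split():
        key, _, val = tok.partition("=")
        params[key] = val if key == "mode" else float(val)
    return np.atleast_2d(np.loadtxt(path, delimiter="\t")), params
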