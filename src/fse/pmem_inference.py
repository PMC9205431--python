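"""Pairwise maximum-entropy (inverse Ising) inference, optionally
constrained by a structural connectome.

The model places binary states ``s_i = +/-1`` on ``N`` regions with energy
``H(s) = -sum_{i<j} J_ij s_i s_j`` (no external field: resting-state data
are modelled as zero-mean) and Boltzmann probability
``Pr(s) = exp(-beta H(s)) / Z``. The couplings ``J`` are estimated by
maximizing the log-pseudolikelihood

    l(J) = (1/t_max) sum_t sum_i [ C_i(t) s_i(t) - ln(e^{C_i(t)} + e^{-C_i(t)}) ]

with local fields ``C_i(t) = beta * sum_m J_im s_m(t)``; pseudolikelihood
replaces the intractable joint likelihood by the product of per-region
conditionals, avoiding the partition function entirely.

The structural constraint (the "function-by-structure embedding") adds a
quadratic penalty pulling coupling magnitudes toward the structural weights,
``-(lambda/2) sum_{i<j} (J_ij - sgn(J_ij) W_ij)^2`` with
``lambda = A / beta``, so that ``|J| ~ W`` while the data choose the signs.
As ``A -> 0`` the fit reduces to the unconstrained model; as ``A -> inf``
the magnitudes converge to ``W`` itself.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np

from .connectome_io import BinarizedActivity, StructuralConnectome, _check_square_symmetric, _default_labels
from .errors import (
    DivergenceError,
    NonConvergenceWarning,
    NonFiniteError,
    ShapeError,
)

__all__ = [
    "InferenceConfig",
    "CouplingMatrix",
    "PseudolikelihoodState",
    "local_fields",
    "log_pseudolikelihood",
    "gradient",
    "fit",
]


@dataclass
class InferenceConfig:
    """Settings for pseudolikelihood gradient ascent.

    Parameters
    ----------
    beta : float
        Inverse temperature assumed while fitting (the grid-search
        "true" beta). Fixed during a fit, never optimized jointly.
    A : float
        Structural-penalty scale, ``A = lambda * beta``. ``A = 0`` gives the
        unconstrained pairwise model (and ``W`` must then be omitted).
    gamma : float
        Initial learning rate; halved whenever a step would decrease the
        penalized objective (simple backtracking).
    max_iter, tol : int, float
        Ascent stops when the max-norm of the update ``gamma * grad`` drops
        below ``tol``, or after ``max_iter`` iterations (with a
        :class:`NonConvergenceWarning`).
    init : str
        ``"small_random"`` (uniform in [-0.01, 0.01], seeded; lets the
        penalty's sign term break symmetry) or ``"zeros"``.
    """

    beta: float = 1.0
    A: float = 0.0
    gamma: float = 0.05
    max_iter: int = 5000
    tol: float = 1e-6
    init: str = "small_random"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.beta <= 0 or self.gamma <= 0 or self.tol <= 0:
            raise ValueError("beta, gamma and tol must be positive")
        if self.A < 0:
            raise ValueError("A must be nonnegative")
        if self.init not in ("zeros", "small_random"):
            raise ValueError(f"unknown init {self.init!r}")


@dataclass
class CouplingMatrix:
    """Symmetric signed interaction matrix with zero diagonal.

    ``provenance`` records how the matrix arose: ``"unconstrained_pmem"``,
    ``"fse"`` (the hybrid resting-state structural connectome) or
    ``"ground_truth"`` (synthetic generator).
    """

    J: np.ndarray
    region_labels: list[str] = field(default_factory=list)
    provenance: str = "unconstrained_pmem"
    fit_info: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.J = _check_square_symmetric(self.J, "coupling matrix")
        np.fill_diagonal(self.J, 0.0)
        self.J = 0.5 * (self.J + self.J.T)
        if not self.region_labels:
            self.region_labels = _default_labels(self.J.shape[0])
        if len(self.region_labels) != self.J.shape[0]:
            raise ShapeError("label count does not match matrix size")

    @property
    def n_regions(self) -> int:
        return self.J.shape[0]


@dataclass
class PseudolikelihoodState:
    """Objective pieces at a given J: local fields, log-pseudolikelihood,
    penalty, and gradient."""

    C: np.ndarray
    logpl: float
    penalty: float
    grad: np.ndarray

    @property
    def objective(self) -> float:
        return self.logpl - self.penalty


def _coerce_J(J) -> np.ndarray:
    return J.J if isinstance(J, CouplingMatrix) else np.asarray(J, dtype=float)


def _coerce_W(W) -> np.ndarray:
    return W.W if isinstance(W, StructuralConnectome) else np.asarray(W, dtype=float)


def _coerce_S(S) -> np.ndarray:
    return S.states.astype(float) if isinstance(S, BinarizedActivity) else np.asarray(S, dtype=float)


def local_fields(J, S, beta: float) -> np.ndarray:
    """Local fields ``C_i(t) = beta * sum_m J_im s_m(t)`` (an N x t_max matrix)."""
    Jm, Sm = _coerce_J(J), _coerce_S(S)
    if Jm.shape[0] != Jm.shape[1] or Jm.shape[0] != Sm.shape[0]:
        raise ShapeError(f"shape mismatch: J {Jm.shape} vs S {Sm.shape}")
    return beta * (Jm @ Sm)


def _penalty_terms(J: np.ndarray, W: np.ndarray, lam: float) -> tuple[float, np.ndarray]:
    """Penalty value over i<j and its entrywise derivative (upper triangle).

    sgn(0) = 0, so an exactly-zero coupling is pulled toward 0 rather than
    toward +/-W: no arbitrary sign is injected.
    """
    D = J - np.sign(J) * W
    iu = np.triu_indices_from(J, k=1)
    value = 0.5 * lam * float(np.sum(D[iu] ** 2))
    dpen = np.zeros_like(J)
    dpen[iu] = lam * D[iu]
    return value, dpen


def log_pseudolikelihood(J, S, beta: float, W=None, A: float = 0.0) -> tuple[float, float]:
    """Log-pseudolikelihood and structural penalty at ``J``.

    Returns ``(logpl, penalty)``; the ascent objective is their difference.
    ``logpl`` is always <= 0 (an average of log-probabilities). The
    log-sum-exp term is evaluated as ``|C| + log1p(exp(-2|C|))`` so large
    fields cannot overflow.
    """
    if A > 0 and W is None:
        raise ValueError("W is required when A > 0")
    Jm, Sm = _coerce_J(J), _coerce_S(S)
    C = local_fields(Jm, Sm, beta)
    if not np.isfinite(C).all():
        raise NonFiniteError("local fields overflowed")
    t_max = Sm.shape[1]
    lse = np.abs(C) + np.log1p(np.exp(-2.0 * np.abs(C)))
    logpl = float(np.sum(C * Sm - lse) / t_max)
    penalty = 0.0
    if A > 0:
        penalty, _ = _penalty_terms(Jm, _coerce_W(W), A / beta)
    return logpl, penalty


def gradient(J, S, beta: float, W=None, A: float = 0.0, symmetrize: bool = True) -> np.ndarray:
    """Gradient of the penalized log-pseudolikelihood with respect to J.

    The data term for entry (i, j) is
    ``(beta/t_max) * sum_t s_j(t) * (s_i(t) - tanh(C_i(t)))`` — the exact
    derivative of the conditional log-probability of region i — and the
    penalty contributes ``-lambda * (J_ij - sgn(J_ij) W_ij)`` on the upper
    triangle. Because conditioning on i versus j gives different data terms,
    the raw gradient is asymmetric; with ``symmetrize=True`` (the default,
    used by :func:`fit`) the (i, j) and (j, i) contributions are averaged so
    the iterate stays symmetric, which is a positive rescaling of the exact
    gradient on the symmetric manifold. ``symmetrize=False`` exposes the raw
    entrywise derivative (used by finite-difference checks).
    """
    if A > 0 and W is None:
        raise ValueError("W is required when A > 0")
    Jm, Sm = _coerce_J(J), _coerce_S(S)
    C = local_fields(Jm, Sm, beta)
    t_max = Sm.shape[1]
    G = (beta / t_max) * ((Sm - np.tanh(C)) @ Sm.T)
    if A > 0:
        _, dpen = _penalty_terms(Jm, _coerce_W(W), A / beta)
        G = G - dpen
    if symmetrize:
        G = 0.5 * (G + G.T)
    np.fill_diagonal(G, 0.0)
    return G


def _objective(J, S, beta, W, A) -> float:
    logpl, pen = log_pseudolikelihood(J, S, beta, W, A)
    return logpl - pen


def fit(S: BinarizedActivity, config: InferenceConfig, W: StructuralConnectome | None = None) -> CouplingMatrix:
    """Fit couplings by penalized pseudolikelihood gradient ascent.

    With ``config.A == 0`` this is the unconstrained pairwise model; with
    ``A > 0`` a structural connectome ``W`` is required and its entries are
    first rescaled to a maximum of 1 (the constraint assumes unit
    normalization). The update is ``J <- J + gamma * grad`` with
    backtracking: a step that lowers the objective is retried at half the
    learning rate, so the objective trace is non-decreasing.

    Returns a :class:`CouplingMatrix` whose ``fit_info`` records iterations,
    final objective, convergence flag and the configuration used.
    """
    if (config.A > 0) != (W is not None):
        raise ValueError("provide W exactly when config.A > 0")
    Sm = _coerce_S(S)
    labels = S.region_labels if isinstance(S, BinarizedActivity) else _default_labels(Sm.shape[0])
    N = Sm.shape[0]
    Wn = None
    if W is not None:
        Wn = _coerce_W(W)
        peak = Wn.max()
        if peak > 0 and abs(peak - 1.0) > 1e-12:
            Wn = Wn / peak

    rng = np.random.default_rng(config.seed)
    if config.init == "zeros":
        J = np.zeros((N, N))
    else:
        J = rng.uniform(-0.01, 0.01, size=(N, N))
        J = 0.5 * (J + J.T)
    np.fill_diagonal(J, 0.0)

    gamma = config.gamma
    obj = _objective(J, Sm, config.beta, Wn, config.A)
    converged = False
    n_done = 0
    for n in range(config.max_iter):
        G = gradient(J, Sm, config.beta, Wn, config.A)
        if np.max(np.abs(gamma * G)) < config.tol:
            converged = True
            break
        while True:
            J_new = J + gamma * G
            obj_new = _objective(J_new, Sm, config.beta, Wn, config.A)
            if np.isfinite(obj_new) and obj_new >= obj - 1e-12:
                break
            gamma *= 0.5
            if gamma < 1e-16:
                if not np.isfinite(obj_new):
                    raise DivergenceError("objective became non-finite")
                J_new, obj_new = J, obj  # stuck: no ascent step possible
                break
        J, obj = J_new, obj_new
        gamma = min(gamma * 1.05, 10.0 * config.gamma)
        n_done = n + 1
    if not converged:
        warnings.warn(
            f"gradient ascent hit max_iter={config.max_iter} before tol={config.tol}",
            NonConvergenceWarning,
            stacklevel=2,
        )
    logpl, pen = log_pseudolikelihood(J, Sm, config.beta, Wn, config.A)
    provenance = "fse" if config.A > 0 else "unconstrained_pmem"
    info = {
        "iterations": n_done,
        "objective": logpl - pen,
        "logpl": logpl,
        "penalty": pen,
        "converged": converged,
        "final_gamma": gamma,
        "config": asdict(config),
    }
    return CouplingMatrix(0.5 * (J + J.T), list(labels), provenance, info)
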