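"""Grid-search optimization of the inference hyperparameters (beta, A).

Two pull-apart metrics score a fitted coupling matrix:

* ``S_m`` — the similarity of the fit to the structural scaffold, the
  Pearson correlation ``r(|J|, W)`` over distinct region pairs. It rises
  toward 1 as the constraint scale A grows.
* ``max f_c`` — the best achievable match between observed functional
  connectivity and the FC reconstructed by simulating the fitted Ising
  system over a grid of simulation temperatures. It degrades when the fit
  is dragged too far from the data.

The grid search maximizes the equal-weight objective
``f(beta, A) = max f_c + S_m`` over a (beta, A) grid, yielding the
"optimized" hybrid resting-state structural connectome for one subject.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .connectome_io import (
    BinarizedActivity,
    FunctionalConnectivity,
    StructuralConnectome,
)
from .errors import ConstantRegionError, DegenerateError, DivergenceError
from .ising_sim import McmcConfig, reconstructed_fc, simulate
from .pmem_inference import CouplingMatrix, InferenceConfig, fit, _coerce_J, _coerce_W

__all__ = [
    "GridSearchConfig",
    "FcCurve",
    "GridSearchResult",
    "similarity_metric",
    "fc_correlation_curve",
    "grid_search",
]


def _default_grid() -> tuple:
    return tuple(np.round(np.arange(0.2, 3.01, 0.2), 10))


@dataclass
class GridSearchConfig:
    """Grids and Monte Carlo settings for the (beta, A) search.

    Defaults follow the standard protocol: beta, A and beta_simulated all
    from 0.2 to 3.0 in steps of 0.2, with 2,000 recorded sweeps per
    simulation. ``repeats`` averages ``max f_c`` over that many independent
    MCMC seeds per cell to damp sampling noise.
    """

    beta_values: tuple = field(default_factory=_default_grid)
    A_values: tuple = field(default_factory=_default_grid)
    beta_sim_values: tuple = field(default_factory=_default_grid)
    mcmc_runs: int = 2000
    repeats: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("beta_values", "A_values", "beta_sim_values"):
            g = np.asarray(getattr(self, name), dtype=float)
            if g.size == 0 or np.any(g <= 0) or np.any(np.diff(g) <= 0):
                raise ValueError(f"{name} must be nonempty, positive, strictly increasing")
        if self.mcmc_runs < 1 or self.repeats < 1:
            raise ValueError("mcmc_runs and repeats must be >= 1")


@dataclass
class FcCurve:
    """Correlation between observed and reconstructed FC per simulated beta.

    Failed cells (frozen simulations with constant rows) are NaN and are
    excluded from the maximum.
    """

    betas: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.betas = np.asarray(self.betas, dtype=float)
        self.values = np.asarray(self.values, dtype=float)

    @property
    def max_fc(self) -> float:
        if np.all(np.isnan(self.values)):
            raise DegenerateError("every simulated beta produced a degenerate trace")
        return float(np.nanmax(self.values))

    @property
    def beta_at_max(self) -> float:
        return float(self.betas[np.nanargmax(self.values)])


@dataclass
class GridSearchResult:
    """Full objective surface plus the selected cell and its coupling matrix."""

    surface: pd.DataFrame
    beta_opt: float
    A_opt: float
    objective_opt: float
    coupling: CouplingMatrix
    observed_fc: FunctionalConnectivity


def _upper(v: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(v.shape[0], k=1)
    return v[iu]


def similarity_metric(J, W) -> float:
    """Pearson correlation between |J| and W over distinct pairs (i < j)."""
    Jm, Wm = _coerce_J(J), _coerce_W(W)
    a, b = np.abs(_upper(Jm)), _upper(Wm)
    if a.std() == 0 or b.std() == 0:
        raise DegenerateError("similarity metric undefined for a constant vector")
    return float(stats.pearsonr(a, b)[0])


def fc_correlation_curve(J, observed_fc: FunctionalConnectivity, sim_cfg: McmcConfig) -> FcCurve:
    """Simulate the fitted system at every ``sim_cfg.beta_grid`` value and
    correlate reconstructed with observed FC (upper triangles).

    The simulation uses the full signed coupling matrix — reconstruction
    probes the fitted interactions directly; only phase-transition scans
    restrict to the positive part.
    """
    betas = np.asarray(sim_cfg.beta_grid, dtype=float)
    if betas.size == 0:
        raise ValueError("sim_cfg.beta_grid is empty")
    obs = _upper(observed_fc.fc)
    seeds = np.random.SeedSequence(sim_cfg.seed).spawn(betas.size)
    values = np.full(betas.size, np.nan)
    for k, beta in enumerate(betas):
        cfg_k = replace(sim_cfg, seed=int(seeds[k].generate_state(1)[0] % (2**31 - 1)))
        trace = simulate(J, float(beta), cfg_k)
        try:
            sim_fc = reconstructed_fc(trace)
        except ConstantRegionError:
            continue  # frozen at this beta; cell recorded as missing
        values[k] = stats.pearsonr(obs, _upper(sim_fc.fc))[0]
    return FcCurve(betas, values)


def grid_search(
    S: BinarizedActivity,
    W: StructuralConnectome,
    observed_fc: FunctionalConnectivity,
    cfg: GridSearchConfig,
    inf_cfg: InferenceConfig | None = None,
) -> GridSearchResult:
    """Fit the constrained model at every (beta, A), score each cell with
    ``S_m`` and ``max f_c``, and select the cell maximizing their sum.

    Ties are broken toward smaller A, then smaller beta (the least
    constrained model at equal fit). Cells where fitting diverges are
    recorded with NaN objective and skipped; if every cell fails a
    ``DivergenceError`` propagates.
    """
    inf_cfg = inf_cfg or InferenceConfig()
    rows = []
    best = None  # (objective, A, beta, J)
    master = np.random.SeedSequence(cfg.seed)
    n_fail = 0
    for A in cfg.A_values:  # A outer: first strict max wins ties at smaller A
        for beta in cfg.beta_values:
            cell_cfg = replace(inf_cfg, beta=float(beta), A=float(A))
            try:
                J_hat = fit(S, cell_cfg, W)
            except DivergenceError:
                n_fail += 1
                rows.append(dict(beta=beta, A=A, S_m=np.nan, max_fc=np.nan,
                                 max_fc_sd=np.nan, beta_sim_at_max=np.nan,
                                 objective=np.nan, converged=False))
                continue
            s_m = similarity_metric(J_hat, W)
            maxima, beta_at = [], []
            child = master.spawn(1)[0]
            for rep in range(cfg.repeats):
                sim_cfg = McmcConfig(
                    runs=cfg.mcmc_runs,
                    beta_grid=tuple(cfg.beta_sim_values),
                    seed=int(child.generate_state(1)[0] % (2**31 - 1)) + rep,
                )
                try:
                    curve = fc_correlation_curve(J_hat, observed_fc, sim_cfg)
                    maxima.append(curve.max_fc)
                    beta_at.append(curve.beta_at_max)
                except DegenerateError:
                    continue
            if not maxima:
                n_fail += 1
                rows.append(dict(beta=beta, A=A, S_m=s_m, max_fc=np.nan,
                                 max_fc_sd=np.nan, beta_sim_at_max=np.nan,
                                 objective=np.nan, converged=J_hat.fit_info["converged"]))
                continue
            max_fc = float(np.mean(maxima))
            objective = max_fc + s_m
            rows.append(dict(
                beta=beta, A=A, S_m=s_m, max_fc=max_fc,
                max_fc_sd=float(np.std(maxima)),
                beta_sim_at_max=float(np.mean(beta_at)),
                objective=objective, converged=J_hat.fit_info["converged"],
            ))
            if best is None or objective > best[0]:
                best = (objective, float(A), float(beta), J_hat)
    if best is None:
        raise DivergenceError("every grid cell failed")
    surface = pd.DataFrame(rows)
    objective_opt, A_opt, beta_opt, J_opt = best
    return GridSearchResult(surface, beta_opt, A_opt, objective_opt, J_opt, observed_fc)
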