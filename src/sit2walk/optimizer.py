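"""CMA-ES optimization of the controller parameter vector.

A standard (mu/mu_w, lambda) Covariance Matrix Adaptation Evolution Strategy
with rank-1 and rank-mu covariance updates, run in normalized coordinates
(each free parameter mapped to [0, 1] over its box), so one step size is
meaningful across heterogeneous gains.  Bounds are honored by projection:
candidates are clipped to the box before evaluation and update.

Supports independent restarts with derived seeds (best kept) and the
progressive warm-start chain across study conditions: each condition's
optimizations start from the best solution of the previous condition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .controller import ParamVector

__all__ = ["OptimizationConfig", "OptimizationResult", "optimize",
           "optimize_parallel", "warm_start_chain"]


@dataclass
class OptimizationConfig:
    population_size: int = 10
    max_generations: int = 300
    sigma0: float = 0.05           # in normalized [0,1] coordinates
    n_parallel: int = 3
    seed: int = 0
    eval_budget: int | None = None
    stagnation_gens: int = 200
    stagnation_tol: float = 1e-6

    def __post_init__(self):
        if self.population_size < 4:
            raise ValueError("population_size must be >= 4")


@dataclass
class OptimizationResult:
    best_params: ParamVector
    best_cost: float
    trace: np.ndarray            # columns: generation, gen best, best ever, median
    seed: int
    generations: int
    condition_id: str = ""
    n_evals: int = 0
    no_solution: bool = False
    meta: dict = field(default_factory=dict)


def _to_norm(values, lo, width):
    return (values - lo) / width


def _from_norm(z, lo, width):
    return lo + z * width


def optimize(cost_fn, x0: ParamVector, config: OptimizationConfig) -> OptimizationResult:
    """Minimize cost_fn over the free entries of x0; deterministic per seed."""
    rng = np.random.default_rng(config.seed)
    free = np.nonzero(x0.free)[0]
    n = free.size
    lo = x0.lower[free]
    width = np.maximum(x0.upper[free] - lo, 1e-12)

    full = x0.values.copy()

    def eval_z(z):
        vals = full.copy()
        vals[free] = _from_norm(z, lo, width)
        return float(cost_fn(x0.with_values(vals)))

    z_mean = np.clip(_to_norm(x0.values[free], lo, width), 0.0, 1.0)
    best_cost = eval_z(z_mean)
    best_z = z_mean.copy()
    n_evals = 1
    trace = [(0, best_cost, best_cost, best_cost)]

    if n == 0 or config.max_generations == 0 or (config.eval_budget is not None
                                                 and config.eval_budget <= 1):
        bp = x0.with_values(full.copy())
        bp.values[free] = _from_norm(best_z, lo, width)
        return OptimizationResult(bp, best_cost, np.array(trace), config.seed,
                                  0, n_evals=n_evals)

    # --- CMA-ES constants ---
    lam = config.population_size
    mu = lam // 2
    wraw = np.log(mu + 0.5) - np.log(np.arange(1, mu + 1))
    weights = wraw / wraw.sum()
    mueff = 1.0 / (weights ** 2).sum()
    cc = (4 + mueff / n) / (n + 4 + 2 * mueff / n)
    cs = (mueff + 2) / (n + mueff + 5)
    c1 = 2 / ((n + 1.3) ** 2 + mueff)
    cmu = min(1 - c1, 2 * (mueff - 2 + 1 / mueff) / ((n + 2) ** 2 + mueff))
    damps = 1 + 2 * max(0.0, np.sqrt((mueff - 1) / (n + 1)) - 1) + cs
    chi_n = np.sqrt(n) * (1 - 1 / (4 * n) + 1 / (21 * n ** 2))

    sigma = config.sigma0
    C = np.eye(n)
    pc = np.zeros(n)
    ps = np.zeros(n)
    B = np.eye(n)
    D = np.ones(n)
    stale = 0
    gen = 0

    for gen in range(1, config.max_generations + 1):
        # sample
        Zn = rng.standard_normal((lam, n))
        Y = Zn @ (B * D).T              # N(0, C) samples
        X = np.clip(z_mean + sigma * Y, 0.0, 1.0)
        costs = np.empty(lam)
        for k in range(lam):
            costs[k] = eval_z(X[k])
        n_evals += lam
        order = np.argsort(costs, kind="stable")
        gen_best = costs[order[0]]
        improved = gen_best < best_cost - config.stagnation_tol
        if gen_best < best_cost:
            best_cost = gen_best
            best_z = X[order[0]].copy()
        stale = 0 if improved else stale + 1
        trace.append((gen, gen_best, best_cost, float(np.median(costs))))

        # recombination (on projected samples, y re-derived from them)
        Xel = X[order[:mu]]
        z_old = z_mean
        z_mean = weights @ Xel
        y_w = (z_mean - z_old) / sigma

        # step-size control
        Cinv_half = B @ np.diag(1.0 / D) @ B.T
        ps = (1 - cs) * ps + np.sqrt(cs * (2 - cs) * mueff) * (Cinv_half @ y_w)
        sigma *= np.exp((cs / damps) * (np.linalg.norm(ps) / chi_n - 1))
        sigma = min(sigma, 1.0)

        # covariance update
        hsig = (np.linalg.norm(ps) / np.sqrt(1 - (1 - cs) ** (2 * gen))
                < (1.4 + 2 / (n + 1)) * chi_n)
        pc = (1 - cc) * pc + hsig * np.sqrt(cc * (2 - cc) * mueff) * y_w
        artmp = (Xel - z_old) / sigma
        C = ((1 - c1 - cmu) * C
             + c1 * (np.outer(pc, pc) + (not hsig) * cc * (2 - cc) * C)
             + cmu * artmp.T @ (weights[:, None] * artmp))
        C = (C + C.T) / 2
        evals_d, B = np.linalg.eigh(C)
        D = np.sqrt(np.maximum(evals_d, 1e-20))

        if stale >= config.stagnation_gens:
            break
        if config.eval_budget is not None and n_evals >= config.eval_budget:
            break

    bp = x0.with_values(full.copy())
    bp.values[free] = _from_norm(best_z, lo, width)
    return OptimizationResult(bp, best_cost, np.array(trace), config.seed,
                              gen, n_evals=n_evals)


def optimize_parallel(cost_fn, x0: ParamVector,
                      config: OptimizationConfig) -> OptimizationResult:
    """n_parallel independent optimizations from the same initial guess;
    the best result is kept.  Evaluations are independent rollouts, so
    results are identical to any execution order."""
    results = []
    for k in range(max(1, config.n_parallel)):
        cfg_k = OptimizationConfig(**{**config.__dict__,
                                      "seed": (config.seed + 9973 * k) % (2 ** 31)})
        results.append(optimize(cost_fn, x0, cfg_k))
    best = min(results, key=lambda r: r.best_cost)
    best.meta["restart_costs"] = [r.best_cost for r in results]
    return best


def warm_start_chain(conditions, base_params: ParamVector, cost_factory,
                     config: OptimizationConfig, feasibility_fn=None):
    """Optimize a severity-ordered condition list with progressive warm starts.

    ``cost_factory(condition)`` returns the cost function of a condition;
    ``feasibility_fn(condition, params)`` (optional) decides whether the
    best solution actually solves the task (e.g., achieves seat-off).  An
    infeasible condition is flagged no_solution and the chain continues
    from the last feasible parameters.
    """
    results = []
    start = base_params
    last_feasible = base_params
    for ci, cond in enumerate(conditions):
        cfg = OptimizationConfig(**{**config.__dict__,
                                    "seed": (config.seed + 131 * ci) % (2 ** 31)})
        res = optimize_parallel(cost_factory(cond), start, cfg)
        res.condition_id = getattr(cond, "condition_id", str(cond))
        if feasibility_fn is not None and not feasibility_fn(cond, res.best_params):
            res.no_solution = True
            start = last_feasible
        else:
            last_feasible = res.best_params
            start = res.best_params
        results.append(res)
    return results
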