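"""Feasibility-seeking (AMS) and superiorization solvers.

The plan reoptimization problem is posed as a feasibility problem: find a
nonnegative fluence vector ``x`` satisfying every per-voxel interval

    L_i <= <a_i, x> <= U_i,

where ``a_i`` is a dose influence row for target voxels and a cDL
(``c * N``) row for organ-at-risk voxels.  The solver is a simultaneous
(Cimmino-type) relaxed projection method in the AMS
(Agmon--Motzkin--Schoenberg) family: every violated slab contributes its
Euclidean projection displacement, the displacements are averaged with
weights normalised over *all* rows, scaled by a relaxation parameter
``0 < lambda <= 2``, and the step is followed by a clamp onto the
nonnegative orthant (physical fluences).  For a consistent system the
iteration is Fejer monotone with respect to the feasible intersection.

Superiorization interlaces bounded negative-gradient perturbations of the
weighted least-squares objective

    chi^2(x) = sum_PTV w_i (Dhat_i - D(x)_i)^2
             + sum_OAR w_i (cDLhat_i - cDL(x)_i)^2

into the feasibility-seeking iteration: before each projection sweep the
iterate moves a step ``beta = alpha**s`` (s incremented on every trial,
``0 < alpha < 1``) along the normalised negative gradient, accepted only
when it does not increase the objective.  Because ``sum_s alpha**s``
converges, the total perturbation is bounded and the perturbed sequence
retains the feasibility behaviour of the unperturbed one, while typically
ending at a feasible point with an equal or lower objective value than
feasibility-seeking alone.  The objective weights decay by ``eta**k``
(``0 < eta < 1``) across outer iterations, progressively de-emphasising
the perturbation targets relative to feasibility.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse

from .constraints import StackedConstraints

__all__ = [
    "AMSParams",
    "SuperiorizationParams",
    "project_interval_row",
    "ams_iteration",
    "ams_sweep",
    "feasibility_seek",
    "weighted_residual",
    "objective_chi2",
    "gradient_chi2",
    "superiorize",
]

#: relative tolerance used to decide whether a bound is violated
VIOLATION_RTOL = 1e-12


@dataclass(frozen=True)
class AMSParams:
    """Feasibility-seeking parameters.

    ``relaxation`` is the AMS relaxation parameter, restricted to
    ``0 < lambda <= 2``; ``tol`` is the weighted residual (Gy) below which
    iteration stops (0 means: stop only at exact feasibility or the
    iteration cap).  ``mode`` selects the projection scheme per iteration:
    ``"cyclic"`` (default) sweeps the rows one by one in ascending weight
    order -- the classical cyclic relaxation method, so the highest-priority
    (target) rows are projected last and land exactly on their bounds --
    while ``"simultaneous"`` applies the Cimmino-type averaged step of
    :func:`ams_iteration`, the form suited to massively parallel hardware.
    Both are Fejer monotone for consistent systems.
    """

    relaxation: float = 1.0
    max_iterations: int = 200
    tol: float = 0.0
    normalize_weights: bool = True
    mode: str = "cyclic"

    def __post_init__(self) -> None:
        if not 0.0 < self.relaxation <= 2.0:
            raise ValueError(f"relaxation must satisfy 0 < lambda <= 2, got {self.relaxation}")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.tol < 0:
            raise ValueError("tol must be >= 0")
        if self.mode not in ("cyclic", "simultaneous"):
            raise ValueError(f"mode must be 'cyclic' or 'simultaneous', got {self.mode!r}")


@dataclass(frozen=True)
class SuperiorizationParams:
    """Perturbation-phase parameters.

    ``alpha`` controls the geometric step schedule ``beta = alpha**s``;
    ``eta`` is the per-outer-iteration objective weight decay; both must
    lie strictly in (0, 1).  ``n_perturbations`` gradient steps are
    attempted per outer iteration.  ``weight_decay`` selects whether the
    decay applies to all objective terms (``"objective"``) or only the OAR
    (cDL-space) terms (``"oar"``).
    """

    alpha: float = 0.5
    eta: float = 0.9
    n_perturbations: int = 1
    outer_iterations: int | None = None
    weight_decay: str = "objective"

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must satisfy 0 < alpha < 1, got {self.alpha}")
        if not 0.0 < self.eta < 1.0:
            raise ValueError(f"eta must satisfy 0 < eta < 1, got {self.eta}")
        if self.n_perturbations < 1:
            raise ValueError("n_perturbations must be >= 1")
        if self.weight_decay not in ("objective", "oar"):
            raise ValueError("weight_decay must be 'objective' or 'oar'")


def project_interval_row(x, a, lower: float, upper: float) -> np.ndarray:
    """Displacement taking ``x`` to its Euclidean projection onto the slab
    ``lower <= <a, x> <= upper``.

    Returns the zero vector when ``x`` already satisfies the interval;
    otherwise ``d = ((bound - <a,x>) / ||a||^2) * a`` for the violated
    bound, so ``x + d`` lands exactly on the slab boundary.
    """
    x = np.asarray(x, dtype=float)
    if sparse.issparse(a):
        a = np.asarray(a.todense()).ravel()
    else:
        a = np.asarray(a, dtype=float).ravel()
    norm_sq = float(a @ a)
    if norm_sq == 0.0:
        raise ValueError("constraint row is all zero; projection undefined")
    t = float(a @ x)
    if t > upper:
        return ((upper - t) / norm_sq) * a
    if t < lower:
        return ((lower - t) / norm_sq) * a
    return np.zeros_like(x)


def _normalized_weights(sc: StackedConstraints, params: AMSParams) -> np.ndarray:
    if params.normalize_weights:
        return sc.weight / sc.weight.sum()
    return sc.weight


def _violation(t: np.ndarray, sc: StackedConstraints) -> np.ndarray:
    """Signed bound excess per row: positive above U, negative below L, 0 inside."""
    scale = np.maximum(np.abs(sc.lower), np.abs(sc.upper)) + 1.0
    over = t - sc.upper
    under = t - sc.lower
    out = np.where(over > VIOLATION_RTOL * scale, over, 0.0)
    out = np.where(under < -VIOLATION_RTOL * scale, under, out)
    return out


def weighted_residual(x, sc: StackedConstraints, params: AMSParams | None = None) -> float:
    """Root weighted mean-square bound violation (Gy)."""
    params = params or AMSParams()
    t = sc.A @ np.asarray(x, dtype=float)
    v = _violation(t, sc)
    wn = _normalized_weights(sc, params)
    return float(np.sqrt(np.sum(wn * v * v)))


def ams_iteration(x, sc: StackedConstraints, params: AMSParams | None = None) -> np.ndarray:
    """One simultaneous relaxed projection step with nonnegativity clamp.

    ``x <- clamp_+( x + lambda * sum_i w~_i d_i )`` where the sum runs over
    violated rows, ``d_i`` is the slab-projection displacement of row
    ``i``, and ``w~`` are the weights normalised over all rows.
    """
    params = params or AMSParams()
    if sc.n_rows == 0:
        raise ValueError("no constraints to project onto")
    x = np.asarray(x, dtype=float)
    t = sc.A @ x
    if not np.all(np.isfinite(t)):
        raise FloatingPointError("non-finite value in forward product")
    v = _violation(t, sc)
    wn = _normalized_weights(sc, params)
    coef = wn * (-v) / sc.row_norm_sq
    step = sc.A.T @ coef
    return np.maximum(x + params.relaxation * step, 0.0)


def _sweep_order(sc: StackedConstraints) -> np.ndarray:
    # lowest-priority rows first; cDL rows before dose rows on weight ties
    keys = np.lexsort((sc.space == "dose", sc.weight))
    return keys


def ams_sweep(x, sc: StackedConstraints, params: AMSParams | None = None) -> np.ndarray:
    """One cyclic pass: relaxed projection onto each violated slab in turn.

    Rows are visited in ascending weight order (see :class:`AMSParams`);
    the nonnegativity clamp is applied after every row projection.
    """
    params = params or AMSParams()
    if sc.n_rows == 0:
        raise ValueError("no constraints to project onto")
    x = np.asarray(x, dtype=float).copy()
    a = sc.A
    indptr, indices, data = a.indptr, a.indices, a.data
    lam = params.relaxation
    for i in _sweep_order(sc):
        lo, hi = indptr[i], indptr[i + 1]
        cols = indices[lo:hi]
        vals = data[lo:hi]
        t = vals @ x[cols]
        if not np.isfinite(t):
            raise FloatingPointError("non-finite value in forward product")
        if t > sc.upper[i]:
            x[cols] = np.maximum(x[cols] + lam * ((sc.upper[i] - t) / sc.row_norm_sq[i]) * vals, 0.0)
        elif t < sc.lower[i]:
            x[cols] = np.maximum(x[cols] + lam * ((sc.lower[i] - t) / sc.row_norm_sq[i]) * vals, 0.0)
    return x


def _ams_step(x, sc: StackedConstraints, params: AMSParams) -> np.ndarray:
    if params.mode == "cyclic":
        return ams_sweep(x, sc, params)
    return ams_iteration(x, sc, params)


def feasibility_seek(x0, sc: StackedConstraints, params: AMSParams | None = None):
    """Run AMS iterations until the residual tolerance or the iteration cap.

    Returns ``(x, diagnostics)`` where diagnostics holds the per-iteration
    weighted residual trace, the chi^2 trace (NaN-free only when every row
    carries a reference value), and the number of iterations performed.
    """
    params = params or AMSParams()
    x = np.asarray(x0, dtype=float).copy()
    if x.min() < 0:
        raise ValueError("initial fluence must be nonnegative")
    has_refs = np.all(np.isfinite(sc.reference))
    residuals = [weighted_residual(x, sc, params)]
    chi2s = [objective_chi2(x, sc)] if has_refs else []
    iterations = 0
    while iterations < params.max_iterations and residuals[-1] > params.tol:
        try:
            x = _ams_step(x, sc, params)
        except FloatingPointError as exc:
            raise FloatingPointError(f"{exc} at iteration {iterations}") from None
        iterations += 1
        residuals.append(weighted_residual(x, sc, params))
        if has_refs:
            chi2s.append(objective_chi2(x, sc))
    diagnostics = {
        "residuals": np.asarray(residuals),
        "chi2": np.asarray(chi2s) if has_refs else None,
        "iterations": iterations,
        "residual": residuals[-1],
    }
    return x, diagnostics


def objective_chi2(x, sc: StackedConstraints, weights: np.ndarray | None = None) -> float:
    """Weighted least-squares objective against the reference values."""
    if not np.all(np.isfinite(sc.reference)):
        raise ValueError("constraint rows are missing reference values")
    w = sc.weight if weights is None else weights
    r = sc.reference - sc.A @ np.asarray(x, dtype=float)
    return float(np.sum(w * r * r))


def gradient_chi2(x, sc: StackedConstraints, weights: np.ndarray | None = None) -> np.ndarray:
    """Gradient of :func:`objective_chi2` with respect to the fluences."""
    if not np.all(np.isfinite(sc.reference)):
        raise ValueError("constraint rows are missing reference values")
    w = sc.weight if weights is None else weights
    r = sc.reference - sc.A @ np.asarray(x, dtype=float)
    return -2.0 * (sc.A.T @ (w * r))


def superiorize(
    x0,
    sc: StackedConstraints,
    ams_params: AMSParams | None = None,
    sup_params: SuperiorizationParams | None = None,
):
    """Superiorized feasibility-seeking.

    Each outer iteration performs (a) ``n_perturbations`` bounded
    negative-gradient perturbations with step ``beta = alpha**s * scale``
    and a function-decrease acceptance test, (b) multiplication of the
    objective weights by ``eta``, and (c) one AMS projection step.  The
    perturbation scale is ``max(1, ||x0||_inf)`` so steps are commensurate
    with the fluence magnitude, and the geometric series bounds the total
    perturbation by ``alpha / (1 - alpha) * scale``.

    Returns ``(x, diagnostics)``; the chi^2 trace is reported at the
    *original* weights so runs are comparable with plain
    :func:`feasibility_seek`.
    """
    ams_params = ams_params or AMSParams()
    sup_params = sup_params or SuperiorizationParams()
    x = np.asarray(x0, dtype=float).copy()
    if x.min() < 0:
        raise ValueError("initial fluence must be nonnegative")
    if not np.all(np.isfinite(sc.reference)):
        raise ValueError("constraint rows are missing reference values")

    n_outer = sup_params.outer_iterations or ams_params.max_iterations
    scale = max(1.0, float(np.max(np.abs(x))) if x.size else 1.0)
    w_obj = sc.weight.astype(float).copy()
    decay_rows = slice(None) if sup_params.weight_decay == "objective" else (sc.space == "cdl")
    s = 1
    residuals = [weighted_residual(x, sc, ams_params)]
    chi2s = [objective_chi2(x, sc)]
    betas = []

    for k in range(n_outer):
        if residuals[-1] <= ams_params.tol and ams_params.tol > 0:
            break
        # (a) perturbation phase
        for _ in range(sup_params.n_perturbations):
            g = gradient_chi2(x, sc, w_obj)
            gnorm = float(np.linalg.norm(g))
            if gnorm == 0.0:
                betas.append(0.0)
                continue
            v = -g / gnorm
            f0 = objective_chi2(x, sc, w_obj)
            accepted = 0.0
            while True:
                beta = sup_params.alpha**s * scale
                s += 1
                if beta < 1e-16 * scale:
                    break
                y = np.maximum(x + beta * v, 0.0)
                if objective_chi2(y, sc, w_obj) <= f0:
                    x = y
                    accepted = beta
                    break
            betas.append(accepted)
        # (b) objective weight decay
        w_obj[decay_rows] *= sup_params.eta
        # (c) one feasibility-seeking step
        try:
            x = _ams_step(x, sc, ams_params)
        except FloatingPointError as exc:
            raise FloatingPointError(f"{exc} at outer iteration {k}") from None
        residuals.append(weighted_residual(x, sc, ams_params))
        chi2s.append(objective_chi2(x, sc))

    diagnostics = {
        "residuals": np.asarray(residuals),
        "chi2": np.asarray(chi2s),
        "betas": np.asarray(betas),
        "iterations": len(residuals) - 1,
        "residual": residuals[-1],
        "final_s": s,
        "weight_scale": w_obj.max() / sc.weight.max() if sc.weight.size else 1.0,
    }
    return x, diagnostics
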