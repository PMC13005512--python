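"""Flux prediction engines: FBA, entropic FBA, MOMA, gene knockouts.

FBA solves ``max c'v  s.t.  S v = 0, lb <= v <= ub`` as a linear program.

Entropic FBA adds a strictly convex flux-entropy term over split forward /
reverse fluxes::

    max  c'(vf - vr) - g * sum_j [vf_j ln vf_j - vf_j + vr_j ln vr_j - vr_j]
    s.t. S (vf - vr) = 0,  vf, vr >= 0,  lb <= vf - vr <= ub

with entropy weight ``g > 0``.  The split bounds vf in [max(lb,0), max(ub,0)]
and vr in [max(-ub,0), max(-lb,0)] encode the net bounds exactly, so the
problem is a separable convex program over a box intersected with the
nullspace of [S, -S].  It is solved by a damped semismooth Newton method on
the dual (metabolite potential) variables with continuation in the entropy
weight; strict convexity makes the primal solution unique, so repeated runs
agree to solver tolerance regardless of initialisation.

MOMA (minimisation of metabolic adjustment) projects a reference flux vector
onto the feasible set of a (possibly perturbed) model:
``min ||v - v_ref||^2  s.t.  S v = 0, lb <= v <= ub`` — the same separable
structure with a quadratic instead of an entropic potential, so it shares
the dual Newton solver.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Callable

import numpy as np
from scipy.optimize import LinearConstraint, linprog, minimize

from .gpr import evaluate_gpr
from .model import MetabolicModel

EXPORT_FLOOR = 1e-9  # fluxes below this magnitude are written as 0 in exports


@dataclass
class FluxState:
    """Forward/reverse/net fluxes for one model solve (umol/gDW/hr)."""

    reaction_ids: list[str]
    vf: np.ndarray
    vr: np.ndarray
    objective_value: float
    status: str  # optimal | infeasible | unbounded | not_converged
    linear_objective: float = float("nan")
    residual: float = float("nan")

    @property
    def v(self) -> np.ndarray:
        return self.vf - self.vr

    @property
    def activity(self) -> np.ndarray:
        """Total unidirectional activity vf + vr."""
        return self.vf + self.vr

    def flux(self, reaction_id: str) -> float:
        return float(self.v[self.reaction_ids.index(reaction_id)])

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.reaction_ids, self.v))

    def to_tsv(self, path: str | Path) -> None:
        v = self.v
        with open(path, "w") as fh:
            fh.write("reaction_id\tvf\tvr\tv\n")
            for i, rid in enumerate(self.reaction_ids):
                vals = [
                    0.0 if abs(x) < EXPORT_FLOOR else x
                    for x in (self.vf[i], self.vr[i], v[i])
                ]
                fh.write(f"{rid}\t{vals[0]:.10g}\t{vals[1]:.10g}\t{vals[2]:.10g}\n")


def _check_bounds(model: MetabolicModel) -> tuple[np.ndarray, np.ndarray]:
    lb, ub = model.bounds_arrays()
    bad = np.nonzero(lb > ub)[0]
    if bad.size:
        rid = model.reaction_ids[bad[0]]
        raise ValueError(f"reaction {rid!r}: lb={lb[bad[0]]} exceeds ub={ub[bad[0]]}")
    return lb, ub


def _objective_vector(model: MetabolicModel, objective: dict[str, float] | None) -> np.ndarray:
    if objective is None:
        c = model.objective_vector()
    else:
        c = np.zeros(len(model.reactions))
        index = {r: j for j, r in enumerate(model.reaction_ids)}
        for rid, w in objective.items():
            if rid not in index:
                raise KeyError(f"objective reaction {rid!r} not in model")
            c[index[rid]] = w
    return c


# ---------------------------------------------------------------------------
# FBA
# ---------------------------------------------------------------------------

def fba(model: MetabolicModel, objective: dict[str, float] | None = None) -> FluxState:
    """Maximise a linear flux objective at steady state.

    ``objective`` maps reaction id -> weight; when omitted the model's own
    objective coefficients are used.  At least one weight must be nonzero.
    """
    if not model.reactions:
        raise ValueError("model has no reactions")
    lb, ub = _check_bounds(model)
    c = _objective_vector(model, objective)
    if not np.any(c):
        raise ValueError("objective has no nonzero weight")
    S = model.stoichiometric_matrix()
    res = linprog(
        -c,
        A_eq=S,
        b_eq=np.zeros(S.shape[0]),
        bounds=list(zip(lb, ub)),
        method="highs",
    )
    rids = model.reaction_ids
    if res.status == 2:
        nan = np.full(len(rids), np.nan)
        return FluxState(rids, nan, nan, float("nan"), "infeasible")
    if res.status == 3:
        nan = np.full(len(rids), np.nan)
        return FluxState(rids, nan, nan, float("inf"), "unbounded")
    v = res.x
    vf = np.maximum(v, 0.0)
    vr = np.maximum(-v, 0.0)
    obj = float(c @ v)
    return FluxState(rids, vf, vr, obj, "optimal", linear_objective=obj,
                     residual=float(np.max(np.abs(S @ v))) if len(v) else 0.0)


# ---------------------------------------------------------------------------
# Separable convex programming on the flux polytope (dual damped Newton)
# ---------------------------------------------------------------------------

def _dual_newton(
    A: np.ndarray,
    lo: np.ndarray,
    hi: np.ndarray,
    x_of_s: Callable[[np.ndarray], np.ndarray],
    dxds_of_x: Callable[[np.ndarray], np.ndarray],
    y0: np.ndarray | None = None,
    tol: float = 1e-9,
    max_iter: int = 200,
) -> tuple[np.ndarray, np.ndarray, float, bool]:
    """Solve min phi(x) s.t. A x = 0, lo <= x <= hi for separable strictly
    convex phi, via semismooth Newton on the metabolite potentials y.

    ``x_of_s`` maps the stationarity value s = -(A'y) to the unconstrained
    minimiser of phi_j(x) - s_j x; ``dxds_of_x`` gives its derivative.
    Returns (x, y, residual, converged).
    """
    m = A.shape[0]
    y = np.zeros(m) if y0 is None else y0.copy()
    eps = 1e-12

    def primal(yv: np.ndarray) -> np.ndarray:
        s = -(A.T @ yv)
        return np.clip(x_of_s(s), lo, hi)

    x = primal(y)
    g = A @ x
    gnorm = np.linalg.norm(g, np.inf)
    for _ in range(max_iter):
        if gnorm <= tol:
            return x, y, gnorm, True
        active = (x > lo + 1e-14) & (x < hi - 1e-14)
        d = np.where(active, dxds_of_x(x), 0.0)
        M = (A * d) @ A.T
        M.flat[:: m + 1] += eps + 1e-14 * np.trace(M) / max(m, 1)
        try:
            step = np.linalg.solve(M, g)
        except np.linalg.LinAlgError:
            eps *= 100
            continue
        t = 1.0
        improved = False
        while t >= 1e-10:
            y_try = y + t * step
            x_try = primal(y_try)
            g_try = A @ x_try
            gn_try = np.linalg.norm(g_try, np.inf)
            if gn_try < gnorm * (1 - 1e-4 * t) or gn_try <= tol:
                y, x, g, gnorm = y_try, x_try, g_try, gn_try
                improved = True
                break
            t *= 0.5
        if improved:
            eps = max(eps / 10, 1e-12)
        else:
            eps *= 100
            if eps > 1e6:
                break
    return x, y, gnorm, gnorm <= tol


def entropic_fba(
    model: MetabolicModel,
    objective: dict[str, float] | None = None,
    entropy_weight: float = 1.0,
    tol: float | None = None,
    max_iter: int = 10_000,
) -> FluxState:
    """Entropy-regularised flux prediction (unique interior solution).

    The entropy weight trades the linear objective against flux dispersion:
    as it shrinks the net fluxes approach an FBA optimum; at moderate values
    parallel equivalent routes share flux evenly.
    """
    if entropy_weight <= 0:
        raise ValueError("entropy_weight must be positive")
    if not model.reactions:
        raise ValueError("model has no reactions")
    lb, ub = _check_bounds(model)
    c = _objective_vector(model, objective)
    S = model.stoichiometric_matrix()
    n = S.shape[1]
    A = np.hstack([S, -S])
    ctil = np.concatenate([c, -c])
    lo = np.concatenate([np.maximum(lb, 0.0), np.maximum(-ub, 0.0)])
    hi = np.concatenate([np.maximum(ub, 0.0), np.maximum(-lb, 0.0)])

    # quick feasibility probe on the net-flux LP
    probe = linprog(
        np.zeros(n), A_eq=S, b_eq=np.zeros(S.shape[0]),
        bounds=list(zip(lb, ub)), method="highs",
    )
    rids = model.reaction_ids
    if probe.status == 2:
        nan = np.full(n, np.nan)
        return FluxState(rids, nan, nan, float("nan"), "infeasible")

    feas_tol = tol if tol is not None else 1e-9

    def make_maps(lam: float):
        def x_of_s(s: np.ndarray) -> np.ndarray:
            with np.errstate(over="ignore"):
                return np.exp(np.clip((ctil + s) / lam, -700.0, 700.0))

        def dxds(x: np.ndarray) -> np.ndarray:
            return x / lam

        return x_of_s, dxds

    # continuation: start at entropy weight >= 1 and anneal down
    lam_seq = []
    lam = max(entropy_weight, 1.0)
    while lam > entropy_weight * 1.0001:
        lam_seq.append(lam)
        lam /= 10.0
    lam_seq.append(entropy_weight)

    y = None
    x = None
    residual = np.inf
    converged = False
    iters_per_stage = max(50, max_iter // max(len(lam_seq), 1))
    for lam in lam_seq:
        x_of_s, dxds = make_maps(lam)
        x, y, residual, converged = _dual_newton(
            A, lo, hi, x_of_s, dxds, y0=y, tol=feas_tol, max_iter=iters_per_stage
        )

    if not converged:
        # fall back to a direct smooth solve (trust-constr) from the Newton iterate
        x_fb, residual_fb, ok = _entropic_trust_constr(
            A, lo, hi, ctil, entropy_weight, x0=x, tol=feas_tol
        )
        if ok and residual_fb <= max(residual, feas_tol):
            x, residual, converged = x_fb, residual_fb, True

    vf, vr = x[:n], x[n:]
    v = vf - vr
    lin = float(c @ v)
    xs = np.maximum(x, 1e-300)
    entropy = float(np.sum(xs * np.log(xs) - x))
    state = FluxState(
        rids, vf, vr,
        objective_value=lin - entropy_weight * entropy,
        status="optimal" if converged else "not_converged",
        linear_objective=lin,
        residual=float(residual),
    )
    return state


def _entropic_trust_constr(A, lo, hi, ctil, lam, x0=None, tol=1e-9):
    """Direct NLP solve of the entropic program; used as a fallback."""
    from scipy.sparse import diags

    n2 = A.shape[1]
    floor = 1e-12

    def f(x):
        xs = np.maximum(x, floor)
        return float(lam * np.sum(xs * np.log(xs) - xs) - ctil @ x)

    def grad(x):
        xs = np.maximum(x, floor)
        return lam * np.log(xs) - ctil

    def hess(x):
        return diags(lam / np.maximum(x, floor))

    x0 = np.clip(np.ones(n2) if x0 is None else x0, np.maximum(lo, floor), np.maximum(hi, floor))
    res = minimize(
        f, x0, jac=grad, hess=hess, method="trust-constr",
        constraints=[LinearConstraint(A, 0.0, 0.0)],
        bounds=list(zip(np.maximum(lo, 0.0), hi)),
        options={"gtol": 1e-12, "xtol": 1e-16, "barrier_tol": 1e-12,
                 "maxiter": 3000, "verbose": 0},
    )
    x = np.clip(res.x, lo, hi)
    residual = float(np.linalg.norm(A @ x, np.inf))
    return x, residual, residual <= max(tol * 10, 1e-7)


# ---------------------------------------------------------------------------
# MOMA
# ---------------------------------------------------------------------------

def moma(model: MetabolicModel, reference: FluxState | np.ndarray) -> FluxState:
    """Minimise squared flux distance to a reference state under the model's
    current bounds (the quadratic variant of minimisation of metabolic
    adjustment, used after gene knockouts)."""
    ref = reference.v if isinstance(reference, FluxState) else np.asarray(reference, float)
    n = len(model.reactions)
    if ref.shape != (n,):
        raise ValueError(f"reference flux dimension {ref.shape} != model size {n}")
    lb, ub = _check_bounds(model)
    S = model.stoichiometric_matrix()
    rids = model.reaction_ids

    probe = linprog(
        np.zeros(n), A_eq=S, b_eq=np.zeros(S.shape[0]),
        bounds=list(zip(lb, ub)), method="highs",
    )
    if probe.status == 2:
        nan = np.full(n, np.nan)
        return FluxState(rids, nan, nan, float("nan"), "infeasible")

    scale = max(1.0, float(np.max(np.abs(ref))), float(np.max(np.abs(ub))), float(np.max(np.abs(lb))))
    feas_tol = 1e-10 * scale

    def x_of_s(s: np.ndarray) -> np.ndarray:
        return ref + s / 2.0

    def dxds(x: np.ndarray) -> np.ndarray:
        return np.full_like(x, 0.5)

    v, _, residual, converged = _dual_newton(
        S, lb, ub, x_of_s, dxds, tol=feas_tol, max_iter=500
    )
    if not converged:
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # scipy grumbles about rank-deficient S
            res = minimize(
                lambda x: float(np.sum((x - ref) ** 2)),
                np.clip(probe.x, lb, ub),
                jac=lambda x: 2.0 * (x - ref),
                method="trust-constr",
                constraints=[LinearConstraint(S, 0.0, 0.0)],
                bounds=list(zip(lb, ub)),
                options={"gtol": 1e-12, "xtol": 1e-14, "maxiter": 3000},
            )
        v = np.clip(res.x, lb, ub)
        residual = float(np.linalg.norm(S @ v, np.inf))
        converged = residual <= feas_tol * 100
    dist = float(np.sum((v - ref) ** 2))
    return FluxState(
        rids, np.maximum(v, 0.0), np.maximum(-v, 0.0),
        objective_value=dist,
        status="optimal" if converged else "not_converged",
        linear_objective=float("nan"),
        residual=float(residual),
    )


# ---------------------------------------------------------------------------
# Knockouts
# ---------------------------------------------------------------------------

def apply_knockout(model: MetabolicModel, genes: set[str]) -> MetabolicModel:
    """Close every reaction whose GPR evaluates inactive when ``genes`` are
    off (all other genes on).  Returns a modified copy."""
    genes = set(genes)
    if not genes:
        raise ValueError("knockout gene set is empty")
    unknown = genes - model.genes
    if unknown:
        raise KeyError(f"unknown gene(s): {sorted(unknown)}")
    out = model.copy()
    for rxn in out.reactions.values():
        if rxn.gpr.is_empty():
            continue
        states = {g: (g not in genes) for g in rxn.genes}
        if not evaluate_gpr(rxn.gpr, states):
            rxn.lb = 0.0
            rxn.ub = 0.0
    return out
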