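"""Stoichiometric and flux consistency checks.

Stoichiometric consistency: existence of strictly positive metabolite
weights orthogonal to every internal (non-exchange) reaction column — i.e.
no internal reaction creates mass from nothing.  Solved as a linear
feasibility problem (w >= 1, S_int' w = 0; any solution can be rescaled).

Flux consistency: a reaction is blocked when it cannot carry |flux| > tol
in any steady state admitted by the bounds; checked by per-reaction flux
maximisation/minimisation (flux variability).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linprog

from .model import MetabolicModel

DEFAULT_TOL = 1e-9


@dataclass
class ConsistencyReport:
    stoichiometrically_consistent: bool
    blocked_reactions: set[str] = field(default_factory=set)
    tol: float = DEFAULT_TOL

    @property
    def flux_consistent(self) -> bool:
        return not self.blocked_reactions


def stoichiometric_consistency(model: MetabolicModel) -> tuple[bool, np.ndarray | None]:
    """Find strictly positive metabolite weights balancing internal reactions.

    Returns (consistent, weights); weights is None when inconsistent.
    """
    S = model.stoichiometric_matrix()
    internal = [j for j, r in enumerate(model.reactions.values()) if not r.is_exchange]
    if not internal:
        return True, np.ones(S.shape[0])
    A_eq = S[:, internal].T  # one row per internal reaction
    n_mets = S.shape[0]
    res = linprog(
        c=np.ones(n_mets),
        A_eq=A_eq,
        b_eq=np.zeros(A_eq.shape[0]),
        bounds=[(1.0, None)] * n_mets,
        method="highs",
    )
    if res.status == 0:
        return True, res.x
    return False, None


def flux_variability(
    model: MetabolicModel, reaction_ids: list[str] | None = None
) -> dict[str, tuple[float, float]]:
    """(min, max) attainable net flux per reaction under Sv=0 and bounds."""
    S = model.stoichiometric_matrix()
    lb, ub = model.bounds_arrays()
    rids = model.reaction_ids
    index = {r: j for j, r in enumerate(rids)}
    targets = reaction_ids if reaction_ids is not None else rids
    bounds = list(zip(lb, ub))
    b_eq = np.zeros(S.shape[0])
    out: dict[str, tuple[float, float]] = {}
    for rid in targets:
        j = index[rid]
        c = np.zeros(len(rids))
        c[j] = 1.0
        lo = linprog(c, A_eq=S, b_eq=b_eq, bounds=bounds, method="highs")
        hi = linprog(-c, A_eq=S, b_eq=b_eq, bounds=bounds, method="highs")
        vmin = lo.x[j] if lo.status == 0 else np.nan
        vmax = hi.x[j] if hi.status == 0 else np.nan
        out[rid] = (vmin, vmax)
    return out


def blocked_reactions(model: MetabolicModel, tol: float = DEFAULT_TOL) -> set[str]:
    """Reactions unable to carry |flux| > tol in any feasible steady state."""
    fva = flux_variability(model)
    blocked = set()
    for rid, (vmin, vmax) in fva.items():
        if np.isnan(vmin) or np.isnan(vmax):
            # infeasible model: every reaction is unusable
            blocked.add(rid)
        elif max(abs(vmin), abs(vmax)) <= tol:
            blocked.add(rid)
    return blocked


def check_consistency(model: MetabolicModel, tol: float = DEFAULT_TOL) -> ConsistencyReport:
    """Report-only consistency check (never raises on an inconsistent model)."""
    if tol <= 0:
        raise ValueError(f"tol must be positive, got {tol}")
    ok, _ = stoichiometric_consistency(model)
    return ConsistencyReport(
        stoichiometrically_consistent=ok,
        blocked_reactions=blocked_reactions(model, tol=tol),
        tol=tol,
    )
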