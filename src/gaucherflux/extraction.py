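"""Context-specific subnetwork extraction.

Given a generic (whole-organism) model and core evidence — genes whose
expression passes an activity threshold plus literature-curated genes and
reactions — extract a flux-consistent subnetwork that contains every
reachable core reaction and as few supporting non-core reactions as a
greedy LP sweep finds.  The procedure is a transparent FASTCORE-style
algorithm:

1. drop reactions blocked in the generic model (core ones among them are
   reported as unreachable, never silently lost);
2. support sweep: an L1 relaxation selects a small set of non-core
   reactions whose fluxes can carry every core reaction at once; if cores
   cannot be co-active, a per-core union of LP supports is used instead;
3. pruning: non-core reactions are visited in descending connectivity
   (ties broken lexicographically by id) and removed whenever every core
   reaction can still carry |flux| >= tolerance without them
   (first-improvement);
4. cleanup: non-core reactions left blocked in the pruned subnetwork are
   removed until the result is flux-consistent.

All tie-breaking is deterministic, so extraction is reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linprog

from .consistency import blocked_reactions, check_consistency
from .model import MetabolicModel, map_genes_to_reactions


@dataclass
class CoreEvidence:
    """Evidence defining the core of a context-specific model."""

    core_genes: set[str] = field(default_factory=set)
    core_reactions: set[str] = field(default_factory=set)
    active_gene_threshold: float = 10.0  # FPKM cutoff for "actively expressed"
    expression: dict[str, float] = field(default_factory=dict)

    def active_genes(self, threshold: float | None = None) -> set[str]:
        """Core genes: explicitly listed plus expression above threshold."""
        thr = self.active_gene_threshold if threshold is None else threshold
        if thr <= 0:
            raise ValueError("active gene threshold must be positive")
        expressed = {g for g, v in self.expression.items() if v > thr}
        return set(self.core_genes) | expressed


@dataclass
class ExtractionParams:
    active_gene_threshold: float = 10.0
    flux_tolerance: float = 1e-6
    core_weight: float = 1.0  # relative inclusion weight of core vs non-core
    solver: str = "highs"

    def __post_init__(self) -> None:
        if self.flux_tolerance <= 0:
            raise ValueError("flux tolerance must be positive")


@dataclass
class ExtractionReport:
    core_reactions: set[str]
    unreachable_core: set[str]
    removed_reactions: set[str]
    n_reactions: int
    params: ExtractionParams


def _core_reaction_set(
    generic: MetabolicModel, evidence: CoreEvidence, params: ExtractionParams
) -> set[str]:
    genes = evidence.active_genes(params.active_gene_threshold)
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # genes absent from GPRs are expected here
        mapped = map_genes_to_reactions(generic, genes) if genes else set()
    explicit = set(evidence.core_reactions) & set(generic.reactions)
    return mapped | explicit


def _cores_supported(
    model: MetabolicModel, keep: set[str], core: set[str], tol: float,
    cache: dict | None = None,
) -> bool:
    """Every core reaction can carry |flux| >= tol within ``keep``?"""
    sub_ids = [r for r in model.reaction_ids if r in keep]
    index = {r: j for j, r in enumerate(sub_ids)}
    S = model.stoichiometric_matrix()
    full_index = {r: j for j, r in enumerate(model.reaction_ids)}
    cols = [full_index[r] for r in sub_ids]
    Ssub = S[:, cols]
    used = np.nonzero(np.any(Ssub != 0, axis=1))[0]
    Ssub = Ssub[used, :]
    lb = np.array([model.reactions[r].lb for r in sub_ids])
    ub = np.array([model.reactions[r].ub for r in sub_ids])
    bounds = list(zip(lb, ub))
    b_eq = np.zeros(Ssub.shape[0])
    for rid in core:
        if rid not in index:
            return False
        j = index[rid]
        c = np.zeros(len(sub_ids))
        c[j] = -1.0
        res = linprog(c, A_eq=Ssub, b_eq=b_eq, bounds=bounds, method="highs")
        if res.status == 0 and res.x[j] >= tol:
            continue
        res = linprog(-c, A_eq=Ssub, b_eq=b_eq, bounds=bounds, method="highs")
        if not (res.status == 0 and res.x[j] <= -tol):
            return False
    return True


def _l1_support(
    model: MetabolicModel, keep: list[str], core: set[str], tol: float
) -> set[str] | None:
    """L1-sparse flux carrying all core reactions at once; None if cores
    cannot be simultaneously active in their forward direction."""
    index = {r: j for j, r in enumerate(keep)}
    S = model.stoichiometric_matrix()
    full_index = {r: j for j, r in enumerate(model.reaction_ids)}
    Ssub = S[:, [full_index[r] for r in keep]]
    n = len(keep)
    lb = np.array([model.reactions[r].lb for r in keep])
    ub = np.array([model.reactions[r].ub for r in keep])
    # force each core reaction forward at >= tol (only meaningful when the
    # forward direction is admissible for every core reaction)
    lo = lb.copy()
    for rid in core:
        j = index[rid]
        if ub[j] < tol:
            return None
        lo[j] = max(lo[j], tol)
    noncore = [j for j, r in enumerate(keep) if r not in core]
    # variables: v (n) plus |v| surrogates t for non-core (len noncore)
    nt = len(noncore)
    c = np.concatenate([np.zeros(n), np.ones(nt)])
    A_eq = np.hstack([Ssub, np.zeros((Ssub.shape[0], nt))])
    # t_k >= v_j and t_k >= -v_j
    A_ub = np.zeros((2 * nt, n + nt))
    for k, j in enumerate(noncore):
        A_ub[2 * k, j] = 1.0
        A_ub[2 * k, n + k] = -1.0
        A_ub[2 * k + 1, j] = -1.0
        A_ub[2 * k + 1, n + k] = -1.0
    bounds = list(zip(lo, ub)) + [(0, None)] * nt
    res = linprog(
        c, A_ub=A_ub, b_ub=np.zeros(2 * nt), A_eq=A_eq,
        b_eq=np.zeros(A_eq.shape[0]), bounds=bounds, method="highs",
    )
    if res.status != 0:
        return None
    v = res.x[:n]
    support = set(core)
    for j, r in enumerate(keep):
        if r not in core and abs(v[j]) > tol * 0.5:
            support.add(r)
    return support


def extract_context_model(
    generic: MetabolicModel,
    evidence: CoreEvidence,
    params: ExtractionParams | None = None,
) -> tuple[MetabolicModel, ExtractionReport]:
    """Extract the context-specific subnetwork defined by ``evidence``.

    The generic model must be stoichiometrically consistent; otherwise the
    caller is directed to ``check_consistency`` first.
    """
    params = params or ExtractionParams()
    tol = params.flux_tolerance
    report_gen = check_consistency(generic, tol=min(tol, 1e-9))
    if not report_gen.stoichiometrically_consistent:
        raise ValueError(
            "generic model is stoichiometrically inconsistent; "
            "run check_consistency and repair it before extraction"
        )

    core = _core_reaction_set(generic, evidence, params)
    blocked = blocked_reactions(generic, tol=tol)
    unreachable = core & blocked
    core = core - blocked
    keep = [r for r in generic.reaction_ids if r not in blocked]

    if not core:
        sub = generic.subnetwork(set(keep), id=f"{generic.id}_context")
        report = ExtractionReport(
            core_reactions=set(), unreachable_core=unreachable,
            removed_reactions=blocked, n_reactions=len(keep), params=params,
        )
        return sub, report

    candidate = _l1_support(generic, keep, core, tol)
    if candidate is None or not _cores_supported(generic, candidate, core, tol):
        candidate = set(keep)

    # first-improvement pruning, descending connectivity, lexicographic ties
    def connectivity(rid: str) -> int:
        return len(generic.reactions[rid].stoichiometry)

    order = sorted(
        (r for r in candidate if r not in core),
        key=lambda r: (-connectivity(r), r),
    )
    current = set(candidate)
    for rid in order:
        trial = current - {rid}
        if _cores_supported(generic, trial, core, tol):
            current = trial

    # cleanup: drop non-core reactions blocked inside the final subnetwork
    while True:
        sub = generic.subnetwork(current, id=f"{generic.id}_context")
        newly_blocked = blocked_reactions(sub, tol=tol) - core
        if not newly_blocked:
            break
        current -= newly_blocked

    removed = (set(generic.reactions) - current) | blocked
    report = ExtractionReport(
        core_reactions=core,
        unreachable_core=unreachable,
        removed_reactions=removed,
        n_reactions=len(current),
        params=params,
    )
    return sub, report


def exhaustive_minimal_subnetwork(
    generic: MetabolicModel,
    core: set[str],
    tol: float = 1e-6,
) -> set[str] | None:
    """Minimum-cardinality flux-consistent subnetwork containing the
    reachable core, by exhaustive enumeration over non-core subsets.

    Reference implementation for small (<= ~12 reaction) networks with
    irreversible internal reactions: a subnetwork counts as flux-consistent
    when one steady state carries every member reaction at >= a positive
    threshold simultaneously, which for irreversible toy instances with
    ample bound headroom coincides with per-reaction consistency.  Returns
    None when no subset supports the core.  Independent of
    :func:`extract_context_model` (no shared search logic).
    """
    from itertools import combinations

    core = set(core) - blocked_reactions(generic, tol=tol)
    noncore = [r for r in generic.reaction_ids if r not in core]
    S = generic.stoichiometric_matrix()
    index = {r: j for j, r in enumerate(generic.reaction_ids)}

    # the simultaneous minimum flux must sit well above the LP solver's
    # feasibility tolerance or infeasible subsets would slip through
    min_flux = max(tol, 1e-3)

    def feasible(subset: set[str]) -> bool:
        cols = [index[r] for r in generic.reaction_ids if r in subset]
        Ssub = S[:, cols]
        used = np.nonzero(np.any(Ssub != 0, axis=1))[0]
        Ssub = Ssub[used, :]
        lo, hi = [], []
        for r in generic.reaction_ids:
            if r not in subset:
                continue
            rxn = generic.reactions[r]
            if rxn.lb >= 0:
                lo.append(max(rxn.lb, min_flux))
                hi.append(rxn.ub)
            elif rxn.ub <= 0:
                lo.append(rxn.lb)
                hi.append(min(rxn.ub, -min_flux))
            else:
                lo.append(rxn.lb)
                hi.append(rxn.ub)
        res = linprog(
            np.zeros(len(cols)), A_eq=Ssub, b_eq=np.zeros(Ssub.shape[0]),
            bounds=list(zip(lo, hi)), method="highs",
        )
        return res.status == 0

    for k in range(len(noncore) + 1):
        for combo in combinations(noncore, k):
            subset = core | set(combo)
            if not subset:
                continue
            if feasible(subset):
                return subset
    return None


def generate_draft_ensemble(
    generic: MetabolicModel,
    evidence: CoreEvidence,
    param_grid: list[ExtractionParams],
) -> list[tuple[MetabolicModel, dict]]:
    """One extracted draft model per parameter-grid point, with a manifest."""
    if not param_grid:
        raise ValueError("parameter grid is empty")
    out = []
    for i, params in enumerate(param_grid):
        model, report = extract_context_model(generic, evidence, params)
        model.id = f"{generic.id}_draft{i}"
        manifest = {
            "index": i,
            "params": {
                "active_gene_threshold": params.active_gene_threshold,
                "flux_tolerance": params.flux_tolerance,
                "core_weight": params.core_weight,
                "solver": params.solver,
            },
            "n_reactions": report.n_reactions,
            "n_core": len(report.core_reactions),
            "unreachable_core": sorted(report.unreachable_core),
        }
        out.append((model, manifest))
    return out
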