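"""Modifier-gene inference by metabolic transformation scoring.

Every single-gene knockout is scored by how far it moves a source flux
state toward a target flux state (the structure of robust metabolic
transformation analysis, in a solver-agnostic LP/QP adaptation):

- the reaction set is partitioned into R_F (must increase), R_B (must
  decrease) and R_S (must stay), derived from ensemble differential flux
  between source and target;
- the worst-case score wTS evaluates the transformation functional at the
  MOMA prediction of the knockout (minimal adjustment from the source);
- the best-case score bTS evaluates the same functional at the
  knockout-constrained flux state maximising an LP surrogate of it;
- the robust score rTS = min(bTS, wTS) when both share a sign, else 0.

The transformation functional for a movement m_r = v_KO,r - v_source,r is

    sum_{R_F} 1[m_r > delta] + sum_{R_B} 1[-m_r > delta]
    - sum_{R_S} min(|m_r| / s_r, 1),      s_r = max(|v_source,r|, 1).

Genes whose knockout leaves no feasible flux state are reported with
``feasible = False`` and no robust score.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linprog

from .ensemble import FluxEnsemble, differential_flux
from .model import MetabolicModel
from .optimize import FluxState, apply_knockout, moma


@dataclass
class TransformationTarget:
    """Reaction partition and reference values for a source->target shift."""

    reaction_ids: list[str]
    r_forward: set[str]  # required to increase
    r_backward: set[str]  # required to decrease
    r_steady: set[str]  # required to stay unchanged
    source_mean: np.ndarray
    target_mean: np.ndarray
    #: movement tolerance; scalar, or one value per reaction
    delta: float | np.ndarray = 1e-6

    def __post_init__(self) -> None:
        if (self.r_forward & self.r_backward) or (self.r_forward & self.r_steady) or (
            self.r_backward & self.r_steady
        ):
            raise ValueError("R_F, R_B, R_S must be disjoint")
        union = self.r_forward | self.r_backward | self.r_steady
        if union != set(self.reaction_ids):
            raise ValueError("R_F, R_B, R_S must partition the analysed reactions")


@dataclass
class TransformationScore:
    gene: str
    bts: float
    wts: float
    rts: float | None  # defined only when feasible
    feasible: bool


def derive_transformation_targets(
    source: FluxEnsemble,
    target: FluxEnsemble,
    fc_threshold: float = 1.0,
    p_threshold: float = 0.05,
    delta: float = 1e-6,
) -> TransformationTarget:
    """Partition reactions into R_F / R_B / R_S from ensemble differences.

    Significance comes from the activity-based differential-flux test; the
    required direction is read off the net-flux means (movements are
    measured in net flux, and for uptake exchanges the activity and net
    directions disagree in sign), with R_F holding reactions whose target
    net mean lies above the source (R_B below).  Everything unflagged (or
    untestable) is R_S.
    """
    if source.reaction_ids != target.reaction_ids:
        raise ValueError("ensembles have mismatched reaction columns")
    diff = differential_flux(
        gd=target, ctrl=source, fc_threshold=fc_threshold, p_threshold=p_threshold
    )
    src_net = dict(zip(source.reaction_ids, source.mean_net()))
    tgt_net = dict(zip(target.reaction_ids, target.mean_net()))
    r_f: set[str] = set()
    r_b: set[str] = set()
    for d in diff:
        if d.flagged:
            rid = d.reaction_id
            (r_f if tgt_net[rid] > src_net[rid] else r_b).add(rid)
    all_ids = set(source.reaction_ids)
    return TransformationTarget(
        reaction_ids=list(source.reaction_ids),
        r_forward=r_f,
        r_backward=r_b,
        r_steady=all_ids - r_f - r_b,
        source_mean=source.mean_net(),
        target_mean=target.mean_net(),
        delta=delta,
    )


def _delta_array(targets: TransformationTarget, n: int) -> np.ndarray:
    return np.broadcast_to(np.asarray(targets.delta, float), (n,))


def _functional(
    m: np.ndarray, rids: list[str], targets: TransformationTarget, scales: np.ndarray
) -> float:
    delta = _delta_array(targets, len(rids))
    score = 0.0
    for j, rid in enumerate(rids):
        if rid in targets.r_forward:
            score += 1.0 if m[j] > delta[j] else 0.0
        elif rid in targets.r_backward:
            score += 1.0 if -m[j] > delta[j] else 0.0
        else:
            score -= min(abs(m[j]) / scales[j], 1.0)
    return float(score)


def _best_case_flux(
    model: MetabolicModel,
    v_source: np.ndarray,
    targets: TransformationTarget,
    scales: np.ndarray,
) -> np.ndarray | None:
    """LP surrogate: maximise capped linear movement credits on R_F/R_B
    minus (uncapped) relative movement on R_S; returns the arg-max flux."""
    rids = model.reaction_ids
    n = len(rids)
    S = model.stoichiometric_matrix()
    lb, ub = model.bounds_arrays()
    fwd = [j for j, r in enumerate(rids) if r in targets.r_forward]
    bwd = [j for j, r in enumerate(rids) if r in targets.r_backward]
    sty = [j for j, r in enumerate(rids) if r in targets.r_steady]
    nf, nb, ns = len(fwd), len(bwd), len(sty)
    # variables: v (n), y (nf <= 1), z (nb <= 1), u (ns >= 0); y/z are capped
    # movement credits (negative when a required movement is reversed, which
    # steers the surrogate away from counterproductive states)
    ntot = n + nf + nb + ns
    c = np.zeros(ntot)
    c[n:n + nf] = -1.0  # maximise
    c[n + nf:n + nf + nb] = -1.0
    c[n + nf + nb:] = 1.0
    delta = _delta_array(targets, n)
    rows = []
    rhs = []
    for k, j in enumerate(fwd):  # y_k <= (v_j - v_src_j - delta_j) / s_j
        row = np.zeros(ntot)
        row[n + k] = 1.0
        row[j] = -1.0 / scales[j]
        rows.append(row)
        rhs.append(-(v_source[j] + delta[j]) / scales[j])
    for k, j in enumerate(bwd):  # z_k <= (v_src_j - v_j - delta_j) / s_j
        row = np.zeros(ntot)
        row[n + nf + k] = 1.0
        row[j] = 1.0 / scales[j]
        rows.append(row)
        rhs.append((v_source[j] - delta[j]) / scales[j])
    for k, j in enumerate(sty):  # u_k >= |v_j - v_src_j| / s_j
        row = np.zeros(ntot)
        row[n + nf + nb + k] = -1.0
        row[j] = 1.0 / scales[j]
        rows.append(row)
        rhs.append(v_source[j] / scales[j])
        row2 = np.zeros(ntot)
        row2[n + nf + nb + k] = -1.0
        row2[j] = -1.0 / scales[j]
        rows.append(row2)
        rhs.append(-v_source[j] / scales[j])
    A_ub = np.vstack(rows) if rows else None
    b_ub = np.array(rhs) if rows else None
    A_eq = np.hstack([S, np.zeros((S.shape[0], ntot - n))])
    bounds = list(zip(lb, ub)) + [(None, 1)] * (nf + nb) + [(0, None)] * ns
    res = linprog(
        c, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=np.zeros(S.shape[0]),
        bounds=bounds, method="highs",
    )
    if res.status != 0:
        return None
    return res.x[:n]


def score_knockout(
    model: MetabolicModel,
    gene: str,
    source_flux: FluxState | np.ndarray,
    targets: TransformationTarget,
) -> TransformationScore:
    """Best-case, worst-case and robust transformation scores for one
    single-gene knockout."""
    if gene not in model.genes:
        raise KeyError(f"unknown gene {gene!r}")
    v_source = source_flux.v if isinstance(source_flux, FluxState) else np.asarray(source_flux, float)
    rids = model.reaction_ids
    if v_source.shape != (len(rids),):
        raise ValueError("source flux dimension does not match the model")
    if targets.reaction_ids != rids:
        raise ValueError("targets were derived for different reaction columns")
    scales = np.maximum(np.abs(v_source), 1.0)

    ko = apply_knockout(model, {gene})
    worst = moma(ko, v_source)
    if worst.status == "infeasible":
        return TransformationScore(gene, float("nan"), float("nan"), None, False)
    wts = _functional(worst.v - v_source, rids, targets, scales)
    v_best = _best_case_flux(ko, v_source, targets, scales)
    if v_best is None:
        return TransformationScore(gene, float("nan"), wts, None, False)
    bts = _functional(v_best - v_source, rids, targets, scales)
    if bts > 0 and wts > 0:
        rts = min(bts, wts)
    elif bts < 0 and wts < 0:
        rts = min(bts, wts)
    else:
        rts = 0.0
    return TransformationScore(gene, bts, wts, float(rts), True)


def rank_modifier_genes(
    model: MetabolicModel,
    source: FluxEnsemble,
    target: FluxEnsemble,
    direction: str = "",
    fc_threshold: float = 1.0,
    p_threshold: float = 0.05,
    delta: float | np.ndarray | None = None,
    gap_fraction: float = 0.1,
    genes: list[str] | None = None,
) -> pd.DataFrame:
    """Score every GPR-bearing gene knockout against the ensemble-mean
    source flux; rank by robust score (descending, ties lexicographic,
    infeasible knockouts last).

    A movement credit on R_F / R_B only fires when the knockout achieves at
    least ``gap_fraction`` of the source-to-target flux gap of that
    reaction (floored at 1e-6); pass ``delta`` explicitly to override.
    ``direction`` is a label recorded in the output (e.g. "healthy->disease").
    """
    gene_pool = sorted(genes if genes is not None else model.genes)
    if not gene_pool:
        raise ValueError("model has no GPR-bearing genes to score")
    # ensemble columns may be a sub- or re-ordering of model reactions
    col = {r: j for j, r in enumerate(source.reaction_ids)}
    try:
        v_source = np.array([source.mean_net()[col[r]] for r in model.reaction_ids])
        t_mean = np.array([target.mean_net()[col[r]] for r in model.reaction_ids])
    except KeyError as exc:
        raise ValueError(f"model reaction {exc} missing from ensembles") from None
    # the ensemble mean of bound-jittered instances is near-feasible but not
    # exactly so; project it onto the source model's flux polytope so that a
    # knockout touching nothing scores exactly zero
    projected = moma(model, v_source)
    if projected.status == "optimal":
        v_source = projected.v
    base_targets = derive_transformation_targets(
        source, target, fc_threshold, p_threshold
    )
    if delta is None:
        delta = np.maximum(1e-6, gap_fraction * np.abs(t_mean - v_source))
    targets = TransformationTarget(
        reaction_ids=list(model.reaction_ids),
        r_forward=base_targets.r_forward & set(model.reaction_ids),
        r_backward=base_targets.r_backward & set(model.reaction_ids),
        r_steady=set(model.reaction_ids) - base_targets.r_forward - base_targets.r_backward,
        source_mean=v_source,
        target_mean=t_mean,
        delta=delta,
    )
    scores = [score_knockout(model, g, v_source, targets) for g in gene_pool]
    scores.sort(
        key=lambda s: (
            not s.feasible,
            -(s.rts if s.rts is not None else -np.inf),
            s.gene,
        )
    )
    return pd.DataFrame(
        {
            "gene": [s.gene for s in scores],
            "bTS": [s.bts for s in scores],
            "wTS": [s.wts for s in scores],
            "rTS": [s.rts if s.rts is not None else np.nan for s in scores],
            "feasible": [s.feasible for s in scores],
            "direction": direction,
        }
    )
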