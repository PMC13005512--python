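"""Ensemble-level analytics over predicted flux distributions.

A :class:`FluxEnsemble` collects entropic-flux solutions of many model
instances of one condition (GD or control).  Analyses:

- differential flux: per-reaction log2 ratio of mean total activity
  (vf + vr) between conditions with a Mann-Whitney U test across ensemble
  members;
- subsystem enrichment of flagged reactions (hypergeometric +
  Benjamini-Hochberg);
- GD-specific correlation modules: reaction pairs strongly rank-correlated
  in GD but not in controls, clustered by average linkage on 1 - |rho_GD|;
- ATP-contribution decomposition across energy-demand levels;
- robustness sweeps over disease-scaling factors and lysosomal substrate
  (ganglioside) uptake levels.

Log ratios use total activity rather than signed net flux: entropic
solutions keep vf + vr strictly positive wherever a reaction is usable, so
the ratio is defined for reversible reactions too.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import hypergeom, mannwhitneyu, spearmanr
from statsmodels.stats.multitest import multipletests

from .model import MetabolicModel
from .optimize import FluxState, entropic_fba

ACTIVITY_EPS = 1e-9


# ---------------------------------------------------------------------------
# Simulation setup
# ---------------------------------------------------------------------------

@dataclass
class SimulationSetup:
    """Objective composition and maintenance constraints for macrophage
    simulations.

    The objective drives flux through viability (biomass_maintenance),
    cellular energy demand (ATPM), mitochondrial ATP synthase (ATPS4mi) and
    the initial ganglioside-synthesis reactions; maintenance lower bounds
    are experimentally derived minimal-viability estimates.
    """

    objective_reactions: dict[str, float] = field(
        default_factory=lambda: {
            "biomass_maintenance": 1.0,
            "ATPM": 1.0,
            "ATPS4mi": 1.0,
            "LACCERS": 1.0,
            "GM3S": 1.0,
        }
    )
    atpm_lb: float = 44.8  # umol/gDW/hr
    biomass_lb: float = 3.45  # umol/gDW/hr
    ganglioside_uptake_levels: tuple[float, ...] = (0.1, 1.0, 5.0, 10.0)
    ganglioside_exchange: str = "EX_gangliosides[l]"

    def __post_init__(self) -> None:
        if self.atpm_lb < 0 or self.biomass_lb < 0:
            raise ValueError("maintenance lower bounds must be non-negative")
        levels = tuple(self.ganglioside_uptake_levels)
        if any(b <= a for a, b in zip(levels, levels[1:])):
            raise ValueError("ganglioside uptake levels must be strictly increasing")

    def apply(
        self,
        model: MetabolicModel,
        ganglioside_uptake: float | None = None,
        atpm_lb: float | None = None,
    ) -> MetabolicModel:
        """Copy of ``model`` with objective and maintenance bounds applied."""
        out = model.copy()
        for rxn in out.reactions.values():
            rxn.objective_coefficient = self.objective_reactions.get(rxn.id, 0.0)
        missing = set(self.objective_reactions) - set(out.reactions)
        if missing:
            raise KeyError(f"objective reactions absent from model: {sorted(missing)}")
        out.reactions["ATPM"].lb = self.atpm_lb if atpm_lb is None else atpm_lb
        out.reactions["biomass_maintenance"].lb = self.biomass_lb
        if ganglioside_uptake is not None:
            if self.ganglioside_exchange not in out.reactions:
                raise KeyError(f"{self.ganglioside_exchange} absent from model")
            ex = out.reactions[self.ganglioside_exchange]
            ex.lb = -abs(ganglioside_uptake)
            ex.ub = -abs(ganglioside_uptake)
        return out


# ---------------------------------------------------------------------------
# Flux ensembles
# ---------------------------------------------------------------------------

@dataclass
class FluxEnsemble:
    """Net fluxes and total activities for an ensemble of model instances."""

    reaction_ids: list[str]
    net: np.ndarray  # models x reactions, net flux v
    activity: np.ndarray  # models x reactions, vf + vr
    condition: str = ""

    def __post_init__(self) -> None:
        self.net = np.atleast_2d(np.asarray(self.net, float))
        self.activity = np.atleast_2d(np.asarray(self.activity, float))
        if self.net.shape != self.activity.shape or self.net.shape[1] != len(self.reaction_ids):
            raise ValueError("ensemble matrices and reaction ids are inconsistent")

    @classmethod
    def from_states(cls, states: list[FluxState], condition: str = "") -> "FluxEnsemble":
        rids = states[0].reaction_ids
        for st in states:
            if st.reaction_ids != rids:
                raise ValueError("flux states have mismatched reaction columns")
        return cls(
            reaction_ids=list(rids),
            net=np.vstack([st.v for st in states]),
            activity=np.vstack([st.activity for st in states]),
            condition=condition,
        )

    @property
    def n_models(self) -> int:
        return self.net.shape[0]

    def mean_net(self) -> np.ndarray:
        return self.net.mean(axis=0)

    def column(self, reaction_id: str) -> int:
        return self.reaction_ids.index(reaction_id)


def simulate_condition_ensemble(
    model: MetabolicModel,
    setup: SimulationSetup,
    n_instances: int,
    seed: int,
    jitter_sd: float = 0.05,
    ganglioside_uptake: float | None = 1.0,
    condition: str = "",
) -> FluxEnsemble:
    """Entropic-flux ensemble over bound-jittered instances of one model.

    Instance-to-instance variability emulates the draft-model ensembles:
    every finite nonzero exchange bound is scaled by a log-normal factor
    (sd ``jitter_sd`` on the log scale), then entropic FBA is solved.
    """
    rng = np.random.default_rng(seed)
    prepared = setup.apply(model, ganglioside_uptake=ganglioside_uptake)
    states = []
    for _ in range(n_instances):
        inst = prepared.copy()
        for rxn in inst.reactions.values():
            if not rxn.is_exchange:
                continue
            factor = float(np.exp(rng.normal(0.0, jitter_sd)))
            if np.isfinite(rxn.lb) and rxn.lb not in (0.0,):
                rxn.lb *= factor
            if np.isfinite(rxn.ub) and rxn.ub not in (0.0,):
                rxn.ub *= factor
        st = entropic_fba(inst)
        if st.status != "optimal":
            raise RuntimeError(f"entropic solve failed for an instance: {st.status}")
        states.append(st)
    return FluxEnsemble.from_states(states, condition=condition)


# ---------------------------------------------------------------------------
# Differential flux
# ---------------------------------------------------------------------------

@dataclass
class DifferentialFluxResult:
    reaction_id: str
    log2_ratio: float  # mean GD activity over mean control activity
    p_value: float
    direction: str  # "up" | "down" | "none"
    flagged: bool


def differential_flux(
    gd: FluxEnsemble,
    ctrl: FluxEnsemble,
    fc_threshold: float = 1.0,
    p_threshold: float = 0.05,
) -> list[DifferentialFluxResult]:
    """Per-reaction activity ratio and Mann-Whitney U test GD vs control.

    Reactions with activity <= eps in every member of both ensembles are
    excluded from testing.  Requires >= 5 models per ensemble.
    """
    if gd.reaction_ids != ctrl.reaction_ids:
        raise ValueError("ensembles have mismatched reaction columns")
    if gd.n_models < 5 or ctrl.n_models < 5:
        raise ValueError("need at least 5 models per ensemble")
    a_gd = gd.activity + ACTIVITY_EPS
    a_ct = ctrl.activity + ACTIVITY_EPS
    results: list[DifferentialFluxResult] = []
    dead = np.all(gd.activity <= ACTIVITY_EPS, axis=0) & np.all(
        ctrl.activity <= ACTIVITY_EPS, axis=0
    )
    cols = [j for j in range(len(gd.reaction_ids)) if not dead[j]]
    if cols:
        x = a_gd[:, cols]
        y = a_ct[:, cols]
        with np.errstate(divide="ignore"):
            ratios = np.log2(x.mean(axis=0) / y.mean(axis=0))
        try:
            pvals = mannwhitneyu(x, y, alternative="two-sided", axis=0).pvalue
        except ValueError:
            pvals = np.array(
                [mannwhitneyu(x[:, k], y[:, k], alternative="two-sided").pvalue
                 for k in range(x.shape[1])]
            )
        pvals = np.where(np.isnan(pvals), 1.0, pvals)
        for k, j in enumerate(cols):
            flag = (abs(ratios[k]) > fc_threshold) and (pvals[k] < p_threshold)
            direction = "none"
            if flag:
                direction = "up" if ratios[k] > 0 else "down"
            results.append(
                DifferentialFluxResult(
                    reaction_id=gd.reaction_ids[j],
                    log2_ratio=float(ratios[k]),
                    p_value=float(pvals[k]),
                    direction=direction,
                    flagged=bool(flag),
                )
            )
    return results


def subsystem_enrichment(
    flagged: set[str], model: MetabolicModel
) -> list[dict]:
    """One-sided hypergeometric enrichment of flagged reactions per
    subsystem, BH-corrected across subsystems."""
    unknown = set(flagged) - set(model.reactions)
    if unknown:
        raise ValueError(f"flagged reactions not in model: {sorted(unknown)}")
    if not flagged:
        return []
    M = len(model.reactions)
    n_flagged = len(flagged)
    rows = []
    subsystems = sorted({r.subsystem for r in model.reactions.values() if r.subsystem})
    for sub in subsystems:
        members = {r.id for r in model.reactions.values() if r.subsystem == sub}
        k = len(members & set(flagged))
        p = float(hypergeom.sf(k - 1, M, len(members), n_flagged))
        rows.append({"subsystem": sub, "n_subsystem": len(members), "n_flagged": k, "p": p})
    if rows:
        qs = multipletests([r["p"] for r in rows], method="fdr_bh")[1]
        for row, q in zip(rows, qs):
            row["q"] = float(q)
    return rows


# ---------------------------------------------------------------------------
# GD-specific correlation modules
# ---------------------------------------------------------------------------

@dataclass
class CorrelationModule:
    reactions: list[str]
    rho_gd: np.ndarray
    rho_ctrl: np.ndarray
    genes: list[str]

    def __post_init__(self) -> None:
        if len(self.reactions) < 2:
            raise ValueError("a correlation module needs at least 2 reactions")


def _spearman_matrix(mat: np.ndarray) -> np.ndarray:
    rho = spearmanr(mat).statistic
    if np.ndim(rho) == 0:  # scipy collapses the 2-column case to a scalar
        rho = np.array([[1.0, float(rho)], [float(rho), 1.0]])
    rho = np.atleast_2d(rho)
    rho = np.where(np.isnan(rho), 0.0, rho)
    np.fill_diagonal(rho, 1.0)
    return rho


def gd_specific_correlations(
    gd: FluxEnsemble,
    ctrl: FluxEnsemble,
    candidate_reactions: set[str],
    model: MetabolicModel | None = None,
    strong: float = 0.7,
    weak: float = 0.3,
    cut_distance: float = 0.3,
) -> list[CorrelationModule]:
    """Modules of reactions whose pairwise coupling is strong in GD
    (|rho| >= strong) but weak in controls (|rho| <= weak).

    Reactions participating in at least one GD-specific pair are clustered
    by average linkage on 1 - |rho_GD| and the dendrogram is cut at
    ``cut_distance``; modules of size >= 2 are returned sorted by size.
    """
    if gd.reaction_ids != ctrl.reaction_ids:
        raise ValueError("ensembles have mismatched reaction columns")
    candidates = sorted(set(candidate_reactions))
    if len(candidates) < 2:
        raise ValueError("need at least 2 candidate reactions")
    missing = set(candidates) - set(gd.reaction_ids)
    if missing:
        raise ValueError(f"candidates absent from ensembles: {sorted(missing)}")
    cols = [gd.column(r) for r in candidates]
    rho_gd = _spearman_matrix(gd.net[:, cols])
    rho_ct = _spearman_matrix(ctrl.net[:, cols])
    specific = (np.abs(rho_gd) >= strong) & (np.abs(rho_ct) <= weak)
    np.fill_diagonal(specific, False)
    in_pair = np.nonzero(specific.any(axis=0))[0]
    if in_pair.size < 2:
        return []
    sub = [candidates[i] for i in in_pair]
    dist = 1.0 - np.abs(rho_gd[np.ix_(in_pair, in_pair)])
    np.fill_diagonal(dist, 0.0)
    dist = (dist + dist.T) / 2  # symmetrise against floating noise
    Z = linkage(squareform(dist, checks=False), method="average")
    labels = fcluster(Z, t=cut_distance, criterion="distance")
    modules: list[CorrelationModule] = []
    for lab in sorted(set(labels)):
        idx = [i for i, l in enumerate(labels) if l == lab]
        if len(idx) < 2:
            continue
        member_ids = [sub[i] for i in idx]
        genes: set[str] = set()
        if model is not None:
            for rid in member_ids:
                if rid in model.reactions:
                    genes |= model.reactions[rid].genes
        gsel = np.ix_(in_pair[idx], in_pair[idx])
        modules.append(
            CorrelationModule(
                reactions=member_ids,
                rho_gd=rho_gd[gsel],
                rho_ctrl=rho_ct[gsel],
                genes=sorted(genes),
            )
        )
    modules.sort(key=lambda m: (-len(m.reactions), m.reactions[0]))
    return modules


def export_module_gene_lists(modules: list[CorrelationModule], directory) -> list[str]:
    """One gene per line per module (plain text, external-tool friendly)."""
    from pathlib import Path

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, mod in enumerate(modules):
        path = directory / f"module_{i + 1}_genes.txt"
        path.write_text("\n".join(mod.genes) + ("\n" if mod.genes else ""))
        paths.append(str(path))
    return paths


# ---------------------------------------------------------------------------
# ATP contribution
# ---------------------------------------------------------------------------

@dataclass
class ATPBreakdown:
    atpm_level: float
    glycolysis: float
    tca: float  # substrate-level phosphorylation in the citric acid cycle
    oxphos: float
    feasible: bool = True

    def fractions(self) -> tuple[float, float, float]:
        return self.glycolysis, self.tca, self.oxphos


def atp_contribution_sweep(
    model: MetabolicModel,
    setup: SimulationSetup,
    atpm_levels: list[float],
    pathway_tags: dict[str, str],
    ganglioside_uptake: float | None = 1.0,
) -> list[ATPBreakdown]:
    """Fractional ATP production by pathway across energy-demand levels.

    At each level the ATPM flux is pinned to the demand (lb = ub = level) so
    the sweep genuinely varies total demand, and entropic FBA distributes
    production.  ATP production of a tagged reaction is its positive flux
    times its ATP stoichiometry; fractions are normalised to total tagged
    production.  Demand levels with no feasible state are reported as such
    and the sweep continues.
    """
    tagged = {rid: tag for rid, tag in pathway_tags.items() if rid in model.reactions}
    if not tagged:
        raise ValueError("no tagged ATP-producing reaction present in the model")
    atp_coef: dict[str, float] = {}
    for rid in tagged:
        coefs = model.reactions[rid].stoichiometry
        coef = sum(v for k, v in coefs.items() if k in ("atp[c]", "atp[m]") and v > 0)
        atp_coef[rid] = coef
    out: list[ATPBreakdown] = []
    for level in atpm_levels:
        prepared = setup.apply(model, ganglioside_uptake=ganglioside_uptake, atpm_lb=level)
        prepared.reactions["ATPM"].ub = level
        st = entropic_fba(prepared)
        if st.status != "optimal":
            out.append(ATPBreakdown(level, np.nan, np.nan, np.nan, feasible=False))
            continue
        flux = st.as_dict()
        produced = {"glycolysis": 0.0, "tca": 0.0, "oxphos": 0.0}
        for rid, tag in tagged.items():
            produced[tag] = produced.get(tag, 0.0) + max(flux[rid], 0.0) * atp_coef[rid]
        total = sum(produced.values())
        if total <= 0:
            out.append(ATPBreakdown(level, np.nan, np.nan, np.nan, feasible=False))
            continue
        out.append(
            ATPBreakdown(
                level,
                glycolysis=produced["glycolysis"] / total,
                tca=produced["tca"] / total,
                oxphos=produced["oxphos"] / total,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Robustness sweep
# ---------------------------------------------------------------------------

def robustness_sweep(
    reference: MetabolicModel,
    de,
    scheme_grid,
    uptake_levels: list[float],
    setup: SimulationSetup,
    gba1_gene: str = "GBA1",
    n_instances: int = 5,
    seed: int = 0,
    jitter_sd: float = 0.05,
    fc_threshold: float = 1.0,
    p_threshold: float = 0.05,
) -> dict:
    """Re-run disease construction + differential flux over a grid of
    scaling schemes and ganglioside uptake levels; report per-reaction
    direction agreement with the default configuration.

    ``scheme_grid`` is a list of ScalingScheme; the first entry is the
    default configuration against which agreement is measured.
    """
    from .disease import build_disease_model  # local import to avoid a cycle

    if not scheme_grid or not uptake_levels:
        raise ValueError("robustness sweep grid is empty")
    runs = []
    rng = np.random.default_rng(seed)
    for scheme in scheme_grid:
        for level in uptake_levels:
            sub_seed = int(rng.integers(0, 2**31 - 1))
            ref_setup = setup.apply(reference, ganglioside_uptake=level)
            gd_model = build_disease_model(reference, de, scheme, gba1_gene=gba1_gene,
                                           setup=setup, ganglioside_uptake=level)
            ctrl_ens = simulate_condition_ensemble(
                reference, setup, n_instances, seed=sub_seed,
                jitter_sd=jitter_sd, ganglioside_uptake=level, condition="control",
            )
            gd_ens = simulate_condition_ensemble(
                gd_model, setup, n_instances, seed=sub_seed + 1,
                jitter_sd=jitter_sd, ganglioside_uptake=level, condition="GD",
            )
            diff = differential_flux(gd_ens, ctrl_ens, fc_threshold, p_threshold)
            runs.append({
                "scheme": scheme,
                "uptake": level,
                "log2_ratio": {d.reaction_id: d.log2_ratio for d in diff},
            })
    base = runs[0]["log2_ratio"]
    agreement: dict[str, float] = {}
    for rid, base_ratio in base.items():
        signs = [np.sign(run["log2_ratio"].get(rid, 0.0)) for run in runs]
        agreement[rid] = float(np.mean([s == np.sign(base_ratio) for s in signs]))
    return {"n_runs": len(runs), "runs": runs, "direction_agreement": agreement}
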