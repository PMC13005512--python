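"""Gaucher-disease model construction from differential expression.

Disease (GD) model instances are derived from validated healthy reference
models by a qualitative bound-scaling scheme that preserves the direction
of transcriptional regulation without assuming flux is proportional to
transcript abundance:

- the upper bound of GBA1-catalysed reactions drops to 10% of reference
  (severe glucocerebrosidase deficiency);
- upper bounds of reactions mapped from down-regulated genes drop to 50%
  (lower bounds too, when strictly positive);
- lower bounds of reactions mapped from up-regulated genes rise to 150%
  of their reference value when strictly positive; for a non-positive
  lower bound the reference entropic flux stands in when it is positive
  (expanding the minimal feasible flux), otherwise the bound is left
  unchanged and the case is logged;
- reactions mapped by both an up- and a down-regulated gene are left
  unchanged and the conflict is logged.

If the scaled model is infeasible under its maintenance constraints, the
up-scaled lower bounds are proportionally relaxed back toward their
reference values by bisection (at most 50 steps) until feasibility is
restored.

Paired GD/control instances are then filtered by t-SNE embedding of their
entropic flux profiles: retained pairs are those whose members fall in
their condition's majority cluster of a 2-means partition.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linprog
from scipy.stats import ttest_ind
from sklearn.cluster import KMeans
from sklearn.manifold import TSNE
from sklearn.metrics import silhouette_score

from .ensemble import SimulationSetup
from .model import MetabolicModel, map_genes_to_reactions
from .optimize import FluxState, entropic_fba

logger = logging.getLogger(__name__)


@dataclass
class DifferentialExpression:
    gene: str
    log2_fold_change: float  # GD over control
    p_value: float

    def __post_init__(self) -> None:
        if not (0.0 < self.p_value <= 1.0):
            raise ValueError(f"p_value for {self.gene!r} must be in (0, 1]")

    @property
    def direction(self) -> str:
        return "up" if self.log2_fold_change > 0 else "down"


@dataclass
class ScalingScheme:
    """Bound-scaling factors for disease-model construction."""

    gba1_factor: float = 0.10
    down_factor: float = 0.50
    up_factor: float = 1.50
    down_range: tuple[float, float] = (0.30, 0.70)  # robustness range
    up_range: tuple[float, float] = (1.30, 1.70)

    def __post_init__(self) -> None:
        if not (0.0 < self.gba1_factor <= 1.0):
            raise ValueError("gba1_factor must be in (0, 1]")
        if not (0.0 < self.down_factor <= 1.0):
            raise ValueError("down_factor must be in (0, 1]")
        if self.up_factor < 1.0:
            raise ValueError("up_factor must be >= 1")


def read_differential_expression(path) -> list[DifferentialExpression]:
    """DE table TSV: gene, log2fc, p."""
    df = pd.read_csv(path, sep="\t")
    return [
        DifferentialExpression(row["gene"], float(row["log2fc"]), float(row["p"]))
        for _, row in df.iterrows()
    ]


# ---------------------------------------------------------------------------
# Differential expression calling
# ---------------------------------------------------------------------------

def call_differential_genes(
    case: pd.DataFrame,
    control: pd.DataFrame,
    fc_threshold: float = 1.0,
    p_threshold: float = 0.05,
) -> list[DifferentialExpression]:
    """Welch two-sample t-test on log2 expression, gene by gene.

    ``case`` and ``control`` are gene x replicate tables of FPKM-like
    values with identical gene indices and >= 2 replicates each.  Genes
    with |log2 fold change| > ``fc_threshold`` and p < ``p_threshold`` are
    returned.
    """
    if not case.index.equals(control.index):
        raise ValueError("case and control gene sets do not match")
    if case.shape[1] < 2 or control.shape[1] < 2:
        raise ValueError("need at least 2 replicates per condition")
    floor = 1e-9
    log_case = np.log2(np.maximum(case.to_numpy(float), floor))
    log_ctrl = np.log2(np.maximum(control.to_numpy(float), floor))
    log2fc = log_case.mean(axis=1) - log_ctrl.mean(axis=1)
    res = ttest_ind(log_case, log_ctrl, axis=1, equal_var=False)
    pvals = np.where(np.isnan(res.pvalue), 1.0, res.pvalue)
    out = []
    for gene, fc, p in zip(case.index, log2fc, pvals):
        if abs(fc) > fc_threshold and p < p_threshold:
            out.append(DifferentialExpression(str(gene), float(fc), float(max(p, np.nextafter(0, 1)))))
    return out


# ---------------------------------------------------------------------------
# Disease model construction
# ---------------------------------------------------------------------------

def _feasible(model: MetabolicModel) -> bool:
    S = model.stoichiometric_matrix()
    lb, ub = model.bounds_arrays()
    res = linprog(
        np.zeros(S.shape[1]), A_eq=S, b_eq=np.zeros(S.shape[0]),
        bounds=list(zip(lb, ub)), method="highs",
    )
    return res.status == 0


def build_disease_model(
    reference: MetabolicModel,
    de: list[DifferentialExpression],
    scheme: ScalingScheme | None = None,
    gba1_gene: str = "GBA1",
    reference_flux: FluxState | None = None,
    setup: SimulationSetup | None = None,
    ganglioside_uptake: float | None = None,
    flux_eps: float = 1e-6,
    max_bisection: int = 50,
) -> MetabolicModel:
    """Scale reference bounds by differential-expression direction.

    The reference must be feasible under its maintenance constraints (if a
    ``setup`` is given it is applied first).  ``reference_flux`` supplies
    the control-state entropic fluxes used for up-regulated reactions with
    non-positive lower bounds; it is computed on demand when omitted.
    """
    scheme = scheme or ScalingScheme()
    base = setup.apply(reference, ganglioside_uptake=ganglioside_uptake) if setup else reference.copy()
    if gba1_gene not in base.genes:
        raise KeyError(f"{gba1_gene!r} not present in the reference model")
    if not _feasible(base):
        raise ValueError("reference model is infeasible under its constraints")

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        gba1_rxns = map_genes_to_reactions(base, {gba1_gene})
        up_genes = {d.gene for d in de if d.direction == "up"} - {gba1_gene}
        down_genes = {d.gene for d in de if d.direction == "down"} - {gba1_gene}
        up_rxns = map_genes_to_reactions(base, up_genes) if up_genes else set()
        down_rxns = map_genes_to_reactions(base, down_genes) if down_genes else set()

    conflicts = (up_rxns & down_rxns) - gba1_rxns
    if conflicts:
        logger.warning(
            "reactions mapped by both up- and down-regulated genes left "
            "unchanged: %s", sorted(conflicts)
        )
    up_rxns -= conflicts | gba1_rxns
    down_rxns -= conflicts | gba1_rxns

    needs_ref_flux = any(base.reactions[r].lb <= 0 for r in up_rxns)
    ref_flux_map: dict[str, float] = {}
    if needs_ref_flux:
        if reference_flux is None:
            reference_flux = entropic_fba(base)
            if reference_flux.status != "optimal":
                raise ValueError("could not compute reference entropic fluxes")
        ref_flux_map = reference_flux.as_dict()

    out = base.copy(id=f"{reference.id}_GD")
    original_lb = {}
    for rid in gba1_rxns:
        out.reactions[rid].ub *= scheme.gba1_factor
        out.reactions[rid].lb = min(out.reactions[rid].lb, out.reactions[rid].ub)
    for rid in down_rxns:
        rxn = out.reactions[rid]
        rxn.ub *= scheme.down_factor
        if rxn.lb > 0:
            rxn.lb *= scheme.down_factor
        rxn.lb = min(rxn.lb, rxn.ub)
    for rid in sorted(up_rxns) if scheme.up_factor > 1.0 else []:
        rxn = out.reactions[rid]
        if rxn.lb > 0:
            target = scheme.up_factor * rxn.lb
        else:
            ref_v = ref_flux_map.get(rid, 0.0)
            if ref_v > flux_eps:
                target = scheme.up_factor * ref_v
            else:
                logger.info(
                    "up-regulated reaction %s has non-positive lb and no "
                    "positive reference flux; bound left unchanged", rid
                )
                continue
        original_lb[rid] = rxn.lb
        rxn.lb = min(target, rxn.ub)

    if not _feasible(out) and original_lb:
        # proportionally relax up-scaled lower bounds back toward reference
        def set_theta(theta: float) -> None:
            for rid, lb0 in original_lb.items():
                rxn = out.reactions[rid]
                target = lb0 + theta * (min_targets[rid] - lb0)
                rxn.lb = min(target, rxn.ub)

        min_targets = {rid: out.reactions[rid].lb for rid in original_lb}
        lo_theta, hi_theta = 0.0, 1.0
        set_theta(0.0)
        if not _feasible(out):
            raise ValueError(
                "disease model infeasible even with up-scaling fully relaxed"
            )
        for _ in range(max_bisection):
            mid = (lo_theta + hi_theta) / 2
            set_theta(mid)
            if _feasible(out):
                lo_theta = mid
            else:
                hi_theta = mid
        set_theta(lo_theta)
        logger.warning(
            "up-scaled lower bounds relaxed to %.1f%% of their increment to "
            "preserve feasibility", 100 * lo_theta,
        )
    return out


# ---------------------------------------------------------------------------
# Pairing and flux-space filtering
# ---------------------------------------------------------------------------

@dataclass
class PairFilterResult:
    retained_pairs: list[int]
    labels_control: np.ndarray
    labels_gd: np.ndarray
    silhouette: float
    separated: bool
    warning: str | None = None


def pair_and_filter(
    controls: list[MetabolicModel],
    gd: list[MetabolicModel],
    setup: SimulationSetup,
    seed: int,
    ganglioside_uptake: float = 1.0,
    silhouette_threshold: float = 0.25,
    flux_matrix: tuple[np.ndarray, np.ndarray] | None = None,
) -> PairFilterResult:
    """Filter paired GD/control instances by flux-space clustering.

    Entropic fluxes of all instances are embedded in 2-D by t-SNE (seeded,
    perplexity min(30, n/3)) and partitioned by 2-means.  A pair is
    retained when each member lands in its condition's majority cluster.
    Without clear separation (silhouette below threshold or coinciding
    majority clusters), all pairs are kept with a warning.

    ``flux_matrix`` (control matrix, gd matrix) bypasses the entropic
    solves when fluxes are already available.
    """
    if len(controls) != len(gd):
        raise ValueError("controls and GD instances must be paired one-to-one")
    n_pairs = len(controls)
    if n_pairs < 5:
        raise ValueError("need at least 5 pairs for flux-space filtering")
    if flux_matrix is not None:
        X_ctrl, X_gd = flux_matrix
    else:
        def solve_all(models: list[MetabolicModel]) -> np.ndarray:
            rows = []
            for m in models:
                st = entropic_fba(setup.apply(m, ganglioside_uptake=ganglioside_uptake))
                if st.status != "optimal":
                    raise RuntimeError(f"entropic solve failed for {m.id}: {st.status}")
                rows.append(st.v)
            return np.vstack(rows)

        X_ctrl = solve_all(controls)
        X_gd = solve_all(gd)
    X = np.vstack([X_ctrl, X_gd])
    n = X.shape[0]
    perplexity = min(30.0, n / 3.0)
    emb = TSNE(
        n_components=2, perplexity=perplexity, random_state=seed, init="pca",
    ).fit_transform(X)
    km = KMeans(n_clusters=2, random_state=seed, n_init=10).fit(emb)
    labels = km.labels_
    lab_ctrl, lab_gd = labels[:n_pairs], labels[n_pairs:]
    sil = float(silhouette_score(emb, labels)) if len(set(labels)) > 1 else -1.0
    maj_ctrl = int(np.round(lab_ctrl.mean()))
    maj_gd = int(np.round(lab_gd.mean()))
    separated = sil > silhouette_threshold and maj_ctrl != maj_gd
    if not separated:
        msg = (
            "flux distributions do not separate by condition "
            f"(silhouette={sil:.3f}); all pairs retained"
        )
        warnings.warn(msg, stacklevel=2)
        return PairFilterResult(
            retained_pairs=list(range(n_pairs)),
            labels_control=lab_ctrl, labels_gd=lab_gd,
            silhouette=sil, separated=False, warning=msg,
        )
    retained = [
        i for i in range(n_pairs)
        if lab_ctrl[i] == maj_ctrl and lab_gd[i] == maj_gd
    ]
    return PairFilterResult(
        retained_pairs=retained,
        labels_control=lab_ctrl, labels_gd=lab_gd,
        silhouette=sil, separated=True,
    )
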