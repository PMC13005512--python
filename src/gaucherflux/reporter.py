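"""Reporter-metabolite scoring.

Differential-expression significance is aggregated from genes onto adjacent
metabolites through the enzyme-metabolite bipartite graph: a metabolite's
neighbours are the GPR genes of every reaction producing or consuming it
(ubiquitous currency metabolites are excluded so that ATP/NAD hubs do not
swamp the statistic).  Per gene, z = Phi^{-1}(1 - p); per metabolite with k
scored neighbours, raw z_m = sum(z) / sqrt(k).  Raw scores are corrected
against the null of random gene sets of the same size drawn from the
scored-gene universe: corrected z_m = (raw z_m - mu_k) / sigma_k with mu_k,
sigma_k estimated from n_null random sets (one shared null per k, seeded),
and an upper-tail empirical p-value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .disease import DifferentialExpression
from .model import MetabolicModel

#: metabolite base names treated as currency (matched in any compartment)
DEFAULT_CURRENCY = frozenset(
    {"atp", "adp", "amp", "h2o", "pi", "ppi", "h", "nad", "nadh",
     "nadp", "nadph", "co2", "o2", "coa", "q10", "q10h2"}
)

P_FLOOR = 1e-15
P_CEILING = 1.0 - 1e-15


@dataclass
class ReporterScore:
    metabolite_id: str
    k: int
    raw_z: float
    corrected_z: float
    p_value: float
    mean_log2fc: float


def gene_zscores(
    de: list[DifferentialExpression],
    p_floor: float = P_FLOOR,
    p_ceiling: float = P_CEILING,
) -> dict[str, float]:
    """Inverse-normal gene scores z = Phi^{-1}(1 - p), p clipped into
    [p_floor, p_ceiling]."""
    out: dict[str, float] = {}
    for d in de:
        if d.p_value <= 0:
            raise ValueError(f"non-positive p-value for gene {d.gene!r}")
        p = min(max(d.p_value, p_floor), p_ceiling)
        out[d.gene] = float(norm.isf(p))
    return out


def metabolite_neighbourhoods(
    model: MetabolicModel,
    exclude_currency: frozenset[str] | set[str] = DEFAULT_CURRENCY,
) -> dict[str, set[str]]:
    """Metabolite -> set of GPR genes of reactions touching it."""
    hoods: dict[str, set[str]] = {}
    for rxn in model.reactions.values():
        genes = rxn.genes
        if not genes:
            continue
        for met_id in rxn.stoichiometry:
            base = met_id.rsplit("[", 1)[0].lower()
            if base in exclude_currency:
                continue
            hoods.setdefault(met_id, set()).update(genes)
    return hoods


def reporter_scores(
    model: MetabolicModel,
    gene_z: dict[str, float],
    n_null: int = 10_000,
    seed: int = 0,
    gene_log2fc: dict[str, float] | None = None,
    exclude_currency: frozenset[str] | set[str] = DEFAULT_CURRENCY,
) -> list[ReporterScore]:
    """Background-corrected reporter scores, sorted by corrected z.

    Only genes present in ``gene_z`` (the scored universe) contribute; a
    metabolite without scored neighbours is skipped, so adding unscored
    genes to the model cannot change any score.
    """
    hoods = metabolite_neighbourhoods(model, exclude_currency)
    universe = sorted(set(gene_z))
    z_universe = np.array([gene_z[g] for g in universe])
    gene_index = {g: i for i, g in enumerate(universe)}
    scored: list[tuple[str, list[int]]] = []
    for met_id in sorted(hoods):
        idx = [gene_index[g] for g in hoods[met_id] if g in gene_index]
        if idx:
            scored.append((met_id, idx))
    if not scored:
        raise ValueError("no metabolite has a scored neighbouring gene")
    k_values = sorted({len(idx) for _, idx in scored})
    too_big = [k for k in k_values if k > len(universe)]
    if too_big:
        raise ValueError(
            f"neighbourhood size {too_big[0]} exceeds the scored-gene "
            f"universe ({len(universe)} genes)"
        )
    rng = np.random.default_rng(seed)
    null_stats: dict[int, tuple[float, float, np.ndarray]] = {}
    G = len(universe)
    for k in k_values:
        # n_null random size-k gene sets without replacement (shared per k)
        if k * k < G:  # rejection sampling: duplicate rows are rare
            picks = rng.integers(0, G, size=(n_null, k))
            bad = np.nonzero(
                (np.sort(picks, axis=1)[:, 1:] == np.sort(picks, axis=1)[:, :-1]).any(axis=1)
            )[0]
            while bad.size:
                picks[bad] = rng.integers(0, G, size=(bad.size, k))
                srt = np.sort(picks[bad], axis=1)
                bad = bad[(srt[:, 1:] == srt[:, :-1]).any(axis=1)]
        else:  # random-key selection, chunked to bound memory
            chunks = []
            step = max(1, min(n_null, 50_000_000 // max(G, 1)))
            for start in range(0, n_null, step):
                rows = min(step, n_null - start)
                keys = rng.random((rows, G))
                chunks.append(np.argpartition(keys, k - 1, axis=1)[:, :k])
            picks = np.vstack(chunks)
        raw = z_universe[picks].sum(axis=1) / np.sqrt(k)
        null_stats[k] = (float(raw.mean()), float(raw.std(ddof=0)), np.sort(raw))
    out: list[ReporterScore] = []
    for met_id, idx in scored:
        k = len(idx)
        raw = float(z_universe[idx].sum() / np.sqrt(k))
        mu, sigma, null_sorted = null_stats[k]
        sigma = max(sigma, 1e-12)
        corrected = (raw - mu) / sigma
        n_ge = len(null_sorted) - np.searchsorted(null_sorted, raw, side="left")
        p = float((1 + n_ge) / (1 + len(null_sorted)))
        fc = float("nan")
        if gene_log2fc is not None:
            fcs = [gene_log2fc[universe[i]] for i in idx if universe[i] in gene_log2fc]
            fc = float(np.mean(fcs)) if fcs else float("nan")
        out.append(ReporterScore(met_id, k, raw, float(corrected), p, fc))
    out.sort(key=lambda s: (-s.corrected_z, s.metabolite_id))
    return out


def reporter_table(
    scores: list[ReporterScore], model: MetabolicModel | None = None
) -> pd.DataFrame:
    """Tabular export: metabolite, k, raw_z, corrected_z, p, mean_log2fc,
    subsystem (majority subsystem of adjacent reactions when a model is
    given)."""
    rows = []
    for s in scores:
        subsystem = ""
        if model is not None:
            counts: dict[str, int] = {}
            for rxn in model.reactions.values():
                if s.metabolite_id in rxn.stoichiometry and rxn.subsystem:
                    counts[rxn.subsystem] = counts.get(rxn.subsystem, 0) + 1
            if counts:
                subsystem = max(sorted(counts), key=lambda k: counts[k])
        rows.append(
            {
                "metabolite": s.metabolite_id,
                "k": s.k,
                "raw_z": s.raw_z,
                "corrected_z": s.corrected_z,
                "p": s.p_value,
                "mean_log2fc": s.mean_log2fc,
                "subsystem": subsystem,
            }
        )
    return pd.DataFrame(rows)
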