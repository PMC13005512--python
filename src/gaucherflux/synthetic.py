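"""Synthetic inputs: toy macrophage network, expression tables, exometabolome.

The toy network is a compartmentalised (c/m/l/e), mass-consistent
macrophage-like metabolism of ~95 reactions: glycolysis with ATP from
phosphoglycerate kinase and pyruvate kinase, a citric-acid cycle with
substrate-level phosphorylation by succinyl-CoA ligase (SUCLG1/SUCLG2),
lumped respiratory complexes pumping protons for the mitochondrial ATP
synthase (ATPS4mi) with adenine-nucleotide transport into the cytosol, a
sphingolipid branch (serine palmitoyltransferase -> ceramide ->
glucosylceramide, degraded by the GBA1 glucosylceramidase in the lysosome),
a ganglioside uptake/degradation chain plus the synthesis route back to
complex gangliosides, cholesterol synthesis and export, fatty-acid
beta-oxidation behind CPT1A, and the maintenance pseudo-reactions ATPM and
biomass_maintenance.  Reaction, gene and pathway identities follow common
human nomenclature so the simulation setup applies without remapping.

Expression tables are log-normal FPKM-like values with planted fold
changes and multiplicative replicate noise; exometabolome tables are
model-predicted exchange rates with multiplicative Gaussian noise.  All
randomness flows from explicit seeds recorded in the manifests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ensemble import FluxEnsemble
from .model import MetabolicModel, Reaction
from .optimize import FluxState
from .validation import ExchangeMeasurement

INF = 1000.0


@dataclass
class ToyNetworkSpec:
    """Module toggles and seed for the toy macrophage network."""

    glycolysis: bool = True
    tca: bool = True
    oxphos: bool = True
    sphingolipid: bool = True
    gangliosides: bool = True
    cholesterol: bool = True
    fatty_acid_oxidation: bool = True
    exchanges: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.glycolysis and self.exchanges):
            raise ValueError("glycolysis and exchanges must be enabled")


# (id, stoichiometry, lb, ub, subsystem, gpr, module)
_REACTIONS: list[tuple] = [
    # --- exchanges (export positive; uptake negative) -------------------
    ("EX_glc[e]", {"glc[e]": -1}, -15, 0, "Exchange", "", "exchanges"),
    ("EX_o2[e]", {"o2[e]": -1}, -80, 0, "Exchange", "", "exchanges"),
    ("EX_co2[e]", {"co2[e]": -1}, 0, INF, "Exchange", "", "exchanges"),
    ("EX_lac[e]", {"lac[e]": -1}, 0, INF, "Exchange", "", "exchanges"),
    ("EX_h2o[e]", {"h2o[e]": -1}, -INF, INF, "Exchange", "", "exchanges"),
    ("EX_pi[e]", {"pi[e]": -1}, -50, 50, "Exchange", "", "exchanges"),
    ("EX_h[e]", {"h[e]": -1}, -INF, INF, "Exchange", "", "exchanges"),
    ("EX_ser[e]", {"ser[e]": -1}, -6, 0, "Exchange", "", "exchanges"),
    ("EX_palm[e]", {"palm[e]": -1}, -6, 0, "Exchange", "", "exchanges"),
    ("EX_chol[e]", {"chol[e]": -1}, 0, 50, "Exchange", "", "cholesterol"),
    ("EX_gal[e]", {"gal[e]": -1}, -3, 30, "Exchange", "", "gangliosides"),
    ("EX_sial[e]", {"sial[e]": -1}, -3, 30, "Exchange", "", "gangliosides"),
    ("EX_hexnac[e]", {"hexnac[e]": -1}, -3, 30, "Exchange", "", "gangliosides"),
    ("EX_sph[e]", {"sph[e]": -1}, 0, INF, "Exchange", "", "sphingolipid"),
    ("EX_fa[e]", {"fa[e]": -1}, 0, INF, "Exchange", "", "sphingolipid"),
    ("EX_gangliosides[l]", {"ganglioside[l]": -1}, -10, 0, "Exchange", "", "gangliosides"),
    ("DM_biomass", {"biomass[c]": -1}, 0, INF, "Exchange", "", "exchanges"),
    # --- transport ------------------------------------------------------
    ("GLCt", {"glc[e]": -1, "glc[c]": 1}, 0, INF, "Transport", "SLC2A1", "exchanges"),
    ("O2t", {"o2[e]": -1, "o2[c]": 1}, -INF, INF, "Transport", "", "exchanges"),
    ("O2tm", {"o2[c]": -1, "o2[m]": 1}, -INF, INF, "Transport", "", "oxphos"),
    ("CO2tm", {"co2[m]": -1, "co2[c]": 1}, -INF, INF, "Transport", "", "tca"),
    ("CO2t", {"co2[c]": -1, "co2[e]": 1}, -INF, INF, "Transport", "", "exchanges"),
    ("LACt", {"lac[c]": -1, "lac[e]": 1}, 0, INF, "Transport", "SLC16A1", "exchanges"),
    ("H2Ot", {"h2o[e]": -1, "h2o[c]": 1}, -INF, INF, "Transport", "", "exchanges"),
    ("H2Otm", {"h2o[c]": -1, "h2o[m]": 1}, -INF, INF, "Transport", "", "tca"),
    ("H2Otl", {"h2o[c]": -1, "h2o[l]": 1}, -INF, INF, "Transport", "", "sphingolipid"),
    ("PIt", {"pi[e]": -1, "pi[c]": 1}, -INF, INF, "Transport", "SLC20A1", "exchanges"),
    ("PItm", {"pi[c]": -1, "pi[m]": 1}, -INF, INF, "Transport", "SLC25A3", "oxphos"),
    ("Ht", {"h[c]": -1, "h[e]": 1}, -INF, INF, "Transport", "", "exchanges"),
    ("Htm", {"h[c]": -1, "h[m]": 1}, -INF, INF, "Transport", "", "oxphos"),
    ("SERt", {"ser[e]": -1, "ser[c]": 1}, 0, INF, "Transport", "SLC1A4", "exchanges"),
    ("PALMt", {"palm[e]": -1, "palm[c]": 1}, 0, INF, "Transport", "CD36", "exchanges"),
    ("CHOLt", {"chol[c]": -1, "chol[e]": 1}, 0, INF, "Transport", "ABCA1", "cholesterol"),
    ("PYRtm", {"pyr[c]": -1, "pyr[m]": 1}, 0, INF, "Transport", "MPC1", "tca"),
    ("ATPtm", {"atp[m]": -1, "adp[c]": -1, "atp[c]": 1, "adp[m]": 1}, 0, 70,
     "Oxidative phosphorylation", "SLC25A4", "oxphos"),
    ("CITtm", {"cit[m]": -1, "cit[c]": 1}, 0, INF, "Transport", "SLC25A1", "cholesterol"),
    ("MALtm", {"mal[c]": -1, "mal[m]": 1}, 0, INF, "Transport", "SLC25A11", "cholesterol"),
    ("GLCtl", {"glc[l]": -1, "glc[c]": 1}, 0, INF, "Transport", "", "sphingolipid"),
    ("GALtl", {"gal[l]": -1, "gal[c]": 1}, 0, INF, "Transport", "", "gangliosides"),
    ("SIALtl", {"sial[l]": -1, "sial[c]": 1}, 0, INF, "Transport", "", "gangliosides"),
    ("HEXNACtl", {"hexnac[l]": -1, "hexnac[c]": 1}, 0, INF, "Transport", "", "gangliosides"),
    ("FAtl", {"fa[l]": -1, "fa[c]": 1}, 0, INF, "Transport", "", "sphingolipid"),
    ("FAt", {"fa[c]": -1, "fa[e]": 1}, 0, INF, "Transport", "", "sphingolipid"),
    ("SPHtl", {"sph[l]": -1, "sph[c]": 1}, 0, INF, "Transport", "", "sphingolipid"),
    ("SPHt", {"sph[c]": -1, "sph[e]": 1}, 0, INF, "Transport", "", "sphingolipid"),
    ("GLCCERtl", {"glccer[c]": -1, "glccer[l]": 1}, 0, INF, "Transport", "", "sphingolipid"),
    ("GGtl", {"ganglioside[c]": -1, "ganglioside[l]": 1}, 0, INF, "Transport", "", "gangliosides"),
    ("GALt", {"gal[e]": -1, "gal[c]": 1}, -INF, INF, "Transport", "SLC5A1", "gangliosides"),
    ("SIALt", {"sial[e]": -1, "sial[c]": 1}, -INF, INF, "Transport", "", "gangliosides"),
    ("HEXNACt", {"hexnac[e]": -1, "hexnac[c]": 1}, -INF, INF, "Transport", "", "gangliosides"),
    # --- glycolysis -----------------------------------------------------
    ("HEX1", {"glc[c]": -1, "atp[c]": -1, "g6p[c]": 1, "adp[c]": 1, "h[c]": 1},
     0, INF, "Glycolysis", "HK1", "glycolysis"),
    ("PGI", {"g6p[c]": -1, "f6p[c]": 1}, -INF, INF, "Glycolysis", "GPI", "glycolysis"),
    ("PFK", {"f6p[c]": -1, "atp[c]": -1, "fdp[c]": 1, "adp[c]": 1, "h[c]": 1},
     0, INF, "Glycolysis", "PFKL", "glycolysis"),
    ("FBA", {"fdp[c]": -1, "g3p[c]": 2}, -INF, INF, "Glycolysis", "ALDOA", "glycolysis"),
    ("GAPD", {"g3p[c]": -1, "nad[c]": -1, "pi[c]": -1, "13bpg[c]": 1, "nadh[c]": 1, "h[c]": 1},
     -INF, INF, "Glycolysis", "GAPDH", "glycolysis"),
    ("PGK", {"13bpg[c]": -1, "adp[c]": -1, "3pg[c]": 1, "atp[c]": 1},
     -INF, INF, "Glycolysis", "PGK1", "glycolysis"),
    ("ENO", {"3pg[c]": -1, "pep[c]": 1, "h2o[c]": 1}, -INF, INF, "Glycolysis", "ENO1", "glycolysis"),
    ("PYK", {"pep[c]": -1, "adp[c]": -1, "h[c]": -1, "pyr[c]": 1, "atp[c]": 1},
     0, INF, "Glycolysis", "PKM", "glycolysis"),
    ("LDH", {"pyr[c]": -1, "nadh[c]": -1, "h[c]": -1, "lac[c]": 1, "nad[c]": 1},
     -INF, INF, "Glycolysis", "LDHA", "glycolysis"),
    # --- citric acid cycle ----------------------------------------------
    ("PDHm", {"pyr[m]": -1, "nad[m]": -1, "coa[m]": -1, "accoa[m]": 1, "co2[m]": 1, "nadh[m]": 1},
     0, 60, "Citric acid cycle", "PDHA1", "tca"),
    ("CSm", {"accoa[m]": -1, "oaa[m]": -1, "h2o[m]": -1, "cit[m]": 1, "coa[m]": 1, "h[m]": 1},
     0, INF, "Citric acid cycle", "CS", "tca"),
    ("ICDHm", {"cit[m]": -1, "nad[m]": -1, "akg[m]": 1, "co2[m]": 1, "nadh[m]": 1},
     0, INF, "Citric acid cycle", "IDH3A", "tca"),
    ("AKGDm", {"akg[m]": -1, "nad[m]": -1, "coa[m]": -1, "succoa[m]": 1, "co2[m]": 1, "nadh[m]": 1},
     0, INF, "Citric acid cycle", "OGDH", "tca"),
    ("SUCOASm", {"succoa[m]": -1, "adp[m]": -1, "pi[m]": -1, "succ[m]": 1, "coa[m]": 1, "atp[m]": 1},
     -INF, INF, "Citric acid cycle", "SUCLG1 and SUCLG2", "tca"),
    ("SUCDm", {"succ[m]": -1, "q10[m]": -1, "fum[m]": 1, "q10h2[m]": 1},
     0, 60, "Citric acid cycle", "SDHA and SDHB", "tca"),
    ("FUMm", {"fum[m]": -1, "h2o[m]": -1, "mal[m]": 1}, -INF, INF,
     "Citric acid cycle", "FH", "tca"),
    ("MDHm", {"mal[m]": -1, "nad[m]": -1, "oaa[m]": 1, "nadh[m]": 1, "h[m]": 1},
     -INF, INF, "Citric acid cycle", "MDH2", "tca"),
    # --- oxidative phosphorylation --------------------------------------
    ("NADH2_u10mi", {"nadh[m]": -1, "q10[m]": -1, "h[m]": -5, "nad[m]": 1, "q10h2[m]": 1, "h[i]": 4},
     0, 50, "Oxidative phosphorylation", "NDUFS1", "oxphos"),
    ("CYOOm", {"q10h2[m]": -1, "o2[m]": -0.5, "h[m]": -6, "q10[m]": 1, "h2o[m]": 1, "h[i]": 6},
     0, 70, "Oxidative phosphorylation", "UQCRC1 and COX4I1", "oxphos"),
    ("ATPS4mi", {"adp[m]": -1, "pi[m]": -1, "h[i]": -4, "atp[m]": 1, "h2o[m]": 1, "h[m]": 3},
     0, INF, "Oxidative phosphorylation", "ATP5F1A", "oxphos"),
    ("NADHshuttle", {"nadh[c]": -1, "nad[m]": -1, "nad[c]": 1, "nadh[m]": 1},
     0, INF, "Transport", "GOT1", "oxphos"),
    # --- cytosolic acetyl-CoA and cholesterol ---------------------------
    ("ACLY", {"cit[c]": -1, "atp[c]": -1, "coa[c]": -1, "h2o[c]": -1,
              "accoa[c]": 1, "oaa[c]": 1, "adp[c]": 1, "pi[c]": 1},
     0, INF, "Cholesterol metabolism", "ACLY", "cholesterol"),
    ("MDH1c", {"oaa[c]": -1, "nadh[c]": -1, "h[c]": -1, "mal[c]": 1, "nad[c]": 1},
     -INF, INF, "Cholesterol metabolism", "MDH1", "cholesterol"),
    ("CHOLSYN", {"accoa[c]": -3, "nadh[c]": -2, "h[c]": -2, "o2[c]": -1,
                 "chol[c]": 1, "coa[c]": 3, "nad[c]": 2, "co2[c]": 1, "h2o[c]": 1},
     0, INF, "Cholesterol metabolism", "HMGCR", "cholesterol"),
    # --- sphingolipids --------------------------------------------------
    ("FACOAL", {"palm[c]": -1, "coa[c]": -1, "atp[c]": -1,
                "palmcoa[c]": 1, "adp[c]": 1, "pi[c]": 1},
     0, INF, "Fatty acid metabolism", "ACSL1", "sphingolipid"),
    ("SPT", {"ser[c]": -1, "palmcoa[c]": -1, "h[c]": -1, "sphgn[c]": 1, "co2[c]": 1, "coa[c]": 1},
     0, INF, "Sphingolipid metabolism", "SPTLC1", "sphingolipid"),
    ("CERS", {"sphgn[c]": -1, "palmcoa[c]": -1, "dhcer[c]": 1, "coa[c]": 1, "h[c]": 1},
     0, INF, "Sphingolipid metabolism", "CERS2", "sphingolipid"),
    ("DES", {"dhcer[c]": -1, "o2[c]": -1, "nadh[c]": -1, "cer[c]": 1, "nad[c]": 1, "h2o[c]": 2},
     0, INF, "Sphingolipid metabolism", "DEGS1", "sphingolipid"),
    ("UGCG", {"cer[c]": -1, "g6p[c]": -1, "glccer[c]": 1, "pi[c]": 1},
     0, INF, "Sphingolipid metabolism", "UGCG", "sphingolipid"),
    ("GBA", {"glccer[l]": -1, "cer[l]": 1, "glc[l]": 1},
     0, 2, "Sphingolipid metabolism", "GBA1", "sphingolipid"),
    # exocytosis/redistribution of undegraded glucosylceramide: the
    # steady-state proxy for lysosomal substrate accumulation
    ("GLCCERex", {"glccer[l]": -1, "glccer[e]": 1}, 0, INF,
     "Transport", "", "sphingolipid"),
    ("EX_glccer[e]", {"glccer[e]": -1}, 0, INF, "Exchange", "", "sphingolipid"),
    # the released fatty acid leaves as a generic efflux species rather than
    # re-entering the cytosolic palmitate pool (toy-scale salvage shortcut)
    ("ASAH", {"cer[l]": -1, "sph[l]": 1, "fa[l]": 1},
     0, INF, "Sphingolipid metabolism", "ASAH1", "sphingolipid"),
    # --- gangliosides ---------------------------------------------------
    ("LACCERS", {"glccer[c]": -1, "gal[c]": -1, "laccer[c]": 1, "h2o[c]": 1},
     0, INF, "Ganglioside metabolism", "B4GALT5", "gangliosides"),
    ("GM3S", {"laccer[c]": -1, "sial[c]": -1, "gm3[c]": 1, "h2o[c]": 1},
     0, INF, "Ganglioside metabolism", "ST3GAL5", "gangliosides"),
    ("GM2S", {"gm3[c]": -1, "hexnac[c]": -1, "gm2[c]": 1, "h2o[c]": 1},
     0, INF, "Ganglioside metabolism", "B4GALNT1", "gangliosides"),
    ("GM1S", {"gm2[c]": -1, "gal[c]": -1, "ganglioside[c]": 1, "h2o[c]": 1},
     0, INF, "Ganglioside metabolism", "B3GALT4", "gangliosides"),
    ("GLB1a", {"ganglioside[l]": -1, "h2o[l]": -1, "gm2[l]": 1, "gal[l]": 1},
     0, INF, "Ganglioside metabolism", "GLB1", "gangliosides"),
    ("HEXAl", {"gm2[l]": -1, "h2o[l]": -1, "gm3[l]": 1, "hexnac[l]": 1},
     0, INF, "Ganglioside metabolism", "HEXA and HEXB", "gangliosides"),
    ("NEU1l", {"gm3[l]": -1, "h2o[l]": -1, "laccer[l]": 1, "sial[l]": 1},
     0, INF, "Ganglioside metabolism", "NEU1", "gangliosides"),
    ("GLB1b", {"laccer[l]": -1, "h2o[l]": -1, "glccer[l]": 1, "gal[l]": 1},
     0, INF, "Ganglioside metabolism", "GLB1", "gangliosides"),
    ("GALEc", {"gal[c]": -1, "glc[c]": 1}, 0, INF,
     "Ganglioside metabolism", "GALE", "gangliosides"),
    # --- fatty acid oxidation -------------------------------------------
    # carnitine shuttle lumped: transfers the acyl moiety, conserving the
    # cytosolic and mitochondrial CoA pools
    ("CPT1", {"palmcoa[c]": -1, "coa[m]": -1, "palmcoa[m]": 1, "coa[c]": 1}, 0, 40,
     "Fatty acid oxidation", "CPT1A", "fatty_acid_oxidation"),
    ("FAOXm", {"palmcoa[m]": -1, "coa[m]": -3, "nad[m]": -4, "q10[m]": -4, "h2o[m]": -4,
               "accoa[m]": 4, "nadh[m]": 4, "q10h2[m]": 4, "h[m]": 4},
     0, INF, "Fatty acid oxidation", "HADHA", "fatty_acid_oxidation"),
    # --- maintenance ----------------------------------------------------
    ("ATPM", {"atp[c]": -1, "h2o[c]": -1, "adp[c]": 1, "pi[c]": 1, "h[c]": 1},
     0, INF, "Maintenance", "", "glycolysis"),
    # membrane turnover routes a constitutive glycosphingolipid load to the
    # lysosome (0.3 glucosylceramide per biomass unit), the macrophage's
    # defining clearance burden
    ("biomass_maintenance",
     {"g6p[c]": -0.2, "ser[c]": -0.1, "palmcoa[c]": -0.05, "atp[c]": -2, "h2o[c]": -2,
      "adp[c]": 2, "pi[c]": 2, "h[c]": 2, "coa[c]": 0.05, "glccer[l]": 0.3,
      "biomass[c]": 1},
     0, INF, "Maintenance", "", "glycolysis"),
]

#: reaction -> ATP-producing pathway tags for contribution analysis
ATP_PATHWAY_TAGS = {
    "PGK": "glycolysis",
    "PYK": "glycolysis",
    "SUCOASm": "tca",
    "ATPS4mi": "oxphos",
}

#: default planted differential expression for GD simulation (log2 scale);
#: GBA1 itself is handled by the dedicated knockdown factor
DEFAULT_DE_DOWN = ("NDUFS1", "SDHA", "PDHA1", "SLC25A4", "COX4I1", "HEXA", "ST3GAL5")
DEFAULT_DE_UP = ("PKM", "PGK1", "LDHA", "SPTLC1", "CERS2", "DEGS1", "HMGCR", "B3GALT4")

#: gene whose knockout is expected to push a healthy state toward disease:
#: blocking acid ceramidase stalls lysosomal glucosylceramide clearance just
#: like the glucocerebrosidase deficiency itself
PLANTED_MODIFIER = "ASAH1"


def make_toy_network(spec: ToyNetworkSpec | None = None) -> tuple[MetabolicModel, dict]:
    """Build the toy macrophage network and its manifest.

    The manifest records counts, the GPR table, the reaction->pathway tags
    for ATP decomposition, the default planted differential-expression
    gene sets, and the seed.
    """
    spec = spec or ToyNetworkSpec()
    enabled = {
        "glycolysis": spec.glycolysis,
        "tca": spec.tca,
        "oxphos": spec.oxphos,
        "sphingolipid": spec.sphingolipid,
        "gangliosides": spec.gangliosides,
        "cholesterol": spec.cholesterol,
        "fatty_acid_oxidation": spec.fatty_acid_oxidation,
        "exchanges": spec.exchanges,
    }
    model = MetabolicModel(id="toy_macrophage")
    for rid, stoich, lb, ub, subsystem, gpr, module in _REACTIONS:
        if not enabled[module]:
            continue
        model.add_reaction(
            Reaction(rid, dict(stoich), float(lb), float(ub), subsystem, gpr)
        )
    # a maintenance objective must be able to carry flux
    from .consistency import blocked_reactions

    blocked = blocked_reactions(model, tol=1e-9)
    if "ATPM" in blocked or "biomass_maintenance" in blocked:
        raise ValueError(
            "enabled modules leave the maintenance objective disconnected"
        )
    manifest = {
        "id": model.id,
        "seed": spec.seed,
        "n_reactions": len(model.reactions),
        "n_metabolites": len(model.metabolites),
        "n_genes": len(model.genes),
        "modules": {k: bool(v) for k, v in enabled.items()},
        "gpr_table": {r.id: r.gpr.to_string() for r in model.reactions.values()},
        "subsystems": {r.id: r.subsystem for r in model.reactions.values()},
        "atp_pathway_tags": dict(ATP_PATHWAY_TAGS),
        "de_down": list(DEFAULT_DE_DOWN),
        "de_up": list(DEFAULT_DE_UP),
        "planted_modifier": PLANTED_MODIFIER,
        "gba1_reactions": [
            r.id for r in model.reactions.values() if "GBA1" in r.genes
        ],
    }
    return model, manifest


def default_differential_expression(
    manifest: dict, log2fc: float = 2.0, p_value: float = 1e-4
):
    """The planted GD-vs-control differential-expression calls for the toy
    network (respiratory chain / pyruvate oxidation / ATP transport down;
    glycolysis, de-novo ceramide synthesis, cholesterol synthesis and late
    ganglioside synthesis up)."""
    from .disease import DifferentialExpression

    out = [
        DifferentialExpression(g, -abs(log2fc), p_value) for g in manifest["de_down"]
    ]
    out += [
        DifferentialExpression(g, abs(log2fc), p_value) for g in manifest["de_up"]
    ]
    return out


# ---------------------------------------------------------------------------
# Expression simulation
# ---------------------------------------------------------------------------

@dataclass
class ExpressionSpec:
    """Log-normal FPKM-like expression with planted fold changes."""

    genes: list[str]
    mean_log2: float = 5.0  # baseline log2 FPKM location
    sd_log2: float = 2.0  # between-gene spread
    de: dict[str, float] = field(default_factory=dict)  # gene -> log2fc in condition 2
    n_replicates: int = 5
    noise_sd: float = 0.2  # replicate noise on the log2 scale
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_replicates < 2:
            raise ValueError("need at least 2 replicates")


def simulate_expression(spec: ExpressionSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """(control, case) gene x replicate FPKM tables.

    Baselines are shared between conditions; planted genes are shifted by
    their log2 fold change in the case condition; every replicate gets
    independent multiplicative noise.
    """
    rng = np.random.default_rng(spec.seed)
    genes = list(spec.genes)
    base = rng.normal(spec.mean_log2, spec.sd_log2, size=len(genes))
    shift = np.array([spec.de.get(g, 0.0) for g in genes])
    cols = [f"rep{i + 1}" for i in range(spec.n_replicates)]

    def draw(loc: np.ndarray) -> pd.DataFrame:
        noise = rng.normal(0.0, spec.noise_sd, size=(len(genes), spec.n_replicates))
        return pd.DataFrame(
            np.exp2(loc[:, None] + noise), index=genes, columns=cols
        )

    control = draw(base)
    case = draw(base + shift)
    return control, case


# ---------------------------------------------------------------------------
# Exometabolome simulation
# ---------------------------------------------------------------------------

def simulate_exometabolome(
    model: MetabolicModel,
    flux: FluxState,
    noise_sd: float = 0.1,
    seed: int = 0,
    excluded: set[str] | None = None,
) -> list[ExchangeMeasurement]:
    """Noisy measured exchange rates from a predicted flux state.

    measured = net exchange flux * (1 + N(0, noise_sd)); uptake stays
    negative by the exchange convention.  ``excluded`` marks metabolites
    (e.g. essential amino acids) to flag as excluded from validation.
    """
    rng = np.random.default_rng(seed)
    excluded = excluded or set()
    flux_map = flux.as_dict()
    out = []
    for rxn in model.reactions.values():
        if not rxn.is_exchange:
            continue
        met_id = next(iter(rxn.stoichiometry))
        rate = flux_map[rxn.id] * (1.0 + rng.normal(0.0, noise_sd))
        out.append(
            ExchangeMeasurement(
                metabolite_id=met_id, rate=float(rate), excluded=met_id in excluded
            )
        )
    return out


# ---------------------------------------------------------------------------
# Synthetic flux-activity ensembles (statistical calibration)
# ---------------------------------------------------------------------------

def simulate_activity_ensembles(
    n_reactions: int,
    n_models: int,
    seed: int,
    planted_fold: dict[int, float] | None = None,
    sd_log2: float = 0.5,
    condition_labels: tuple[str, str] = ("control", "GD"),
) -> tuple[FluxEnsemble, FluxEnsemble]:
    """Paired null/planted activity ensembles for calibrating the
    differential-flux statistics.

    Activities are log-normal per reaction around a shared baseline;
    columns listed in ``planted_fold`` are multiplied by the fold factor in
    the second ensemble.  Net fluxes carry a random (per-reaction) sign.
    """
    rng = np.random.default_rng(seed)
    rids = [f"R{i:04d}" for i in range(n_reactions)]
    base = rng.normal(2.0, 1.0, size=n_reactions)  # log2 activity location
    signs = rng.choice([-1.0, 1.0], size=n_reactions)

    def draw(shift: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        act = np.exp2(
            base[None, :] + shift[None, :]
            + rng.normal(0.0, sd_log2, size=(n_models, n_reactions))
        )
        return act * signs[None, :], act

    zero = np.zeros(n_reactions)
    shift = np.zeros(n_reactions)
    for j, fold in (planted_fold or {}).items():
        shift[j] = np.log2(fold)
    net_a, act_a = draw(zero)
    net_b, act_b = draw(shift)
    return (
        FluxEnsemble(rids, net_a, act_a, condition=condition_labels[0]),
        FluxEnsemble(rids, net_b, act_b, condition=condition_labels[1]),
    )


def make_reporter_testbed(
    n_mets: int = 60,
    genes_per_met: int = 3,
    hub_met: int | None = None,
    hub_size: int = 5,
    seed: int = 0,
) -> tuple[MetabolicModel, list[str]]:
    """Bipartite-style network with controlled metabolite neighbourhoods.

    Metabolite ``m{i}[c]`` is touched by ``genes_per_met`` dedicated
    single-gene reactions (``hub_size`` for the optional hub metabolite),
    so reporter scores can be validated against planted gene signals.
    Returns (model, hub gene ids).
    """
    model = MetabolicModel(id=f"reporter_testbed_{seed}")
    gene_counter = 0
    hub_genes: list[str] = []
    for i in range(n_mets):
        k = hub_size if (hub_met is not None and i == hub_met) else genes_per_met
        for j in range(k):
            gene = f"g{gene_counter:05d}"
            gene_counter += 1
            if hub_met is not None and i == hub_met:
                hub_genes.append(gene)
            model.add_reaction(
                Reaction(
                    f"R_{i}_{j}", {f"m{i}[c]": -1, f"aux_{i}_{j}[c]": 1},
                    0, 10, gpr=gene,
                )
            )
    return model, hub_genes


def make_instance_pairs(
    control: MetabolicModel,
    gd: MetabolicModel,
    n_pairs: int,
    seed: int,
    jitter_sd: float = 0.05,
) -> tuple[list[MetabolicModel], list[MetabolicModel]]:
    """Paired bound-jittered control/GD model instances (shared per-pair
    jitter factors, emulating paired draft-model origins)."""
    rng = np.random.default_rng(seed)
    controls, gds = [], []
    for i in range(n_pairs):
        factors = {}
        for rid, rxn in control.reactions.items():
            if rxn.is_exchange:
                factors[rid] = float(np.exp(rng.normal(0.0, jitter_sd)))
        for src, dest, label in ((control, controls, "control"), (gd, gds, "GD")):
            inst = src.copy(id=f"{src.id}_{label}_{i}")
            for rid, f in factors.items():
                rxn = inst.reactions[rid]
                if np.isfinite(rxn.lb) and rxn.lb != 0.0:
                    rxn.lb *= f
                if np.isfinite(rxn.ub) and rxn.ub != 0.0:
                    rxn.ub *= f
            dest.append(inst)
    return controls, gds


# ---------------------------------------------------------------------------
# Random small generic networks (extraction benchmarking)
# ---------------------------------------------------------------------------

def make_random_generic_network(
    n_internal: int = 8,
    n_core: int = 3,
    seed: int = 0,
) -> tuple[MetabolicModel, set[str]]:
    """A small random irreversible generic network with designated core
    reactions; used to benchmark extraction against exhaustive search.

    The network is a random layered conversion graph between an uptaken
    substrate and an excreted product: a backbone chain keeps every
    metabolite reachable, extra forward edges add alternative routes.
    Every internal reaction converts one metabolite into another, so the
    network is stoichiometrically consistent by construction.
    """
    rng = np.random.default_rng(seed)
    n_mets = max(3, n_internal // 2 + 2)
    mets = [f"x{i}[c]" for i in range(n_mets)]
    model = MetabolicModel(id=f"generic_{seed}")
    model.add_reaction(Reaction("EX_in", {"x0[c]": -1}, -10, 0, "Exchange"))
    model.add_reaction(Reaction("EX_out", {mets[-1]: -1}, 0, 10, "Exchange"))
    edges = [(i, i + 1) for i in range(min(n_mets - 1, n_internal))]
    while len(edges) < n_internal:
        a, b = rng.choice(n_mets, size=2, replace=False)
        if a > b:
            a, b = b, a
        edges.append((int(a), int(b)))
    for i, (a, b) in enumerate(edges):
        model.add_reaction(
            Reaction(f"R{i:02d}", {mets[a]: -1, mets[b]: 1}, 0, 10, "Internal",
                     gpr=f"g{i:02d}")
        )
    internal_ids = [f"R{i:02d}" for i in range(n_internal)]
    core = set(rng.choice(internal_ids, size=min(n_core, n_internal), replace=False))
    return model, core
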