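"""In-memory representation of a constraint-based metabolic model.

The model is a stoichiometric network: metabolites (rows of S), reactions
(columns of S) with flux bounds in umol/gDW/hr, gene-protein-reaction rules,
and pathway (subsystem) labels.  Metabolite identifiers carry their
compartment as a ``[x]`` suffix, e.g. ``glc[e]`` (extracellular glucose) —
compartments used here are ``c`` cytosol, ``m`` mitochondrion, ``l``
lysosome and ``e`` extracellular.

Sign conventions: a negative stoichiometric coefficient means the metabolite
is consumed.  Exchange reactions are written as ``1 met[e] ->`` so that
export is a positive flux and uptake a negative one.
"""

from __future__ import annotations

import copy as _copy
import re
import warnings
from dataclasses import dataclass, field

import numpy as np

from .gpr import GPRRule, parse_gpr

_COMPARTMENT_RE = re.compile(r"^(?P<base>.+)\[(?P<comp>[a-zA-Z0-9]+)\]$")


class ModelValidationError(ValueError):
    """Raised when a model violates a structural invariant."""


def compartment_of(metabolite_id: str) -> str:
    """Compartment tag derived from the ``[x]`` suffix of a metabolite id."""
    m = _COMPARTMENT_RE.match(metabolite_id)
    if m is None:
        raise ModelValidationError(
            f"metabolite id {metabolite_id!r} lacks a [compartment] suffix"
        )
    return m.group("comp")


@dataclass
class Metabolite:
    id: str
    name: str = ""
    formula: str | None = None

    @property
    def compartment(self) -> str:
        return compartment_of(self.id)


@dataclass
class Reaction:
    id: str
    stoichiometry: dict[str, float]
    lb: float
    ub: float
    subsystem: str = ""
    gpr: GPRRule = field(default_factory=GPRRule)
    objective_coefficient: float = 0.0

    def __post_init__(self) -> None:
        if isinstance(self.gpr, str):
            self.gpr = parse_gpr(self.gpr)
        if not self.stoichiometry:
            raise ModelValidationError(f"reaction {self.id!r}: empty stoichiometry")
        if self.lb > self.ub:
            raise ModelValidationError(
                f"reaction {self.id!r}: lb={self.lb} exceeds ub={self.ub}"
            )

    @property
    def is_exchange(self) -> bool:
        """Boundary pseudo-reaction touching exactly one metabolite."""
        return len(self.stoichiometry) == 1

    @property
    def genes(self) -> set[str]:
        return self.gpr.genes()

    def copy(self) -> "Reaction":
        return Reaction(
            id=self.id,
            stoichiometry=dict(self.stoichiometry),
            lb=self.lb,
            ub=self.ub,
            subsystem=self.subsystem,
            gpr=self.gpr,  # immutable tree, safe to share
            objective_coefficient=self.objective_coefficient,
        )


class MetabolicModel:
    """A stoichiometric network with bounds, GPRs and subsystem labels.

    Reactions and metabolites keep insertion order; the stoichiometric
    matrix ``S`` (metabolites x reactions) is derived on demand.
    """

    def __init__(
        self,
        id: str = "model",
        metabolites: list[Metabolite] | None = None,
        reactions: list[Reaction] | None = None,
    ) -> None:
        self.id = id
        self.metabolites: dict[str, Metabolite] = {}
        self.reactions: dict[str, Reaction] = {}
        for met in metabolites or []:
            self.add_metabolite(met)
        for rxn in reactions or []:
            self.add_reaction(rxn)

    # -- construction ----------------------------------------------------
    def add_metabolite(self, met: Metabolite) -> None:
        if met.id in self.metabolites:
            raise ModelValidationError(f"duplicate metabolite id {met.id!r}")
        compartment_of(met.id)  # validates suffix
        self.metabolites[met.id] = met

    def add_reaction(self, rxn: Reaction) -> None:
        if rxn.id in self.reactions:
            raise ModelValidationError(f"duplicate reaction id {rxn.id!r}")
        for met_id in rxn.stoichiometry:
            if met_id not in self.metabolites:
                # implicit metabolite declaration keeps toy construction terse
                self.add_metabolite(Metabolite(id=met_id))
        self.reactions[rxn.id] = rxn

    # -- views -----------------------------------------------------------
    @property
    def metabolite_ids(self) -> list[str]:
        return list(self.metabolites)

    @property
    def reaction_ids(self) -> list[str]:
        return list(self.reactions)

    @property
    def genes(self) -> set[str]:
        out: set[str] = set()
        for rxn in self.reactions.values():
            out |= rxn.genes
        return out

    @property
    def exchanges(self) -> list[str]:
        return [r.id for r in self.reactions.values() if r.is_exchange]

    def exchange_for_metabolite(self, met_id: str) -> str | None:
        """Id of the exchange reaction whose sole metabolite is ``met_id``."""
        for rxn in self.reactions.values():
            if rxn.is_exchange and next(iter(rxn.stoichiometry)) == met_id:
                return rxn.id
        return None

    def stoichiometric_matrix(self) -> np.ndarray:
        """Dense S (metabolites x reactions) in insertion order."""
        met_index = {m: i for i, m in enumerate(self.metabolites)}
        S = np.zeros((len(self.metabolites), len(self.reactions)))
        for j, rxn in enumerate(self.reactions.values()):
            for met_id, coef in rxn.stoichiometry.items():
                S[met_index[met_id], j] = coef
        return S

    def bounds_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        lb = np.array([r.lb for r in self.reactions.values()])
        ub = np.array([r.ub for r in self.reactions.values()])
        return lb, ub

    def objective_vector(self) -> np.ndarray:
        return np.array([r.objective_coefficient for r in self.reactions.values()])

    def copy(self, id: str | None = None) -> "MetabolicModel":
        out = MetabolicModel(id=id or self.id)
        for met in self.metabolites.values():
            out.add_metabolite(_copy.copy(met))
        for rxn in self.reactions.values():
            out.add_reaction(rxn.copy())
        return out

    def subnetwork(self, reaction_ids: set[str] | list[str], id: str | None = None) -> "MetabolicModel":
        """Model restricted to ``reaction_ids``; orphan metabolites dropped."""
        keep = set(reaction_ids)
        missing = keep - set(self.reactions)
        if missing:
            raise ModelValidationError(f"unknown reactions in subnetwork: {sorted(missing)}")
        out = MetabolicModel(id=id or f"{self.id}_sub")
        used_mets: set[str] = set()
        for rid in self.reactions:  # preserve original order
            if rid in keep:
                used_mets |= set(self.reactions[rid].stoichiometry)
        for met_id, met in self.metabolites.items():
            if met_id in used_mets:
                out.add_metabolite(_copy.copy(met))
        for rid in self.reactions:
            if rid in keep:
                out.add_reaction(self.reactions[rid].copy())
        return out

    def validate(self) -> None:
        """Check structural invariants; raises ModelValidationError."""
        for rxn in self.reactions.values():
            if rxn.lb > rxn.ub:
                raise ModelValidationError(
                    f"reaction {rxn.id!r}: lb={rxn.lb} exceeds ub={rxn.ub}"
                )
            for met_id in rxn.stoichiometry:
                if met_id not in self.metabolites:
                    raise ModelValidationError(
                        f"reaction {rxn.id!r} references unknown metabolite {met_id!r}"
                    )

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"<MetabolicModel {self.id}: {len(self.metabolites)} metabolites, "
            f"{len(self.reactions)} reactions, {len(self.genes)} genes>"
        )


def map_genes_to_reactions(model: MetabolicModel, gene_set: set[str]) -> set[str]:
    """Reactions with at least one GPR leaf in ``gene_set``.

    Genes absent from every GPR are reported in a warning (they map to
    nothing, typically non-metabolic genes in a differential-expression
    table).
    """
    gene_set = set(gene_set)
    hit: set[str] = set()
    seen: set[str] = set()
    for rxn in model.reactions.values():
        leaves = rxn.genes
        seen |= leaves & gene_set
        if leaves & gene_set:
            hit.add(rxn.id)
    missing = gene_set - seen
    if missing:
        warnings.warn(
            f"{len(missing)} gene(s) not present in any GPR: {sorted(missing)}",
            stacklevel=2,
        )
    return hit
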