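"""Flux prediction engines: FBA, entropic FBA, MOMA, knockouts.

Cross-checks use independent solvers: cobra/GLPK for linear programs and
scipy's trust-constr NLP solver for the entropic and quadratic programs —
neither shares code with the package's own HiGHS / dual-Newton routes.
"""

import numpy as np
import pytest

from gaucherflux.model import MetabolicModel, Reaction
from gaucherflux.optimize import apply_knockout, entropic_fba, fba, moma

from conftest import random_toy_lp_model


def cobra_fba_objective(model: MetabolicModel, objective: dict[str, float]) -> float:
    """Independent LP oracle: the same problem through cobra + GLPK."""
    import cobra

    cm = cobra.Model(model.id)
    mets = {
        m: cobra.Metabolite(m.replace("[", "_").replace("]", ""), compartment="c")
        for m in model.metabolites
    }
    rxns = []
    for rxn in model.reactions.values():
        cr = cobra.Reaction(rxn.id)
        cr.lower_bound, cr.upper_bound = rxn.lb, rxn.ub
        rxns.append((cr, {mets[m]: c for m, c in rxn.stoichiometry.items()}))
    cm.add_reactions([cr for cr, _ in rxns])
    for cr, sto in rxns:
        cr.add_metabolites(sto)
    cm.objective = {cm.reactions.get_by_id(r): w for r, w in objective.items()}
    sol = cm.optimize()
    assert sol.status == "optimal"
    return float(sol.objective_value)


class TestFBA:
    def test_linear_chain_throughput(self, chain_model):
        state = fba(chain_model, {"EX_b": 1.0})
        assert state.status == "optimal"
        assert state.objective_value == pytest.approx(10.0, abs=1e-9)
        assert state.flux("EX_a") == pytest.approx(-10.0, abs=1e-9)

    def test_invalid_bounds_error(self, chain_model):
        chain_model.reactions["CONV"].lb = 5
        chain_model.reactions["CONV"].ub = 2
        with pytest.raises(ValueError, match="CONV"):
            fba(chain_model, {"EX_b": 1.0})

    def test_no_objective_error(self, chain_model):
        with pytest.raises(ValueError, match="objective"):
            fba(chain_model, {})

    def test_infeasible_reported_as_status(self, chain_model):
        chain_model.reactions["EX_b"].lb = 100  # forced beyond uptake capacity
        state = fba(chain_model, {"EX_b": 1.0})
        assert state.status == "infeasible"

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_independent_lp_solver(self, seed):
        """FBA optimum equals a cobra/GLPK solve on 20 random toy models."""
        model = random_toy_lp_model(seed)
        objective = {"EX_out": 1.0}
        state = fba(model, objective)
        assert state.status == "optimal"
        oracle = cobra_fba_objective(model, objective)
        assert state.objective_value == pytest.approx(oracle, rel=1e-6, abs=1e-6)

    def test_toy_composite_objective_matches_oracle(self, control_prepared):
        objective = {
            r.id: r.objective_coefficient
            for r in control_prepared.reactions.values()
            if r.objective_coefficient
        }
        state = fba(control_prepared)
        oracle = cobra_fba_objective(control_prepared, objective)
        assert state.objective_value == pytest.approx(oracle, rel=1e-6)

    @pytest.mark.parametrize("seed", [3, 17, 29])
    def test_steady_state_residual(self, seed):
        model = random_toy_lp_model(seed)
        state = fba(model, {"EX_out": 1.0})
        S = model.stoichiometric_matrix()
        assert np.max(np.abs(S @ state.v)) <= 1e-6


class TestEntropicFBA:
    def test_symmetric_parallel_routes_split_evenly(self):
        m = MetabolicModel("par")
        m.add_reaction(Reaction("EX_a", {"a[e]": -1}, -10, -10))
        m.add_reaction(Reaction("R1", {"a[e]": -1, "b[c]": 1}, 0, 1000))
        m.add_reaction(Reaction("R2", {"a[e]": -1, "b[c]": 1}, 0, 1000))
        m.add_reaction(Reaction("EX_b", {"b[c]": -1}, 0, 1000))
        state = entropic_fba(m, {"EX_b": 1.0})
        assert state.status == "optimal"
        assert state.flux("R1") == pytest.approx(5.0, abs=1e-9)
        assert state.flux("R2") == pytest.approx(5.0, abs=1e-9)

    @staticmethod
    def _oracle_solve(A, lo, hi, ctil, lam):
        """Independent interior-point solve (trust-constr, exact Hessian)."""
        from scipy.optimize import LinearConstraint, minimize
        from scipy.sparse import diags

        floor = 1e-12

        # drop degenerate fixed variables (lo == hi), then reduce A x = 0 to
        # a full-rank equivalent: both defeat barrier stalling
        free = hi > lo
        Af = A[:, free]
        cf = ctil[free]
        lof, hif = np.maximum(lo[free], 0.0), hi[free]
        _, sv, Vt = np.linalg.svd(Af, full_matrices=False)
        B = Vt[sv > sv.max() * 1e-12]

        def f(x):
            xs = np.maximum(x, floor)
            return float(lam * np.sum(xs * np.log(xs) - xs) - cf @ x)

        res = minimize(
            f,
            np.clip(np.ones(Af.shape[1]), np.maximum(lof, floor), hif),
            jac=lambda x: lam * np.log(np.maximum(x, floor)) - cf,
            hess=lambda x: diags(lam / np.maximum(x, floor)),
            method="trust-constr",
            constraints=[LinearConstraint(B, 0.0, 0.0)],
            bounds=list(zip(lof, hif)),
            options={"gtol": 1e-14, "xtol": 1e-16, "barrier_tol": 1e-14,
                     "maxiter": 5000},
        )
        out = np.array(lo, float)
        out[free] = res.x
        return out

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_independent_convex_solver(self, seed):
        """Dual-Newton solution equals an interior-point solve to 1e-6."""
        model = random_toy_lp_model(seed, n_mets=5, n_rxns=8)
        state = entropic_fba(model, {"EX_out": 1.0})
        assert state.status == "optimal"
        S = model.stoichiometric_matrix()
        lb, ub = model.bounds_arrays()
        c = np.zeros(len(model.reactions))
        c[model.reaction_ids.index("EX_out")] = 1.0
        A = np.hstack([S, -S])
        ctil = np.concatenate([c, -c])
        lo = np.concatenate([np.maximum(lb, 0), np.maximum(-ub, 0)])
        hi = np.concatenate([np.maximum(ub, 0), np.maximum(-lb, 0)])
        x = self._oracle_solve(A, lo, hi, ctil, 1.0)
        n = len(model.reactions)
        v_oracle = x[:n] - x[n:]
        assert np.max(np.abs(state.v - v_oracle)) <= 1e-6

    def test_small_entropy_weight_approaches_fba(self, chain_model):
        lp = fba(chain_model, {"EX_b": 1.0})
        state = entropic_fba(chain_model, {"EX_b": 1.0}, entropy_weight=1e-6)
        assert state.status == "optimal"
        assert np.max(np.abs(state.v - lp.v)) <= 1e-3

    def test_deterministic_across_runs(self, control_prepared):
        a = entropic_fba(control_prepared)
        b = entropic_fba(control_prepared)
        assert np.max(np.abs(a.v - b.v)) <= 1e-6

    def test_linear_part_never_exceeds_fba(self, control_prepared):
        lp = fba(control_prepared)
        ent = entropic_fba(control_prepared)
        assert ent.linear_objective <= lp.objective_value + 1e-6

    def test_steady_state_and_nonnegative_split(self, control_prepared):
        state = entropic_fba(control_prepared)
        assert np.all(state.vf >= 0) and np.all(state.vr >= 0)
        S = control_prepared.stoichiometric_matrix()
        assert np.max(np.abs(S @ state.v)) <= 1e-6
        lb, ub = control_prepared.bounds_arrays()
        assert np.all(state.v >= lb - 1e-8) and np.all(state.v <= ub + 1e-8)

    def test_nonpositive_entropy_weight_rejected(self, chain_model):
        with pytest.raises(ValueError):
            entropic_fba(chain_model, {"EX_b": 1.0}, entropy_weight=0.0)


class TestMOMA:
    def test_feasible_reference_returns_itself(self, chain_model):
        ref = fba(chain_model, {"EX_b": 1.0})
        state = moma(chain_model, ref)
        assert state.status == "optimal"
        assert state.objective_value == pytest.approx(0.0, abs=1e-8)
        assert np.max(np.abs(state.v - ref.v)) <= 1e-4

    def test_knockout_distance_matches_qp_oracle(self):
        """Closing one of two unequal routes: projection distance equals an
        independent trust-constr QP solve."""
        from scipy.optimize import LinearConstraint, minimize

        m = MetabolicModel("two_routes")
        m.add_reaction(Reaction("EX_a", {"a[e]": -1}, -10, 0))
        m.add_reaction(Reaction("R1", {"a[e]": -1, "b[c]": 1}, 0, 1000, gpr="G1"))
        m.add_reaction(Reaction("R2", {"a[e]": -1, "b[c]": 1}, 0, 6))
        m.add_reaction(Reaction("EX_b", {"b[c]": -1}, 0, 1000))
        ref = entropic_fba(m, {"EX_b": 1.0})
        ko = apply_knockout(m, {"G1"})
        state = moma(ko, ref)
        assert state.status == "optimal"

        S = ko.stoichiometric_matrix()
        lb, ub = ko.bounds_arrays()
        res = minimize(
            lambda v: float(np.sum((v - ref.v) ** 2)),
            np.clip(ref.v, lb, ub),
            jac=lambda v: 2 * (v - ref.v),
            method="trust-constr",
            constraints=[LinearConstraint(S, 0, 0)],
            bounds=list(zip(lb, ub)),
            options={"gtol": 1e-12, "xtol": 1e-14},
        )
        assert state.objective_value == pytest.approx(res.fun, rel=1e-6, abs=1e-8)

    def test_knockout_of_only_route_with_demand_is_infeasible(self, chain_model):
        chain_model.reactions["EX_b"].lb = 1.0  # maintenance-like demand
        ref = fba(chain_model, {"EX_b": 1.0})
        ko = apply_knockout(chain_model, {"G1"})
        state = moma(ko, ref)
        assert state.status == "infeasible"

    def test_dimension_mismatch_rejected(self, chain_model):
        with pytest.raises(ValueError):
            moma(chain_model, np.zeros(3))


class TestKnockout:
    @pytest.mark.parametrize(
        "gpr, genes, closed",
        [
            ("G", {"G"}, True),
            ("A or B", {"A"}, False),
            ("A and B", {"A"}, True),
        ],
    )
    def test_gpr_semantics(self, gpr, genes, closed):
        m = MetabolicModel()
        m.add_reaction(Reaction("R", {"a[c]": -1, "b[c]": 1}, -5, 10, gpr=gpr))
        ko = apply_knockout(m, genes)
        if closed:
            assert (ko.reactions["R"].lb, ko.reactions["R"].ub) == (0.0, 0.0)
        else:
            assert (ko.reactions["R"].lb, ko.reactions["R"].ub) == (-5, 10)
        # input model untouched
        assert (m.reactions["R"].lb, m.reactions["R"].ub) == (-5, 10)

    def test_unknown_gene_error(self, chain_model):
        with pytest.raises(KeyError):
            apply_knockout(chain_model, {"NOPE"})

    def test_empty_gene_set_error(self, chain_model):
        with pytest.raises(ValueError):
            apply_knockout(chain_model, set())
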