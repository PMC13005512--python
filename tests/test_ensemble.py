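"""Ensemble analytics: differential flux, enrichment, modules, ATP split."""

import numpy as np
import pytest
from scipy.stats import hypergeom

from gaucherflux.disease import ScalingScheme
from gaucherflux.ensemble import (
    FluxEnsemble,
    SimulationSetup,
    atp_contribution_sweep,
    differential_flux,
    gd_specific_correlations,
    robustness_sweep,
    subsystem_enrichment,
)
from gaucherflux.synthetic import (
    ATP_PATHWAY_TAGS,
    simulate_activity_ensembles,
)


class TestSimulationSetup:
    def test_defaults_carry_maintenance_bounds(self, toy_model, setup):
        prepared = setup.apply(toy_model, ganglioside_uptake=1.0)
        assert prepared.reactions["ATPM"].lb == 44.8
        assert prepared.reactions["biomass_maintenance"].lb == 3.45
        assert prepared.reactions["EX_gangliosides[l]"].lb == -1.0
        assert prepared.reactions["EX_gangliosides[l]"].ub == -1.0
        weights = {
            r.id: r.objective_coefficient
            for r in prepared.reactions.values()
            if r.objective_coefficient
        }
        assert weights == {
            "biomass_maintenance": 1.0, "ATPM": 1.0, "ATPS4mi": 1.0,
            "LACCERS": 1.0, "GM3S": 1.0,
        }

    def test_uptake_levels_must_increase(self):
        with pytest.raises(ValueError):
            SimulationSetup(ganglioside_uptake_levels=(1.0, 0.5))

    def test_negative_maintenance_bound_rejected(self):
        with pytest.raises(ValueError):
            SimulationSetup(atpm_lb=-1.0)


class TestDifferentialFlux:
    def test_planted_fold_change_recovered(self):
        ctrl, gd = simulate_activity_ensembles(
            100, 30, seed=5, planted_fold={7: 4.0}, sd_log2=0.3
        )
        results = differential_flux(gd, ctrl)
        hit = next(r for r in results if r.reaction_id == "R0007")
        assert hit.flagged and hit.direction == "up"
        assert hit.log2_ratio == pytest.approx(2.0, abs=0.3)

    def test_identical_ensembles_not_flagged(self):
        ctrl, _ = simulate_activity_ensembles(50, 30, seed=2)
        results = differential_flux(ctrl, ctrl)
        assert not any(r.flagged for r in results)

    def test_null_type_one_rate(self):
        """Independent null ensembles: flagged-by-p fraction near 5%."""
        ctrl, gd = simulate_activity_ensembles(2000, 30, seed=8)
        results = differential_flux(gd, ctrl, fc_threshold=0.0)
        rate = np.mean([r.p_value < 0.05 for r in results])
        assert abs(rate - 0.05) <= 0.02

    def test_dead_reactions_excluded(self):
        rids = ["A", "B", "C"]
        net = np.array([[1.0, 0, 2], [1.1, 0, 2.2]] * 3)
        act = np.abs(net)
        gd = FluxEnsemble(rids, net, act, "GD")
        ctrl = FluxEnsemble(rids, net * 1.1, act * 1.1, "control")
        results = differential_flux(gd, ctrl)
        assert {r.reaction_id for r in results} == {"A", "C"}

    def test_antisymmetry_of_log_ratios(self):
        ctrl, gd = simulate_activity_ensembles(40, 10, seed=3, planted_fold={1: 3.0})
        fwd = {r.reaction_id: r.log2_ratio for r in differential_flux(gd, ctrl)}
        rev = {r.reaction_id: r.log2_ratio for r in differential_flux(ctrl, gd)}
        for rid in fwd:
            assert fwd[rid] == pytest.approx(-rev[rid], abs=1e-12)

    def test_mismatched_columns_rejected(self):
        a, _ = simulate_activity_ensembles(5, 6, seed=0)
        b, _ = simulate_activity_ensembles(6, 6, seed=0)
        with pytest.raises(ValueError):
            differential_flux(a, b)

    def test_small_ensembles_rejected(self):
        a, b = simulate_activity_ensembles(5, 4, seed=0)
        with pytest.raises(ValueError, match="5 models"):
            differential_flux(a, b)


class TestSubsystemEnrichment:
    def test_matches_closed_form_hypergeometric(self, toy_model):
        # build a 50-reaction model with one 5-reaction subsystem fully flagged
        from gaucherflux.model import MetabolicModel, Reaction

        m = MetabolicModel("enrich")
        for i in range(50):
            sub = "Target" if i < 5 else f"Other{i % 4}"
            m.add_reaction(
                Reaction(f"R{i}", {f"m{i}[c]": -1, f"n{i}[c]": 1}, 0, 1, subsystem=sub)
            )
        flagged = {f"R{i}" for i in range(5)}
        rows = subsystem_enrichment(flagged, m)
        target = next(r for r in rows if r["subsystem"] == "Target")
        assert target["p"] == pytest.approx(float(hypergeom.sf(4, 50, 5, 5)))

    def test_empty_flagged_set_gives_empty_table(self, toy_model):
        assert subsystem_enrichment(set(), toy_model) == []

    def test_all_flagged_gives_p_one(self, toy_model):
        rows = subsystem_enrichment(set(toy_model.reactions), toy_model)
        assert rows and all(r["p"] == pytest.approx(1.0) for r in rows)

    def test_unknown_flagged_reaction_rejected(self, toy_model):
        with pytest.raises(ValueError):
            subsystem_enrichment({"NOPE"}, toy_model)


class TestCorrelationModules:
    def make_block_ensembles(self, seed=0):
        """Two planted correlation blocks in GD, independent in control."""
        rng = np.random.default_rng(seed)
        n_models = 40
        rids = [f"R{i}" for i in range(6)]
        z1, z2 = rng.normal(size=(2, n_models))
        noise = 0.05 * rng.normal(size=(n_models, 6))
        gd_net = np.column_stack([
            z1, z1 * 2 + noise[:, 1], z1 * 0.5 + noise[:, 2],
            z2, z2 * 3 + noise[:, 4], z2 + noise[:, 5],
        ])
        ctrl_net = rng.normal(size=(n_models, 6))
        gd = FluxEnsemble(rids, gd_net, np.abs(gd_net), "GD")
        ctrl = FluxEnsemble(rids, ctrl_net, np.abs(ctrl_net), "control")
        return gd, ctrl, rids

    def test_planted_blocks_recovered_exactly(self):
        gd, ctrl, rids = self.make_block_ensembles()
        modules = gd_specific_correlations(gd, ctrl, set(rids))
        groups = sorted(tuple(sorted(m.reactions)) for m in modules)
        assert groups == [("R0", "R1", "R2"), ("R3", "R4", "R5")]

    def test_pair_below_strong_threshold_not_flagged(self):
        rng = np.random.default_rng(4)
        n = 60
        z = rng.normal(size=n)
        # correlation ~0.5: below the 0.7 bar
        a = z + rng.normal(scale=1.2, size=n)
        net_gd = np.column_stack([z, a])
        net_ct = rng.normal(size=(n, 2))
        gd = FluxEnsemble(["A", "B"], net_gd, np.abs(net_gd), "GD")
        ctrl = FluxEnsemble(["A", "B"], net_ct, np.abs(net_ct), "control")
        assert gd_specific_correlations(gd, ctrl, {"A", "B"}) == []

    def test_perfect_gd_specific_pair_flagged(self):
        n = 30
        z = np.linspace(-1, 1, n)
        rng = np.random.default_rng(0)
        net_gd = np.column_stack([z, 2 * z])  # rho_GD = 1
        net_ct = np.column_stack([rng.normal(size=n), rng.normal(size=n)])
        gd = FluxEnsemble(["A", "B"], net_gd, np.abs(net_gd), "GD")
        ctrl = FluxEnsemble(["A", "B"], net_ct, np.abs(net_ct), "control")
        modules = gd_specific_correlations(gd, ctrl, {"A", "B"})
        assert len(modules) == 1 and sorted(modules[0].reactions) == ["A", "B"]

    def test_clustering_invariant_to_reaction_order(self):
        gd, ctrl, rids = self.make_block_ensembles(seed=7)
        perm = [3, 0, 5, 1, 4, 2]
        gd_p = FluxEnsemble(
            [rids[i] for i in perm], gd.net[:, perm], gd.activity[:, perm], "GD"
        )
        ct_p = FluxEnsemble(
            [rids[i] for i in perm], ctrl.net[:, perm], ctrl.activity[:, perm], "control"
        )
        base = sorted(tuple(sorted(m.reactions)) for m in
                      gd_specific_correlations(gd, ctrl, set(rids)))
        permuted = sorted(tuple(sorted(m.reactions)) for m in
                          gd_specific_correlations(gd_p, ct_p, set(rids)))
        assert base == permuted

    def test_gene_lists_attached_from_gprs(self, condition_ensembles, toy_model):
        ctrl, gd = condition_ensembles
        modules = gd_specific_correlations(
            gd, ctrl, set(toy_model.reaction_ids), model=toy_model
        )
        for mod in modules:
            expected = set()
            for rid in mod.reactions:
                expected |= toy_model.reactions[rid].genes
            assert set(mod.genes) == expected

    def test_fewer_than_two_candidates_rejected(self, condition_ensembles):
        ctrl, gd = condition_ensembles
        with pytest.raises(ValueError):
            gd_specific_correlations(gd, ctrl, {"GBA"})


class TestATPContribution:
    def test_fractions_sum_to_one(self, toy_model, setup):
        breakdowns = atp_contribution_sweep(
            toy_model, setup, [20, 30, 44.8], ATP_PATHWAY_TAGS
        )
        for b in breakdowns:
            assert b.feasible
            assert sum(b.fractions()) == pytest.approx(1.0, abs=1e-6)

    def test_closed_atp_synthase_shifts_all_to_other_pathways(self, toy_model, setup):
        closed = toy_model.copy()
        closed.reactions["ATPS4mi"].ub = 0.0
        breakdowns = atp_contribution_sweep(closed, setup, [20], ATP_PATHWAY_TAGS)
        b = breakdowns[0]
        assert b.feasible
        assert b.oxphos == pytest.approx(0.0, abs=1e-9)
        assert b.glycolysis + b.tca == pytest.approx(1.0, abs=1e-6)

    def test_gd_shifts_away_from_oxphos_at_every_level(
        self, toy_model, gd_model, setup
    ):
        levels = [20, 30, 40, 44.8]
        ctrl = atp_contribution_sweep(toy_model, setup, levels, ATP_PATHWAY_TAGS)
        gd = atp_contribution_sweep(gd_model, setup, levels, ATP_PATHWAY_TAGS)
        for c, g in zip(ctrl, gd):
            assert c.feasible and g.feasible
            assert g.oxphos < c.oxphos
            assert g.glycolysis > c.glycolysis

    def test_infeasible_level_reported_and_sweep_continues(self, gd_model, setup):
        breakdowns = atp_contribution_sweep(
            gd_model, setup, [44.8, 500.0, 20.0], ATP_PATHWAY_TAGS
        )
        assert [b.feasible for b in breakdowns] == [True, False, True]

    def test_fractions_invariant_to_common_bound_rescaling(self, toy_model):
        setup = SimulationSetup(atpm_lb=44.8, biomass_lb=3.45)
        scaled = toy_model.copy()
        for rxn in scaled.reactions.values():
            rxn.lb *= 2.0
            rxn.ub *= 2.0
        setup2 = SimulationSetup(atpm_lb=2 * 44.8, biomass_lb=2 * 3.45)
        base = atp_contribution_sweep(toy_model, setup, [30], ATP_PATHWAY_TAGS,
                                      ganglioside_uptake=1.0)[0]
        double = atp_contribution_sweep(scaled, setup2, [60], ATP_PATHWAY_TAGS,
                                        ganglioside_uptake=2.0)[0]
        # the entropy term is not positively homogeneous, so the rescaled
        # entropic solution tracks the original fractions only approximately
        # (exact invariance holds in the linear-objective limit)
        assert base.oxphos == pytest.approx(double.oxphos, abs=0.1)
        assert base.glycolysis == pytest.approx(double.glycolysis, abs=0.1)

    def test_fractions_exactly_invariant_to_flux_rescaling(self, toy_model, setup):
        """The decomposition itself is scale-free: doubling a flux state
        leaves the fractions untouched."""
        from gaucherflux.optimize import entropic_fba

        prepared = setup.apply(toy_model, ganglioside_uptake=1.0, atpm_lb=30.0)
        prepared.reactions["ATPM"].ub = 30.0
        st = entropic_fba(prepared)
        coefs = {
            rid: sum(v for k, v in toy_model.reactions[rid].stoichiometry.items()
                     if k in ("atp[c]", "atp[m]") and v > 0)
            for rid in ATP_PATHWAY_TAGS
        }

        def fractions(scale):
            produced = {}
            for rid, tag in ATP_PATHWAY_TAGS.items():
                produced[tag] = produced.get(tag, 0.0) + max(
                    st.flux(rid) * scale, 0.0
                ) * coefs[rid]
            total = sum(produced.values())
            return {t: p / total for t, p in produced.items()}

        assert fractions(1.0) == pytest.approx(fractions(7.3))

    def test_missing_tagged_reactions_rejected(self, chain_model, setup):
        with pytest.raises(ValueError, match="tagged"):
            atp_contribution_sweep(chain_model, setup, [10], {"NOPE": "glycolysis"})


class TestRobustnessSweep:
    def test_runs_recorded_and_gba_direction_stable(
        self, toy_model, planted_de, setup
    ):
        schemes = [
            ScalingScheme(),
            ScalingScheme(down_factor=0.30, up_factor=1.30),
            ScalingScheme(down_factor=0.70, up_factor=1.70),
        ]
        report = robustness_sweep(
            toy_model, planted_de, schemes, uptake_levels=[0.1, 1.0],
            setup=setup, n_instances=5, seed=17,
        )
        assert report["n_runs"] == 6
        assert report["direction_agreement"]["GBA"] == 1.0

    def test_empty_grid_rejected(self, toy_model, planted_de, setup):
        with pytest.raises(ValueError):
            robustness_sweep(toy_model, planted_de, [], [1.0], setup=setup)
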