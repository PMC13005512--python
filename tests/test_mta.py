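"""Knockout transformation scoring and modifier-gene ranking."""

import numpy as np
import pytest

from gaucherflux.mta import (
    TransformationTarget,
    derive_transformation_targets,
    rank_modifier_genes,
    score_knockout,
)
from gaucherflux.optimize import entropic_fba
from gaucherflux.synthetic import simulate_activity_ensembles


class TestTargets:
    def test_source_equals_target_puts_everything_in_steady(self):
        ens, _ = simulate_activity_ensembles(30, 10, seed=1)
        targets = derive_transformation_targets(ens, ens)
        assert targets.r_forward == set()
        assert targets.r_backward == set()
        assert targets.r_steady == set(ens.reaction_ids)

    def test_planted_perturbations_partitioned_correctly(self):
        src, tgt = simulate_activity_ensembles(
            60, 30, seed=2, planted_fold={3: 5.0, 9: 0.2}, sd_log2=0.2
        )
        targets = derive_transformation_targets(src, tgt)
        # net sign is random per reaction; direction follows the net means
        net_gap = tgt.mean_net() - src.mean_net()
        assert ("R0003" in targets.r_forward) == (net_gap[3] > 0)
        assert ("R0009" in targets.r_forward) == (net_gap[9] > 0)
        assert {"R0003", "R0009"} & targets.r_steady == set()

    def test_partition_covers_all_reactions_without_overlap(self):
        src, tgt = simulate_activity_ensembles(40, 12, seed=3, planted_fold={1: 4.0})
        t = derive_transformation_targets(src, tgt)
        union = t.r_forward | t.r_backward | t.r_steady
        assert union == set(src.reaction_ids)
        assert not (t.r_forward & t.r_backward)

    def test_invalid_partition_rejected(self):
        with pytest.raises(ValueError, match="disjoint|partition"):
            TransformationTarget(
                reaction_ids=["a", "b"],
                r_forward={"a"}, r_backward={"a"}, r_steady={"b"},
                source_mean=np.zeros(2), target_mean=np.zeros(2),
            )

    def test_mismatched_columns_rejected(self):
        a, _ = simulate_activity_ensembles(5, 6, seed=0)
        b, _ = simulate_activity_ensembles(6, 6, seed=0)
        with pytest.raises(ValueError):
            derive_transformation_targets(a, b)


class TestScoreKnockout:
    def test_noop_knockout_scores_zero(self):
        """A gene rescued by an OR isozyme leaves fluxes untouched, so all
        score components vanish."""
        from gaucherflux.model import MetabolicModel, Reaction

        m = MetabolicModel("noop")
        m.add_reaction(Reaction("EX_a", {"a[e]": -1}, -10, 0))
        m.add_reaction(Reaction("R", {"a[e]": -1, "b[c]": 1}, 0, 1000, gpr="G1 or G2"))
        m.add_reaction(Reaction("EX_b", {"b[c]": -1}, 0, 1000))
        state = entropic_fba(m, {"EX_b": 1.0})
        rids = m.reaction_ids
        targets = TransformationTarget(
            reaction_ids=rids,
            r_forward=set(), r_backward=set(), r_steady=set(rids),
            source_mean=state.v, target_mean=state.v,
        )
        score = score_knockout(m, "G1", state, targets)
        assert score.feasible
        assert score.wts == pytest.approx(0.0, abs=1e-6)
        assert score.rts == pytest.approx(0.0, abs=1e-6)

    def test_unknown_gene_rejected(self, control_prepared):
        ens, _ = simulate_activity_ensembles(3, 6, seed=0)
        with pytest.raises(KeyError):
            score_knockout(control_prepared, "NOPE", np.zeros(3), None)

    def test_source_equals_target_never_scores_positive(
        self, toy_model, setup, condition_ensembles
    ):
        """With no required movement, only the steady penalty can fire."""
        ctrl, _ = condition_ensembles
        model = setup.apply(toy_model, ganglioside_uptake=1.0)
        table = rank_modifier_genes(model, ctrl, ctrl, direction="self")
        feasible = table[table["feasible"]]
        assert (feasible["wTS"] <= 1e-9).all()
        assert (feasible["rTS"] <= 0).all()


class TestRanking:
    def test_planted_modifier_in_top_three_forward(
        self, toy_model, gd_model, setup, condition_ensembles, toy_manifest
    ):
        ctrl, gd = condition_ensembles
        model = setup.apply(toy_model, ganglioside_uptake=1.0)
        table = rank_modifier_genes(model, ctrl, gd, direction="healthy->disease")
        top3 = list(table["gene"].head(3))
        assert toy_manifest["planted_modifier"] in top3
        assert table["rTS"].iloc[0] > 0

    def test_reverse_direction_finds_no_positive_knockout(
        self, gd_model, condition_ensembles
    ):
        ctrl, gd = condition_ensembles
        table = rank_modifier_genes(gd_model, gd, ctrl, direction="disease->healthy")
        feasible = table[table["feasible"]]
        assert (feasible["rTS"] <= 0).all()

    def test_ranking_equals_exhaustive_scoring(
        self, toy_model, setup, condition_ensembles
    ):
        """The ranking performs no pruning: it equals scoring every gene."""
        from gaucherflux.mta import TransformationTarget
        from gaucherflux.optimize import moma

        ctrl, gd = condition_ensembles
        model = setup.apply(toy_model, ganglioside_uptake=1.0)
        table = rank_modifier_genes(model, ctrl, gd, direction="fwd")
        col = {r: j for j, r in enumerate(ctrl.reaction_ids)}
        v_src = np.array([ctrl.mean_net()[col[r]] for r in model.reaction_ids])
        t_mean = np.array([gd.mean_net()[col[r]] for r in model.reaction_ids])
        v_src = moma(model, v_src).v
        base = derive_transformation_targets(ctrl, gd)
        delta = np.maximum(1e-6, 0.1 * np.abs(t_mean - v_src))
        targets = TransformationTarget(
            reaction_ids=list(model.reaction_ids),
            r_forward=base.r_forward & set(model.reaction_ids),
            r_backward=base.r_backward & set(model.reaction_ids),
            r_steady=set(model.reaction_ids) - base.r_forward - base.r_backward,
            source_mean=v_src, target_mean=t_mean, delta=delta,
        )
        for gene in list(model.genes)[:8]:
            direct = score_knockout(model, gene, v_src, targets)
            row = table[table["gene"] == gene].iloc[0]
            if direct.feasible:
                assert row["rTS"] == pytest.approx(direct.rts, abs=1e-9)
            else:
                assert not row["feasible"]

    def test_infeasible_knockouts_ranked_last(
        self, toy_model, setup, condition_ensembles
    ):
        ctrl, gd = condition_ensembles
        model = setup.apply(toy_model, ganglioside_uptake=1.0)
        table = rank_modifier_genes(model, ctrl, gd, direction="fwd")
        flags = list(table["feasible"])
        assert flags == sorted(flags, reverse=True)
        # lethal knockouts exist on the toy network (e.g. sole ATP synthase)
        assert not table[table["gene"] == "ATP5F1A"]["feasible"].iloc[0]

    def test_steady_duplicate_with_zero_flux_does_not_change_score(self):
        """Adding a zero-flux steady reaction leaves rTS untouched."""
        from gaucherflux.model import MetabolicModel, Reaction

        m = MetabolicModel("dup")
        m.add_reaction(Reaction("EX_a", {"a[e]": -1}, -10, 0))
        m.add_reaction(Reaction("R1", {"a[e]": -1, "b[c]": 1}, 0, 1000, gpr="G1"))
        m.add_reaction(Reaction("R2", {"a[e]": -1, "b[c]": 1}, 0, 6, gpr="G2"))
        m.add_reaction(Reaction("EX_b", {"b[c]": -1}, 1, 1000))
        state = entropic_fba(m, {"EX_b": 1.0})
        rids = m.reaction_ids
        targets = TransformationTarget(
            reaction_ids=rids, r_forward=set(), r_backward={"R1"},
            r_steady=set(rids) - {"R1"},
            source_mean=state.v, target_mean=state.v,
        )
        s1 = score_knockout(m, "G1", state, targets)

        m2 = m.copy()
        m2.add_reaction(Reaction("DUP", {"a[e]": -1, "b[c]": 1}, 0, 0, gpr="G3"))
        state2 = entropic_fba(m2, {"EX_b": 1.0})
        targets2 = TransformationTarget(
            reaction_ids=m2.reaction_ids, r_forward=set(), r_backward={"R1"},
            r_steady=set(m2.reaction_ids) - {"R1"},
            source_mean=state2.v, target_mean=state2.v,
        )
        s2 = score_knockout(m2, "G1", state2, targets2)
        assert s1.rts == pytest.approx(s2.rts, abs=1e-6)

    def test_empty_gene_list_rejected(self, condition_ensembles):
        from gaucherflux.model import MetabolicModel, Reaction

        ctrl, gd = condition_ensembles
        m = MetabolicModel("nogenes")
        m.add_reaction(Reaction("R", {"a[c]": -1, "b[c]": 1}, 0, 1))
        with pytest.raises(ValueError):
            rank_modifier_genes(m, ctrl, gd)
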