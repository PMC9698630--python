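import math

import numpy as np
import pandas as pd
import pytest

from rapaflux import gsmm, synthgen
from rapaflux.exceptions import (ConfigurationError, NamedEntityError,
                                 NormalizationError, ParameterError,
                                 SchemaError)
from rapaflux.gsmm import (FluxDistribution, MetabolicModel, Reaction,
                           apply_experimental_constraints, f_ph, fba, moma,
                           read_model, simulate_knockout,
                           simulate_overexpression, screen_targets,
                           steady_state_residual, write_model)

from .conftest import make_random_network
from .oracles import slsqp_qp, vertex_enumeration_lp


def model_from_matrix(S, lb, ub, objective=None, names=None):
    n_mets, n_rxns = S.shape
    mets = {f"x{i}": f"x{i}" for i in range(n_mets)}
    rxns = {}
    for j in range(n_rxns):
        rid = names[j] if names else f"v{j}"
        stoich = {f"x{i}": float(S[i, j]) for i in range(n_mets) if S[i, j]}
        rxns[rid] = Reaction(rid, rid, stoich, float(lb[j]), float(ub[j]),
                             reversible=lb[j] < 0)
    return MetabolicModel(metabolites=mets, reactions=rxns,
                          objective_id=objective or list(rxns)[-1])


def diamond_model():
    """r1: -> A; r2, r3: A -> B; r4: B -> (all bounds [0, 20])."""
    S = np.array([[1, -1, -1, 0],
                  [0, 1, 1, -1]], float)
    return model_from_matrix(S, np.zeros(4), np.full(4, 20.0),
                             objective="v3", names=["v0", "v1", "v2", "v3"])


class TestModelIO:
    def test_round_trip(self, tmp_path, toy_model):
        path = tmp_path / "model.json"
        write_model(toy_model, path)
        assert read_model(path) == toy_model

    def test_inverted_bounds_rejected(self, tmp_path, toy_model):
        bad = toy_model.copy()
        bad.reactions["PGI"].lower_bound = 5.0
        bad.reactions["PGI"].upper_bound = -5.0
        with pytest.raises(SchemaError, match="PGI"):
            write_model(bad, tmp_path / "m.json")

    def test_undeclared_metabolite_rejected(self):
        m = MetabolicModel(
            metabolites={"a": "a"},
            reactions={"r": Reaction("r", "r", {"ghost": -1.0})},
            objective_id="r")
        with pytest.raises(SchemaError, match="ghost"):
            m.validate()


class TestExperimentalConstraints:
    def test_measured_bounds_applied(self, toy_model):
        m = apply_experimental_constraints(toy_model)
        assert m.reactions["EX_glc"].upper_bound == 1.08
        assert m.reactions["EX_nh3"].upper_bound == 0.132
        assert m.reactions["EX_pi"].upper_bound == 0.0074
        assert m.reactions["EX_rapa"].lower_bound == pytest.approx(2.1e-5)

    def test_idempotent(self, toy_model):
        once = apply_experimental_constraints(toy_model)
        twice = apply_experimental_constraints(once)
        assert once == twice

    def test_missing_exchange_is_configuration_error(self, toy_model):
        broken = toy_model.copy()
        del broken.reactions["EX_nh3"]
        with pytest.raises(ConfigurationError, match="EX_nh3"):
            apply_experimental_constraints(broken)


class TestFBA:
    def test_linear_chain(self):
        # EX_A (ub 10) -> A -> B -> out; objective = terminal drain
        S = np.array([[1, -1, 0],
                      [0, 1, -1]], float)
        m = model_from_matrix(S, np.zeros(3), np.array([10.0, 50.0, 50.0]),
                              objective="v2")
        sol = fba(m)
        assert sol.objective_value == pytest.approx(10.0, abs=1e-9)
        assert np.allclose(sol.fluxes, [10, 10, 10], atol=1e-8)

    def test_closed_exchanges_zero_growth(self, toy_model):
        closed = toy_model.copy()
        for rid, r in closed.reactions.items():
            if rid.startswith("EX_"):
                r.lower_bound = 0.0
                r.upper_bound = 0.0
        closed.reactions["ATPM"].lower_bound = 0.0
        sol = fba(closed)
        assert sol.status == "optimal"
        assert abs(sol.objective_value) < 1e-9

    def test_matches_vertex_enumeration_oracle(self):
        hits = 0
        for seed in range(12):
            rng = np.random.default_rng(seed)
            S, lb, ub = make_random_network(rng, n_mets=3, n_rxns=6)
            c = np.zeros(6)
            c[5] = 1.0
            m = model_from_matrix(S, lb, ub, objective="v5")
            sol = fba(m)
            best, _ = vertex_enumeration_lp(S, lb, ub, c)
            assert sol.status == "optimal" and np.isfinite(best)
            assert sol.objective_value == pytest.approx(best, abs=1e-7)
            hits += 1
        assert hits == 12

    def test_objective_dominates_random_feasible_points(self, constrained_model,
                                                        wt_flux):
        """FBA growth beats the growth of 50 random feasible flux states."""
        S, _, rxns = constrained_model.stoichiometric_matrix()
        lb, ub = constrained_model.bounds_arrays()
        obj_idx = rxns.index(constrained_model.objective_id)
        from scipy.optimize import linprog
        rng = np.random.default_rng(0)
        for _ in range(50):
            c = rng.normal(size=len(rxns))
            res = linprog(c, A_eq=S, b_eq=np.zeros(S.shape[0]),
                          bounds=list(zip(lb, ub)), method="highs")
            assert res.status == 0
            assert res.x[obj_idx] <= wt_flux.objective_value + 1e-8

    def test_infeasible_model_reported(self):
        S = np.array([[1.0, -1.0]])
        m = model_from_matrix(S, np.array([5.0, 0.0]), np.array([10.0, 0.0]),
                              objective="v0")
        assert fba(m).status == "infeasible"

    def test_unknown_objective(self, toy_model):
        with pytest.raises(NamedEntityError):
            fba(toy_model, objective_id="nope")


class TestMOMA:
    def test_wild_type_projection_is_identity(self, constrained_model, wt_flux):
        back = moma(constrained_model, wt_flux)
        assert back.status == "optimal"
        dist = float(np.sum((back.fluxes - wt_flux.fluxes) ** 2))
        assert dist < 1e-10

    def test_diamond_knockout_hand_solution(self):
        """v_wt = (10, 6, 4, 10), knock out v1 -> (8, 0, 8, 8), distance 60."""
        m = diamond_model()
        v_wt = FluxDistribution(
            fluxes=pd.Series([10.0, 6.0, 4.0, 10.0],
                             index=["v0", "v1", "v2", "v3"]),
            objective_value=10.0, rapamycin_rate=math.nan, status="optimal")
        mut = simulate_knockout(m, "v1", v_wt)
        assert mut.status == "optimal"
        assert np.allclose(mut.fluxes, [8.0, 0.0, 8.0, 8.0], atol=1e-7)
        dist = float(np.sum((mut.fluxes - v_wt.fluxes) ** 2))
        assert dist == pytest.approx(60.0, abs=1e-6)

    def test_matches_slsqp_oracle_on_random_networks(self):
        checked = 0
        for seed in range(15):
            rng = np.random.default_rng(100 + seed)
            S, lb, ub = make_random_network(rng, n_mets=4, n_rxns=7)
            m = model_from_matrix(S, lb, ub, objective="v6")
            ref = rng.uniform(-5, 5, 7)
            v_ref = FluxDistribution(
                fluxes=pd.Series(ref, index=[f"v{j}" for j in range(7)]),
                objective_value=0.0, rapamycin_rate=math.nan, status="optimal")
            ours = moma(m, v_ref)
            oracle = slsqp_qp(S, lb, ub, ref)
            if ours.status != "optimal" or oracle is None:
                continue
            d_ours = float(np.sum((ours.fluxes.to_numpy() - ref) ** 2))
            d_oracle = float(np.sum((oracle - ref) ** 2))
            assert d_ours <= d_oracle + 1e-6
            checked += 1
        assert checked >= 10

    def test_infeasible_mutant_reported(self):
        m = diamond_model()
        m.reactions["v3"].lower_bound = 5.0  # force production
        v_wt = FluxDistribution(
            fluxes=pd.Series([10.0, 6.0, 4.0, 10.0],
                             index=["v0", "v1", "v2", "v3"]),
            objective_value=10.0, rapamycin_rate=math.nan, status="optimal")
        m.reactions["v1"].upper_bound = 0.0
        m.reactions["v2"].upper_bound = 0.0  # A -> B severed but output forced
        assert moma(m, v_wt).status == "infeasible"

    def test_scale_equivariance(self):
        """Scaling all bounds and the reference by c scales the solution by c."""
        m = diamond_model()
        m.reactions["v1"].upper_bound = 0.0
        ref = np.array([10.0, 6.0, 4.0, 10.0])
        ids = ["v0", "v1", "v2", "v3"]
        def solve(scale):
            ms = m.copy()
            for r in ms.reactions.values():
                r.lower_bound *= scale
                r.upper_bound *= scale
            v = FluxDistribution(fluxes=pd.Series(ref * scale, index=ids),
                                 objective_value=0, rapamycin_rate=math.nan,
                                 status="optimal")
            return moma(ms, v).fluxes.to_numpy()
        assert np.allclose(solve(3.0), 3.0 * solve(1.0), atol=1e-6)

    def test_conservation_residuals(self, constrained_model, wt_flux):
        assert steady_state_residual(constrained_model, wt_flux) < 1e-8
        mut = simulate_knockout(constrained_model, "r279", wt_flux)
        assert steady_state_residual(constrained_model, mut) < 1e-8


class TestPerturbations:
    def test_knockout_of_silent_reaction_is_noop(self, constrained_model,
                                                 wt_flux):
        assert abs(wt_flux["r23"]) < 1e-9
        mut = simulate_knockout(constrained_model, "r23", wt_flux)
        assert f_ph(mut, wt_flux) == pytest.approx(1.0, abs=1e-6)

    def test_glucose_knockout_starves(self, toy_model):
        # with maintenance demands relaxed, losing the sole carbon source
        # zeroes growth instead of making the model infeasible
        m = toy_model.copy()
        m.reactions["ATPM"].lower_bound = 0.0
        wt = fba(m)
        assert wt.objective_value > 0
        mut = simulate_knockout(m, "EX_glc", wt)
        assert mut.status == "optimal"
        assert mut.objective_value < 1e-6

    def test_gdh_knockout_boosts_product(self, constrained_model, wt_flux):
        """Removing NADPH-consuming glutamate dehydrogenase frees reducing
        power for the product pathway."""
        mut = simulate_knockout(constrained_model, "r279", wt_flux)
        assert mut.rapamycin_rate / wt_flux.rapamycin_rate > 1.0

    def test_dahp_synthase_overexpression_boosts_product(
            self, constrained_model, wt_flux):
        mut = simulate_overexpression(constrained_model, "r532", wt_flux)
        assert mut.rapamycin_rate / wt_flux.rapamycin_rate > 1.0

    def test_overexpression_continuity_at_factor_one(self, constrained_model,
                                                     wt_flux):
        mut = simulate_overexpression(constrained_model, "r532", wt_flux,
                                      factor=1.0 + 1e-6)
        assert float(np.max(np.abs(mut.fluxes - wt_flux.fluxes))) < 1e-3

    def test_dead_end_overexpression_infeasible(self, constrained_model,
                                                wt_flux):
        m = constrained_model.copy()
        m.metabolites["orphan"] = "orphan"
        m.reactions["DEAD"] = Reaction("DEAD", "dead end", {"orphan": 1.0},
                                       0.0, 10.0)
        wt = fba(m)
        mut = simulate_overexpression(m, "DEAD", wt)
        assert mut.status == "infeasible"

    def test_factor_must_exceed_one(self, constrained_model, wt_flux):
        with pytest.raises(ParameterError):
            simulate_overexpression(constrained_model, "r532", wt_flux,
                                    factor=0.5)


class TestFPH:
    def make(self, mu, q):
        return FluxDistribution(fluxes=pd.Series(dtype=float),
                                objective_value=mu, rapamycin_rate=q,
                                status="optimal")

    def test_identity(self):
        wt = self.make(0.05, 2e-5)
        for w in (0.0, 0.3, 1.0):
            assert f_ph(wt, wt, w=w) == 1.0

    def test_weight_limits(self):
        wt = self.make(0.05, 2e-5)
        mut = self.make(0.04, 6e-5)
        assert f_ph(mut, wt, w=0.0) == pytest.approx(3.0)
        assert f_ph(mut, wt, w=1.0) == pytest.approx(0.8)

    def test_lethal_knockout_with_growth_only_weight(self):
        wt = self.make(0.05, 2e-5)
        dead = self.make(0.0, 2e-5)
        assert f_ph(dead, wt, w=1.0) == 0.0

    def test_geometric_variant(self):
        wt = self.make(0.05, 2e-5)
        mut = self.make(0.025, 8e-5)
        assert f_ph(mut, wt, w=0.5, variant="geometric") == pytest.approx(
            math.sqrt(0.5 * 4.0))

    def test_nonpositive_wild_type_rejected(self):
        wt = self.make(0.0, 2e-5)
        with pytest.raises(NormalizationError):
            f_ph(self.make(0.1, 1e-5), wt)


class TestScreen:
    def test_silent_candidate_scores_exactly_one(self, constrained_model):
        scores = screen_targets(constrained_model, [("r23", "knockout")])
        assert len(scores) == 1
        assert scores[0].f_ph == pytest.approx(1.0, abs=1e-6)

    def test_top_k_not_padded(self, constrained_model):
        scores = screen_targets(constrained_model,
                                [("r23", "knockout"), ("r18", "knockout")],
                                top_k=10)
        assert len(scores) == 2

    def test_empty_candidates_rejected(self, constrained_model):
        with pytest.raises(ParameterError):
            screen_targets(constrained_model, [])

    def test_ranking_sorted_and_deterministic(self, constrained_model):
        cands = synthgen.DEFAULT_SCREEN_CANDIDATES
        a = screen_targets(constrained_model, cands)
        b = screen_targets(constrained_model, cands)
        assert [s.reaction_id for s in a] == [s.reaction_id for s in b]
        fs = [s.f_ph for s in a]
        assert fs == sorted(fs, reverse=True)
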