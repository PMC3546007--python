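import numpy as np
import pandas as pd
import pytest

from spineplan import (
    DesignSpace,
    build_design_space,
    centered_l2_discrepancy,
    encode_config,
    fit_surrogate,
    index_patient_fixture,
    load_published_strategies,
    load_weight_profiles,
    make_context,
    minimize_phi,
    phi,
    predict_descriptors,
    run_batch,
    summarize_strategies,
    uniform_design,
)
from spineplan.design_opt import (
    RESPONSE_FIELDS,
    ConfigurationError,
    FitError,
    ResponseTable,
    SurrogateModel,
    codes_of_config,
    codes_to_unit,
    decode_codes,
)


@pytest.fixture(scope="module")
def space():
    return build_design_space()


@pytest.fixture(scope="module")
def small_space():
    return DesignSpace(
        uiv_levels=("T3", "T4"), liv_levels=("L1", "L2"),
        density_levels=("every", "ends_apex"), type_levels=("screw",),
        rod_thoracic_levels=(10.0, 30.0), rod_lumbar_levels=(30.0,))


def _synthetic_surrogate(space, seed=0, scale=10.0):
    """Surrogate with known linear coefficients (intercepts near preop)."""
    rng = np.random.default_rng(seed)
    coef = np.vstack([
        rng.uniform(10.0, 60.0, len(RESPONSE_FIELDS)),   # intercepts
        rng.uniform(-scale, scale, (6, len(RESPONSE_FIELDS))),
    ])
    return SurrogateModel(
        coef=pd.DataFrame(coef, index=["intercept"] + [f"x{j}" for j in range(6)],
                          columns=list(RESPONSE_FIELDS)),
        diagnostics=pd.DataFrame(index=list(RESPONSE_FIELDS)),
        space=space)


class TestDesignSpace:
    def test_default_cardinality(self, space):
        assert space.cardinality == 4 * 6 * 3 * 2 * 3 * 3 == 1296

    def test_infeasible_pair_rejected(self):
        with pytest.raises(ConfigurationError):
            build_design_space({"uiv_levels": ["T10"], "liv_levels": ["T5"]})

    def test_every_grid_point_decodes_and_reencodes(self, space):
        rng = np.random.default_rng(2)
        codes = space.enumerate_codes()
        for row in codes[rng.choice(len(codes), 120, replace=False)]:
            config = decode_codes(row, space)
            config.validate()
            assert np.array_equal(codes_of_config(config, space), row)

    def test_unit_encoding_bounds_and_midpoint(self, space):
        lowest = decode_codes(np.zeros(6, dtype=int), space)
        assert np.allclose(encode_config(lowest, space), -1.0)
        highest = decode_codes(np.array(space.level_counts) - 1, space)
        assert np.allclose(encode_config(highest, space), 1.0)
        mid = codes_to_unit(np.array([[0, 0, 1, 0, 1, 1]]), space)[0]
        assert mid[2] == 0.0 and mid[4] == 0.0 and mid[5] == 0.0


class TestUniformDesign:
    def test_default_702_runs_distinct_balanced(self, space):
        dm = uniform_design(space, 702, seed=0)
        assert dm.n_runs == 702
        assert len(np.unique(dm.codes, axis=0)) == 702
        for j, q in enumerate(space.level_counts):
            counts = np.bincount(dm.codes[:, j], minlength=q)
            assert counts.min() >= 702 // q
            assert counts.max() <= -(-702 // q)
        for row in dm.codes[::97]:
            decode_codes(row, space).validate()

    def test_full_enumeration_when_n_equals_cardinality(self, small_space):
        dm = uniform_design(small_space, small_space.cardinality, seed=0)
        assert len(np.unique(dm.codes, axis=0)) == small_space.cardinality

    def test_oversized_request_rejected(self, small_space):
        with pytest.raises(ConfigurationError):
            uniform_design(small_space, small_space.cardinality + 1)

    def test_beats_random_designs_on_discrepancy(self, space):
        dm = uniform_design(space, 96, seed=5)
        rng = np.random.default_rng(5)
        rand = [centered_l2_discrepancy(
            np.column_stack([rng.integers(0, q, 96) for q in space.level_counts]),
            space.level_counts) for _ in range(50)]
        assert dm.discrepancy <= np.mean(rand)

    def test_seeded_and_deterministic(self, space):
        a = uniform_design(space, 60, seed=3)
        b = uniform_design(space, 60, seed=3)
        assert np.array_equal(a.codes, b.codes)


class TestSurrogate:
    def test_exact_recovery_of_noiseless_linear_responses(self, space):
        rng = np.random.default_rng(1)
        dm = uniform_design(space, 60, seed=1)
        X = dm.encoded()
        truth = rng.uniform(-5, 5, (7, len(RESPONSE_FIELDS)))
        Y = np.column_stack([np.ones(len(X))]) @ truth[:1] + X @ truth[1:]
        rows = []
        for r in range(len(X)):
            rec = {f"code{j}": int(c) for j, c in enumerate(dm.codes[r])}
            rec.update({f"x{j}": X[r, j] for j in range(6)})
            rec.update({k: Y[r, i] for i, k in enumerate(RESPONSE_FIELDS)})
            rec.update({"converged": True, "F": 7})
            rows.append(rec)
        rt = ResponseTable(table=pd.DataFrame(rows), space=space)
        sm = fit_surrogate(rt)
        assert np.abs(sm.coef.to_numpy() - truth).max() < 1e-8
        # fitted values reproduce the design-point responses exactly
        pred = sm.predict_matrix(X)
        assert np.abs(pred - Y).max() < 1e-8
        assert np.all(sm.diagnostics["r2"] > 1.0 - 1e-12)

    def test_constant_variable_is_named_in_rank_error(self, space):
        dm = uniform_design(space, 60, seed=1)
        X = dm.encoded().copy()
        X[:, 3] = 0.0  # implant type held constant
        rows = []
        for r in range(len(X)):
            rec = {f"x{j}": X[r, j] for j in range(6)}
            rec.update({k: 1.0 for k in RESPONSE_FIELDS})
            rec.update({"converged": True, "F": 7})
            rows.append(rec)
        rt = ResponseTable(table=pd.DataFrame(rows), space=space)
        with pytest.raises(FitError, match="implant_type"):
            fit_surrogate(rt)

    def test_negative_nonnegative_predictions_are_clamped(self, space):
        sm = _synthetic_surrogate(space, seed=4)
        sm.coef.loc["intercept", "theta_PT"] = -30.0
        sm.coef.loc[[f"x{j}" for j in range(6)], "theta_PT"] = 0.0
        config = decode_codes(np.zeros(6, dtype=int), space)
        d = predict_descriptors(sm, config)
        assert d.theta_PT == 0.0
        assert d.F == 17 - config.fused_levels


@pytest.fixture(scope="module")
def ctx():
    pre = __import__("spineplan").compute_all(index_patient_fixture())
    return make_context(pre, 35.0, 50.0, F0=10)


class TestMinimizePhi:

    def test_matches_brute_force_enumeration(self, space, ctx):
        sm = _synthetic_surrogate(space, seed=7)
        w = load_weight_profiles()[0]
        opt = minimize_phi(sm, ctx, w, space)
        # independent brute force over the whole grid
        best = None
        for row in space.enumerate_codes():
            config = decode_codes(row, space)
            val = phi(predict_descriptors(sm, config, space), ctx, w)
            if best is None or val < best[0] - 1e-15:
                best = (val, row)
        assert opt.predicted_phi == pytest.approx(best[0], rel=1e-12)
        assert opt.continuous_phi <= opt.predicted_phi + 1e-9

    def test_dominates_design_matrix_rows(self, space, ctx):
        sm = _synthetic_surrogate(space, seed=8)
        w = load_weight_profiles()[2]
        opt = minimize_phi(sm, ctx, w, space)
        dm = uniform_design(space, 96, seed=8)
        for row in dm.codes[::7]:
            config = decode_codes(row, space)
            val = phi(predict_descriptors(sm, config, space), ctx, w)
            assert opt.predicted_phi <= val + 1e-12

    def test_mobility_only_profile_picks_shortest_fusion(self, space, ctx):
        from spineplan.objective import WeightProfile

        w = WeightProfile(surgeon_id="mob", W1=0, W2=0, W3=0, W4=100,
                          a1=25, a2=25, a3=25, a4=25, b1=50, b2=50,
                          c1=20, c2=20, c3=20, c4=20, c5=10, c6=10)
        sm = _synthetic_surrogate(space, seed=9)
        opt = minimize_phi(sm, ctx, w, space)
        assert opt.config.uiv == "T5" and opt.config.liv == "T11"


class TestBatch:
    def test_small_batch_shape_contract(self, index_model, small_space):
        dm = uniform_design(small_space, 6, seed=2)
        rt = run_batch(index_model, dm)
        assert len(rt.table) == 6
        assert set(RESPONSE_FIELDS) <= set(rt.table.columns)
        assert rt.table["converged"].dtype == bool
        conv = rt.converged_rows()
        assert conv[list(RESPONSE_FIELDS)].notna().all().all()


class TestSummaries:
    def test_published_strategy_table_statistics(self):
        t2 = load_published_strategies()
        s = summarize_strategies(t2)
        assert s.loc["n_fused_levels", "mean_printed"] == 11.2
        assert s.loc["n_fused_levels", "sd_printed"] == 2.1
        assert s.loc["n_implants", "sd_printed"] == 1.4
        assert s.loc["n_implants", "min"] == 8 and s.loc["n_implants", "max"] == 13

    def test_single_row_degenerates_cleanly(self):
        df = pd.DataFrame({"n_fused_levels": [10]})
        s = summarize_strategies(df)
        assert s.loc["n_fused_levels", "sd_population"] == 0.0
        assert s.loc["n_fused_levels", "min"] == s.loc["n_fused_levels", "max"] == 10

    def test_empty_table_rejected(self):
        with pytest.raises(Exception):
            summarize_strategies(pd.DataFrame())
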