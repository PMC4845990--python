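"""Flux balance, model variants, matching condition, uncertainty."""

import numpy as np
import pytest
from dataclasses import replace

from tebmodel.elongation import (
    ModelConfig,
    RegionParams,
    TEBElongationModel,
    balance_residual,
    cap_fraction_from_counts,
    compute_fluxes,
    elongation_rate,
    minimal_delta,
    propagate_uncertainty,
    run_model,
    solve_matching_X,
)
from tebmodel.errors import ConfigError, DataError, FluxError
from tebmodel.geometry import RegionId


def _params(values):
    """values: dict region -> (N, r, d); unspecified regions get N=100, r=d=0."""
    out = []
    for i in range(1, 9):
        n, r, d = values.get(i, (100.0, 0.0, 0.0))
        out.append(RegionParams(RegionId(i), n, r, d))
    return out


def _random_params(rng):
    return [
        RegionParams(
            RegionId(i),
            N=float(rng.integers(50, 400)),
            r_per_h=float(rng.uniform(0.0, 0.05)),
            d_per_h=float(rng.uniform(0.0, 0.01)),
        )
        for i in range(1, 9)
    ]


class TestBalance:
    def test_zero_everything(self):
        p = RegionParams(RegionId(1), 100, 0.0, 0.0)
        assert balance_residual(p, 0.0, 0.0) == 0.0

    def test_production_exits_downstream(self):
        p = RegionParams(RegionId(1), 100, 0.01, 0.0)
        assert balance_residual(p, 0.0, 1.0) == 0.0

    @pytest.mark.parametrize("seed", range(5))
    def test_residuals_vanish_for_computed_fluxes(self, seed):
        rng = np.random.default_rng(seed)
        params = _random_params(rng)
        cfg = ModelConfig(21.5, 7.0, delta=0.5, X=0.4, T=1.3)
        res = TEBElongationModel(params, cfg).fit(variant=4)
        for resid in res.residuals().values():
            assert resid == pytest.approx(0.0, abs=1e-9)


class TestFluxes:
    def test_linear_sum(self):
        params = _params({1: (100, 0.01, 0.0), 2: (200, 0.01, 0.0), 3: (300, 0.01, 0.0)})
        f = compute_fluxes(params, ModelConfig(21.5, 7.0, X=0.0))
        assert f.phi_basal == pytest.approx(6.0)

    def test_all_rates_zero(self):
        f = compute_fluxes(_params({}), ModelConfig(21.5, 7.0))
        assert f.phi_basal == f.phi_luminal == f.phi_bas_to_lum == 0.0
        assert all(v == 0.0 for v in f.chain.values())

    def test_leak_conserves_total_cells(self):
        rng = np.random.default_rng(0)
        params = _random_params(rng)
        cfg0 = ModelConfig(21.5, 7.0, X=0.0)
        cfg1 = ModelConfig(21.5, 7.0, X=0.6)
        f0, f1 = compute_fluxes(params, cfg0), compute_fluxes(params, cfg1)
        # the leak moves cells between layers without creating or destroying any
        assert f0.phi_basal + f0.phi_luminal == pytest.approx(f1.phi_basal + f1.phi_luminal)
        assert f0.phi_basal - f1.phi_basal == pytest.approx(f1.phi_bas_to_lum)

    def test_negative_net_flux_flagged_not_raised(self):
        params = _params({1: (100, 0.0, 0.01)})
        f = compute_fluxes(params, ModelConfig(21.5, 7.0))
        assert f.shrinking_layer


class TestElongationRate:
    def test_unit_conversion(self):
        # 1 cell/h of 2 um cells extends one monolayer side by 1 um/h = 0.024 mm/day
        assert elongation_rate(1.0, 2.0) == pytest.approx(0.024)

    def test_zero_flux(self):
        assert elongation_rate(0.0, 21.5) == 0.0


class TestVariants:
    def test_nesting_identities(self, region_params):
        cfg = ModelConfig(21.5, 7.0, delta=0.97, X=0.54, T=1.31)
        m1 = run_model(region_params, replace(cfg, X=0.0), 2)
        base = run_model(region_params, cfg, 1)
        assert (m1.lambda_basal, m1.lambda_luminal) == (base.lambda_basal, base.lambda_luminal)
        m2 = run_model(region_params, replace(cfg, delta=0.0), 3)
        m2_ref = run_model(region_params, cfg, 2)
        assert (m2.lambda_basal, m2.lambda_luminal) == (m2_ref.lambda_basal, m2_ref.lambda_luminal)
        m3 = run_model(region_params, replace(cfg, T=1.0), 4)
        m3_ref = run_model(region_params, cfg, 3)
        assert m3.lambda_basal == pytest.approx(m3_ref.lambda_basal)
        assert m3.lambda_luminal == pytest.approx(m3_ref.lambda_luminal)

    def test_variant4_is_variant3_over_T(self, region_params):
        cfg = ModelConfig(21.5, 7.0, delta=0.97, X=0.54, T=1.31)
        v3 = run_model(region_params, cfg, 3)
        v4 = run_model(region_params, cfg, 4)
        assert v4.lambda_basal == pytest.approx(v3.lambda_basal / 1.31)
        assert v4.lambda_luminal == pytest.approx(v3.lambda_luminal / 1.31)

    def test_missing_config_names_symbol(self, region_params):
        with pytest.raises(ConfigError, match="X"):
            run_model(region_params, ModelConfig(21.5, 7.0), 2)
        with pytest.raises(ConfigError, match="delta"):
            run_model(region_params, ModelConfig(21.5, 7.0, X=0.5), 3)
        with pytest.raises(ConfigError, match="T"):
            run_model(region_params, ModelConfig(21.5, 7.0, X=0.5, delta=0.9), 4)

    def test_monotone_in_X_and_T(self, region_params):
        lams_b, lams_l = [], []
        for x in (0.0, 0.25, 0.5, 0.75, 1.0):
            est = run_model(region_params, ModelConfig(21.5, 7.0, X=x), 2)
            lams_b.append(est.lambda_basal)
            lams_l.append(est.lambda_luminal)
        assert all(a >= b for a, b in zip(lams_b, lams_b[1:]))
        assert all(a <= b for a, b in zip(lams_l, lams_l[1:]))
        prev = np.inf
        for t in (1.0, 1.2, 1.5, 2.0):
            est = run_model(region_params, ModelConfig(21.5, 7.0, X=0.3, delta=0.5, T=t), 4)
            assert est.lambda_basal <= prev
            prev = est.lambda_basal


class TestMatching:
    def test_already_matched_at_zero(self):
        # l_bas * Phi_bas == l_lum * Phi_lum with no death: X must be 0
        params = _params({1: (100, 0.01, 0.0), 5: (100, 0.02, 0.0)})
        cfg = ModelConfig(cell_length_basal_um=14.0, cell_length_luminal_um=7.0)
        x, in_range = solve_matching_X(params, cfg)
        assert x == pytest.approx(0.0, abs=1e-12)
        assert in_range

    @pytest.mark.parametrize("seed", range(5))
    def test_solution_reinjection_matches_layers(self, seed):
        rng = np.random.default_rng(100 + seed)
        params = _random_params(rng)
        cfg = ModelConfig(21.5, 7.0, delta=0.97, donor_regions=(1, 2))
        x, in_range = solve_matching_X(params, cfg)
        if not in_range:
            pytest.skip("unbounded matching solution for this draw")
        est = run_model(params, replace(cfg, X=x), 3)
        assert abs(est.lambda_basal - est.lambda_luminal) < 1e-10

    def test_zero_production_raises(self):
        with pytest.raises(FluxError):
            solve_matching_X(_params({}), ModelConfig(21.5, 7.0))

    def test_out_of_range_solution_is_clipped_and_flagged(self):
        # enormous luminal flux: matching would need X > 1
        params = _params({1: (10, 0.001, 0.0), 5: (1000, 0.05, 0.0)})
        x, in_range = solve_matching_X(params, ModelConfig(21.5, 21.5))
        assert not in_range
        assert x == 0.0  # clipped at the lower bound (negative solution)


class TestDelta:
    @pytest.mark.parametrize(
        "measured,corrected,expected",
        [(0.05, 0.05, 0.0), (0.11 / 2.55, 0.085, 0.97), (0.04, 0.08, 1.0)],
    )
    def test_minimal_delta(self, measured, corrected, expected):
        assert round(minimal_delta(measured, corrected), 2) == expected

    def test_negative_delta_returned_for_smaller_corrected(self):
        assert minimal_delta(0.1, 0.05) < 0

    def test_zero_measured_raises(self):
        with pytest.raises(DataError):
            minimal_delta(0.0, 0.05)


class TestCapFraction:
    def test_zero_resident_cells(self, region_params):
        assert cap_fraction_from_counts({5: 0, 6: 0}, region_params) == 0.0

    def test_recovers_imposed_migration_fraction(self, region_params):
        from tebmodel.simulate import SimTEBConfig, simulate_teb_forward

        x_true = 0.3
        cfg = SimTEBConfig(params=tuple(region_params), X_true=x_true, donor_regions=(1, 2),
                           timestep_h=0.5, horizon_h=400.0, seed=5)
        res = simulate_teb_forward(cfg)
        residence = 8.0
        standing = res.migration_count / res.horizon_h * residence
        x_est = cap_fraction_from_counts({5: standing}, region_params,
                                         donor_regions=(1, 2), residence_time_h=residence)
        assert x_est == pytest.approx(x_true, abs=0.05)

    def test_zero_production_undefined(self):
        with pytest.raises(FluxError):
            cap_fraction_from_counts({5: 10}, _params({}))


class TestUncertainty:
    def test_zero_ses_give_zero_halfwidth(self, region_params):
        est = propagate_uncertainty(region_params, ModelConfig(21.5, 7.0, X=0.0), 1,
                                    n_draws=200, seed=0)
        assert est.lambda_basal_halfwidth == 0.0
        assert est.lambda_luminal_halfwidth == 0.0

    def test_matches_delta_method_for_single_uncertain_input(self):
        # lambda_bas is linear in N_1: output SD must equal |dlam/dN| * se
        se = 5.0
        params = _params({1: (200, 0.02, 0.0)})
        params[0] = replace(params[0], N_se=se)
        cfg = ModelConfig(21.5, 7.0, X=0.0)
        est = propagate_uncertainty(params, cfg, 1, n_draws=20000, seed=1)
        dlam_dN = 0.02 * 21.5 / 2 * 0.024
        assert est.lambda_basal_halfwidth == pytest.approx(dlam_dN * se, rel=0.05)

    def test_doubling_input_se_doubles_output_sd(self):
        params = _params({1: (200, 0.02, 0.0), 2: (150, 0.01, 0.0)})
        cfg = ModelConfig(21.5, 7.0, X=0.0)
        p1 = [replace(p, N_se=p.N * 0.05) for p in params]
        p2 = [replace(p, N_se=p.N * 0.10) for p in params]
        e1 = propagate_uncertainty(p1, cfg, 1, n_draws=5000, seed=2)
        e2 = propagate_uncertainty(p2, cfg, 1, n_draws=5000, seed=2)
        assert e2.lambda_basal_halfwidth / e1.lambda_basal_halfwidth == pytest.approx(2.0, rel=0.1)


class TestModelFrontEnd:
    def test_from_dataframe_roundtrip(self, region_params, config):
        import pandas as pd

        df = pd.DataFrame(
            [dict(region=p.region.index, N=p.N, r_per_h=p.r_per_h, d_per_h=p.d_per_h)
             for p in region_params]
        )
        m = TEBElongationModel.from_dataframe(df, config)
        direct = TEBElongationModel(region_params, config)
        assert m.fit(variant=3).lambda_basal == direct.fit(variant=3).lambda_basal

    def test_param_file_roundtrip(self, tmp_path, config):
        doc = """
cell_length_basal_um: 21.5
cell_length_luminal_um: 7.0
delta: 0.97
X: 0.54
T: 1.31
donor_regions: [1, 2]
regions:
  1: {N: 32, r: 0.0465, d: 0.000125}
  2: {N: 22, r: 0.0399, d: 0.000375}
  3: {N: 57, r: 0.0399, d: 0.000625}
  4: {N: 20, r: 0.0, d: 0.0}
  5: {N: 168, r: 0.0465, d: 0.005}
  6: {N: 166, r: 0.0233, d: 0.006625}
  7: {N: 313, r: 0.0233, d: 0.004375}
  8: {N: 62, r: 0.0, d: 0.0}
"""
        p = tmp_path / "params.yaml"
        p.write_text(doc)
        m = TEBElongationModel.from_param_file(p)
        res = m.fit(variant=4)
        assert res.lambda_basal > 0 and res.lambda_luminal > 0

    def test_summary_mentions_all_parameters(self, region_params, config):
        text = TEBElongationModel(region_params, config).fit(variant=4).summary()
        for token in ("lambda basal", "lambda luminal", "X", "delta", "T (tortuosity)"):
            assert token in text

    def test_solve_x_then_fit_matches_layers(self, region_params):
        cfg = ModelConfig(21.5, 7.0, delta=0.97, T=1.31)
        res = TEBElongationModel(region_params, cfg).fit(variant=3, solve_x=True)
        assert abs(res.lambda_basal - res.lambda_luminal) < 1e-10
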