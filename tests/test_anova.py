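"""ANOVA partition, lack-of-fit decomposition, and the F-tail primitive."""

import numpy as np
import pytest
from scipy.integrate import quad

import rsmkit as rk


@pytest.fixture(scope="module")
def table(cellulase, cellulase_model):
    design, responses = cellulase
    return rk.anova_partition(cellulase_model, design, responses)


class TestCellulaseAnova:
    """The bundled experiment's ANOVA at report precision."""

    def test_model_row(self, table):
        row = table.row("Model")
        assert round(row.ss, 2) == 156.43
        assert row.df == 9
        assert round(row.F, 2) == 53.89
        assert row.p < 1e-4

    @pytest.mark.parametrize(
        "term, ss, F, p",
        [
            ("shaker_speed", 3.95, 12.24, 0.0100),
            ("temperature", 18.00, 55.80, 0.0001),
            ("incubation_time", 4.96, 15.38, 0.0057),
            ("shaker_speed:temperature", 0.02, 0.05, 0.8255),
            ("temperature:incubation_time", 0.44, 1.35, 0.2833),
            ("shaker_speed^2", 60.00, 186.02, None),
            ("temperature^2", 18.83, 58.39, 0.0001),
            ("incubation_time^2", 37.52, 116.31, None),
        ],
    )
    def test_term_rows(self, table, term, ss, F, p):
        row = table.row(term)
        assert round(row.ss, 2) == ss
        assert row.df == 1
        assert round(row.F, 2) == F
        if p is None:
            assert row.p < 1e-4
        else:
            assert round(row.p, 4) == p

    def test_partial_ss_closed_form_for_orthogonal_column(
        self, table, cellulase_model
    ):
        # orthogonal linear column: partial SS = 8 * b^2
        b_A = cellulase_model.b_lin[0]
        assert table.row("shaker_speed").ss == pytest.approx(8 * b_A**2, rel=1e-8)
        assert round(8 * b_A**2, 3) == 3.948

    def test_ss_and_df_conservation(self, table):
        assert table.row("Model").ss + table.row("Residual").ss == pytest.approx(
            table.row("Cor Total").ss, rel=1e-8
        )
        assert table.row("Lack of Fit").ss + table.row("Pure Error").ss == (
            pytest.approx(table.row("Residual").ss, rel=1e-8)
        )
        assert table.row("Model").df + table.row("Residual").df == table.row(
            "Cor Total"
        ).df
        assert (
            table.row("Lack of Fit").df + table.row("Pure Error").df
            == table.row("Residual").df
        )

    def test_lack_of_fit_row(self, table):
        lof = table.row("Lack of Fit")
        pe = table.row("Pure Error")
        assert (round(lof.ss, 2), lof.df) == (1.87, 3)
        assert (round(pe.ss, 2), pe.df) == (0.39, 4)
        assert round(pe.ms, 3) == 0.097
        assert round(lof.F, 2) == 6.42
        assert round(lof.p, 4) == 0.0522

    def test_formatted_table_uses_report_style(self, table):
        fmt = table.formatted()
        model_p = fmt.loc[fmt["term"] == "Model", "p"].iloc[0]
        assert model_p == "<0.0001"


def test_lack_of_fit_from_center_replicates(cellulase, cellulase_model):
    design, responses = cellulase
    lof = rk.lack_of_fit(design, responses, cellulase_model)
    # pure error from the 5 center replicates 10.32/10.68/10.26/10.81/10.98
    center = np.array([10.32, 10.68, 10.26, 10.81, 10.98])
    assert lof.ss_pe == pytest.approx(((center - center.mean()) ** 2).sum())
    assert (lof.df_lof, lof.df_pe) == (3, 4)
    assert round(lof.F, 2) == 6.42


def test_lack_of_fit_requires_replicates(three_factors):
    design = rk.make_bbd(three_factors, n_center=1)
    # perturb the center so all 13 runs are distinct
    coded = design.coded.copy()
    coded[-1] = [0.1, 0.0, 0.0]
    distinct = rk.design_from_settings(three_factors, design.run_ids, coded)
    rng = np.random.default_rng(0)
    responses = rk.ResponseTable(
        {rid: float(v) for rid, v in zip(distinct.run_ids, rng.normal(5, 1, 13))}
    )
    model = rk.fit_quadratic(distinct, responses)
    with pytest.raises(rk.NoReplicatesError):
        rk.lack_of_fit(distinct, responses, model)


def test_zero_noise_data_has_zero_lack_of_fit(concave_truth):
    import dataclasses

    spec = dataclasses.replace(concave_truth, noise_sd=0.0)
    design, responses = rk.simulate_bbd_experiment(spec)
    model = rk.fit_quadratic(design, responses)
    lof = rk.lack_of_fit(design, responses, model)
    assert abs(lof.ss_pe) < 1e-10
    assert abs(lof.ss_lof) < 1e-10


class TestFUpperTail:
    def test_reported_value(self):
        assert round(rk.f_upper_tail(12.24, 1, 7), 4) == 0.0100

    def test_f_zero_gives_one(self):
        assert rk.f_upper_tail(0.0, 3, 4) == 1.0

    def test_negative_f_rejected(self):
        with pytest.raises(ValueError):
            rk.f_upper_tail(-1.0, 1, 1)

    @pytest.mark.parametrize(
        "F, df1, df2",
        [(0.5, 1, 7), (2.3, 3, 4), (6.42, 3, 4), (53.89, 9, 7), (1.0, 10, 10)],
    )
    def test_matches_quadrature_of_f_density(self, F, df1, df2):
        from scipy.special import beta as beta_fn

        d1, d2 = df1, df2

        def density(x):
            return (
                (d1 / d2) ** (d1 / 2)
                * x ** (d1 / 2 - 1)
                * (1 + d1 * x / d2) ** (-(d1 + d2) / 2)
                / beta_fn(d1 / 2, d2 / 2)
            )

        oracle, err = quad(density, F, np.inf, limit=200)
        assert err < 1e-8
        assert rk.f_upper_tail(F, df1, df2) == pytest.approx(oracle, abs=1e-6)

    def test_p_strictly_decreasing_in_f(self):
        fs = np.linspace(0.01, 20, 50)
        ps = [rk.f_upper_tail(f, 3, 7) for f in fs]
        assert np.all(np.diff(ps) < 0)


def test_saturated_model_rejected(three_factors):
    design = rk.make_bbd(three_factors, n_center=1)
    # a full-rank 10-run subset: the fit is saturated (residual df = 0)
    keep = [0, 1, 2, 3, 4, 5, 6, 8, 9, 12]
    sat = rk.design_from_settings(
        three_factors,
        np.array(design.run_ids)[keep],
        design.coded[keep],
    )
    rng = np.random.default_rng(1)
    responses = rk.ResponseTable(
        {rid: float(v) for rid, v in zip(sat.run_ids, rng.normal(size=10))}
    )
    model = rk.fit_quadratic(sat, responses)
    with pytest.raises(rk.anova.NoErrorEstimateError):
        rk.anova_partition(model, sat, responses)
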