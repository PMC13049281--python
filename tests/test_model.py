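"""Bounded L1 fitting: plausibility filter, round trips, batch behaviour."""

import numpy as np
import pandas as pd
import pytest

import ogsekit as ok
from ogsekit.model import GM_INIT, WM_INIT, KurtosisExchangeModel, MKDataset, filter_mk


def make_dataset(operator, params, label="roi", cls="GM"):
    mk = operator.predict_params(params)
    return MKDataset(label, cls, dict(zip(operator.labels, mk)), ground_truth=params)


class TestFilter:
    def test_excludes_values_outside_plausible_range(self):
        kept, removed = filter_mk([0.5, 3.2, -0.1, 1.0])
        assert kept.tolist() == [0.5, 1.0]
        assert removed == 2

    def test_boundaries_are_retained(self):
        kept, removed = filter_mk([0.0, 3.0, 1.5])
        assert kept.tolist() == [0.0, 3.0, 1.5]
        assert removed == 0

    def test_in_range_unchanged(self):
        kept, removed = filter_mk([0.2, 0.9])
        assert removed == 0 and len(kept) == 2

    def test_dataset_rejects_unfiltered_values(self):
        with pytest.raises(ValueError, match="filtered"):
            MKDataset("r", "GM", {"30Hz-N1": 3.5})


class TestFitRoundTrips:
    def test_start_at_noiseless_truth_returns_unchanged(self, operator):
        """Data generated at the WM starting point, fit initialised there:
        zero loss, parameters returned unchanged."""
        ds = make_dataset(operator, WM_INIT, cls="WM")
        fit = ok.fit_roi(ds, operator, init=WM_INIT, n_starts=1)
        assert fit.loss == pytest.approx(0.0, abs=1e-9)
        assert fit.params.as_array() == pytest.approx(WM_INIT.as_array(), rel=1e-6)

    def test_noiseless_gm_median_recovery(self, operator, gm_median):
        """Generate-then-fit round trip from the GM starting point recovers
        the median parameters within 5%."""
        ds = make_dataset(operator, gm_median, cls="GM")
        fit = ok.fit_roi(ds, operator)
        assert fit.params.as_array() == pytest.approx(gm_median.as_array(), rel=0.05)
        assert fit.loss < 1e-6

    def test_single_point_perturbation_bounds_loss_increase(self, operator, gm_median):
        """Perturbing one waveform's MK by +0.1 raises the loss at the
        unperturbed optimum by at most 0.1 (L1 geometry)."""
        model = KurtosisExchangeModel(make_dataset(operator, gm_median), operator)
        theta = gm_median.as_array()
        base = model.loss(theta)
        mk = dict(zip(operator.labels, operator.predict_params(gm_median)))
        mk["60Hz-N1"] += 0.1
        pert = KurtosisExchangeModel(
            MKDataset("roi", "GM", mk), operator
        )
        assert pert.loss(theta) - base <= 0.1 + 1e-12

    def test_estimates_respect_bounds(self, operator, gm_median):
        rng = np.random.default_rng(3)
        mk = operator.predict_params(gm_median) + 0.05 * rng.standard_normal(6)
        ds = MKDataset("noisy", "GM", dict(zip(operator.labels, np.clip(mk, 0, 3))))
        fit = ok.fit_roi(ds, operator)
        for name in ok.PARAM_NAMES:
            lo, hi = ok.PARAM_BOUNDS[name]
            assert lo <= getattr(fit.params, name) <= hi

    def test_loss_never_worse_than_initialization(self, operator, gm_median):
        rng = np.random.default_rng(11)
        mk = operator.predict_params(gm_median) + 0.03 * rng.standard_normal(6)
        ds = MKDataset("noisy", "GM", dict(zip(operator.labels, np.clip(mk, 0, 3))))
        model = KurtosisExchangeModel(ds, operator)
        fit = model.fit()
        init_loss = model.loss(GM_INIT.as_array())
        assert fit.loss <= init_loss + 1e-12

    def test_same_seed_reproduces_bit_identical_estimates(self, operator, gm_median):
        rng = np.random.default_rng(5)
        mk = operator.predict_params(gm_median) + 0.02 * rng.standard_normal(6)
        ds = MKDataset("noisy", "GM", dict(zip(operator.labels, np.clip(mk, 0, 3))))
        f1 = ok.fit_roi(ds, operator, seed=0)
        f2 = ok.fit_roi(ds, operator, seed=0)
        assert f1.params.as_array().tolist() == f2.params.as_array().tolist()


class TestDegeneracy:
    def test_too_few_waveforms_raise(self, protocol):
        sub = protocol.subset(["30Hz-N1", "40Hz-N1", "50Hz-N1", "60Hz-N1"])
        ds = MKDataset("r", "GM", {l: 0.6 for l in sub.labels})
        with pytest.raises(ValueError, match="degenerate"):
            KurtosisExchangeModel(ds, sub)

    def test_four_waveforms_suffice_with_fixed_offset(self, protocol, gm_median):
        sub = protocol.subset(["30Hz-N1", "40Hz-N1", "50Hz-N1", "60Hz-N1"])
        op = ok.ForwardOperator(sub)
        ds = make_dataset(op, gm_median)
        fit = ok.fit_roi(ds, op, fix_k_inf=gm_median.k_inf)
        assert fit.params.k_inf == gm_median.k_inf
        assert fit.loss < 1e-6


class TestBatch:
    def test_tissue_class_selects_initialization(self, operator, gm_median, wm_median):
        datasets = [
            make_dataset(operator, wm_median, "wm_roi", "WM"),
            make_dataset(operator, gm_median, "gm_roi", "GM"),
        ]
        table, fits = ok.batch_fit(datasets, operator)
        assert table.set_index("roi_label").loc["wm_roi", "init_tex_ms"] == WM_INIT.t_ex
        assert table.set_index("roi_label").loc["gm_roi", "init_tex_ms"] == GM_INIT.t_ex

    def test_empty_input_gives_empty_output(self, operator):
        table, fits = ok.batch_fit([], operator)
        assert len(table) == 0 and fits == []

    def test_duplicated_rois_give_identical_estimates(self, operator, gm_median):
        ds = make_dataset(operator, gm_median)
        table, _ = ok.batch_fit([ds, ds], operator)
        a, b = table.iloc[0], table.iloc[1]
        for col in ("tex_ms", "fic", "alpha_d", "alpha_c_sqrt_ms", "k_inf"):
            assert a[col] == b[col]

    def test_per_roi_errors_are_collected_not_raised(self, protocol, operator, gm_median):
        bad = MKDataset("bad", "GM", {"30Hz-N1": 0.6})  # too few waveforms
        good = make_dataset(operator, gm_median, "good")
        table, fits = ok.batch_fit([bad, good], operator)
        assert len(fits) == 1
        assert "degenerate" in table.set_index("roi_label").loc["bad", "error"]


class TestSummary:
    def test_summary_contains_estimates_and_loss(self, operator, gm_median):
        fit = ok.fit_roi(make_dataset(operator, gm_median), operator)
        text = fit.summary()
        assert "t_ex" in text and "L1 loss" in text and "GM" in text
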