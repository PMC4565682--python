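import numpy as np
import pandas as pd
import pytest

from mircross.io_formats import Sample, SampleSheet
from mircross.qpcr import (
    enrichment_impact,
    fit_standard_curve,
    fold_decrease,
    group_compare,
    quantify,
    signed_fold_change,
    spikein_control,
    spikein_normalise,
)


def _curve_points(slope, intercept, decades=range(3, 9)):
    return [(10.0**d, intercept + slope * d) for d in decades]


class TestStandardCurve:
    def test_perfect_efficiency_two(self):
        curve = fit_standard_curve(_curve_points(-3.3219, 40.0), "a")
        assert curve.slope == pytest.approx(-3.3219)
        assert curve.efficiency == pytest.approx(2.0, abs=1e-4)
        assert curve.qc_pass
        assert curve.r_squared == pytest.approx(1.0)

    def test_efficiency_boundary_1_8_passes(self):
        curve = fit_standard_curve(_curve_points(-3.9, 40.0), "a")
        assert curve.efficiency == pytest.approx(1.8, abs=0.01)
        assert curve.qc_pass

    def test_overefficient_curve_fails_qc(self):
        curve = fit_standard_curve(_curve_points(-2.5, 40.0), "a")
        assert curve.efficiency == pytest.approx(2.51, abs=0.01)
        assert not curve.qc_pass

    def test_too_few_dilutions_is_error_and_short_series_warns(self):
        with pytest.raises(ValueError):
            fit_standard_curve(_curve_points(-3.3, 40, decades=[4, 5]))
        with pytest.warns(UserWarning, match="6"):
            fit_standard_curve(_curve_points(-3.3, 40, decades=[4, 5, 6]))

    def test_non_positive_copies_is_error(self):
        with pytest.raises(ValueError):
            fit_standard_curve([(0.0, 40.0), (10.0, 36.7), (100.0, 33.4)])


class TestQuantify:
    def _cq(self, cq_values, assay="a", fraction="total"):
        return pd.DataFrame(
            {
                "sample_id": [f"s{i}" for i in range(len(cq_values))],
                "assay_id": assay,
                "fraction": fraction,
                "replicate": 1,
                "cq": cq_values,
            }
        )

    def test_cq_at_intercept_is_one_copy(self):
        curve = fit_standard_curve(_curve_points(-3.3219, 40.0), "a")
        quant = quantify(self._cq([40.0]), {"a": curve})
        assert quant["raw_copies"].iloc[0] == pytest.approx(1.0)
        assert bool(quant["extrapolated"].iloc[0])  # below curve range

    def test_one_slope_unit_below_intercept_is_ten_copies(self):
        curve = fit_standard_curve(_curve_points(-3.3219, 40.0), "a")
        quant = quantify(self._cq([40.0 - 3.3219]), {"a": curve})
        assert quant["raw_copies"].iloc[0] == pytest.approx(10.0)

    def test_triplicates_averaged_in_cq_domain(self):
        curve = fit_standard_curve(_curve_points(-3.3219, 40.0), "a")
        cq = pd.DataFrame(
            {
                "sample_id": "s0",
                "assay_id": "a",
                "fraction": "total",
                "replicate": [1, 2, 3],
                "cq": [20.0, 21.0, 22.0],
            }
        )
        quant = quantify(cq, {"a": curve})
        assert quant["mean_cq"].iloc[0] == pytest.approx(21.0)
        assert quant["raw_copies"].iloc[0] == pytest.approx(10 ** ((21.0 - 40.0) / -3.3219))

    def test_missing_curve_is_error_and_qc_fail_needs_override(self):
        curve = fit_standard_curve(_curve_points(-2.5, 40.0), "a")
        with pytest.raises(KeyError):
            quantify(self._cq([20.0], assay="b"), {"a": curve})
        with pytest.raises(ValueError, match="QC"):
            quantify(self._cq([20.0]), {"a": curve})
        quantify(self._cq([20.0]), {"a": curve}, allow_qc_fail=True)


class TestSpikeNormalise:
    def _quant(self):
        rows = []
        for i, cq in enumerate([25.0, 26.0, 27.0]):
            rows.append({"sample_id": f"s{i}", "assay_id": "spike", "fraction": "total",
                         "mean_cq": cq, "raw_copies": 1e6, "extrapolated": False})
            rows.append({"sample_id": f"s{i}", "assay_id": "tgt", "fraction": "total",
                         "mean_cq": 20.0, "raw_copies": 1e5, "extrapolated": False})
        return pd.DataFrame(rows)

    def test_median_sample_unchanged_and_one_cycle_doubles(self):
        quant = self._quant()
        spike = spikein_control(quant, "spike")
        out = spikein_normalise(quant, spike, efficiency_spike=2.0)
        tgt = out[out["assay_id"] == "tgt"].set_index("sample_id")
        assert tgt.at["s1", "normalised_copies"] == pytest.approx(1e5)  # spike at median
        assert tgt.at["s2", "normalised_copies"] == pytest.approx(2e5)  # one cycle above
        assert tgt.at["s0", "normalised_copies"] == pytest.approx(5e4)

    def test_missing_spike_row_flagged_not_silent(self):
        quant = self._quant()
        quant = pd.concat(
            [quant, pd.DataFrame([{"sample_id": "s9", "assay_id": "tgt", "fraction": "total",
                                   "mean_cq": 20.0, "raw_copies": 1e5, "extrapolated": False}])],
            ignore_index=True,
        )
        spike = spikein_control(quant, "spike")
        out = spikein_normalise(quant, spike, 2.0)
        s9 = out[(out["sample_id"] == "s9")]
        assert s9["normalised_copies"].isna().all()


class TestFoldChanges:
    def test_enrichment_fold_identity(self):
        assert fold_decrease(5.0, 5.0) == pytest.approx(1.0)

    def test_printed_means_reproduce_fold_decrease(self):
        assert fold_decrease(6.88e7, 5.87e6) == pytest.approx(11.70, abs=0.05)

    def test_signed_fold_change_conventions(self):
        assert signed_fold_change(4.24e7, 7.78e6) == pytest.approx(-5.45, abs=0.005)
        assert signed_fold_change(1.0, 1.0) == pytest.approx(1.0)
        assert signed_fold_change(2.0, 6.0) == pytest.approx(3.0)

    def test_enrichment_impact_on_paired_fractions(self):
        rng = np.random.default_rng(12)
        rows = []
        for i in range(8):
            rows.append({"sample_id": f"s{i}", "assay_id": "a", "fraction": "total",
                         "mean_cq": 20.0, "raw_copies": 1e6 * rng.lognormal(0, 0.1)})
            rows.append({"sample_id": f"s{i}", "assay_id": "a", "fraction": "enriched",
                         "mean_cq": 24.0, "raw_copies": 2e5 * rng.lognormal(0, 0.1)})
        impact = enrichment_impact(pd.DataFrame(rows))
        assert impact["fold_decrease"].iloc[0] == pytest.approx(5.0, rel=0.15)
        assert impact["p"].iloc[0] < 0.01


class TestGroupCompare:
    def test_welch_and_signed_fold_per_assay(self):
        rng = np.random.default_rng(21)
        sheet = SampleSheet(
            [Sample(f"c{i}", "control") for i in range(6)]
            + [Sample(f"x{i}", "case") for i in range(6)]
        )
        rows = []
        for s in sheet.samples:
            level = 1e6 if s.group == "control" else 2.5e5
            rows.append({"sample_id": s.sample_id, "assay_id": "a", "fraction": "enriched",
                         "mean_cq": 20.0, "raw_copies": np.nan,
                         "normalised_copies": level * rng.lognormal(0, 0.05)})
        out = group_compare(pd.DataFrame(rows), sheet)
        row = out.iloc[0]
        assert row["fold_change"] == pytest.approx(-4.0, rel=0.1)
        assert row["p"] < 0.001
        assert row["n_control"] == 6 and row["n_case"] == 6
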