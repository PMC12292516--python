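"""Method-comparison battery against textbook oracles and pingouin."""

import math

import numpy as np
import pytest

import somascan as sm
from somascan.agreement import pooled_sd
from somascan.errors import ArgumentError, SingularFitError, UndefinedStatisticError


def _pairs(ref, cand):
    return list(zip(ref, cand))


class TestBlandAltman:
    def test_identical_methods(self):
        ba = sm.bland_altman(_pairs([1, 2, 3], [1, 2, 3]))
        assert ba.mean_diff == 0 and ba.loa_low == 0 and ba.loa_high == 0

    def test_alternating_differences(self):
        ba = sm.bland_altman(_pairs([0, 0, 0, 0], [1, -1, 1, -1]))
        assert ba.mean_diff == pytest.approx(0.0, abs=1e-12)
        assert ba.sd_diff == pytest.approx(1.1547005384, rel=1e-9)
        assert ba.loa_low == pytest.approx(-2.2632130552, rel=1e-9)
        assert ba.loa_high == pytest.approx(2.2632130552, rel=1e-9)

    def test_constant_offset_collapses_loa(self):
        ba = sm.bland_altman(_pairs([1, 2, 3], [1.7, 2.7, 3.7]))
        assert ba.loa_low == pytest.approx(0.7) and ba.loa_high == pytest.approx(0.7)

    def test_points_are_mean_difference_pairs(self):
        ba = sm.bland_altman(_pairs([1, 3], [2, 5]))
        assert ba.points == ((1.5, 1.0), (4.0, 2.0))

    def test_too_few_pairs(self):
        with pytest.raises(ArgumentError):
            sm.bland_altman([(1, 1)])

    def test_loa_coverage_converges_to_95_percent(self, rng):
        diffs = rng.normal(0.3, 1.2, 5000)
        ref = rng.normal(10, 2, 5000)
        ba = sm.bland_altman(_pairs(ref, ref + diffs))
        inside = np.mean((diffs >= ba.loa_low) & (diffs <= ba.loa_high))
        assert 0.93 < inside < 0.97


class TestIcc:
    def test_perfect_agreement(self):
        p = _pairs([1, 2, 3, 4], [1, 2, 3, 4])
        assert sm.icc(p, "agreement") == pytest.approx(1.0)
        assert sm.icc(p, "consistency") == pytest.approx(1.0)

    def test_constant_offset_anova_oracle(self):
        # hand ANOVA: MSR=2, MSC=1.5, MSE=0 -> C,1 = 1; A,1 = 2/3
        p = _pairs([1, 2, 3], [2, 3, 4])
        assert sm.icc(p, "consistency") == pytest.approx(1.0)
        assert sm.icc(p, "agreement") == pytest.approx(2.0 / 3.0, rel=1e-12)

    def test_independent_noise_gives_zero(self, rng):
        p = _pairs(rng.normal(0, 1, 4000), rng.normal(0, 1, 4000))
        assert abs(sm.icc(p, "agreement")) < 0.06
        assert abs(sm.icc(p, "consistency")) < 0.06

    def test_zero_between_subject_variance(self):
        with pytest.raises(UndefinedStatisticError):
            sm.icc(_pairs([5, 5, 5], [5, 5, 5]))

    def test_consistency_offset_invariance_agreement_penalty(self, rng):
        ref = rng.normal(10, 3, 60)
        cand = ref + rng.normal(0, 0.5, 60)
        base_r = sm.icc(_pairs(ref, cand), "consistency")
        base_a = sm.icc(_pairs(ref, cand), "agreement")
        shifted = cand + 2.0
        assert sm.icc(_pairs(ref, shifted), "consistency") == pytest.approx(base_r, rel=1e-9)
        assert sm.icc(_pairs(ref, shifted), "agreement") < base_a

    def test_matches_pingouin(self, rng):
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd

        ref = rng.normal(10, 3, 30)
        cand = ref + 0.8 + rng.normal(0, 1.0, 30)
        frame = pd.DataFrame(
            {
                "subject": list(range(30)) * 2,
                "rater": ["ref"] * 30 + ["cand"] * 30,
                "score": np.concatenate([ref, cand]),
            }
        )
        table = pingouin.intraclass_corr(
            frame, targets="subject", raters="rater", ratings="score"
        ).set_index("Type")
        p = _pairs(ref, cand)
        assert sm.icc(p, "agreement") == pytest.approx(table.loc["ICC(A,1)", "ICC"], abs=1e-6)
        assert sm.icc(p, "consistency") == pytest.approx(table.loc["ICC(C,1)", "ICC"], abs=1e-6)


class TestSee:
    def test_exact_linear_relation(self):
        p = _pairs([1, 2, 3, 4], [2.5, 4.5, 6.5, 8.5])
        assert sm.see(p) == pytest.approx(0.0, abs=1e-9)

    def test_three_point_closed_form(self):
        # OLS of (0,0),(1,1),(2,3): slope 1.5, intercept -1/6, SSR = 1/6
        p = _pairs([0, 1, 2], [0, 1, 3])
        assert sm.see(p) == pytest.approx(math.sqrt(1.0 / 6.0), rel=1e-12)

    def test_noise_recovery(self, rng):
        ref = rng.uniform(0, 10, 4000)
        p = _pairs(ref, ref + rng.normal(0, 0.5, 4000))
        assert sm.see(p) == pytest.approx(0.5, rel=0.05)

    def test_offset_carrier_invariance(self, rng):
        ref = rng.normal(5, 2, 40)
        cand = ref + rng.normal(0, 0.3, 40)
        a = sm.see(_pairs(ref, cand + 1.5))
        b = sm.see(_pairs(ref + 1.5, cand))
        assert a == pytest.approx(b, rel=1e-9)
        # rmse, by contrast, feels the offset
        assert sm.rmse(_pairs(ref, cand + 1.5)) != pytest.approx(
            sm.rmse(_pairs(ref, cand)), rel=1e-3
        )

    def test_degenerate_reference(self):
        with pytest.raises(SingularFitError):
            sm.see(_pairs([2, 2, 2], [1, 2, 3]))


class TestRmse:
    @pytest.mark.parametrize(
        "pairs, expected",
        [
            (_pairs([1, 2, 3], [1, 2, 3]), 0.0),
            (_pairs([0, 0], [3, 4]), math.sqrt(12.5)),
            ([(0, -2.5)], 2.5),
        ],
    )
    def test_values(self, pairs, expected):
        assert sm.rmse(pairs) == pytest.approx(expected, rel=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ArgumentError):
            sm.rmse([])

    def test_decomposition_identity(self, rng):
        # rmse^2 == mean_diff^2 + (n-1)/n * sd_diff^2 for any data
        for _ in range(10):
            n = rng.integers(2, 50)
            ref = rng.normal(0, 3, n)
            cand = ref + rng.normal(1, 2, n)
            p = _pairs(ref, cand)
            ba = sm.bland_altman(p)
            assert sm.rmse(p) ** 2 == pytest.approx(
                ba.mean_diff**2 + (n - 1) / n * ba.sd_diff**2, rel=1e-9
            )


class TestSme:
    def test_perfect_agreement_gives_zero(self):
        assert sm.sme(_pairs([1, 2, 3], [1, 2, 3])) == pytest.approx(0.0, abs=1e-9)

    def test_formula_identity(self, rng):
        ref = rng.normal(10, 3, 40)
        cand = ref + rng.normal(0, 1, 40)
        p = _pairs(ref, cand)
        for form in ("agreement", "consistency"):
            expected = pooled_sd(p) * math.sqrt(1 - sm.icc(p, form))
            assert sm.sme(p, form) == pytest.approx(expected, rel=1e-12)

    def test_recovers_known_error_sd(self, rng):
        # truth +/- independent noise sigma on both methods: SEM ~ sigma
        sigma = 0.8
        truth = rng.normal(20, 5, 3000)
        p = _pairs(truth + rng.normal(0, sigma, 3000), truth + rng.normal(0, sigma, 3000))
        assert sm.sme(p, "consistency") == pytest.approx(sigma, rel=0.1)


class TestCv:
    def test_identical_methods(self):
        assert sm.cv(_pairs([8, 10, 12], [8, 10, 12])) == 0.0

    def test_hand_value(self):
        # diffs {+1, -1}: SD = sqrt(2); grand mean 10 -> CV = 10%
        p = _pairs([9.5, 10.5], [10.5, 9.5])
        assert sm.cv(p) == pytest.approx(10.0, rel=1e-9)

    def test_recovers_known_within_subject_cv(self, rng):
        mean, wcv = 50.0, 0.04
        truth = np.full(4000, mean)
        noise = mean * wcv
        p = _pairs(truth + rng.normal(0, noise, 4000), truth + rng.normal(0, noise, 4000))
        assert sm.cv(p) == pytest.approx(100 * wcv, rel=0.1)

    def test_non_positive_grand_mean_rejected(self):
        with pytest.raises(sm.DomainError):
            sm.cv(_pairs([-1, -2], [1, 2]))


class TestAgreementReport:
    def test_perfect_cohort(self):
        pairs = _pairs([1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0])
        rep = sm.agreement_report({"endomorphy": pairs})
        row = rep.components["endomorphy"]
        assert row.mean_diff == 0 and row.rmse == 0 and row.see == pytest.approx(0, abs=1e-9)
        assert row.icc_a == pytest.approx(1.0) and row.icc_r == pytest.approx(1.0)
        assert row.loa_low == 0 and row.loa_high == 0

    def test_injected_bias_recovered(self, rng):
        ref = rng.normal(4.8, 1.5, 300)
        cand = ref + 0.25 + rng.normal(0, 0.1, 300)
        rep = sm.agreement_report({"endomorphy": _pairs(ref, cand)})
        assert rep.components["endomorphy"].mean_diff == pytest.approx(0.25, abs=0.03)

    def test_loa_brackets_mean_and_rmse_dominates_bias(self, rng):
        ref = rng.normal(5, 2, 80)
        cand = ref + rng.normal(0.5, 0.7, 80)
        row = sm.agreement_report({"c": _pairs(ref, cand)}).components["c"]
        assert row.loa_low <= row.mean_diff <= row.loa_high
        assert row.rmse >= abs(row.mean_diff)

    def test_error_isolation(self, rng):
        good = _pairs(rng.normal(5, 1, 20), rng.normal(5, 1, 20))
        rep = sm.agreement_report({"good": good, "empty": [], "flat": _pairs([2, 2, 2], [2, 2, 2])})
        assert "good" in rep.components
        assert "empty" in rep.failed
        flat = rep.components["flat"]  # BA fine, ICC/SEE cells flagged
        assert flat.icc_a is None and flat.see is None
        assert dict(flat.errors)  # reasons recorded

    def test_frame_column_order_and_write(self, tmp_path, rng):
        import pandas as pd

        ref = rng.normal(5, 2, 30)
        rep = sm.agreement_report(
            {c: _pairs(ref, ref + rng.normal(0.2, 0.4, 30)) for c in ("endo", "meso", "ecto")}
        )
        frame = rep.to_frame()
        assert list(frame.columns) == list(sm.AgreementReport.COLUMNS)
        csv_path = tmp_path / "report.csv"
        xlsx_path = tmp_path / "report.xlsx"
        rep.write(csv_path)
        rep.write(xlsx_path)
        back = pd.read_csv(csv_path, index_col="component")
        assert back.loc["endo", "rmse"] == pytest.approx(frame.loc["endo", "rmse"], rel=1e-9)
        back_x = pd.read_excel(xlsx_path, index_col=0)
        assert list(back_x.columns) == list(sm.AgreementReport.COLUMNS)


def test_bland_altman_plot_writes_file(tmp_path, rng):
    ref = rng.normal(5, 2, 40)
    fig = sm.agreement.bland_altman_plot(
        list(zip(ref, ref + rng.normal(0.3, 0.5, 40))),
        title="endomorphy",
        path=tmp_path / "ba.png",
    )
    assert (tmp_path / "ba.png").stat().st_size > 0
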