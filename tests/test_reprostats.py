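import numpy as np
import pandas as pd
import pytest

from lgequant.reprostats import (
    SampleSizeSpec,
    bland_altman,
    cv,
    icc,
    per_patient_diffs,
    quality_correlation,
    run_reproducibility,
    sample_size,
    sample_size_exact,
    variance_components,
)


def table_from_matrix(x, method="M"):
    """Patient x reader matrix -> long-format measurement table."""
    x = np.asarray(x, dtype=float)
    rows = []
    for i in range(x.shape[0]):
        for j in range(x.shape[1]):
            rows.append(
                {
                    "patient": f"P{i:03d}",
                    "reader": f"r{j}",
                    "method": method,
                    "percent_lv": x[i, j],
                    "mass_g": np.nan,
                    "lv_mass_g": np.nan,
                }
            )
    return pd.DataFrame(rows)


def icc21_oracle(x):
    """Brute-force ICC(2,1) from explicitly enumerated mean squares."""
    x = np.asarray(x, dtype=float)
    n, k = x.shape
    grand = x.mean()
    msr = k * sum((x[i].mean() - grand) ** 2 for i in range(n)) / (n - 1)
    msc = n * sum((x[:, j].mean() - grand) ** 2 for j in range(k)) / (k - 1)
    sse = sum(
        (x[i, j] - x[i].mean() - x[:, j].mean() + grand) ** 2
        for i in range(n)
        for j in range(k)
    )
    mse = sse / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)


TWO_PATIENT = table_from_matrix([[10, 12, 14], [20, 20, 26]])


class TestPerPatientDiffs:
    def test_perfect_agreement(self):
        t = table_from_matrix([[10, 10, 10], [20, 20, 20]])
        _, mean, sd = per_patient_diffs(t, "M")
        assert mean == 0.0 and sd == 0.0

    def test_hand_enumeration(self):
        # readers (10,12,14): pair diffs 2,4,2 -> 8/3; (20,20,26): 0,6,6 -> 4
        diffs, mean, sd = per_patient_diffs(TWO_PATIENT, "M")
        assert diffs == pytest.approx([8 / 3, 4.0])
        assert mean == pytest.approx(10 / 3, abs=0.005)
        assert sd == pytest.approx(0.94, abs=0.005)

    def test_translation_invariance(self):
        shifted = TWO_PATIENT.copy()
        shifted["percent_lv"] += 7.0
        d0, _, _ = per_patient_diffs(TWO_PATIENT, "M")
        d1, _, _ = per_patient_diffs(shifted, "M")
        assert d0 == pytest.approx(d1)

    def test_missing_cell_raises(self):
        t = TWO_PATIENT.drop(index=4)
        with pytest.raises(ValueError, match="P001"):
            per_patient_diffs(t, "M")


class TestCV:
    def test_perfect_agreement_zero(self):
        t = table_from_matrix([[10, 10, 10], [20, 20, 20]])
        assert cv(t, "M") == 0.0

    def test_hand_arithmetic(self):
        # SD of diffs 0.943, mean size 17.0 -> 5.54%
        assert cv(TWO_PATIENT, "M") == pytest.approx(5.54, abs=0.01)

    def test_scale_invariance(self):
        scaled = TWO_PATIENT.copy()
        scaled["percent_lv"] *= 3.0
        assert cv(scaled, "M") == pytest.approx(cv(TWO_PATIENT, "M"))

    def test_zero_mean_rejected(self):
        t = table_from_matrix([[0, 0, 0], [0, 0, 0]])
        with pytest.raises(ValueError):
            cv(t, "M")


class TestICC:
    def test_identical_readers_unity(self):
        t = table_from_matrix([[10, 10, 10], [20, 20, 20], [30, 30, 30]])
        value, _ = icc(t, "M")
        assert value == pytest.approx(1.0)

    def test_matches_mean_squares_oracle(self):
        x = [[9, 2, 5], [6, 1, 3], [8, 4, 6], [7, 1, 2]]
        value, _ = icc(table_from_matrix(x), "M")
        assert value == pytest.approx(icc21_oracle(x), abs=1e-12)

    def test_matches_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(0)
        x = rng.normal(20, 10, size=(8, 3)) + rng.normal(0, 2, size=(8, 3))
        t = table_from_matrix(x)
        value, (lo, hi) = icc(t, "M")
        long = t.rename(columns={"patient": "targets", "reader": "raters"})
        res = pingouin.intraclass_corr(
            data=long, targets="targets", raters="raters", ratings="percent_lv"
        )
        row = res[res["Type"].isin(["ICC2", "ICC(A,1)"])].iloc[0]
        ci_col = "CI95%" if "CI95%" in res.columns else "CI95"
        assert value == pytest.approx(row["ICC"], abs=1e-9)
        assert lo == pytest.approx(row[ci_col][0], abs=0.02)
        assert hi == pytest.approx(row[ci_col][1], abs=0.02)

    def test_null_distribution_centred_at_zero(self):
        """Pure noise with no patient effect gives ICC near 0."""
        rng = np.random.default_rng(42)
        x = rng.normal(0, 1, size=(500, 3))
        value, _ = icc(table_from_matrix(x), "M")
        assert abs(value) < 0.1

    def test_too_small_rejected(self):
        with pytest.raises(ValueError):
            icc(table_from_matrix([[1, 2, 3]]), "M")


class TestBlandAltman:
    def test_identical_pairs(self):
        t = table_from_matrix([[10, 10], [20, 20], [30, 30]])
        ba = bland_altman(t, "M", ("r0", "r1"))
        assert ba.bias == 0.0 and ba.sd == 0.0
        assert ba.loa_low == 0.0 and ba.loa_high == 0.0

    def test_constant_offset(self):
        t = table_from_matrix([[12, 10], [22, 20], [32, 30]])
        ba = bland_altman(t, "M", ("r0", "r1"))
        assert ba.bias == pytest.approx(2.0)
        assert ba.sd == 0.0

    def test_hand_arithmetic(self):
        # differences (-1, 0, 1, 4): bias 1.0, sd 2.160, limits 1 +/- 1.96 sd
        x = [[9, 10], [10, 10], [11, 10], [14, 10]]
        ba = bland_altman(table_from_matrix(x), "M", ("r0", "r1"))
        assert ba.bias == pytest.approx(1.0)
        assert ba.sd == pytest.approx(2.160, abs=0.001)
        assert ba.loa_low == pytest.approx(1.0 - 1.96 * ba.sd)
        assert ba.loa_high == pytest.approx(1.0 + 1.96 * ba.sd)
        assert 0.0 < ba.p_value < 1.0


class TestVarianceComponents:
    def test_identical_readers(self):
        t = table_from_matrix([[10, 10, 10], [20, 20, 20], [30, 30, 30]])
        sT2, se2, share = variance_components(t, "M")
        assert se2 == 0.0 and share == 0.0
        assert sT2 > 0

    def test_parameter_recovery(self):
        """Injected (sigma_T, sigma_e) = (10, 2) recovered within 10%."""
        rng = np.random.default_rng(7)
        n, k = 2000, 3
        x = rng.normal(20, 10, size=(n, 1)) + rng.normal(0, 2, size=(n, k))
        sT2, se2, _ = variance_components(table_from_matrix(x), "M")
        assert 9.0 <= np.sqrt(sT2) <= 11.0
        assert 1.8 <= np.sqrt(se2) <= 2.2

    def test_constant_table_guarded(self):
        t = table_from_matrix([[5, 5, 5], [5, 5, 5]])
        sT2, se2, share = variance_components(t, "M")
        assert sT2 == 0.0 and se2 == 0.0 and share == 0.0


class TestSampleSize:
    def test_published_quantiles_worked_example(self):
        # sigma 10, delta 5, alpha 0.05, beta 0.2 -> 62.79 -> 63
        spec = SampleSizeSpec(delta=5.0, sigma=10.0)
        assert sample_size_exact(spec) == pytest.approx(62.79, abs=0.01)
        assert sample_size(spec) == 63

    def test_delta_scaling_law_exact(self):
        a = sample_size_exact(SampleSizeSpec(delta=3.0, sigma=8.0))
        b = sample_size_exact(SampleSizeSpec(delta=6.0, sigma=8.0))
        assert a / b == pytest.approx(4.0, abs=1e-12)

    def test_zero_sigma_warns(self):
        with pytest.warns(UserWarning):
            assert sample_size(SampleSizeSpec(delta=5.0, sigma=0.0)) == 0

    def test_components_combined_in_quadrature(self):
        spec = SampleSizeSpec(delta=5.0, sigma_T=8.0, sigma_e=6.0)
        assert spec.sigma == pytest.approx(10.0)

    def test_monotone_in_sigma_and_delta(self):
        n_sig = [sample_size_exact(SampleSizeSpec(delta=5.0, sigma=s)) for s in (5, 10, 15)]
        assert n_sig[0] < n_sig[1] < n_sig[2]
        n_del = [sample_size_exact(SampleSizeSpec(delta=d, sigma=10.0)) for d in (3, 5, 7)]
        assert n_del[0] > n_del[1] > n_del[2]

    def test_invalid_delta_rejected(self):
        with pytest.raises(ValueError):
            SampleSizeSpec(delta=0.0, sigma=10.0)


class TestQualityCorrelation:
    def test_perfect_linear(self):
        x = np.arange(10.0)
        r, slope, _ = quality_correlation(2 * x, x)
        assert r == pytest.approx(1.0)
        assert slope == pytest.approx(2.0)

    def test_independent_null(self):
        rng = np.random.default_rng(3)
        r, _, _ = quality_correlation(rng.normal(size=1000), rng.normal(size=1000))
        assert abs(r) < 0.1

    def test_affine_invariance(self):
        rng = np.random.default_rng(4)
        a, b = rng.normal(size=50), rng.normal(size=50)
        r0, _, _ = quality_correlation(a, b)
        r1, _, _ = quality_correlation(3 * a + 1, -0.5 * b + 2)
        assert abs(r0) == pytest.approx(abs(r1))

    def test_degenerate_rejected(self):
        with pytest.raises(ValueError):
            quality_correlation(np.ones(5), np.arange(5.0))


class TestRunReproducibility:
    def _two_method_table(self, se_a=1.0, se_b=3.0, seed=0, n=40):
        rng = np.random.default_rng(seed)
        truth = rng.normal(20, 10, size=(n, 1)).clip(2)
        frames = []
        for m, se in (("A", se_a), ("B", se_b)):
            x = truth + rng.normal(0, se, size=(n, 3))
            frames.append(table_from_matrix(x, method=m))
        return pd.concat(frames, ignore_index=True)

    def test_duplicated_method_identical_reports(self):
        t = table_from_matrix([[10, 12, 14], [20, 22, 18], [30, 28, 33]], "A")
        t2 = t.copy()
        t2["method"] = "B"
        reports = run_reproducibility(pd.concat([t, t2], ignore_index=True))
        a, b = reports["A"], reports["B"]
        assert a.cv == b.cv and a.icc == b.icc and a.sigma_e2 == b.sigma_e2

    def test_noisier_method_ranks_worse(self):
        """Higher reader noise -> higher CV, lower ICC, larger within share."""
        reports = run_reproducibility(self._two_method_table())
        assert reports["B"].cv > reports["A"].cv
        assert reports["B"].icc < reports["A"].icc
        assert reports["B"].within_share > reports["A"].within_share

    def test_coverage_contract(self):
        rng = np.random.default_rng(1)
        frames = [
            table_from_matrix(rng.normal(20, 5, size=(6, 3)).clip(1), method=f"M{i}")
            for i in range(8)
        ]
        reports = run_reproducibility(pd.concat(frames, ignore_index=True))
        assert len(reports) == 8
        for r in reports.values():
            assert len(r.bland_altman) == 3
            assert set(r.sample_sizes) == {3.0, 5.0, 7.0}
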