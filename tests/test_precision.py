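import numpy as np
import pytest
from scipy import stats

from msfingerprint import precision
from msfingerprint.dscore import DScoreRecord


def rec(d, cultivar="c1", run_index=1, class_label="A"):
    return DScoreRecord(
        sample_id=f"{cultivar}_r{run_index}", cultivar=cultivar, run_index=run_index,
        p=0.5, log_odds=0.0, d=d, decision="A" if d > 0 else "B", class_label=class_label,
    )


def paired_records(cultivar_scores: dict[str, tuple[float, float]], class_label="A"):
    return [
        rec(d, cultivar=c, run_index=i + 1, class_label=class_label)
        for c, pair in cultivar_scores.items()
        for i, d in enumerate(pair)
    ]


class TestClassificationSd:
    def test_identical_scores_give_zero(self):
        records = paired_records({"c1": (1.0, 1.0), "c2": (1.0, 1.0)})
        assert precision.classification_sd(records) == 0.0

    def test_closed_form_duplicated_means(self):
        records = paired_records({"c1": (1.4, 1.4), "c2": (0.6, 0.6)})
        assert precision.classification_sd(records) == pytest.approx(0.46188, abs=1e-5)

    def test_needs_two_scores(self):
        with pytest.raises(ValueError):
            precision.classification_sd([rec(1.0)])


class TestIntermediateSd:
    def test_identical_duplicates_give_zero(self):
        records = paired_records({"c1": (0.9, 0.9), "c2": (1.2, 1.2)})
        assert precision.intermediate_sd(records) == 0.0

    def test_single_pair_closed_form(self):
        records = paired_records({"c1": (1.1, 0.9)})
        assert precision.intermediate_sd(records) == pytest.approx(0.2 / np.sqrt(2), abs=1e-9)

    def test_pooled_two_cultivars(self):
        # per-cultivar replicate SDs 0.1 and 0.2 -> sqrt((0.01 + 0.04)/2)
        records = paired_records(
            {"c1": (1.0 - 0.1 / np.sqrt(2), 1.0 + 0.1 / np.sqrt(2)),
             "c2": (0.8 - 0.2 / np.sqrt(2), 0.8 + 0.2 / np.sqrt(2))}
        )
        assert precision.intermediate_sd(records) == pytest.approx(0.158114, abs=1e-6)

    def test_duplicate_pair_formula_oracle(self):
        rng = np.random.default_rng(3)
        pairs = {f"c{i}": tuple(rng.normal(1.0, 0.3, size=2)) for i in range(8)}
        records = paired_records(pairs)
        oracle = np.sqrt(np.mean([(d1 - d2) ** 2 / 2.0 for d1, d2 in pairs.values()]))
        assert precision.intermediate_sd(records) == pytest.approx(oracle, abs=1e-12)

    def test_invariant_to_orderings(self):
        pairs = {"c1": (1.3, 0.9), "c2": (0.7, 1.1), "c3": (1.0, 1.4)}
        forward = precision.intermediate_sd(paired_records(pairs))
        swapped = precision.intermediate_sd(
            paired_records({c: (b, a) for c, (a, b) in reversed(list(pairs.items()))})
        )
        assert forward == pytest.approx(swapped, abs=1e-15)

    def test_singleton_cultivar_rejected(self):
        records = paired_records({"c1": (1.0, 1.1)}) + [rec(0.9, cultivar="c2")]
        with pytest.raises(ValueError, match="c2"):
            precision.intermediate_sd(records)


class TestMisclassificationRisk:
    def test_reported_class_spreads_give_half_percent(self):
        # normal tail beyond the zero threshold for class means +/-1
        risk_pos = precision.misclassification_risk(1.0, 0.393)
        risk_neg = precision.misclassification_risk(-1.0, 0.391)
        assert risk_pos == pytest.approx(stats.norm.cdf(-1.0 / 0.393), abs=1e-12)
        assert risk_pos == pytest.approx(0.005471, abs=1e-6)
        assert risk_neg == pytest.approx(0.005271, abs=1e-6)
        assert risk_pos < 0.01 and risk_neg < 0.01

    def test_symmetry_of_sides(self):
        assert precision.misclassification_risk(1.0, 0.4) == pytest.approx(
            precision.misclassification_risk(-1.0, 0.4), abs=1e-15
        )

    def test_small_sd_limit(self):
        assert precision.misclassification_risk(1.0, 1e-6) == pytest.approx(0.0, abs=1e-12)

    def test_mean_on_threshold_warns_half(self):
        with pytest.warns(UserWarning):
            assert precision.misclassification_risk(0.0, 1.0) == 0.5

    def test_invalid_sd(self):
        with pytest.raises(ValueError):
            precision.misclassification_risk(1.0, 0.0)

    def test_monte_carlo_oracle(self):
        rng = np.random.default_rng(17)
        n = 100_000
        for mean, sd in [(1.0, 0.393), (-1.0, 0.391), (0.5, 0.8)]:
            draws = rng.normal(mean, sd, size=n)
            wrong = np.mean(draws < 0) if mean > 0 else np.mean(draws > 0)
            analytic = precision.misclassification_risk(mean, sd)
            se = np.sqrt(analytic * (1 - analytic) / n)
            assert abs(analytic - wrong) < 3 * se + 1e-12


class TestReport:
    def synthetic_records(self, seed=0, run_sd=0.05, cultivar_sd=0.4):
        """Hierarchical normal D scores: cultivar means around +/-1, replicate
        noise within cultivar."""
        rng = np.random.default_rng(seed)
        records = []
        for cls, center in (("A", 1.0), ("B", -1.0)):
            for ci in range(11):
                mu = center + rng.normal(0.0, cultivar_sd)
                d1, d2 = mu + rng.normal(0.0, run_sd, size=2)
                records.extend(
                    paired_records({f"{cls}{ci:02d}": (d1, d2)}, class_label=cls)
                )
        return records

    def test_two_classes_reported_with_expected_ordering(self):
        report = precision.build_precision_report(self.synthetic_records())
        assert len(report.classes) == 2
        assert [c.class_label for c in report.classes] == ["A", "B"]
        for cls in report.classes:
            assert cls.n_cultivars == 11
            assert cls.intermediate_sd < cls.classification_sd  # run noise << cultivar spread
            assert 0.0 <= cls.misclassification_risk <= 1.0

    def test_variance_decomposition_identity(self):
        # balanced duplicates: (2n-1) s_total^2 = 2(n-1) s_means^2 + n s_within^2
        report = precision.build_precision_report(self.synthetic_records(seed=4))
        n = 11
        for cls in report.classes:
            lhs = (2 * n - 1) * cls.classification_sd**2
            rhs = 2 * (n - 1) * cls.cultivar_mean_sd**2 + n * cls.intermediate_sd**2
            assert lhs == pytest.approx(rhs, rel=1e-12)

    def test_requires_both_classes(self):
        records = paired_records({"c1": (1.0, 1.1), "c2": (0.8, 0.9)})
        with pytest.raises(ValueError, match="both classes"):
            precision.build_precision_report(records)

    def test_frame_and_json_serialization(self, tmp_path):
        report = precision.build_precision_report(self.synthetic_records())
        df = report.to_frame()
        assert set(df.columns) >= {
            "class_label", "mean_d", "classification_sd", "intermediate_sd",
            "misclassification_risk",
        }
        out = report.to_json(tmp_path / "precision.json")
        assert out.exists() and out.read_text().startswith("[")
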