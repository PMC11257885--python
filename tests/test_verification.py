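"""Fold-ratio bands and visual predictive checks."""
import dataclasses

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dexpbpk.pbpk import DoseDesign
from dexpbpk.synthetic import DEFAULT_TEMPLATES, generate_study
from dexpbpk.verification import (
    ObservedStudy,
    fold_band,
    run_vpc,
    verify_against,
)


class TestFoldBand:
    @pytest.mark.parametrize(
        "ratio,band",
        [
            (1.0, "within 1.25-fold"),
            (1.2, "within 1.25-fold"),
            (0.6, "within 2-fold"),  # 1/0.6 = 1.67
            (1.4, "within 1.5-fold"),
            (2.0, "within 2-fold"),  # boundary counts inward
            (2.01, "outside 2-fold"),
        ],
    )
    def test_band_assignment(self, ratio, band):
        assert fold_band(ratio) == band

    @settings(max_examples=1000, deadline=None, derandomize=True)
    @given(st.floats(min_value=1e-3, max_value=1e3))
    def test_symmetry_in_reciprocal(self, ratio):
        assert fold_band(ratio) == fold_band(1.0 / ratio)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            fold_band(0.0)


def _tiny_study():
    rows = []
    for sid in ("a", "b", "c"):
        for t in (0.5, 1, 2, 4, 8, 12):
            rows.append(
                {
                    "subject_id": sid,
                    "time_h": t,
                    "conc_mg_L": 0.5 * np.exp(-0.15 * t),
                    "below_lloq": False,
                    "dose_mg": 4.0,
                }
            )
    return ObservedStudy(
        study_id="tiny",
        design=DoseDesign(4.0, "mg", n_doses=1),
        age_min_years=2.0,
        age_max_years=6.0,
        records=pd.DataFrame(rows),
        lloq_mg_L=0.001,
    )


class TestVerifyAgainst:
    def test_empty_study_list_gives_empty_report(self, pop_config, compound):
        report = verify_against([], pop_config, compound, n_virtual=2, n_replicates=1)
        assert report.table.empty
        assert np.isnan(report.fraction_within_2fold)

    def test_deterministic_given_seed(self, pop_config, compound):
        study = _tiny_study()
        kw = dict(n_virtual=5, n_replicates=2, seed=42)
        a = verify_against([study], pop_config, compound, **kw)
        b = verify_against([study], pop_config, compound, **kw)
        pd.testing.assert_frame_equal(a.table, b.table)

    def test_reported_pk_ratio_arithmetic(self, pop_config, compound, monkeypatch):
        """A study reporting PK values directly yields ratio = GM(pred)/reported."""
        study = dataclasses.replace(
            _tiny_study(), reported_pk={"auc_0_48": 10.0}
        )
        report = verify_against(
            [study], pop_config, compound, n_virtual=5, n_replicates=1, seed=1
        )
        row = report.table.set_index("metric").loc["auc_0_48"]
        assert row["ratio"] == pytest.approx(row["predicted"] / 10.0, rel=1e-12)
        assert row["band"] == fold_band(row["ratio"])

    def test_self_consistency_smoke(self, pop_config, compound):
        """Synthetic data from the model itself verify within 1.5-fold even
        with small cohorts (the tight 1.25-fold check runs at full size in
        the acceptance suite)."""
        studies = [
            generate_study(
                dataclasses.replace(DEFAULT_TEMPLATES[1], seed=8, n_subjects=20),
                pop_config,
                compound,
            )
        ]
        report = verify_against(
            studies, pop_config, compound,
            n_virtual=50, n_replicates=2, seed=8, residual_cv=0.2,
        )
        assert not report.table.empty
        assert (report.table["band"] != "outside 2-fold").all()
        ratios = report.table["ratio"]
        assert ((ratios > 1 / 1.5) & (ratios < 1.5)).all()


class TestVpc:
    def test_single_subject_degenerate_band(self, pop_config, compound):
        study = _tiny_study()
        vpc = run_vpc(study, pop_config, compound, n_virtual=1, seed=0)
        np.testing.assert_allclose(vpc.predicted_p5, vpc.predicted_mean)
        np.testing.assert_allclose(vpc.predicted_p95, vpc.predicted_mean)

    def test_deterministic_given_seed(self, pop_config, compound):
        study = _tiny_study()
        a = run_vpc(study, pop_config, compound, n_virtual=10, seed=3, residual_cv=0.2)
        b = run_vpc(study, pop_config, compound, n_virtual=10, seed=3, residual_cv=0.2)
        np.testing.assert_array_equal(a.predicted_p95, b.predicted_p95)
        assert a.coverage_fraction == b.coverage_fraction

    def test_envelope_brackets_mean_and_coverage_in_range(self, pop_config, compound):
        study = generate_study(
            dataclasses.replace(DEFAULT_TEMPLATES[0], seed=5, n_subjects=10),
            pop_config,
            compound,
        )
        vpc = run_vpc(
            study, pop_config, compound, n_virtual=40, seed=5, residual_cv=0.2
        )
        assert np.all(vpc.predicted_p5 <= vpc.predicted_mean + 1e-12)
        assert np.all(vpc.predicted_mean <= vpc.predicted_p95 + 1e-12)
        assert 0.0 <= vpc.coverage_fraction <= 1.0
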