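import numpy as np
import pandas as pd
import pytest

from hierattn import (
    EligibilityConfig,
    FeatureTensor,
    apply_eligibility,
    apply_normalizer,
    clean_events,
    derive_labels,
    fit_normalizer,
    tensorize_cohort,
)
from hierattn.tensorize import aggregate_annual, aggregate_cohort, build_tensor


def _statics(rows):
    defaults = dict(sex="F", ses_quintile=2.0,
                    registry_entry_date="2010-01-01",
                    registry_exit_date=pd.NaT, death_date=pd.NaT)
    recs = []
    for r in rows:
        d = {**defaults, **r}
        recs.append(d)
    df = pd.DataFrame(recs)
    for c in ("birth_date", "registry_entry_date", "registry_exit_date", "death_date"):
        df[c] = pd.to_datetime(df[c])
    return df


def _events(rows):
    df = pd.DataFrame(rows, columns=["patient_id", "date", "domain", "code", "value"])
    df["date"] = pd.to_datetime(df["date"])
    return df


class TestCleanEvents:
    def test_duplicate_diagnoses_collapse(self):
        st = _statics([{"patient_id": 1, "birth_date": "1940-01-01"}])
        ev = _events([
            (1, "2015-03-01", "diagnosis", "Z74.1", np.nan),
            (1, "2015-03-01", "diagnosis", "Z74.1", np.nan),
            (1, "2015-03-02", "diagnosis", "Z74.1", np.nan),
        ])
        clean, log = clean_events(ev, st)
        assert len(clean) == 2
        assert log["duplicate_diagnosis"] == 1

    def test_event_after_death_removed(self):
        st = _statics([{"patient_id": 1, "birth_date": "1940-01-01",
                        "death_date": "2015-06-01"}])
        ev = _events([
            (1, "2015-05-01", "diagnosis", "I00.9", np.nan),
            (1, "2015-07-01", "diagnosis", "I01.9", np.nan),
            (1, "1939-12-31", "diagnosis", "I02.9", np.nan),   # before birth
        ])
        clean, log = clean_events(ev, st)
        assert list(clean["code"]) == ["I00.9"]
        assert log["inconsistent_date"] == 2

    def test_wrong_sex_code_removed(self, schema):
        st = _statics([{"patient_id": 1, "birth_date": "1940-01-01", "sex": "F"}])
        ev = _events([
            (1, "2015-05-01", "diagnosis", "C61.9", np.nan),   # male-only
            (1, "2015-05-02", "diagnosis", "C53.9", np.nan),   # female-only
        ])
        clean, log = clean_events(ev, st, schema.sex_specific_codes)
        assert list(clean["code"]) == ["C53.9"]
        assert log["wrong_sex_code"] == 1

    def test_empty_events_identity(self):
        st = _statics([{"patient_id": 1, "birth_date": "1940-01-01"}])
        clean, log = clean_events(_events([]), st)
        assert clean.empty
        assert sum(log.values()) == 0

    def test_unknown_patient_rejected(self):
        st = _statics([{"patient_id": 1, "birth_date": "1940-01-01"}])
        with pytest.raises(ValueError, match="unknown patient"):
            clean_events(_events([(9, "2015-01-01", "visit", "VIS0", np.nan)]), st)


class TestEligibility:
    def _visit(self, pid, date):
        return (pid, date, "visit", "VIS0", np.nan)

    def test_centenarian_at_start_excluded(self):
        st = _statics([{"patient_id": 1, "birth_date": "1909-06-01"}])
        ev = _events([self._visit(1, "2012-01-01")])
        cohort, counts = apply_eligibility(st, ev, EligibilityConfig())
        assert cohort.empty
        assert counts["too_old_at_start"] == 1

    def test_turning_65_enters_mid_study(self):
        st = _statics([{"patient_id": 1, "birth_date": "1949-05-10"}])
        ev = _events([self._visit(1, "2015-01-01")])
        cohort, _ = apply_eligibility(st, ev, EligibilityConfig())
        assert cohort.loc[0, "entry_year"] == 2014
        assert cohort.loc[0, "index_year"] == 2018     # 1-year window

    def test_zero_visits_excluded(self):
        st = _statics([{"patient_id": 1, "birth_date": "1940-01-01"}])
        ev = _events([(1, "2015-01-01", "lab", "LAB00", 100.0)])
        cohort, counts = apply_eligibility(st, ev, EligibilityConfig())
        assert cohort.empty
        assert counts["no_visits"] == 1

    def test_short_followup_excluded_per_window(self):
        st = _statics([{"patient_id": 1, "birth_date": "1940-01-01",
                        "registry_exit_date": "2013-06-01"}])
        ev = _events([self._visit(1, "2011-01-01")])
        ok_1y, _ = apply_eligibility(st, ev, EligibilityConfig(prediction_window=1))
        assert len(ok_1y) == 1
        gone_5y, counts = apply_eligibility(st, ev,
                                            EligibilityConfig(prediction_window=5))
        assert gone_5y.empty
        assert counts["insufficient_followup"] == 1


class TestAggregateAnnual:
    def test_lab_mean_count_and_flag(self, schema):
        ev = _events([
            (1, "2015-02-01", "lab", "LAB00", 90.0),
            (1, "2015-09-01", "lab", "LAB00", 110.0),
        ])
        values, flags = aggregate_annual(ev, schema, 1, 2015)
        assert values[schema.index_of("lab_00_mean")] == pytest.approx(100.0)
        assert values[schema.index_of("lab_00_count")] == 2
        assert flags[schema.index_of("lab_00_mean")] == 1
        assert values[schema.index_of("lab_00_oor")] == 0   # range (80, 120)

    def test_out_of_range_counted(self, schema):
        ev = _events([(1, "2015-02-01", "lab", "LAB00", 150.0)])
        values, _ = aggregate_annual(ev, schema, 1, 2015)
        assert values[schema.index_of("lab_00_oor")] == 1

    def test_empty_year_counts_known_zero_means_unknown(self, schema):
        values, flags = aggregate_annual(_events([]), schema, 1, 2015)
        assert values[schema.index_of("lab_00_count")] == 0
        assert flags[schema.index_of("lab_00_count")] == 1
        assert flags[schema.index_of("lab_00_mean")] == 0
        assert values[schema.index_of("lab_00_mean")] == 0

    def test_chronic_flag_carries_forward(self, schema):
        ev = _events([(1, "2013-02-01", "diagnosis", "I00.9", np.nan)])
        cohort = pd.DataFrame({"patient_id": [1], "entry_year": [2012],
                               "index_year": [2015]})
        values, recorded, years = aggregate_cohort(ev, schema, cohort)
        j = schema.index_of("chronic_00")
        got = values[0, :, j]
        assert list(got) == [0, 1, 1, 1]          # 2012..2015

    def test_categorical_mode_with_tie_break(self, schema):
        ev = _events([
            (1, "2015-01-01", "measure", "CMEAS00", 2.0),
            (1, "2015-02-01", "measure", "CMEAS00", 0.0),
            (1, "2015-03-01", "measure", "CMEAS00", 2.0),
            (1, "2015-04-01", "measure", "CMEAS00", 0.0),
        ])
        values, flags = aggregate_annual(ev, schema, 1, 2015)
        assert values[schema.index_of("cmeas_00_mode")] == 0.0   # tie -> smallest
        assert flags[schema.index_of("cmeas_00_mode")] == 1


class TestLabels:
    def _cohort(self):
        return pd.DataFrame({"patient_id": [1], "entry_year": [2012],
                             "end_year": [2016], "index_year": [2015]})

    def test_home_care_code_within_window(self):
        st = _statics([{"patient_id": 1, "birth_date": "1940-01-01"}])
        ev = _events([(1, "2016-09-20", "diagnosis", "Z74.1", np.nan)])
        labels, omitted = derive_labels(ev, st, self._cohort(), window=1)
        assert labels.loc[0, "home_care"] == 1
        assert labels.loc[0, "nursing_home"] == 0
        assert omitted == 0

    def test_nursing_home_code_within_window(self):
        st = _statics([{"patient_id": 1, "birth_date": "1940-01-01"}])
        ev = _events([(1, "2016-03-01", "diagnosis", "Z59.3", np.nan)])
        labels, _ = derive_labels(ev, st, self._cohort(), window=1)
        assert labels.loc[0, "nursing_home"] == 1

    def test_event_outside_window_ignored(self):
        st = _statics([{"patient_id": 1, "birth_date": "1940-01-01"}])
        ev = _events([(1, "2015-06-01", "diagnosis", "Z74.1", np.nan)])  # before index end
        labels, _ = derive_labels(ev, st, self._cohort(), window=1)
        assert labels.loc[0, "home_care"] == 0

    def test_death_in_window_sets_mortality(self):
        st = _statics([{"patient_id": 1, "birth_date": "1940-01-01",
                        "death_date": "2016-07-01"}])
        labels, _ = derive_labels(_events([]), st, self._cohort(), window=1)
        assert labels.loc[0, "mortality"] == 1

    def test_null_case_all_zero(self):
        st = _statics([{"patient_id": 1, "birth_date": "1940-01-01"}])
        labels, _ = derive_labels(_events([]), st, self._cohort(), window=1)
        assert labels.loc[0, ["mortality", "nursing_home", "home_care"]].sum() == 0

    def test_censored_before_window_end_omitted(self):
        st = _statics([{"patient_id": 1, "birth_date": "1940-01-01",
                        "registry_exit_date": "2016-03-01"}])
        labels, omitted = derive_labels(_events([]), st, self._cohort(), window=1)
        assert labels.empty
        assert omitted == 1


class TestTensor:
    def test_padding_and_mask_hierarchy(self, small_tensor):
        tensor, _, _ = small_tensor
        tensor.validate_masks()
        hist = tensor.index_year - tensor.entry_year + 1
        assert np.array_equal(tensor.period_mask.sum(axis=1).astype(int), hist)
        # right alignment: last column always real
        assert (tensor.period_mask[:, -1] == 1).all()

    def test_all_equal_lengths_no_padding(self, schema):
        st = _statics([
            {"patient_id": i, "birth_date": "1940-01-01"} for i in (1, 2)])
        ev = _events(
            [(i, f"{y}-06-01", "visit", "VIS0", np.nan)
             for i in (1, 2) for y in (2010, 2011, 2012)])
        cohort = pd.DataFrame({"patient_id": [1, 2], "entry_year": [2010] * 2,
                               "index_year": [2012] * 2})
        values, recorded, years = aggregate_cohort(ev, schema, cohort)
        tensor = build_tensor(values, recorded, years, cohort, st, schema)
        assert tensor.t_max == 3
        assert (tensor.period_mask == 1).all()

    def test_prediction_window_events_do_not_leak(self, schema, small_cohort):
        """Injecting a sentinel event inside the outcome window leaves the
        feature tensor bit-identical."""
        events, statics, _, _ = small_cohort
        tensor, labels, _ = tensorize_cohort(events, statics, schema,
                                             EligibilityConfig())
        pid = int(tensor.patient_ids[0])
        iy = int(tensor.index_year[0])
        sentinel = _events([(pid, f"{iy + 1}-06-15", "lab", "LAB00", 999.0),
                            (pid, f"{iy + 1}-06-16", "visit", "VIS0", np.nan)])
        tensor2, _, _ = tensorize_cohort(
            pd.concat([events, sentinel], ignore_index=True), statics, schema,
            EligibilityConfig())
        assert np.array_equal(tensor.X, tensor2.X)
        assert np.array_equal(tensor.value_mask, tensor2.value_mask)

    def test_round_trip_io(self, small_tensor, tmp_path):
        tensor, _, _ = small_tensor
        tensor.save(tmp_path / "t")
        back = FeatureTensor.load(tmp_path / "t")
        assert np.array_equal(back.X, tensor.X)
        assert np.array_equal(back.value_mask, tensor.value_mask)
        assert np.array_equal(back.period_mask, tensor.period_mask)
        assert back.variable_index == tensor.variable_index
        assert back.schema_hash == tensor.schema_hash


class TestNormalization:
    def _tensor_with_values(self, schema, vals, var="lab_00_mean"):
        n = len(vals)
        V = schema.total_dynamic
        X = np.zeros((n, 1, V), dtype=np.float32)
        vm = np.zeros_like(X)
        j = schema.index_of(var)
        X[:, 0, j] = vals
        vm[:, 0, j] = 1
        return FeatureTensor(
            X=X, period_mask=np.ones((n, 1), np.float32), value_mask=vm,
            S=np.zeros((n, 2), np.float32), variable_index=schema.variable_ids,
            static_index=["sex", "ses_quintile"],
            patient_ids=np.arange(n), entry_year=np.full(n, 2015),
            index_year=np.full(n, 2015))

    def test_population_z_score(self, schema):
        tensor = self._tensor_with_values(schema, [1.0, 2.0, 3.0])
        stats = fit_normalizer(tensor, tensor.patient_ids, schema)
        out = apply_normalizer(tensor, stats)
        j = schema.index_of("lab_00_mean")
        np.testing.assert_allclose(out.X[:, 0, j], [-1.2247, 0.0, 1.2247],
                                   atol=1e-4)

    def test_constant_variable_maps_to_zero(self, schema):
        tensor = self._tensor_with_values(schema, [5.0, 5.0, 5.0])
        stats = fit_normalizer(tensor, tensor.patient_ids, schema)
        out = apply_normalizer(tensor, stats)
        assert (out.X[:, 0, schema.index_of("lab_00_mean")] == 0).all()

    def test_masked_entries_stay_zero(self, schema):
        tensor = self._tensor_with_values(schema, [1.0, 2.0, 3.0])
        stats = fit_normalizer(tensor, tensor.patient_ids, schema)
        out = apply_normalizer(tensor, stats)
        masked = out.value_mask == 0
        assert (out.X[masked] == 0).all()
        again = apply_normalizer(out, stats)
        assert (again.X[masked] == 0).all()   # idempotent on masked positions

    def test_stats_fitted_on_train_only(self, schema):
        tensor = self._tensor_with_values(schema, [1.0, 2.0, 3.0, 100.0])
        stats = fit_normalizer(tensor, tensor.patient_ids[:3], schema)
        j = schema.index_of("lab_00_mean")
        assert stats.mean[j] == pytest.approx(2.0)
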