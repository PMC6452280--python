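from collections import Counter

import numpy as np
import pytest

from glucaudit.errors import ConfigError
from glucaudit.insulin import DEFAULT_PROTOCOL
from glucaudit.records import write_stream
from glucaudit.synthetic import (
    GeneratorConfig,
    generate_cohort,
    generate_dataset,
    generate_insulin_administrations,
    generate_meter_stream,
    generate_transcriptions,
)


# ---------------------------------------------------------------- cohort

def test_cohort_size_and_unique_vins():
    eps = generate_cohort(GeneratorConfig(), seed=5)
    assert len(eps) == 234
    assert len({e.vin for e in eps}) == 234
    assert all(e.admit < e.discharge for e in eps)


def test_single_patient_cohort():
    assert len(generate_cohort(GeneratorConfig(n_patients=1), seed=0)) == 1


def test_degenerate_diabetes_mix_rejected():
    cfg = GeneratorConfig(diabetes_mix={"yes": 0.0, "no": 0.0, "unknown": 0.0})
    with pytest.raises(ConfigError, match="degenerate"):
        generate_cohort(cfg, seed=0)


def test_diabetes_proportions_within_three_se():
    cfg = GeneratorConfig(n_patients=10_000)
    eps = generate_cohort(cfg, seed=7)
    n = len(eps)
    for status, p in cfg.diabetes_mix.items():
        obs = sum(e.diabetes == status for e in eps) / n
        se = np.sqrt(p * (1 - p) / n)
        assert abs(obs - p) <= 3 * se


# ---------------------------------------------------------------- meters

def test_all_diabetic_mean_test_count_near_target():
    cfg = GeneratorConfig(
        n_patients=1000, diabetes_mix={"yes": 1.0, "no": 0.0, "unknown": 0.0}
    )
    eps = generate_cohort(cfg, seed=11)
    recs, eps_out = generate_meter_stream(eps, cfg, seed=12)
    counts = Counter(r.vin for r in recs)
    mean = np.mean([counts.get(e.vin, 0) for e in eps_out])
    assert abs(mean - 60) <= 6  # within 10% of the configured mean


def test_zero_test_episodes_produce_no_records(small_study):
    vins_with_records = {m.vin for m in small_study.meters}
    silent = [e for e in small_study.episodes if e.vin not in vins_with_records]
    # no records for silent episodes, by construction of the counter
    assert all(m.vin != e.vin for m in small_study.meters for e in silent)


def test_dock_time_never_precedes_test_time(study):
    assert all(m.dock_time >= m.test_time for m in study.meters)


def test_test_times_within_stay(small_study):
    bounds = {e.vin: (e.admit, e.discharge) for e in small_study.episodes}
    for m in small_study.meters:
        a, d = bounds[m.vin]
        assert a <= m.test_time <= d


def test_glucose_within_reportable_range(small_study):
    lo, hi = small_study.config.reportable
    assert all(lo <= m.glucose_mgdl <= hi for m in small_study.meters)


# ---------------------------------------------------------------- entries

def test_no_error_limit_transcribes_exact_values():
    cfg = GeneratorConfig(
        n_patients=30,
        error_prob={"paper_log": 0.0, "flow_sheet": 0.0},
        joint_error_prob=0.0,
    )
    ds = generate_dataset(cfg, seed=3)
    value = {m.record_id: m.glucose_mgdl for m in ds.meters}
    lab = ds.truth.labels
    transcribed = lab[lab.transcribed]
    entry_value = {e.entry_id: e.value_mgdl for e in ds.entries}
    assert all(
        entry_value[row.entry_id] == value[row.record_id]
        for row in transcribed.itertuples()
    )


def test_total_missingness_yields_no_entries():
    cfg = GeneratorConfig(
        n_patients=10,
        miss_prob={"paper_log": 1.0, "flow_sheet": 1.0},
        joint_miss_prob=1.0,
        post_discharge_count=0,
    )
    ds = generate_dataset(cfg, seed=4)
    assert ds.entries == []
    assert not ds.truth.labels.transcribed.any()


def test_joint_miss_exceeding_marginal_rejected():
    cfg = GeneratorConfig(joint_miss_prob=0.5)  # > paper_log marginal 0.1204
    with pytest.raises(ConfigError, match="joint_miss_prob"):
        cfg.validate()


def test_coupled_missingness_inclusion_exclusion(study):
    lab = study.truth.labels
    miss = {
        s: set(lab[(lab.source == s) & ~lab.transcribed].record_id)
        for s in ("paper_log", "flow_sheet")
    }
    both = miss["paper_log"] & miss["flow_sheet"]
    assert len(both) <= min(len(miss["paper_log"]), len(miss["flow_sheet"]))
    n = len(study.meters)
    documented_both = n - len(miss["paper_log"]) - len(miss["flow_sheet"]) + len(both)
    lab_doc = lab[lab.transcribed]
    doc_sets = {
        s: set(lab_doc[lab_doc.source == s].record_id) for s in ("paper_log", "flow_sheet")
    }
    assert documented_both == len(doc_sets["paper_log"] & doc_sets["flow_sheet"])


def test_injected_error_implies_transcribed_and_nonzero_delta(study):
    lab = study.truth.labels
    assert (lab.injected_error <= lab.transcribed).all()
    assert ((lab.injected_delta != 0) == lab.injected_error).all()


def test_injected_values_stay_in_reportable_range(study):
    lo, hi = study.config.reportable
    assert all(lo <= e.value_mgdl <= hi for e in study.entries)


def test_fixed_seed_dataset_is_byte_identical(tmp_path):
    cfg = GeneratorConfig(n_patients=25)
    files = []
    for run in ("a", "b"):
        ds = generate_dataset(cfg, seed=42)
        p = tmp_path / f"meters_{run}.csv"
        q = tmp_path / f"entries_{run}.csv"
        write_stream(ds.meters, p, "meter")
        write_stream(ds.entries, q, "entry")
        files.append(p.read_bytes() + q.read_bytes())
    assert files[0] == files[1]


# ---------------------------------------------------------------- insulin admin

def test_insulin_administrations_follow_protocol(small_study):
    doses = generate_insulin_administrations(small_study.entries)
    flow = [e for e in small_study.entries if e.source == "flow_sheet"]
    assert len(doses) == len(flow)
    by_entry = {e.entry_id: e.value_mgdl for e in flow}
    for row in doses.itertuples():
        assert not row.out_of_protocol
        assert row.dose_units == DEFAULT_PROTOCOL.dose(by_entry[row.entry_id])


def test_administered_doses_monotone_in_transcribed_value(small_study):
    doses = generate_insulin_administrations(small_study.entries)
    d = doses.sort_values("value_mgdl")
    assert d.dose_units.is_monotonic_increasing
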