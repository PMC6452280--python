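import numpy as np
import pytest

from glucaudit.audit import (
    EMPTY_SUMMARY,
    classify,
    magnitude_summary,
    tally_undocumented,
    unique_patients_affected,
)
from glucaudit.linkage import MatchResult


# ---------------------------------------------------------------- classify

@pytest.mark.parametrize(
    "meter, paper, flow, label",
    [
        (180, 180, 180, "no_error"),
        (180, 108, 180, "paper_log_error"),
        (180, 180, 810, "flow_sheet_error"),
        (180, 108, 801, "both_error"),
        (180, None, 180, "no_error"),
        (180, None, 175, "flow_sheet_error"),
        (180, 108, None, "paper_log_error"),
        (180, None, None, "no_error"),
    ],
)
def test_classification_taxonomy(meter, paper, flow, label):
    assert classify(meter, paper, flow).label == label


def test_discrepancy_is_transcribed_minus_meter():
    ec = classify(180, 108, 180)
    assert ec.discrepancy["paper_log"] == -72
    assert ec.discrepancy["flow_sheet"] == 0


def test_classify_symmetric_under_source_swap():
    a = classify(200, 230, 200)
    b = classify(200, 200, 230)
    assert a.label == "paper_log_error" and b.label == "flow_sheet_error"
    assert a.discrepancy["paper_log"] == b.discrepancy["flow_sheet"] == 30


# ---------------------------------------------------------------- tallies

def _fake_results(n, miss_p, miss_f, miss_both):
    """miss_both records missing in both, then paper-only, flow-only misses."""
    res = []
    for i in range(n):
        r = MatchResult(record_id=f"R{i}")
        if i < miss_both:
            pass
        elif i < miss_p:
            r.matches["flow_sheet"] = f"F{i}"
        elif i < miss_p + (miss_f - miss_both):
            r.matches["paper_log"] = f"P{i}"
        else:
            r.matches["paper_log"] = f"P{i}"
            r.matches["flow_sheet"] = f"F{i}"
        res.append(r)
    return res


def test_tally_undocumented_study_counts():
    out = tally_undocumented(_fake_results(5049, 608, 2064, 239))
    assert out["paper_log"]["n"] == 608
    assert out["flow_sheet"]["n"] == 2064
    assert out["both"]["n"] == 239
    assert round(out["paper_log"]["pct"], 2) == 12.04
    assert round(out["flow_sheet"]["pct"], 2) == 40.88
    assert round(out["both"]["pct"], 2) == 4.73
    assert out["documented_both"] == 2616


def test_tally_zero_missing():
    out = tally_undocumented(_fake_results(100, 0, 0, 0))
    assert out["paper_log"]["pct"] == out["flow_sheet"]["pct"] == out["both"]["pct"] == 0.0


@pytest.mark.parametrize("seed", range(5))
def test_inclusion_exclusion_identity_on_random_indicators(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(10, 200))
    doc_p = rng.random(n) < rng.random()
    doc_f = rng.random(n) < rng.random()
    res = []
    for i in range(n):
        r = MatchResult(record_id=f"R{i}")
        if doc_p[i]:
            r.matches["paper_log"] = f"P{i}"
        if doc_f[i]:
            r.matches["flow_sheet"] = f"F{i}"
        res.append(r)
    out = tally_undocumented(res)
    # independent oracle: direct set counting
    assert out["documented_both"] == int((doc_p & doc_f).sum())
    assert out["both"]["n"] == int((~doc_p & ~doc_f).sum())
    assert (
        out["documented_both"]
        == n - out["paper_log"]["n"] - out["flow_sheet"]["n"] + out["both"]["n"]
    )


# ---------------------------------------------------------------- magnitudes

def _quartile_oracle(xs, q):
    """Sort-and-index linear interpolation, written independently."""
    xs = sorted(xs)
    h = (len(xs) - 1) * q
    lo = int(np.floor(h))
    if lo == len(xs) - 1:
        return float(xs[-1])
    return xs[lo] + (h - lo) * (xs[lo + 1] - xs[lo])


def test_magnitude_summary_range_fixture():
    fixture = [-92, -12, -5, -1, 2, 7, 92]
    s = magnitude_summary(fixture)
    assert s["min"] == -92 and s["max"] == 92
    assert s["mmol"]["min"] == -5.1 and s["mmol"]["max"] == 5.1


def test_magnitude_summary_single_element():
    s = magnitude_summary([5])
    assert s["min"] == s["q1"] == s["q3"] == s["max"] == 5


def test_magnitude_summary_empty_sentinel():
    assert magnitude_summary([]) == EMPTY_SUMMARY


@pytest.mark.parametrize("seed", range(6))
def test_quartiles_match_sort_and_index_oracle(seed):
    rng = np.random.default_rng(seed)
    xs = rng.integers(-110, 111, size=int(rng.integers(1, 21))).tolist()
    s = magnitude_summary(xs)
    assert s["q1"] == pytest.approx(_quartile_oracle(xs, 0.25))
    assert s["q3"] == pytest.approx(_quartile_oracle(xs, 0.75))
    assert s["min"] == min(xs) and s["max"] == max(xs)


# ---------------------------------------------------------------- patients

def test_patient_counted_once_per_category():
    labels = ["paper_log_error"] * 10
    vins = ["p1"] * 10
    assert unique_patients_affected(labels, vins)["paper_log_error"] == 1


def test_overall_is_union_across_categories():
    labels = ["paper_log_error", "paper_log_error", "flow_sheet_error", "flow_sheet_error"]
    vins = ["p1", "p2", "p2", "p3"]
    out = unique_patients_affected(labels, vins)
    assert out["paper_log_error"] == 2 and out["flow_sheet_error"] == 2
    assert out["overall"] == 3


def test_synthetic_patients_affected_matches_ground_truth(study):
    from glucaudit import TranscriptionAudit

    res = TranscriptionAudit(study.meters, study.entries, study.episodes).fit()
    lab = study.truth.labels
    recoverable = lab[lab.transcribed & (lab.within_window == True) & lab.injected_error]
    assert res.patients_affected["overall"] == recoverable.vin.nunique()
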