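"""Error classification and audit tallies.

A *transcription error* is any nonzero difference between a documented
value and the meter's value for the matched test — integer comparison,
no tolerance band, regardless of magnitude. Per-source error rates use
per-source documented denominators (tests never transcribed into a
source cannot be audited there); the joint category is evaluated among
tests documented in both sources.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .records import mgdl_to_mmol

SOURCES = ("paper_log", "flow_sheet")

LABELS = ("no_error", "paper_log_error", "flow_sheet_error", "both_error")


@dataclass(frozen=True)
class ErrorClass:
    """Classification of one matched test under the error taxonomy."""

    label: str
    documented: dict  # source -> bool
    discrepancy: dict  # source -> signed mg/dL (0 when correct or undocumented)


def classify(
    meter_value: int,
    paper_value: Optional[int] = None,
    flow_value: Optional[int] = None,
) -> ErrorClass:
    """Classify one test given its documented values (None = undocumented).

    Per-source classification is independent: a source is wrong iff its
    documented value differs from the meter value. The joint label is
    ``both_error`` only when both sources are documented and both wrong.
    """
    documented = {"paper_log": paper_value is not None, "flow_sheet": flow_value is not None}
    disc = {
        "paper_log": (paper_value - meter_value) if paper_value is not None else 0,
        "flow_sheet": (flow_value - meter_value) if flow_value is not None else 0,
    }
    wrong_p = documented["paper_log"] and disc["paper_log"] != 0
    wrong_f = documented["flow_sheet"] and disc["flow_sheet"] != 0
    if wrong_p and wrong_f:
        label = "both_error"
    elif wrong_p:
        label = "paper_log_error"
    elif wrong_f:
        label = "flow_sheet_error"
    else:
        label = "no_error"
    return ErrorClass(label=label, documented=documented, discrepancy=disc)


def tally_undocumented(matches) -> dict:
    """Per-source and joint undocumented counts and percentages.

    ``matches`` is a LinkageResult (or its ``results`` list). The joint
    count is records undocumented in *both* sources simultaneously; all
    percentages are of the total number of meter records.
    """
    results = getattr(matches, "results", matches)
    n = len(results)
    miss = {s: sum(not r.matched(s) for r in results) for s in SOURCES}
    miss_both = sum(
        not r.matched("paper_log") and not r.matched("flow_sheet") for r in results
    )
    out = {"n_tests": n}
    for s in SOURCES:
        out[s] = {"n": miss[s], "pct": 100.0 * miss[s] / n if n else 0.0}
    out["both"] = {"n": miss_both, "pct": 100.0 * miss_both / n if n else 0.0}
    # inclusion-exclusion: tests documented in both sources
    out["documented_both"] = n - miss["paper_log"] - miss["flow_sheet"] + miss_both
    return out


#: Sentinel returned for an empty discrepancy collection.
EMPTY_SUMMARY = {"min": None, "q1": None, "q3": None, "max": None, "n": 0}


def magnitude_summary(discrepancies: Sequence[float]) -> dict:
    """{min, q1, q3, max} of signed discrepancies, in mg/dL and mmol/L.

    Quartiles use linear interpolation between order statistics. The
    mmol/L figures convert the absolute magnitude and reattach the sign,
    matching how paired values are printed in clinical reports.
    """
    d = np.asarray(list(discrepancies), dtype=float)
    if d.size == 0:
        return dict(EMPTY_SUMMARY)
    stats = {
        "min": float(np.min(d)),
        "q1": float(np.quantile(d, 0.25)),
        "q3": float(np.quantile(d, 0.75)),
        "max": float(np.max(d)),
        "n": int(d.size),
    }
    stats["mmol"] = {
        k: float(np.sign(stats[k]) * mgdl_to_mmol(abs(stats[k])))
        for k in ("min", "q1", "q3", "max")
    }
    return stats


def unique_patients_affected(labels: Sequence[str], vins: Sequence[str]) -> dict:
    """Distinct-VIN counts per error category and overall.

    A patient is counted once per category regardless of how many errors
    they accumulated; ``overall`` is the union over all error categories.
    Inputs are aligned sequences of classification labels and VINs.
    """
    labels, vins = list(labels), list(vins)
    if len(labels) != len(vins):
        raise ValueError("labels and vins must align")
    per_cat: dict = {lab: set() for lab in LABELS if lab != "no_error"}
    for lab, vin in zip(labels, vins):
        if lab in per_cat:
            per_cat[lab].add(vin)
    overall = set().union(*per_cat.values()) if per_cat else set()
    out = {lab: len(v) for lab, v in per_cat.items()}
    out["overall"] = len(overall)
    return out


def classify_matches(meters, entries, linkage) -> pd.DataFrame:
    """Classify every meter record given a LinkageResult.

    Returns one row per record: record_id, vin, label, per-source
    documented flags and signed discrepancies, and the matched entry ids.
    """
    value_by_entry = {e.entry_id: e.value_mgdl for e in entries}
    meter_by_id = {m.record_id: m for m in meters}
    rows = []
    for r in linkage.results:
        m = meter_by_id[r.record_id]
        pv = value_by_entry.get(r.matches.get("paper_log"))
        fv = value_by_entry.get(r.matches.get("flow_sheet"))
        ec = classify(m.glucose_mgdl, pv, fv)
        rows.append(
            dict(
                record_id=m.record_id,
                vin=m.vin,
                test_time=m.test_time,
                glucose_mgdl=m.glucose_mgdl,
                label=ec.label,
                paper_documented=ec.documented["paper_log"],
                flow_documented=ec.documented["flow_sheet"],
                paper_discrepancy=ec.discrepancy["paper_log"],
                flow_discrepancy=ec.discrepancy["flow_sheet"],
                paper_entry_id=r.matches.get("paper_log"),
                flow_entry_id=r.matches.get("flow_sheet"),
            )
        )
    return pd.DataFrame(rows)


def error_table(classified: pd.DataFrame) -> dict:
    """Per-source and joint error counts with documented denominators."""
    doc_p = classified["paper_documented"]
    doc_f = classified["flow_documented"]
    err_p = doc_p & (classified["paper_discrepancy"] != 0)
    err_f = doc_f & (classified["flow_discrepancy"] != 0)
    both_doc = doc_p & doc_f
    both_err = both_doc & err_p & err_f

    def block(err_mask, denom_mask, disc=None):
        n_doc = int(denom_mask.sum())
        n_err = int(err_mask.sum())
        b = {
            "analyzed": n_doc,
            "errors": n_err,
            "pct": 100.0 * n_err / n_doc if n_doc else 0.0,
        }
        if disc is not None:
            b["magnitude"] = magnitude_summary(disc[err_mask])
        return b

    return {
        "paper_log": block(err_p, doc_p, classified["paper_discrepancy"]),
        "flow_sheet": block(err_f, doc_f, classified["flow_discrepancy"]),
        # the joint category: both documented, both wrong; magnitude is the
        # flow-sheet discrepancy (the value driving insulin decisions) —
        # reported although clinical audits typically leave it out
        "both": block(both_err, both_doc, classified["flow_discrepancy"]),
    }
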