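"""Study statistics: contingency tests, t tests, rates, latency summaries.

The shift comparison uses the Pearson chi-square on a 2x2 table of
errors vs non-errors by shift, with the Yates continuity correction on
by default (|O-E| reduced by 0.5 before squaring) — the correction is
standard for 2x2 tables with modest cell counts and is what clinical
journals typically print. The diabetic/nondiabetic test-count comparison
uses the unequal-variance (Welch) two-sample t from summary statistics
with Welch-Satterthwaite degrees of freedom; the pooled-variance variant
is available for sensitivity analysis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .audit import magnitude_summary
from .errors import DataIntegrityError


def chisq_2x2(table, continuity: bool = True) -> dict:
    """Pearson chi-square for a 2x2 count table, Yates-corrected by default.

    Returns {"statistic", "df", "p"}; df is always 1. Raises on a zero
    marginal (the test is undefined there).
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("table must be 2x2 with non-negative counts")
    rows, cols, n = t.sum(axis=1), t.sum(axis=0), t.sum()
    if (rows == 0).any() or (cols == 0).any():
        raise ValueError("chi-square undefined: a marginal total is zero")
    expected = np.outer(rows, cols) / n
    dev = np.abs(t - expected)
    if continuity:
        dev = np.maximum(dev - 0.5, 0.0)
    stat = float((dev**2 / expected).sum())
    return {"statistic": stat, "df": 1, "p": float(sps.chi2.sf(stat, 1))}


def welch_t_summary(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int
) -> dict:
    """Welch two-sample t from summary statistics.

    Returns {"t", "df", "df_rounded", "p"}; df by Welch-Satterthwaite.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("both groups need n >= 2")
    if sd1 < 0 or sd2 < 0:
        raise ValueError("standard deviations must be non-negative")
    v1, v2 = sd1**2 / n1, sd2**2 / n2
    if v1 + v2 == 0:
        raise ValueError("degenerate test: both standard deviations are zero")
    t = (mean1 - mean2) / math.sqrt(v1 + v2)
    df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    return {
        "t": t,
        "df": df,
        "df_rounded": int(round(df)),
        "p": float(2 * sps.t.sf(abs(t), df)),
    }


def pooled_t_summary(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int
) -> dict:
    """Classical pooled-variance (Student) t from summary statistics."""
    if n1 < 2 or n2 < 2:
        raise ValueError("both groups need n >= 2")
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / df
    if sp2 == 0:
        raise ValueError("degenerate test: pooled variance is zero")
    t = (mean1 - mean2) / math.sqrt(sp2 * (1 / n1 + 1 / n2))
    return {"t": t, "df": df, "df_rounded": df, "p": float(2 * sps.t.sf(abs(t), df))}


def per_patient_rate(error_count: int, n_patients: int) -> float:
    """Errors per patient, rounded to one decimal (fraction retained)."""
    if n_patients <= 0:
        raise ValueError("n_patients must be positive")
    return round(error_count / n_patients, 1)


def docking_summary(meters) -> dict:
    """Latency from test to meter docking, in fractional hours.

    Records without a dock time are counted separately as ``n_undocked``;
    a dock time before its test raises, naming the offending records.
    """
    latencies, undocked, bad = [], 0, []
    for m in meters:
        if m.dock_time is None:
            undocked += 1
            continue
        h = (m.dock_time - m.test_time).total_seconds() / 3600.0
        if h < 0:
            bad.append(m.record_id)
        latencies.append(h)
    if bad:
        raise DataIntegrityError(f"negative docking latency for records: {bad[:10]}")
    d = np.asarray(latencies, dtype=float)
    if d.size == 0:
        return {"mean": None, "median": None, "q1": None, "q3": None, "max": None,
                "n": 0, "n_undocked": undocked}
    return {
        "mean": float(d.mean()),
        "median": float(np.median(d)),
        "q1": float(np.quantile(d, 0.25)),
        "q3": float(np.quantile(d, 0.75)),
        "max": float(d.max()),
        "n": int(d.size),
        "n_undocked": undocked,
    }


# ---------------------------------------------------------------------------
# report assembly
# ---------------------------------------------------------------------------

@dataclass
class AuditReport:
    """The full audit summary; every percentage keeps its n/d pair."""

    cohort: dict
    test_counts: dict
    undocumented: dict
    errors: dict
    shift_tests: dict
    insulin: dict
    docking: dict
    post_discharge_count: int
    patients_affected: dict

    def tables(self) -> dict[str, pd.DataFrame]:
        """Machine-readable DataFrames, one per report block."""
        und = pd.DataFrame(
            [
                dict(
                    source=s,
                    undocumented_n=self.undocumented[s]["n"],
                    undocumented_pct=round(self.undocumented[s]["pct"], 2),
                    analyzed_n=self.errors[s]["analyzed"],
                    errors_n=self.errors[s]["errors"],
                    errors_pct=round(self.errors[s]["pct"], 2),
                    error_rate_per_patient=per_patient_rate(
                        self.errors[s]["errors"], self.cohort["n_patients"]
                    ),
                )
                for s in ("paper_log", "flow_sheet", "both")
            ]
        )
        shift = pd.DataFrame(
            [
                dict(source=s, **{k: v for k, v in blk.items()})
                for s, blk in self.shift_tests.items()
            ]
        )
        return {"documentation": und, "shift": shift}

    def summary(self) -> str:
        """Human-readable text report."""
        L = []
        c = self.cohort
        L.append("Glucose transcription-error audit")
        L.append("=" * 50)
        L.append(f"Patients: {c['n_patients']}   Tests: {self.undocumented['n_tests']}")
        L.append("")
        L.append("Documentation and transcription errors")
        L.append(
            f"{'source':<12}{'undoc n (%)':>16}{'analyzed':>10}{'errors n (%)':>16}"
            f"{'per patient':>13}"
        )
        for s in ("paper_log", "flow_sheet", "both"):
            u, e = self.undocumented[s], self.errors[s]
            rate = per_patient_rate(e["errors"], c["n_patients"])
            L.append(
                f"{s:<12}{u['n']:>8} ({u['pct']:5.2f}){e['analyzed']:>10}"
                f"{e['errors']:>8} ({e['pct']:5.2f}){rate:>13.1f}"
            )
        L.append(f"documented in both sources: {self.undocumented['documented_both']}")
        L.append("")
        L.append("Errors by shift (Yates-corrected chi-square)")
        for s, blk in self.shift_tests.items():
            L.append(
                f"  {s:<12} day {blk['day_errors']}/{blk['day_n']}  "
                f"night {blk['night_errors']}/{blk['night_n']}  "
                f"chi2={blk['statistic']:.1f} df={blk['df']} p={blk['p']:.2f}"
            )
        L.append("")
        ins = self.insulin
        L.append(
            f"Insulin errors: {ins['n_errors']} among {ins['n_assessed']} assessed "
            f"transcription errors; {ins.get('n_patients', 0)} patients affected"
        )
        if ins["n_errors"]:
            L.append(
                f"  dose discrepancy range: {ins['min_discrepancy']} to "
                f"{ins['max_discrepancy']} U"
            )
        d = self.docking
        if d["n"]:
            L.append(
                f"Docking latency (h): mean {d['mean']:.1f}, median {d['median']:.1f}, "
                f"IQR {d['q1']:.1f}-{d['q3']:.1f}, max {d['max']:.1f}"
            )
        L.append(f"Entries documented after discharge: {self.post_discharge_count}")
        pa = self.patients_affected
        L.append(
            f"Patients with any transcription error: {pa['overall']} "
            f"({100.0 * pa['overall'] / c['n_patients']:.1f}%)"
        )
        return "\n".join(L)


def render_report(
    episodes,
    meters,
    undocumented: dict,
    errors: dict,
    shift_tests: dict,
    insulin: dict,
    docking: dict,
    post_discharge_count: int,
    patients_affected: dict,
) -> AuditReport:
    """Assemble the audit report from stage outputs (consistency-checked)."""
    n_tests = undocumented.get("n_tests", 0)
    if n_tests != len(list(meters)):
        raise DataIntegrityError(
            f"stage outputs disagree: {n_tests} tests tallied vs {len(list(meters))} meter records"
        )
    episodes = list(episodes)
    ages = [e.age for e in episodes]
    cohort = {
        "n_patients": len(episodes),
        "age_mean": float(np.mean(ages)) if ages else None,
        "age_sd": float(np.std(ages, ddof=1)) if len(ages) > 1 else None,
        "male_n": sum(e.sex == "male" for e in episodes),
        "diabetes": {
            k: sum(e.diabetes == k for e in episodes) for k in ("yes", "no", "unknown")
        },
    }
    counts = pd.Series([m.vin for m in meters]).value_counts()
    by_status = {}
    status_of = {e.vin: e.diabetes for e in episodes}
    for st in ("yes", "no"):
        vals = [int(counts[v]) for v in counts.index if status_of.get(v) == st]
        if vals:
            by_status[st] = {
                "n": len(vals),
                "min": int(min(vals)),
                "median": float(np.median(vals)),
                "mean": float(np.mean(vals)),
                "sd": float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0,
                "max": int(max(vals)),
            }
    test_counts = {"by_status": by_status}
    if "yes" in by_status and "no" in by_status:
        a, b = by_status["yes"], by_status["no"]
        if a["n"] >= 2 and b["n"] >= 2 and (a["sd"] or b["sd"]):
            test_counts["welch"] = welch_t_summary(
                a["mean"], a["sd"], a["n"], b["mean"], b["sd"], b["n"]
            )
    return AuditReport(
        cohort=cohort,
        test_counts=test_counts,
        undocumented=undocumented,
        errors=errors,
        shift_tests=shift_tests,
        insulin=insulin,
        docking=docking,
        post_discharge_count=post_discharge_count,
        patients_affected=patients_affected,
    )
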