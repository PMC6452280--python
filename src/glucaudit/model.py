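"""Model-style front end: build an audit from data, fit, inspect results.

    >>> from glucaudit import TranscriptionAudit
    >>> from glucaudit.synthetic import generate_dataset
    >>> ds = generate_dataset(seed=7)
    >>> res = TranscriptionAudit(ds.meters, ds.entries, ds.episodes).fit()
    >>> print(res.summary())

`TranscriptionAudit` holds the three record streams and the audit
configuration (matching window, shift boundaries, insulin protocol);
`fit()` runs linkage, classification, insulin assessment and the study
statistics, returning an :class:`AuditResults` carrying every table with
its numerator/denominator pairs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd

from . import audit as _audit
from . import linkage as _linkage
from . import stats as _stats
from .insulin import DEFAULT_PROTOCOL, InsulinProtocol, assess_insulin
from .records import ShiftConfig, assign_shift, read_stream

SOURCES = ("paper_log", "flow_sheet")


class TranscriptionAudit:
    """Transcription-error audit of a reference meter stream.

    Parameters
    ----------
    meters, entries, episodes
        Collections of MeterRecord, TranscribedEntry and PatientEpisode.
    window_minutes : float
        Matching window after the test (default 60).
    forward_only : bool
        Whether transcriptions may only follow the test (default True);
        set False for a symmetric-window sensitivity analysis.
    shift : ShiftConfig
        Day/night boundaries for the shift stratification.
    protocol : InsulinProtocol
        Sliding scale used to translate glucose discrepancies into dose
        discrepancies.
    """

    def __init__(
        self,
        meters,
        entries,
        episodes,
        window_minutes: float = 60.0,
        forward_only: bool = True,
        shift: ShiftConfig = ShiftConfig(),
        protocol: InsulinProtocol = DEFAULT_PROTOCOL,
        continuity: bool = True,
    ):
        self.meters = list(meters)
        self.entries = list(entries)
        self.episodes = list(episodes)
        self.window_minutes = window_minutes
        self.forward_only = forward_only
        self.shift = shift
        self.protocol = protocol
        self.continuity = continuity

    @classmethod
    def from_csv(cls, meters_path, entries_path, episodes_path, **kwargs):
        return cls(
            read_stream(meters_path, "meter"),
            read_stream(entries_path, "entry"),
            read_stream(episodes_path, "episode"),
            **kwargs,
        )

    def fit(self) -> "AuditResults":
        link = _linkage.match_records(
            self.meters,
            self.entries,
            window_minutes=self.window_minutes,
            forward_only=self.forward_only,
        )
        classified = _audit.classify_matches(self.meters, self.entries, link)
        undocumented = _audit.tally_undocumented(link)
        errors = _audit.error_table(classified)
        shift_tests = self._shift_tests(classified)
        insulin = self._insulin_summary(classified)
        docking = _stats.docking_summary(self.meters)
        post = _linkage.flag_post_discharge(self.entries, self.episodes)
        patients = _audit.unique_patients_affected(classified["label"], classified["vin"])
        report = _stats.render_report(
            self.episodes,
            self.meters,
            undocumented,
            errors,
            shift_tests,
            insulin,
            docking,
            len(post),
            patients,
        )
        return AuditResults(
            model=self,
            report=report,
            linkage=link,
            classified=classified,
            post_discharge_entries=post,
        )

    # -- helpers ------------------------------------------------------------

    def _shift_tests(self, classified: pd.DataFrame) -> dict:
        shifts = classified["test_time"].map(lambda t: assign_shift(t, self.shift))
        day = shifts == "day"
        masks = {
            "paper_log": (
                classified["paper_documented"],
                classified["paper_discrepancy"] != 0,
            ),
            "flow_sheet": (
                classified["flow_documented"],
                classified["flow_discrepancy"] != 0,
            ),
            "both": (
                classified["paper_documented"] & classified["flow_documented"],
                (classified["paper_discrepancy"] != 0)
                & (classified["flow_discrepancy"] != 0),
            ),
        }
        out = {}
        for source, (doc, err) in masks.items():
            err = doc & err
            blk = {
                "day_n": int((doc & day).sum()),
                "day_errors": int((err & day).sum()),
                "night_n": int((doc & ~day).sum()),
                "night_errors": int((err & ~day).sum()),
            }
            table = [
                [blk["day_errors"], blk["day_n"] - blk["day_errors"]],
                [blk["night_errors"], blk["night_n"] - blk["night_errors"]],
            ]
            try:
                blk.update(_stats.chisq_2x2(table, continuity=self.continuity))
            except ValueError:
                blk.update({"statistic": None, "df": 1, "p": None})
            out[source] = blk
        return out

    def _insulin_summary(self, classified: pd.DataFrame) -> dict:
        """Insulin assessments of every transcription-error case.

        Per-category views mirror the error table: paper-log errors
        assessed through the paper-log value, flow-sheet errors through
        the flow-sheet value (the value that drives dosing), the joint
        category through the flow-sheet value. Insulin errors are
        counted per test.
        """
        cats = {}
        any_err_records = set()
        any_err_vins = {}
        specs = {
            "paper_log": (classified["paper_discrepancy"] != 0)
            & classified["paper_documented"],
            "flow_sheet": (classified["flow_discrepancy"] != 0)
            & classified["flow_documented"],
        }
        specs["both"] = specs["paper_log"] & specs["flow_sheet"]
        col = {"paper_log": "paper_discrepancy", "flow_sheet": "flow_discrepancy",
               "both": "flow_discrepancy"}
        for cat, mask in specs.items():
            sub = classified[mask]
            assessments, vins = [], []
            for _, row in sub.iterrows():
                a = assess_insulin(
                    int(row["glucose_mgdl"]),
                    int(row["glucose_mgdl"] + row[col[cat]]),
                    self.protocol,
                )
                assessments.append(a)
                vins.append(row["vin"])
                if a.is_error and cat in ("paper_log", "flow_sheet"):
                    any_err_records.add(row["record_id"])
                    any_err_vins[row["record_id"]] = row["vin"]
            from .insulin import summarize_insulin_errors

            cats[cat] = summarize_insulin_errors(assessments, vins)
        n_assessed_unique = int((specs["paper_log"] | specs["flow_sheet"]).sum())
        overall = {
            # unique tests: a test wrong in both sources is assessed in both
            # category views but counted once here
            "n_assessed": n_assessed_unique,
            "n_errors": len(any_err_records),
            "n_unique_tests": len(any_err_records),
            "n_patients": len(set(any_err_vins.values())),
            "min_discrepancy": min(
                (c["min_discrepancy"] for c in cats.values() if c["min_discrepancy"] is not None),
                default=None,
            ),
            "max_discrepancy": max(
                (c["max_discrepancy"] for c in cats.values() if c["max_discrepancy"] is not None),
                default=None,
            ),
            "by_category": cats,
        }
        return overall


@dataclass
class AuditResults:
    """Fitted audit: report, linkage, per-test classifications."""

    model: TranscriptionAudit
    report: _stats.AuditReport
    linkage: _linkage.LinkageResult
    classified: pd.DataFrame
    post_discharge_entries: list

    def summary(self) -> str:
        return self.report.summary()

    def tables(self) -> dict:
        return self.report.tables()

    @property
    def undocumented(self) -> dict:
        return self.report.undocumented

    @property
    def errors(self) -> dict:
        return self.report.errors

    @property
    def insulin(self) -> dict:
        return self.report.insulin

    @property
    def docking(self) -> dict:
        return self.report.docking

    @property
    def shift_tests(self) -> dict:
        return self.report.shift_tests

    @property
    def patients_affected(self) -> dict:
        return self.report.patients_affected
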