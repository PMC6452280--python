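"""Temporal linkage of meter records to transcription entries.

Each reference meter record is matched, per documentation source, to the
entry with the same patient VIN, the same calendar date, and a
transcription timestamp within a 1-hour window *after* the test
(forward-only: a transcription cannot precede the test it copies).
Matching is globally one-to-one per source: among all feasible
record-entry pairings it maximises the number of matched records and,
among those, minimises the total time offset (solved as a rectangular
assignment problem per patient-day), with ties broken by entry id for
determinism. A meter record with no match in a source is *undocumented*
there; an entry consumed by no record is an *orphan*.

Two point-of-care tests on the same patient within the same hour compete
for entries; the one-to-one minimum-offset assignment is this package's
resolution of that ambiguity (configurable window; symmetric windows are
available for sensitivity analysis) and is checked against a brute-force
enumeration oracle on small instances in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .errors import DataIntegrityError
from .records import MeterRecord, PatientEpisode, TranscribedEntry

SOURCES = ("paper_log", "flow_sheet")


@dataclass
class MatchResult:
    """Linkage outcome for one meter record."""

    record_id: str
    matches: dict = field(default_factory=dict)  # source -> entry_id or None
    offsets: dict = field(default_factory=dict)  # source -> minutes or None

    def matched(self, source: str) -> bool:
        return self.matches.get(source) is not None


@dataclass
class LinkageResult:
    """All match results plus per-source orphan entries."""

    results: list
    orphans: dict  # source -> list of entry_ids never matched

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.results:
            for source in SOURCES:
                rows.append(
                    dict(
                        record_id=r.record_id,
                        source=source,
                        entry_id=r.matches.get(source),
                        offset_minutes=r.offsets.get(source),
                        status="matched" if r.matched(source) else "undocumented",
                    )
                )
        return pd.DataFrame(rows)


def match_records(
    meters: Sequence[MeterRecord],
    entries: Sequence[TranscribedEntry],
    window_minutes: float = 60.0,
    forward_only: bool = True,
) -> LinkageResult:
    """Match meter records to entries per source under the window rule.

    Candidates share the VIN and the calendar date of the test, with
    offset = entry_time - test_time satisfying 0 <= offset <= window
    (or |offset| <= window when ``forward_only`` is False). Per
    patient-day the feasible pairs are resolved as a one-to-one
    assignment maximising matched records and minimising total |offset|;
    equal-offset ties go to the lexicographically earlier entry id.
    """
    if window_minutes <= 0:
        raise ValueError("window_minutes must be positive")
    ids = [e.entry_id for e in entries]
    if len(ids) != len(set(ids)):
        raise DataIntegrityError("duplicate entry_ids in transcription entries")

    # infeasible-pair cost; must dominate any sum of feasible offsets so the
    # assignment first maximises cardinality, then minimises total offset
    big = 1e9

    results = {m.record_id: MatchResult(record_id=m.record_id) for m in meters}
    orphans = {}
    for source in SOURCES:
        src_entries = [e for e in entries if e.source == source]
        by_key: dict = {}
        for e in src_entries:
            by_key.setdefault((e.vin, e.entry_time.date()), []).append(e)
        groups: dict = {}
        for m in meters:
            groups.setdefault((m.vin, m.test_time.date()), []).append(m)

        used_entries: set = set()
        for key, ms in groups.items():
            cand = by_key.get(key, [])
            if not cand:
                continue
            cand = sorted(cand, key=lambda e: e.entry_id)
            cost = np.full((len(ms), len(cand)), big)
            offs = np.zeros_like(cost)
            for i, m in enumerate(ms):
                for j, e in enumerate(cand):
                    off = (e.entry_time - m.test_time).total_seconds() / 60.0
                    ok = (
                        (0 <= off <= window_minutes)
                        if forward_only
                        else (abs(off) <= window_minutes)
                    )
                    offs[i, j] = off
                    if ok:
                        # epsilon on the entry index makes equal-offset ties
                        # deterministic in favour of the earlier entry id
                        cost[i, j] = abs(off) + 1e-9 * j
            rows, cols = linear_sum_assignment(cost)
            for i, j in zip(rows, cols):
                if cost[i, j] >= big:
                    continue
                rid = ms[i].record_id
                results[rid].matches[source] = cand[j].entry_id
                results[rid].offsets[source] = float(offs[i, j])
                used_entries.add(cand[j].entry_id)
        orphans[source] = sorted(
            e.entry_id for e in src_entries if e.entry_id not in used_entries
        )

    return LinkageResult(results=list(results.values()), orphans=orphans)


def flag_post_discharge(
    entries: Sequence[TranscribedEntry], episodes: Sequence[PatientEpisode]
) -> list[TranscribedEntry]:
    """Entries timestamped strictly after their episode's discharge.

    Entries whose VIN is unknown are ignored here (they surface as
    orphans in linkage).
    """
    discharge = {e.vin: e.discharge for e in episodes}
    return [
        e
        for e in entries
        if e.vin in discharge and e.entry_time > discharge[e.vin]
    ]
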