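"""Shift-stratified test sampling with episode expansion.

The study design audits a fraction of all meter tests, stratified by
working shift (fatigue at shift end is the hypothesised error driver),
then *expands* the sample to every test belonging to the same admission
episode so errors can be evaluated per patient. A test's stratum is the
shift of its test time — the moment the transcription act happened.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .records import MeterRecord, ShiftConfig, assign_shift


def stratified_sample(
    meters: Sequence[MeterRecord],
    fraction: float,
    shift: ShiftConfig = ShiftConfig(),
    seed: int = 0,
) -> list[MeterRecord]:
    """Draw floor(fraction x stratum size) records per shift stratum.

    Sampling is uniform without replacement within each stratum and
    deterministic under ``seed``. An empty input yields an empty sample.
    """
    if not 0 < fraction <= 1:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    meters = list(meters)
    if not meters:
        return []
    rng = np.random.default_rng(seed)
    out = []
    for label in ("day", "night"):
        stratum = [m for m in meters if assign_shift(m.test_time, shift) == label]
        k = int(np.floor(fraction * len(stratum)))
        if k > 0:
            idx = rng.choice(len(stratum), size=k, replace=False)
            out.extend(stratum[i] for i in sorted(idx))
    return out


def expand_episodes(
    sampled: Sequence[MeterRecord], all_meters: Sequence[MeterRecord]
) -> list[MeterRecord]:
    """All records of ``all_meters`` whose VIN appears in the sample.

    A superset of the sample with no duplicates; idempotent.
    """
    sampled_ids = {m.record_id for m in sampled}
    all_ids = {m.record_id for m in all_meters}
    if not sampled_ids <= all_ids:
        raise ValueError("sampled records must be a subset of all_meters")
    vins = {m.vin for m in sampled}
    return [m for m in all_meters if m.vin in vins]
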