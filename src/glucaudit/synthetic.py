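"""Synthetic study generator with ground-truth labels.

Real point-of-care audit data are protected hospital records, so every
downstream stage is exercised against a generated surrogate: a cohort of
admission episodes, a reference meter stream, and two transcription
streams into which missingness and value errors are injected at
configured rates. Every injection decision is recorded in a
:class:`GroundTruth` table so the audit pipeline's output can be checked
label-by-label.

Calibration defaults emulate a four-month surgical-trauma ICU audit:
234 episodes yielding ~5049 tests with heavy-tailed per-patient counts
(negative binomial per diabetes status), per-source undocumented rates
of 12.04% (paper log) and 40.88% (flow sheet) with 4.73% jointly
missing, per-source error rates 2.21% / 8.11% with a correlated joint
rate of 1.64% (nurses sometimes copy the technician's wrong paper-log
value), right-skewed meter docking latencies (median 5.5 h, mean 8 h,
max ~56 h), a day-heavy shift mix, and a small count of anomalous
entries timestamped after discharge.

Two structural simplifications keep injected labels exactly recoverable
by the 1-hour-window matcher: same-patient tests are spaced at least
~2 h apart, and a transcription is timestamped on the same calendar date
as its test. Real streams violate both; the matcher handles collisions
by its one-to-one nearest-offset rule, which is oracle-tested
separately.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from datetime import datetime, timedelta
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError
from .insulin import DEFAULT_PROTOCOL, InsulinProtocol
from .records import MeterRecord, PatientEpisode, TranscribedEntry

SOURCES = ("paper_log", "flow_sheet")

#: Minimum gap between two tests on the same patient, minutes (post clock-warp).
MIN_SAME_VIN_GAP_MIN = 125.0


def _check_prob(name: str, p: float) -> None:
    if not 0.0 <= p <= 1.0:
        raise ConfigError(f"{name} must be a probability, got {p}")


@dataclass
class GeneratorConfig:
    """All knobs of the synthetic study; defaults are the study conditions."""

    n_patients: int = 234
    diabetes_mix: dict = field(
        default_factory=lambda: {"yes": 44 / 234, "no": 93 / 234, "unknown": 97 / 234}
    )
    # per-status negative-binomial test-count targets (mean, sd)
    count_mean: dict = field(
        default_factory=lambda: {"yes": 60.0, "no": 19.0, "unknown": 6.6}
    )
    count_sd: dict = field(
        default_factory=lambda: {"yes": 126.0, "no": 40.0, "unknown": 12.0}
    )
    # lognormal glucose, truncated to the reportable range
    glucose_median: float = 140.0
    glucose_sigma: float = 0.35
    reportable: tuple = (10, 600)
    # per-source probability a result is never transcribed; joint = both missing
    miss_prob: dict = field(
        default_factory=lambda: {"paper_log": 0.1204, "flow_sheet": 0.4088}
    )
    joint_miss_prob: float = 0.0473
    # per-source probability a transcribed value is wrong; joint = both wrong
    error_prob: dict = field(
        default_factory=lambda: {"paper_log": 0.0221, "flow_sheet": 0.0811}
    )
    joint_error_prob: float = 0.0164
    copy_prob: float = 0.8  # P(flow copies the wrong paper value | both wrong)
    # signed-slip magnitude model: uniform 1..small_slip_max with P(negative),
    # plus a digit-transposition tail
    small_slip_max: dict = field(
        default_factory=lambda: {"paper_log": 15, "flow_sheet": 6}
    )
    neg_prob: dict = field(default_factory=lambda: {"paper_log": 0.62, "flow_sheet": 0.45})
    transpose_prob: dict = field(
        default_factory=lambda: {"paper_log": 0.15, "flow_sheet": 0.10}
    )
    max_error_magnitude: int = 115
    # docking latency: lognormal hours, resampled above the max
    dock_median_h: float = 5.5
    dock_mean_h: float = 8.0
    dock_max_h: float = 60.0
    # transcription delay, minutes; a small late tail falls outside the window
    delay_min: float = 2.0
    delay_max: float = 58.0
    late_prob: float = 0.004
    late_min: float = 61.0
    late_max: float = 120.0
    # anomalous documentation after discharge
    post_discharge_count: int = 40
    # clock-time mix: share of tests performed on the day shift (07:00-19:00)
    day_share: float = 0.62
    # demographics
    age_mean: float = 57.5
    age_sd: float = 17.4
    male_prob: float = 0.56
    los_mean_days: float = 24.8
    los_sd_days: float = 48.3
    study_start: datetime = datetime(2016, 7, 1)
    study_span_days: int = 122
    n_operators: int = 13

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ConfigError("n_patients must be positive")
        total = sum(self.diabetes_mix.values())
        if total <= 0:
            raise ConfigError("diabetes_mix is degenerate (all zero)")
        for s in SOURCES:
            _check_prob(f"miss_prob[{s}]", self.miss_prob[s])
            _check_prob(f"error_prob[{s}]", self.error_prob[s])
        _check_prob("joint_miss_prob", self.joint_miss_prob)
        _check_prob("joint_error_prob", self.joint_error_prob)
        _check_prob("copy_prob", self.copy_prob)
        _check_prob("late_prob", self.late_prob)
        _check_prob("day_share", self.day_share)
        if self.joint_miss_prob > min(self.miss_prob.values()) + 1e-12:
            raise ConfigError("joint_miss_prob exceeds a per-source miss probability")
        if self.joint_error_prob > min(self.error_prob.values()) + 1e-12:
            raise ConfigError("joint_error_prob exceeds a per-source error probability")
        ep, ef = self.error_prob["paper_log"], self.error_prob["flow_sheet"]
        if ep < 1.0 and (ef - self.joint_error_prob) > (1.0 - ep) + 1e-12:
            raise ConfigError("joint_error_prob incompatible with the marginals")

    # -- derived quantities the recovery tests compare against -------------
    def expected_undocumented_prob(self, source: str) -> float:
        """P(the audit sees no in-window entry) = missing or transcribed late."""
        m = self.miss_prob[source]
        return m + (1.0 - m) * self.late_prob

    def expected_joint_undocumented_prob(self) -> float:
        mp, mf = self.miss_prob["paper_log"], self.miss_prob["flow_sheet"]
        jb = self.joint_miss_prob
        lp = self.late_prob
        both_miss = jb
        p_only = mp - jb
        f_only = mf - jb
        neither = 1.0 - mp - mf + jb
        return both_miss + p_only * lp + f_only * lp + neither * lp * lp


@dataclass
class GroundTruth:
    """Per record and source: what the generator actually did.

    ``labels`` has one row per (meter record, source) with columns
    transcribed, entry_id, injected_error, injected_delta and
    within_window (True only when the entry is matchable under the
    1-hour same-date rule; None when untranscribed).
    ``post_discharge_entry_ids`` lists the injected anomalous entries.
    """

    labels: pd.DataFrame
    post_discharge_entry_ids: list


# ---------------------------------------------------------------------------
# cohort
# ---------------------------------------------------------------------------

def generate_cohort(config: GeneratorConfig, seed: int) -> list[PatientEpisode]:
    """Draw ``n_patients`` admission episodes with unique VINs."""
    config.validate()
    rng = np.random.default_rng(seed)
    statuses = list(config.diabetes_mix)
    probs = np.array([config.diabetes_mix[s] for s in statuses], dtype=float)
    probs = probs / probs.sum()

    # lognormal length of stay matched to the target mean/sd by moments
    cv2 = (config.los_sd_days / config.los_mean_days) ** 2
    sigma = math.sqrt(math.log1p(cv2))
    mu = math.log(config.los_mean_days) - sigma**2 / 2

    episodes = []
    for i in range(config.n_patients):
        status = statuses[rng.choice(len(statuses), p=probs)]
        age = int(np.clip(rng.normal(config.age_mean, config.age_sd), 16, 100))
        sex = "male" if rng.random() < config.male_prob else "female"
        admit = config.study_start + timedelta(
            days=float(rng.uniform(0, config.study_span_days)),
        )
        admit = admit.replace(microsecond=0)
        los_days = max(0.25, float(rng.lognormal(mu, sigma)))
        discharge = admit + timedelta(days=los_days)
        discharge = discharge.replace(microsecond=0)
        episodes.append(
            PatientEpisode(
                vin=f"VIN{i + 1:05d}",
                age=age,
                sex=sex,
                diabetes=status,
                admit=admit,
                discharge=discharge,
            )
        )
    return episodes


# ---------------------------------------------------------------------------
# meter stream
# ---------------------------------------------------------------------------

def _nb_draw(rng, mean: float, sd: float, size: int):
    """Negative-binomial counts matched to (mean, sd); Poisson if not overdispersed."""
    var = sd * sd
    if var <= mean:
        return rng.poisson(mean, size=size)
    r = mean * mean / (var - mean)
    p = r / (r + mean)
    return rng.negative_binomial(r, p, size=size)


def _clock_warp(day_share: float):
    """Piecewise-linear map of a uniform clock onto a day-heavy one.

    Maps [0, 24) onto itself, sending a ``day_share`` fraction of uniform
    clock mass into the 07:00-19:00 window. Returns (xp, fp, min_slope).
    """
    w_day = day_share * 24.0
    w_night = 24.0 - w_day
    ne = w_night * (7.0 / 12.0)  # source width mapping to 00:00-07:00
    nl = w_night * (5.0 / 12.0)  # source width mapping to 19:00-24:00
    xp = [0.0, ne, ne + w_day, 24.0]
    fp = [0.0, 7.0, 19.0, 24.0]
    min_slope = min(7.0 / ne, 12.0 / w_day, 5.0 / nl)
    return xp, fp, min_slope


def generate_meter_stream(
    episodes: Sequence[PatientEpisode], config: GeneratorConfig, seed: int
):
    """Generate the reference meter stream.

    Returns ``(records, episodes_out)``: the discharge of an episode is
    extended when its drawn test count needs more room than the
    provisional stay (test times must lie within the stay with enough
    spacing for unambiguous window matching), so the possibly-adjusted
    episode list is returned alongside the records.
    """
    if not episodes:
        raise ConfigError("episodes must be nonempty")
    config.validate()
    rng = np.random.default_rng(seed)
    xp, fp, min_slope = _clock_warp(config.day_share)
    pre_step_min = MIN_SAME_VIN_GAP_MIN / min_slope  # pre-warp spacing floor

    glu_mu = math.log(config.glucose_median)
    dock_mu = math.log(config.dock_median_h)
    dock_sigma = math.sqrt(max(1e-9, 2.0 * math.log(config.dock_mean_h / config.dock_median_h)))
    lo, hi = config.reportable

    records: list[MeterRecord] = []
    episodes_out: list[PatientEpisode] = []
    rid = 0
    for ep in episodes:
        k = int(_nb_draw(rng, config.count_mean[ep.diabetes], config.count_sd[ep.diabetes], 1)[0])
        stay_min = (ep.discharge - ep.admit).total_seconds() / 60.0
        step = max(pre_step_min + 10.0, stay_min / (k + 1))
        needed = step * (k + 1)
        if needed > stay_min:
            ep = replace(ep, discharge=ep.admit + timedelta(minutes=needed))
        episodes_out.append(ep)
        if k == 0:
            continue
        jit = min(30.0, (step - pre_step_min) / 2.0)
        offsets = step * np.arange(1, k + 1) + rng.uniform(-jit, jit, size=k)
        t_pre = pd.Timestamp(ep.admit) + pd.to_timedelta(offsets, unit="m")
        midnight = t_pre.normalize()
        clock = (t_pre - midnight).total_seconds() / 3600.0
        warped = np.interp(clock, xp, fp)
        times = (midnight + pd.to_timedelta(warped, unit="h")).floor("s")
        glucose = np.clip(
            np.round(rng.lognormal(glu_mu, config.glucose_sigma, size=k)), lo, hi
        ).astype(int)
        lat = rng.lognormal(dock_mu, dock_sigma, size=k)
        bad = lat > config.dock_max_h
        while bad.any():
            lat[bad] = rng.lognormal(dock_mu, dock_sigma, size=int(bad.sum()))
            bad = lat > config.dock_max_h
        docks = (times + pd.to_timedelta(lat, unit="h")).floor("s")
        ops = rng.integers(1, config.n_operators + 1, size=k)
        for i in range(k):
            rid += 1
            records.append(
                MeterRecord(
                    record_id=f"R{rid:06d}",
                    vin=ep.vin,
                    test_time=times[i].to_pydatetime(),
                    glucose_mgdl=int(glucose[i]),
                    operator_id=f"TECH{int(ops[i]):02d}",
                    dock_time=docks[i].to_pydatetime(),
                )
            )
    return records, episodes_out


# ---------------------------------------------------------------------------
# transcription streams
# ---------------------------------------------------------------------------

def _transpose_digits(value: int, rng) -> Optional[int]:
    """Swap one adjacent digit pair; None when no swap changes the value."""
    s = list(str(value))
    if len(s) < 2:
        return None
    idxs = [i for i in range(len(s) - 1) if s[i] != s[i + 1]]
    if not idxs:
        return None
    i = int(rng.choice(idxs))
    s[i], s[i + 1] = s[i + 1], s[i]
    if s[0] == "0":
        return None
    return int("".join(s))


def _draw_delta(value: int, source: str, config: GeneratorConfig, rng) -> int:
    """Signed transcription slip, guaranteed nonzero and in-range."""
    lo, hi = config.reportable
    for _ in range(50):
        if rng.random() < config.transpose_prob[source]:
            wrong = _transpose_digits(value, rng)
            if wrong is None:
                continue
            delta = wrong - value
        else:
            mag = int(rng.integers(1, config.small_slip_max[source] + 1))
            sign = -1 if rng.random() < config.neg_prob[source] else 1
            delta = sign * mag
        if delta != 0 and lo <= value + delta <= hi and abs(delta) <= config.max_error_magnitude:
            return delta
    # extremely unlikely fallback: smallest in-range slip
    return 1 if value + 1 <= hi else -1


def _end_of_day(t: datetime) -> datetime:
    return t.replace(hour=23, minute=59, second=59, microsecond=0)


def generate_transcriptions(
    meters: Sequence[MeterRecord],
    config: GeneratorConfig,
    seed: int,
    episodes: Optional[Sequence[PatientEpisode]] = None,
):
    """Inject missingness and transcription errors; return entries + labels.

    Per meter record a coupled four-cell draw decides which sources
    document it (honouring the joint missing probability); documented
    sources receive an entry timestamped on the test's calendar date,
    usually within the hour, occasionally late. Error indicators are
    drawn with the configured paper/flow coupling; when both sources are
    wrong the flow sheet usually repeats the paper log's wrong value.

    When ``episodes`` is given, entry times are additionally clamped to
    the episode discharge and ``post_discharge_count`` anomalous extra
    entries are appended after discharge.
    """
    if not meters:
        raise ConfigError("meters must be nonempty")
    config.validate()
    rng = np.random.default_rng(seed)

    mp, mf = config.miss_prob["paper_log"], config.miss_prob["flow_sheet"]
    jb = config.joint_miss_prob
    cell_p = np.array([jb, mp - jb, mf - jb, 1.0 - mp - mf + jb])
    if (cell_p < -1e-12).any():
        raise ConfigError("joint_miss_prob exceeds a marginal miss probability")
    cell_p = np.clip(cell_p, 0.0, 1.0)
    cell_p /= cell_p.sum()

    ep_err = config.error_prob["paper_log"]
    ef_err = config.error_prob["flow_sheet"]
    if ep_err > 0:
        c1 = min(1.0, config.joint_error_prob / ep_err)
        c0 = (ef_err - ep_err * c1) / (1.0 - ep_err) if ep_err < 1.0 else 0.0
    else:
        c1, c0 = 0.0, ef_err
    c0 = min(1.0, max(0.0, c0))

    discharge_by_vin = {e.vin: e.discharge for e in episodes} if episodes else {}

    entries: list[TranscribedEntry] = []
    rows = []
    counters = {"paper_log": 0, "flow_sheet": 0}
    prefix = {"paper_log": "P", "flow_sheet": "F"}

    for rec in meters:
        cell = int(rng.choice(4, p=cell_p))
        documented = {
            "paper_log": cell in (2, 3),
            "flow_sheet": cell in (1, 3),
        }
        err = {"paper_log": rng.random() < ep_err}
        err["flow_sheet"] = rng.random() < (c1 if err["paper_log"] else c0)

        delta = {"paper_log": 0, "flow_sheet": 0}
        if err["paper_log"]:
            delta["paper_log"] = _draw_delta(rec.glucose_mgdl, "paper_log", config, rng)
        if err["flow_sheet"]:
            if err["paper_log"] and rng.random() < config.copy_prob:
                delta["flow_sheet"] = delta["paper_log"]
            else:
                delta["flow_sheet"] = _draw_delta(rec.glucose_mgdl, "flow_sheet", config, rng)

        for source in SOURCES:
            if not documented[source]:
                rows.append(
                    dict(
                        record_id=rec.record_id,
                        vin=rec.vin,
                        source=source,
                        transcribed=False,
                        entry_id=None,
                        injected_error=False,
                        injected_delta=0,
                        within_window=None,
                    )
                )
                continue
            late = rng.random() < config.late_prob
            if late:
                delay = float(rng.uniform(config.late_min, config.late_max))
            else:
                delay = float(rng.uniform(config.delay_min, config.delay_max))
            t = rec.test_time + timedelta(minutes=delay)
            t = min(t, _end_of_day(rec.test_time))
            if rec.vin in discharge_by_vin:
                t = min(t, discharge_by_vin[rec.vin])
            t = max(t.replace(microsecond=0), rec.test_time)
            offset_min = (t - rec.test_time).total_seconds() / 60.0
            within = offset_min <= 60.0

            is_err = bool(err[source])
            d = int(delta[source]) if is_err else 0
            counters[source] += 1
            eid = f"{prefix[source]}{counters[source]:06d}"
            entries.append(
                TranscribedEntry(
                    entry_id=eid,
                    source=source,
                    vin=rec.vin,
                    entry_time=t,
                    value_mgdl=rec.glucose_mgdl + d,
                )
            )
            rows.append(
                dict(
                    record_id=rec.record_id,
                    vin=rec.vin,
                    source=source,
                    transcribed=True,
                    entry_id=eid,
                    injected_error=is_err,
                    injected_delta=d,
                    within_window=within,
                )
            )

    post_ids = []
    if episodes and config.post_discharge_count > 0:
        glu_mu = math.log(config.glucose_median)
        lo, hi = config.reportable
        eps = list(episodes)
        for j in range(config.post_discharge_count):
            e = eps[int(rng.integers(0, len(eps)))]
            source = SOURCES[int(rng.integers(0, 2))]
            counters[source] += 1
            eid = f"{prefix[source]}{counters[source]:06d}"
            t = e.discharge + timedelta(hours=float(rng.uniform(2.0, 48.0)))
            value = int(np.clip(round(rng.lognormal(glu_mu, config.glucose_sigma)), lo, hi))
            entries.append(
                TranscribedEntry(
                    entry_id=eid,
                    source=source,
                    vin=e.vin,
                    entry_time=t.replace(microsecond=0),
                    value_mgdl=value,
                )
            )
            post_ids.append(eid)

    labels = pd.DataFrame(rows)
    return entries, GroundTruth(labels=labels, post_discharge_entry_ids=post_ids)


# ---------------------------------------------------------------------------
# insulin administrations
# ---------------------------------------------------------------------------

def generate_insulin_administrations(
    entries: Sequence[TranscribedEntry], protocol: InsulinProtocol = DEFAULT_PROTOCOL
) -> pd.DataFrame:
    """Dose records for flow-sheet entries: the nurse doses off the flow sheet.

    One row per flow-sheet entry with the protocol dose for its
    (possibly wrong) value; values outside the protocol domain are
    flagged ``out_of_protocol`` with no dose.
    """
    rows = []
    lo, hi = protocol.domain
    for e in entries:
        if e.source != "flow_sheet":
            continue
        if lo <= e.value_mgdl <= hi:
            rows.append(
                dict(
                    entry_id=e.entry_id,
                    vin=e.vin,
                    value_mgdl=e.value_mgdl,
                    dose_units=protocol.dose(e.value_mgdl),
                    out_of_protocol=False,
                )
            )
        else:
            rows.append(
                dict(
                    entry_id=e.entry_id,
                    vin=e.vin,
                    value_mgdl=e.value_mgdl,
                    dose_units=None,
                    out_of_protocol=True,
                )
            )
    return pd.DataFrame(
        rows, columns=["entry_id", "vin", "value_mgdl", "dose_units", "out_of_protocol"]
    )


# ---------------------------------------------------------------------------
# one-call dataset
# ---------------------------------------------------------------------------

@dataclass
class SyntheticDataset:
    episodes: list
    meters: list
    entries: list
    truth: GroundTruth
    config: GeneratorConfig


def generate_dataset(config: Optional[GeneratorConfig] = None, seed: int = 0) -> SyntheticDataset:
    """Generate a full synthetic study (cohort, meters, transcriptions)."""
    config = config or GeneratorConfig()
    ss = np.random.SeedSequence(seed)
    s_cohort, s_meters, s_entries = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(3)]
    episodes = generate_cohort(config, s_cohort)
    meters, episodes = generate_meter_stream(episodes, config, s_meters)
    entries, truth = generate_transcriptions(meters, config, s_entries, episodes=episodes)
    return SyntheticDataset(
        episodes=episodes, meters=meters, entries=entries, truth=truth, config=config
    )
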