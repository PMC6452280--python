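"""End-to-end orchestration: generate -> sample -> link -> audit -> report.

Every stage's inputs and outputs are persisted to the output directory
(the audit trail is the point of the exercise) and a manifest records
the seed and a hash of the configuration, so a run is reproducible from
its artifacts alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from datetime import datetime
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from .errors import ConfigError
from .insulin import DEFAULT_PROTOCOL, InsulinProtocol, load_protocol
from .model import TranscriptionAudit
from .records import ShiftConfig, read_stream, write_stream
from .sampling import expand_episodes, stratified_sample
from .synthetic import GeneratorConfig, generate_dataset

log = logging.getLogger("glucaudit")


def load_generator_config(path) -> GeneratorConfig:
    """Build a GeneratorConfig from a YAML mapping; unknown keys are errors."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    valid = {f.name for f in dataclasses.fields(GeneratorConfig)}
    bad = set(raw) - valid
    if bad:
        raise ConfigError(f"unknown generator config key(s): {sorted(bad)}")
    if "study_start" in raw and isinstance(raw["study_start"], str):
        raw["study_start"] = datetime.fromisoformat(raw["study_start"])
    cfg = GeneratorConfig(**raw)
    cfg.validate()
    return cfg


def _config_hash(config: GeneratorConfig) -> str:
    payload = json.dumps(
        {k: str(v) for k, v in dataclasses.asdict(config).items()}, sort_keys=True
    )
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_pipeline(
    outdir,
    seed: int,
    config: Optional[GeneratorConfig] = None,
    meters_csv=None,
    entries_csv=None,
    episodes_csv=None,
    sample_fraction: Optional[float] = None,
    window_minutes: float = 60.0,
    forward_only: bool = True,
    continuity: bool = True,
    protocol: InsulinProtocol = DEFAULT_PROTOCOL,
    shift: ShiftConfig = ShiftConfig(),
):
    """Run the full audit and persist every intermediate.

    Either generates a synthetic study (default) or audits user-supplied
    CSVs when all three paths are given. Returns the fitted
    :class:`~glucaudit.model.AuditResults`.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config = config or GeneratorConfig()

    supplied = [meters_csv, entries_csv, episodes_csv]
    if any(supplied) and not all(supplied):
        raise ConfigError("supply all of meters/entries/episodes CSVs, or none")

    if all(supplied):
        meters = read_stream(meters_csv, "meter")
        entries = read_stream(entries_csv, "entry")
        episodes = read_stream(episodes_csv, "episode")
        truth = None
    else:
        ds = generate_dataset(config, seed=seed)
        meters, entries, episodes, truth = ds.meters, ds.entries, ds.episodes, ds.truth
        truth.labels.to_csv(outdir / "groundtruth.csv", index=False)
    log.info("stage=input meters=%d entries=%d episodes=%d", len(meters), len(entries), len(episodes))

    write_stream(meters, outdir / "meters.csv", "meter")
    write_stream(entries, outdir / "entries.csv", "entry")
    write_stream(episodes, outdir / "episodes.csv", "episode")

    if sample_fraction is not None:
        sampled = stratified_sample(meters, sample_fraction, shift=shift, seed=seed)
        meters_audit = expand_episodes(sampled, meters)
        write_stream(sampled, outdir / "sampled_meters.csv", "meter")
        write_stream(meters_audit, outdir / "expanded_meters.csv", "meter")
        log.info(
            "stage=sample fraction=%s sampled=%d expanded=%d",
            sample_fraction, len(sampled), len(meters_audit),
        )
    else:
        meters_audit = meters

    model = TranscriptionAudit(
        meters_audit,
        entries,
        episodes,
        window_minutes=window_minutes,
        forward_only=forward_only,
        shift=shift,
        protocol=protocol,
        continuity=continuity,
    )
    res = model.fit()
    log.info(
        "stage=audit tests=%d undocumented_paper=%d undocumented_flow=%d",
        res.undocumented["n_tests"],
        res.undocumented["paper_log"]["n"],
        res.undocumented["flow_sheet"]["n"],
    )

    res.linkage.to_frame().to_csv(outdir / "matches.csv", index=False)
    res.classified.to_csv(outdir / "audit.csv", index=False)
    for name, df in res.tables().items():
        df.to_csv(outdir / f"table_{name}.csv", index=False)
    (outdir / "report.txt").write_text(res.summary() + "\n")

    manifest = {
        "seed": seed,
        "config_hash": _config_hash(config),
        "window_minutes": window_minutes,
        "forward_only": forward_only,
        "continuity": continuity,
        "sample_fraction": sample_fraction,
        "n_meters": len(meters),
        "n_meters_audited": len(meters_audit),
        "n_entries": len(entries),
        "n_episodes": len(episodes),
        "post_discharge_flagged": len(res.post_discharge_entries),
        "synthetic": truth is not None,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return res
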