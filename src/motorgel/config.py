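"""Flat YAML run-configuration files.

Keys are exactly the :class:`~motorgel.params.ModelParams` field names plus
two schedule extras (``frame_interval`` and, for fixed-volume runs,
``radius_schedule`` as a list of ``[time, radius]`` pairs).  Unknown keys
are rejected and every defaulted value is logged.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, fields
from pathlib import Path
from typing import Tuple

import yaml

from .dynamics import Schedule
from .params import ConfigurationError, ModelParams, make_params

__all__ = ["read_config", "write_config"]

log = logging.getLogger("motorgel")

_SCHEDULE_KEYS = ("frame_interval", "radius_schedule")


def read_config(path) -> Tuple[ModelParams, Schedule]:
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigurationError(f"cannot parse {path}: {exc}") from exc
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigurationError(f"{path}: top level must be a key-value mapping")

    frame_interval = raw.pop("frame_interval", None)
    radius_schedule = raw.pop("radius_schedule", None)
    if radius_schedule is not None:
        try:
            radius_schedule = [(float(t), float(r)) for t, r in radius_schedule]
        except (TypeError, ValueError) as exc:
            raise ConfigurationError(
                f"{path}: radius_schedule must be a list of [time, radius] pairs"
            ) from exc
    params = make_params(raw)
    for f in fields(ModelParams):
        if f.name not in raw:
            log.debug("config %s: %s defaulted to %r", path.name, f.name, getattr(params, f.name))
    if frame_interval is not None:
        frame_interval = int(frame_interval)
    schedule = Schedule.from_params(params, frame_interval=frame_interval,
                                    radius_schedule=radius_schedule)
    return params, schedule


def write_config(path, params: ModelParams, schedule: Schedule | None = None) -> None:
    data = asdict(params)
    if schedule is not None:
        data["frame_interval"] = schedule.frame_interval
        if schedule.radius_schedule is not None:
            data["radius_schedule"] = [list(p) for p in schedule.radius_schedule]
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))
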