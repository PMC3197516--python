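"""YAML loaders for the allowance policy and the generator configuration."""

from __future__ import annotations

from pathlib import Path

import yaml

from .metrics import AllowancePolicy
from .simulate import GeneratorConfig, dist_from_spec

__all__ = ["load_policy", "load_generator_config"]

_DIST_FIELDS = (
    "arrest_duration_s",
    "time_to_cpr_s",
    "handover_time_s",
    "defib_arrival_s",
    "first_rhythm_s",
    "responder_nfr_target",
    "team_nfr_target",
    "compression_rate_cpm",
    "pause_length_s",
)


def load_policy(path: str | Path) -> AllowancePolicy:
    """Allowance policy from YAML; omitted fields keep the guideline defaults."""
    payload = yaml.safe_load(Path(path).read_text()) or {}
    return AllowancePolicy(**payload)


def load_generator_config(path: str | Path, **overrides) -> GeneratorConfig:
    """Generator configuration from YAML, with keyword overrides (e.g. seed).

    Distribution-valued fields accept either a bare number (held fixed) or a
    mapping with a ``family`` key; see :func:`noflow.simulate.dist_from_spec`.
    """
    payload = yaml.safe_load(Path(path).read_text()) or {}
    payload.update(overrides)
    for f in _DIST_FIELDS:
        if f in payload:
            payload[f] = dist_from_spec(payload[f])
    return GeneratorConfig(**payload)
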