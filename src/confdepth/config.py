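"""Plain-text ``key = value`` configuration files.

Recognised keys (all optional; defaults are the library defaults):

    mask_kind = soft | hard | uniform
    theta     = 0.5        # confidence threshold
    lambda    = 10         # soft-mask sharpness
    alpha     = 0.5        # gradient-term weight
    levels    = 4          # pyramid scale levels (K)
    c         = 4.685      # IRLS biweight tuning constant

Lines starting with '#' and blank lines are ignored.  CLI flags override
file values.
"""

from __future__ import annotations

from pathlib import Path

from .alignment import IRLSConfig
from .errors import ConfigError
from .loss import LossConfig, WeightConfig

__all__ = ["parse_config_text", "load_config", "build_configs"]

_KEYS = {"mask_kind", "theta", "lambda", "alpha", "levels", "c"}


def parse_config_text(text: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ConfigError(f"line {lineno}: expected 'key = value', got {raw!r}")
        key, value = (part.strip() for part in line.split("=", 1))
        if key not in _KEYS:
            raise ConfigError(f"line {lineno}: unknown key {key!r}")
        out[key] = value
    return out


def load_config(path: str | Path) -> dict[str, str]:
    return parse_config_text(Path(path).read_text())


def build_configs(
    values: dict[str, str], overrides: dict[str, object] | None = None
) -> tuple[LossConfig, IRLSConfig]:
    """Merge file values and CLI overrides into typed configs."""
    merged: dict[str, object] = dict(values)
    for key, val in (overrides or {}).items():
        if val is not None:
            merged[key] = val
    try:
        weight = WeightConfig(
            mask_kind=str(merged.get("mask_kind", "soft")),
            threshold=float(merged.get("theta", 0.5)),
            sharpness=float(merged.get("lambda", 10.0)),
        )
        loss = LossConfig(
            gradient_weight=float(merged.get("alpha", 0.5)),
            scale_levels=int(merged.get("levels", 4)),
            weight=weight,
        )
        irls = IRLSConfig(tuning_constant=float(merged.get("c", 4.685)))
    except (ValueError, TypeError) as exc:
        raise ConfigError(f"invalid configuration value: {exc}") from exc
    return loss, irls
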