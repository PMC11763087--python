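"""Configuration loading: coding tables, weights and cutoffs from YAML/JSON.

The default configuration shipped with the package lives in
``data/default_config.yaml``. A user config needs to supply only the
keys it overrides; anything omitted falls back to the default.
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path
from typing import Any

import yaml

from .scoring import Band, BandTable, CodingTables, ScoreWeights

__all__ = ["default_config_dict", "default_config", "load_config", "build_tables"]

# (config key, attribute on CodingTables, domain minimum, required domain maximum)
_TABLE_SPECS = [
    ("gcs_bands", "gcs", 3, 15),
    ("sbp_rts_bands", "sbp_rts", 0, None),
    ("rr_bands", "rr", 0, None),
    ("sbp_nts_bands", "sbp_nts", 0, None),
    ("spo2_bands", "spo2", 0, 100),
]


def default_config_dict() -> dict[str, Any]:
    """The shipped default configuration as a plain dict."""
    text = (
        resources.files("traumascore").joinpath("data/default_config.yaml").read_text()
    )
    return yaml.safe_load(text)


def build_tables(cfg: dict[str, Any]) -> tuple[CodingTables, ScoreWeights]:
    """Validate a config dict and build the coding tables and weights."""
    kwargs = {}
    for key, attr, dmin, dmax in _TABLE_SPECS:
        raw = cfg.get(key)
        if raw is None:
            raise ValueError(f"config missing required table {key!r}")
        bands = [Band(low=int(b[0]), high=None if b[1] is None else int(b[1]), code=int(b[2]))
                 for b in raw]
        table = BandTable(attr, bands, domain_min=dmin)
        if dmax is not None and table.max_value != dmax:
            raise ValueError(
                f"{key}: bands must cover exactly {dmin}..{dmax}, "
                f"got upper edge {table.max_value}"
            )
        kwargs[attr] = table
    tables = CodingTables(**kwargs)
    weights = ScoreWeights(**cfg.get("weights", {}), **cfg.get("cutoffs", {}))
    return tables, weights


def default_config() -> tuple[CodingTables, ScoreWeights]:
    """Coding tables and weights from the shipped defaults."""
    return build_tables(default_config_dict())


def load_config(path: str | Path | None = None) -> tuple[CodingTables, ScoreWeights]:
    """Load configuration from a YAML or JSON file, merged over defaults.

    Parameters
    ----------
    path : str or Path, optional
        Config file; ``None`` returns the shipped defaults. Top-level
        keys present in the file replace the corresponding default keys
        wholesale (a partial band table is not merged band-by-band).
    """
    cfg = default_config_dict()
    if path is not None:
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(f"config file not found: {path}")
        text = path.read_text()
        user = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        if not isinstance(user, dict):
            raise ValueError(f"config file {path} must contain a mapping")
        for key, value in user.items():
            if key in ("weights", "cutoffs"):
                merged = dict(cfg.get(key, {}))
                merged.update(value)
                cfg[key] = merged
            else:
                cfg[key] = value
    return build_tables(cfg)
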