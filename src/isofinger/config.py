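"""Run configuration: one YAML/JSON file drives every workflow command.

Schema (YAML)::

    substrate:
      formula: C7H7NO2          # Hill notation
      adduct: "[M+H]+"          # optional; only protonation implemented
      name: methyl-nicotinate   # optional
      sites:                    # labeled sites measured by 1H NMR
        - {site: C2, d: 0.30}
        - {site: C4, d: 0.64}
        - {site: C6, d: 0.94}
    candidates:
      - {name: 2-aryl, consumed_site: C2, delta: "+C7H6"}
      - {name: RPh, consumed_site: null, delta: "+C7H6"}  # unlabeled site
    window: 6          # optional; mass-shift bins 0..window
    tol: 0.3           # optional; extraction tolerance, Da
    method: auto       # auto | ols | nnls
    seed: 1            # optional; simulation seed

The loader validates the schema before any computation and raises
:class:`ConfigError` with the offending field.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import yaml

from .chem import CandidateProduct, Formula, LabelingScheme, Substrate, make_candidate


class ConfigError(ValueError):
    """Invalid or incomplete run configuration."""


@dataclass(frozen=True)
class RunConfig:
    substrate: Substrate
    candidates: tuple[CandidateProduct, ...]
    window: int | None = None
    tol: float = 0.3
    method: str = "auto"
    seed: int = 0
    raw: dict | None = None

    def config_hash(self) -> str:
        """Stable digest of the resolved configuration, for run logs."""
        payload = json.dumps(self.raw, sort_keys=True, default=str).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


def _require(mapping: dict, key: str, ctx: str):
    if key not in mapping:
        raise ConfigError(f"missing required key {key!r} in {ctx}")
    return mapping[key]


def load_config(path: str | Path) -> RunConfig:
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    try:
        data = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"cannot parse {path}: {exc}") from exc
    if not isinstance(data, dict):
        raise ConfigError(f"config root must be a mapping, got {type(data).__name__}")
    return parse_config(data)


def parse_config(data: dict) -> RunConfig:
    sub_cfg = _require(data, "substrate", "config")
    sites_cfg = _require(sub_cfg, "sites", "substrate")
    if not isinstance(sites_cfg, list) or not sites_cfg:
        raise ConfigError("substrate.sites must be a nonempty list of {site, d}")
    try:
        scheme = LabelingScheme.from_dict(
            {_require(s, "site", "substrate.sites"): float(_require(s, "d", "substrate.sites"))
             for s in sites_cfg}
        )
        substrate = Substrate(
            Formula.parse(_require(sub_cfg, "formula", "substrate")),
            scheme,
            adduct=sub_cfg.get("adduct", "[M+H]+"),
            name=sub_cfg.get("name", ""),
        )
    except (ValueError, TypeError) as exc:
        raise ConfigError(f"invalid substrate: {exc}") from exc

    cand_cfg = _require(data, "candidates", "config")
    if not isinstance(cand_cfg, list) or not cand_cfg:
        raise ConfigError("candidates must be a nonempty list")
    candidates = []
    for i, c in enumerate(cand_cfg):
        try:
            candidates.append(
                make_candidate(
                    substrate,
                    c.get("consumed_site"),
                    _require(c, "delta", f"candidates[{i}]"),
                    name=c.get("name", ""),
                )
            )
        except (ValueError, TypeError) as exc:
            raise ConfigError(f"invalid candidate #{i}: {exc}") from exc

    method = data.get("method", "auto")
    if method not in ("auto", "ols", "nnls"):
        raise ConfigError(f"method must be auto|ols|nnls, got {method!r}")
    tol = float(data.get("tol", 0.3))
    if not (0.0 < tol < 0.5):
        raise ConfigError(f"tol must be in (0, 0.5) Da, got {tol}")
    window = data.get("window")
    if window is not None:
        window = int(window)
        if window < 1:
            raise ConfigError("window must be >= 1")
    return RunConfig(
        substrate=substrate,
        candidates=tuple(candidates),
        window=window,
        tol=tol,
        method=method,
        seed=int(data.get("seed", 0)),
        raw=data,
    )
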