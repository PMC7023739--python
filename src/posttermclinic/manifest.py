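"""Run manifests: YAML/JSON configuration files for sweeps and trials."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import yaml

__all__ = ["RunManifest", "parse_config", "ManifestError"]

#: the study lattice each factor level must stay inside
_LATTICE = {
    "x0": set(range(2, 21)),
    "x1": {"All", "Half"},
    "x2": {"Mid", "Doc"},
    "x3": {2, 3},
    "x4": {2, 3},
    "x5": {3, 4},
}
_DEFAULT_LEVELS = {
    "x0": list(range(2, 21)),
    "x1": ["All", "Half"],
    "x2": ["Mid", "Doc"],
    "x3": [2, 3],
    "x4": [2, 3],
    "x5": [3, 4],
}
_ALLOWED_KEYS = {"master_seed", "n_reps", "output_dir", "fixture_path",
                 "factor_levels", "overrides"}
_ALLOWED_OVERRIDES = {"reception_staff", "open_time", "close_time", "horizon",
                      "background_stream_enabled", "background_rate"}


class ManifestError(ValueError):
    """A named validation or parse error in a run manifest."""


@dataclass
class RunManifest:
    """Everything needed to reproduce a run: seed, sizes, levels, overrides."""

    master_seed: int
    n_reps: int = 10_000
    output_dir: Path = Path("results")
    fixture_path: Optional[Path] = None
    factor_levels: dict = field(default_factory=lambda: {k: list(v) for k, v in _DEFAULT_LEVELS.items()})
    overrides: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "master_seed": self.master_seed,
            "n_reps": self.n_reps,
            "output_dir": str(self.output_dir),
            "fixture_path": None if self.fixture_path is None else str(self.fixture_path),
            "factor_levels": self.factor_levels,
            "overrides": self.overrides,
        }

    def save(self, path: Union[str, Path]) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))


def _validate_levels(levels: Mapping[str, Sequence]) -> dict:
    merged = {k: list(v) for k, v in _DEFAULT_LEVELS.items()}
    for factor, values in levels.items():
        if factor not in _LATTICE:
            raise ManifestError(f"unknown factor {factor!r} in factor_levels")
        values = list(values)
        bad = [v for v in values if v not in _LATTICE[factor]]
        if bad:
            raise ManifestError(
                f"factor {factor!r} levels {bad} outside the study lattice "
                f"{sorted(_LATTICE[factor], key=str)}"
            )
        if not values:
            raise ManifestError(f"factor {factor!r} has no levels")
        merged[factor] = values
    return merged


def parse_config(path: Union[str, Path]) -> RunManifest:
    """Parse and validate a YAML manifest, filling defaults.

    Unknown keys, unknown factors and out-of-lattice levels raise
    :class:`ManifestError` naming the offender; YAML syntax errors carry the
    problem line.
    """
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        mark = getattr(exc, "problem_mark", None)
        where = f" at line {mark.line + 1}" if mark is not None else ""
        raise ManifestError(f"malformed manifest {path}{where}: {exc}") from exc
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ManifestError(f"manifest {path} must be a mapping")
    unknown = set(raw) - _ALLOWED_KEYS
    if unknown:
        raise ManifestError(f"unknown manifest keys: {sorted(unknown)}")
    if "master_seed" not in raw:
        raise ManifestError("manifest must set master_seed")
    overrides = dict(raw.get("overrides") or {})
    bad = set(overrides) - _ALLOWED_OVERRIDES
    if bad:
        raise ManifestError(f"unknown override keys: {sorted(bad)}")
    manifest = RunManifest(
        master_seed=int(raw["master_seed"]),
        n_reps=int(raw.get("n_reps", 10_000)),
        output_dir=Path(raw.get("output_dir", "results")),
        fixture_path=None if raw.get("fixture_path") is None else Path(raw["fixture_path"]),
        factor_levels=_validate_levels(raw.get("factor_levels") or {}),
        overrides=overrides,
    )
    if manifest.n_reps < 2:
        raise ManifestError("n_reps must be >= 2")
    return manifest
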