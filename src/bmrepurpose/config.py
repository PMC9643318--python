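"""Pipeline configuration.

All numeric knobs of the pipeline live in a single flat, immutable
:class:`PipelineConfig`.  Defaults are the study conditions: DEG filter at
adjusted p < 0.05 and |log2FC| > 1, macrophage-correlation screen at r > 0.3,
50-drug source cutoff, composite weights (0.45, 0.45, 0.1), Ward cut at 80%
minimum Tanimoto similarity, network weights omega_bm = 0.3 / omega_m2 = 0.7,
20% missingness discard, 10 uM sensitivity threshold, and Ki conversion at
298.15 K.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Tuple


class ConfigError(ValueError):
    """Malformed configuration document."""


class ConfigValidationError(ConfigError):
    """A configuration value violates an invariant."""


@dataclass(frozen=True)
class PipelineConfig:
    deg_p_threshold: float = 0.05
    deg_lfc_threshold: float = 1.0
    corr_threshold: float = 0.3
    corr_p_threshold: float = 0.05
    rank_cutoff: int = 50
    codres_weights: Tuple[float, float, float] = (0.45, 0.45, 0.1)
    tanimoto_min_similarity: float = 0.80
    fingerprint_length: int = 2048
    omega_bm: float = 0.3
    omega_m2: float = 0.7
    na_max_fraction: float = 0.20
    ic50_sensitive_um: float = 10.0
    knn_k: int = 5
    temperature_k: float = 298.15
    random_seed: int = 0
    # normalize Score_M2 by max|raw_M2| (False) or by max|raw_BM| (True)
    m2_norm_by_bm: bool = False

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        w = self.codres_weights
        if len(w) != 3:
            raise ConfigValidationError("codres_weights must have 3 entries")
        if any(x < 0 for x in w):
            raise ConfigValidationError("codres_weights must be non-negative")
        if abs(sum(w) - 1.0) > 1e-9:
            raise ConfigValidationError(
                f"codres_weights must sum to 1 (got {sum(w)!r})"
            )
        if abs(self.omega_bm + self.omega_m2 - 1.0) > 1e-9:
            raise ConfigValidationError(
                "omega_bm + omega_m2 must equal 1 "
                f"(got {self.omega_bm} + {self.omega_m2})"
            )
        for key in (
            "deg_p_threshold",
            "deg_lfc_threshold",
            "corr_threshold",
            "corr_p_threshold",
            "na_max_fraction",
            "ic50_sensitive_um",
            "temperature_k",
        ):
            if not getattr(self, key) > 0:
                raise ConfigValidationError(f"{key} must be strictly positive")
        for key in ("rank_cutoff", "fingerprint_length", "knn_k"):
            if not (isinstance(getattr(self, key), int) and getattr(self, key) >= 1):
                raise ConfigValidationError(f"{key} must be a positive integer")
        if not 0.0 < self.tanimoto_min_similarity < 1.0:
            raise ConfigValidationError(
                "tanimoto_min_similarity must lie strictly inside (0, 1)"
            )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["codres_weights"] = list(self.codres_weights)
        return d


_FIELD_NAMES = {f.name for f in dataclasses.fields(PipelineConfig)}


def load_config(path: str | Path) -> PipelineConfig:
    """Load a flat JSON config; absent keys take defaults, unknown keys error."""
    text = Path(path).read_text()
    try:
        raw = json.loads(text) if text.strip() else {}
    except json.JSONDecodeError as exc:
        raise ConfigError(
            f"{path}: malformed JSON at line {exc.lineno}: {exc.msg}"
        ) from exc
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: config must be a flat JSON object")
    unknown = sorted(set(raw) - _FIELD_NAMES)
    if unknown:
        raise ConfigValidationError(f"unknown config keys: {', '.join(unknown)}")
    if "codres_weights" in raw:
        raw["codres_weights"] = tuple(raw["codres_weights"])
    try:
        return PipelineConfig(**raw)
    except ConfigError:
        raise
    except TypeError as exc:  # pragma: no cover - defensive
        raise ConfigValidationError(str(exc)) from exc
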