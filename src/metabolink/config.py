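"""Run configuration: every tunable of the pipeline in one validated object."""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Optional

import yaml


@dataclass(frozen=True)
class RunConfig:
    """All pipeline knobs with their defaults.

    ``alpha`` weights structure vs expression in the fused score;
    ``bicluster_cutoff`` (0.6) thresholds the microbe × drug matrix before
    biclustering and the network build; ``linkage_cutoff`` (0.9) gates
    annotation propagation; ``benchmark_thresholds`` is the descending
    precision ladder.  ``qubic_*`` are the biclustering parameters
    (discretization rank r, extreme-quantile q, consistency c, max blocks o,
    overlap tolerance f).
    """

    alpha: float = 0.5
    expression_method: str = "spearman"  # or "connectivity"
    top_n: int = 50
    fp_kind: str = "morgan"
    fp_radius: int = 2
    fp_bits: int = 2048
    benchmark_thresholds: tuple[float, ...] = (0.9, 0.8, 0.7, 0.6)
    inclusive_threshold: bool = False
    bicluster_cutoff: float = 0.6
    linkage_cutoff: float = 0.9
    qubic_r: int = 1
    qubic_q: float = 0.06
    qubic_c: float = 0.95
    qubic_o: int = 100
    qubic_f: float = 1.0
    hub_ranking: str = "atc_class"  # or "degree"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")
        if self.expression_method not in ("spearman", "connectivity"):
            raise ValueError(f"unknown expression_method {self.expression_method!r}")
        if self.fp_kind not in ("morgan", "rdkit"):
            raise ValueError(f"unknown fp_kind {self.fp_kind!r}")
        if self.top_n < 1 or self.fp_radius < 0 or self.fp_bits < 8:
            raise ValueError("top_n, fp_radius or fp_bits out of range")
        for name in ("bicluster_cutoff", "linkage_cutoff", "qubic_f"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        ts = self.benchmark_thresholds
        if any(not 0.0 <= t <= 1.0 for t in ts):
            raise ValueError("benchmark thresholds must lie in [0, 1]")
        if any(a <= b for a, b in zip(ts, ts[1:])):
            raise ValueError("benchmark thresholds must be strictly descending")
        if not 0.0 < self.qubic_q < 0.5:
            raise ValueError("qubic_q must lie in (0, 0.5)")
        if not 0.5 < self.qubic_c <= 1.0:
            raise ValueError("qubic_c must lie in (0.5, 1]")
        if self.qubic_r < 1 or self.qubic_o < 1:
            raise ValueError("qubic_r and qubic_o must be >= 1")
        if self.hub_ranking not in ("atc_class", "degree"):
            raise ValueError(f"unknown hub_ranking {self.hub_ranking!r}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        """Load a config from a YAML key: value file; unknown keys rejected."""
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"{path}: config must be a mapping")
        names = {f.name for f in fields(cls)}
        unknown = sorted(set(raw) - names)
        if unknown:
            raise ValueError(f"{path}: unknown config key(s): {', '.join(unknown)}")
        if "benchmark_thresholds" in raw:
            raw["benchmark_thresholds"] = tuple(raw["benchmark_thresholds"])
        return cls(**raw)

    def with_overrides(self, **kwargs) -> "RunConfig":
        """A copy with the given fields replaced (CLI flags win over file keys)."""
        kwargs = {k: v for k, v in kwargs.items() if v is not None}
        if "benchmark_thresholds" in kwargs:
            kwargs["benchmark_thresholds"] = tuple(kwargs["benchmark_thresholds"])
        return replace(self, **kwargs)

    def as_dict(self) -> dict:
        d = {f.name: getattr(self, f.name) for f in fields(self)}
        d["benchmark_thresholds"] = list(d["benchmark_thresholds"])
        return d
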