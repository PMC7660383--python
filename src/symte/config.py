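"""Pipeline configuration."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from symte.inference import DEFAULT_ALPHA, DEFAULT_B


@dataclass
class PipelineConfig:
    """Fixed choices of a full pipeline run plus input file paths."""

    window_start: str = "1999-01"
    window_end: str = "2017-12"
    exclude: tuple[str, ...] = ("CT", "HI")
    B: int = DEFAULT_B
    alpha: float = DEFAULT_ALPHA
    seed: int = 0
    n_list: tuple[int, ...] = (1, 3, 5, 7, 9)
    decomposition: str = "classical"
    states_csv: str = ""
    bc_csv: str = ""
    media_fc_csv: str = ""
    media_s_csv: str = ""
    events_csv: str = ""
    distances_csv: str = ""

    def __post_init__(self) -> None:
        start = pd.Period(self.window_start, "M")
        end = pd.Period(self.window_end, "M")
        if (end - start).n + 1 < 24:
            raise ValueError("study window must span at least 24 months")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if self.B < 1:
            raise ValueError("B must be at least 1")
        self.exclude = tuple(str(c).upper() for c in self.exclude)
        self.n_list = tuple(int(n) for n in self.n_list)

    @property
    def window(self) -> tuple[str, str]:
        return (self.window_start, self.window_end)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_dict(self) -> dict:
        return asdict(self)

    def content_hash(self) -> str:
        """Stable hash of the configuration for provenance sidecars."""
        canon = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]
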