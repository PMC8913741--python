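"""Run configuration shared by the pipeline commands."""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

from .pdockq import DEFAULT_PARAMS, PDockQParams

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """Thresholds and knobs for one pipeline run.

    ``pdockq_threshold`` governs the binary interaction call.  The
    shipped default of 0.5 is a placeholder, not a calibrated operating
    point: calibrate it on your own labelled data (e.g. the threshold
    maximising Youden's J on an ROC curve) before trusting the calls.
    """

    chain_a: str = "A"
    chain_b: str = "B"
    interface_cutoff: float = 8.0
    dockq_threshold: float = 0.23
    pdockq_threshold: float = 0.5
    log_base: float = 10.0
    max_gap_fraction: float = 0.9
    identity_threshold: float = 0.62
    coverage_threshold: float = 0.9
    strict: bool = False
    seed: int = 0
    params: PDockQParams = field(default_factory=lambda: DEFAULT_PARAMS)

    def __post_init__(self) -> None:
        for name in ("interface_cutoff", "dockq_threshold", "pdockq_threshold"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def to_json(self, path: str | Path | None = None) -> str:
        d = asdict(self)
        text = json.dumps(d, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, text_or_path: str | Path) -> "RunConfig":
        p = Path(str(text_or_path))
        text = p.read_text() if p.exists() else str(text_or_path)
        d = json.loads(text)
        if "params" in d and isinstance(d["params"], dict):
            d["params"] = PDockQParams(**d["params"])
        return cls(**d)
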