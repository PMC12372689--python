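"""Per-generation trajectory records from the deterministic engines."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd

__all__ = ["Trajectory", "STOP_MAX_GENERATIONS", "STOP_EXTINCT", "STOP_CONVERGED"]

STOP_MAX_GENERATIONS = "max_generations"
STOP_EXTINCT = "extinct"
STOP_CONVERGED = "converged"


@dataclass
class Trajectory:
    """Ordered per-generation record of a deterministic run.

    ``columns`` maps column names (``generation``, the inversion frequency,
    the class allele frequencies, fitness components and the relative fitness
    ``w_rel``) to equal-length lists.  ``stop_reason`` is one of
    ``max_generations``, ``extinct`` (frequency dropped below the extinction
    threshold) or ``converged`` (sup-norm state change below tolerance).
    """

    columns: dict[str, list[float]]
    stop_reason: str
    metadata: dict[str, Any] = field(default_factory=dict)

    @property
    def extinct(self) -> bool:
        return self.stop_reason == STOP_EXTINCT

    @property
    def converged(self) -> bool:
        return self.stop_reason == STOP_CONVERGED

    def __len__(self) -> int:
        return len(self.columns["generation"])

    def __getitem__(self, name: str) -> list[float]:
        return self.columns[name]

    def final(self, name: str) -> float:
        return self.columns[name][-1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.columns)

    def write(self, csv_path: str | Path, metadata_path: str | Path | None = None) -> None:
        """Write the tidy CSV plus an optional JSON run-metadata sidecar."""
        csv_path = Path(csv_path)
        self.to_frame().to_csv(csv_path, index=False)
        if metadata_path is None:
            metadata_path = csv_path.with_suffix(".json")
        payload = dict(self.metadata)
        payload["stop_reason"] = self.stop_reason
        payload["generations_recorded"] = len(self)
        Path(metadata_path).write_text(json.dumps(payload, indent=2, sort_keys=True))
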