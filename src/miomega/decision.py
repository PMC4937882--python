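"""Shared result record for the two eta decision procedures."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd


@dataclass
class EtaDecision:
    """Outcome of an eta determination plus its audit trail.

    ``eta`` is None when no grid point qualified (``grid_exhausted`` set in
    ``details``).  ``worksheet`` carries the per-window (moving regression) or
    per-m (confidence interval) table the decision scanned, mirroring the
    layout a reader would check by hand.
    """

    method: str
    cutoff: float
    eta: int | None
    worksheet: pd.DataFrame
    outlier_events: list = field(default_factory=list)
    details: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "cutoff": self.cutoff,
            "eta": self.eta,
            "outlier_events": self.outlier_events,
            "details": self.details,
            "worksheet": self.worksheet.to_dict(orient="records"),
        }

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2, default=float) + "\n"
        if path is not None:
            Path(path).write_text(text)
        return text
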