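"""Force-extension trace container shared by the simulator, the detector and
file I/O."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class TraceError(ValueError):
    """Malformed or physically inconsistent trace."""


@dataclass
class ForceExtensionTrace:
    """One constant-velocity stretch or relax sweep.

    ``time`` in s, ``extension`` (tether end-to-end distance) in nm,
    ``force`` in pN.  ``sweep`` is ``"stretch"`` or ``"relax"``.
    """

    time: np.ndarray
    extension: np.ndarray
    force: np.ndarray
    molecule_id: int = 0
    cycle: int = 0
    sweep: str = "stretch"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.extension = np.asarray(self.extension, dtype=float)
        self.force = np.asarray(self.force, dtype=float)
        n = self.time.size
        if self.extension.size != n or self.force.size != n:
            raise TraceError("time/extension/force must have equal length")
        if n >= 2 and np.any(np.diff(self.time) <= 0):
            raise TraceError("time must be strictly increasing")
        if self.sweep not in ("stretch", "relax"):
            raise TraceError(f"sweep must be 'stretch' or 'relax', got {self.sweep!r}")

    def __len__(self) -> int:
        return self.time.size

    @property
    def sample_rate(self) -> float:
        dt = np.median(np.diff(self.time))
        return 1.0 / dt

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time_s": self.time, "extension_nm": self.extension, "force_pN": self.force}
        )
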