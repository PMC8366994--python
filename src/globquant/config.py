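"""Run configuration: one YAML document drives every pipeline stage.

Every CLI run writes its fully resolved configuration next to its
outputs so results can be reproduced parameter-for-parameter.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import stains
from .ihc import IHCParams
from .inclusions import GlobuleParams, default_candidates
from .stains import StainMatrix
from .tissue import TissueParams


@dataclass
class RunConfig:
    default_mpp: float = 0.50
    seed: int = 0
    tissue: TissueParams = field(default_factory=TissueParams)
    globules: GlobuleParams = field(default_factory=GlobuleParams)
    candidates: list[GlobuleParams] = field(default_factory=default_candidates)
    ihc: IHCParams = field(default_factory=IHCParams)
    pasd_matrix: StainMatrix = field(default_factory=stains.default_pasd_matrix)
    ihc_matrix: StainMatrix = field(default_factory=stains.default_ihc_matrix)
    dunn_adjust: str | None = None
    column_map: dict[str, str] = field(default_factory=dict)
    manual_exclusions: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.default_mpp <= 0:
            raise ValueError("default_mpp must be > 0")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["pasd_matrix"] = self.pasd_matrix.to_dict()
        d["ihc_matrix"] = self.ihc_matrix.to_dict()
        return d

    def dump(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(self.to_dict(), sort_keys=False)
        )

    @classmethod
    def load(cls, path: str | Path | None = None) -> "RunConfig":
        """Load a YAML config; absent keys fall back to defaults."""
        if path is None:
            return cls()
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs: dict = {}
        for key in ("default_mpp", "seed", "dunn_adjust", "column_map",
                    "manual_exclusions"):
            if key in raw:
                kwargs[key] = raw[key]
        if "tissue" in raw:
            kwargs["tissue"] = TissueParams(**raw["tissue"])
        if "globules" in raw:
            kwargs["globules"] = GlobuleParams(**raw["globules"])
        if "candidates" in raw:
            kwargs["candidates"] = [
                GlobuleParams(**c) for c in raw["candidates"]
            ]
        if "ihc" in raw:
            kwargs["ihc"] = IHCParams(**raw["ihc"])
        if "pasd_matrix" in raw:
            kwargs["pasd_matrix"] = StainMatrix.from_dict(raw["pasd_matrix"])
        if "ihc_matrix" in raw:
            kwargs["ihc_matrix"] = StainMatrix.from_dict(raw["ihc_matrix"])
        return cls(**kwargs)
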