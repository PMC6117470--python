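"""Run configuration and provenance.

A single :class:`Config` carries the physical calibration and the
stage-specific parameter blocks for a whole pipeline run.  All randomness
flows from one master seed which is split deterministically per stage, so a
rerun with the same config file reproduces every output byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import yaml

__all__ = ["Config", "Provenance", "split_seed"]


def split_seed(master_seed: int, stage: str) -> int:
    """Derive a stage seed from the master seed, deterministically.

    Uses SHA-256 of ``"<seed>:<stage>"`` truncated to 31 bits so the result
    is a valid seed for every RNG backend.
    """
    h = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


@dataclass
class Config:
    """Pipeline run configuration.

    Parameters
    ----------
    pixel_size_nm : tuple of float
        Physical size of one pixel along (y, x), in nm.  Default 84 nm,
        the lateral sampling of the spinning-disk platform.
    z_step_nm : float
        Optical slice spacing in nm (default 500).
    voxel_size_um : float
        Edge of the square mapping voxel in micrometres (default 19.2).
    coloc_threshold_nm : float
        Centroid-distance threshold for two-channel colocalization
        (default 500 nm, on the scale of one postsynaptic density).
    channels : tuple of str
        Channel names; channel 0 is the PSD95-like marker, channel 1 the
        SAP102-like marker.
    seed : int
        Master seed; every stage derives its own stream from it.
    stages : dict
        Free-form stage-specific parameter blocks keyed by stage name.
    """

    pixel_size_nm: tuple[float, float] = (84.0, 84.0)
    z_step_nm: float = 500.0
    voxel_size_um: float = 19.2
    coloc_threshold_nm: float = 500.0
    channels: tuple[str, str] = ("PSD95", "SAP102")
    seed: int = 0
    stages: dict[str, dict[str, Any]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        py, px = self.pixel_size_nm
        if py <= 0 or px <= 0 or self.z_step_nm <= 0:
            raise ValueError("physical pixel sizes must be positive")
        if self.voxel_size_um <= 0:
            raise ValueError("voxel size must be positive")
        if self.voxel_size_um * 1000.0 < max(py, px):
            raise ValueError("voxel edge must be at least one pixel")
        if self.coloc_threshold_nm <= 0:
            raise ValueError("colocalization threshold must be positive")

    def stage_seed(self, stage: str) -> int:
        return split_seed(self.seed, stage)

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["pixel_size_nm"] = list(self.pixel_size_nm)
        d["channels"] = list(self.channels)
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "Config":
        d = dict(d)
        if "pixel_size_nm" in d:
            d["pixel_size_nm"] = tuple(d["pixel_size_nm"])
        if "channels" in d:
            d["channels"] = tuple(d["channels"])
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "Config":
        """Load from a YAML or JSON file (YAML is a JSON superset)."""
        text = Path(path).read_text()
        return cls.from_dict(yaml.safe_load(text) or {})

    def to_file(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @property
    def hash(self) -> str:
        """Stable short hash of the configuration contents."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


@dataclass
class Provenance:
    """Provenance header attached to every written artifact.

    The timestamp is optional and excluded from equality-relevant fields so
    that reruns with identical config and seed produce byte-identical files.
    """

    config_hash: str
    stage: str
    inputs: tuple[str, ...] = ()
    seed: int = 0
    timestamp: str | None = None

    def header_lines(self) -> list[str]:
        lines = [
            f"# provenance: stage={self.stage} config={self.config_hash} seed={self.seed}",
        ]
        if self.inputs:
            lines.append("# inputs: " + ",".join(self.inputs))
        if self.timestamp is not None:
            lines.append(f"# timestamp: {self.timestamp}")
        return lines

    @classmethod
    def from_header_lines(cls, lines: list[str]) -> "Provenance | None":
        stage = cfg = None
        seed = 0
        inputs: tuple[str, ...] = ()
        ts = None
        for line in lines:
            line = line.lstrip("# ").rstrip()
            if line.startswith("provenance:"):
                for tok in line.split(":", 1)[1].split():
                    k, _, v = tok.partition("=")
                    if k == "stage":
                        stage = v
                    elif k == "config":
                        cfg = v
                    elif k == "seed":
                        seed = int(v)
            elif line.startswith("inputs:"):
                inputs = tuple(line.split(":", 1)[1].strip().split(","))
            elif line.startswith("timestamp:"):
                ts = line.split(":", 1)[1].strip()
        if stage is None or cfg is None:
            return None
        return cls(config_hash=cfg, stage=stage, inputs=inputs, seed=seed, timestamp=ts)


def rng_for(config: Config, stage: str) -> np.random.Generator:
    """Stage-scoped random generator derived from the master seed."""
    return np.random.default_rng(config.stage_seed(stage))
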