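"""Particle sets: coordinates plus one scalar property per particle.

A :class:`ParticleSet` records a rigid body at its reference pose.  The
scalar property is whatever the interaction law consumes (a charge for
electrostatics, unity for property-free laws).

File formats: CSV with header ``x,y,z,prop`` is the native format; extended
XYZ files whose atom lines end in four numeric columns (x, y, z, property)
are accepted as input.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["ParticleSet", "read_particles"]


@dataclass
class ParticleSet:
    coords: np.ndarray
    props: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.coords = np.atleast_2d(np.asarray(self.coords, dtype=float))
        self.props = np.asarray(self.props, dtype=float).ravel()
        if self.coords.shape[0] < 1:
            raise ValueError("particle set must contain at least one particle")
        if self.coords.shape[1] != 3:
            raise ValueError("coords must be an (M, 3) array")
        if self.props.shape[0] != self.coords.shape[0]:
            raise ValueError("props length must match number of particles")
        if not (np.isfinite(self.coords).all() and np.isfinite(self.props).all()):
            raise ValueError("coordinates and properties must be finite")

    @property
    def n(self) -> int:
        return self.coords.shape[0]

    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame(
            {"x": self.coords[:, 0], "y": self.coords[:, 1],
             "z": self.coords[:, 2], "prop": self.props}
        )
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, label: str = "") -> "ParticleSet":
        df = pd.read_csv(path)
        missing = {"x", "y", "z", "prop"} - set(df.columns)
        if missing:
            raise ValueError(f"particle CSV missing columns {sorted(missing)}")
        return cls(df[["x", "y", "z"]].to_numpy(), df["prop"].to_numpy(),
                   label=label or Path(path).stem)

    @classmethod
    def from_xyz(cls, path: str | Path, label: str = "") -> "ParticleSet":
        """Read an (extended) XYZ file whose atom lines end in four numeric
        fields: x, y, z and one scalar property."""
        lines = Path(path).read_text().splitlines()
        if len(lines) < 3:
            raise ValueError("XYZ file too short")
        n = int(lines[0].split()[0])
        rows = []
        for ln in lines[2:2 + n]:
            tok = ln.split()
            if len(tok) < 4:
                raise ValueError(f"XYZ atom line has too few fields: {ln!r}")
            rows.append([float(t) for t in tok[-4:]])
        arr = np.asarray(rows, dtype=float)
        return cls(arr[:, :3], arr[:, 3], label=label or Path(path).stem)


def read_particles(path: str | Path, label: str = "") -> ParticleSet:
    """Dispatch on extension: ``.xyz`` via the XYZ reader, else CSV."""
    if str(path).lower().endswith(".xyz"):
        return ParticleSet.from_xyz(path, label=label)
    return ParticleSet.from_csv(path, label=label)
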