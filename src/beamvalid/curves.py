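"""Curve: the common container for TPS-predicted and measured profiles.

A Curve is an ordered set of (position, value) samples along one scan axis
(crossline, inline, diagonal, or depth) together with the metadata needed
to pair a measured curve with its TPS prediction: axis, depth and field
size.  Curves are exchanged on disk as small commented CSV files.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from .beam import FieldSize

__all__ = ["Curve", "AXES"]

AXES = ("crossline", "inline", "diagonal", "depth")


@dataclass(frozen=True, eq=False)
class Curve:
    """Ordered (position, value) samples with pairing metadata.

    positions are isocenter-relative cm (depth cm, positive downward, for
    depth curves); values are relative dose (raw model units or percent
    after normalization).  provenance is "tps" or "measured".
    """

    axis: str
    depth_cm: float | None
    field_size: FieldSize
    positions: np.ndarray
    values: np.ndarray
    provenance: str = "tps"

    def __post_init__(self) -> None:
        if self.axis not in AXES:
            raise ValueError(f"unknown axis {self.axis!r}")
        p = np.asarray(self.positions, dtype=float)
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "positions", p)
        object.__setattr__(self, "values", v)
        if p.ndim != 1 or p.shape != v.shape:
            raise ValueError("positions and values must be equal-length 1D arrays")
        if p.size == 0:
            raise ValueError("empty curve")
        if not (np.all(np.isfinite(p)) and np.all(np.isfinite(v))):
            raise ValueError("non-finite sample in curve")
        if p.size > 1 and not np.all(np.diff(p) > 0):
            raise ValueError("positions must be strictly increasing")
        if self.axis == "depth" and self.depth_cm is not None:
            raise ValueError("depth curves carry no depth_cm metadata")

    def __eq__(self, other) -> bool:
        if not isinstance(other, Curve):
            return NotImplemented
        return (
            self.axis == other.axis
            and self.depth_cm == other.depth_cm
            and self.field_size == other.field_size
            and self.provenance == other.provenance
            and np.array_equal(self.positions, other.positions)
            and np.array_equal(self.values, other.values)
        )

    # -- pairing ---------------------------------------------------------
    @property
    def key(self) -> tuple:
        """Metadata key used to pair measured and TPS curves."""
        d = None if self.depth_cm is None else round(float(self.depth_cm), 3)
        return (self.axis, self.field_size.label(), d)

    # -- handy numerics --------------------------------------------------
    def interp(self, x) -> np.ndarray:
        return np.interp(x, self.positions, self.values)

    @property
    def lo(self) -> float:
        return float(self.positions[0])

    @property
    def hi(self) -> float:
        return float(self.positions[-1])

    def with_values(self, values) -> "Curve":
        return replace(self, values=np.asarray(values, dtype=float))

    def with_positions(self, positions) -> "Curve":
        return replace(self, positions=np.asarray(positions, dtype=float))

    # -- CSV I/O ---------------------------------------------------------
    def to_csv(self, path: str | Path | None = None) -> str:
        """Serialize as commented-header CSV (6 decimal places).

        Returns the text; also writes it if ``path`` is given.  Identical
        curves serialize to byte-identical text.
        """
        buf = io.StringIO()
        depth = "-" if self.depth_cm is None else f"{self.depth_cm:g}"
        buf.write(f"# axis: {self.axis}\n")
        buf.write(f"# depth_cm: {depth}\n")
        buf.write(f"# field_size_cm: {self.field_size.label()}\n")
        buf.write(f"# provenance: {self.provenance}\n")
        buf.write("position_cm,dose\n")
        for p, v in zip(self.positions, self.values):
            buf.write(f"{p:.6f},{v:.6f}\n")
        text = buf.getvalue()
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_csv(cls, source: str | Path) -> "Curve":
        """Read a curve written by :meth:`to_csv` (path or CSV text)."""
        text = source if isinstance(source, str) and "\n" in source else Path(source).read_text()
        meta: dict[str, str] = {}
        pos, val = [], []
        for line in text.splitlines():
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                k, _, v = line.lstrip("# ").partition(":")
                meta[k.strip()] = v.strip()
            elif not line.startswith("position_cm"):
                p, _, v = line.partition(",")
                pos.append(float(p))
                val.append(float(v))
        depth = None if meta.get("depth_cm", "-") == "-" else float(meta["depth_cm"])
        return cls(
            axis=meta["axis"],
            depth_cm=depth,
            field_size=FieldSize.from_label(meta["field_size_cm"]),
            positions=np.asarray(pos),
            values=np.asarray(val),
            provenance=meta.get("provenance", "tps"),
        )
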