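"""Electrode-grid geometry for high-density surface EMG.

The detection system is a planar rectangular grid of electrodes with a
fixed pitch. Real grids are often cut to follow the limb: rectangular
blocks of cells may be excluded (the packaged 128-electrode layout is a
12 x 12 grid with two 4-column x 2-row blocks removed at the ulnar
proximal and distal corners). One column of the grid is aligned to an
anatomical reference line on the skin; that column defines the origin of
the medio-lateral (x) axis.

Coordinate convention
---------------------
``x = (col - reference_col) * pitch`` — medio-lateral, positive toward
the radial side (columns are numbered ulnar to radial).
``y = (row - 1) * pitch`` — proximal-distal, origin at the proximal row,
positive distally.

Channels are identified by strings ``"rRRcCC"`` (1-based row/column) and
enumerated row-major: proximal to distal, then ulnar to radial. File I/O
relies on this ordering.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

from .errors import GridSpecError, UnknownChannelError

#: inclusive 1-based ((row_start, row_stop), (col_start, col_stop))
Block = tuple[tuple[int, int], tuple[int, int]]


def channel_id(row: int, col: int) -> str:
    """Canonical channel identifier for a (1-based) grid cell."""
    return f"r{row:02d}c{col:02d}"


def _as_block(b) -> Block:
    (r0, r1), (c0, c1) = b
    return ((int(r0), int(r1)), (int(c0), int(c1)))


@dataclass(frozen=True)
class GridSpec:
    """Declarative description of an electrode grid.

    Parameters
    ----------
    n_rows, n_cols:
        Grid extent in cells.
    pitch_mm:
        Distance between adjacent electrodes, millimetres.
    missing_blocks:
        Rectangular exclusions, each ``((row_start, row_stop),
        (col_start, col_stop))`` with inclusive 1-based bounds.
    reference_col:
        Column aligned with the anatomical reference line (x origin).
    """

    n_rows: int
    n_cols: int
    pitch_mm: float = 10.0
    missing_blocks: tuple[Block, ...] = ()
    reference_col: int = 1
    name: str = "custom"

    def __post_init__(self):
        object.__setattr__(
            self, "missing_blocks", tuple(_as_block(b) for b in self.missing_blocks)
        )
        if self.n_rows < 1 or self.n_cols < 1:
            raise GridSpecError("grid must have at least one row and one column")
        if not self.pitch_mm > 0:
            raise GridSpecError(f"pitch must be positive, got {self.pitch_mm}")
        if not 1 <= self.reference_col <= self.n_cols:
            raise GridSpecError(
                f"reference_col {self.reference_col} outside [1, {self.n_cols}]"
            )
        cells: set[tuple[int, int]] = set()
        for (r0, r1), (c0, c1) in self.missing_blocks:
            if not (1 <= r0 <= r1 <= self.n_rows and 1 <= c0 <= c1 <= self.n_cols):
                raise GridSpecError(
                    f"missing block (({r0},{r1}),({c0},{c1})) outside "
                    f"{self.n_rows}x{self.n_cols} grid"
                )
            block = {
                (r, c) for r in range(r0, r1 + 1) for c in range(c0, c1 + 1)
            }
            if cells & block:
                raise GridSpecError("missing blocks overlap")
            cells |= block
        if len(cells) >= self.n_rows * self.n_cols:
            raise GridSpecError("missing blocks remove every electrode")

    @property
    def excluded_cells(self) -> frozenset[tuple[int, int]]:
        out: set[tuple[int, int]] = set()
        for (r0, r1), (c0, c1) in self.missing_blocks:
            out |= {(r, c) for r in range(r0, r1 + 1) for c in range(c0, c1 + 1)}
        return frozenset(out)

    @property
    def n_channels(self) -> int:
        return self.n_rows * self.n_cols - len(self.excluded_cells)

    # --- serialization (JSON keys are the documented interface) ---

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "n_rows": self.n_rows,
            "n_cols": self.n_cols,
            "pitch_mm": self.pitch_mm,
            "missing_blocks": [
                [list(rr), list(cc)] for rr, cc in self.missing_blocks
            ],
            "reference_col": self.reference_col,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GridSpec":
        return cls(
            n_rows=int(d["n_rows"]),
            n_cols=int(d["n_cols"]),
            pitch_mm=float(d.get("pitch_mm", 10.0)),
            missing_blocks=tuple(_as_block(b) for b in d.get("missing_blocks", [])),
            reference_col=int(d.get("reference_col", 1)),
            name=str(d.get("name", "custom")),
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "GridSpec":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass(frozen=True)
class GridLayout:
    """Concrete electrode layout: channel ids, positions, validity mask.

    ``channels`` is the canonical row-major ordering; ``positions[i]`` is
    the (x_mm, y_mm) position of ``channels[i]``; ``valid_mask`` is a
    (n_rows, n_cols) boolean array, False inside missing blocks.
    """

    spec: GridSpec
    channels: tuple[str, ...]
    rows: np.ndarray  # 1-based row per channel
    cols: np.ndarray  # 1-based col per channel
    positions: np.ndarray  # (n_channels, 2) in mm
    valid_mask: np.ndarray  # (n_rows, n_cols) bool
    _index: dict = field(default_factory=dict, repr=False, compare=False)
    _cell_index: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        self._index.update({ch: i for i, ch in enumerate(self.channels)})
        cell = np.full((self.spec.n_rows, self.spec.n_cols), -1, dtype=int)
        cell[self.rows - 1, self.cols - 1] = np.arange(len(self.channels))
        object.__setattr__(self, "_cell_index", cell)

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    def index(self, channel: str) -> int:
        try:
            return self._index[channel]
        except KeyError:
            raise UnknownChannelError(f"unknown channel {channel!r}") from None

    def cell_channel(self, row: int, col: int) -> str | None:
        """Channel at a (1-based) cell, or None for excluded cells."""
        if not (1 <= row <= self.spec.n_rows and 1 <= col <= self.spec.n_cols):
            return None
        i = self._cell_index[row - 1, col - 1]
        return None if i < 0 else self.channels[i]

    def position(self, channel: str) -> tuple[float, float]:
        i = self.index(channel)
        return (float(self.positions[i, 0]), float(self.positions[i, 1]))

    def neighbors(self, channel: str, connectivity: int = 4) -> set[str]:
        if connectivity not in (4, 8):
            raise GridSpecError(f"connectivity must be 4 or 8, got {connectivity}")
        i = self.index(channel)
        r, c = int(self.rows[i]), int(self.cols[i])
        offsets = [(-1, 0), (1, 0), (0, -1), (0, 1)]
        if connectivity == 8:
            offsets += [(-1, -1), (-1, 1), (1, -1), (1, 1)]
        out = set()
        for dr, dc in offsets:
            ch = self.cell_channel(r + dr, c + dc)
            if ch is not None:
                out.add(ch)
        return out

    # --- grid <-> vector helpers used by the map layer ---

    def to_grid(self, values: np.ndarray, fill: float = np.nan) -> np.ndarray:
        """Arrange per-channel values on the (n_rows, n_cols) grid."""
        values = np.asarray(values)
        if values.shape != (self.n_channels,):
            raise ValueError(
                f"expected {self.n_channels} values, got shape {values.shape}"
            )
        g = np.full((self.spec.n_rows, self.spec.n_cols), fill, dtype=float)
        g[self.rows - 1, self.cols - 1] = values
        return g

    def from_grid(self, grid: np.ndarray) -> np.ndarray:
        """Extract per-channel values from a (n_rows, n_cols) array."""
        return np.asarray(grid)[self.rows - 1, self.cols - 1]


def build_grid(spec: GridSpec) -> GridLayout:
    """Enumerate the layout of a :class:`GridSpec`.

    Channels are ordered row-major (proximal to distal, then ulnar to
    radial); positions follow the module coordinate convention.
    """
    excluded = spec.excluded_cells
    rows, cols, chans = [], [], []
    for r in range(1, spec.n_rows + 1):
        for c in range(1, spec.n_cols + 1):
            if (r, c) in excluded:
                continue
            rows.append(r)
            cols.append(c)
            chans.append(channel_id(r, c))
    rows_a = np.asarray(rows, dtype=int)
    cols_a = np.asarray(cols, dtype=int)
    positions = np.column_stack(
        [
            (cols_a - spec.reference_col) * spec.pitch_mm,
            (rows_a - 1) * spec.pitch_mm,
        ]
    ).astype(float)
    valid = np.ones((spec.n_rows, spec.n_cols), dtype=bool)
    for r, c in excluded:
        valid[r - 1, c - 1] = False
    return GridLayout(
        spec=spec,
        channels=tuple(chans),
        rows=rows_a,
        cols=cols_a,
        positions=positions,
        valid_mask=valid,
    )


def channel_position(layout: GridLayout, channel: str) -> tuple[float, float]:
    """Planar (x_mm, y_mm) position of a channel."""
    return layout.position(channel)


def neighbors(layout: GridLayout, channel: str, connectivity: int = 4) -> set[str]:
    """Valid grid neighbors of a channel under 4- or 8-connectivity."""
    return layout.neighbors(channel, connectivity)


def standard_grid_spec() -> GridSpec:
    """The packaged 128-electrode forearm grid (12x12, 10 mm pitch,
    two 4x2 ulnar-corner blocks removed, reference column 3)."""
    with resources.files("emgrid.data").joinpath("standard_grid_128.json").open() as f:
        return GridSpec.from_dict(json.load(f))


def standard_layout() -> GridLayout:
    """Built layout of :func:`standard_grid_spec`."""
    return build_grid(standard_grid_spec())
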