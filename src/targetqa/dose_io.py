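"""Reading, writing and slicing DOSXYZnrc ``3ddose`` dose grids.

The ``3ddose`` text format stores a rectilinear 3-D dose grid:

* record 1 — the voxel counts ``nx ny nz``;
* records 2-4 — the x, y and z voxel *boundary* coordinates in cm
  (``n + 1`` strictly increasing numbers per axis, one line per record);
* record 5 — ``nx * ny * nz`` dose values with x varying fastest, then y,
  then z (may span several lines);
* record 6 — the same count of fractional (type-A) relative uncertainties.

Doses are per incident particle; all coordinates are cm. Voxel centers are
boundary midpoints, and every downstream sampling operation in this package
works on centers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "DoseGrid",
    "DosePlane",
    "Parse3ddoseError",
    "read_3ddose",
    "write_3ddose",
    "extract_plane",
]

#: plane orientation -> (normal axis index, in-plane axis indices, labels)
_ORIENTATIONS = {
    "transverse": (2, (0, 1), ("x", "y")),  # fixed depth z
    "coronal": (1, (0, 2), ("x", "z")),     # fixed y
    "sagittal": (0, (1, 2), ("y", "z")),    # fixed x
}


class Parse3ddoseError(ValueError):
    """A ``3ddose`` file violated the format; ``record`` names the offender."""

    def __init__(self, record: str, message: str):
        self.record = record
        super().__init__(f"3ddose {record} record: {message}")


def _centers(bounds: np.ndarray) -> np.ndarray:
    return 0.5 * (bounds[:-1] + bounds[1:])


@dataclass
class DoseGrid:
    """Rectilinear 3-D dose + relative-uncertainty grid (the 3ddose payload).

    ``dose`` and ``rel_unc`` have shape ``(nx, ny, nz)``; boundary arrays have
    one more entry than the voxel count along their axis.
    """

    x_bounds: np.ndarray
    y_bounds: np.ndarray
    z_bounds: np.ndarray
    dose: np.ndarray
    rel_unc: np.ndarray

    def __post_init__(self) -> None:
        self.x_bounds = np.asarray(self.x_bounds, dtype=float)
        self.y_bounds = np.asarray(self.y_bounds, dtype=float)
        self.z_bounds = np.asarray(self.z_bounds, dtype=float)
        self.dose = np.asarray(self.dose, dtype=float)
        self.rel_unc = np.asarray(self.rel_unc, dtype=float)
        shape = self.dose.shape
        if self.rel_unc.shape != shape:
            raise ValueError(
                f"dose shape {shape} != rel_unc shape {self.rel_unc.shape}"
            )
        for name, bounds, n in (
            ("x", self.x_bounds, shape[0]),
            ("y", self.y_bounds, shape[1]),
            ("z", self.z_bounds, shape[2]),
        ):
            if bounds.ndim != 1 or len(bounds) != n + 1:
                raise ValueError(
                    f"{name}_bounds must have {n + 1} entries, got {len(bounds)}"
                )
            if not np.all(np.diff(bounds) > 0):
                raise ValueError(f"{name}_bounds must be strictly increasing")
        if np.any(self.dose < 0):
            raise ValueError("dose values must be non-negative")
        if np.any((self.rel_unc < 0) | (self.rel_unc > 1)):
            raise ValueError("rel_unc values must lie in [0, 1]")

    # -- derived geometry ---------------------------------------------------
    @property
    def nx(self) -> int:
        return self.dose.shape[0]

    @property
    def ny(self) -> int:
        return self.dose.shape[1]

    @property
    def nz(self) -> int:
        return self.dose.shape[2]

    @property
    def x_centers(self) -> np.ndarray:
        return _centers(self.x_bounds)

    @property
    def y_centers(self) -> np.ndarray:
        return _centers(self.y_bounds)

    @property
    def z_centers(self) -> np.ndarray:
        return _centers(self.z_bounds)


@dataclass
class DosePlane:
    """A 2-D dose slice with voxel-center positions along its two axes."""

    ax1_positions: np.ndarray
    ax2_positions: np.ndarray
    dose: np.ndarray
    orientation: str = "transverse"
    coordinate: float = 0.0
    ax1_label: str = "x"
    ax2_label: str = "y"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.ax1_positions = np.asarray(self.ax1_positions, dtype=float)
        self.ax2_positions = np.asarray(self.ax2_positions, dtype=float)
        self.dose = np.asarray(self.dose, dtype=float)
        if self.dose.shape != (len(self.ax1_positions), len(self.ax2_positions)):
            raise ValueError("plane dose shape does not match position arrays")
        for name, pos in (("ax1", self.ax1_positions), ("ax2", self.ax2_positions)):
            if not np.all(np.diff(pos) > 0):
                raise ValueError(f"{name} positions must be strictly increasing")
        if np.any(self.dose < 0):
            raise ValueError("plane dose must be non-negative")


# ---------------------------------------------------------------------------
# parsing


def _parse_floats(tokens: list[str], record: str) -> np.ndarray:
    try:
        return np.array([float(t) for t in tokens])
    except ValueError as exc:
        raise Parse3ddoseError(record, f"non-numeric token ({exc})") from None


def read_3ddose(path: str | Path) -> DoseGrid:
    """Parse a ``3ddose`` file into a :class:`DoseGrid`.

    Raises :class:`Parse3ddoseError` naming the offending record for a
    malformed header, boundary-count mismatch, non-monotone boundaries,
    value-count mismatch or non-numeric payload.
    """
    lines = [ln for ln in Path(path).read_text().splitlines() if ln.strip()]
    if not lines:
        raise Parse3ddoseError("header", "file is empty")

    header = lines[0].split()
    if len(header) != 3:
        raise Parse3ddoseError(
            "header", f"expected 3 voxel counts, got {len(header)} tokens"
        )
    try:
        nx, ny, nz = (int(t) for t in header)
    except ValueError:
        raise Parse3ddoseError("header", "voxel counts must be integers") from None
    if min(nx, ny, nz) < 1:
        raise Parse3ddoseError("header", "voxel counts must be positive")

    if len(lines) < 4:
        raise Parse3ddoseError("x boundaries", "missing boundary records")
    bounds = []
    for record, n, line in (
        ("x boundaries", nx, lines[1]),
        ("y boundaries", ny, lines[2]),
        ("z boundaries", nz, lines[3]),
    ):
        tokens = line.split()
        if len(tokens) != n + 1:
            raise Parse3ddoseError(
                record, f"expected {n + 1} boundary values, got {len(tokens)}"
            )
        arr = _parse_floats(tokens, record)
        if not np.all(np.diff(arr) > 0):
            raise Parse3ddoseError(record, "boundaries are not strictly increasing")
        bounds.append(arr)

    nvox = nx * ny * nz
    payload = " ".join(lines[4:]).split()
    if len(payload) < nvox:
        raise Parse3ddoseError(
            "dose values", f"expected {nvox} values, got {len(payload)}"
        )
    if len(payload) != 2 * nvox:
        raise Parse3ddoseError(
            "uncertainty values",
            f"expected {nvox} values after the dose record, "
            f"got {len(payload) - nvox}",
        )
    dose = _parse_floats(payload[:nvox], "dose values")
    rel_unc = _parse_floats(payload[nvox:], "uncertainty values")
    if np.any(dose < 0):
        raise Parse3ddoseError("dose values", "negative dose value")
    if np.any((rel_unc < 0) | (rel_unc > 1)):
        raise Parse3ddoseError("uncertainty values", "value outside [0, 1]")

    # x varies fastest in the flattened records
    dose3 = dose.reshape((nx, ny, nz), order="F")
    unc3 = rel_unc.reshape((nx, ny, nz), order="F")
    return DoseGrid(bounds[0], bounds[1], bounds[2], dose3, unc3)


def write_3ddose(grid: DoseGrid, path: str | Path, per_line: int = 6) -> None:
    """Write ``grid`` in 3ddose layout with >= 6 significant digits."""
    # DoseGrid.__post_init__ has already enforced the invariants.
    out = []
    out.append(f"{grid.nx} {grid.ny} {grid.nz}")
    for bounds in (grid.x_bounds, grid.y_bounds, grid.z_bounds):
        out.append(" ".join(f"{b:.9g}" for b in bounds))
    for values in (grid.dose, grid.rel_unc):
        flat = values.reshape(-1, order="F")
        for i in range(0, len(flat), per_line):
            out.append(" ".join(f"{v:.8e}" for v in flat[i : i + per_line]))
    Path(path).write_text("\n".join(out) + "\n")


def extract_plane(
    grid: DoseGrid, orientation: str, coordinate: float
) -> DosePlane:
    """Slice the voxel layer whose center is nearest ``coordinate``.

    Ties between two equidistant layers break toward the smaller coordinate.
    The returned plane records the coordinate actually used.
    """
    if orientation not in _ORIENTATIONS:
        raise ValueError(
            f"orientation must be one of {sorted(_ORIENTATIONS)}, got {orientation!r}"
        )
    normal, in_plane, labels = _ORIENTATIONS[orientation]
    bounds = (grid.x_bounds, grid.y_bounds, grid.z_bounds)[normal]
    if not bounds[0] <= coordinate <= bounds[-1]:
        raise ValueError(
            f"coordinate {coordinate} outside grid extent "
            f"[{bounds[0]}, {bounds[-1]}] along {'xyz'[normal]}"
        )
    centers = _centers(bounds)
    # argmin returns the first (smaller-coordinate) index on exact ties
    layer = int(np.argmin(np.abs(centers - coordinate)))
    dose = np.take(grid.dose, layer, axis=normal)
    all_centers = (grid.x_centers, grid.y_centers, grid.z_centers)
    return DosePlane(
        ax1_positions=all_centers[in_plane[0]],
        ax2_positions=all_centers[in_plane[1]],
        dose=dose,
        orientation=orientation,
        coordinate=float(centers[layer]),
        ax1_label=labels[0],
        ax2_label=labels[1],
        meta={"requested_coordinate": float(coordinate), "layer_index": layer},
    )
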