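"""Marker layout: the circumferential grid an OEP-style acquisition uses.

The canonical seated-protocol layout covers the trunk with a grid of seven
circumferential rows, five anterior and five posterior columns, plus
lateral markers on each side and a few extra anterior costal/abdominal
stations, for 89 markers in total. The exact anatomical positions are a
laboratory convention; everything here is configuration-driven so variants
(e.g. a 52-marker supine set) can be described in a small YAML file.

Conventions
-----------
* Azimuth is measured in the transverse (x, y) plane, degrees in [0, 360):
  0 = right lateral (+x), 90 = anterior centre (+y), 180 = left lateral,
  270 = posterior centre.
* Row 1 is the highest (cranial) row; z decreases with row index.
* Compartments (pulmonary ribcage RCp, abdominal ribcage RCa, abdomen AB)
  are inclusive row ranges; adjacent compartments share their boundary row.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

COMPARTMENTS = ("RCp", "RCa", "AB")
LEVELS = ("louis_angle", "xiphoid", "umbilicus")


class LayoutError(ValueError):
    """Raised when a marker-layout description is inconsistent."""


@dataclass(frozen=True)
class Station:
    """One marker position slot: a (row, azimuth) grid location."""

    label: str
    row: int
    azimuth_deg: float
    kind: str  # front | back | lateral_right | lateral_left | extra


@dataclass
class MarkerLayout:
    rows: int
    front_cols: int
    back_cols: int
    lateral_rows_right: tuple[int, ...]
    lateral_rows_left: tuple[int, ...]
    extra_stations: dict[int, tuple[float, ...]]
    level_rows: dict[str, int]
    compartment_rows: dict[str, tuple[int, int]]
    total_markers: int
    stations: list[Station] = field(init=False)

    def __post_init__(self) -> None:
        self.stations = self._build_stations()
        self._validate()

    # -- construction ---------------------------------------------------
    def _build_stations(self) -> list[Station]:
        front_az = np.linspace(180.0, 0.0, self.front_cols + 2)[1:-1]
        back_az = np.linspace(180.0, 360.0, self.back_cols + 2)[1:-1]
        stations: list[Station] = []
        for r in range(1, self.rows + 1):
            row: list[Station] = []
            for c, az in enumerate(front_az, start=1):
                # F1 is the subject's left-most anterior column
                row.append(Station(f"r{r}_F{c}", r, float(az), "front"))
            for c, az in enumerate(back_az, start=1):
                row.append(Station(f"r{r}_B{c}", r, float(az), "back"))
            if r in self.lateral_rows_right:
                row.append(Station(f"r{r}_LR", r, 0.0, "lateral_right"))
            if r in self.lateral_rows_left:
                row.append(Station(f"r{r}_LL", r, 180.0, "lateral_left"))
            for k, az in enumerate(self.extra_stations.get(r, ()), start=1):
                row.append(Station(f"r{r}_X{k}", r, float(az), "extra"))
            row.sort(key=lambda s: s.azimuth_deg)
            stations.extend(row)
        return stations

    def _validate(self) -> None:
        if self.rows < 2:
            raise LayoutError("need at least 2 rows")
        if len(self.stations) != self.total_markers:
            raise LayoutError(
                f"total_markers={self.total_markers} but layout defines "
                f"{len(self.stations)} stations"
            )
        labels = [s.label for s in self.stations]
        if len(set(labels)) != len(labels):
            raise LayoutError("duplicate marker labels")
        for name in LEVELS:
            if name not in self.level_rows:
                raise LayoutError(f"missing level row: {name}")
            r = self.level_rows[name]
            if not 1 <= r <= self.rows:
                raise LayoutError(f"level row {name}={r} outside 1..{self.rows}")
        seq = [self.level_rows[name] for name in LEVELS]
        if not (seq[0] < seq[1] < seq[2]):
            raise LayoutError(
                "level rows must be strictly increasing louis_angle < xiphoid "
                f"< umbilicus, got {dict(zip(LEVELS, seq))}"
            )
        # compartments must tile 1..rows, sharing exactly the boundary rows
        for name in COMPARTMENTS:
            if name not in self.compartment_rows:
                raise LayoutError(f"missing compartment: {name}")
            lo, hi = self.compartment_rows[name]
            if not (1 <= lo < hi <= self.rows):
                raise LayoutError(f"compartment {name} rows ({lo}, {hi}) invalid")
        ranges = sorted(self.compartment_rows.values())
        if ranges[0][0] != 1 or ranges[-1][1] != self.rows:
            raise LayoutError("compartments must cover rows 1..rows")
        for (_, hi), (lo2, _) in zip(ranges, ranges[1:]):
            if hi != lo2:
                raise LayoutError(
                    "adjacent compartments must share exactly their boundary row"
                )

    # -- lookups --------------------------------------------------------
    @property
    def marker_labels(self) -> list[str]:
        return [s.label for s in self.stations]

    def index_of(self, label: str) -> int:
        try:
            return self.marker_labels.index(label)
        except ValueError:
            raise KeyError(f"unknown marker label: {label}") from None

    def row_indices(self, row: int) -> np.ndarray:
        """Marker indices of one row, sorted by azimuth (a closed ring)."""
        return np.array(
            [i for i, s in enumerate(self.stations) if s.row == row], dtype=int
        )

    def row_azimuths(self, row: int) -> np.ndarray:
        return np.array(
            [s.azimuth_deg for s in self.stations if s.row == row], dtype=float
        )

    def lateral_indices(self, side: str, rows: tuple[int, int] | None = None) -> np.ndarray:
        kind = {"right": "lateral_right", "left": "lateral_left"}[side]
        lo, hi = rows if rows is not None else (1, self.rows)
        return np.array(
            [i for i, s in enumerate(self.stations)
             if s.kind == kind and lo <= s.row <= hi],
            dtype=int,
        )

    def central_index(self, row: int, side: str) -> int:
        """Index of the front-central / back-central marker of a row."""
        target = 90.0 if side == "front" else 270.0
        kinds = ("front", "extra") if side == "front" else ("back",)
        cand = [
            (abs(s.azimuth_deg - target), i)
            for i, s in enumerate(self.stations)
            if s.row == row and s.kind in kinds
        ]
        if not cand:
            raise LayoutError(f"row {row} has no {side} markers")
        return min(cand)[1]

    def scope_rows(self, scope: str) -> tuple[int, int]:
        if scope == "trunk":
            return (1, self.rows)
        if scope in self.compartment_rows:
            return self.compartment_rows[scope]
        raise LayoutError(f"unknown scope: {scope!r}")


def default_layout() -> MarkerLayout:
    """The canonical 89-marker seated layout (7 rows, 5+5 columns,
    full lateral columns, five extra anterior costal/abdominal stations)."""
    return MarkerLayout(
        rows=7,
        front_cols=5,
        back_cols=5,
        lateral_rows_right=tuple(range(1, 8)),
        lateral_rows_left=tuple(range(1, 8)),
        extra_stations={r: (75.0,) for r in range(3, 8)},
        level_rows={"louis_angle": 2, "xiphoid": 4, "umbilicus": 6},
        compartment_rows={"RCp": (1, 4), "RCa": (4, 5), "AB": (5, 7)},
        total_markers=89,
    )


def load_layout(path: str | Path | None = None) -> MarkerLayout:
    """Load a layout config (YAML, flat keys); default layout when omitted.

    Raises LayoutError naming the offending key on malformed input.
    """
    if path is None:
        return default_layout()
    path = Path(path)
    with open(path) as fh:
        try:
            raw = yaml.safe_load(fh)
        except yaml.YAMLError as exc:
            raise LayoutError(f"cannot parse layout file {path}: {exc}") from exc
    if not isinstance(raw, dict):
        raise LayoutError(f"layout file {path} is not a mapping")
    required = ["rows", "front_cols", "back_cols", "total_markers"]
    for key in required:
        if key not in raw:
            raise LayoutError(f"layout file missing key: {key}")
    try:
        return MarkerLayout(
            rows=int(raw["rows"]),
            front_cols=int(raw["front_cols"]),
            back_cols=int(raw["back_cols"]),
            lateral_rows_right=tuple(raw.get("lateral_rows_right", range(1, int(raw["rows"]) + 1))),
            lateral_rows_left=tuple(raw.get("lateral_rows_left", range(1, int(raw["rows"]) + 1))),
            extra_stations={
                int(k): tuple(float(a) for a in v)
                for k, v in (raw.get("extra_stations") or {}).items()
            },
            level_rows={k: int(v) for k, v in raw["level_rows"].items()},
            compartment_rows={
                k: (int(v[0]), int(v[1])) for k, v in raw["compartment_rows"].items()
            },
            total_markers=int(raw["total_markers"]),
        )
    except KeyError as exc:
        raise LayoutError(f"layout file missing key: {exc.args[0]}") from exc


def save_layout(layout: MarkerLayout, path: str | Path) -> None:
    raw = {
        "rows": layout.rows,
        "front_cols": layout.front_cols,
        "back_cols": layout.back_cols,
        "lateral_rows_right": list(layout.lateral_rows_right),
        "lateral_rows_left": list(layout.lateral_rows_left),
        "extra_stations": {r: list(az) for r, az in layout.extra_stations.items()},
        "level_rows": dict(layout.level_rows),
        "compartment_rows": {k: list(v) for k, v in layout.compartment_rows.items()},
        "total_markers": layout.total_markers,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(raw, fh, sort_keys=False)
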