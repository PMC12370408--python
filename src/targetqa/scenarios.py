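"""Target geometry, degradation scenarios and the severity scale.

A degraded linac photon target is modeled as a cylindrical vacuum hole of a
given depth and width burned into the tungsten button at the focal spot.
The built-in library holds the twelve named conditions studied for a
Varian C-series target (0.889 mm tungsten on a 1.575 mm copper base): the
nominal condition NC, depth steps D0.1-D0.7 at 1 mm width, full tungsten
burn-through at 1 and 2 mm width (W1, W2), burn-through 1 mm into the
copper (WC), and full two-layer penetration (Z2, Z3).

``severity`` collapses (depth, width) to one non-negative scalar that the
synthetic beam generator couples to output loss, horn sag, beam softening
and monitor-chamber response. Depth dominates by design (cubic by default)
because simulated output falls sharply with depth but only gently with
width.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator

import yaml

__all__ = [
    "TargetGeometry",
    "DegradationScenario",
    "ScenarioLibrary",
    "builtin_library",
    "severity",
    "fine_sweep",
]


@dataclass(frozen=True)
class TargetGeometry:
    """Two-layer target: tungsten button on a copper base (thicknesses in mm)."""

    tungsten_mm: float = 0.889
    copper_mm: float = 1.575

    def __post_init__(self) -> None:
        if self.tungsten_mm <= 0 or self.copper_mm <= 0:
            raise ValueError("layer thicknesses must be positive")

    @property
    def total_mm(self) -> float:
        return self.tungsten_mm + self.copper_mm


@dataclass(frozen=True)
class DegradationScenario:
    """A named cylindrical vacuum zone: hole depth and diameter in mm."""

    name: str
    depth_mm: float
    width_mm: float

    def __post_init__(self) -> None:
        if self.depth_mm < 0 or self.width_mm < 0:
            raise ValueError("depth and width must be non-negative")
        if self.depth_mm > 0 and self.width_mm <= 0:
            raise ValueError("a degraded scenario (depth > 0) needs width > 0")
        if self.depth_mm == 0 and self.width_mm != 0:
            raise ValueError("the nominal scenario (depth 0) must have width 0")

    @property
    def is_nominal(self) -> bool:
        return self.depth_mm == 0

    def validate_against(self, geometry: TargetGeometry) -> None:
        if self.depth_mm > geometry.total_mm + 1e-12:
            raise ValueError(
                f"scenario {self.name}: depth {self.depth_mm} mm exceeds the "
                f"{geometry.total_mm} mm target thickness"
            )


class ScenarioLibrary:
    """Ordered, name-unique collection of scenarios; NC present exactly once."""

    def __init__(self, scenarios: list[DegradationScenario]):
        names = [s.name for s in scenarios]
        if len(set(names)) != len(names):
            raise ValueError("scenario names must be unique")
        if sum(s.is_nominal for s in scenarios) != 1:
            raise ValueError("library must contain exactly one nominal scenario")
        self._by_name = {s.name: s for s in scenarios}
        self._order = list(scenarios)

    def __iter__(self) -> Iterator[DegradationScenario]:
        return iter(self._order)

    def __len__(self) -> int:
        return len(self._order)

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    def __getitem__(self, name: str) -> DegradationScenario:
        try:
            return self._by_name[name]
        except KeyError:
            raise KeyError(
                f"unknown scenario {name!r}; available: {sorted(self._by_name)}"
            ) from None

    @property
    def names(self) -> list[str]:
        return [s.name for s in self._order]

    @property
    def nominal(self) -> DegradationScenario:
        return next(s for s in self._order if s.is_nominal)

    def add(self, scenario: DegradationScenario) -> None:
        if scenario.name in self._by_name:
            raise ValueError(f"duplicate scenario name {scenario.name!r}")
        if scenario.is_nominal:
            raise ValueError("library already contains a nominal scenario")
        self._by_name[scenario.name] = scenario
        self._order.append(scenario)

    @classmethod
    def from_config(cls, path: str | Path) -> "ScenarioLibrary":
        """Load scenarios from a JSON or YAML list of flat records.

        Each record holds ``name``, ``depth_mm`` and ``width_mm``.
        """
        text = Path(path).read_text()
        if str(path).endswith(".json"):
            records = json.loads(text)
        else:
            records = yaml.safe_load(text)
        return cls(
            [
                DegradationScenario(
                    name=str(r["name"]),
                    depth_mm=float(r["depth_mm"]),
                    width_mm=float(r["width_mm"]),
                )
                for r in records
            ]
        )


#: (name, depth mm, width mm) for the twelve studied conditions
_BUILTIN = [
    ("NC", 0.0, 0.0),
    ("D0.1", 0.1, 1.0),
    ("D0.3", 0.3, 1.0),
    ("D0.5", 0.5, 1.0),
    ("D0.6", 0.6, 1.0),
    ("D0.6W2.0", 0.6, 2.0),
    ("D0.7", 0.7, 1.0),
    ("W1", 0.889, 1.0),
    ("W2", 0.889, 2.0),
    ("WC", 1.889, 2.0),
    ("Z2", 2.464, 2.0),
    ("Z3", 2.464, 3.0),
]


def builtin_library() -> ScenarioLibrary:
    """The twelve named degradation conditions of the study design."""
    return ScenarioLibrary(
        [DegradationScenario(n, d, w) for n, d, w in _BUILTIN]
    )


def fine_sweep(
    depths_mm,
    widths_mm,
    include_nominal: bool = True,
) -> ScenarioLibrary:
    """Build a D{depth}W{width} sweep library (e.g. 0.2 mm increments)."""
    scenarios = []
    if include_nominal:
        scenarios.append(DegradationScenario("NC", 0.0, 0.0))
    for d in depths_mm:
        for w in widths_mm:
            scenarios.append(
                DegradationScenario(f"D{d:g}W{w:g}", float(d), float(w))
            )
    return ScenarioLibrary(scenarios)


def severity(
    scenario: DegradationScenario,
    geometry: TargetGeometry = TargetGeometry(),
    depth_exponent: float = 3.0,
    width_exponent: float = 0.5,
    width_scale_mm: float = 1.0,
) -> float:
    """Dimensionless degradation severity, 0 for the nominal condition.

    ``severity = (depth / tungsten)^a * (width / w0)^b`` with ``a = 3``,
    ``b = 0.5`` by default, so severity is strictly increasing in depth at
    fixed width and non-decreasing in width at fixed depth, and depth
    dominates. ``severity = 1`` at full tungsten burn-through with a 1 mm
    hole (scenario W1).
    """
    if depth_exponent <= 0 or width_exponent <= 0:
        raise ValueError("severity exponents must be positive")
    scenario.validate_against(geometry)
    if scenario.is_nominal:
        return 0.0
    return (scenario.depth_mm / geometry.tungsten_mm) ** depth_exponent * (
        scenario.width_mm / width_scale_mm
    ) ** width_exponent
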