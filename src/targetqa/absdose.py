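"""Absolute-dose correction chain and derived output factors.

A simulated dose-per-particle value ``D_dpp`` is converted to absolute dose
(cGy/MU) through the monitor-chamber correction chain

    D_abs = D_dpp * R_ch(f, scenario) * F_backscatter(f) * F_cal

where ``R_ch`` is the nominal-to-degraded ratio of dose deposited in the
linac monitor chamber (1 under the nominal condition — a degraded target
dumps extra dose on the chamber, so the machine terminates each MU early
and the whole output rescales), ``F_backscatter`` corrects for field-size-
dependent jaw backscatter into the chamber (1 for the 10 cm reference
field), and ``F_cal`` ties the calibration condition (10 cm field, SSD
100 cm, z_max) to 1 cGy/MU.  Backscatter factors are inputs, not
recomputed: they require jaw-scatter transport; a plausible monotone
default table normalized to 1 at 10 cm ships with the package, and the
degraded-target values are taken equal to the nominal ones (they differ by
under 1%).

Derived quantities: the relative output factor ``ROF(f) = D_abs(f) /
D_abs(10) = (D_dpp(f)/D_dpp(10)) * F_backscatter(f)``, the wedge factor
``WF = D_wedge / D_open`` at z_max on the CAX (the wedge sits far from the
chamber, so its chamber ratio is 1), and percent output deviations from
the nominal baseline.  Uncertainties propagate in first-order quadrature
of relative terms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

from .beam_synth import RCH_FIXTURE

__all__ = [
    "CorrectionFactors",
    "OutputRecord",
    "AbsoluteDose",
    "default_factors",
    "absolute_dose",
    "chamber_amplification",
    "rof",
    "wedge_factor",
    "output_deviation",
]

#: default jaw-backscatter correction per field size (cm), 1 at the
#: 10 cm reference field, monotone in field size.
DEFAULT_BACKSCATTER = {
    3.0: 0.9938,
    6.0: 0.9965,
    10.0: 1.0,
    15.0: 1.0040,
    20.0: 1.0075,
    30.0: 1.0137,
}


@dataclass
class CorrectionFactors:
    """Correction-factor tables for the absolute-dose chain."""

    rch: Mapping[str, float] = field(default_factory=dict)
    rch_unc: Mapping[str, float] = field(default_factory=dict)
    f_backscatter: Mapping[float, float] = field(
        default_factory=lambda: dict(DEFAULT_BACKSCATTER)
    )
    f_cal: float = 9.3925e15          # particles per MU at calibration
    f_cal_rel_unc: float = 0.0024
    d_abs_cal: float = 1.0            # cGy/MU at the calibration condition
    d_dpp_cal: float = 1.0            # simulated d_dpp at the same condition

    def __post_init__(self) -> None:
        for name, value in (("f_cal", self.f_cal),
                            ("d_abs_cal", self.d_abs_cal),
                            ("d_dpp_cal", self.d_dpp_cal)):
            if value <= 0:
                raise ValueError(f"{name} must be positive")
        if any(v <= 0 for v in self.rch.values()):
            raise ValueError("R_ch values must be positive")
        if any(v <= 0 for v in self.f_backscatter.values()):
            raise ValueError("backscatter factors must be positive")

    def rch_for(self, scenario: str) -> float:
        if scenario == "NC":
            return 1.0
        try:
            return self.rch[scenario]
        except KeyError:
            raise KeyError(f"no R_ch entry for scenario {scenario!r}") from None

    def backscatter_for(self, field_size: float) -> float:
        try:
            return self.f_backscatter[float(field_size)]
        except KeyError:
            raise KeyError(
                f"no backscatter factor for the {field_size} cm field"
            ) from None


def default_factors(d_dpp_cal: float = 1.0) -> CorrectionFactors:
    """Factors table with the reference chamber-response ratios built in."""
    return CorrectionFactors(
        rch=dict(RCH_FIXTURE),
        rch_unc={"D0.1": 0.012, "D0.3": 0.012, "D0.5": 0.012, "D0.6": 0.007,
                 "D0.7": 0.010, "W1": 0.004, "W2": 0.002, "WC": 0.0002,
                 "Z2": 0.004, "Z3": 0.004},
        d_dpp_cal=d_dpp_cal,
    )


@dataclass
class AbsoluteDose:
    """An absolute dose with its propagated relative uncertainty."""

    value: float
    rel_unc: float = 0.0


@dataclass
class OutputRecord:
    """Beam output of one scenario/field, absolute and relative to nominal."""

    scenario: str
    field_size: float
    absolute_dose: float
    deviation_pct: float = 0.0
    rel_unc_pct: float = 0.0


def absolute_dose(
    d_dpp: float,
    field_size: float,
    scenario: str,
    factors: CorrectionFactors,
    d_dpp_rel_unc: float = 0.0,
) -> AbsoluteDose:
    """Apply the full correction chain to a simulated dose-per-particle."""
    r_ch = factors.rch_for(scenario)
    f_b = factors.backscatter_for(field_size)
    value = d_dpp * r_ch * f_b * (factors.d_abs_cal / factors.d_dpp_cal)
    rch_unc = 0.0 if scenario == "NC" else factors.rch_unc.get(scenario, 0.0)
    rel_unc = math.sqrt(
        d_dpp_rel_unc**2 + rch_unc**2 + factors.f_cal_rel_unc**2
    )
    return AbsoluteDose(value=value, rel_unc=rel_unc)


def chamber_amplification(scenario: str, factors: CorrectionFactors) -> float:
    """Fold-increase of the monitor-chamber dose over baseline (2 sig figs).

    The chamber response ratio is nominal/degraded chamber dose, so the
    degraded chamber sees ``1 / R_ch`` times the baseline dose.
    """
    r_ch = factors.rch_for(scenario)
    if r_ch <= 0:
        raise ValueError("R_ch must be positive")
    amplification = 1.0 / r_ch
    exponent = math.floor(math.log10(abs(amplification)))
    scale = 10.0 ** (exponent - 1)
    return round(amplification / scale) * scale


def rof(
    d_dpp_f: float,
    d_dpp_10: float,
    field_size: float,
    factors: CorrectionFactors,
) -> float:
    """Relative output factor vs the 10 cm field, backscatter-corrected.

    The chamber ratio cancels between the two fields of the same scenario,
    leaving ``(D_dpp(f) / D_dpp(10)) * F_backscatter(f)``; nominal-condition
    backscatter values are used for degraded scenarios.
    """
    if d_dpp_10 <= 0:
        raise ValueError("reference-field dose must be positive")
    return d_dpp_f / d_dpp_10 * factors.backscatter_for(field_size)


def wedge_factor(d_dpp_wedge: float, d_dpp_open: float) -> float:
    """Wedge factor: CAX dose ratio wedge/open at z_max (chamber ratio 1)."""
    if d_dpp_open <= 0:
        raise ValueError("open-field dose must be positive")
    return d_dpp_wedge / d_dpp_open


def output_deviation(test, baseline) -> float:
    """Percent deviation of a test output from the nominal baseline."""
    t = getattr(test, "absolute_dose", test)
    b = getattr(baseline, "absolute_dose", baseline)
    if b == 0:
        raise ValueError("baseline output is zero")
    return (t - b) / b * 100.0
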