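"""Scenario sweeps, degradation-detection rules and reporting.

``run_sweep`` generates (or reuses) water-phantom grids for every scenario
in a library at the requested field sizes, computes the full metric set
against the nominal-condition baseline — beam-output deviation, PDD20,10
deviation, per-side maximum profile deviations in the 0.8 and 0.95
field-size regions, flatness, relative-output-factor and wedge-factor
deviations — and applies the detection rules:

* output change beyond 3% in a day or 6% in a week (sudden-change safety
  thresholds);
* diagonal profile deviation beyond 3% in the 0.95 field-size region for
  fields of 30 cm or larger;
* any profile deviation beyond the 1% action level at any field and axis.

``friedman_test`` is the nonparametric repeated-measures test used to ask
whether a factor (axis choice, region of interest, wedge, depth) shifts
the observed deviations: within-block ranks (mean ranks on ties), the
rank-sum chi-square statistic and an asymptotic chi-square p-value.

All randomness flows from one integer seed; two runs with the same seed
produce identical results.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import chi2, rankdata

from . import absdose, metrics
from .beam_synth import (
    BeamModelParams,
    GridSpec,
    generate_field,
    water_phantom_grid,
)
from .scenarios import ScenarioLibrary

__all__ = [
    "DetectionRules",
    "SweepResult",
    "run_sweep",
    "apply_rules",
    "friedman_test",
    "report",
]


@dataclass(frozen=True)
class DetectionRules:
    """Action thresholds for flagging target degradation, all in percent."""

    daily_output_pct: float = 3.0
    weekly_output_pct: float = 6.0
    diagonal_deviation_pct: float = 3.0   # 0.95 FS region, fields >= 30 cm
    diagonal_min_field: float = 30.0
    any_profile_pct: float = 1.0

    def __post_init__(self) -> None:
        if min(self.daily_output_pct, self.weekly_output_pct,
               self.diagonal_deviation_pct, self.any_profile_pct) <= 0:
            raise ValueError("all thresholds must be positive")


@dataclass
class SweepResult:
    """Tidy metric table plus the raised detection flags."""

    metrics: pd.DataFrame   # scenario, field, metric, axis, depth, region, value
    flags: pd.DataFrame     # scenario, flag, threshold, value
    seed: int
    params: BeamModelParams

    @property
    def any_fired(self) -> bool:
        return len(self.flags) > 0


def _seed_for(seed: int, *indices: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, *indices]))


def _profile_chain(grid, axis, depth, field_size, resample_step=0.1):
    curve = metrics.extract_profile(grid, axis, depth, field_size=field_size)
    curve = metrics.resample(curve, resample_step)
    return metrics.smooth_profile(curve)


def run_sweep(
    library: ScenarioLibrary,
    fields: tuple[float, ...] = (10.0, 30.0),
    params: BeamModelParams | None = None,
    rules: DetectionRules | None = None,
    seed: int = 0,
    *,
    dxy: float = 0.5,
    dz: float = 0.5,
    depth_extent: float = 22.0,
    profile_depths: tuple[float, ...] = (5.0, 10.0),
    regions: tuple[float, ...] = (0.8, 0.95),
    axes: tuple[str, ...] = ("x", "y", "diagonal"),
    include_wedge: bool = False,
    noise: float | None = None,
) -> SweepResult:
    """Generate grids for every scenario and field, metric them vs nominal.

    The nominal grid of each field is generated once and reused as its own
    comparison, so the NC rows are exactly zero.  PDD20,10 rows require
    ``depth_extent >= 20`` cm; profile metrics use the smoothed, 1 mm
    resampled off-axis-factor chain.  ROF rows appear when the 10 cm
    reference field is part of the sweep.
    """
    if "NC" not in library:
        raise ValueError("the sweep library must contain the NC scenario")
    params = params or BeamModelParams()
    rules = rules or DetectionRules()
    factors = absdose.default_factors()
    want_pdd = depth_extent >= 20.0 + dz
    rows: list[dict] = []

    def grid_for(field_size: float) -> GridSpec:
        half = field_size * 0.62 + 2.5
        return water_phantom_grid(
            half_width=half, dxy=dxy, depth=depth_extent, dz=dz,
            z_first_center=dz,
        )

    # generate everything once: cache[(scenario, field, wedge)] = SimulatedField
    cache: dict[tuple[str, float, bool], object] = {}
    wedge_flags = (False, True) if include_wedge else (False,)
    for fi, f in enumerate(fields):
        spec = grid_for(f)
        for si, scen in enumerate(library):
            for wedge in wedge_flags:
                rng = _seed_for(seed, fi, si, int(wedge))
                cache[(scen.name, f, wedge)] = generate_field(
                    scen, f, spec, params, wedge=wedge, noise=noise, rng=rng
                )

    def add(scenario, f, metric, value, axis="", depth=np.nan, region=np.nan):
        rows.append(
            dict(scenario=scenario, field=f, metric=metric, axis=axis,
                 depth=depth, region=region, value=value)
        )

    for f in fields:
        nc = cache[("NC", f, False)]
        nc_output = metrics.beam_output(nc.grid)
        nc_pdd = (
            metrics.pdd_ratio_20_10(metrics.extract_pdd(nc.grid, f))
            if want_pdd else None
        )
        nc_profiles = {
            (axis, depth): _profile_chain(nc.grid, axis, depth, f)
            for axis, depth in itertools.product(axes, profile_depths)
        }
        nc_flatness = {
            (axis, depth): metrics.flatness(curve)
            for (axis, depth), curve in nc_profiles.items()
            if depth == 10.0
        }
        nc_rof = None
        if 10.0 in fields and f != 10.0:
            nc_rof = absdose.rof(
                nc_output, metrics.beam_output(cache[("NC", 10.0, False)].grid),
                f, factors,
            )
        nc_wf = None
        if include_wedge:
            zmax = params.z_max
            nc_wf = absdose.wedge_factor(
                metrics.beam_output(cache[("NC", f, True)].grid, depth=zmax),
                metrics.beam_output(nc.grid, depth=zmax),
            )

        for scen in library:
            sf = cache[(scen.name, f, False)]
            out = metrics.beam_output(sf.grid)
            add(scen.name, f, "output_deviation",
                absdose.output_deviation(out, nc_output))
            if want_pdd:
                ratio = metrics.pdd_ratio_20_10(metrics.extract_pdd(sf.grid, f))
                add(scen.name, f, "pdd_ratio_20_10_deviation",
                    (ratio / nc_pdd - 1.0) * 100.0)
            for (axis, depth), base in nc_profiles.items():
                test = _profile_chain(sf.grid, axis, depth, f)
                for region in regions:
                    rep = metrics.deviation_max(test, base, region)
                    add(scen.name, f, "deviation_max",
                        max(rep.negative, rep.positive),
                        axis=axis, depth=depth, region=region)
                if depth == 10.0:
                    flat = metrics.flatness(test)
                    add(scen.name, f, "flatness", flat,
                        axis=axis, depth=depth, region=0.8)
                    add(scen.name, f, "flatness_deviation",
                        flat - nc_flatness[(axis, depth)],
                        axis=axis, depth=depth, region=0.8)
            if nc_rof is not None:
                r = absdose.rof(
                    out, metrics.beam_output(cache[(scen.name, 10.0, False)].grid),
                    f, factors,
                )
                add(scen.name, f, "rof_deviation", (r / nc_rof - 1.0) * 100.0)
            if include_wedge:
                zmax = params.z_max
                wf = absdose.wedge_factor(
                    metrics.beam_output(cache[(scen.name, f, True)].grid,
                                        depth=zmax),
                    metrics.beam_output(sf.grid, depth=zmax),
                )
                add(scen.name, f, "wf_deviation", (wf / nc_wf - 1.0) * 100.0)

    table = pd.DataFrame(rows)
    flags = apply_rules(table, rules)
    return SweepResult(metrics=table, flags=flags, seed=seed, params=params)


def apply_rules(table: pd.DataFrame, rules: DetectionRules) -> pd.DataFrame:
    """Evaluate the detection rules over a tidy metric table.

    Output rules compare ``|output_deviation|`` per scenario/field with the
    daily and weekly thresholds; the diagonal rule looks at 0.95-region
    diagonal deviations of large fields; the action level looks at every
    profile deviation.  Raising any threshold can only remove flags.
    """
    out: list[dict] = []

    def fire(scenario, flag, threshold, value):
        out.append(dict(scenario=scenario, flag=flag,
                        threshold=threshold, value=value))

    dev = table[table.metric == "output_deviation"]
    for _, r in dev.iterrows():
        mag = abs(r.value)
        if mag > rules.weekly_output_pct:
            fire(r.scenario, "weekly_output", rules.weekly_output_pct, r.value)
        if mag > rules.daily_output_pct:
            fire(r.scenario, "daily_output", rules.daily_output_pct, r.value)

    prof = table[table.metric == "deviation_max"]
    diag = prof[
        (prof.axis == "diagonal")
        & (prof.region == 0.95)
        & (prof.field >= rules.diagonal_min_field)
    ]
    for _, r in diag.iterrows():
        if r.value > rules.diagonal_deviation_pct:
            fire(r.scenario, "diagonal_095", rules.diagonal_deviation_pct, r.value)
    for _, r in prof.iterrows():
        if r.value > rules.any_profile_pct:
            fire(r.scenario, "profile_action_level", rules.any_profile_pct,
                 r.value)
    flags = pd.DataFrame(out, columns=["scenario", "flag", "threshold", "value"])
    if len(flags):
        # one flag per (scenario, flag): keep the most extreme value
        flags = (
            flags.assign(_mag=flags.value.abs())
            .sort_values("_mag", ascending=False)
            .drop_duplicates(["scenario", "flag"])
            .drop(columns="_mag")
            .sort_values(["scenario", "flag"])
            .reset_index(drop=True)
        )
    return flags


def friedman_test(blocks: np.ndarray) -> tuple[float, float]:
    """Friedman rank test on a (blocks x treatments) matrix.

    Within-block ranks use mean ranks on ties; the statistic is
    ``12 / (n k (k+1)) * sum_j R_j^2 - 3 n (k+1)`` with rank sums ``R_j``,
    referred to a chi-square with ``k - 1`` degrees of freedom.
    """
    data = np.asarray(blocks, dtype=float)
    if data.ndim != 2:
        raise ValueError("blocks must be a 2-D (blocks x treatments) matrix")
    if np.any(np.isnan(data)):
        raise ValueError("missing cells are not allowed")
    n, k = data.shape
    if k < 2 or n < 2:
        raise ValueError("need at least 2 treatments and 2 blocks")
    ranks = np.apply_along_axis(rankdata, 1, data)
    rank_sums = ranks.sum(axis=0)
    stat = 12.0 / (n * k * (k + 1)) * np.sum(rank_sums**2) - 3.0 * n * (k + 1)
    stat = max(stat, 0.0)  # guard tiny negative round-off under heavy ties
    return float(stat), float(chi2.sf(stat, k - 1))


def report(
    sweep: SweepResult,
    outdir: str | Path,
    plots: bool = False,
) -> list[Path]:
    """Write the tidy metric CSV and flag summary (optionally plots).

    Reruns on identical input produce byte-identical CSVs.
    """
    if len(sweep.metrics) == 0:
        raise ValueError("empty sweep: nothing to report")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    metrics_path = outdir / "metrics.csv"
    sweep.metrics.to_csv(metrics_path, index=False, float_format="%.6g")
    written.append(metrics_path)
    flags_path = outdir / "flags.csv"
    sweep.flags.to_csv(flags_path, index=False, float_format="%.6g")
    written.append(flags_path)
    if plots:
        written.extend(_plots(sweep, outdir))
    return written


def _plots(sweep: SweepResult, outdir: Path) -> list[Path]:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    written = []
    table = sweep.metrics
    out = table[table.metric == "output_deviation"]
    if len(out):
        fig, ax = plt.subplots(figsize=(7, 4))
        for f, sub in out.groupby("field"):
            ax.plot(sub.scenario, sub.value, "o-", label=f"{f:g} cm")
        ax.set_ylabel("output deviation (%)")
        ax.axhline(0, color="k", lw=0.5)
        ax.legend()
        fig.autofmt_xdate(rotation=45)
        p = outdir / "output_deviation.png"
        fig.savefig(p, dpi=120, bbox_inches="tight")
        plt.close(fig)
        written.append(p)
    dev = table[table.metric == "deviation_max"]
    if len(dev):
        fig, ax = plt.subplots(figsize=(7, 4))
        groups = [g.value.values for _, g in dev.groupby("scenario", sort=False)]
        ax.boxplot(groups, tick_labels=list(dev.scenario.unique()))
        ax.set_ylabel("maximum profile deviation (%)")
        fig.autofmt_xdate(rotation=45)
        p = outdir / "deviation_boxplot.png"
        fig.savefig(p, dpi=120, bbox_inches="tight")
        plt.close(fig)
        written.append(p)
    return written
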