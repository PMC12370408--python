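"""Sweep orchestration, detection rules and the Friedman test."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import friedmanchisquare

from targetqa.qa_pipeline import (
    DetectionRules,
    apply_rules,
    friedman_test,
    report,
    run_sweep,
)
from targetqa.scenarios import DegradationScenario, ScenarioLibrary


def nc_only():
    return ScenarioLibrary([DegradationScenario("NC", 0, 0)])


def small_sweep_kwargs():
    return dict(fields=(10.0,), dxy=1.0, dz=1.0, depth_extent=12.0,
                profile_depths=(10.0,), axes=("x", "diagonal"))


def test_nc_only_sweep_is_all_zero(params):
    result = run_sweep(nc_only(), params=params, seed=3, **small_sweep_kwargs())
    deviations = result.metrics[result.metrics.metric != "flatness"]
    assert np.allclose(deviations.value, 0.0)
    assert not result.any_fired
    assert set(result.metrics.scenario) == {"NC"}


def test_sweep_requires_nominal(params):
    lib = ScenarioLibrary([DegradationScenario("NC", 0, 0),
                           DegradationScenario("D0.6", 0.6, 1.0)])
    lib._by_name.pop("NC")  # force a library with no baseline
    lib._order = [s for s in lib._order if s.name != "NC"]
    with pytest.raises(ValueError, match="NC"):
        run_sweep(lib, params=params, **small_sweep_kwargs())


def test_sweep_deterministic_under_seed(params):
    lib = ScenarioLibrary([DegradationScenario("NC", 0, 0),
                           DegradationScenario("D0.7", 0.7, 1.0)])
    a = run_sweep(lib, params=params, seed=11, **small_sweep_kwargs())
    b = run_sweep(lib, params=params, seed=11, **small_sweep_kwargs())
    pd.testing.assert_frame_equal(a.metrics, b.metrics)
    pd.testing.assert_frame_equal(a.flags, b.flags)


def test_large_loss_scenario_raises_weekly_flag(params):
    lib = ScenarioLibrary([DegradationScenario("NC", 0, 0),
                           DegradationScenario("D0.7W2.0", 0.7, 2.0)])
    result = run_sweep(lib, params=params, seed=5, **small_sweep_kwargs())
    fired = set(result.flags.flag[result.flags.scenario == "D0.7W2.0"])
    assert "weekly_output" in fired  # anchor loss ~ -24%
    assert "daily_output" in fired
    assert "NC" not in set(result.flags.scenario)


def _random_table(rng):
    rows = []
    for scen, field in itertools.product(("A", "B", "C"), (10.0, 30.0)):
        rows.append(dict(scenario=scen, field=field, metric="output_deviation",
                         axis="", depth=np.nan, region=np.nan,
                         value=rng.normal(0, 6)))
        for axis, region in itertools.product(("x", "diagonal"), (0.8, 0.95)):
            rows.append(dict(scenario=scen, field=field, metric="deviation_max",
                             axis=axis, depth=10.0, region=region,
                             value=abs(rng.normal(0, 3))))
    return pd.DataFrame(rows)


@settings(derandomize=True, max_examples=40)
@given(
    seed=st.integers(0, 10_000),
    bump=st.tuples(*[st.floats(0.0, 5.0) for _ in range(4)]),
)
def test_raising_thresholds_never_adds_flags(seed, bump):
    table = _random_table(np.random.default_rng(seed))
    base = DetectionRules()
    raised = DetectionRules(
        daily_output_pct=base.daily_output_pct + bump[0],
        weekly_output_pct=base.weekly_output_pct + bump[1],
        diagonal_deviation_pct=base.diagonal_deviation_pct + bump[2],
        any_profile_pct=base.any_profile_pct + bump[3],
    )
    f_base = apply_rules(table, base)
    f_raised = apply_rules(table, raised)
    assert len(f_raised) <= len(f_base)
    keys = lambda f: set(zip(f.scenario, f.flag))
    assert keys(f_raised) <= keys(f_base)


# -- Friedman ---------------------------------------------------------------

def test_friedman_identical_treatments():
    stat, p = friedman_test(np.ones((6, 3)))
    assert stat == 0.0
    assert p == 1.0


@pytest.mark.parametrize("n", [4, 9, 15])
def test_friedman_two_treatments_perfect_ordering(n):
    """k = 2 with one treatment always larger: the statistic equals n."""
    rng = np.random.default_rng(n)
    base = rng.random(n)
    data = np.column_stack([base, base + 1.0])
    stat, p = friedman_test(data)
    assert stat == pytest.approx(float(n))


def test_friedman_matches_scipy_without_ties():
    rng = np.random.default_rng(8)
    data = rng.random((10, 4))
    stat, p = friedman_test(data)
    s_stat, s_p = friedmanchisquare(*data.T)
    assert stat == pytest.approx(s_stat, rel=1e-12)
    assert p == pytest.approx(s_p, rel=1e-9)


def test_friedman_permutation_oracle():
    """Asymptotic p within 0.05 of the exact within-block permutation p."""
    data = np.array([[1.0, 2.0, 3.5],
                     [2.2, 1.1, 2.9],
                     [0.5, 0.7, 1.9],
                     [1.4, 1.0, 2.6]])
    stat, p = friedman_test(data)
    perms = list(itertools.permutations(range(3)))
    count = total = 0
    for combo in itertools.product(perms, repeat=4):
        permuted = np.vstack([data[i, list(c)] for i, c in enumerate(combo)])
        s, _ = friedman_test(permuted)
        count += s >= stat - 1e-12
        total += 1
    p_exact = count / total
    assert abs(p - p_exact) <= 0.05


def test_friedman_input_guards():
    with pytest.raises(ValueError, match="missing"):
        friedman_test(np.array([[1.0, np.nan], [2.0, 3.0]]))
    with pytest.raises(ValueError, match="at least 2"):
        friedman_test(np.ones((5, 1)))
    with pytest.raises(ValueError, match="at least 2"):
        friedman_test(np.ones((1, 3)))


# -- reporting --------------------------------------------------------------

def test_report_written_and_reproducible(tmp_path, params):
    result = run_sweep(nc_only(), params=params, seed=1, **small_sweep_kwargs())
    d1, d2 = tmp_path / "a", tmp_path / "b"
    files = report(result, d1)
    assert all(p.exists() for p in files)
    report(result, d2)
    assert (d1 / "metrics.csv").read_bytes() == (d2 / "metrics.csv").read_bytes()
    table = pd.read_csv(d1 / "metrics.csv")
    assert set(table.scenario) == {"NC"}
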