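"""Monte Carlo sampler, RMSE objective, staging and recovery."""

import math

import numpy as np
import pandas as pd
import pytest

from prljag.errors import DataError, ValidationError
from prljag.fitting import (DEFAULT_VARIED, JAG1_TIMES_H, PSTAT3_TIMES_MIN,
                            DOSES_NG_ML, ObservationSet, PerturbationSpec,
                            model_grid_folds, rmse, run_stage,
                            sample_parameters, score_iteration,
                            two_stage_fit, default_stage_specs)


def _spec(anchor, c_max=0.3, n=10, seed=5):
    return PerturbationSpec(p_init=anchor, c_max=c_max, n_iterations=n,
                            seed=seed)


def test_sampler_zero_cmax_identity(anchor):
    out = sample_parameters(_spec(anchor, c_max=0.0), 3)
    assert out == anchor


def test_sampler_nonnegative_and_reproducible(anchor):
    spec = _spec(anchor, c_max=1.0, n=50)
    for it in (0, 7, 49):
        a = sample_parameters(spec, it)
        b = sample_parameters(spec, it)
        assert a == b
        assert all(v >= 0 for v in a.values())
    assert sample_parameters(spec, 0) != sample_parameters(spec, 1)


def test_sampler_distribution_matches_3sigma_construction():
    """Monte Carlo oracle for the ±C_max-at-3-sigma sampler: with
    C_max = 0.3 the draws of one parameter have mean ~P_init and ~99.7%
    of them fall within ±30% of P_init."""
    p0 = 2.5
    spec = PerturbationSpec(p_init={"k4": p0}, c_max=0.3,
                            n_iterations=100_000, seed=99,
                            varied_names=("k4",))
    draws = np.array([sample_parameters(spec, i)["k4"]
                      for i in range(100_000)])
    assert abs(draws.mean() - p0) / p0 < 0.01
    inside = np.mean(np.abs(draws - p0) <= 0.3 * p0)
    assert abs(inside - 0.997) < 0.003


def test_rmse_cases():
    assert rmse([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == 0.0
    assert rmse([2.0], [1.0]) == 1.0
    assert rmse([1.0, 2.0, 3.0], [1.0, 1.0, 1.0]) == \
        pytest.approx(math.sqrt(5 / 3))
    assert rmse([1.0, 5.0], [2.0, 3.0]) == rmse([2.0, 3.0], [1.0, 5.0])
    with pytest.raises(ValidationError):
        rmse([1.0], [1.0, 2.0])


def test_rmse_matches_brute_force_on_random_vectors():
    rng = np.random.default_rng(11)
    for _ in range(25):
        n = rng.integers(1, 40)
        a, b = rng.normal(size=n), rng.normal(size=n)
        brute = math.sqrt(sum((x - y) ** 2 for x, y in zip(a, b)) / n)
        assert rmse(a, b) == pytest.approx(brute, abs=1e-12)


def test_observation_grid_validation(phenom_obs):
    frame = phenom_obs.frame
    # dropping one cell must be rejected
    cut = frame[~((frame["readout"] == "JAG1")
                  & np.isclose(frame["dose_ng_ml"], 60.0)
                  & np.isclose(frame["time_h"], 24.0))]
    with pytest.raises(DataError, match="incomplete"):
        ObservationSet(cut)
    with pytest.raises(DataError, match="positive"):
        bad = frame.copy()
        bad.loc[bad.index[0], "fold_change"] = 0.0
        ObservationSet(bad)


def test_residual_counts_are_12_and_9(net, phenom_obs, anchor):
    """The pSTAT3 RMSE pools 4 timepoints x 3 doses and the JAG1 RMSE
    3 x 3, against replicate means."""
    assert len(PSTAT3_TIMES_MIN) * len(DOSES_NG_ML) == 12
    assert len(JAG1_TIMES_H) * len(DOSES_NG_ML) == 9
    ps, jg = model_grid_folds(anchor, net)
    assert len(ps) == 12 and len(jg) == 9


def test_score_self_consistency_zero_rmse(net, anchor, noiseless_model_obs):
    """Observations generated noiselessly from the same parameters score
    zero RMSE up to integrator tolerance."""
    res = score_iteration(anchor, net, noiseless_model_obs)
    assert res.rmse_pstat3 < 1e-6
    assert res.rmse_jag1 < 1e-6


def test_score_contains_integrator_failure(net, anchor, phenom_obs,
                                           monkeypatch):
    """A failing integration yields an infinite-distance result instead of
    aborting the run."""
    import prljag.fitting as fitting
    from prljag.errors import SimulationError

    def boom(*args, **kwargs):
        raise SimulationError("forced failure", params=None)

    monkeypatch.setattr(fitting, "simulate", boom)
    res = score_iteration(anchor, net, phenom_obs)
    assert math.isinf(res.distance)
    spec = PerturbationSpec(p_init=anchor, c_max=0.0, n_iterations=1,
                            seed=0)
    ranked = run_stage(spec, net, phenom_obs)
    assert len(ranked) == 2  # anchor + one draw, both contained
    assert all(math.isinf(r.distance) for r in ranked)


def test_degenerate_stage_equals_direct_score(net, anchor, phenom_obs):
    spec = PerturbationSpec(p_init=anchor, c_max=0.0, n_iterations=1,
                            seed=123)
    ranked = run_stage(spec, net, phenom_obs)
    direct = score_iteration(anchor, net, phenom_obs)
    # C_max = 0: the single draw and the anchor are both P_init
    for r in ranked:
        assert r.rmse_pstat3 == pytest.approx(direct.rmse_pstat3)
        assert r.rmse_jag1 == pytest.approx(direct.rmse_jag1)


def test_stage_determinism_and_selection_optimality(net, anchor, phenom_obs):
    spec = PerturbationSpec(p_init=anchor, c_max=1.0, n_iterations=12,
                            seed=77)
    r1 = run_stage(spec, net, phenom_obs)
    r2 = run_stage(spec, net, phenom_obs)
    assert [(a.iteration, a.distance) for a in r1] == \
        [(a.iteration, a.distance) for a in r2]
    # exhaustive re-scan: the head of the ranked list is the minimizer
    best = min(r1, key=lambda r: (r.distance, r.iteration))
    assert r1[0].iteration == best.iteration
    assert all(r1[i].distance <= r1[i + 1].distance
               for i in range(len(r1) - 1))


def test_stage_resume_matches_fresh_run(net, anchor, phenom_obs):
    spec = PerturbationSpec(p_init=anchor, c_max=1.0, n_iterations=8,
                            seed=31)
    fresh = run_stage(spec, net, phenom_obs)
    partial = [r for r in fresh if r.iteration < 4]
    resumed = run_stage(spec, net, phenom_obs, resume_from=partial)
    assert [(a.iteration, a.distance) for a in fresh] == \
        [(a.iteration, a.distance) for a in resumed]


def test_default_budgets(anchor):
    s1, s2 = default_stage_specs(anchor, seed=0)
    assert (s1.n_iterations, s1.c_max) == (10_000, 1.0)
    assert (s2.n_iterations, s2.c_max) == (30_000, 0.3)
    s1s, s2s = default_stage_specs(anchor, seed=0, budget_scale=0.05)
    assert (s1s.n_iterations, s2s.n_iterations) == (500, 1500)


def test_stage2_samples_are_more_concentrated(anchor):
    """C_max = 0.3 draws have a smaller spread than C_max = 1.0 draws."""
    wide = PerturbationSpec(p_init=anchor, c_max=1.0, n_iterations=2000,
                            seed=5)
    narrow = PerturbationSpec(p_init=anchor, c_max=0.3, n_iterations=2000,
                              seed=5)
    for name in ("k4", "S3c", "deg_ratio"):
        w = np.std([sample_parameters(wide, i)[name] for i in range(2000)])
        n = np.std([sample_parameters(narrow, i)[name] for i in range(2000)])
        assert n < w


def test_two_stage_monotone_improvement(recovery_fit_noiseless):
    res = recovery_fit_noiseless
    assert res.winner.distance <= res.stage1_winner.distance


def test_noiseless_recovery_hits_near_zero_rmse(recovery_fit_noiseless):
    """Reduced-budget (500 + 1500) fit on noiseless self-generated
    observations attains an RMSE pair below 0.05."""
    res = recovery_fit_noiseless
    assert res.winner.rmse_pstat3 < 0.05
    assert res.winner.rmse_jag1 < 0.05


def test_noisy_recovery_trajectories_close_to_truth(
        net, anchor, recovery_fit_noisy):
    """With 5% multiplicative noise the winner's RMSE pair sits below
    twice the noise floor and its normalized readouts stay within 10% of
    the noiseless truth at every comparison cell."""
    res, obs = recovery_fit_noisy
    noise_floor = 0.05 * 2.2  # sd x typical fold magnitude, conservative
    assert res.winner.rmse_pstat3 < 2 * noise_floor
    assert res.winner.rmse_jag1 < 2 * noise_floor
    truth_ps, truth_jg = model_grid_folds(anchor, net)
    win_ps, win_jg = model_grid_folds(dict(res.winner.values), net)
    for cell, v in truth_ps.items():
        assert abs(win_ps[cell] - v) / v < 0.10
    for cell, v in truth_jg.items():
        assert abs(win_jg[cell] - v) / v < 0.10


def test_two_stage_audit_and_percent_change(recovery_fit_noiseless, anchor):
    res = recovery_fit_noiseless
    audit = res.audit_frame
    assert set(audit["stage"]) == {"stage1", "stage2"}
    assert {"iteration", "rmse_pstat3", "rmse_jag1", "distance"} <= \
        set(audit.columns)
    assert len(audit) == (500 + 1) + (1500 + 1)
    pct = res.percent_change(anchor)
    assert set(pct.columns) == {"name", "initial", "fitted",
                                "percent_change"}
    assert len(pct) == len(anchor)
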