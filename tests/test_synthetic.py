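"""Synthetic cohort generator: template, determinism, trial models."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from gearmorph.scoring import score_trials_table
from gearmorph.synthetic import (
    SynthParams,
    body_depth,
    make_template,
    simulate_cohort,
    simulate_trap_trials,
    simulate_trawl_trials,
    template_sliders,
    write_cohort,
)
from gearmorph.tps_io import read_covariates, read_sliders, read_tps


def test_template_counts_default():
    t = make_template()
    roles = np.asarray(t.landmark_roles)
    assert t.k == 91
    assert (roles == "fixed").sum() == 19
    assert (roles == "semi").sum() == 72
    counts = pd.Series(list(t.curve_memberships.values())).value_counts()
    assert sorted(counts.to_dict().items()) == [
        ("a", 8), ("b", 15), ("c", 10), ("d", 14), ("e", 17), ("f", 8)
    ]


def test_template_minimal_curves_and_geometry():
    t = make_template(curve_counts=(1,) * 6)
    assert t.k == 25
    pts = t.configurations[0].points
    d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
    np.fill_diagonal(d, np.inf)
    assert d.min() > 0  # no coincident points
    from gearmorph.procrustes import centroid_size

    assert centroid_size(pts) > 0


def test_template_sliders_reference_semis_only():
    t = make_template()
    s = template_sliders(t)
    roles = np.asarray(t.landmark_roles)
    assert s.m == 72
    assert all(roles[i - 1] == "semi" for i in s.rows[:, 1])
    s.validate_against(t)


def test_cohort_deterministic_under_seed():
    p = SynthParams(seed=77, n_fish=15)
    c1, c2 = simulate_cohort(p), simulate_cohort(p)
    np.testing.assert_array_equal(c1.landmarks.coords(), c2.landmarks.coords())
    pd.testing.assert_frame_equal(c1.covariates.frame, c2.covariates.frame)
    t1, t2 = simulate_trawl_trials(c1), simulate_trawl_trials(c2)
    pd.testing.assert_frame_equal(t1, t2)
    c3 = simulate_cohort(SynthParams(seed=78, n_fish=15))
    assert not np.array_equal(c1.landmarks.coords(), c3.landmarks.coords())


def test_zero_noise_zero_effects_reproduce_template():
    p = SynthParams(
        seed=1,
        n_fish=5,
        landmark_noise_sd=0.0,
        vulnerability_effect_magnitude=0.0,
        sex_effect_magnitude=0.0,
        allometry_slope=0.0,
        sd_log_length=0.0,
        mass_noise_sd=0.0,
    )
    c = simulate_cohort(p)
    coords = c.landmarks.coords()
    for i in range(1, 5):
        np.testing.assert_allclose(coords[i], coords[0], atol=1e-12)


def test_mass_length_power_law():
    p = SynthParams(seed=5, n_fish=400, mass_noise_sd=0.0)
    c = simulate_cohort(p)
    df = c.covariates.frame
    slope = np.polyfit(np.log(df.standard_length), np.log(df.mass), 1)[0]
    assert slope == pytest.approx(p.mass_length_exponent, abs=1e-8)


def test_trawl_trials_vocabulary_and_times():
    c = simulate_cohort(SynthParams(seed=9, n_fish=50))
    trials = simulate_trawl_trials(c)
    assert len(trials) == 150
    assert set(trials.outcome) <= {"E_B", "E_F", "C_N", "C_C"}
    cc = trials[trials.outcome == "C_C"]
    assert cc.capture_time_s.between(0, 600).all()
    assert trials[trials.outcome != "C_C"].capture_time_s.isna().all()


def test_trawl_null_coupling_uncorrelated():
    """With zero depth coupling and zero outcome slope the trawl score is
    independent of the latent trait (|r| small at n=200)."""
    p = SynthParams(
        seed=10, n_fish=200, depth_vulnerability_coupling=0.0, trawl_outcome_slope=0.0
    )
    c = simulate_cohort(p)
    trials = simulate_trawl_trials(c)
    scores = {i.fish_id: i.score for i in score_trials_table(trials)}
    latent = [c.ground_truth["latent_vulnerability"][f] for f in scores]
    r = np.corrcoef(latent, list(scores.values()))[0, 1]
    assert abs(r) <= 0.15


def test_trawl_extreme_slope_saturates():
    """A huge outcome slope drives every top-decile latent fish to C_N or
    C_C in all three trials."""
    p = SynthParams(seed=11, n_fish=100, trawl_outcome_slope=50.0)
    c = simulate_cohort(p)
    trials = simulate_trawl_trials(c)
    latent = pd.Series(c.ground_truth["latent_vulnerability"])
    top = set(latent[latent >= latent.quantile(0.9)].index)
    severe = trials.outcome.isin(["C_N", "C_C"])
    assert severe[trials.fish_id.isin(top)].all()


@pytest.mark.parametrize("p_all,expected", [(50.0, 6.0), (-50.0, 0.0)])
def test_trap_probability_extremes(p_all, expected):
    """Intercept at +-50 logits forces capture probability to ~1 or ~0."""
    p = SynthParams(seed=12, n_fish=20, gear="trap", trap_intercept=p_all, trap_slope=0.0)
    c = simulate_cohort(p)
    trials = simulate_trap_trials(c)
    scores = [i.score for i in score_trials_table(trials)]
    assert all(s == expected for s in scores)


def test_trap_moderate_slope_rank_correlates():
    p = SynthParams(seed=13, n_fish=200, gear="trap")
    c = simulate_cohort(p)
    trials = simulate_trap_trials(c)
    scores = {i.fish_id: i.score for i in score_trials_table(trials)}
    latent = [c.ground_truth["latent_vulnerability"][f] for f in scores]
    rho = stats.spearmanr(latent, list(scores.values())).statistic
    assert rho > 0.3


def test_depth_vector_contracts_body_depth():
    """Positive shallowness makes generated bodies shallower."""
    deep = simulate_cohort(
        SynthParams(seed=14, n_fish=60, vulnerability_effect_magnitude=4.0,
                    landmark_noise_sd=0.0)
    )
    shal = pd.Series(deep.ground_truth["shallowness"])
    depths = {
        cfg.specimen_id: body_depth(cfg.points / cfg.points.std())
        for cfg in deep.landmarks.configurations
    }
    r = np.corrcoef(shal[list(depths)], list(depths.values()))[0, 1]
    assert r < -0.5


def test_write_cohort_roundtrips(tmp_path):
    c = simulate_cohort(SynthParams(seed=15, n_fish=8))
    trials = simulate_trawl_trials(c)
    paths = write_cohort(c, tmp_path, trials=trials)
    back = read_tps(paths["tps"])
    assert back.ids == c.landmarks.ids
    np.testing.assert_allclose(back.coords(), c.landmarks.coords(), atol=1e-5)
    assert read_sliders(paths["sliders"]).m == 72
    assert len(read_covariates(paths["covariates"])) == 8
    assert paths["ground_truth"].exists() and paths["trials"].exists()


def test_params_validation():
    with pytest.raises(ValueError, match="coupling"):
        SynthParams(seed=1, depth_vulnerability_coupling=1.5)
    with pytest.raises(ValueError, match=">= 0"):
        SynthParams(seed=1, landmark_noise_sd=-0.1)
    with pytest.raises(ValueError, match="gear"):
        SynthParams(seed=1, gear="net")
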