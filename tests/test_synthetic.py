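"""Generator correctness: beat model, rhythm rules, survival and phenotype
parameter recovery, cohort assembly, determinism."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from ecgpheno.synthetic import (BeatParams, CohortConfig, InvalidParameterError,
                                SubjectSpec, simulate_beat, simulate_cohort,
                                simulate_ecg, simulate_feature_clusters,
                                simulate_phenotypes, simulate_survival,
                                BinaryEffect, ContinuousEffect,
                                terminal_window_mask)


# ---------------------------------------------------------------------------
# beat model
# ---------------------------------------------------------------------------

def test_zero_amplitudes_give_zero_waveform():
    p = BeatParams.default()
    p.amplitudes = {w: 0.0 for w in p.amplitudes}
    assert np.all(simulate_beat(p, 400.0) == 0.0)


def test_beat_generator_is_homogeneous():
    p1 = BeatParams.default()
    p1.notch_mv = 0.2
    p2 = p1.copy()
    p2.amplitudes = {w: 2 * a for w, a in p1.amplitudes.items()}
    p2.notch_mv = 2 * p1.notch_mv
    np.testing.assert_allclose(simulate_beat(p2, 400.0),
                               2 * simulate_beat(p1, 400.0), atol=1e-12)


def test_r_peak_equals_lead_scaling_entry():
    # Gaussian peak evaluated analytically: with only the R wave present and
    # its center on the sample grid, the per-lead maximum is exactly
    # 1.0 * lead_scale.
    p = BeatParams.default()
    p.amplitudes = {"P": 0.0, "Q": 0.0, "R": 1.0, "S": 0.0, "T": 0.0}
    w = simulate_beat(p, 400.0)
    peaks = np.where(p.lead_scale >= 0, w.max(axis=1), w.min(axis=1))
    np.testing.assert_allclose(peaks, p.lead_scale, atol=1e-12)


@pytest.mark.parametrize("mutate", [
    lambda p: p.widths_ms.update(R=-1.0),
    lambda p: setattr(p, "pr_ms", 0.0),
    lambda p: setattr(p, "t_flatten", 1.5),
    lambda p: setattr(p, "lead_scale", np.ones(5)),
])
def test_invalid_beat_params_rejected(mutate):
    p = BeatParams.default()
    mutate(p)
    with pytest.raises(InvalidParameterError):
        BeatParams(**{f.name: getattr(p, f.name)
                      for f in dataclasses.fields(p)})


def test_nonpositive_fs_rejected():
    with pytest.raises(InvalidParameterError):
        simulate_beat(BeatParams.default(), 0.0)


# ---------------------------------------------------------------------------
# whole records
# ---------------------------------------------------------------------------

def test_sinus_tachy_record_is_fast_and_labelled():
    rec, lab = simulate_ecg(SubjectSpec(rhythm="sinus_tachy"),
                            rng=np.random.default_rng(0))
    rr = np.diff(rec.fiducials)
    assert 60.0 / rr.mean() > 100.0
    assert lab.sinus_tachy == 1 and lab.sinus_brady == 0


def test_afib_record_has_dispersed_rr_and_no_p_wave():
    rec, lab = simulate_ecg(SubjectSpec(rhythm="afib"),
                            rng=np.random.default_rng(1))
    rr = np.diff(rec.fiducials)
    assert rr.std() / rr.mean() >= 0.15
    assert lab.afib == 1
    # the P-wave region (just before each R) is empty for AF: compare its
    # energy against a sinus record on noise/drift-free signals
    rec, _ = simulate_ecg(SubjectSpec(rhythm="afib"),
                          rng=np.random.default_rng(1),
                          noise_sd=0.0, drift_amplitude=0.0)
    rec_s, _ = simulate_ecg(SubjectSpec(rhythm="sinus"),
                            rng=np.random.default_rng(1),
                            noise_sd=0.0, drift_amplitude=0.0)

    def p_energy(r):
        # beats preceded by a long RR, so the window holds no prior-beat T
        fs, vals = r.fs, []
        for prev, tb in zip(r.fiducials, r.fiducials[1:]):
            if tb - prev < 0.75:
                continue
            i0, i1 = int((tb - 0.21) * fs), int((tb - 0.15) * fs)
            if i0 >= 0 and i1 < r.signal.shape[1]:
                vals.append(float((r.signal[1, i0:i1] ** 2).mean()))
        return np.mean(vals)

    assert p_energy(rec) < 0.5 * p_energy(rec_s)


def test_identical_seed_gives_bit_identical_records():
    spec = SubjectSpec(rhythm="sinus", group="B")
    r1, _ = simulate_ecg(spec, rng=np.random.default_rng(42))
    r2, _ = simulate_ecg(spec, rng=np.random.default_rng(42))
    assert np.array_equal(r1.signal, r2.signal)


def test_labels_rederivable_from_signal_measurables():
    """Every generated flag follows from rate / RR variability / PR / QRS
    thresholds applied to the record's measurable properties."""
    rng = np.random.default_rng(7)
    for rhythm in ("sinus", "sinus_brady", "sinus_tachy", "afib"):
        for avb in (False, True):
            for bbb in ("none", "rbbb"):
                spec = SubjectSpec(rhythm=rhythm, first_degree_avb=avb,
                                   bundle_branch_block=bbb)
                rec, lab = simulate_ecg(spec, rng=rng)
                rr = np.diff(rec.fiducials)
                rate = 60.0 / rr.mean()
                cv = rr.std() / rr.mean()
                assert lab.afib == int(cv >= 0.15)
                assert lab.sinus_tachy == int(rate > 100 and cv < 0.15)
                assert lab.sinus_brady == int(rate < 50 and cv < 0.15)
                assert lab.first_degree_avb == int(rec.meta["pr_ms"] > 200)
                assert (lab.rbbb or lab.lbbb) == int(rec.meta["qrs_ms"] > 120)


def test_unknown_rhythm_rejected():
    with pytest.raises(InvalidParameterError):
        SubjectSpec(rhythm="ventricular")


# ---------------------------------------------------------------------------
# survival generator
# ---------------------------------------------------------------------------

def test_equal_multipliers_give_equal_event_rates():
    rng = np.random.default_rng(0)
    groups = np.repeat(["A", "B"], 2500)
    df = simulate_survival(groups, 0.05, {"A": 1.0, "B": 1.0}, 5.0, rng)
    ra = df.loc[np.asarray(groups) == "A", "event"].mean()
    rb = df.loc[np.asarray(groups) == "B", "event"].mean()
    se = np.sqrt(2 * ra * (1 - ra) / 2500)
    assert abs(ra - rb) < 3 * max(se, 1e-3)


def test_tiny_censor_time_censors_everyone():
    df = simulate_survival(["A"] * 50, 0.02, censor_time=1e-9,
                           rng=np.random.default_rng(0))
    assert (df["event"] == 0).all()


def test_event_fraction_matches_exponential_cdf():
    # hazard 0.02 * 2.57 = 0.0514/yr, censored at 5 yr:
    # P(event) = 1 - exp(-0.257)
    rng = np.random.default_rng(3)
    df = simulate_survival(["B"] * 10000, 0.02, {"A": 1.0, "B": 2.57},
                           5.0, rng)
    expected = 1.0 - np.exp(-0.0514 * 5)
    se = np.sqrt(expected * (1 - expected) / 10000)
    assert abs(df["event"].mean() - expected) < 3 * se


def test_survival_input_validation():
    rng = np.random.default_rng(0)
    with pytest.raises(InvalidParameterError):
        simulate_survival(["A"], 0.0, rng=rng)
    with pytest.raises(InvalidParameterError):
        simulate_survival(["A", "B"], 0.02, {"A": 1.0, "B": -2.0}, 5.0, rng)
    with pytest.raises(InvalidParameterError):
        simulate_survival(["A", "B"], 0.02, {"A": 2.0, "B": 1.0}, 5.0, rng)


# ---------------------------------------------------------------------------
# phenotype generator
# ---------------------------------------------------------------------------

def test_null_phenotype_effects_show_no_group_difference():
    rng = np.random.default_rng(5)
    groups = np.array(["A", "B"])[rng.integers(0, 2, 5000)]
    table = {"null_bin": BinaryEffect(0.2, 1.0),
             "null_cont": ContinuousEffect(10.0, 2.0, 0.0)}
    df = simulate_phenotypes(groups, table, rng)
    b = groups == "B"
    a, c = df.loc[~b, "null_bin"], df.loc[b, "null_bin"]
    lo = np.log((c.mean() / (1 - c.mean())) / (a.mean() / (1 - a.mean())))
    se = np.sqrt(sum(1.0 / x for x in
                     [c.sum(), (1 - c).sum(), a.sum(), (1 - a).sum()]))
    assert abs(lo) < 3 * se
    diff = df.loc[b, "null_cont"].mean() - df.loc[~b, "null_cont"].mean()
    assert abs(diff) < 3 * 2.0 * np.sqrt(1 / b.sum() + 1 / (~b).sum())


def test_generating_odds_ratio_recovered_from_contingency_table():
    # brute-force 2x2 odds ratio from simulated counts at n=20000
    rng = np.random.default_rng(8)
    groups = np.array(["A", "B"])[rng.integers(0, 2, 20000)]
    df = simulate_phenotypes(groups, {"d": BinaryEffect(0.05, 2.89)}, rng)
    b = groups == "B"
    n11 = df.loc[b, "d"].sum()
    n10 = (~df.loc[b, "d"].astype(bool)).sum()
    n01 = df.loc[~b, "d"].sum()
    n00 = (~df.loc[~b, "d"].astype(bool)).sum()
    log_or = np.log(n11 * n00 / (n10 * n01))
    se = np.sqrt(1 / n11 + 1 / n10 + 1 / n01 + 1 / n00)
    assert abs(log_or - np.log(2.89)) < 3 * se


def test_invalid_odds_ratio_rejected():
    with pytest.raises(InvalidParameterError):
        BinaryEffect(0.05, -1.0)


# ---------------------------------------------------------------------------
# cohort assembly
# ---------------------------------------------------------------------------

def test_degenerate_group_proportions():
    cohort = simulate_cohort(CohortConfig(n=10, group_proportions=(1, 0, 0),
                                          seed=0))
    assert (cohort.groups["group"] == "A").all()


def test_group_counts_match_multinomial_expectation():
    cfg = CohortConfig(n=3000, group_proportions=(0.5, 0.35, 0.15), seed=7,
                       noise_sd=0.0, drift_amplitude=0.0)
    cohort = simulate_cohort(cfg)
    counts = cohort.groups["group"].value_counts()
    for g, p in zip("ABC", cfg.group_proportions):
        se = np.sqrt(3000 * p * (1 - p))
        assert abs(counts.get(g, 0) - 3000 * p) < 3 * se


def test_zero_prevalence_means_all_labels_zero():
    cfg = CohortConfig(n=25, seed=1, p_sinus_brady=0, p_sinus_tachy=0,
                       p_afib=0, p_first_degree_avb=0, p_rbbb=0, p_lbbb=0)
    cohort = simulate_cohort(cfg)
    assert cohort.labels.drop(columns="subject_id").to_numpy().sum() == 0


def test_bad_proportions_rejected():
    with pytest.raises(InvalidParameterError):
        simulate_cohort(CohortConfig(n=5, group_proportions=(0.5, 0.3, 0.3)))


def test_cohort_determinism_and_alignment():
    cfg = CohortConfig(n=12, seed=99)
    c1, c2 = simulate_cohort(cfg), simulate_cohort(cfg)
    assert np.array_equal(c1.signals_array(), c2.signals_array())
    pd.testing.assert_frame_equal(c1.survival, c2.survival)
    pd.testing.assert_frame_equal(c1.phenotypes, c2.phenotypes)
    assert c1.subject_ids == list(c1.labels["subject_id"])


def test_feature_cluster_generator_geometry():
    X, labels = simulate_feature_clusters(600, rng=np.random.default_rng(0))
    centers = np.stack([X[labels == g].mean(0) for g in range(3)])
    for i in range(3):
        for j in range(i + 1, 3):
            assert abs(np.linalg.norm(centers[i] - centers[j]) - 10.0) < 0.5


def test_terminal_window_mask_covers_post_r_regions():
    rec, _ = simulate_ecg(SubjectSpec(), rng=np.random.default_rng(2))
    mask = terminal_window_mask(rec)
    assert mask.dtype == bool and mask.shape == (4096,)
    frac = mask.mean()
    assert 0.05 < frac < 0.40  # per-beat windows, not the whole record
    # no mass before the first beat
    first = int(rec.fiducials[0] * 400) + 48
    assert not mask[:first].any()
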