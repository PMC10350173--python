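"""Photometry preprocessing identities, bout taxonomy, peri-event logic."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import _oracles
from cofosnet.photometry import (
    PhotometrySession,
    classify_bouts,
    peri_event,
    pre_post_stats,
    preprocess,
)
from cofosnet.simulate import PhotomSimConfig, simulate_photometry


def _session(signal, control, rate=10.0, baseline=(0.0, 70.0), events=None):
    n = len(signal)
    ev = events if events is not None else pd.DataFrame(
        {"label": ["investigation"], "start_s": [80.0], "stop_s": [81.0]}
    )
    return PhotometrySession(
        time_s=np.arange(n) / rate,
        signal=np.asarray(signal, float),
        control=np.asarray(control, float),
        rate_hz=rate,
        baseline_window_s=baseline,
        events=ev,
    )


def test_constant_trace_rejected_for_zero_variance():
    n = 1000
    s = _session(np.full(n, 10.0), np.zeros(n))
    with pytest.raises(ValueError, match="z-score"):
        preprocess(s)


def test_step_change_gives_exact_dff():
    # corrected = F0*(1 + 0.1*step): dF/F steps from 0 to exactly 0.1
    rate, n = 10.0, 1200
    t = np.arange(n) / rate
    f0 = 50.0
    corrected = f0 * (1 + 0.1 * (t > 90))
    s = _session(corrected, np.zeros(n))
    z = preprocess(s)
    # invert the z-score to recover dF/F
    dff = (corrected - f0) / f0
    expected = (dff - dff.mean()) / dff.std()
    assert z == pytest.approx(expected, abs=1e-10)
    assert len(np.unique(np.round(dff, 12))) == 2


def test_zscore_normalisation_identity():
    cfg = PhotomSimConfig(duration_s=200, event_times_s=(150.0,), seed=3)
    s = simulate_photometry(cfg)
    z = preprocess(s)
    assert z.mean() == pytest.approx(0.0, abs=1e-10)
    assert z.std() == pytest.approx(1.0, abs=1e-10)


def test_affine_rescaling_invariance():
    cfg = PhotomSimConfig(duration_s=200, event_times_s=(150.0,), seed=4)
    s = simulate_photometry(cfg)
    z1 = preprocess(s)
    s2 = _session(3.7 * s.signal, 3.7 * s.control, rate=s.rate_hz,
                  baseline=s.baseline_window_s, events=s.events)
    z2 = preprocess(s2)
    assert z2 == pytest.approx(z1, abs=1e-10)


def test_negative_baseline_rejected():
    n = 1000
    rng = np.random.default_rng(0)
    s = _session(rng.standard_normal(n) - 5.0, np.zeros(n))
    with pytest.raises(ValueError, match="F0"):
        preprocess(s)


def test_bout_classification_rules():
    ev = pd.DataFrame(
        {
            "label": ["investigation", "attack", "investigation", "investigation"],
            "start_s": [130.0, 134.0, 150.0, 200.0],
            "stop_s": [133.0, 138.0, 155.0, 202.0],
        }
    )
    out, day = classify_bouts(ev, gap_s=2.0)
    by_start = out.set_index("start_s")["bout_class"]
    assert by_start[130.0] == "investigation_preceding_attack"  # ends 1 s before
    assert by_start[150.0] == "investigation_isolated"  # 10+ s from any attack
    assert by_start[200.0] == "investigation_isolated"
    assert by_start[134.0] == "attack_with_prior_investigation"
    assert day == "attack_day"

    no_attack = ev[ev["label"] != "attack"]
    out2, day2 = classify_bouts(no_attack, gap_s=2.0)
    assert (out2["bout_class"] == "investigation_isolated").all()
    assert day2 == "no_attack_day"

    overlap = pd.DataFrame(
        {"label": ["attack", "attack"], "start_s": [130.0, 132.0], "stop_s": [135.0, 140.0]}
    )
    with pytest.raises(ValueError):
        classify_bouts(overlap)


@given(
    st.lists(
        st.tuples(
            st.sampled_from(["investigation", "attack", "odour"]),
            st.floats(min_value=120, max_value=500, allow_nan=False),
            st.floats(min_value=0.5, max_value=10, allow_nan=False),
        ),
        min_size=0,
        max_size=12,
    ),
    st.floats(min_value=0, max_value=5),
)
def test_classification_matches_interval_scan(raw, gap):
    # build non-overlapping bouts per label by stacking within each label
    per_label = {}
    rows = []
    for label, start, dur in raw:
        t0 = max(start, per_label.get(label, 0.0) + 0.01)
        rows.append((label, t0, t0 + dur))
        per_label[label] = t0 + dur
    ev = pd.DataFrame(rows, columns=["label", "start_s", "stop_s"])
    out, _ = classify_bouts(ev, gap_s=gap) if len(ev) else (ev.assign(bout_class=[]), "")
    expected = _oracles.classify_bouts_scan(rows, gap)
    got = list(zip(out.get("label", []), out.get("start_s", []),
                   out.get("stop_s", []), out.get("bout_class", [])))
    assert got == expected


def test_peri_event_alignment_and_exclusion():
    rate = 10.0
    n = 3000
    trace = np.zeros(n)
    trace[1500:1510] = 5.0  # transient at t=150 s
    events = pd.DataFrame(
        {
            "label": ["investigation"] * 3,
            "start_s": [150.0, 1.0, 150.0],
            "stop_s": [151.0, 2.0, 151.0],
            "bout_class": ["investigation_isolated"] * 3,
        }
    )
    sets = peri_event(trace, rate, events, window_s=(4.0, 4.0))
    ps = sets["investigation_isolated"]
    assert ps.n_trials == 2  # event at t=1 s excluded: window leaves recording
    assert ps.n_excluded == 1
    assert np.array_equal(ps.matrix[0], ps.matrix[1])  # identical events, identical rows
    # peak strictly after the alignment index
    assert ps.matrix[0][: ps.alignment].max() == 0.0
    assert ps.matrix[0][ps.alignment :].max() == 5.0


def test_peri_event_zero_usable_trials_is_empty_not_error():
    events = pd.DataFrame(
        {"label": ["attack"], "start_s": [0.5], "stop_s": [1.0],
         "bout_class": ["attack_without_prior_investigation"]}
    )
    sets = peri_event(np.zeros(100), 10.0, events, window_s=(2.0, 2.0))
    ps = sets["attack_without_prior_investigation"]
    assert ps.n_trials == 0 and ps.n_excluded == 1


def test_pre_post_stats_flat_and_transient():
    flat = pd.DataFrame(
        {"label": ["investigation"] * 3, "start_s": [100.0, 120.0, 140.0],
         "stop_s": [101.0, 121.0, 141.0], "bout_class": ["investigation_isolated"] * 3}
    )
    sets = peri_event(np.zeros(2000), 10.0, flat, window_s=(2.0, 2.0))
    summ, _ = pre_post_stats(sets)
    s = summ["investigation_isolated"]
    assert s.pre_means == pytest.approx(np.zeros(3))
    assert s.post_means == pytest.approx(np.zeros(3))

    # transient after each event: post > pre for every trial
    cfg = PhotomSimConfig(
        duration_s=400, noise_sd=0.0,
        event_times_s=(150.0, 200.0, 250.0), transient_amplitude=1.0, seed=5,
    )
    sess = simulate_photometry(cfg)
    z = preprocess(sess)
    labelled, _ = classify_bouts(sess.events)
    sets = peri_event(z, sess.rate_hz, labelled, window_s=(4.0, 4.0))
    summ, _ = pre_post_stats(sets)
    (s,) = summ.values()
    assert (s.post_means > s.pre_means).all()


def test_between_class_difference_detected():
    # transients only on investigations that precede attacks
    events, transients = [], []
    t = 130.0
    for k in range(40):
        start, stop = t, t + 2.0
        events.append(("investigation", start, stop))
        if k % 2 == 0:
            events.append(("attack", stop + 1.0, stop + 4.0))
            transients.append(start)
            t += 20.0
        else:
            t += 12.0
    cfg = PhotomSimConfig(
        duration_s=t + 60,
        event_times_s=tuple(e[1] for e in events),
        event_labels=tuple(e[0] for e in events),
        event_durations_s=tuple(e[2] - e[1] for e in events),
        transient_times_s=tuple(transients),
        transient_amplitude=1.0, noise_sd=0.5, seed=6,
    )
    sess = simulate_photometry(cfg)
    z = preprocess(sess)
    labelled, day = classify_bouts(sess.events)
    assert day == "attack_day"
    sets = peri_event(z, sess.rate_hz, labelled, window_s=(4.0, 4.0))
    assert sets["investigation_preceding_attack"].n_trials == 20
    assert sets["investigation_isolated"].n_trials == 20
    summ, between = pre_post_stats(sets)
    row = between[
        (between["class_a"] == "investigation_isolated")
        & (between["class_b"] == "investigation_preceding_attack")
    ].iloc[0]
    assert row["p_between"] < 0.01
    assert summ["investigation_preceding_attack"].mean_difference > summ[
        "investigation_isolated"
    ].mean_difference
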