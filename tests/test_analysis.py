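"""Measurement layer: STI against closed-form oracles, filter specs,
similarity angle identities, latencies, spatial spread."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spindleloop import (
    AnalysisError,
    bandpass_check,
    compute_sti,
    make_fixture,
    similarity_angle,
    spatial_spread,
)
from spindleloop.analysis import heatmap, propagation_latencies


# -- spindle tendency index -------------------------------------------------


def bruteforce_sti(v, t, t_off, threshold_frac=0.01):
    """Independent STI oracle: plain sample-by-sample peak scan on the raw
    trace, no smoothing, no interpolation."""
    thr = threshold_frac * np.abs(v).max()
    post = np.nonzero(t >= t_off)[0]
    peaks = [
        i
        for i in post[1:-1]
        if v[i] >= thr and v[i] > v[i - 1] and v[i] >= v[i + 1]
    ]
    if not peaks:
        return 0.0
    below = [i for i in post if i < peaks[0] and v[i] < -thr]
    start = t[below[0]] if below else t_off
    after = [i for i in post if i > peaks[-1] and v[i] < thr]
    end = t[after[0]] if after else t[-1]
    return end - start


def test_sti_zero_trace():
    t = np.arange(4000) * 5e-4
    assert compute_sti(np.zeros_like(t), t, t_off=0.5) == 0.0


def test_sti_matches_damped_cosine_envelope():
    """For a 10 Hz damped cosine with tau = 0.15 s the rebound sequence ends
    at the last 0.1 s-spaced peak whose envelope still clears the 1%
    threshold, i.e. floor(tau*ln(100)*f)/f after shutdown."""
    t, v = make_fixture("damped_cosine", {"f": 10.0, "tau": 0.15, "t_off": 0.5, "T": 2.5})
    sti = compute_sti(v, t, t_off=0.5)
    oracle = bruteforce_sti(v, t, 0.5)
    assert sti == pytest.approx(oracle, abs=0.02)
    last_peak = np.floor(0.15 * np.log(100.0) * 10.0) / 10.0
    assert sti == pytest.approx(last_peak, abs=0.05)


@pytest.mark.parametrize("tau", [0.08, 0.25])
def test_sti_oracle_agreement_other_decays(tau):
    t, v = make_fixture("damped_cosine", {"f": 10.0, "tau": tau, "t_off": 0.5, "T": 3.0})
    assert compute_sti(v, t, 0.5) == pytest.approx(bruteforce_sti(v, t, 0.5), abs=0.02)


def test_sti_guards():
    t = np.arange(100) * 5e-4
    with pytest.raises(AnalysisError):
        compute_sti(np.zeros_like(t), t, t_off=1.0)  # trace ends before t_off
    with pytest.raises(AnalysisError):
        compute_sti(np.zeros_like(t), t, t_off=0.01, threshold_frac=0.0)


# -- band-pass check --------------------------------------------------------


def test_bandpass_center_gain_near_unity():
    t, v = make_fixture("pure_tone", {"f": 10.0, "T": 4.0})
    filtered, power = bandpass_check(v, fs=2000.0)
    mid = slice(2000, -2000)  # ignore edge transients
    gain = np.abs(filtered[mid]).max()
    assert gain == pytest.approx(1.0, abs=0.01)
    assert power > 0.3


def test_bandpass_stopband_attenuation():
    t, v = make_fixture("pure_tone", {"f": 1.0, "T": 4.0})
    filtered, _ = bandpass_check(v, fs=2000.0)
    mid = slice(2000, -2000)
    atten_db = 20 * np.log10(np.abs(filtered[mid]).max())
    assert atten_db <= -20.0


def test_bandpass_rejects_dc_and_nyquist():
    v = np.full(4000, 0.7)
    filtered, _ = bandpass_check(v, fs=2000.0)
    assert np.abs(filtered[1000:-1000].mean()) < 1e-6
    with pytest.raises(AnalysisError):
        bandpass_check(v, fs=25.0)


# -- similarity angle -------------------------------------------------------


def test_similarity_angle_examples():
    A = np.array([[1.0, 0.0], [0.0, 0.0]])
    B = np.array([[1.0, 1.0], [0.0, 0.0]])
    assert similarity_angle(A, A) == pytest.approx(0.0, abs=1e-9)
    assert similarity_angle(A, -A) == pytest.approx(180.0)
    assert similarity_angle(A, np.rot90(A)) == pytest.approx(90.0)
    assert similarity_angle(A, B) == pytest.approx(45.0)
    with pytest.raises(AnalysisError):
        similarity_angle(A, np.zeros((2, 2)))


@settings(max_examples=30, deadline=None)
@given(
    seed=st.integers(min_value=0, max_value=10_000),
    scale=st.floats(min_value=0.01, max_value=50.0),
)
def test_similarity_angle_invariances(seed, scale):
    rng = np.random.default_rng(seed)
    A = rng.normal(size=(6, 9))
    B = rng.normal(size=(6, 9))
    assert similarity_angle(A, B) == pytest.approx(similarity_angle(B, A))
    assert similarity_angle(A, scale * A) == pytest.approx(0.0, abs=1e-5)
    assert similarity_angle(scale * A, B) == pytest.approx(similarity_angle(A, B))


# -- spatial spread and latencies ------------------------------------------


def test_fwhm_single_neuron_is_one():
    hm = np.zeros((21, 4))
    hm[10, 2] = 0.8
    assert spatial_spread(hm, 2) == pytest.approx(1.0)


def test_fwhm_gaussian_closed_form():
    idx = np.arange(400)
    sigma = 12.0
    col = np.exp(-0.5 * ((idx - 200) / sigma) ** 2)
    hm = col[:, np.newaxis]
    assert spatial_spread(hm, 0) == pytest.approx(2.3548 * sigma, rel=0.01)


def test_fwhm_zero_column_is_nan():
    assert np.isnan(spatial_spread(np.zeros((10, 3)), 1))


def test_latency_translation_equivariance(preset_cache):
    """Moving the stimulated site translates the onset pattern."""
    import spindleloop as sl
    from spindleloop.stimuli import StimulusProtocol

    circuit = sl.build_circuit(sl.default_config(
        mixing_mode="thalamoreticular", mixing_efficacy=1.0,
        cortical_feedback_tc=True, l5_trn_fraction=0.05))
    res100 = sl.integrate(
        circuit, [StimulusProtocol(target="TRN_C", center_index=100),
                  StimulusProtocol(target="TRN_M", center_index=100)], T=1.2)
    res80 = sl.integrate(
        circuit, [StimulusProtocol(target="TRN_C", center_index=80),
                  StimulusProtocol(target="TRN_M", center_index=80)], T=1.2)
    lat100 = propagation_latencies(res100, "PV+", sites=(100, 113, 128))
    lat80 = propagation_latencies(res80, "PV+", sites=(80, 93, 108))
    for d in (0, 13, 28):
        assert lat80[80 + d] == pytest.approx(lat100[100 + d], abs=2e-3)


def test_heatmap_contract(anchor_runs):
    res = anchor_runs["fig6a"].result
    hm = heatmap(res, "PV+")
    assert hm.shape == (res.config.N, len(res.times))
    with pytest.raises(AnalysisError):
        heatmap(res, "L9")
    # locality: the stimulated row reaches threshold first
    lat = propagation_latencies(res, "PV+", sites=(100, 120, 140))
    assert lat[100] == min(lat.values())
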