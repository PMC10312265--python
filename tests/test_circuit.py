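"""Wiring audit: each population's afferents under every flag combination,
mixing rules, ratio constraints, and configuration validation."""

import itertools
import warnings

import numpy as np
import pytest

import spindleloop as sl
from spindleloop import ConfigurationError, ConfigurationWarning
from spindleloop.circuit import POPULATIONS


def expected_incoming(local, fb_tc, fb_trn, l5_trn, mode, efficacy):
    """Independent statement of the connectivity table: population ->
    set of (presynaptic population, sign)."""
    E, I = "excitatory", "inhibitory"
    table = {
        "CB+": {("TRN_M", I)},
        "PV+": {("TRN_C", I)},
        "CB-": set(),
        "PV-": set(),
        "TRN_M": {("CB+", E)},
        "TRN_C": {("PV+", E)},
        "L1-3a": {("CB+", E)},
        "L3b-4": {("PV+", E)},
        "L5": {("L1-3a", E)},
        "L6": {("L3b-4", E)},
    }
    if local:
        table["CB+"].add(("CB-", I))
        table["PV+"].add(("PV-", I))
        table["CB-"] |= {("CB+", E), ("TRN_M", I), ("L5", E)} if l5_trn > 0 else {
            ("CB+", E), ("TRN_M", I)}
        table["PV-"] |= {("PV+", E), ("TRN_C", I), ("L6", E)}
    if fb_trn:
        table["TRN_C"].add(("L6", E))
        if l5_trn > 0:
            table["TRN_M"].add(("L5", E))
    if fb_tc:
        table["PV+"].add(("L6", E))
        table["CB+"].add(("L5", E))
    table["TRN_M"].add(("TRN_M", I))
    table["TRN_C"].add(("TRN_C", I))
    if efficacy > 0:
        if mode == "thalamoreticular":
            table["TRN_M"].add(("PV+", E))
            table["TRN_C"].add(("CB+", E))
        elif mode == "corticoreticular":
            table["TRN_M"].add(("L6", E))
            table["TRN_C"].add(("L5", E))
        elif mode == "cortical":
            table["L5"].add(("L6", E))
            table["L6"].add(("L5", E))
    return table


@pytest.mark.parametrize("mode", ["none", "thalamoreticular", "corticoreticular", "cortical"])
def test_structural_audit(mode):
    """Incoming projections match the connectivity table for all 2^3 flag
    combinations x L5->TRN_M on/off under each mixing mode."""
    for local, fb_tc, fb_trn, l5_trn in itertools.product(
        [False, True], [False, True], [False, True], [0.0, 0.05]
    ):
        cfg = sl.default_config(
            N=20,
            local_inhibition=local,
            cortical_feedback_tc=fb_tc,
            cortical_feedback_trn=fb_trn,
            l5_trn_fraction=l5_trn,
            mixing_mode=mode,
            mixing_efficacy=0.5 if mode != "none" else 0.0,
        )
        circuit = sl.build_circuit(cfg)
        want = expected_incoming(local, fb_tc, fb_trn, l5_trn, mode, cfg.mixing_efficacy)
        for pop in POPULATIONS:
            assert circuit.incoming(pop) == want[pop], (
                f"{pop} under local={local} fb_tc={fb_tc} fb_trn={fb_trn} "
                f"l5_trn={l5_trn} mode={mode}"
            )


def test_inhibitory_populations_only_inhibit():
    cfg = sl.default_config(N=20, local_inhibition=True, cortical_feedback_tc=True)
    circuit = sl.build_circuit(cfg)
    for kernel in circuit.kernels:
        if kernel.pre in {"CB-", "PV-", "TRN_M", "TRN_C"}:
            assert kernel.sign == "inhibitory"
        else:
            assert kernel.sign == "excitatory"
        assert (kernel.gain >= 0) and (kernel.sigma > 0)


def test_ratio_constraints_resolved():
    cfg = sl.default_config()
    assert cfg.gain("L5->CB+") == pytest.approx(20.0 * cfg.gain("L6->PV+"))
    assert cfg.gain("L5->TRN_M") == pytest.approx(0.0)
    c2 = cfg.copy_with(l5_trn_fraction=0.05)
    assert c2.gain("L5->TRN_M") == pytest.approx(0.05 * c2.gain("L6->TRN_C"))
    assert c2.gain("L5->CB-") == pytest.approx(0.05 * c2.gain("L6->PV-"))


def test_l5_trn_zero_fraction_gives_zero_matrix():
    cfg = sl.default_config(
        N=20, l5_trn_fraction=0.0, cortical_feedback_trn=True
    )
    circuit = sl.build_circuit(cfg)
    for kernel, W in zip(circuit.kernels, circuit.weights):
        if kernel.pre == "L5" and kernel.post == "TRN_M":
            assert not W.any()


def test_matrix_kernels_broader_than_core():
    cfg = sl.default_config()
    assert cfg.sigma("CB+->L1-3a") == pytest.approx(4.0 * cfg.sigma("PV+->L3b-4"))
    assert cfg.sigma("L5->CB+") == pytest.approx(4.0 * cfg.sigma("L6->PV+"))


def test_cortical_mixing_gain_ratio():
    """Core fraction 0.8 yields a 4:1 core:matrix cross-coupling asymmetry."""
    cfg = sl.default_config(
        N=20, mixing_mode="cortical", mixing_ratio=0.8, mixing_efficacy=0.6
    )
    circuit = sl.build_circuit(cfg)
    gains = {(k.pre, k.post): k.gain for k in circuit.kernels}
    assert gains[("L6", "L5")] / gains[("L5", "L6")] == pytest.approx(4.0)
    assert gains[("L6", "L5")] == pytest.approx(0.6 * 0.8 * cfg.cortical_mix_gain)


def test_zero_efficacy_degenerates_to_unmixed():
    plain = sl.build_circuit(sl.default_config(N=20))
    mixed = sl.build_circuit(
        sl.default_config(N=20, mixing_mode="cortical", mixing_efficacy=0.0)
    )
    keys = lambda c: {(k.pre, k.post) for k in c.kernels}  # noqa: E731
    assert keys(plain) == keys(mixed)
    for kp, wp in zip(plain.kernels, plain.weights):
        wm = next(
            w for k, w in zip(mixed.kernels, mixed.weights)
            if (k.pre, k.post) == (kp.pre, kp.post)
        )
        np.testing.assert_allclose(wp, wm)


def test_apply_mixing_roundtrip():
    base = sl.build_circuit(sl.default_config(N=20))
    mixed = sl.apply_mixing(base, "thalamoreticular", ratio=0.5, efficacy=1.0)
    assert ("PV+", "TRN_M") in {(k.pre, k.post) for k in mixed.kernels}
    # ratio 1 degenerates to pure core drive: matrix loop drives zeroed
    pure_core = sl.apply_mixing(base, "thalamoreticular", ratio=1.0, efficacy=1.0)
    gains = {(k.pre, k.post): k.gain for k in pure_core.kernels}
    assert gains[("CB+", "TRN_M")] == 0.0


def test_validation_errors_and_warnings():
    with pytest.raises(ConfigurationError):
        sl.default_config(l5_cb_over_l6_pv=1500.0)  # matrix oscillation lost
    with pytest.raises(ConfigurationError):
        sl.default_config(l5_trn_fraction=-0.1)
    with pytest.raises(ConfigurationError):
        sl.default_config(mixing_mode="sideways")
    with pytest.raises(ConfigurationError):
        sl.default_config(decay_overrides={"XX": 10.0})
    with pytest.raises(ConfigurationError):
        sl.default_config(projections={"L5->CB+": {"gain": 3.0}})
    with pytest.warns(ConfigurationWarning):
        sl.default_config(mixing_mode="none", mixing_ratio=0.7)


def test_yaml_roundtrip(tmp_path):
    cfg = sl.default_config(l5_trn_fraction=0.05, local_inhibition=True)
    path = tmp_path / "circuit.yaml"
    cfg.to_yaml(path)
    back = sl.CircuitConfig.from_yaml(path)
    assert back.to_dict() == cfg.to_dict()
    with warnings.catch_warnings():
        warnings.simplefilter("error")
        sl.build_circuit(back)
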