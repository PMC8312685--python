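"""Flux conversion, integration, conservation, determinism and result I/O."""

import numpy as np
import pytest

import trisyn
import trisyn.kernel as K
from trisyn.simulator import SimulationError, current_to_flux, initial_state

VOL_A, VOL_S, AREA = 1.885e-17, 8.5883e-16, 1.4137e-13


def test_current_to_flux_values():
    assert current_to_flux(0.0, 1, AREA, VOL_A) == 0.0
    rate = current_to_flux(0.1081, 1, AREA, VOL_A, compartment="ast")
    assert abs(rate) == pytest.approx(8.403, abs=5e-3)  # mM/s
    assert rate < 0.0  # positive (efflux) current drains the astrocyte
    syn = current_to_flux(0.1081, 1, AREA, VOL_S, compartment="syn")
    assert syn / abs(rate) == pytest.approx(VOL_A / VOL_S, rel=1e-12)
    with pytest.raises(ValueError):
        current_to_flux(1.0, 0, AREA, VOL_A)


def test_zero_duration_returns_initial_state_only():
    cfg = trisyn.default_config(duration=0.0)
    proto = trisyn.Protocol(total_duration=0.0)
    res = trisyn.run(cfg, proto)
    assert res.time.shape == (1,)
    assert res.spikes_pre.size == 0
    assert np.array_equal(res.final_state, initial_state(cfg).to_vector())


def test_determinism_bit_identical(driven_run):
    cfg, proto, first = driven_run
    second = trisyn.run(cfg, proto)
    assert first.equals(second)


def test_python_reference_engine_matches_kernel():
    cfg = trisyn.default_config(duration=0.08)
    proto = trisyn.Protocol(window_start=0.01, window_duration=0.02,
                            pulse_width=0.02, total_duration=0.08)
    fast = trisyn.run(cfg, proto, engine="numba")
    slow = trisyn.run(cfg, proto, engine="python")
    assert np.array_equal(fast.final_state, slow.final_state)
    assert np.array_equal(fast.spikes_pre, slow.spikes_pre)
    for name in fast.traces:
        assert np.array_equal(fast.traces[name], slow.traces[name])


def test_mass_conservation_with_injection_ledger(driven_run):
    """Total moles per species across both compartments change only by the
    externally injected amounts (Glu and K+ at presynaptic spikes)."""
    cfg, proto, res = driven_run
    s0 = initial_state(cfg).to_vector()
    fs = res.final_state
    checks = {
        "na": (K.S_NA_SYN, K.S_NA_AST, None),
        "k": (K.S_K_SYN, K.S_K_AST, K.S_LED_K),
        "glu": (K.S_GLU_SYN, K.S_GLU_AST, K.S_LED_GLU),
        "ca": (K.S_CA_SYN, K.S_CA_AST, None),
        "gaba": (K.S_GABA_SYN, K.S_GABA_AST, None),
    }
    assert res.spikes_pre.size > 0  # the ledger is actually exercised
    for name, (i_syn, i_ast, i_led) in checks.items():
        m0 = (VOL_A * s0[i_ast] + VOL_S * s0[i_syn]) / 1e3
        m1 = (VOL_A * fs[i_ast] + VOL_S * fs[i_syn]) / 1e3
        injected = fs[i_led] if i_led is not None else 0.0
        assert m1 - m0 - injected == pytest.approx(0.0, abs=1e-9 * m0), name
    # the Glu ledger equals glu_scale x released fractions (> 0 here)
    assert fs[K.S_LED_GLU] > 0.0 and fs[K.S_LED_K] > 0.0


def test_resource_fractions_conserved_over_run(driven_run):
    _, _, res = driven_run
    total = res.traces["x"] + res.traces["y"] + res.traces["z"]
    assert np.abs(total - 1.0).max() < 1e-9


def test_concentrations_stay_positive_or_fail_loudly():
    """Sustained drive sends the printed model out of its physical domain;
    positivity is enforced by failure (with the species named), never by
    clamping."""
    cfg = trisyn.default_config(gat3_enabled=False, gabaa_placement="none",
                                duration=12.0)
    proto = trisyn.Protocol(window_start=1.0, window_duration=11.0,
                            total_duration=12.0)
    with pytest.raises(SimulationError, match="ca_ast"):
        trisyn.run(cfg, proto)
    partial = trisyn.run(cfg, proto, on_error="partial")
    assert partial.status == "nonpositive"
    assert partial.fail_time > 0.0
    assert "ca_ast" in partial.fail_detail
    conc = partial.to_dataframe()[["na_syn", "k_syn", "glu_syn", "ca_syn",
                                   "gaba_syn", "na_ast", "k_ast", "glu_ast",
                                   "ca_ast", "gaba_ast"]].to_numpy()
    assert (conc > 0).all()  # recorded trajectory never contains bad values


def test_result_round_trip(tmp_path, driven_run):
    _, _, res = driven_run
    path = tmp_path / "run.h5"
    res.save(path)
    back = trisyn.SimResult.load(path)
    assert back.equals(res)


def test_csv_export_schema(tmp_path, driven_run):
    import pandas as pd

    _, _, res = driven_run
    path = tmp_path / "run.csv"
    res.export_csv(path)
    df = pd.read_csv(path)
    assert list(df.columns) == ["t"] + list(res.traces.keys())
    assert len(df) == res.time.size


def test_config_hash_embedded(driven_run):
    cfg, _, res = driven_run
    from trisyn.params import config_hash, normalize_units
    assert res.config_hash == config_hash(normalize_units(cfg))


def test_step_requires_leaks(default_config):
    state = initial_state(default_config)
    with pytest.raises(ValueError):
        trisyn.step(state, default_config, 1e-5)
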