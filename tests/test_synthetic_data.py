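"""Synthetic dataset generators: determinism, noise model, ground truth."""

import numpy as np
import pytest

from sqtpharm.calibration import herg_dose_response, ic50_from_curve
from sqtpharm.drug_engine import DRUGS
from sqtpharm.synthetic_data import SyntheticBlockSpec, gen_block_dataset, \
    gen_fixture_waveform


def _spec(sigma=0.02, seed=5):
    return SyntheticBlockSpec(
        kind="herg_dose_response", drug="quinidine",
        true_params=DRUGS["quinidine"].herg_binding["WT"],
        concentrations=(0.1, 0.3, 0.62, 1.5, 4.0, 10.0), condition="WT",
        sigma=sigma, seed=seed)


def test_seeded_reproducibility():
    a = gen_block_dataset(_spec())
    b = gen_block_dataset(_spec())
    assert a.equals(b)
    c = gen_block_dataset(_spec(seed=6))
    assert not a.equals(c)


def test_zero_noise_matches_simulator_exactly():
    ds = gen_block_dataset(_spec(sigma=0.0))
    sim = herg_dose_response("WT", DRUGS["quinidine"].herg_binding["WT"],
                             (0.1, 0.3, 0.62, 1.5, 4.0, 10.0))
    got = ds[ds.concentration_uM > 0].fractional_block.to_numpy()
    assert np.allclose(got, sim.fractional_block.to_numpy())
    assert (ds.concentration_uM == 0).sum() == 1  # drug-free row present


def test_noisy_dose_response_recovers_true_ic50():
    ds = gen_block_dataset(_spec())
    d = ds[ds.concentration_uM > 0]
    fit = ic50_from_curve(d.concentration_uM, d.fractional_block)
    assert fit.ok
    assert fit.ic50 == pytest.approx(0.62, rel=0.05)


def test_block_stays_in_unit_interval_and_reports_clipping():
    ds = gen_block_dataset(_spec(sigma=0.3, seed=2))
    assert ds.fractional_block.between(0, 1).all()
    assert ds.attrs["clipping_rate"] > 0


def test_use_dependence_dataset_shape():
    spec = SyntheticBlockSpec(
        kind="na_use_dependence", drug="disopyramide",
        true_params=DRUGS["disopyramide"].na_binding,
        concentrations=(10.0,), sigma=0.0)
    ds = gen_block_dataset(spec)
    assert len(ds) == 30
    assert ds.pulse_index.max() == 30


def test_fixture_truths_are_self_consistent():
    t, y, truth = gen_fixture_waveform("trapezoid_ap")
    assert y.max() == pytest.approx(truth["v_peak"])
    t2, y2, truth2 = gen_fixture_waveform("qrst_pecg")
    assert truth2["qt"] > 0
    t3, y3, truth3 = gen_fixture_waveform("am_sine", dict(freq_hz=6.0))
    assert truth3["dominant_hz"] == 6.0
    with pytest.raises(ValueError):
        gen_fixture_waveform("sawtooth")
    with pytest.raises(ValueError):
        SyntheticBlockSpec(kind="herg_dose_response", drug="x",
                           true_params=None, sigma=-0.1)
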