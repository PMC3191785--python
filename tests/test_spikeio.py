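"""Data model, I/O round-trips, binning, classification and screening."""

import numpy as np
import pytest

from spikeglm import (
    CellMeta,
    ParseError,
    SpikeEnsemble,
    TrialRecord,
    ValidationError,
    baseline_rates,
    bin_spikes,
    classify_cell_types,
    ensembles_equal,
    make_ground_truth,
    read_ensemble,
    screen_task_related,
    simulate_ensemble,
    write_ensemble,
)
from spikeglm.spikeio import FS_CENTROID, RS_CENTROID

from conftest import full_trial_spec


def _tiny_ensemble():
    cells = [CellMeta(cell_id=0, putative_type="RS"), CellMeta(cell_id=1, putative_type="FS")]
    trials = [
        TrialRecord(
            trial_id=0,
            outcome="successful",
            trial_length_s=3.0,
            epochs={"background": (0.0, 1.5), "reaching": (1.5, 3.0)},
            spikes=[np.array([0.1, 0.5, 2.0]), np.array([1.6])],
        ),
        TrialRecord(
            trial_id=1,
            outcome="unsuccessful",
            trial_length_s=3.0,
            epochs={"background": (0.0, 1.5), "reaching": (1.5, 3.0)},
            spikes=[np.array([]), np.array([0.25, 0.75])],
        ),
    ]
    return SpikeEnsemble(cells=cells, trials=trials, name="tiny")


def test_roundtrip_identity(tmp_path, scheme3):
    gt = make_ground_truth(2, 1, scheme3, density=0.3, seed=3)
    ens = simulate_ensemble(gt, full_trial_spec(5))
    path = tmp_path / "ens.spikes"
    write_ensemble(ens, path)
    back = read_ensemble(path)
    assert ensembles_equal(ens, back)
    # a second write of the re-read ensemble is byte-identical
    path2 = tmp_path / "ens2.spikes"
    write_ensemble(back, path2)
    assert path.read_bytes() == path2.read_bytes()


def test_read_rejects_out_of_range_spike(tmp_path):
    ens = _tiny_ensemble()
    path = tmp_path / "bad.spikes"
    write_ensemble(ens, path)
    with open(path, "a") as fh:
        fh.write("tiny\t0\t0\t3.000000\n")  # t == trial_length
    with pytest.raises(ValidationError):
        read_ensemble(path)


def test_read_reports_malformed_line_number(tmp_path):
    ens = _tiny_ensemble()
    path = tmp_path / "bad.spikes"
    write_ensemble(ens, path)
    with open(path, "a") as fh:
        fh.write("tiny\t0\tnot_a_cell\n")
    with pytest.raises(ParseError, match=r":8:"):
        read_ensemble(path)


def test_unknown_outcome_label_rejected():
    with pytest.raises(ValidationError, match="outcome"):
        TrialRecord(
            trial_id=0,
            outcome="maybe",
            trial_length_s=3.0,
            epochs={"all": (0.0, 3.0)},
            spikes=[np.array([])],
        )


def test_summary_counts():
    s = _tiny_ensemble().summary()
    assert s["n_trials"] == 2
    assert s["n_cells"] == 2
    assert (s["n_successful"], s["n_unsuccessful"]) == (1, 1)
    assert s["n_spikes"] == 6


# ---------------------------------------------------------------------------
# Binning


def test_bin_collision_saturates_to_one():
    cells = [CellMeta(cell_id=0)]
    tr = TrialRecord(
        trial_id=0,
        outcome="successful",
        trial_length_s=0.01,
        epochs={"all": (0.0, 0.01)},
        spikes=[np.array([0.001, 0.0019])],
    )
    b = bin_spikes(SpikeEnsemble([cells[0]], [tr]), "all", delta_s=0.001)
    assert b.indicators.sum() == 1
    assert b.indicators[0, 0, 1] == 1
    assert b.n_collisions == 1


def test_bin_empty_trial_is_all_zero():
    tr = TrialRecord(
        trial_id=0,
        outcome="successful",
        trial_length_s=3.0,
        epochs={"all": (0.0, 3.0)},
        spikes=[np.array([])],
    )
    b = bin_spikes(SpikeEnsemble([CellMeta(cell_id=0)], [tr]), "all")
    assert b.n_bins == 3000
    assert b.indicators.sum() == 0


def test_bin_rate_matches_binomial_oracle():
    # 20 spikes/s Poisson, 3 s epoch, Delta = 1 ms: indicator mean ~ 0.02
    rng = np.random.default_rng(11)
    trials = []
    for i in range(50):
        t = np.sort(rng.uniform(0, 3.0, rng.poisson(60)))
        t = np.unique(np.round(t, 6))
        trials.append(
            TrialRecord(
                trial_id=i,
                outcome="successful",
                trial_length_s=3.0,
                epochs={"all": (0.0, 3.0)},
                spikes=[t],
            )
        )
    b = bin_spikes(SpikeEnsemble([CellMeta(cell_id=0)], trials), "all")
    m = b.indicators.mean()
    n = b.indicators.size
    se = np.sqrt(0.02 * 0.98 / n)
    assert abs(m - 0.02) < 3 * se + 0.02 * 0.01  # 3 SE plus tiny collision slack


def test_bin_missing_epoch_raises():
    with pytest.raises(ValidationError, match="epoch"):
        bin_spikes(_tiny_ensemble(), "feed")


def test_baseline_rates_simple():
    tr = TrialRecord(
        trial_id=0,
        outcome="successful",
        trial_length_s=3.0,
        epochs={"all": (0.0, 3.0)},
        spikes=[np.linspace(0.01, 2.99, 30)],
    )
    r = baseline_rates(SpikeEnsemble([CellMeta(cell_id=0)], [tr]))
    assert r[0] == pytest.approx(10.0)


def test_generator_rate_regimes(scheme3):
    gt = make_ground_truth(60, 40, scheme3, density=0.0, seed=5)
    rates = np.array([c.baseline_rate for c in gt.cell_meta()])
    assert abs(rates[:60].mean() - 8.5) < 3 * 3.6 / np.sqrt(60)
    assert abs(rates[60:].mean() - 22.7) < 3 * 9.6 / np.sqrt(40)


# ---------------------------------------------------------------------------
# RS/FS classification


def test_classify_two_archetypes():
    types = classify_cell_types([8.0, 25.0], [0.9, 0.4])
    assert types == ["RS", "FS"]


def test_classify_identical_cells_all_rs():
    assert classify_cell_types([10.0] * 4, [0.6] * 4) == ["RS"] * 4


def test_classify_permutation_equivariant():
    rng = np.random.default_rng(2)
    rates = np.r_[rng.normal(8.5, 1.0, 5), rng.normal(22.7, 2.0, 5)]
    durs = np.r_[rng.normal(0.9, 0.05, 5), rng.normal(0.45, 0.03, 5)]
    base = classify_cell_types(rates, durs)
    perm = rng.permutation(10)
    permuted = classify_cell_types(rates[perm], durs[perm])
    assert [base[i] for i in perm] == permuted


def test_classify_recovers_generator_labels():
    rng = np.random.default_rng(9)
    agree = 0
    for _ in range(50):
        n_rs, n_fs = 6, 4
        rates = np.r_[
            rng.normal(RS_CENTROID[1], 1.5, n_rs), rng.normal(FS_CENTROID[1], 2.5, n_fs)
        ]
        durs = np.r_[
            rng.normal(RS_CENTROID[0], 0.05, n_rs), rng.normal(FS_CENTROID[0], 0.04, n_fs)
        ]
        got = classify_cell_types(rates, durs)
        agree += got == ["RS"] * n_rs + ["FS"] * n_fs
    assert agree == 50


def test_classify_single_cell_falls_back_to_centroid():
    with pytest.warns(UserWarning, match="centroid"):
        assert classify_cell_types([8.0], [0.9]) == ["RS"]


# ---------------------------------------------------------------------------
# Task-relatedness screening


def _rate_ensemble(rng, bg_rate, reach_rate, n_trials=20):
    trials = []
    for i in range(n_trials):
        bg = np.sort(rng.uniform(0.0, 1.5, rng.poisson(bg_rate * 1.5)))
        re = np.sort(rng.uniform(1.5, 3.0, rng.poisson(reach_rate * 1.5)))
        spikes = np.unique(np.round(np.r_[bg, re], 6))
        trials.append(
            TrialRecord(
                trial_id=i,
                outcome="successful",
                trial_length_s=3.0,
                epochs={"background": (0.0, 1.5), "reaching": (1.5, 3.0)},
                spikes=[spikes],
            )
        )
    return SpikeEnsemble([CellMeta(cell_id=0)], trials)


def test_screen_constant_rate_type_one_error():
    rng = np.random.default_rng(21)
    false_pos = sum(
        screen_task_related(_rate_ensemble(rng, 10, 10), ["background", "reaching"], 0.05)[0]
        for _ in range(100)
    )
    assert false_pos <= 10  # ~5% nominal; false in >= 90% of runs


def test_screen_detects_strong_modulation():
    rng = np.random.default_rng(22)
    ens = _rate_ensemble(rng, 8, 24)
    assert screen_task_related(ens, ["background", "reaching"], 0.05)[0]


def test_screen_alpha_one_always_true():
    rng = np.random.default_rng(23)
    ens = _rate_ensemble(rng, 10, 10)
    assert screen_task_related(ens, ["background", "reaching"], alpha=1.0).all()


def test_screen_requires_background():
    rng = np.random.default_rng(24)
    with pytest.raises(ValidationError):
        screen_task_related(_rate_ensemble(rng, 10, 10), ["reaching"], 0.05)
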