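"""Generator tests: design validation, planted structure, determinism."""

import numpy as np
import pandas as pd
import pytest

from top2itox import simulate
from top2itox.simulate import (
    MotifSpec,
    SimDesign,
    ac_variance_inflation,
    contrast_pairs,
    default_motifs,
    ll4,
    motif_recovery_errors,
    planted_parameters,
    simulate_calcium_trace,
    simulate_counts,
    simulate_viability_plate,
)


def test_design_layout_and_dtypes(small_experiment):
    experiment, truth = small_experiment
    assert experiment.counts.shape == (300, 6 * 6 * 2)
    assert experiment.counts.dtypes.eq(np.int64).all()
    assert (experiment.counts.to_numpy() >= 0).all()
    groups = experiment.samples.groupby(["treatment", "time"]).size()
    assert (groups == 6).all() and len(groups) == 12
    assert experiment.samples["individual"].nunique() == 6
    assert truth.lfc.shape == (300, 10)
    assert set(truth.motif_labels.unique()) <= {"NR", "LR", "EAR", "ESR"}


def test_simulation_is_deterministic():
    d = SimDesign(n_genes=80, seed=5)
    e1, t1 = simulate_counts(d)
    e2, t2 = simulate_counts(SimDesign(n_genes=80, seed=5))
    pd.testing.assert_frame_equal(e1.counts, e2.counts)
    pd.testing.assert_frame_equal(t1.lfc, t2.lfc)
    e3, _ = simulate_counts(SimDesign(n_genes=80, seed=6))
    assert not e1.counts.equals(e3.counts)


def test_planted_lfc_follows_motif_patterns(small_experiment):
    _, truth = small_experiment
    pairs = [simulate.pair_key(*p) for p in contrast_pairs()]
    spec = {m.label: m.q for m in default_motifs()}
    for gene, label in truth.motif_labels.items():
        row = truth.lfc.loc[gene].to_numpy()
        q = spec[label]
        assert (row[q == 0.0] == 0.0).all()
        active = row[q == 1.0]
        if active.size:
            # one magnitude and sign shared across the gene's DE contrasts
            assert np.allclose(active, active[0])
            assert np.abs(active[0]) >= 0.5
    assert list(truth.lfc.columns) == pairs


def test_planted_effects_visible_in_counts(small_experiment):
    experiment, truth = small_experiment
    lib = experiment.counts.sum(axis=0)
    cpm = experiment.counts / lib * 1e6
    dox24 = experiment.group_samples("DOX", "24h")
    veh24 = experiment.group_samples("VEH", "24h")
    obs = np.log2(cpm[dox24].mean(axis=1) + 0.5) - np.log2(cpm[veh24].mean(axis=1) + 0.5)
    planted = truth.lfc["DOX_24h"]
    strong = planted.index[(planted.abs() > 1.0) & (cpm[veh24].mean(axis=1) > 5)]
    assert len(strong) > 5
    r = np.corrcoef(obs.loc[strong], planted.loc[strong])[0, 1]
    assert r > 0.9


def test_variance_inflation_is_planted(inflated_experiment):
    experiment, truth = inflated_experiment
    assert truth.variance_factors[("DOX", "24h")] == 1.5
    assert truth.variance_factors[("MTX", "24h")] == 1.0
    lib = experiment.counts.sum(axis=0)
    lcpm = np.log2((experiment.counts + 0.5) / (lib + 1.0) * 1e6)
    expressed = lcpm.mean(axis=1) > 2
    v_dox = lcpm.loc[expressed, experiment.group_samples("DOX", "24h")].var(axis=1)
    v_veh = lcpm.loc[expressed, experiment.group_samples("VEH", "24h")].var(axis=1)
    med_f = float((v_dox / v_veh).median())
    # SD factor 1.5 -> variance factor 2.25 in the individual-effect component
    assert 1.5 < med_f < 3.0


def test_design_validation_errors():
    with pytest.raises(ValueError, match="n_genes"):
        SimDesign(n_genes=0).validate()
    bad = [MotifSpec("A", 0.7, np.zeros(10)), MotifSpec("B", 0.7, np.zeros(10))]
    with pytest.raises(ValueError, match="sum"):
        SimDesign(motif_spec=bad).validate()
    with pytest.raises(ValueError, match="q length"):
        SimDesign(motif_spec=[MotifSpec("A", 1.0, np.zeros(3))]).validate()
    with pytest.raises(ValueError, match="0/1"):
        MotifSpec("A", 1.0, np.full(10, 0.5))
    with pytest.raises(ValueError, match="dispersion"):
        SimDesign(dispersion=-1.0).validate()


def test_default_motif_proportions():
    motifs = default_motifs()
    assert [m.label for m in motifs] == ["NR", "LR", "EAR", "ESR"]
    assert np.isclose(sum(m.proportion for m in motifs), 1.0)
    q, pi, labels = planted_parameters(SimDesign())
    assert q.shape == (4, 10) and np.isclose(pi.sum(), 1.0)
    # TRZ never responds in any planted motif
    pairs = [simulate.pair_key(*p) for p in contrast_pairs()]
    trz_cols = [i for i, p in enumerate(pairs) if p.startswith("TRZ")]
    assert (q[:, trz_cols] == 0).all()


def test_motif_recovery_errors_matching():
    q_true = np.array([[0.0, 0.0], [1.0, 1.0]])
    pi_true = np.array([0.7, 0.3])
    # fitted motifs given in swapped order
    res = motif_recovery_errors(
        np.array([[0.95, 0.9], [0.05, 0.1]]), np.array([0.28, 0.72]), q_true, pi_true
    )
    assert res["permutation"] == [1, 0]
    assert res["max_q_err"] == pytest.approx(0.1)
    assert res["max_pi_err"] == pytest.approx(0.02)


def test_viability_plate_layout_and_noiseless_values():
    params = {"DOX": (1.5, 0.05, 14.0), "TRZ": (1.0, 0.99, 50.0)}
    plate = simulate_viability_plate(params, noise_sd=0.0, seed=3)
    # 6 background + (vehicle + 2 drugs) x 8 concentrations x 4 replicates
    assert len(plate) == 6 + 3 * 8 * 4
    bg = plate[plate["is_background"]]
    assert np.allclose(bg["rflu"], 100.0)
    veh = plate[(plate["drug"] == "VEH")]
    assert np.allclose(veh["rflu"], 1100.0)
    dox = plate[plate["drug"] == "DOX"]
    for conc, grp in dox.groupby("conc_uM"):
        assert np.allclose(grp["rflu"], 100.0 + 1000.0 * ll4(conc, 1.5, 0.05, 14.0))


def test_viability_plate_validation():
    with pytest.raises(ValueError, match="e must be"):
        simulate_viability_plate({"DOX": (1.0, 0.1, -1.0)})
    with pytest.raises(ValueError, match="c must be"):
        simulate_viability_plate({"DOX": (1.0, 1.2, 5.0)})
    with pytest.raises(ValueError, match="noise_sd"):
        simulate_viability_plate({"DOX": (1.0, 0.1, 5.0)}, noise_sd=-0.1)


def test_calcium_trace_events_and_baseline():
    trace = simulate_calcium_trace(rate_hz=1.0, duration_s=10.0, noise_sd=0.0)
    assert len(trace.event_times) == 10
    assert trace.intensity.shape == trace.time_s.shape
    # baseline 1 before the first event
    pre = trace.intensity[trace.time_s < trace.event_times[0]]
    assert np.allclose(pre, 1.0)
    # every planted event raises the trace to about baseline + amplitude
    for t0 in trace.event_times:
        window = trace.intensity[(trace.time_s >= t0) & (trace.time_s <= t0 + 0.3)]
        assert window.max() > 1.0 + 0.8 * 2.0


def test_calcium_events_fit_within_recording():
    # at 0.75 Hz x 10 s a naive count would plant an event at exactly t = 10 s
    trace = simulate_calcium_trace(rate_hz=0.75, duration_s=10.0)
    assert (trace.event_times < trace.time_s[-1]).all()
    assert len(trace.event_times) == 7


def test_calcium_trace_validation():
    with pytest.raises(ValueError, match="fs"):
        simulate_calcium_trace(rate_hz=20.0, fs=31.34)
    with pytest.raises(ValueError, match="duration"):
        simulate_calcium_trace(rate_hz=1.0, duration_s=0.0)
    with pytest.raises(ValueError, match="decay_tau"):
        simulate_calcium_trace(rate_hz=1.0, decay_tau=0.0)


def test_ac_variance_inflation_keys():
    vi = ac_variance_inflation(2.0)
    assert vi == {("DOX", "24h"): 2.0, ("EPI", "24h"): 2.0, ("DNR", "24h"): 2.0}
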