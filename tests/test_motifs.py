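"""Correlation-motif model: densities, EM behaviour, labelling rules."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from top2itox import motifs
from top2itox.motifs import (
    MotifFit,
    _label_motif,
    _log_f1,
    _log_t_pdf,
    assign_signatures,
    drug_specific_genes,
    fit_motifs,
    select_motif_number,
)

PAIR_COLS = [
    f"{d}_{tp}" for d in ("DOX", "EPI", "DNR", "MTX", "TRZ") for tp in ("3h", "24h")
]


def test_log_t_pdf_matches_scipy(rng):
    t = rng.normal(0, 3, size=50)
    for df in (2.5, 10.0, 123.4):
        assert np.allclose(_log_t_pdf(t, df), stats.t.logpdf(t, df), atol=1e-10)
    # huge df falls back to the Gaussian limit
    assert np.allclose(_log_t_pdf(t, 1e12), stats.norm.logpdf(t), atol=1e-5)


def test_log_f1_is_scaled_t(rng):
    t = rng.normal(0, 3, size=50)
    df, v = 14.0, 3.0
    s = np.sqrt(1.0 + v)
    expected = stats.t.logpdf(t / s, df) - np.log(s)
    assert np.allclose(_log_f1(t, np.array([df]), np.array([v])), expected, atol=1e-10)


def _toy_t_matrix(rng, g=1200, df=20.0, v=24.0):
    """Two planted motifs over 4 conditions."""
    q_true = np.array([[0.0, 0.0, 0.0, 0.0], [1.0, 1.0, 0.0, 0.0]])
    pi_true = np.array([0.6, 0.4])
    motif = rng.choice(2, size=g, p=pi_true)
    is_de = rng.uniform(size=(g, 4)) < q_true[motif]
    t = stats.t.rvs(df, size=(g, 4), random_state=rng.integers(2**31))
    t = np.where(is_de, t * np.sqrt(1.0 + v), t)
    return pd.DataFrame(t, index=[f"g{i}" for i in range(g)]), df, q_true, pi_true


def test_em_recovers_two_motifs_and_is_monotone(rng):
    tmat, df, q_true, pi_true = _toy_t_matrix(rng)
    fit = fit_motifs(tmat, df, k=2, seed=11)
    assert fit.converged
    assert np.all(np.diff(fit.loglik_history) > -1e-6 * np.abs(fit.loglik))
    order = np.argsort(fit.q.sum(axis=1))  # null motif first
    q_err = np.abs(fit.q[order] - q_true)
    # true-signal entries recovered sharply; null entries inside the DE motif
    # are weakly identified near the v >= 1 floor, so judge them on average
    assert q_err[q_true == 1.0].max() < 0.1
    assert q_err.mean() < 0.1
    assert np.abs(np.sort(fit.pi) - np.sort(pi_true)).max() < 0.05
    assert fit.n_params == 1 + 2 * 4 + 4
    assert fit.gene_posterior.shape == (1200, 2)
    assert np.allclose(fit.gene_posterior.sum(axis=1), 1.0)
    assert ((fit.de_posterior.to_numpy() >= 0) & (fit.de_posterior.to_numpy() <= 1)).all()


def test_bic_selects_true_motif_number(rng):
    tmat, df, _, _ = _toy_t_matrix(rng)
    sel = select_motif_number(tmat, df, k_range=range(1, 4), seed=5)
    assert sel.best_k == 2
    assert list(sel.scores["k"]) == [1, 2, 3]
    assert sel.best_fit is sel.fits[2]


def test_fit_motifs_input_errors():
    t = pd.DataFrame(np.zeros((5, 2)))
    with pytest.raises(ValueError, match="k must be"):
        fit_motifs(t, 10.0, k=0)
    with pytest.raises(ValueError, match="more genes"):
        fit_motifs(t, 10.0, k=5)
    with pytest.raises(ValueError, match="k_range"):
        select_motif_number(t, 10.0, k_range=[])


def _q_row(values: dict) -> np.ndarray:
    row = np.zeros(len(PAIR_COLS))
    for key, v in values.items():
        row[PAIR_COLS.index(key)] = v
    return row


def test_label_motif_rules():
    top2i = ("DOX", "EPI", "DNR", "MTX")
    high3 = {f"{d}_3h": 0.9 for d in top2i}
    high24 = {f"{d}_24h": 0.9 for d in top2i}
    assert _label_motif(_q_row(high3), PAIR_COLS) == "EAR"
    assert _label_motif(_q_row(high24), PAIR_COLS) == "LR"
    assert _label_motif(_q_row({**high3, **high24}), PAIR_COLS) == "ESR"
    assert _label_motif(_q_row({}), PAIR_COLS) == "NR"
    # exactly 3 of 4 drugs above threshold still counts as responsive
    three = {f"{d}_24h": 0.9 for d in ("DOX", "EPI", "DNR")}
    assert _label_motif(_q_row(three), PAIR_COLS) == "LR"
    # 2 of 4 is neither a response nor a clean non-response
    two = {f"{d}_24h": 0.9 for d in ("DOX", "EPI")}
    assert _label_motif(_q_row(two), PAIR_COLS) == "other"
    # TRZ-only signal does not create a TOP2i response
    assert _label_motif(_q_row({"TRZ_3h": 0.9, "TRZ_24h": 0.9}), PAIR_COLS) == "NR"


def _manual_fit(posterior: np.ndarray, q: np.ndarray) -> MotifFit:
    g, k = posterior.shape
    genes = [f"g{i}" for i in range(g)]
    return MotifFit(
        k=k, pi=np.full(k, 1.0 / k), q=q, v=np.ones(len(PAIR_COLS)),
        gene_posterior=pd.DataFrame(posterior, index=genes,
                                    columns=[f"motif{i+1}" for i in range(k)]),
        de_posterior=pd.DataFrame(np.zeros((g, len(PAIR_COLS))), index=genes,
                                  columns=PAIR_COLS),
        loglik=0.0, bic=0.0, aic=0.0, n_params=0, converged=True, n_iter=1,
    )


def test_assign_signatures_threshold_and_ties():
    q = np.vstack([
        _q_row({}),
        _q_row({f"{d}_{tp}": 0.9 for d in ("DOX", "EPI", "DNR", "MTX")
                for tp in ("3h", "24h")}),
    ])
    post = np.array([[0.9, 0.1], [0.5, 0.5], [0.2, 0.8]])
    res = assign_signatures(_manual_fit(post, q))
    assert res.motif_labels == ["NR", "ESR"]
    assert list(res.labels) == ["NR", "unassigned", "ESR"]
    assert res.assigned_fraction == pytest.approx(2.0 / 3.0)


def test_drug_specific_genes_two_step_rule():
    genes = ["g1", "g2", "g3", "g4"]
    mk = lambda vals: pd.DataFrame({"p_adj": vals}, index=genes)
    tables = {
        "DOX": mk([0.005, 0.005, 0.04, 0.005]),
        "EPI": mk([0.50, 0.04, 0.50, 0.50]),
        "DNR": mk([0.90, 0.90, 0.90, 0.051]),
    }
    out = drug_specific_genes(tables, "DOX", strict=0.01, lenient=0.05)
    # g1: passes both steps; g2: EPI p_adj 0.04 < lenient -> rejected;
    # g3: target p_adj 0.04 >= strict -> rejected; g4: passes (0.051 > 0.05)
    assert list(out) == ["g1", "g4"]
    with pytest.raises(KeyError):
        drug_specific_genes(tables, "MTX")


def test_condition_statistics_shapes(small_experiment):
    experiment, _ = small_experiment
    pairs = [("DOX", "24h"), ("TRZ", "3h")]
    tmat, dfs = motifs.condition_statistics(experiment, pairs)
    assert list(tmat.columns) == ["DOX_24h", "TRZ_3h"]
    assert dfs.shape == (2,) and (dfs > 10).all()
    assert np.isfinite(tmat.to_numpy()).all()
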