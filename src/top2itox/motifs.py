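"""Joint correlation-motif model over all drug-vs-vehicle test pairs.

Genes are modelled as a mixture over K motifs; motif k carries a vector
q_k of per-condition differential-expression probabilities. Observed
moderated t statistics follow a central t density under no DE and a
variance-inflated (scaled) t density under DE. The model is fit by EM with
seeded restarts; the motif number is chosen by BIC, and motifs are labelled
EAR / ESR / LR / NR from their q patterns over the TOP2i conditions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special

from .containers import CountExperiment
from .de import fit_pair, filter_expressed, log2_cpm
from .simulate import TOP2I_DRUGS, VEHICLE, pair_key

SIGNATURE_LABELS = ("EAR", "ESR", "LR", "NR")


def condition_statistics(
    experiment: CountExperiment,
    pairs: list[tuple[str, str]],
    vehicle: str = VEHICLE,
    expression_threshold: float = 0.0,
):
    """Moderated t matrix (genes x conditions) and per-condition total df.

    Each condition is one (drug, time) pair fit against the vehicle at the
    same timepoint on TMM-normalized log2 cpm with precision weights.
    """
    lcpm = log2_cpm(experiment.counts)
    expressed = filter_expressed(lcpm, expression_threshold)
    cols, dfs = {}, []
    for drug, time in pairs:
        fit = fit_pair(experiment, drug, time, vehicle=vehicle, expressed=expressed)
        cols[pair_key(drug, time)] = fit.table["moderated_t"]
        dfs.append(fit.df_total)
    t_matrix = pd.DataFrame(cols)
    return t_matrix, np.asarray(dfs, dtype=float)


_NORMAL_DF_CUTOFF = 1e6  # beyond this the t density is numerically Gaussian


def _t_const(df: np.ndarray) -> np.ndarray:
    """log normalizing constant of the t density; Gaussian limit for huge df."""
    df = np.atleast_1d(np.asarray(df, dtype=float))
    big = df > _NORMAL_DF_CUTOFF
    safe = np.where(big, 1.0, df)
    return np.where(
        big,
        -0.5 * np.log(2.0 * np.pi),
        special.gammaln((safe + 1.0) / 2.0)
        - special.gammaln(safe / 2.0)
        - 0.5 * np.log(safe * np.pi),
    )


def _t_kernel(tsq: np.ndarray, df) -> np.ndarray:
    """log t density minus its constant, from squared arguments.

    ``df`` broadcasts along the trailing (condition) axis.
    """
    df = np.asarray(df, dtype=float)
    big = df > _NORMAL_DF_CUTOFF
    safe = np.where(big, 1.0, df)
    return np.where(big, -0.5 * tsq, -(safe + 1.0) / 2.0 * np.log1p(tsq / safe))


def _log_t_pdf(t: np.ndarray, df) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    return _t_const(df) + _t_kernel(t * t, df)


def _log_f1(t: np.ndarray, df: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Scaled-t alternative: t / sqrt(1+v) is t(df) distributed."""
    s = np.sqrt(1.0 + v)
    return _log_t_pdf(t / s, df) - np.log(s)


@dataclass
class MotifFit:
    """Fitted correlation-motif mixture."""

    k: int
    pi: np.ndarray  # (K,) motif frequencies
    q: np.ndarray  # (K, D) per-motif DE probabilities
    v: np.ndarray  # (D,) alternative-density variance inflations
    gene_posterior: pd.DataFrame  # (G, K)
    de_posterior: pd.DataFrame  # (G, D)
    loglik: float
    bic: float
    aic: float
    n_params: int
    converged: bool
    n_iter: int
    loglik_history: np.ndarray = field(repr=False, default=None)
    empty_motifs: list = field(default_factory=list)


_GOLDEN = (np.sqrt(5.0) - 1.0) / 2.0


def _update_v(t, df, wbar, v, bounds, n_iter=16):
    """Per-condition variance inflation by golden-section maximization of the
    expected complete-data term sum_g wbar_gd log f1_d(t_gd; v_d), vectorized
    over the conditions that carry DE mass. Only accepted when it improves
    the objective, which keeps the EM loglik monotone."""
    wsum = wbar.sum(axis=0)
    active = np.flatnonzero(wsum > 1e-8)
    if active.size == 0:
        return v
    dfa, wa = df[active], wbar[:, active]
    usq = t[:, active] ** 2  # squared statistics, shared across evaluations
    wsa = wsum[active]
    lo = np.full(active.size, np.log(bounds[0]))
    hi = np.full(active.size, np.log(bounds[1]))

    def h(logv):  # objective per active condition (constants in v included)
        s2 = 1.0 + np.exp(logv)
        kern = np.einsum("gd,gd->d", wa, _t_kernel(usq / s2, dfa))
        return kern - 0.5 * wsa * np.log(s2)

    for _ in range(n_iter):
        x1 = hi - _GOLDEN * (hi - lo)
        x2 = lo + _GOLDEN * (hi - lo)
        shrink_left = h(x1) < h(x2)  # maximum lies right of x1
        lo = np.where(shrink_left, x1, lo)
        hi = np.where(shrink_left, hi, x2)
    v_new = np.exp((lo + hi) / 2.0)
    out = v.copy()
    improves = h(np.log(v_new)) >= h(np.log(v[active]))
    out[active] = np.where(improves, v_new, v[active])
    return out


def _pattern_init(t, k, rng):
    """Data-driven start: k-means on the thresholded |t| pattern matrix."""
    from sklearn.cluster import KMeans

    z = (np.abs(t) > 2.0).astype(float)
    km = KMeans(n_clusters=k, n_init=1, random_state=int(rng.integers(0, 2**31 - 1)))
    labels = km.fit_predict(z)
    q = np.vstack([
        z[labels == i].mean(axis=0) if (labels == i).any() else rng.uniform(0.1, 0.9, t.shape[1])
        for i in range(k)
    ])
    q = np.clip(q, 0.05, 0.95)
    pi = np.bincount(labels, minlength=k).astype(float) + 1.0
    return pi / pi.sum(), q


def _em_once(t, df, k, rng, max_iter, tol, init="random", v_bounds=(1.0, 1e4)):
    # v is bounded below at 1 (alternative variance at least twice the null):
    # as v -> 0 the DE density collapses onto the null and q becomes
    # unidentifiable in conditions without signal.
    g, d = t.shape
    if init == "pattern" and k > 1:
        pi, q = _pattern_init(t, k, rng)
    else:
        pi = np.full(k, 1.0 / k)
        q = rng.uniform(0.1, 0.9, size=(k, d))
    v = np.ones(d)
    logf0 = _log_t_pdf(t, df)  # (G, D)
    logf1 = _log_f1(t, df, v)
    history = []
    loglik = -np.inf
    converged = False
    for it in range(max_iter):
        # E-step
        a = np.log(q)[None, :, :] + logf1[:, None, :]  # (G, K, D)
        b = np.log1p(-q)[None, :, :] + logf0[:, None, :]
        logmix = np.logaddexp(a, b)
        logjoint = np.log(pi)[None, :] + logmix.sum(axis=2)  # (G, K)
        m = logjoint.max(axis=1, keepdims=True)
        lse = m[:, 0] + np.log(np.exp(logjoint - m).sum(axis=1))
        new_loglik = float(lse.sum())
        r = np.exp(logjoint - lse[:, None])  # (G, K)
        w = np.exp(a - logmix)  # (G, K, D) P(DE | motif k, data)
        history.append(new_loglik)
        if np.isfinite(loglik) and abs(new_loglik - loglik) <= tol * (abs(loglik) + 1.0):
            loglik = new_loglik
            converged = True
            break
        loglik = new_loglik
        # M-step
        rk = r.sum(axis=0)
        pi = np.clip(rk / g, 1e-12, None)
        pi /= pi.sum()
        q = np.einsum("gk,gkd->kd", r, w) / np.clip(rk[:, None], 1e-12, None)
        q = np.clip(q, 1e-8, 1.0 - 1e-8)
        wbar = np.einsum("gk,gkd->gd", r, w)
        v = _update_v(t, df, wbar, v, v_bounds)
        logf1 = _log_f1(t, df, v)
    de_post = np.einsum("gk,gkd->gd", r, w)
    return pi, q, v, r, de_post, loglik, np.asarray(history), converged, it + 1


def fit_motifs(
    t_matrix,
    df,
    k: int,
    seed: int = 0,
    n_restarts: int = 5,
    max_iter: int = 500,
    tol: float = 1e-6,
) -> MotifFit:
    """Fit the K-motif mixture by EM, keeping the best of several starts.

    The first start is pattern-based (k-means on the thresholded |t| matrix);
    the remainder are seeded random starts. Free parameters for the
    information criteria: K-1 motif frequencies, K*D motif DE probabilities
    and D variance inflations.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    is_frame = isinstance(t_matrix, pd.DataFrame)
    t = t_matrix.to_numpy(dtype=float) if is_frame else np.asarray(t_matrix, float)
    df = np.broadcast_to(np.asarray(df, dtype=float), (t.shape[1],))
    g, d = t.shape
    if g <= k:
        raise ValueError("need many more genes than motifs")
    master = np.random.default_rng(seed)
    best = None
    for restart in range(n_restarts):
        rng = np.random.default_rng(master.integers(0, 2**31 - 1))
        init = "pattern" if restart == 0 else "random"
        out = _em_once(t, df, k, rng, max_iter, tol, init=init)
        if best is None or out[5] > best[5]:
            best = out
    pi, q, v, r, de_post, loglik, history, converged, n_iter = best
    empty = [i for i in range(k) if r.sum(axis=0)[i] < 1.0]
    if empty:
        warnings.warn(f"motifs with (near-)empty membership: {empty}")
    n_params = (k - 1) + k * d + d
    genes = t_matrix.index if is_frame else pd.RangeIndex(g)
    cols = t_matrix.columns if is_frame else pd.RangeIndex(d)
    return MotifFit(
        k=k,
        pi=pi,
        q=q,
        v=v,
        gene_posterior=pd.DataFrame(r, index=genes, columns=[f"motif{i+1}" for i in range(k)]),
        de_posterior=pd.DataFrame(de_post, index=genes, columns=cols),
        loglik=loglik,
        bic=-2.0 * loglik + n_params * np.log(g),
        aic=-2.0 * loglik + 2.0 * n_params,
        n_params=n_params,
        converged=converged,
        n_iter=n_iter,
        loglik_history=history,
        empty_motifs=empty,
    )


@dataclass
class MotifSelection:
    best_k: int
    scores: pd.DataFrame
    fits: dict

    @property
    def best_fit(self) -> MotifFit:
        return self.fits[self.best_k]


def select_motif_number(
    t_matrix,
    df,
    k_range=range(1, 9),
    seed: int = 0,
    **fit_kwargs,
) -> MotifSelection:
    """Fit every K in ``k_range`` and pick the BIC minimizer."""
    k_range = list(k_range)
    if not k_range:
        raise ValueError("k_range is empty")
    fits = {}
    rows = []
    for k in k_range:
        fit = fit_motifs(t_matrix, df, k, seed=seed + k, **fit_kwargs)
        fits[k] = fit
        rows.append((k, fit.loglik, fit.n_params, fit.bic, fit.aic))
    scores = pd.DataFrame(rows, columns=["k", "loglik", "n_params", "bic", "aic"])
    best_k = int(scores.loc[scores["bic"].idxmin(), "k"])
    return MotifSelection(best_k=best_k, scores=scores, fits=fits)


@dataclass
class SignatureAssignment:
    labels: pd.Series  # gene -> EAR/ESR/LR/NR/other/unassigned
    motif_labels: list  # per-motif label, index-aligned with the fit
    assigned_fraction: float


def _label_motif(
    q_row: np.ndarray,
    columns,
    top2i_drugs=TOP2I_DRUGS,
    timepoints=("3h", "24h"),
    q_threshold: float = 0.5,
    min_drugs: int = 3,
) -> str:
    """Label one motif from its DE-probability pattern over TOP2i pairs.

    A motif counts as responsive at a timepoint when q > threshold for at
    least ``min_drugs`` of the TOP2i drugs at that timepoint (tolerating a
    weaker MTX response within an otherwise shared motif).
    """
    cols = list(columns)
    idx = {c: i for i, c in enumerate(cols)}
    top2i_cols = {
        tp: [idx[pair_key(dr, tp)] for dr in top2i_drugs if pair_key(dr, tp) in idx]
        for tp in timepoints
    }
    early, late = timepoints[0], timepoints[1]
    resp = {
        tp: sum(q_row[i] > q_threshold for i in top2i_cols[tp]) >= min_drugs
        for tp in timepoints
    }
    all_cols = [i for tp in timepoints for i in top2i_cols[tp]]
    if resp[early] and resp[late]:
        return "ESR"
    if resp[early]:
        return "EAR"
    if resp[late]:
        return "LR"
    if all(q_row[i] <= q_threshold for i in all_cols):
        return "NR"
    return "other"


def assign_signatures(
    fit: MotifFit,
    top2i_drugs=TOP2I_DRUGS,
    timepoints=("3h", "24h"),
    posterior_threshold: float = 0.5,
    q_threshold: float = 0.5,
    min_drugs: int = 3,
) -> SignatureAssignment:
    """Assign genes to motifs and name motifs by response pattern.

    A gene is assigned to motif k iff its posterior for k exceeds the
    threshold strictly and every other motif's posterior lies strictly below
    it (a 0.5/0.5 tie is unassigned).
    """
    motif_labels = [
        _label_motif(
            fit.q[i], fit.de_posterior.columns, top2i_drugs, timepoints,
            q_threshold, min_drugs,
        )
        for i in range(fit.k)
    ]
    if "other" in motif_labels:
        warnings.warn("motif q pattern matching no signature template; labelled 'other'")
    post = fit.gene_posterior.to_numpy()
    best = post.argmax(axis=1)
    best_p = post[np.arange(post.shape[0]), best]
    others_ok = (post < posterior_threshold).sum(axis=1) >= fit.k - 1
    assigned = (best_p > posterior_threshold) & others_ok
    labels = np.where(assigned, np.array(motif_labels, dtype=object)[best], "unassigned")
    return SignatureAssignment(
        labels=pd.Series(labels, index=fit.gene_posterior.index, name="signature"),
        motif_labels=motif_labels,
        assigned_fraction=float(assigned.mean()),
    )


def drug_specific_genes(
    tables: dict,
    target_drug: str,
    strict: float = 0.01,
    lenient: float = 0.05,
) -> pd.Index:
    """Genes DE in exactly one drug at a timepoint, by the two-step rule:
    adjusted p < ``strict`` for the target drug and adjusted p > ``lenient``
    in every other drug."""
    if target_drug not in tables:
        raise KeyError(f"no contrast table for drug {target_drug!r}")

    def _padj(t):
        return (t.table if hasattr(t, "table") else t)["p_adj"]

    sel = _padj(tables[target_drug]) < strict
    for drug, table in tables.items():
        if drug == target_drug:
            continue
        sel &= _padj(table).reindex(sel.index) > lenient
    return sel.index[sel]
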