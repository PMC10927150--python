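"""Viability plate processing, log-logistic dose-response fits, LD50.

Curves follow the LL.4 convention with the upper asymptote fixed at one:
f(x) = c + (1 - c) / (1 + exp(b (ln x - ln e))), b > 0 for a decreasing
curve. LD50 is defined on the absolute scale: the concentration at which
fitted viability equals 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .simulate import ll4


class InsufficientDataError(ValueError):
    pass


def normalize_plate(readings: pd.DataFrame, vehicle: str = "VEH") -> pd.DataFrame:
    """Background-subtract and vehicle-normalize plate fluorescence.

    Per plate, the mean RFLU of the no-cell wells is subtracted from every
    well; each well is then divided by the mean background-corrected vehicle
    RFLU at the same concentration. Vehicle wells therefore average to
    viability 1 at every concentration by construction.
    """
    req = {"plate", "drug", "conc_uM", "rflu", "is_background"}
    missing = req - set(readings.columns)
    if missing:
        raise ValueError(f"plate table missing columns: {sorted(missing)}")
    out = []
    for plate, grp in readings.groupby("plate"):
        bg_wells = grp[grp["is_background"].astype(bool)]
        if bg_wells.empty:
            raise ValueError(f"plate {plate}: no background wells")
        bg = bg_wells["rflu"].mean()
        cells = grp[~grp["is_background"].astype(bool)].copy()
        cells["corrected"] = cells["rflu"] - bg
        veh = cells[cells["drug"] == vehicle]
        veh_mean = veh.groupby("conc_uM")["corrected"].mean()
        for conc, sub in cells.groupby("conc_uM"):
            if conc not in veh_mean.index:
                raise ValueError(
                    f"plate {plate}: no vehicle wells at concentration {conc}"
                )
            denom = veh_mean.loc[conc]
            if denom <= 0:
                raise ValueError(
                    f"plate {plate}: mean vehicle RFLU <= 0 at concentration {conc}"
                )
            sub = sub.copy()
            sub["viability"] = sub["corrected"] / denom
            sub["replicate"] = np.arange(1, len(sub) + 1)
            out.append(sub)
    res = pd.concat(out, ignore_index=True)
    cols = ["plate", "drug", "conc_uM", "replicate", "viability"]
    if "well" in res.columns:
        cols.insert(1, "well")
    return res[cols]


@dataclass
class DoseResponseFit:
    """LL.4 parameters (upper asymptote fixed at 1) and the derived LD50."""

    b: float
    c: float
    e: float
    rss: float
    ld50_uM: float | None
    degenerate: bool = False
    converged: bool = True
    d: float = 1.0  # fixed upper asymptote

    def predict(self, x):
        return ll4(x, self.b, self.c, self.e)


# deterministic multiplicative restarts around the initial inflection guess
_E0_JITTERS = (1.0, 0.1, 10.0, 0.01, 100.0)


def _initial_e(conc: np.ndarray, viab: np.ndarray) -> float:
    """Geometric mean of the concentrations bracketing viability 0.5."""
    order = np.argsort(conc)
    cs, vs = conc[order], viab[order]
    # mean viability per distinct concentration
    uconc = np.unique(cs)
    vmean = np.array([vs[cs == u].mean() for u in uconc])
    above = vmean > 0.5
    for i in range(len(uconc) - 1):
        if above[i] != above[i + 1]:
            return float(np.sqrt(uconc[i] * uconc[i + 1]))
    return float(np.median(uconc))


def fit_ll4_fixed_upper(
    conc,
    viability,
    flat_tolerance: float = 0.05,
) -> DoseResponseFit:
    """Least-squares LL.4 fit with fixed upper asymptote.

    Initialization is deterministic (inflection guess from the concentrations
    bracketing half-viability, slope 1, floor at the clipped minimum
    viability) with a fixed ladder of multiplicative restarts on the
    inflection, so the fit is reproducible. A fit whose predicted viability
    varies by less than ``flat_tolerance`` across the tested concentrations
    is flagged degenerate and carries no LD50.
    """
    conc = np.asarray(conc, dtype=float)
    viab = np.asarray(viability, dtype=float)
    if conc.shape != viab.shape:
        raise ValueError("conc and viability must be the same length")
    if not np.isfinite(viab).all():
        raise ValueError("viabilities must be finite")
    if (conc <= 0).any():
        raise ValueError("concentrations must be positive")
    if np.unique(conc).size < 4:
        raise InsufficientDataError("need at least 4 distinct concentrations")

    logc = np.log(conc)
    e0 = _initial_e(conc, viab)
    c0 = float(np.clip(viab.min(), 0.0, 0.45))

    def residuals(theta):
        b, c, loge = theta
        return c + (1.0 - c) / (1.0 + np.exp(b * (logc - loge))) - viab

    span = np.log(conc.max() / conc.min())
    bounds = (
        [1e-3, 0.0, np.log(conc.min()) - span - 5.0],
        [50.0, 0.999, np.log(conc.max()) + span + 5.0],
    )
    best = None
    for jit in _E0_JITTERS:
        x0 = np.array([1.0, c0, np.clip(np.log(e0 * jit), bounds[0][2], bounds[1][2])])
        try:
            sol = optimize.least_squares(
                residuals, x0, bounds=bounds, xtol=1e-15, ftol=1e-15, gtol=1e-15,
                max_nfev=2000,
            )
        except Exception:
            continue
        rss = float(2.0 * sol.cost)
        if best is None or rss < best[1]:
            best = (sol, rss)
    if best is None:
        return DoseResponseFit(np.nan, np.nan, np.nan, np.inf, None,
                               degenerate=True, converged=False)
    sol, rss = best
    b, c, loge = sol.x
    e = float(np.exp(loge))
    pred = ll4(conc, b, c, e)
    degenerate = float(pred.max() - pred.min()) < flat_tolerance
    fit = DoseResponseFit(float(b), float(c), e, rss, None,
                          degenerate=degenerate, converged=bool(sol.success))
    fit.ld50_uM = extract_ld50(fit)
    return fit


def extract_ld50(fit: DoseResponseFit) -> float | None:
    """Concentration at which fitted viability equals 0.5 (absolute scale).

    Undefined (None) when the fitted floor c >= 0.5 — the curve never reaches
    half-kill — or when the fit is degenerate (flat over the tested range).
    """
    if fit.degenerate or not np.isfinite(fit.c) or fit.c >= 0.5 or fit.b <= 0:
        return None
    return float(fit.e * ((1.0 - fit.c) / (0.5 - fit.c) - 1.0) ** (1.0 / fit.b))


def summarize_ld50(ld50_table: pd.DataFrame, reference_drug: str = "DOX"):
    """Per-drug LD50 medians across individuals and Welch t tests vs a
    reference drug.

    ``ld50_table`` needs columns individual, drug, ld50_uM (one row per
    replicate fit; replicates of an individual are averaged first, matching
    how reported per-individual values are formed).
    """
    tab = ld50_table.copy()
    per_ind = (
        tab.groupby(["drug", "individual"])["ld50_uM"]
        .mean()
        .reset_index()
    )
    rows = []
    for drug, grp in per_ind.groupby("drug"):
        vals = grp["ld50_uM"].dropna()
        rows.append(
            {
                "drug": drug,
                "n_individuals": len(vals),
                "median_ld50_uM": vals.median() if len(vals) else np.nan,
                "mean_ld50_uM": vals.mean() if len(vals) else np.nan,
                "estimable": len(vals) > 0,
            }
        )
    summary = pd.DataFrame(rows).set_index("drug")
    comparisons = []
    if reference_drug in summary.index:
        ref = per_ind.loc[per_ind["drug"] == reference_drug, "ld50_uM"].dropna()
        for drug, grp in per_ind.groupby("drug"):
            if drug == reference_drug:
                continue
            vals = grp["ld50_uM"].dropna()
            if len(vals) < 2 or len(ref) < 2:
                continue
            t, p = stats.ttest_ind(vals, ref, equal_var=False)
            comparisons.append({"drug": drug, "vs": reference_drug,
                                "t": float(t), "p": float(p)})
    return summary, pd.DataFrame(comparisons, columns=["drug", "vs", "t", "p"])


def correlate_stress(
    viability: pd.DataFrame,
    ldh: pd.DataFrame,
    vehicle: str = "VEH",
) -> pd.DataFrame:
    """Spearman correlation between viability and vehicle-normalized LDH
    release, per drug, across concentrations and individuals.

    ``ldh`` needs columns individual, drug, conc_uM, ldh; each LDH value is
    first normalized to the matched vehicle value for the same individual and
    concentration. ``viability`` needs individual, drug, conc_uM, viability.
    """
    veh = (
        ldh[ldh["drug"] == vehicle]
        .groupby(["individual", "conc_uM"])["ldh"]
        .mean()
        .rename("ldh_veh")
    )
    drug_ldh = ldh[ldh["drug"] != vehicle].merge(
        veh, on=["individual", "conc_uM"], how="left"
    )
    drug_ldh["ldh_norm"] = drug_ldh["ldh"] / drug_ldh["ldh_veh"]
    via = (
        viability[viability["drug"] != vehicle]
        .groupby(["individual", "drug", "conc_uM"])["viability"]
        .mean()
        .reset_index()
    )
    merged = via.merge(
        drug_ldh.groupby(["individual", "drug", "conc_uM"])["ldh_norm"].mean().reset_index(),
        on=["individual", "drug", "conc_uM"],
    )
    rows = []
    for drug, grp in merged.groupby("drug"):
        n = len(grp)
        if n < 3 or grp["viability"].nunique() < 2 or grp["ldh_norm"].nunique() < 2:
            rows.append({"drug": drug, "rho": np.nan, "p": np.nan, "n": n})
            continue
        rho, p = stats.spearmanr(grp["viability"], grp["ldh_norm"])
        rows.append({"drug": drug, "rho": float(rho), "p": float(p), "n": n})
    return pd.DataFrame(rows).set_index("drug")
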