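"""Synthetic inputs with the statistical structure the analysis assumes.

Emulates the study design: six individuals, five drugs plus vehicle, two
timepoints, negative-binomial counts with planted response motifs
(early-acute / early-sustained / late / non-response), anthracycline-specific
variance inflation at 24 h, four-parameter log-logistic viability plates, and
periodic calcium transients with rise/decay kinetics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import CountExperiment

TREATMENTS = ("DOX", "EPI", "DNR", "MTX", "TRZ", "VEH")
TIMEPOINTS = ("3h", "24h")
TOP2I_DRUGS = ("DOX", "EPI", "DNR", "MTX")
AC_DRUGS = ("DOX", "EPI", "DNR")
VEHICLE = "VEH"

#: the eight-point dilution series used for the viability plates (uM)
VIABILITY_CONCENTRATIONS = (50.0, 10.0, 5.0, 1.0, 0.5, 0.1, 0.05, 0.01)


def contrast_pairs(treatments=TREATMENTS, timepoints=TIMEPOINTS, vehicle=VEHICLE):
    """All (drug, time) test pairs: each non-vehicle treatment at each time."""
    return [(t, tp) for t in treatments if t != vehicle for tp in timepoints]


def pair_key(drug: str, time: str) -> str:
    return f"{drug}_{time}"


@dataclass
class MotifSpec:
    """One planted response motif.

    ``q`` holds the planted per-contrast DE indicators (0/1) in the order of
    :func:`contrast_pairs`. Effect magnitudes for DE contrasts are drawn as
    ``|N(0, lfc_scale)| + lfc_shift`` (log2 scale), one draw per gene, with a
    random sign shared across that gene's DE contrasts.
    """

    label: str
    proportion: float
    q: np.ndarray
    lfc_scale: float = 1.0
    lfc_shift: float = 0.5

    def __post_init__(self):
        self.q = np.asarray(self.q, dtype=float)
        if not np.isin(self.q, (0.0, 1.0)).all():
            raise ValueError(f"motif {self.label}: q entries must be 0/1")


def default_motifs(treatments=TREATMENTS, timepoints=TIMEPOINTS) -> list[MotifSpec]:
    """The four response patterns the joint model is expected to recover.

    Non-response (NR), late response (LR: TOP2i at 24 h only), early-acute
    (EAR: TOP2i at 3 h only) and early-sustained (ESR: TOP2i at both
    timepoints). TRZ carries no signal in any motif.
    """
    pairs = contrast_pairs(treatments, timepoints)
    d = len(pairs)

    def q_for(times):
        q = np.zeros(d)
        for i, (drug, tp) in enumerate(pairs):
            if drug in TOP2I_DRUGS and tp in times:
                q[i] = 1.0
        return q

    return [
        MotifSpec("NR", 0.50, np.zeros(d)),
        MotifSpec("LR", 0.35, q_for({"24h"})),
        MotifSpec("EAR", 0.08, q_for({"3h"})),
        MotifSpec("ESR", 0.07, q_for({"3h", "24h"})),
    ]


def ac_variance_inflation(factor: float = 1.5, time: str = "24h") -> dict:
    """Anthracycline-specific inflation of across-individual effect SD."""
    return {(drug, time): factor for drug in AC_DRUGS}


@dataclass
class SimDesign:
    """Parameters of the count simulation (defaults emulate the study)."""

    n_individuals: int = 6
    treatments: tuple = TREATMENTS
    timepoints: tuple = TIMEPOINTS
    n_genes: int = 5000
    motif_spec: list[MotifSpec] = field(default_factory=default_motifs)
    dispersion: float = 0.01
    lib_size_range: tuple = (2.0e7, 4.0e7)
    individual_sd: float = 0.4
    variance_inflation: dict = field(default_factory=dict)
    baseline_log2cpm_mean: float = 4.0
    baseline_log2cpm_sd: float = 2.0
    vehicle: str = VEHICLE
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes <= 0:
            raise ValueError("n_genes must be positive")
        if len(self.treatments) == 0:
            raise ValueError("treatments must be non-empty")
        if self.vehicle not in self.treatments:
            raise ValueError("vehicle must be among treatments")
        disp = np.asarray(self.dispersion, dtype=float)
        if (disp <= 0).any():
            raise ValueError("dispersion must be > 0")
        props = np.array([m.proportion for m in self.motif_spec])
        if not np.isclose(props.sum(), 1.0, atol=1e-8):
            raise ValueError(f"motif proportions sum to {props.sum()}, not 1")
        d = len(self.pairs)
        for m in self.motif_spec:
            if m.q.shape != (d,):
                raise ValueError(f"motif {m.label}: q length {m.q.shape} != {d}")
        if self.n_individuals < 1:
            raise ValueError("need at least one individual")

    @property
    def pairs(self) -> list[tuple[str, str]]:
        return contrast_pairs(self.treatments, self.timepoints, self.vehicle)


@dataclass
class SimTruth:
    """Planted truth paired with a simulated experiment."""

    motif_labels: pd.Series  # gene -> motif label
    lfc: pd.DataFrame  # gene x contrast true log2 fold change
    variance_factors: dict  # (treatment, time) -> SD inflation factor

    def de_genes(self, pair: tuple[str, str]) -> pd.Index:
        col = pair_key(*pair)
        return self.lfc.index[self.lfc[col] != 0.0]


def simulate_counts(design: SimDesign) -> tuple[CountExperiment, SimTruth]:
    """Draw a gene-by-sample NB count matrix with planted response motifs.

    Counts follow a gamma-Poisson with mean
    ``lib * p_g * 2^(k * u_gi + lfc_gd)`` where ``p_g`` is the gene's
    baseline relative abundance, ``u_gi`` a per-(gene, individual) effect
    shared by all of that individual's samples (log2 SD ``individual_sd``),
    ``k`` the group's variance-inflation factor and ``lfc_gd`` the planted
    log2 fold change of the sample's (treatment, time) contrast.
    """
    design.validate()
    rng = np.random.default_rng(design.seed)
    g = design.n_genes
    pairs = design.pairs
    d = len(pairs)
    genes = pd.Index([f"G{i + 1:05d}" for i in range(g)], name="gene")

    # baseline relative abundance from a lognormal log2-cpm draw
    base_log2 = rng.normal(design.baseline_log2cpm_mean, design.baseline_log2cpm_sd, g)
    p = np.exp2(base_log2)
    p /= p.sum()

    # motif assignment and planted effects
    props = np.array([m.proportion for m in design.motif_spec])
    motif_idx = rng.choice(len(design.motif_spec), size=g, p=props)
    magnitudes = np.empty(g)
    for k, m in enumerate(design.motif_spec):
        sel = motif_idx == k
        magnitudes[sel] = np.abs(rng.normal(0.0, m.lfc_scale, sel.sum())) + m.lfc_shift
    signs = rng.choice([-1.0, 1.0], size=g)
    q_planted = np.stack([design.motif_spec[k].q for k in motif_idx])  # g x d
    lfc = (signs * magnitudes)[:, None] * q_planted

    # per-(gene, individual) effects, log2 scale
    u = rng.normal(0.0, design.individual_sd, size=(g, design.n_individuals))

    # sample layout
    records = []
    for i in range(design.n_individuals):
        for trt in design.treatments:
            for tp in design.timepoints:
                records.append((f"ind{i + 1}_{trt}_{tp}", f"ind{i + 1}", trt, tp))
    samples = pd.DataFrame(
        records, columns=["sample_id", "individual", "treatment", "time"]
    ).set_index("sample_id")
    n_s = len(samples)
    lib = rng.uniform(*design.lib_size_range, size=n_s)

    pair_index = {pk: j for j, pk in enumerate(pair_key(*pr) for pr in pairs)}
    mean = np.empty((g, n_s))
    for s, (sid, row) in enumerate(samples.iterrows()):
        i = int(row["individual"][3:]) - 1
        k = design.variance_inflation.get((row["treatment"], row["time"]), 1.0)
        log2_eff = k * u[:, i]
        if row["treatment"] != design.vehicle:
            log2_eff = log2_eff + lfc[:, pair_index[pair_key(row["treatment"], row["time"])]]
        mean[:, s] = lib[s] * p * np.exp2(log2_eff)

    disp = np.broadcast_to(
        np.asarray(design.dispersion, dtype=float).reshape(-1, 1), (g, 1)
    ) * np.ones((1, n_s))
    lam = rng.gamma(shape=1.0 / disp, scale=mean * disp)
    counts = rng.poisson(lam).astype(np.int64)

    experiment = CountExperiment(
        pd.DataFrame(counts, index=genes, columns=samples.index), samples
    )
    truth = SimTruth(
        motif_labels=pd.Series(
            [design.motif_spec[k].label for k in motif_idx], index=genes, name="motif"
        ),
        lfc=pd.DataFrame(lfc, index=genes, columns=[pair_key(*pr) for pr in pairs]),
        variance_factors={
            (t, tp): design.variance_inflation.get((t, tp), 1.0)
            for t in design.treatments
            for tp in design.timepoints
        },
    )
    return experiment, truth


def planted_parameters(design: SimDesign):
    """Planted motif parameters as arrays: (q (K x D), pi (K,), labels)."""
    q = np.stack([m.q for m in design.motif_spec])
    pi = np.array([m.proportion for m in design.motif_spec])
    labels = [m.label for m in design.motif_spec]
    return q, pi, labels


def motif_recovery_errors(q_fit, pi_fit, q_true, pi_true) -> dict:
    """Recovery errors of a fitted motif mixture against planted parameters.

    Fitted motifs are matched to planted ones by the permutation minimizing
    the total L1 distance between Q rows. Returns the mean per-entry absolute
    Q error, the max Q entry error, the max pi error, and the permutation
    (fitted index for each planted motif).
    """
    from itertools import permutations

    q_fit = np.asarray(q_fit, dtype=float)
    q_true = np.asarray(q_true, dtype=float)
    pi_fit = np.asarray(pi_fit, dtype=float)
    pi_true = np.asarray(pi_true, dtype=float)
    if q_fit.shape != q_true.shape:
        raise ValueError(f"Q shapes differ: {q_fit.shape} vs {q_true.shape}")
    k = q_true.shape[0]
    best_perm, best_cost = None, np.inf
    for perm in permutations(range(k)):
        cost = float(np.abs(q_fit[list(perm)] - q_true).sum())
        if cost < best_cost:
            best_cost, best_perm = cost, perm
    perm = list(best_perm)
    q_err = np.abs(q_fit[perm] - q_true)
    pi_err = np.abs(pi_fit[perm] - pi_true)
    return {
        "mean_q_l1": float(q_err.mean()),
        "max_q_err": float(q_err.max()),
        "max_pi_err": float(pi_err.max()),
        "permutation": perm,
    }


def ll4(x, b: float, c: float, e: float):
    """Four-parameter log-logistic with upper asymptote fixed at one."""
    x = np.asarray(x, dtype=float)
    return c + (1.0 - c) / (1.0 + np.exp(b * (np.log(x) - np.log(e))))


def simulate_viability_plate(
    true_params: dict,
    concentrations=VIABILITY_CONCENTRATIONS,
    n_reps: int = 4,
    noise_sd: float = 0.02,
    background: float = 100.0,
    scale: float = 1000.0,
    n_background_wells: int = 6,
    plate_id: str = "P1",
    vehicle: str = VEHICLE,
    seed: int = 0,
) -> pd.DataFrame:
    """One viability plate: quadruplicate drug wells, volume-matched vehicle
    wells at every concentration, and no-cell background wells.

    ``true_params`` maps drug -> (b, c, e) of the planted log-logistic curve.
    RFLU = background + scale * (viability + Gaussian noise).
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    for drug, (b, c, e) in true_params.items():
        if e <= 0:
            raise ValueError(f"{drug}: e must be > 0")
        if not (0 <= c < 1):
            raise ValueError(f"{drug}: c must be in [0, 1)")
    rng = np.random.default_rng(seed)
    rows = []
    well = 0
    for _ in range(n_background_wells):
        well += 1
        rows.append((plate_id, f"W{well:03d}", "NONE", 0.0,
                     background + scale * rng.normal(0.0, noise_sd), True))
    for conc in concentrations:
        for _ in range(n_reps):
            well += 1
            rows.append((plate_id, f"W{well:03d}", vehicle, conc,
                         background + scale * (1.0 + rng.normal(0.0, noise_sd)), False))
    for drug, (b, c, e) in true_params.items():
        for conc in concentrations:
            v = float(ll4(conc, b, c, e))
            for _ in range(n_reps):
                well += 1
                rows.append((plate_id, f"W{well:03d}", drug, conc,
                             background + scale * (v + rng.normal(0.0, noise_sd)), False))
    return pd.DataFrame(
        rows, columns=["plate", "well", "drug", "conc_uM", "rflu", "is_background"]
    )


@dataclass
class CalciumTraceSim:
    """Simulated fluorescence recording plus the planted event times."""

    time_s: np.ndarray
    intensity: np.ndarray
    event_times: np.ndarray
    fs: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_s": self.time_s, "intensity": self.intensity})


def simulate_calcium_trace(
    rate_hz: float,
    rise_tau: float = 0.05,
    decay_tau: float = 0.25,
    amplitude: float = 2.0,
    duration_s: float = 10.0,
    fs: float = 31.34,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> CalciumTraceSim:
    """Baseline-1 trace with regular transients at ``rate_hz``.

    Events sit at (i + 0.5) / rate_hz; an event whose kernel peak would fall
    beyond the last recorded frame is not planted, so ``event_times`` lists
    exactly the transients observable in the trace.

    Each transient is ``amplitude * (1 - exp(-t/rise_tau)) * exp(-t/decay_tau)``
    normalized so its maximum equals ``amplitude``; Gaussian noise of SD
    ``noise_sd`` is added frame-wise.
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be > 0")
    if decay_tau <= 0:
        raise ValueError("decay_tau must be > 0")
    if rise_tau <= 0:
        raise ValueError("rise_tau must be > 0")
    if fs <= 2.0 * rate_hz:
        raise ValueError("fs must exceed twice the beat rate")
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs

    # normalize the rise*decay kernel to unit peak
    t_peak = rise_tau * np.log1p(decay_tau / rise_tau)
    peak_val = (1.0 - np.exp(-t_peak / rise_tau)) * np.exp(-t_peak / decay_tau)

    # periodic events; keep only those whose kernel peak falls inside the
    # recorded frames, so event_times is exactly the observable truth
    event_times = np.arange(0.5 / rate_hz, duration_s, 1.0 / rate_hz)
    event_times = event_times[event_times + t_peak <= t[-1]]
    intensity = np.ones(n)
    for t0 in event_times:
        tau = t - t0
        mask = tau >= 0
        intensity[mask] += (
            amplitude
            * (1.0 - np.exp(-tau[mask] / rise_tau))
            * np.exp(-tau[mask] / decay_tau)
            / peak_val
        )
    if noise_sd > 0:
        intensity = intensity + rng.normal(0.0, noise_sd, n)
    return CalciumTraceSim(t, intensity, event_times, fs)
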