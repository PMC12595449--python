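"""Synthetic cohorts: behavioral trajectories, PIR activity streams and
RNA-seq counts with the statistical structure the downstream analyses
assume.

The generator emulates a monoiodoacetate (MIA) joint-pain study: injury at
day 0 produces a sensory burden that rises to a plateau within days;
treatment windows (an FKBP51 inhibitor given "early", bracketing injury, or
"late", after pain is established) multiplicatively rescue the burden while
active, with the early window leaving a lasting residual rescue. One latent
standard-normal frailty factor per animal scales both the sensory burden
and the susceptibility to late emotional comorbidities, which is what makes
early pain burden predictive of late anhedonia. A configurable fraction of
injured animals is resilient: their sucrose preference never drops.

Activity streams come from a two-state (active/inactive) Markov chain per
10-s epoch whose transition probabilities differ between light and dark
phase and are sinusoidally modulated with a 24-h period; counts in active
epochs are Poisson. Injury reduces dark-phase bout persistence, which
fragments rhythms exactly the way the actigraphy statistics measure.

Counts are negative-binomial with log-normal library sizes, a planted set
of treatment DEGs, and a planted set of genes whose log-mean is linear in
each sample's log mechanical threshold.

All randomness flows from a root seed; per-animal / per-matrix child
streams are derived with ``numpy.random.SeedSequence`` spawn keys so any
subset can be regenerated without replaying the whole cohort.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.stats import norm

from .actigraphy import ActivityStream

__all__ = [
    "CohortDesign",
    "TrajectoryParams",
    "ActivitySimParams",
    "CountSimParams",
    "generate_cohort",
    "generate_activity_stream",
    "generate_counts",
    "default_design",
    "default_count_samples",
]

ASSAYS = ("vf_threshold_g", "wb_pct", "spt_pct", "oft_center_s", "affective_s")


def _child_rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=key))


@dataclass(frozen=True)
class CohortDesign:
    n_per_group: int = 6
    sexes: tuple[str, ...] = ("male", "female")
    groups: tuple[str, ...] = ("control", "MIA_vehicle")
    timepoints_days: tuple[float, ...] = (
        -1.0, 3.0, 7.0, 10.0, 14.0, 21.0, 28.0, 42.0, 60.0, 90.0, 120.0, 180.0,
    )
    #: group -> [(start_day, end_day)] during which the compound is active.
    treatment_windows: Mapping[str, tuple[tuple[float, float], ...]] = field(
        default_factory=dict
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 1:
            raise ValueError("n_per_group must be >= 1")
        if not self.groups:
            raise ValueError("empty group list")
        if len(set(self.groups)) != len(self.groups):
            raise ValueError("duplicate group labels")
        tp = self.timepoints_days
        if any(b <= a for a, b in zip(tp, tp[1:])):
            raise ValueError("timepoints must be strictly increasing")
        for g, wins in self.treatment_windows.items():
            if g not in self.groups:
                raise ValueError(f"treatment window for unknown group {g!r}")
            for lo, hi in wins:
                if hi <= lo:
                    raise ValueError("treatment window must have start < end")


@dataclass(frozen=True)
class TrajectoryParams:
    baseline_threshold_g: float = 1.0
    injury_drop: float = 0.8        # fractional threshold reduction at plateau
    rise_rate_per_day: float = 0.5
    treatment_rescue: float = 0.7
    persistent_rescue_early: float = 0.5
    frailty_sd: float = 0.3
    resilient_fraction: float = 0.3
    comorbidity_onset_day: float = 90.0
    comorbidity_onset_scale_days: float = 15.0
    noise_sd: Mapping[str, float] = field(
        default_factory=lambda: {
            "vf_threshold_log10": 0.08,
            "wb_pct": 2.5,
            "spt_pct": 4.0,
            "oft_center_s": 5.0,
            "affective_s": 1.5,
        }
    )

    def __post_init__(self) -> None:
        for name in ("injury_drop", "treatment_rescue",
                     "persistent_rescue_early", "resilient_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.baseline_threshold_g <= 0:
            raise ValueError("baseline threshold must be positive")
        if self.rise_rate_per_day <= 0:
            raise ValueError("rise rate must be positive")
        if self.frailty_sd < 0 or any(s < 0 for s in self.noise_sd.values()):
            raise ValueError("standard deviations must be nonnegative")


def _injury_burden(
    days: np.ndarray,
    params: TrajectoryParams,
    windows: tuple[tuple[float, float], ...],
    frailty_mult: float,
) -> np.ndarray:
    """Fractional burden in [0, 1): saturating rise to plateau,
    multiplicatively rescued inside treatment windows (with a residual
    rescue after an early, pre-day-7 window closes), then warped by the
    per-animal frailty factor as an exponent on the survival scale:
    B = 1 - (1 - b0)**frailty_mult. The warp is monotone in frailty, never
    saturates, and makes log10(1 - B) exactly linear in the frailty
    multiplier, which is what couples early sensory burden to late
    comorbidity across assays."""
    rise = 1.0 - np.exp(-params.rise_rate_per_day * np.maximum(days, 0.0))
    b0 = params.injury_drop * rise
    rescue = np.ones_like(b0)
    for lo, hi in windows:
        inside = (days >= lo) & (days <= hi)
        rescue[inside] *= 1.0 - params.treatment_rescue
        if lo <= 7.0:  # early window: lasting residual effect afterwards
            after = days > hi
            rescue[after] *= 1.0 - params.persistent_rescue_early
    return 1.0 - (1.0 - b0 * rescue) ** frailty_mult


def generate_cohort(
    design: CohortDesign, params: TrajectoryParams
) -> tuple["pd.DataFrame", pd.DataFrame]:
    """Simulate a longitudinal behavioral cohort.

    Returns ``(records, truth)``: a long-format table (animal_id, sex,
    group, day, assay, value) and a per-animal truth table with the latent
    frailty factor and resilience label. Control groups ("control" in the
    label, or groups with no injury) carry zero burden. Reproducible from
    the design seed alone.
    """
    days = np.asarray(design.timepoints_days, dtype=float)
    rows: list[tuple] = []
    truth_rows: list[tuple] = []
    for gi, group in enumerate(design.groups):
        injured = not group.lower().startswith("control")
        windows = tuple(design.treatment_windows.get(group, ()))
        for si, sex in enumerate(design.sexes):
            for ai in range(design.n_per_group):
                rng = _child_rng(design.seed, gi, si, ai)
                animal = f"{group}_{sex[0]}{ai:02d}"
                z = rng.standard_normal()
                frailty_mult = float(np.exp(params.frailty_sd * z))
                # Resilience shares the frailty axis (susceptibility score
                # z + independent noise, thresholded at the quantile that
                # keeps the marginal resilient fraction): low-frailty
                # animals are the ones whose sucrose preference holds.
                # With frailty_sd = 0 the score has no phenotypic effect,
                # so the early-late null is preserved exactly.
                score = (z + rng.standard_normal()) / np.sqrt(2.0)
                resilient = bool(score < norm.ppf(params.resilient_fraction))
                burden = (
                    _injury_burden(days, params, windows, frailty_mult)
                    if injured else np.zeros_like(days)
                )
                # Emotional comorbidity develops late (logistic onset) and
                # only in non-resilient animals; shares the frailty factor.
                onset = 1.0 / (1.0 + np.exp(
                    -(days - params.comorbidity_onset_day)
                    / params.comorbidity_onset_scale_days
                ))
                comorb = np.zeros_like(days) if resilient else burden * onset
                sd = params.noise_sd
                vf = params.baseline_threshold_g * 10.0 ** (
                    np.log10(1.0 - burden)
                    + sd.get("vf_threshold_log10", 0.0) * rng.standard_normal(days.size)
                )
                wb = (
                    50.0 - 20.0 * burden
                    + sd.get("wb_pct", 0.0) * rng.standard_normal(days.size)
                )
                spt = (
                    75.0 - 30.0 * comorb
                    + sd.get("spt_pct", 0.0) * rng.standard_normal(days.size)
                )
                oft = np.maximum(
                    40.0 - 25.0 * comorb
                    + sd.get("oft_center_s", 0.0) * rng.standard_normal(days.size),
                    0.0,
                )
                aff = np.clip(
                    2.0 + 12.0 * burden
                    + sd.get("affective_s", 0.0) * rng.standard_normal(days.size),
                    0.0, 30.0,
                )
                for assay, vals in zip(ASSAYS, (vf, wb, spt, oft, aff)):
                    for d, v in zip(days, vals):
                        rows.append((animal, sex, group, float(d), assay, float(v)))
                truth_rows.append((animal, sex, group, z, frailty_mult,
                                   resilient and injured))
    records = pd.DataFrame(
        rows, columns=["animal_id", "sex", "group", "day", "assay", "value"]
    )
    truth = pd.DataFrame(
        truth_rows,
        columns=["animal_id", "sex", "group", "frailty_z", "frailty_mult",
                 "resilient"],
    )
    return records, truth


@dataclass(frozen=True)
class ActivitySimParams:
    epoch_s: int = 10
    days: int = 14
    lights_on_zt0_clock: str = "07:00"
    p_stay_active_dark: float = 0.98
    p_stay_active_light: float = 0.90
    p_become_active_dark: float = 0.02
    p_become_active_light: float = 0.005
    amplitude: float = 0.5
    injury_fragmentation: float = 0.5
    lambda_active: float = 3.0

    def __post_init__(self) -> None:
        for name in ("p_stay_active_dark", "p_stay_active_light",
                     "p_become_active_dark", "p_become_active_light"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0, 1)")
        if self.amplitude < 0 or self.injury_fragmentation < 0:
            raise ValueError("amplitude and fragmentation must be >= 0")
        if self.days < 1:
            raise ValueError("days must be >= 1")
        if self.lambda_active <= 0:
            raise ValueError("lambda_active must be positive")


def generate_activity_stream(
    params: ActivitySimParams,
    injured: bool = False,
    seed: int = 0,
    animal_id: str = "sim",
) -> ActivityStream:
    """Simulate one PIR stream from the two-state Markov model.

    Transition probabilities toward the active state are scaled by
    ``1 + amplitude * cos(2*pi*(ZT - 18)/24)`` (peaking mid-dark) and
    clipped into (0, 1), with a warning when clipping occurs. Injury
    divides the odds of remaining active in the dark by
    ``1 + injury_fragmentation``, shortening dark-phase activity bouts
    without changing the light phase.
    """
    rng = _child_rng(seed, 997)
    epd = 86400 // params.epoch_s
    n = params.days * epd
    zt = (np.arange(n) % epd) * (24.0 / epd)
    dark = zt >= 12.0
    mod = 1.0 + params.amplitude * np.cos(2.0 * np.pi * (zt - 18.0) / 24.0)
    p_stay_dark = params.p_stay_active_dark
    if injured and params.injury_fragmentation > 0:
        odds = p_stay_dark / (1.0 - p_stay_dark)
        odds /= 1.0 + params.injury_fragmentation
        p_stay_dark = odds / (1.0 + odds)
    p_stay = np.where(dark, p_stay_dark, params.p_stay_active_light)
    p_become = np.where(
        dark, params.p_become_active_dark, params.p_become_active_light
    ) * mod
    eps = 1e-9
    if (p_become <= 0).any() or (p_become >= 1).any():
        warnings.warn("modulated transition probabilities clipped into (0, 1)")
    p_become = np.clip(p_become, eps, 1.0 - eps)
    u = rng.random(n)
    active = np.empty(n, dtype=bool)
    state = bool(rng.random() < 0.5)
    for i in range(n):
        state = (u[i] < p_stay[i]) if state else (u[i] < p_become[i])
        active[i] = state
    counts = np.zeros(n, dtype=np.int64)
    n_active = int(active.sum())
    if n_active:
        counts[active] = rng.poisson(params.lambda_active, n_active) + 1
    return ActivityStream(
        animal_id=animal_id, counts=counts, epoch_s=params.epoch_s,
        lights_on_epoch=0,
    )


@dataclass(frozen=True)
class CountSimParams:
    n_genes: int = 2000
    library_size_log_mean: float = float(np.log(2.0e7))
    library_size_log_sd: float = 0.2
    #: NB size parameter r: variance = mu + mu^2 / r (larger r = less noise).
    dispersion: float = 10.0
    n_deg_treatment: int = 200
    log2fc_treatment: float = 1.5
    n_pheno_linked: int = 100
    pheno_slope: float = 4.0  # log2CPM per unit log10-gram threshold
    baseline_log2cpm_mean: float = 4.0
    baseline_log2cpm_sd: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")
        if self.n_deg_treatment + self.n_pheno_linked > self.n_genes:
            raise ValueError("planted gene totals exceed n_genes")
        if min(self.n_genes, self.n_deg_treatment, self.n_pheno_linked) < 0:
            raise ValueError("gene counts must be nonnegative")


def default_count_samples(
    n_per_cell: int = 8, seed: int = 0
) -> pd.DataFrame:
    """A 2x2 (treatment x timing) sample sheet with realistic covariates.

    Vehicle-treated injured animals sit at low mechanical thresholds
    (~0.07 g); SAFit2 rescues thresholds (~0.4 g). The guarding index
    varies between animals independently of treatment here, so the two
    phenotype covariates are decoupled and the correlation filter's
    exclusion arm has a well-defined null. Covariate noise is independent
    of the count noise.
    """
    rng = _child_rng(seed, 499)
    rows = []
    for timing in ("early", "late"):
        for treatment in ("SAFit2", "vehicle"):
            for i in range(n_per_cell):
                thr_mu = np.log10(0.4) if treatment == "SAFit2" else np.log10(0.07)
                rows.append((
                    f"{timing}_{treatment}_{i:02d}",
                    treatment,
                    timing,
                    thr_mu + 0.15 * rng.standard_normal(),
                    max(0.25 + 0.10 * rng.standard_normal(), 0.0),
                ))
    return pd.DataFrame(
        rows,
        columns=["sample_id", "treatment", "timing", "threshold_log_g",
                 "guarding_index"],
    ).set_index("sample_id")


def generate_counts(
    params: CountSimParams, samples: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a gene x sample NB count matrix with planted structure.

    ``samples`` must carry treatment, timing, threshold_log_g and
    guarding_index (see :func:`default_count_samples`). Returns
    ``(counts, truth)`` where truth labels each gene as treatment-DEG
    (with its planted signed log2FC) and/or phenotype-linked (with its
    slope). Treatment DEGs shift the log2 mean in SAFit2 samples by
    +-log2fc_treatment (alternating signs); phenotype-linked genes have
    log2 mean linear in the sample's log10 threshold.
    """
    required = {"treatment", "timing", "threshold_log_g", "guarding_index"}
    if not required <= set(samples.columns):
        raise ValueError(f"sample sheet missing {required - set(samples.columns)}")
    rng = _child_rng(params.seed, 7919)
    g, s = params.n_genes, len(samples)
    genes = [f"gene{i:05d}" for i in range(g)]
    base = (
        params.baseline_log2cpm_mean
        + params.baseline_log2cpm_sd * rng.standard_normal(g)
    )
    perm = rng.permutation(g)
    deg_idx = perm[: params.n_deg_treatment]
    pheno_idx = perm[
        params.n_deg_treatment: params.n_deg_treatment + params.n_pheno_linked
    ]
    is_treated = (samples["treatment"] == "SAFit2").to_numpy(dtype=float)
    thr = samples["threshold_log_g"].to_numpy(dtype=float)
    thr_c = thr - thr.mean()
    # Signs of planted effects are assigned greedily so the expected total
    # RNA mass per sample stays balanced: counts are compositional, and an
    # unbalanced spike-in would shift every null gene's CPM (the artifact
    # TMM-style normalization exists to absorb).
    deg_sign = _balanced_signs(
        2.0 ** base[deg_idx], 2.0 ** params.log2fc_treatment
    )
    # Covariate-linked genes flip their fold per sample (2**(+-slope*thr)),
    # so the balance condition is equal total mass of +slope and -slope
    # genes, not the fixed-fold condition used for the treatment DEGs.
    pheno_sign = _equal_mass_signs(2.0 ** base[pheno_idx])
    log2mu = np.tile(base[:, None], (1, s))
    log2mu[deg_idx] += np.outer(deg_sign * params.log2fc_treatment, is_treated)
    log2mu[pheno_idx] += np.outer(
        pheno_sign * params.pheno_slope, thr_c
    )
    lib = np.exp(
        params.library_size_log_mean
        + params.library_size_log_sd * rng.standard_normal(s)
    )
    mass = 2.0 ** log2mu
    frac = mass / mass.sum(axis=0, keepdims=True)
    mu = frac * lib[None, :]
    r = params.dispersion
    p_nb = r / (r + mu)
    counts = rng.negative_binomial(r, p_nb)
    counts_df = pd.DataFrame(counts, index=genes, columns=samples.index)
    truth = pd.DataFrame(
        {
            "is_treatment_deg": False,
            "planted_log2fc": 0.0,
            "is_pheno_linked": False,
            "planted_pheno_slope": 0.0,
        },
        index=pd.Index(genes, name="gene"),
    )
    truth.iloc[deg_idx, truth.columns.get_loc("is_treatment_deg")] = True
    truth.iloc[deg_idx, truth.columns.get_loc("planted_log2fc")] = (
        deg_sign * params.log2fc_treatment
    )
    truth.iloc[pheno_idx, truth.columns.get_loc("is_pheno_linked")] = True
    truth.iloc[pheno_idx, truth.columns.get_loc("planted_pheno_slope")] = (
        pheno_sign * params.pheno_slope
    )
    return counts_df, truth


def _balanced_signs(masses: np.ndarray, fold: float) -> np.ndarray:
    """Assign +1/-1 effect signs so the summed linear-scale mass change is
    near zero (greedy, heaviest genes first)."""
    n = masses.size
    signs = np.ones(n)
    if n == 0 or fold == 1.0:
        return signs
    order = np.argsort(-masses)
    delta = 0.0
    up = fold - 1.0
    down = 1.0 / fold - 1.0
    for i in order:
        d_up = masses[i] * up
        d_down = masses[i] * down
        if abs(delta + d_up) <= abs(delta + d_down):
            signs[i] = 1.0
            delta += d_up
        else:
            signs[i] = -1.0
            delta += d_down
    return signs


def _equal_mass_signs(masses: np.ndarray) -> np.ndarray:
    """Assign +1/-1 so the two sign groups carry near-equal total mass."""
    signs = np.ones(masses.size)
    delta = 0.0
    for i in np.argsort(-masses):
        if delta > 0:
            signs[i] = -1.0
            delta -= masses[i]
        else:
            signs[i] = 1.0
            delta += masses[i]
    return signs


def default_design(
    n_per_group: int = 6, seed: int = 0
) -> tuple[CohortDesign, TrajectoryParams]:
    """The packaged demo study: control, vehicle-treated MIA, and MIA with
    the inhibitor given early (days -3 to 14) or late (days 20 to 34)."""
    design = CohortDesign(
        n_per_group=n_per_group,
        groups=("control", "MIA_vehicle", "MIA_safit2_early", "MIA_safit2_late"),
        treatment_windows={
            "MIA_safit2_early": ((-3.0, 14.0),),
            "MIA_safit2_late": ((20.0, 34.0),),
        },
        seed=seed,
    )
    return design, TrajectoryParams()
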