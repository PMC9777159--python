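"""Virtual neonatal cohorts and sparse opportunistic concentration datasets.

The generator emulates the covariate structure of a 78-neonate meropenem
study population: a preterm/term mixture of gestational ages, log-normal
postnatal age, birth weight coupled to gestational age through a log-linear
fetal-growth regression, postnatal weight gain, and right-skewed renal/
hepatic laboratory markers.  Default parameters are calibrated to the study
population's summary statistics (GA mean 35.0 SD 4.65 wk, median 36.5;
PNA median 12 d, range 1-113; CW mean 2661 SD 927 g, median 2680; 44.9%
of neonates with GA > 37 wk), so downstream estimation and simulation
stages can be exercised without the (unavailable) real data.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import TYPE_CHECKING, Sequence

import numpy as np
from scipy import stats

from .pkmodel import DoseEvent, PopModel, concentration, individual_params

if TYPE_CHECKING:  # pragma: no cover
    from .dataset import StudyDataset

#: Assay lower limit of quantification (mg/L).
LLOQ_MG_L = 0.2


@dataclass(frozen=True)
class CovariateRecord:
    """One neonate's demographic and laboratory covariates.

    Units: GA and PMA in weeks, PNA in days, weights in grams, creatinine
    in umol/L, urea nitrogen in mmol/L, albumin in g/L.  PMA is the
    construction identity GA + PNA/7.
    """

    ga_weeks: float
    pna_days: float
    pma_weeks: float
    bw_g: float
    cw_g: float
    crea_umol_L: float
    bun_mmol_L: float
    alb_g_L: float

    def __post_init__(self) -> None:
        for name in (
            "ga_weeks", "pna_days", "pma_weeks", "bw_g",
            "cw_g", "crea_umol_L", "bun_mmol_L", "alb_g_L",
        ):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")
        expected_pma = self.ga_weeks + self.pna_days / 7.0
        if abs(self.pma_weeks - expected_pma) > 1e-9:
            raise ValueError(
                f"pma_weeks {self.pma_weeks} != ga + pna/7 = {expected_pma}"
            )
        if not 400.0 <= self.cw_g <= 6000.0:
            raise ValueError(f"cw_g {self.cw_g} outside plausibility window [400, 6000]")
        if not 22.0 <= self.ga_weeks <= 46.0:
            raise ValueError(f"ga_weeks {self.ga_weeks} outside [22, 46]")

    @property
    def cw_kg(self) -> float:
        return self.cw_g / 1000.0


def make_record(
    ga_weeks: float,
    pna_days: float,
    bw_g: float,
    cw_g: float,
    crea_umol_L: float = 23.8,
    bun_mmol_L: float = 3.79,
    alb_g_L: float = 25.6,
) -> CovariateRecord:
    """Build a record with PMA computed from the GA + PNA/7 identity."""
    return CovariateRecord(
        ga_weeks=ga_weeks,
        pna_days=pna_days,
        pma_weeks=ga_weeks + pna_days / 7.0,
        bw_g=bw_g,
        cw_g=cw_g,
        crea_umol_L=crea_umol_L,
        bun_mmol_L=bun_mmol_L,
        alb_g_L=alb_g_L,
    )


@dataclass(frozen=True)
class TruncNorm:
    """Truncated normal; scale 0 degenerates to a point mass at loc."""

    loc: float
    scale: float
    lower: float
    upper: float

    def __post_init__(self) -> None:
        if self.lower >= self.upper:
            raise ValueError(f"truncation bounds unordered: [{self.lower}, {self.upper}]")
        if self.scale < 0:
            raise ValueError("scale must be >= 0")

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.scale == 0:
            return np.full(n, self.loc)
        a = (self.lower - self.loc) / self.scale
        b = (self.upper - self.loc) / self.scale
        return stats.truncnorm.rvs(
            a, b, loc=self.loc, scale=self.scale, size=n, random_state=rng
        )


@dataclass(frozen=True)
class TruncLogNorm:
    """Log-normal truncated to [lower, upper] on the natural scale."""

    log_loc: float       # median = exp(log_loc)
    log_scale: float
    lower: float
    upper: float

    def __post_init__(self) -> None:
        if not 0 < self.lower < self.upper:
            raise ValueError(f"truncation bounds unordered: [{self.lower}, {self.upper}]")
        if self.log_scale < 0:
            raise ValueError("log_scale must be >= 0")

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.log_scale == 0:
            return np.full(n, np.exp(self.log_loc))
        a = (np.log(self.lower) - self.log_loc) / self.log_scale
        b = (np.log(self.upper) - self.log_loc) / self.log_scale
        z = stats.truncnorm.rvs(a, b, size=n, random_state=rng)
        return np.exp(self.log_loc + self.log_scale * z)


@dataclass(frozen=True)
class GaMixture:
    """Preterm/term two-component truncated-normal gestational-age mixture.

    Neonatal GA distributions are left-skewed: a narrow term cluster near
    39-40 wk plus a broad preterm tail. A single normal cannot match the
    study's mean 35.0 / median 36.5 / 44.9% > 37 wk simultaneously.
    """

    w_term: float = 0.46
    term: TruncNorm = field(
        default_factory=lambda: TruncNorm(39.2, 1.3, 26.3, 42.1)
    )
    preterm: TruncNorm = field(
        default_factory=lambda: TruncNorm(31.6, 3.0, 26.3, 42.1)
    )

    def __post_init__(self) -> None:
        if not 0.0 <= self.w_term <= 1.0:
            raise ValueError("w_term must be in [0, 1]")

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        is_term = rng.random(n) < self.w_term
        out = np.empty(n)
        n_term = int(is_term.sum())
        out[is_term] = self.term.sample(n_term, rng)
        out[~is_term] = self.preterm.sample(n - n_term, rng)
        return out


@dataclass(frozen=True)
class WeightModel:
    """Birth weight from GA (log-linear fetal growth) and postnatal gain.

    ln(BW) = intercept + slope*GA + N(0, bw_sd); BW clipped to bw_range.
    CW = BW * (1 + gain_per_day * max(PNA - gain_lag_days, 0)) * exp(N(0, cw_sd)),
    clipped to cw_range.
    """

    intercept: float = 4.49
    slope: float = 0.0916
    bw_sd: float = 0.10
    bw_range: tuple[float, float] = (480.0, 4100.0)
    gain_per_day: float = 0.011
    gain_lag_days: float = 7.0
    cw_sd: float = 0.03
    cw_range: tuple[float, float] = (980.0, 5310.0)

    def sample(
        self, ga: np.ndarray, pna: np.ndarray, rng: np.random.Generator
    ) -> tuple[np.ndarray, np.ndarray]:
        log_bw = self.intercept + self.slope * ga
        if self.bw_sd > 0:
            log_bw = log_bw + rng.normal(0.0, self.bw_sd, size=ga.shape)
        bw = np.clip(np.exp(log_bw), *self.bw_range)
        growth = 1.0 + self.gain_per_day * np.maximum(pna - self.gain_lag_days, 0.0)
        cw = bw * growth
        if self.cw_sd > 0:
            cw = cw * np.exp(rng.normal(0.0, self.cw_sd, size=ga.shape))
        return bw, np.clip(cw, *self.cw_range)


@dataclass(frozen=True)
class CohortSpec:
    """Cohort size, seed, and covariate distribution parameters."""

    n_subjects: int = 78
    seed: int | None = None
    ga: GaMixture = field(default_factory=GaMixture)
    pna: TruncLogNorm = field(
        default_factory=lambda: TruncLogNorm(np.log(12.0), 0.875, 1.0, 113.0)
    )
    crea: TruncLogNorm = field(
        default_factory=lambda: TruncLogNorm(np.log(23.8), 0.785, 1.1, 145.2)
    )
    bun: TruncLogNorm = field(
        default_factory=lambda: TruncLogNorm(np.log(3.79), 0.547, 0.5, 19.6)
    )
    alb: TruncNorm = field(
        default_factory=lambda: TruncNorm(26.3, 5.84, 16.7, 44.6)
    )
    weight: WeightModel = field(default_factory=WeightModel)

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")

    @classmethod
    def degenerate(cls, n_subjects: int = 1) -> "CohortSpec":
        """Every covariate pinned at its population median (zero variance)."""
        pin = TruncNorm(36.5, 0.0, 22.0, 46.0)
        return cls(
            n_subjects=n_subjects,
            ga=GaMixture(w_term=1.0, term=pin, preterm=pin),
            pna=TruncLogNorm(np.log(12.0), 0.0, 1.0, 113.0),
            crea=TruncLogNorm(np.log(23.8), 0.0, 1.1, 145.2),
            bun=TruncLogNorm(np.log(3.79), 0.0, 0.5, 19.6),
            alb=TruncNorm(25.6, 0.0, 16.7, 44.6),
            weight=WeightModel(
                intercept=float(np.log(2680.0)), slope=0.0, bw_sd=0.0,
                gain_per_day=0.0, cw_sd=0.0,
            ),
        )


def generate_cohort(
    spec: CohortSpec, seed: int | None = None
) -> list[CovariateRecord]:
    """Draw a virtual cohort; deterministic given the seed.

    ``seed`` overrides ``spec.seed`` when given.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    n = spec.n_subjects
    ga = spec.ga.sample(n, rng)
    pna = spec.pna.sample(n, rng)
    bw, cw = spec.weight.sample(ga, pna, rng)
    crea = spec.crea.sample(n, rng)
    bun = spec.bun.sample(n, rng)
    alb = spec.alb.sample(n, rng)
    return [
        make_record(
            ga_weeks=float(ga[i]),
            pna_days=float(pna[i]),
            bw_g=float(bw[i]),
            cw_g=float(cw[i]),
            crea_umol_L=float(crea[i]),
            bun_mmol_L=float(bun[i]),
            alb_g_L=float(alb[i]),
        )
        for i in range(n)
    ]


@dataclass(frozen=True)
class SamplingScheme:
    """Dosing regimen and sampling design used to simulate a study.

    The default is the sparse opportunistic design of the emulated study:
    20 mg/kg q8h 1-h infusions over 5 treatment days, with 1 + Poisson(0.4)
    samples per subject (mean 1.4, so a 78-subject study yields ~110
    observations) drawn uniformly over a random treatment day.
    """

    dose_mg_per_kg: float = 20.0
    interval_h: float = 8.0
    infusion_h: float = 1.0
    n_days: int = 5
    mean_samples_per_subject: float = 1.4
    rich_offsets_h: tuple[float, ...] | None = None
    rich_dose_index: int = 6  # sample after the 7th dose (treatment day 3)

    def __post_init__(self) -> None:
        if self.infusion_h >= self.interval_h:
            raise ValueError("infusion must be shorter than the dosing interval")
        if self.mean_samples_per_subject < 1:
            raise ValueError("mean samples per subject must be >= 1")

    @classmethod
    def rich(cls, n_samples: int = 8) -> "SamplingScheme":
        """Dense design for parameter-recovery experiments.

        Samples at fixed offsets after a steady-state-ish dose (day 3),
        covering the infusion, distribution and elimination phases.
        """
        offsets = (0.5, 1.0, 1.5, 2.0, 3.0, 4.5, 6.0, 7.9)[:n_samples]
        return cls(rich_offsets_h=offsets)

    @property
    def n_doses(self) -> int:
        return int(round(self.n_days * 24.0 / self.interval_h))


def generate_dataset(
    cohort: Sequence[CovariateRecord],
    model: PopModel,
    sampling: SamplingScheme | None = None,
    seed: int | None = None,
) -> "StudyDataset":
    """Simulate a concentration study over a cohort.

    Draws log-normal etas per subject, computes noiseless concentrations
    from the closed-form infusion model, applies proportional residual
    error, and flags observations below the 0.2 mg/L quantification limit.
    True etas and individual parameters are retained for recovery tests.
    """
    from .dataset import Observation, SimTruth, StudyDataset, Subject

    if len(cohort) == 0:
        raise ValueError("cohort must not be empty")
    sampling = sampling or SamplingScheme()
    rng = np.random.default_rng(seed)
    chol = np.linalg.cholesky(
        np.asarray(model.omega) + 1e-30 * np.eye(2)
    ) if np.any(model.omega) else np.zeros((2, 2))

    subjects = []
    etas: dict[str, tuple[float, float]] = {}
    params: dict[str, IndividualParams] = {}
    for i, cov in enumerate(cohort):
        sid = f"S{i + 1:03d}"
        eta = chol @ rng.standard_normal(2)
        p = individual_params(model, cov, eta)
        amount = sampling.dose_mg_per_kg * cov.cw_kg
        doses = [
            DoseEvent(amount, k * sampling.interval_h, sampling.infusion_h)
            for k in range(sampling.n_doses)
        ]
        if sampling.rich_offsets_h is not None:
            t0 = sampling.rich_dose_index * sampling.interval_h
            times = np.array([t0 + dt for dt in sampling.rich_offsets_h])
        else:
            n_obs = 1 + rng.poisson(sampling.mean_samples_per_subject - 1.0)
            day = rng.integers(1, sampling.n_days + 1, size=n_obs)
            times = np.sort(24.0 * (day - 1) + rng.uniform(0.0, 24.0, size=n_obs))
        true_c = concentration(times, doses, p)
        eps = rng.standard_normal(times.size)
        obs_c = true_c * (1.0 + model.sigma_prop * eps)
        observations = [
            Observation(float(t), float(c), bql=bool(c < LLOQ_MG_L))
            for t, c in zip(times, obs_c)
        ]
        subjects.append(Subject(sid, cov, doses, observations))
        etas[sid] = (float(eta[0]), float(eta[1]))
        params[sid] = p

    ds = StudyDataset(subjects=subjects, truth=SimTruth(etas=etas, params=params))
    ds.validate()
    return ds
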