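"""Synthetic cohort and multiplex-plate generators.

Produces stage/treatment-homogeneous patient cohorts with the statistical
structure the downstream analysis assumes: a latent senescence factor that
loads on a subset of the 19 serum analytes and simultaneously raises the
disease-specific death hazard, a brachytherapy benefit concentrated in
high-senescence patients, and 5-year administrative censoring. Also builds a
raw bead-array plate table (standards + samples) with known ground truth for
exercising the preprocessing stage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

from .config import COHORT_DEFS, SimulationConfig


@dataclass(frozen=True)
class PatientRecord:
    """Clinical covariates and survival outcome for one subject."""

    id: str
    age: float
    stage: str          # "II" or "III"
    treatment: str      # "EBRT" or "EBRT+BT"
    time: float         # follow-up, years (> 0, <= horizon)
    event: int          # 1 = disease-specific death
    latent_z: float     # simulated only; hidden from inference


@dataclass
class CohortDataset:
    """A named cohort with aligned clinical table and analyte matrix.

    ``patients`` has columns id, age, stage, treatment, time, event,
    latent_z; ``analytes`` is indexed by patient id with one log2-scale
    column per analyte, rows aligned with ``patients``.
    """

    label: str
    patients: pd.DataFrame
    analytes: pd.DataFrame

    def __post_init__(self) -> None:
        if len(self.patients) != len(self.analytes):
            raise ValueError("patient table and analyte matrix disagree on n")
        stage, treatment = COHORT_DEFS[self.label]
        if not (self.patients["stage"] == stage).all():
            raise ValueError(f"{self.label} must be homogeneous stage {stage}")
        if not (self.patients["treatment"] == treatment).all():
            raise ValueError(
                f"{self.label} must be homogeneous treatment {treatment}")

    @property
    def n(self) -> int:
        return len(self.patients)

    @property
    def analyte_names(self) -> list[str]:
        return list(self.analytes.columns)

    def records(self) -> list[PatientRecord]:
        return [PatientRecord(**row) for row in
                self.patients.to_dict(orient="records")]

    def write(self, patients_path, analytes_path) -> None:
        self.patients.drop(columns=["latent_z"]).to_csv(
            patients_path, index=False, float_format="%.6g")
        self.analytes.to_csv(analytes_path, float_format="%.6g")

    @classmethod
    def read(cls, label: str, patients_path, analytes_path) -> "CohortDataset":
        patients = pd.read_csv(patients_path, dtype={"id": str})
        if "latent_z" not in patients.columns:
            patients["latent_z"] = np.nan
        analytes = pd.read_csv(analytes_path, index_col=0)
        analytes.index = analytes.index.astype(str)
        return cls(label=label, patients=patients,
                   analytes=analytes.loc[patients["id"].to_numpy()])


def _no_bt_log_hr(z: np.ndarray, config: SimulationConfig) -> np.ndarray:
    """Log hazard ratio of omitting brachytherapy at latent factor z."""
    lo, hi = config.log_hr_no_bt_low, config.log_hr_no_bt_high
    return lo + (hi - lo) * expit(config.bt_logistic_slope * z)


def generate_cohorts(config: SimulationConfig) -> list[CohortDataset]:
    """Draw one CohortDataset per configured group, reproducibly from seed.

    Event times are exponential given covariates (constant baseline hazard
    scaled by exp of the linear predictor); observed time is the minimum of
    event time, exponential dropout and the administrative horizon.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    names = list(config.analyte_names)
    means = np.array([config.analyte_means[a] for a in names])
    sds = np.array([config.analyte_sds[a] for a in names])
    loadings = np.array([config.sasp_loadings[a] for a in names])

    cohorts = []
    for label, n in config.group_sizes.items():
        stage, treatment = COHORT_DEFS[label]
        z = rng.standard_normal(n)
        age = np.clip(rng.normal(49.0, 10.0, size=n), 26.0, 82.0)
        analytes = means + np.outer(z, loadings) + rng.standard_normal(
            (n, len(names))) * sds

        eta = config.log_hr_senescence * z
        if stage == "III":
            eta = eta + config.log_hr_stage3
        if treatment == "EBRT":
            eta = eta + _no_bt_log_hr(z, config)
        hazard = config.baseline_hazard * np.exp(eta)
        t_event = rng.exponential(1.0, size=n) / hazard
        if config.dropout_rate > 0:
            t_drop = rng.exponential(1.0 / config.dropout_rate, size=n)
        else:
            t_drop = np.full(n, np.inf)
        t_cens = np.minimum(t_drop, config.horizon)
        time = np.minimum(t_event, t_cens)
        event = (t_event <= t_cens).astype(int)
        # follow-up must be strictly positive for risk-set arithmetic
        time = np.maximum(time, 1e-6)

        ids = [f"{label}-{i:04d}" for i in range(n)]
        patients = pd.DataFrame({
            "id": ids, "age": age, "stage": stage, "treatment": treatment,
            "time": time, "event": event, "latent_z": z,
        })
        analyte_df = pd.DataFrame(analytes, index=pd.Index(ids, name="id"),
                                  columns=names)
        cohorts.append(CohortDataset(label, patients, analyte_df))
    return cohorts


def pool_cohorts(cohorts: list[CohortDataset]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Concatenate cohorts into one clinical table + aligned analyte matrix."""
    patients = pd.concat([c.patients for c in cohorts], ignore_index=True)
    analytes = pd.concat([c.analytes for c in cohorts])
    return patients, analytes


def high_low_hazard_ratio(config: SimulationConfig,
                          high_fraction: float = 0.60) -> float:
    """Implied hazard ratio between the top ``high_fraction`` and bottom
    stratum of the latent factor.

    Uses the truncated-normal means of z above/below the split point, so a
    "generative high/low HR of 3.5" is a statement about the dichotomized
    latent factor rather than the per-unit-z effect.
    """
    from scipy.stats import norm
    z0 = norm.ppf(1.0 - high_fraction)
    mean_high = norm.pdf(z0) / high_fraction
    mean_low = -norm.pdf(z0) / (1.0 - high_fraction)
    return float(np.exp(config.log_hr_senescence * (mean_high - mean_low)))


def with_high_low_hr(config: SimulationConfig, target_hr: float,
                     high_fraction: float = 0.60) -> SimulationConfig:
    """Copy of ``config`` with the per-unit-z effect set so the implied
    high/low dichotomy hazard ratio equals ``target_hr``."""
    import dataclasses

    from scipy.stats import norm
    z0 = norm.ppf(1.0 - high_fraction)
    delta = norm.pdf(z0) / high_fraction + norm.pdf(z0) / (1.0 - high_fraction)
    return dataclasses.replace(config,
                               log_hr_senescence=np.log(target_hr) / delta)


# ---------------------------------------------------------------------------
# Raw plate fixture

#: Per-analyte true calibration: log2(MFI) = intercept + slope * log2(conc).
_CURVE_INTERCEPT = 2.0
_CURVE_SLOPE = 0.9


def true_curve_params(analyte_index: int) -> tuple[float, float]:
    """Ground-truth (intercept, slope) of the analyte's standard curve."""
    return (_CURVE_INTERCEPT + 0.05 * analyte_index,
            _CURVE_SLOPE + 0.01 * (analyte_index % 5))


def generate_plate(config: SimulationConfig, n_standards: int = 8,
                   n_replicates: int = 2, n_samples: int = 24,
                   noise_sd: float = 0.05, mean_beads: float = 80.0,
                   analytes: list[str] | None = None) -> pd.DataFrame:
    """Emit a raw multiplex plate table with known ground truth.

    Standards form a serial 4-fold dilution with known concentrations;
    sample wells carry their generative concentration in ``known_conc`` so
    quantification can be checked against truth. ``noise_sd`` is the SD of
    Gaussian noise added to log2(MFI).
    """
    if n_standards < 4:
        raise ValueError("need at least 4 standards for curve fitting")
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 777)))
    names = list(analytes) if analytes is not None else list(config.analyte_names)
    rows = []
    for ai, analyte in enumerate(names):
        b0, b1 = true_curve_params(list(config.analyte_names).index(analyte)
                                   if analyte in config.analyte_names else ai)
        std_conc = 10000.0 / 4.0 ** np.arange(n_standards)
        for si, conc in enumerate(std_conc):
            for rep in range(n_replicates):
                log2_mfi = b0 + b1 * np.log2(conc) + rng.normal(0, noise_sd)
                rows.append({
                    "well": f"STD{si + 1}-{rep + 1}-{analyte}",
                    "analyte": analyte,
                    "mfi": float(2.0 ** log2_mfi),
                    "bead_count": int(rng.poisson(mean_beads)),
                    "replicate": f"std-{analyte}-{si + 1}",
                    "is_standard": 1,
                    "known_conc": float(conc),
                })
        true_conc = 2.0 ** rng.normal(config.analyte_means.get(analyte, 8.0),
                                      1.0, size=n_samples)
        for wi, conc in enumerate(true_conc):
            for rep in range(n_replicates):
                log2_mfi = b0 + b1 * np.log2(conc) + rng.normal(0, noise_sd)
                rows.append({
                    "well": f"S{wi + 1:03d}-{rep + 1}-{analyte}",
                    "analyte": analyte,
                    "mfi": float(2.0 ** log2_mfi),
                    "bead_count": int(rng.poisson(mean_beads)),
                    "replicate": f"smp-{analyte}-{wi + 1}",
                    "is_standard": 0,
                    "known_conc": float(conc),
                })
    return pd.DataFrame(rows)
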