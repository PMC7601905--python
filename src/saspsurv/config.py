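"""Configuration objects: simulation settings, panel presets, seed derivation.

The defaults encode the study design this package analyses: three
stage/treatment-homogeneous cervical-cancer cohorts (stage II with
brachytherapy, stage III with and without brachytherapy), a 19-analyte serum
protein panel of which a senescence-associated subset carries prognostic
signal, exponential event times under proportional hazards, and
administrative censoring at five years.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np
import yaml

#: The 19 serum analytes measured on the multiplex bead array (log2 scale).
ANALYTES: tuple[str, ...] = (
    "CRP", "GRO", "HGF", "IGFBP2", "LEPTIN", "MIG", "MMP1", "PDGFAA",
    "PDGFABBB", "SAA", "SCCA", "sE.Selectin", "sEGFR", "sIL1RII", "sIL2Ra",
    "sIL6R", "sTNFRI", "sTNFRII", "tPAI1",
)

#: Prognostic proteins elevated in poor-survival patients (positive loading on
#: the latent senescence factor). Leptin is prognostic too but runs opposite.
SASP_POSITIVE: tuple[str, ...] = (
    "CRP", "GRO", "HGF", "MIG", "MMP1", "SAA", "SCCA", "sIL2Ra", "tPAI1",
)

#: Named protein panels used to build multi-protein risk scores.
PANELS: dict[str, tuple[str, ...]] = {
    "p8": ("CRP", "GRO", "LEPTIN", "MIG", "MMP1", "SCCA", "SAA", "sIL2Ra"),
    "p7": ("CRP", "GRO", "LEPTIN", "MIG", "MMP1", "SCCA", "HGF"),
}

#: Cohort label -> (FIGO stage, treatment arm).
COHORT_DEFS: dict[str, tuple[str, str]] = {
    "RTBT2": ("II", "EBRT+BT"),
    "RTBT3": ("III", "EBRT+BT"),
    "RT3": ("III", "EBRT"),
}

#: Fraction of patients labelled high-SASP by a dichotomizing model, per the
#: cohort the models are optimized for (cutoff percentile = 100*(1 - high)).
HIGH_FRACTION_PRESETS: dict[str, float] = {"RTBT2": 0.60, "RT3": 0.40}


def _default_group_sizes() -> dict[str, int]:
    return {"RTBT2": 276, "RTBT3": 203, "RT3": 86}


def _default_loadings() -> dict[str, float]:
    loadings = {name: 0.0 for name in ANALYTES}
    loadings.update({name: 0.6 for name in SASP_POSITIVE})
    loadings["LEPTIN"] = -0.4
    return loadings


def _default_means() -> dict[str, float]:
    # Typical serum log2 concentrations; staggered so analytes are not
    # interchangeable on raw scale.
    return {name: 8.0 + 0.5 * i for i, name in enumerate(ANALYTES)}


def _default_sds() -> dict[str, float]:
    return {name: 1.0 for name in ANALYTES}


@dataclass
class SimulationConfig:
    """Generative settings for the synthetic three-cohort study.

    A single latent senescence factor ``z ~ N(0, 1)`` drives both the
    correlated analyte block (analyte_j = mean_j + loading_j * z + noise) and
    the hazard. The log hazard is::

        log h(t) = log(baseline_hazard)
                   + log_hr_stage3 * 1[stage III]
                   + log_hr_senescence * z
                   + noBT(z) * 1[no brachytherapy]

    where ``noBT(z)`` interpolates between ``log_hr_no_bt_low`` (z -> -inf)
    and ``log_hr_no_bt_high`` (z -> +inf) through a logistic in z, so the
    harm of omitting brachytherapy is concentrated in high-senescence
    patients. Follow-up is administratively censored at ``horizon`` years
    with independent exponential loss to follow-up.
    """

    group_sizes: dict[str, int] = field(default_factory=_default_group_sizes)
    analyte_names: tuple[str, ...] = ANALYTES
    analyte_means: dict[str, float] = field(default_factory=_default_means)
    analyte_sds: dict[str, float] = field(default_factory=_default_sds)
    sasp_loadings: dict[str, float] = field(default_factory=_default_loadings)
    baseline_hazard: float = 0.12          # events / year at covariates 0
    log_hr_stage3: float = math.log(2.3)
    log_hr_no_bt_high: float = math.log(3.3)
    log_hr_no_bt_low: float = math.log(1.0)
    log_hr_senescence: float = math.log(1.9)
    bt_logistic_slope: float = 2.0         # steepness of noBT(z) in z
    dropout_rate: float = 0.02             # exponential loss to follow-up / year
    horizon: float = 5.0                   # administrative censoring, years
    seed: int = 0

    def validate(self) -> None:
        if not self.group_sizes:
            raise ValueError("group_sizes must be non-empty")
        for label, n in self.group_sizes.items():
            if label not in COHORT_DEFS:
                raise ValueError(f"unknown cohort label {label!r}")
            if n <= 0:
                raise ValueError(f"group size for {label} must be > 0, got {n}")
        if len(self.sasp_loadings) != len(self.analyte_names):
            raise ValueError("sasp_loadings must cover every analyte")
        missing = set(self.analyte_names) - set(self.sasp_loadings)
        if missing:
            raise ValueError(f"loadings missing for {sorted(missing)}")
        for name in self.analyte_names:
            if self.analyte_sds[name] <= 0:
                raise ValueError(f"analyte_sds[{name}] must be > 0")
        if self.baseline_hazard <= 0:
            raise ValueError("baseline_hazard must be > 0")
        if self.horizon <= 0:
            raise ValueError("horizon must be > 0")
        if self.dropout_rate < 0:
            raise ValueError("dropout_rate must be >= 0")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["analyte_names"] = list(self.analyte_names)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "analyte_names" in d:
            d["analyte_names"] = tuple(d["analyte_names"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def null(self) -> "SimulationConfig":
        """Copy with all analyte loadings and the senescence effect zeroed."""
        cfg = dataclasses.replace(
            self,
            sasp_loadings={name: 0.0 for name in self.analyte_names},
            log_hr_senescence=0.0,
        )
        return cfg


def spawn_seeds(master_seed: int, n: int) -> list[int]:
    """Derive ``n`` independent 31-bit stage seeds from one master seed."""
    ss = np.random.SeedSequence(master_seed)
    return [int(s) % (2**31) for s in ss.generate_state(n)]


def resolve_panel(panel) -> tuple[str, ...]:
    """Map a preset name ('p8', 'p7') or explicit list to a protein tuple."""
    if isinstance(panel, str):
        try:
            return PANELS[panel]
        except KeyError:
            raise ValueError(f"unknown panel preset {panel!r}") from None
    return tuple(panel)
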