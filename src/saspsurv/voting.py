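"""Consensus classification by plurality voting of ensemble models.

Each model casts one binary vote (SASP-high or SASP-low) per patient. The
binary consensus calls a patient high when strictly more than 50% of models
vote high; the ternary rule adds a medium class for patients neither >75%
high-voted nor >75% low-voted. Boundary fractions resolve downward (strict
inequalities throughout).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ensemble import SASP_HIGH, RidgeCoxModel, dichotomize


@dataclass
class VoteMatrix:
    """Binary model-by-patient votes (1 = SASP-high); complete by design."""

    model_ids: list[int]
    patient_ids: list[str]
    votes: np.ndarray       # (n_models, n_patients) of {0,1}

    def __post_init__(self) -> None:
        self.votes = np.asarray(self.votes, dtype=int)
        if self.votes.shape != (len(self.model_ids), len(self.patient_ids)):
            raise ValueError("vote matrix shape mismatch with id lists")
        if not np.isin(self.votes, (0, 1)).all():
            raise ValueError("votes must be binary")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.votes,
                            index=pd.Index(self.model_ids, name="model_id"),
                            columns=self.patient_ids)


@dataclass
class ConsensusAssignment:
    patient_id: str
    high_fraction: float
    binary_label: str    # H / L
    ternary_label: str   # H / M / L

    @property
    def confidence(self) -> float:
        return max(self.high_fraction, 1.0 - self.high_fraction)


def build_vote_matrix(models: list[RidgeCoxModel],
                      analytes: pd.DataFrame) -> VoteMatrix:
    """Apply every model's frozen dichotomization to every patient."""
    if not models:
        raise ValueError("no models")
    votes = np.stack([dichotomize(m, analytes) == SASP_HIGH for m in models])
    return VoteMatrix(model_ids=[m.model_id for m in models],
                      patient_ids=[str(i) for i in analytes.index],
                      votes=votes.astype(int))


def consensus(matrix: VoteMatrix) -> list[ConsensusAssignment]:
    """Plurality-vote labels: binary at >50% high, ternary at >75%/<25%."""
    fractions = matrix.votes.mean(axis=0)
    out = []
    for pid, f in zip(matrix.patient_ids, fractions):
        binary = "H" if f > 0.5 else "L"
        if f > 0.75:
            ternary = "H"
        elif f < 0.25:
            ternary = "L"
        else:
            ternary = "M"
        out.append(ConsensusAssignment(pid, float(f), binary, ternary))
    return out


def consensus_frame(assignments: list[ConsensusAssignment]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"patient_id": a.patient_id, "high_fraction": a.high_fraction,
          "binary": a.binary_label, "ternary": a.ternary_label}
         for a in assignments])


def confidence_summary(assignments: list[ConsensusAssignment],
                       threshold: float = 0.75) -> dict:
    """Fraction of patients whose consensus confidence reaches ``threshold``.

    Confidence is max(high_fraction, 1 - high_fraction), i.e. the share of
    models agreeing with the plurality call.
    """
    if not assignments:
        raise ValueError("no assignments")
    conf = np.array([a.confidence for a in assignments])
    labels = np.array([a.binary_label for a in assignments])
    high_conf = conf >= threshold
    by_class = {
        lbl: {"n": int(np.sum(labels == lbl)),
              "high_confidence": int(np.sum(high_conf & (labels == lbl)))}
        for lbl in ("H", "L")
    }
    frac = float(high_conf.mean())
    return {"high_confidence_fraction": frac,
            "low_confidence_fraction": 1.0 - frac,
            "by_class": by_class}
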