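"""Per-protein quartile screening of survival association.

Each analyte's distribution is cut at its 25th/50th/75th percentiles
(linear interpolation, lower-closed assignment, so 578 distinct values split
145/144/144/145) and quartiles 2-4 are contrasted against quartile 1 in a
Cox model, adjusted for stage and treatment in the pooled analysis and
unadjusted inside stage/treatment-homogeneous cohorts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .survival import cox_fit

QUARTILE_LABELS = ("Q1", "Q2", "Q3", "Q4")


@dataclass
class QuartileAssignment:
    protein: str
    labels: np.ndarray           # per-patient "Q1".."Q4"
    counts: dict[str, int]
    cutpoints: tuple[float, float, float]


def assign_quartiles(values, protein: str = "") -> QuartileAssignment:
    """Quartile membership with cutpoints at interpolated percentiles.

    A value less than or equal to a cutpoint falls in the lower group, so
    tied masses share a quartile and counts may be unequal under ties.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 8:
        raise ValueError("need at least 8 values to form quartiles")
    if np.any(~np.isfinite(values)):
        raise ValueError("non-finite values")
    if values.min() == values.max():
        raise ValueError("all values identical: quartiles undefined")
    c1, c2, c3 = np.quantile(values, [0.25, 0.5, 0.75], method="linear")
    labels = np.full(values.shape, "Q4", dtype=object)
    labels[values <= c3] = "Q3"
    labels[values <= c2] = "Q2"
    labels[values <= c1] = "Q1"
    counts = {q: int(np.sum(labels == q)) for q in QUARTILE_LABELS}
    return QuartileAssignment(protein, labels.astype(str), counts,
                              (float(c1), float(c2), float(c3)))


@dataclass
class QuartileHRRow:
    protein: str
    cohort: str                      # cohort label or "all"
    counts: dict[str, int]
    hr: dict[str, float]             # Q2..Q4 vs Q1
    ci: dict[str, tuple[float, float]]
    p: dict[str, float]
    flagged: bool = False            # a quartile had zero events

    def as_flat(self) -> dict:
        row = {"protein": self.protein, "cohort": self.cohort}
        for q in QUARTILE_LABELS:
            row[f"n_{q.lower()}"] = self.counts[q]
        for q in ("Q2", "Q3", "Q4"):
            row[f"hr_{q.lower()}"] = self.hr[q]
            row[f"ci_lo_{q.lower()}"] = self.ci[q][0]
            row[f"ci_hi_{q.lower()}"] = self.ci[q][1]
            row[f"p_{q.lower()}"] = self.p[q]
        row["flagged"] = self.flagged
        return row


def quartile_cox(patients: pd.DataFrame, values, protein: str,
                 adjust: list[str] | None = None,
                 cohort: str = "all") -> QuartileHRRow:
    """Cox contrast of quartiles 2-4 vs quartile 1 for one protein.

    ``adjust`` may contain "stage" and/or "treatment"; adjusters constant in
    the data are rejected (rank deficiency) rather than silently dropped.
    """
    assignment = assign_quartiles(values, protein)
    labels = assignment.labels
    cols: list[np.ndarray] = []
    names: list[str] = []
    for q in ("Q2", "Q3", "Q4"):
        cols.append((labels == q).astype(float))
        names.append(q)
    for adj in adjust or []:
        if adj == "stage":
            col = (patients["stage"].to_numpy() == "III").astype(float)
        elif adj == "treatment":
            col = (patients["treatment"].to_numpy() == "EBRT").astype(float)
        else:
            raise ValueError(f"unknown adjuster {adj!r}")
        if col.min() == col.max():
            raise ValueError(f"adjuster {adj!r} is constant: rank deficient")
        cols.append(col)
        names.append(adj)
    X = np.column_stack(cols)
    event = patients["event"].to_numpy()
    flagged = any(event[labels == q].sum() == 0 for q in QUARTILE_LABELS)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        fit = cox_fit(patients["time"].to_numpy(), event, X, names=names)
    flagged = flagged or not fit.converged
    hr = {q: float(fit.hr[i]) for i, q in enumerate(("Q2", "Q3", "Q4"))}
    ci = {q: (float(fit.ci95[i, 0]), float(fit.ci95[i, 1]))
          for i, q in enumerate(("Q2", "Q3", "Q4"))}
    p = {q: float(fit.p[i]) for i, q in enumerate(("Q2", "Q3", "Q4"))}
    return QuartileHRRow(protein, cohort, assignment.counts, hr, ci, p,
                         flagged)


def screen_panel(cohorts, proteins, adjust=("stage", "treatment"),
                 alpha: float = 0.05) -> pd.DataFrame:
    """Quartile screen over cohorts: pooled (adjusted) + per-cohort rows.

    Emits a pooled row only when more than one cohort is supplied. Holm
    multiple-testing adjustment of the Q4 p-values is applied within each
    cohort stratum across proteins; ``candidate`` flags proteins whose Q4
    contrast is significant (raw p) in any stratum.
    """
    proteins = list(proteins)
    if not proteins:
        return pd.DataFrame(columns=["protein", "cohort"])
    rows = []
    if len(cohorts) > 1:
        from .simulate import pool_cohorts
        patients, analytes = pool_cohorts(cohorts)
        for protein in proteins:
            rows.append(quartile_cox(patients, analytes[protein].to_numpy(),
                                     protein, adjust=list(adjust),
                                     cohort="all").as_flat())
    for cohort in cohorts:
        for protein in proteins:
            rows.append(quartile_cox(
                cohort.patients, cohort.analytes[protein].to_numpy(),
                protein, adjust=None, cohort=cohort.label).as_flat())
    table = pd.DataFrame(rows)
    table["p_q4_holm"] = np.nan
    for _, idx in table.groupby("cohort").groups.items():
        pvals = table.loc[idx, "p_q4"].to_numpy()
        table.loc[idx, "p_q4_holm"] = multipletests(pvals, method="holm")[1]
    sig = table[table["p_q4"] < alpha]["protein"].unique()
    table["candidate"] = table["protein"].isin(sig)
    return table
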