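"""Treatment-benefit analysis stratified by senescence class.

Pools the stage III cohorts (treated with and without brachytherapy),
labels each patient SASP-low / (medium) / SASP-high by a single model or by
the consensus ternary rule, and contrasts survival without vs with
brachytherapy inside each stratum. Hazard ratios treat the no-brachytherapy
arm as exposed, so HR > 1 reads as a brachytherapy benefit. Per-model
p-values are Bonferroni-multiplied by the number of models examined,
deliberately uncapped at 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .survival import km_estimate, logrank_test, two_group_cox


@dataclass
class StratumResult:
    stratum: str            # SASP_L / SASP_M / SASP_H
    n_bt: int
    n_nobt: int
    hr: float               # no-BT vs BT
    ci_lo: float
    ci_hi: float
    p: float                # Wald
    p_logrank: float
    adj_p: float
    flagged: bool = False   # single treatment arm: no contrast possible

    def as_flat(self) -> dict:
        return {"stratum": self.stratum, "n_bt": self.n_bt,
                "n_nobt": self.n_nobt, "hr": self.hr, "ci_lo": self.ci_lo,
                "ci_hi": self.ci_hi, "p": self.p,
                "p_logrank": self.p_logrank, "adj_p": self.adj_p,
                "flagged": self.flagged}


def adjust_pvalues(p: float, n_models: int) -> float:
    """Bonferroni adjustment by ensemble size, not capped at 1."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must be in [0, 1]")
    if n_models < 1:
        raise ValueError("n_models must be >= 1")
    return p * n_models


def stratified_bt_effect(patients: pd.DataFrame, strata_labels,
                         n_models: int = 1) -> list[StratumResult]:
    """No-BT vs BT survival contrast within each senescence stratum.

    ``patients`` must be stage III only (mixed-stage input is rejected:
    stage would confound the treatment contrast). ``strata_labels`` is a
    per-patient array over {SASP_L, SASP_M, SASP_H}; the M stratum appears
    only when present in the labels (consensus mode).
    """
    if not (patients["stage"] == "III").all():
        raise ValueError("treatment-benefit analysis is restricted to "
                         "stage III patients")
    strata_labels = np.asarray(strata_labels)
    if len(strata_labels) != len(patients):
        raise ValueError("label / patient length mismatch")
    no_bt = patients["treatment"].to_numpy() == "EBRT"
    time = patients["time"].to_numpy()
    event = patients["event"].to_numpy()
    results = []
    for stratum in ("SASP_L", "SASP_M", "SASP_H"):
        mask = strata_labels == stratum
        if not mask.any():
            continue
        n_nobt = int(np.sum(mask & no_bt))
        n_bt = int(np.sum(mask & ~no_bt))
        if n_nobt == 0 or n_bt == 0:
            results.append(StratumResult(stratum, n_bt, n_nobt, np.nan,
                                         np.nan, np.nan, np.nan, np.nan,
                                         np.nan, flagged=True))
            continue
        res = two_group_cox(time[mask], event[mask], no_bt[mask])
        _, p_lr = logrank_test(time[mask & no_bt], event[mask & no_bt],
                               time[mask & ~no_bt], event[mask & ~no_bt])
        adj = adjust_pvalues(res["p"], n_models) if np.isfinite(res["p"]) \
            else np.nan
        results.append(StratumResult(
            stratum, n_bt, n_nobt, res["hr"], res["ci_lo"], res["ci_hi"],
            res["p"], p_lr, adj, flagged=res["flagged"]))
    return results


def strata_table(results: list[StratumResult],
                 model_id=None) -> pd.DataFrame:
    rows = [r.as_flat() for r in results]
    table = pd.DataFrame(rows)
    if model_id is not None:
        table.insert(0, "model_id", model_id)
    return table


def multifactor_strata(patients: pd.DataFrame, sasp_labels) -> pd.DataFrame:
    """Survival summaries per stage x SASP x treatment category.

    Returns one row per non-empty category with Kaplan-Meier 1- and 5-year
    survival, ordered worst to best 5-year survival.
    """
    sasp_labels = np.asarray(sasp_labels)
    if len(sasp_labels) != len(patients):
        raise ValueError("label / patient length mismatch")
    df = patients.copy()
    df["sasp"] = sasp_labels
    rows = []
    for (stage, sasp, treatment), sub in df.groupby(
            ["stage", "sasp", "treatment"], sort=True):
        if len(sub) == 0:
            continue
        km = km_estimate(sub["time"].to_numpy(), sub["event"].to_numpy())
        bt = "BT" if treatment == "EBRT+BT" else "noBT"
        rows.append({
            "category": f"stage{stage}_{sasp}_{bt}",
            "stage": stage, "sasp": sasp, "treatment": treatment,
            "n": len(sub), "events": int(sub["event"].sum()),
            "surv_1yr": km.survival_at(1.0), "surv_5yr": km.survival_at(5.0),
        })
    table = pd.DataFrame(rows)
    if len(table):
        table = table.sort_values("surv_5yr").reset_index(drop=True)
    return table
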