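"""Split-pair ridge-score ensemble: train, dichotomize, select, validate.

The procedure repeatedly halves a cohort into train/test pairs, fits a ridge
Cox score on the training half (penalty chosen by cross-validation within
that half), freezes a percentile cutoff of the training scores to
dichotomize patients into SASP-high vs SASP-low, and keeps the models whose
high/low hazard ratio is consistently large and significant in both halves.
Retained models are validated by repeated 70% subsampling of the full
training cohort (the cutoff percentile is re-derived within each subsample)
and by frozen-cutoff application to independent cohorts.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import HIGH_FRACTION_PRESETS, resolve_panel
from .simulate import CohortDataset
from .survival import (RidgeCoxFit, cv_lambda_min, linear_predictor,
                       ridge_cox_fit, two_group_cox)

#: Default lambda grid / folds for the per-split inner cross-validation.
INNER_LAMBDA_GRID = np.geomspace(1e-2, 1e2, 8)
INNER_CV_FOLDS = 5

SASP_HIGH = "SASP_H"
SASP_LOW = "SASP_L"


@dataclass
class RidgeCoxModel:
    """A frozen ensemble member: protein subset, penalized coefficients,
    and the score cutoff learned on its training half.

    Coefficients are stored already oriented so that scores above
    ``cutoff_value`` mark the higher-hazard (SASP-high) group; ``flipped``
    records whether a sign flip was needed and ``unstable`` whether the
    training contrast was too weak to pin the orientation down reliably.
    """

    model_id: int
    proteins: tuple[str, ...]
    fit: RidgeCoxFit
    cutoff_percentile: float
    cutoff_value: float
    high_is_worse: bool = True
    flipped: bool = False
    unstable: bool = False
    trained_on: str = ""

    def score(self, analytes: pd.DataFrame) -> np.ndarray:
        missing = [p for p in self.proteins if p not in analytes.columns]
        if missing:
            raise ValueError(f"missing proteins {missing}")
        return linear_predictor(self.fit,
                                analytes[list(self.proteins)].to_numpy())

    def to_dict(self) -> dict:
        return {
            "model_id": self.model_id, "proteins": list(self.proteins),
            "beta": self.fit.beta.tolist(), "lambda": self.fit.lam,
            "center": self.fit.center.tolist(),
            "scale": self.fit.scale.tolist(),
            "cutoff_percentile": self.cutoff_percentile,
            "cutoff_value": self.cutoff_value,
            "high_is_worse": self.high_is_worse, "flipped": self.flipped,
            "unstable": self.unstable, "trained_on": self.trained_on,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RidgeCoxModel":
        fit = RidgeCoxFit(
            names=list(d["proteins"]), beta=np.array(d["beta"]),
            lam=float(d["lambda"]), center=np.array(d["center"]),
            scale=np.array(d["scale"]), loglik=np.nan, converged=True)
        return cls(model_id=int(d["model_id"]),
                   proteins=tuple(d["proteins"]), fit=fit,
                   cutoff_percentile=float(d["cutoff_percentile"]),
                   cutoff_value=float(d["cutoff_value"]),
                   high_is_worse=bool(d["high_is_worse"]),
                   flipped=bool(d["flipped"]), unstable=bool(d["unstable"]),
                   trained_on=str(d["trained_on"]))


@dataclass
class SplitEvaluation:
    train: dict
    test: dict
    split_seed: int


@dataclass
class BootstrapSummary:
    n_boot: int
    subsample_fraction: float
    mean_hr: float
    geometric_mean_hr: float
    bins: dict[str, int]      # "p_gt_05", "p_05_001", "p_le_001"
    passed: bool
    n_redraws: int = 0


@dataclass
class ModelRecord:
    model: RidgeCoxModel
    split_eval: SplitEvaluation
    bootstrap: BootstrapSummary | None = None
    external: list[dict] = field(default_factory=list)

    def as_flat(self) -> dict:
        row = {"model_id": self.model.model_id,
               "panel": "+".join(self.model.proteins),
               "lambda": self.model.fit.lam,
               "cutoff_percentile": self.model.cutoff_percentile,
               "train_hr": self.split_eval.train["hr"],
               "train_ci_lo": self.split_eval.train["ci_lo"],
               "train_ci_hi": self.split_eval.train["ci_hi"],
               "train_p": self.split_eval.train["p"],
               "test_hr": self.split_eval.test["hr"],
               "test_ci_lo": self.split_eval.test["ci_lo"],
               "test_ci_hi": self.split_eval.test["ci_hi"],
               "test_p": self.split_eval.test["p"]}
        if self.bootstrap is not None:
            row.update({"boot_mean_hr": self.bootstrap.mean_hr,
                        "boot_p_gt_05": self.bootstrap.bins["p_gt_05"],
                        "boot_p_05_001": self.bootstrap.bins["p_05_001"],
                        "boot_p_le_001": self.bootstrap.bins["p_le_001"],
                        "boot_pass": self.bootstrap.passed})
        for ext in self.external:
            lbl = ext["cohort"].lower()
            row.update({f"{lbl}_hr": ext["hr"], f"{lbl}_ci_lo": ext["ci_lo"],
                        f"{lbl}_ci_hi": ext["ci_hi"], f"{lbl}_p": ext["p"]})
        return row


def _percentile_cutoff(scores: np.ndarray, pct: float) -> float:
    """Cutoff such that exactly ceil(pct/100 * n) tie-free scores fall at
    or below it (empirical inverse-CDF quantile)."""
    return float(np.quantile(scores, pct / 100.0, method="inverted_cdf"))


def sample_split_pairs(n: int, events, n_pairs: int, fraction: float = 50.0,
                       seed: int = 0):
    """Random event-stratified partitions into disjoint train/test halves."""
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    if not 0 < fraction < 100:
        raise ValueError("fraction must be in (0, 100)")
    events = np.asarray(events, dtype=int)
    n_events = int(events.sum())
    if n_events < 2:
        raise ValueError("need >= 2 events to stratify a split")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    ev_idx = np.flatnonzero(events == 1)
    cs_idx = np.flatnonzero(events == 0)
    train_size = int(round(n * fraction / 100.0))
    ev_train = int(np.clip(round(n_events * fraction / 100.0), 1,
                           n_events - 1))
    cs_train = train_size - ev_train
    if cs_train < 0 or cs_train > cs_idx.size:
        raise ValueError("cannot satisfy stratified split sizes")
    pairs = []
    for _ in range(n_pairs):
        ev_perm = rng.permutation(ev_idx)
        cs_perm = rng.permutation(cs_idx)
        train = np.sort(np.concatenate([ev_perm[:ev_train],
                                        cs_perm[:cs_train]]))
        test = np.sort(np.concatenate([ev_perm[ev_train:],
                                       cs_perm[cs_train:]]))
        pairs.append((train, test))
    return pairs


def train_model(time, event, analytes: pd.DataFrame, proteins,
                cutoff_percentile: float = 40.0, lambda_grid=None,
                cv_folds: int = INNER_CV_FOLDS, seed: int = 0,
                model_id: int = 0, trained_on: str = "",
                score_family: str = "cox") -> RidgeCoxModel:
    """Fit one ridge score on a training subset and freeze its cutoff.

    The penalty is chosen by cross-validated partial deviance within the
    training subset only. The sign of the score is oriented so the
    above-cutoff group has training hazard ratio >= 1; orientation is
    flagged unstable when the training contrast is weak or when
    cross-validation finds no held-out signal in the panel at all.
    """
    proteins = resolve_panel(proteins)
    X = analytes[list(proteins)].to_numpy()
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if lambda_grid is None:
        lambda_grid = INNER_LAMBDA_GRID
    lambda_grid = np.asarray(lambda_grid, dtype=float)
    lam, cv_curve = cv_lambda_min(time, event, X, lambda_grid=lambda_grid,
                                  n_folds=cv_folds, seed=seed)
    cv_dev = dict(cv_curve)
    # held-out evidence of any signal: deviance improvement of the chosen
    # penalty over maximal shrinkage (~ the null model)
    cv_improvement = cv_dev[max(cv_dev)] - cv_dev[lam]
    if score_family == "cox":
        fit = ridge_cox_fit(time, event, X, lam, names=list(proteins))
    elif score_family == "logistic":
        from .survival import ridge_logistic_fit
        fit = ridge_logistic_fit(time, event, X, lam, names=list(proteins))
    else:
        raise ValueError(f"unknown score_family {score_family!r}")
    scores = linear_predictor(fit, X)
    if scores.max() == scores.min():
        raise ValueError("degenerate scores: all patients identical")
    cutoff = _percentile_cutoff(scores, cutoff_percentile)
    res = two_group_cox(time, event, scores > cutoff)
    flipped = False
    if res["flagged"] or not np.isfinite(res["hr"]) or res["hr"] < 1.0:
        flipped_fit = RidgeCoxFit(fit.names, -fit.beta, fit.lam, fit.center,
                                  fit.scale, fit.loglik, fit.converged)
        flipped_scores = -scores
        flipped_cutoff = _percentile_cutoff(flipped_scores, cutoff_percentile)
        flipped_res = two_group_cox(time, event,
                                    flipped_scores > flipped_cutoff)
        if not flipped_res["flagged"] and (
                not np.isfinite(res["hr"]) or
                (np.isfinite(flipped_res["hr"]) and
                 flipped_res["hr"] >= res["hr"])):
            fit, cutoff, res, flipped = (flipped_fit, flipped_cutoff,
                                         flipped_res, True)
    # orientation is unreliable when the training contrast is itself weak or
    # when cross-validation finds no predictive signal in the panel
    # (in-sample contrasts are overfit-biased, so CV carries the evidence)
    unstable = ((not np.isfinite(res["p"])) or res["p"] > 0.05
                or cv_improvement < 2.0)
    return RidgeCoxModel(model_id=model_id, proteins=proteins, fit=fit,
                         cutoff_percentile=cutoff_percentile,
                         cutoff_value=cutoff, flipped=flipped,
                         unstable=unstable, trained_on=trained_on)


def dichotomize(model: RidgeCoxModel, analytes: pd.DataFrame) -> np.ndarray:
    """SASP_H iff score > frozen cutoff (ties go low); never re-centered."""
    scores = model.score(analytes)
    return np.where(scores > model.cutoff_value, SASP_HIGH, SASP_LOW)


def evaluate_split(model: RidgeCoxModel, train_patients, train_analytes,
                   test_patients, test_analytes,
                   split_seed: int = 0) -> SplitEvaluation:
    """Unadjusted high-vs-low Cox contrast on both halves of the split."""
    out = []
    for patients, analytes in ((train_patients, train_analytes),
                               (test_patients, test_analytes)):
        labels = dichotomize(model, analytes)
        out.append(two_group_cox(patients["time"].to_numpy(),
                                 patients["event"].to_numpy(),
                                 labels == SASP_HIGH))
    return SplitEvaluation(train=out[0], test=out[1], split_seed=split_seed)


def select_models(records: list[ModelRecord], hr_min: float = 3.0,
                  p_max: float = 0.05) -> list[ModelRecord]:
    """Keep models with train and test HR >= hr_min and both p <= p_max."""
    if not records:
        raise ValueError("no records to select from")
    kept = []
    for rec in records:
        tr, te = rec.split_eval.train, rec.split_eval.test
        if (np.isfinite(tr["hr"]) and np.isfinite(te["hr"])
                and tr["hr"] >= hr_min and te["hr"] >= hr_min
                and tr["p"] <= p_max and te["p"] <= p_max
                and not tr["flagged"] and not te["flagged"]):
            kept.append(rec)
    # strongest held-out evidence first (bootstrap ordering applied later)
    kept.sort(key=lambda r: (r.split_eval.test["p"],
                             r.model.model_id if r.model is not None else -1))
    return kept


def bootstrap_validate(model: RidgeCoxModel, patients: pd.DataFrame,
                       analytes: pd.DataFrame, n_boot: int = 1000,
                       subsample_fraction: float = 70.0, seed: int = 0,
                       with_replacement: bool = False) -> BootstrapSummary:
    """Repeated subsample validation with the cutoff re-derived per draw.

    Each iteration draws ``subsample_fraction`` percent of the cohort
    (without replacement by default), recomputes scores with the frozen
    coefficients, re-derives the percentile cutoff *within the subsample*,
    and records the high/low hazard ratio and p-value. A draw whose
    subsample has no events or a single label is redrawn (up to 10 tries).
    """
    scores = model.score(analytes)
    time = patients["time"].to_numpy()
    event = patients["event"].to_numpy()
    n = len(patients)
    m = int(round(n * subsample_fraction / 100.0))
    rng = np.random.default_rng(np.random.SeedSequence((seed, model.model_id)))
    hrs = np.empty(n_boot)
    pvals = np.empty(n_boot)
    n_redraws = 0
    for b in range(n_boot):
        for _ in range(10):
            idx = (rng.choice(n, size=m, replace=True) if with_replacement
                   else rng.permutation(n)[:m])
            if event[idx].sum() == 0:
                n_redraws += 1
                continue
            cut = _percentile_cutoff(scores[idx], model.cutoff_percentile)
            high = scores[idx] > cut
            if high.all() or not high.any():
                n_redraws += 1
                continue
            res = two_group_cox(time[idx], event[idx], high)
            if not np.isfinite(res["hr"]):
                n_redraws += 1
                continue
            hrs[b], pvals[b] = res["hr"], res["p"]
            break
        else:
            raise RuntimeError("bootstrap subsample degenerate 10x in a row")
    bins = {"p_gt_05": int(np.sum(pvals > 0.05)),
            "p_05_001": int(np.sum((pvals <= 0.05) & (pvals > 0.001))),
            "p_le_001": int(np.sum(pvals <= 0.001))}
    passed = bins["p_gt_05"] <= 0.05 * n_boot
    return BootstrapSummary(
        n_boot=n_boot, subsample_fraction=subsample_fraction,
        mean_hr=float(hrs.mean()),
        geometric_mean_hr=float(np.exp(np.log(hrs).mean())),
        bins=bins, passed=passed, n_redraws=n_redraws)


def external_validate(model: RidgeCoxModel,
                      cohorts: list[CohortDataset]) -> list[dict]:
    """Frozen-cutoff two-group contrast on independent cohorts."""
    results = []
    for cohort in cohorts:
        if cohort.label == model.trained_on:
            raise ValueError(
                f"cohort {cohort.label} is the model's training cohort")
        labels = dichotomize(model, cohort.analytes)
        res = two_group_cox(cohort.patients["time"].to_numpy(),
                            cohort.patients["event"].to_numpy(),
                            labels == SASP_HIGH)
        results.append({"cohort": cohort.label, **res})
    return results


def run_ensemble(cohort: CohortDataset, panel, n_pairs: int = 3000,
                 n_boot: int = 1000, max_models: int | None = 25,
                 high_fraction: float | None = None, hr_min: float = 3.0,
                 p_max: float = 0.05, subsample_fraction: float = 70.0,
                 validation_cohorts: list[CohortDataset] | None = None,
                 seed: int = 0) -> list[ModelRecord]:
    """Full ensemble pass on one cohort.

    Split pairs are drawn, a model trained and evaluated per pair, the
    consistent ones selected, capped at ``max_models`` (best held-out
    p-value first), then bootstrap-validated on the full cohort and
    frozen-cutoff validated on the independent cohorts. Records come back
    ordered by bootstrap robustness (fewest non-significant bootstraps).
    Model ids are split indices (1-based).
    """
    if high_fraction is None:
        high_fraction = HIGH_FRACTION_PRESETS.get(cohort.label, 0.60)
    cutoff_percentile = 100.0 * (1.0 - high_fraction)
    proteins = resolve_panel(panel)
    time = cohort.patients["time"].to_numpy()
    event = cohort.patients["event"].to_numpy()
    ss = np.random.SeedSequence(seed)
    split_seed, train_seed, boot_seed = [int(s) % (2 ** 31)
                                         for s in ss.generate_state(3)]
    pairs = sample_split_pairs(cohort.n, event, n_pairs, 50.0, split_seed)
    records = []
    for i, (train_idx, test_idx) in enumerate(pairs, start=1):
        tr_pat = cohort.patients.iloc[train_idx]
        tr_ana = cohort.analytes.iloc[train_idx]
        try:
            model = train_model(tr_pat["time"].to_numpy(),
                                tr_pat["event"].to_numpy(), tr_ana, proteins,
                                cutoff_percentile=cutoff_percentile,
                                seed=train_seed + i, model_id=i,
                                trained_on=cohort.label)
        except ValueError:
            continue
        ev = evaluate_split(model, tr_pat, tr_ana,
                            cohort.patients.iloc[test_idx],
                            cohort.analytes.iloc[test_idx], split_seed=i)
        records.append(ModelRecord(model=model, split_eval=ev))
    if not records:
        return []
    selected = select_models(records, hr_min=hr_min, p_max=p_max)
    if max_models is not None:
        selected = selected[:max_models]
    for rec in selected:
        if n_boot > 0:
            rec.bootstrap = bootstrap_validate(
                rec.model, cohort.patients, cohort.analytes, n_boot=n_boot,
                subsample_fraction=subsample_fraction, seed=boot_seed)
        if validation_cohorts:
            rec.external = external_validate(rec.model, validation_cohorts)
    if n_boot > 0:
        selected.sort(key=lambda r: (r.bootstrap.bins["p_gt_05"],
                                     -r.bootstrap.mean_hr, r.model.model_id))
    return selected


_TABLE_COLUMNS = ["model_id", "panel", "lambda", "cutoff_percentile",
                  "train_hr", "train_ci_lo", "train_ci_hi", "train_p",
                  "test_hr", "test_ci_lo", "test_ci_hi", "test_p"]


def records_to_table(records: list[ModelRecord]) -> pd.DataFrame:
    if not records:
        return pd.DataFrame(columns=_TABLE_COLUMNS)
    return pd.DataFrame([r.as_flat() for r in records])


def records_to_jsonl(records: list[ModelRecord], path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            line = {"model": rec.model.to_dict(),
                    "split_eval": {"train": rec.split_eval.train,
                                   "test": rec.split_eval.test,
                                   "split_seed": rec.split_eval.split_seed},
                    "bootstrap": (None if rec.bootstrap is None else {
                        "n_boot": rec.bootstrap.n_boot,
                        "subsample_fraction": rec.bootstrap.subsample_fraction,
                        "mean_hr": rec.bootstrap.mean_hr,
                        "geometric_mean_hr": rec.bootstrap.geometric_mean_hr,
                        "bins": rec.bootstrap.bins,
                        "passed": rec.bootstrap.passed}),
                    "external": rec.external}
            fh.write(json.dumps(line, default=float) + "\n")


def load_models_jsonl(path) -> list[RidgeCoxModel]:
    models = []
    with open(path) as fh:
        for line in fh:
            models.append(RidgeCoxModel.from_dict(json.loads(line)["model"]))
    return models
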