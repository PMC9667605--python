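"""Model evaluation and survival analysis.

Confusion metrics (death = positive class), one-by-one feature importance
weights (AUC reduction under single-feature deletion), whole-group ablation
(e.g. dropping every lung-related feature), 2:1 cohort splitting, risk
stratification from the predicted survival status, Kaplan-Meier estimation,
the two-group log-rank test, and pairwise-complete Pearson correlation of
features against pulmonary-function / blood-gas indicators.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test

from .errors import DomainError, SchemaError
from .model import LinearSVMModel, SVMConfig, decision_values, roc_auc, train_final

LOW_RISK = "low"
HIGH_RISK = "high"


# ---------------------------------------------------------------------------
# cohort split
# ---------------------------------------------------------------------------

@dataclass
class CohortSplit:
    training: list
    validation: list
    seed: int | None = None


def split_cohort(ids, seed: int | None = None, n_training: int | None = None) -> CohortSplit:
    """Random 2:1 training/validation split, reproducible from the seed.

    ``n_training`` defaults to round(2n/3); pass it explicitly to honour a
    reported cohort size (e.g. 200 of 298).
    """
    ids = list(ids)
    n = len(ids)
    if n < 3:
        raise DomainError("need at least 3 ids to split 2:1")
    if n_training is None:
        n_training = int(round(2 * n / 3))
    if not 0 < n_training < n:
        raise DomainError(f"n_training must be in (0, {n}), got {n_training}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    training = [ids[i] for i in order[:n_training]]
    validation = [ids[i] for i in order[n_training:]]
    return CohortSplit(training=training, validation=validation, seed=seed)


# ---------------------------------------------------------------------------
# confusion metrics
# ---------------------------------------------------------------------------

@dataclass
class ConfusionSummary:
    """Rates in percent; death is the positive class."""

    tpr_pct: float
    tnr_pct: float
    f1: float
    overall_accuracy_pct: float
    average_accuracy_pct: float
    tp: int
    fn: int
    tn: int
    fp: int

    def __post_init__(self):
        expected = (self.tpr_pct + self.tnr_pct) / 2.0
        assert abs(self.average_accuracy_pct - expected) < 1e-9

    def as_dict(self) -> dict:
        return {
            "TPR_pct": self.tpr_pct,
            "TNR_pct": self.tnr_pct,
            "F1": self.f1,
            "overall_accuracy_pct": self.overall_accuracy_pct,
            "average_accuracy_pct": self.average_accuracy_pct,
        }


def confusion_from_counts(tp: int, fn: int, tn: int, fp: int) -> ConfusionSummary:
    """Metrics from raw confusion counts.

    average accuracy = (TPR + TNR) / 2; overall accuracy = correct / all;
    F1 on the positive (death) class.
    """
    if min(tp, fn, tn, fp) < 0 or (tp + fn) == 0 or (tn + fp) == 0:
        raise DomainError("both classes must be present in the truth")
    tpr = 100.0 * tp / (tp + fn)
    tnr = 100.0 * tn / (tn + fp)
    overall = 100.0 * (tp + tn) / (tp + fn + tn + fp)
    denom = 2 * tp + fp + fn
    f1 = 2.0 * tp / denom if denom else 0.0
    return ConfusionSummary(
        tpr_pct=tpr, tnr_pct=tnr, f1=f1, overall_accuracy_pct=overall,
        average_accuracy_pct=(tpr + tnr) / 2.0, tp=tp, fn=fn, tn=tn, fp=fp,
    )


def confusion_metrics(pred, truth) -> ConfusionSummary:
    pred = np.asarray(pred).astype(int)
    truth = np.asarray(truth).astype(int)
    if pred.shape != truth.shape:
        raise SchemaError("prediction and truth vectors have different lengths")
    tp = int(((pred == 1) & (truth == 1)).sum())
    fn = int(((pred == 0) & (truth == 1)).sum())
    tn = int(((pred == 0) & (truth == 0)).sum())
    fp = int(((pred == 1) & (truth == 0)).sum())
    return confusion_from_counts(tp, fn, tn, fp)


# ---------------------------------------------------------------------------
# importance weights and group ablation
# ---------------------------------------------------------------------------

@dataclass
class ImportanceWeight:
    feature: str
    iw: float
    rank: int
    auc_without: float


def _auc_of(train_table, train_labels, selected, svm, eval_table, eval_labels) -> float:
    model = train_final(train_table, train_labels, selected, svm)
    return roc_auc(decision_values(model, eval_table), eval_labels).auc


def importance_weights(
    train_table, train_labels, selected: list[str],
    svm: SVMConfig | None = None,
    eval_table=None, eval_labels=None,
) -> tuple[float, list[ImportanceWeight]]:
    """One-by-one feature deletion: IW_f = AUC(full) - AUC(without f).

    The evaluation cohort defaults to the training cohort, so both
    training-column and validation-column rankings are producible. Returns
    (full-model AUC, descending-IW list).
    """
    if len(selected) < 2:
        raise DomainError("importance weights need at least 2 selected features")
    svm = svm or SVMConfig()
    if eval_table is None:
        eval_table, eval_labels = train_table, train_labels
    auc_full = _auc_of(train_table, train_labels, selected, svm, eval_table, eval_labels)
    rows = []
    for f in selected:
        rest = [g for g in selected if g != f]
        auc_wo = _auc_of(train_table, train_labels, rest, svm, eval_table, eval_labels)
        rows.append((f, auc_full - auc_wo, auc_wo))
    rows.sort(key=lambda r: -r[1])
    weights = [
        ImportanceWeight(feature=f, iw=float(iw), rank=i + 1, auc_without=float(auc_wo))
        for i, (f, iw, auc_wo) in enumerate(rows)
    ]
    return float(auc_full), weights


def ablate_group(
    train_table, train_labels, selected: list[str], group_prefix: str,
    svm: SVMConfig | None = None, eval_table=None, eval_labels=None,
) -> tuple[float, float, float]:
    """Drop every selected feature bearing the prefix (e.g. ``LUNG_``),
    retrain, and report (AUC_full, AUC_without_group, delta)."""
    svm = svm or SVMConfig()
    if eval_table is None:
        eval_table, eval_labels = train_table, train_labels
    kept = [f for f in selected if not f.startswith(group_prefix)]
    if not kept:
        raise DomainError(f"removing prefix '{group_prefix}' empties the model")
    auc_full = _auc_of(train_table, train_labels, selected, svm, eval_table, eval_labels)
    if kept == list(selected):
        return auc_full, auc_full, 0.0
    auc_wo = _auc_of(train_table, train_labels, kept, svm, eval_table, eval_labels)
    return auc_full, auc_wo, auc_full - auc_wo


# ---------------------------------------------------------------------------
# risk stratification and survival
# ---------------------------------------------------------------------------

def stratify(records: pd.DataFrame) -> pd.DataFrame:
    """Assign risk groups from the predicted survival status.

    Predicted survivors (status 0) form the low-risk group; predicted deaths
    (status 1) the high-risk group. Pure function of ``predicted_status``.
    """
    if "predicted_status" not in records.columns:
        raise SchemaError("records need a 'predicted_status' column")
    out = records.copy()
    out["risk_group"] = np.where(out["predicted_status"].astype(int) == 1,
                                 HIGH_RISK, LOW_RISK)
    return out


@dataclass
class KMEstimate:
    """Product-limit survival curve with right censoring."""

    times: np.ndarray
    survival: np.ndarray
    n: int
    n_events: int

    def survival_at(self, t: float) -> float:
        """S(t): probability of surviving beyond t months."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def km_estimate(times, events) -> KMEstimate:
    """Kaplan-Meier estimate; times in months, event = death."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events).astype(int)
    if times.size == 0:
        raise DomainError("need at least one record")
    if (times < 0).any():
        raise DomainError("negative survival times")
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    sf = kmf.survival_function_
    return KMEstimate(
        times=sf.index.to_numpy(dtype=float),
        survival=sf.iloc[:, 0].to_numpy(dtype=float),
        n=int(times.size),
        n_events=int(events.sum()),
    )


def logrank(times, events, groups) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi-square statistic, p-value)."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events).astype(int)
    groups = np.asarray(groups)
    labels = np.unique(groups)
    if labels.size != 2:
        raise DomainError(f"log-rank needs exactly 2 groups, got {labels.size}")
    if events.sum() == 0:
        raise DomainError("log-rank undefined without any event")
    a = groups == labels[0]
    res = logrank_test(times[a], times[~a], events[a], events[~a])
    return float(res.test_statistic), float(res.p_value)


def survival_report(records: pd.DataFrame, horizon_months: float = 36.0) -> dict:
    """KM per risk group, survival at the horizon (3-year OS), and log-rank."""
    for col in ("time_months", "event", "risk_group"):
        if col not in records.columns:
            raise SchemaError(f"records need a '{col}' column")
    out: dict = {"groups": {}}
    for group, part in records.groupby("risk_group"):
        km = km_estimate(part["time_months"], part["event"])
        out["groups"][str(group)] = {
            "n": km.n,
            "n_events": km.n_events,
            "survival_at_horizon": km.survival_at(horizon_months),
        }
    if records["risk_group"].nunique() == 2:
        stat, p = logrank(records["time_months"], records["event"], records["risk_group"])
        out["logrank_statistic"] = stat
        out["logrank_p"] = p
    return out


# ---------------------------------------------------------------------------
# feature-indicator correlation
# ---------------------------------------------------------------------------

def pearson_matrix(
    feature_table: pd.DataFrame, indicator_table: pd.DataFrame, min_pairs: int = 3
) -> pd.DataFrame:
    """Pairwise-complete Pearson r for every (feature, indicator) pair.

    Missing values are excluded pairwise; a cell with fewer than
    ``min_pairs`` complete pairs (or a constant column) is NaN.
    """
    out = pd.DataFrame(
        index=feature_table.columns, columns=indicator_table.columns, dtype=float
    )
    for f in feature_table.columns:
        x = pd.to_numeric(feature_table[f], errors="coerce")
        for g in indicator_table.columns:
            y = pd.to_numeric(indicator_table[g], errors="coerce")
            ok = x.notna() & y.notna()
            if ok.sum() < min_pairs:
                continue
            xs, ys = x[ok], y[ok]
            if xs.std(ddof=0) == 0 or ys.std(ddof=0) == 0:
                continue
            out.loc[f, g] = float(np.corrcoef(xs, ys)[0, 1])
    return out
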