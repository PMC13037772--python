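"""Hold-one-dog-out classification of cancer vs healthy samples.

Four fragmentomic features (qPCR short index, HMM tumor fraction, WGS short-
and long-fragment proportions) feed a random forest evaluated with grouped
cross-validation: every fold holds out all samples of one subject, so the
scoring model never sees any sample of the subject it scores.  Out-of-fold
scores from all folds are pooled into one ROC.  Two evaluation modes mirror
the study design: ``all_samples`` (pre- and posttreatment rows of the test
subject are scored) and ``pretreatment_only`` (one row per subject).
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.ensemble import RandomForestClassifier

__all__ = [
    "FEATURES",
    "SensSpecResult",
    "build_feature_table",
    "hold_one_dog_out_folds",
    "cv_scores",
    "roc_auc",
    "roc_curve_points",
    "sensitivity_at_specificity",
]

FEATURES = ["short_index_qpcr", "tf_ichor", "prop_short_wgs", "prop_long_wgs"]
N_TREES = 500
MODES = {"all_samples", "pretreatment_only"}


def build_feature_table(
    samples: pd.DataFrame,
    short_index: pd.Series | dict,
    tf: pd.Series | dict,
    prop_short: pd.Series | dict,
    prop_long: pd.Series | dict,
) -> pd.DataFrame:
    """Join per-sample features onto the sample sheet, dropping unusable rows.

    Rows with any non-finite feature are excluded (with a logged count) so the
    classifier never sees missing values.
    """
    table = samples[["sample_id", "subject_id", "group", "timepoint"]].copy()
    for name, values in zip(FEATURES, (short_index, tf, prop_short, prop_long)):
        mapping = values if isinstance(values, dict) else values.to_dict()
        table[name] = table["sample_id"].map(mapping)
    feat = table[FEATURES].to_numpy(dtype=float)
    ok = np.isfinite(feat).all(axis=1)
    if (~ok).any():
        warnings.warn(f"excluding {int((~ok).sum())} sample(s) with missing features",
                      stacklevel=2)
    return table.loc[ok].reset_index(drop=True)


def _eligible(table: pd.DataFrame, mode: str) -> pd.DataFrame:
    if mode == "all_samples":
        return table
    # pretreatment_only: cancer subjects contribute their pretreatment row;
    # healthy subjects have no treatment axis, so their samples stay eligible
    keep = (table["timepoint"] == "pretreatment") | (table["group"] == "healthy")
    return table.loc[keep]


def hold_one_dog_out_folds(
    table: pd.DataFrame, mode: str = "all_samples"
) -> list[tuple[pd.DataFrame, pd.DataFrame]]:
    """One (train, test) split per subject; test = all of that subject's rows.

    In ``pretreatment_only`` mode both sides are restricted to pretreatment
    rows (healthy rows count as pretreatment).  Subjects with no eligible row
    in the active mode are skipped with a warning.
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {sorted(MODES)}")
    eligible = _eligible(table, mode)
    for group in ("healthy", "cancer"):
        if eligible.loc[eligible["group"] == group, "subject_id"].nunique() < 2:
            raise ValueError(f"need >= 2 subjects in group {group!r}")
    folds = []
    for subject in table["subject_id"].unique():
        test = eligible[eligible["subject_id"] == subject]
        if len(test) == 0:
            warnings.warn(f"subject {subject!r} has no eligible samples in mode {mode!r}",
                          stacklevel=2)
            continue
        train = eligible[eligible["subject_id"] != subject]
        folds.append((train, test))
    return folds


def _fold_seed(master_seed: int, subject_id: str) -> int:
    """Stable per-fold RNG seed derived from the master seed and subject id."""
    return zlib.crc32(f"{master_seed}:{subject_id}".encode()) % (2**31)


def cv_scores(
    table: pd.DataFrame,
    mode: str = "all_samples",
    seed: int = 0,
    n_trees: int = N_TREES,
) -> pd.DataFrame:
    """Out-of-fold random-forest cancer scores for every eligible sample.

    The forest (``n_trees`` trees, sqrt-of-4 features per split, unlimited
    depth) is retrained per fold on the four features; a sample's score is
    the fraction of trees voting cancer.  Deterministic given ``seed``.
    """
    folds = hold_one_dog_out_folds(table, mode)
    out = []
    for train, test in folds:
        assert not set(train["subject_id"]) & set(test["subject_id"]), "subject leakage"
        y = (train["group"] == "cancer").to_numpy()
        if y.all() or not y.any():
            raise ValueError("training fold contains a single class")
        clf = RandomForestClassifier(
            n_estimators=n_trees,
            max_features="sqrt",
            random_state=_fold_seed(seed, str(test["subject_id"].iloc[0])),
            n_jobs=1,
        )
        clf.fit(train[FEATURES].to_numpy(), y)
        prob = clf.predict_proba(test[FEATURES].to_numpy())[:, list(clf.classes_).index(True)]
        for (_, row), p in zip(test.iterrows(), prob):
            out.append({"sample_id": row["sample_id"], "subject_id": row["subject_id"],
                        "group": row["group"], "score": float(p),
                        "fold": row["subject_id"], "mode": mode})
    result = pd.DataFrame(out)
    assert not result["sample_id"].duplicated().any(), "sample scored more than once"
    return result


# ---------------------------------------------------------------------------
# ROC / operating points
# ---------------------------------------------------------------------------

def roc_auc(scores, labels) -> float:
    """AUC by the rank (Mann-Whitney) formulation; tied scores count 1/2.

    Equals the trapezoidal area under the step ROC, and equals U / (n1 * n2)
    for the Mann-Whitney U statistic on the same scores.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    ranks = rankdata(s)
    u = ranks[y].sum() - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * n_neg))


def roc_curve_points(scores, labels) -> pd.DataFrame:
    """Step-ROC operating points (threshold, fpr, tpr) at strict score > cut."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    rows = [{"threshold": np.inf, "fpr": 0.0, "tpr": 0.0}]
    for thr in np.unique(s)[::-1]:
        pred = s > thr
        rows.append({
            "threshold": thr,
            "fpr": float((pred & ~y).sum() / n_neg),
            "tpr": float((pred & y).sum() / n_pos),
        })
        # the lowest unique score as threshold already yields pred-none; add
        # the all-positive endpoint explicitly
    rows.append({"threshold": -np.inf, "fpr": 1.0, "tpr": 1.0})
    return pd.DataFrame(rows)


@dataclass
class SensSpecResult:
    sensitivity: float
    specificity: float
    threshold: float
    tp: int
    fp: int
    tn: int
    fn: int
    target_reached: bool


def sensitivity_at_specificity(scores, labels, target_spec: float) -> SensSpecResult:
    """Best sensitivity subject to specificity >= target, with confusion counts.

    Predictions use strict score > threshold; candidate thresholds are the
    observed scores (each realizable cut).  Ties in sensitivity break toward
    the more specific (higher) threshold.  If no cut reaches the target the
    most specific cut is returned flagged ``target_reached=False``.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    best = None  # (sens, spec, thr)
    for thr in np.unique(s)[::-1]:  # descending: most specific cuts first
        pred = s > thr
        sens = (pred & y).sum() / n_pos
        spec = (~pred & ~y).sum() / n_neg
        if spec >= target_spec and (best is None or sens > best[0]):
            best = (sens, spec, thr)
    reached = best is not None
    if not reached:  # most specific realizable cut: predict nothing positive
        thr = float(np.max(s))
        pred = s > thr
        best = ((pred & y).sum() / n_pos, 1.0, thr)
    sens, spec, thr = best
    pred = s > thr
    return SensSpecResult(
        sensitivity=float(sens),
        specificity=float(spec),
        threshold=float(thr),
        tp=int((pred & y).sum()),
        fp=int((pred & ~y).sum()),
        tn=int((~pred & ~y).sum()),
        fn=int((~pred & y).sum()),
        target_reached=reached,
    )
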