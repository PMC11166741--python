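"""Nested cross-validation, brain-age bias correction, and scoring.

The cohort is split at the subject level into k=5 outer folds (20% test
each); the remaining 80% is split again into training (64% of all subjects)
and validation (16%) sets.  Raw predicted brain age (PBA) is linearly
bias-corrected per fold: alpha and beta are the OLS slope/intercept of PBA on
chronological age over that fold's train+validation scans, and
PBA' = (PBA - beta) / alpha is applied to the fold's test scans.  The brain
age index is BAI = PBA' - PMA at scan.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from surfage.synthetic_cortex import Cohort


@dataclass
class FoldPlan:
    """Subject-level nested split: per fold, disjoint test/train/validation
    subject sets; the k test sets partition all subjects."""

    folds: list[dict[str, list[str]]]  # keys: test, train, val
    k: int
    seed: int

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump({"k": self.k, "seed": self.seed, "folds": self.folds}, fh)

    @classmethod
    def from_json(cls, path: str) -> "FoldPlan":
        with open(path) as fh:
            d = json.load(fh)
        return cls(d["folds"], d["k"], d["seed"])

    def check_no_leakage(self) -> None:
        all_subjects: set[str] = set()
        test_union: list[str] = []
        for i, f in enumerate(self.folds):
            test, train, val = set(f["test"]), set(f["train"]), set(f["val"])
            if test & train or test & val or train & val:
                raise AssertionError(f"fold {i}: overlapping subject sets")
            all_subjects |= test | train | val
            test_union.extend(f["test"])
        if len(test_union) != len(set(test_union)):
            raise AssertionError("a subject is tested in more than one fold")
        if set(test_union) != all_subjects:
            raise AssertionError("test sets do not partition the subjects")


@dataclass
class PredictionResult:
    scan_id: str
    fold: int
    pba_raw: float
    pba_corrected: float
    pma_scan: float

    @property
    def bai(self) -> float:
        return self.pba_corrected - self.pma_scan


def results_frame(results: list[PredictionResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "scan_id": [r.scan_id for r in results],
            "fold": [r.fold for r in results],
            "pba_raw": [r.pba_raw for r in results],
            "pba_corrected": [r.pba_corrected for r in results],
            "pma_scan": [r.pma_scan for r in results],
            "bai": [r.bai for r in results],
        }
    )


def make_folds(
    metadata: pd.DataFrame | Cohort, k: int = 5, seed: int = 0
) -> FoldPlan:
    """Stratified subject-level nested split.

    Subjects are stratified on the PMA quintile of their first scan, shuffled
    within strata, and dealt round-robin to the k test folds; within each
    fold's remainder, every fifth subject (20%) becomes validation, yielding
    64/16/20 train/validation/test proportions within +-1 subject.  All scans
    of a subject stay together.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    meta = metadata.metadata() if isinstance(metadata, Cohort) else metadata
    first = (
        meta.sort_values("pma_scan").groupby("subject_id", sort=True)["pma_scan"].first()
    )
    subjects = np.asarray(first.index)
    if len(subjects) < k:
        raise ValueError(f"need at least {k} subjects, have {len(subjects)}")
    quint = pd.qcut(first.to_numpy(), q=min(5, len(subjects)), labels=False,
                    duplicates="drop")
    rng = np.random.default_rng(seed)

    fold_of: dict[str, int] = {}
    counter = 0
    for q in np.unique(quint):
        idx = np.flatnonzero(quint == q)
        rng.shuffle(idx)
        for i in idx:
            fold_of[subjects[i]] = counter % k
            counter += 1

    folds = []
    for f in range(k):
        test = sorted(s for s, ff in fold_of.items() if ff == f)
        rest = sorted(s for s, ff in fold_of.items() if ff != f)
        order = rng.permutation(len(rest))
        n_val = int(round(len(rest) * (1.0 / k)))  # 16% of all = 20% of the 80%
        val_idx = set(order[:n_val].tolist())
        val = sorted(rest[i] for i in val_idx)
        train = sorted(rest[i] for i in range(len(rest)) if i not in val_idx)
        folds.append({"test": test, "train": train, "val": val})
    plan = FoldPlan(folds, k, seed)
    plan.check_no_leakage()
    return plan


def fit_bias_correction(
    pba_raw: np.ndarray, age: np.ndarray, fit_mask: np.ndarray | None = None
) -> tuple[float, float]:
    """OLS of raw PBA on chronological age over the fitting set -> (alpha, beta).

    The corrected prediction PBA' = (PBA - beta) / alpha then regresses on age
    with slope 1 and intercept 0 over the same set.
    """
    pba_raw = np.asarray(pba_raw, float)
    age = np.asarray(age, float)
    if fit_mask is not None:
        pba_raw, age = pba_raw[fit_mask], age[fit_mask]
    if pba_raw.size < 3:
        raise ValueError("need at least 3 fitting points")
    if np.var(age) == 0:
        raise ValueError("zero age variance in the fitting set")
    alpha, beta = np.polyfit(age, pba_raw, 1)
    if abs(alpha) < 1e-6:
        raise ValueError(
            f"degenerate predictor: bias-correction slope alpha={alpha:.2e}"
        )
    return float(alpha), float(beta)


def correct_and_index(
    pba_raw: np.ndarray,
    alpha: float,
    beta: float,
    pma: np.ndarray,
    scan_ids: list[str] | None = None,
    fold: int = 0,
) -> list[PredictionResult]:
    """Apply PBA' = (PBA - beta)/alpha and BAI = PBA' - PMA."""
    pba_raw = np.asarray(pba_raw, float)
    pma = np.asarray(pma, float)
    corrected = (pba_raw - beta) / alpha
    if scan_ids is None:
        scan_ids = [f"scan-{i}" for i in range(len(pba_raw))]
    return [
        PredictionResult(sid, fold, float(r), float(c), float(a))
        for sid, r, c, a in zip(scan_ids, pba_raw, corrected, pma)
    ]


def score_predictions(results: list[PredictionResult]) -> dict[str, float]:
    """Pooled MAE (weeks) and Pearson r of corrected PBA vs chronological PMA."""
    if len(results) < 2:
        raise ValueError("need at least 2 predictions to score")
    pred = np.array([r.pba_corrected for r in results])
    age = np.array([r.pma_scan for r in results])
    if np.var(age) == 0:
        raise ValueError("zero age variance: correlation undefined")
    mae = float(np.mean(np.abs(pred - age)))
    if np.var(pred) == 0:
        raise ValueError("constant predictions: correlation undefined")
    r = float(np.corrcoef(pred, age)[0, 1])
    return {"mae": mae, "r": r}


# --------------------------------------------------------------------------
# end-to-end pipeline
# --------------------------------------------------------------------------


@dataclass
class CVOutcome:
    results: list[PredictionResult]
    scores: dict[str, float]
    fold_params: list[dict] = field(default_factory=dict)


def _scan_split(meta: pd.DataFrame, subjects: list[str]) -> np.ndarray:
    return meta["subject_id"].isin(subjects).to_numpy()


def run_nested_cv(
    features: np.ndarray,
    meta: pd.DataFrame,
    predictor_factory,
    plan: FoldPlan | None = None,
    k: int = 5,
    seed: int = 0,
    folds_subset: list[int] | None = None,
) -> CVOutcome:
    """Nested k-fold CV of any predictor over a cohort.

    ``predictor_factory(fold_index)`` must return an object with
    ``fit(train_x, train_y, val_x, val_y)`` and ``predict(x) -> ages``.
    Per fold: fit on train (validation used for early stopping / model
    selection), fit bias correction on train+validation raw predictions,
    apply it to the fold's test scans.  Test predictions are pooled and
    scored jointly.  ``folds_subset`` restricts the run to some outer folds
    (a scaled-down evaluation; the pooled score then covers only those
    folds' test sets).
    """
    if plan is None:
        plan = make_folds(meta, k=k, seed=seed)
    plan.check_no_leakage()
    ages = meta["pma_scan"].to_numpy(float)
    all_results: list[PredictionResult] = []
    fold_params = []
    for f, fold in enumerate(plan.folds):
        if folds_subset is not None and f not in folds_subset:
            continue
        tr = _scan_split(meta, fold["train"])
        va = _scan_split(meta, fold["val"])
        te = _scan_split(meta, fold["test"])
        predictor = predictor_factory(f)
        predictor.fit(features[tr], ages[tr], features[va], ages[va])
        fit_mask = tr | va
        raw_fit = predictor.predict(features[fit_mask])
        alpha, beta = fit_bias_correction(raw_fit, ages[fit_mask])
        raw_test = predictor.predict(features[te])
        all_results.extend(
            correct_and_index(
                raw_test, alpha, beta, ages[te],
                scan_ids=meta.loc[te, "scan_id"].tolist(), fold=f,
            )
        )
        fold_params.append({"fold": f, "alpha": alpha, "beta": beta})
    return CVOutcome(all_results, score_predictions(all_results), fold_params)
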