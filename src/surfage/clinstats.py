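"""Downstream clinical statistics on the brain age index (BAI).

Clinical variables are dichotomized (clinically defined threshold, e.g.
birthweight < 1000 g, or a median split when no threshold is established);
group differences in BAI are tested with a linear mixed-effects model
(random intercept per subject, handling repeat scans) correcting for PMA at
scan and the other clinical factors; p-values are Benjamini-Hochberg
adjusted; and BAI is correlated with neurodevelopmental outcome scores.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.regression.mixed_linear_model import MixedLM
from statsmodels.stats.multitest import multipletests


def dichotomize(
    values: np.ndarray | pd.Series,
    rule: str = "median",
    threshold: float | None = None,
    low_is_one: bool = True,
) -> np.ndarray:
    """Binary coding of a clinical variable.

    ``threshold`` rule: label 1 for values <= threshold when ``low_is_one``
    (e.g. birthweight <= 1000 g codes the at-risk group as 1), else 1 above.
    ``median`` rule: split at the sample median, ties assigned to the lower
    group.  Already-binary input is returned unchanged.
    """
    v = np.asarray(values, dtype=float)
    uniq = np.unique(v[~np.isnan(v)])
    if set(uniq.tolist()) <= {0.0, 1.0}:
        return v.astype(int)
    if rule == "threshold":
        if threshold is None:
            raise ValueError("threshold rule requires a threshold")
        cut = threshold
    elif rule == "median":
        if uniq.size < 2:
            raise ValueError("constant input cannot be median-split")
        cut = float(np.nanmedian(v))
    else:
        raise ValueError(f"unknown rule {rule!r}")
    labels = (v <= cut).astype(int)
    return labels if low_is_one else 1 - labels


@dataclass
class AssocResult:
    factor: str
    estimate: float
    se: float
    t: float
    p: float
    n_scans: int
    dropped_covariates: list[str]


def _drop_collinear(x: np.ndarray, names: list[str]) -> tuple[np.ndarray, list[str], list[str]]:
    kept_idx: list[int] = []
    dropped: list[str] = []
    for j in range(x.shape[1]):
        trial = x[:, kept_idx + [j]]
        if np.linalg.matrix_rank(trial) == len(kept_idx) + 1:
            kept_idx.append(j)
        else:
            dropped.append(names[j])
    return x[:, kept_idx], [names[j] for j in kept_idx], dropped


def mixed_assoc(
    bai: np.ndarray,
    factor: np.ndarray,
    subject_ids: np.ndarray | list[str],
    covariates: pd.DataFrame | None = None,
) -> AssocResult:
    """Fixed effect of a binary clinical factor on BAI.

    Model: BAI ~ factor + covariates with a random intercept per subject
    (REML).  Covariates that are collinear with the factor or each other are
    dropped with a warning.  With one scan per subject the random intercept
    is unidentifiable and the estimates collapse to ordinary least squares.
    """
    bai = np.asarray(bai, float)
    factor = np.asarray(factor, float)
    groups = np.asarray(subject_ids)
    levels, counts = np.unique(factor, return_counts=True)
    if len(levels) < 2 or counts.min() < 2:
        raise ValueError("each factor level needs at least 2 scans")

    cols = [np.ones_like(bai), factor]
    names = ["intercept", "factor"]
    if covariates is not None:
        for c in covariates.columns:
            col = covariates[c]
            if col.dtype == object or str(col.dtype) == "category":
                col = pd.factorize(col, sort=True)[0]
            cols.append(np.asarray(col, float))
            names.append(str(c))
    x = np.column_stack(cols)
    x, kept, dropped = _drop_collinear(x, names)
    if "factor" not in kept:
        raise ValueError("factor is collinear with the covariates")
    if dropped:
        warnings.warn(f"dropped collinear covariates: {dropped}", stacklevel=2)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = MixedLM(bai, x, groups=groups)
        try:
            fit = model.fit(reml=True)
        except np.linalg.LinAlgError:
            fit = model.fit(reml=True, method="powell")
    if not np.all(np.isfinite(fit.params)):
        raise RuntimeError("mixed model did not converge (non-finite estimates)")
    j = kept.index("factor")
    return AssocResult(
        factor="factor",
        estimate=float(fit.fe_params[j]),
        se=float(fit.bse_fe[j]),
        t=float(fit.tvalues[j]),
        p=float(fit.pvalues[j]),
        n_scans=len(bai),
        dropped_covariates=dropped,
    )


def fdr_adjust(p_values: np.ndarray | list[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values."""
    p = np.asarray(p_values, float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def association_table(
    bai_frame: pd.DataFrame,
    factors: list[str],
    covariate_names: list[str] | None = None,
    min_level_count: int = 10,
) -> pd.DataFrame:
    """Univariate mixed-model association of BAI with each dichotomized
    factor, correcting for PMA at scan and the other factors; FDR across
    factors.  Factors whose minority level has fewer than ``min_level_count``
    scans are excluded (small-sample guard, as for necrotizing enterocolitis).
    """
    covariate_names = covariate_names or ["pma_scan"]
    usable = []
    for f in factors:
        counts = bai_frame[f].value_counts()
        if len(counts) >= 2 and counts.min() >= min_level_count:
            usable.append(f)
    rows = []
    for f in usable:
        others = [c for c in usable if c != f]
        cov = bai_frame[covariate_names + others]
        res = mixed_assoc(
            bai_frame["bai"].to_numpy(),
            bai_frame[f].to_numpy(),
            bai_frame["subject_id"].to_numpy(),
            covariates=cov,
        )
        rows.append(
            {"factor": f, "estimate": res.estimate, "se": res.se,
             "t": res.t, "p": res.p}
        )
    out = pd.DataFrame(rows)
    if len(out):
        out["q"] = fdr_adjust(out["p"].to_numpy())
    return out


def outcome_correlation(
    bai_frame: pd.DataFrame, outcome_names: list[str]
) -> pd.DataFrame:
    """Pearson correlation of BAI with each outcome score, FDR-adjusted.

    For longitudinal subjects only the latest scan is used; subjects without
    a given outcome are dropped pairwise.
    """
    latest = (
        bai_frame.sort_values("pma_scan").groupby("subject_id", sort=True).last()
    )
    rows = []
    for name in outcome_names:
        if name not in latest.columns:
            continue
        sub = latest[["bai", name]].dropna()
        if len(sub) < 4:
            raise ValueError(f"fewer than 4 paired observations for {name}")
        x, y = sub["bai"].to_numpy(), sub[name].to_numpy()
        if np.var(x) == 0 or np.var(y) == 0:
            raise ValueError(f"zero variance in BAI or {name}")
        r, p = stats.pearsonr(x, y)
        rows.append({"outcome": name, "r": float(r), "p": float(p), "n": len(sub)})
    out = pd.DataFrame(rows)
    if len(out):
        out["q"] = fdr_adjust(out["p"].to_numpy())
    return out
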