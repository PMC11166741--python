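"""Parametric empirical-Bayes ComBat harmonization of vertexwise features.

Removes additive (location) and multiplicative (scale) acquisition-site
effects from scans x vertices feature matrices while preserving designated
biological covariates (PMA at scan, sex, ...).  Site parameters are shrunk
toward an across-vertex prior by the standard parametric EB update: a normal
prior on the location gamma and an inverse-gamma prior on the squared scale
delta^2, iterated to convergence.
"""

from __future__ import annotations

import json
import zipfile
from dataclasses import dataclass

import numpy as np
import pandas as pd

_SIGMA_FLOOR = 1e-8


@dataclass
class CombatModel:
    sites: list[str]
    grand_mean: np.ndarray  # alpha_v, (n_vertices,)
    beta: np.ndarray  # covariate coefficients, (n_covariates, n_vertices)
    pooled_sd: np.ndarray  # sigma_v, (n_vertices,)
    gamma_star: np.ndarray  # (n_sites, n_vertices)
    delta_star: np.ndarray  # (n_sites, n_vertices), > 0
    covariate_names: list[str]

    def save(self, path: str) -> None:
        with zipfile.ZipFile(path, "w") as zf:
            zf.writestr(
                "header.json",
                json.dumps({"sites": self.sites, "covariates": self.covariate_names}),
            )
            for name in ("grand_mean", "beta", "pooled_sd", "gamma_star", "delta_star"):
                arr = np.atleast_2d(getattr(self, name))
                zf.writestr(
                    name + ".tsv",
                    "\n".join("\t".join(repr(float(v)) for v in row) for row in arr),
                )

    @classmethod
    def load(cls, path: str) -> "CombatModel":
        with zipfile.ZipFile(path) as zf:
            header = json.loads(zf.read("header.json"))

            def read(name):
                rows = zf.read(name + ".tsv").decode().splitlines()
                return np.array([[float(v) for v in r.split("\t")] for r in rows])

            return cls(
                sites=header["sites"],
                grand_mean=read("grand_mean").ravel(),
                beta=read("beta"),
                pooled_sd=read("pooled_sd").ravel(),
                gamma_star=read("gamma_star"),
                delta_star=read("delta_star"),
                covariate_names=header["covariates"],
            )


def _design(covariates: pd.DataFrame | np.ndarray | None) -> tuple[np.ndarray, list[str]]:
    if covariates is None:
        return np.empty((0, 0)), []
    if isinstance(covariates, pd.DataFrame):
        x = covariates.copy()
        for col in x.columns:
            if x[col].dtype == object or str(x[col].dtype) == "category":
                x[col] = pd.factorize(x[col], sort=True)[0]
        return x.to_numpy(float), list(covariates.columns)
    arr = np.asarray(covariates, float)
    if arr.ndim == 1:
        arr = arr[:, None]
    return arr, [f"x{i}" for i in range(arr.shape[1])]


def _postmean(g_hat, g_bar, n, d_star, t2):
    return (n * t2 * g_hat + d_star * g_bar) / (n * t2 + d_star)


def _postvar(ssq, n, lam, theta):
    return (theta + 0.5 * ssq) / (n / 2.0 + lam - 1.0)


def fit_combat(
    data: np.ndarray,
    site: np.ndarray | list[str],
    covariates: pd.DataFrame | np.ndarray | None = None,
    tol: float = 1e-6,
    max_iter: int = 200,
) -> CombatModel:
    """Fit parametric EB ComBat on a scans x vertices matrix.

    ``covariates`` are the protected biological covariates (columns of the
    design besides site, e.g. PMA at scan and sex); their contribution is
    estimated jointly with site means and restored unchanged after
    harmonization.
    """
    y = np.asarray(data, float)
    site = np.asarray(site)
    n, _ = y.shape
    sites = sorted(pd.unique(site).tolist())
    if len(sites) < 1:
        raise ValueError("no sites")
    counts = {s: int((site == s).sum()) for s in sites}
    singles = [s for s, c in counts.items() if c < 2]
    if singles:
        raise ValueError(
            f"site(s) {singles} have <2 scans; use a reference-site design "
            "or merge sites before harmonization"
        )
    batch = np.column_stack([(site == s).astype(float) for s in sites])
    x_cov, cov_names = _design(covariates)
    design = np.column_stack([batch, x_cov]) if cov_names else batch
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        raise ValueError(
            f"design is rank deficient ({rank} < {design.shape[1]}); a covariate "
            "is collinear with site or another covariate"
        )

    # OLS per vertex; grand mean is the scan-count-weighted mean of site means
    bhat, *_ = np.linalg.lstsq(design, y, rcond=None)
    site_means = bhat[: len(sites)]
    weights = np.array([counts[s] / n for s in sites])
    grand = weights @ site_means
    beta_cov = bhat[len(sites):]
    fitted = design @ bhat
    var_pooled = ((y - fitted) ** 2).mean(axis=0)
    sigma = np.sqrt(np.maximum(var_pooled, _SIGMA_FLOOR**2))

    stand = grand + (x_cov @ beta_cov if cov_names else 0.0)
    z = (y - stand) / sigma

    gamma_star = np.empty((len(sites), y.shape[1]))
    delta_star = np.empty_like(gamma_star)
    for i, s in enumerate(sites):
        zi = z[site == s]
        ni = zi.shape[0]
        g_hat = zi.mean(axis=0)
        d_hat = zi.var(axis=0, ddof=1)
        # hyperpriors by moments across vertices
        g_bar, t2 = g_hat.mean(), g_hat.var()
        m, v = d_hat.mean(), d_hat.var()
        lam = (m**2 + 2 * v) / v if v > 0 else 2.0
        theta = (m**3 + m * v) / v if v > 0 else 1.0
        g_new, d_new = g_hat.copy(), d_hat.copy()
        for _ in range(max_iter):
            g_old, d_old = g_new, d_new
            g_new = _postmean(g_hat, g_bar, ni, d_new, t2) if t2 > 0 else g_hat
            ssq = ((zi - g_new) ** 2).sum(axis=0)
            d_new = _postvar(ssq, ni, lam, theta)
            change = max(
                np.abs(g_new - g_old).max() / (np.abs(g_old).max() + 1e-12),
                np.abs(d_new - d_old).max() / (np.abs(d_old).max() + 1e-12),
            )
            if change < tol:
                break
        gamma_star[i] = g_new
        delta_star[i] = np.sqrt(np.maximum(d_new, _SIGMA_FLOOR**2))
    return CombatModel(
        sites=sites,
        grand_mean=grand,
        beta=beta_cov,
        pooled_sd=sigma,
        gamma_star=gamma_star,
        delta_star=delta_star,
        covariate_names=cov_names,
    )


def apply_combat(
    model: CombatModel,
    data: np.ndarray,
    site: np.ndarray | list[str],
    covariates: pd.DataFrame | np.ndarray | None = None,
) -> np.ndarray:
    """Harmonize: Y* = (sigma_v / delta*_iv) (Z - gamma*_iv) + alpha_v + X beta_v."""
    y = np.asarray(data, float)
    site = np.asarray(site)
    unseen = set(pd.unique(site)) - set(model.sites)
    if unseen:
        raise ValueError(f"site(s) {sorted(unseen)} not present in the fitted model")
    x_cov, cov_names = _design(covariates)
    if cov_names and len(cov_names) != len(model.covariate_names):
        raise ValueError(
            f"expected covariates {model.covariate_names}, got {cov_names}"
        )
    stand = model.grand_mean + (x_cov @ model.beta if cov_names else 0.0)
    z = (y - stand) / model.pooled_sd
    out = np.empty_like(y)
    for i, s in enumerate(model.sites):
        m = site == s
        if not m.any():
            continue
        adj = (z[m] - model.gamma_star[i]) / model.delta_star[i]
        out[m] = adj * model.pooled_sd + (
            stand[m] if np.ndim(stand) == 2 else stand
        )
    # degenerate (zero-variance) vertices: sigma at floor -> pass input through
    degen = model.pooled_sd <= _SIGMA_FLOOR
    if degen.any():
        out[:, degen] = y[:, degen]
    if not np.all(np.isfinite(out)):
        raise FloatingPointError("non-finite harmonized values")
    return out


def harmonize_cohort(
    features: np.ndarray,
    site: np.ndarray | list[str],
    covariates: pd.DataFrame | None = None,
) -> tuple[np.ndarray, list[CombatModel]]:
    """Fit-and-apply ComBat independently per feature channel.

    ``features``: (n_scans, n_vertices, n_features).  Fitting on the whole
    cohort before cross-validation mirrors harmonization being performed
    prior to model training; see the methods note for the leakage trade-off
    and the fold-wise alternative.
    """
    out = np.empty_like(features)
    models = []
    for f in range(features.shape[2]):
        model = fit_combat(features[:, :, f], site, covariates)
        out[:, :, f] = apply_combat(model, features[:, :, f], site, covariates)
        models.append(model)
    return out, models
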