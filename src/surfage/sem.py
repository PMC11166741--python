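"""RAM-parameterized structural equation modelling with latent variables.

A model over v variables (observed + latent) is held as the reticular action
model triple (A, S, F): A collects directed path coefficients, S symmetric
(co)variances of the exogenous terms, and F filters the observed rows.  The
implied covariance of the observed variables is

    Sigma(theta) = F (I - A)^(-1) S (I - A)^(-T) F^T.

Parameters are estimated by minimizing the maximum-likelihood discrepancy
F_ML = ln|Sigma| + tr(C Sigma^(-1)) - ln|C| - p with an analytic gradient;
chi-square = (n - 1) F_ML at the optimum.  Indirect (mediation) effects are
products of path coefficients with nonparametric-bootstrap intervals.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats


@dataclass
class SemSpec:
    """Free/fixed structure of the RAM matrices.

    ``a_free``/``s_free`` hold the parameter index at each free cell (-1 if
    fixed); fixed values live in ``a_fixed``/``s_fixed``.  One loading per
    latent must be fixed (usually to 1) for identification.
    """

    variables: list[str]
    observed: list[str]
    a_free: np.ndarray
    a_fixed: np.ndarray
    s_free: np.ndarray
    s_fixed: np.ndarray
    param_names: list[str]

    @property
    def n_params(self) -> int:
        return len(self.param_names)

    @property
    def latent(self) -> list[str]:
        return [v for v in self.variables if v not in self.observed]

    def filter_matrix(self) -> np.ndarray:
        f = np.zeros((len(self.observed), len(self.variables)))
        for i, name in enumerate(self.observed):
            f[i, self.variables.index(name)] = 1.0
        return f

    def degrees_of_freedom(self) -> int:
        p = len(self.observed)
        return p * (p + 1) // 2 - self.n_params

    def matrices(self, theta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        a = self.a_fixed.copy()
        s = self.s_fixed.copy()
        mask_a = self.a_free >= 0
        a[mask_a] = theta[self.a_free[mask_a]]
        mask_s = self.s_free >= 0  # symmetric by construction
        s[mask_s] = theta[self.s_free[mask_s]]
        return a, s

    @classmethod
    def from_lines(cls, lines: list[str], observed: list[str]) -> "SemSpec":
        """Build a spec from a small path DSL.

        ``A -> B`` free path from A to B; ``A -> B @1`` fixes it (e.g. the
        identifying loading); ``A ~~ B`` free (co)variance; ``A ~~ B @0.5``
        fixed.  Every variable automatically gets a free variance unless its
        ``A ~~ A`` entry is given explicitly.
        """
        paths, covs = [], []
        names: list[str] = []

        def note(v):
            if v not in names:
                names.append(v)

        pat = re.compile(r"^\s*(\S+)\s*(->|~~)\s*(\S+)\s*(?:@([-\d.eE]+))?\s*$")
        for line in lines:
            line = line.split("#")[0].strip()
            if not line:
                continue
            m = pat.match(line)
            if not m:
                raise ValueError(f"cannot parse model line: {line!r}")
            src, op, dst, fixed = m.groups()
            note(src), note(dst)
            val = None if fixed is None else float(fixed)
            (paths if op == "->" else covs).append((src, dst, val))

        variables = [v for v in observed if v in names] + [
            v for v in names if v not in observed
        ]
        nv = len(variables)
        idx = {v: i for i, v in enumerate(variables)}
        a_free = -np.ones((nv, nv), dtype=np.int64)
        a_fixed = np.zeros((nv, nv))
        s_free = -np.ones((nv, nv), dtype=np.int64)
        s_fixed = np.zeros((nv, nv))
        param_names: list[str] = []

        def new_param(name):
            param_names.append(name)
            return len(param_names) - 1

        for src, dst, val in paths:
            i, j = idx[dst], idx[src]  # A[i, j]: path j -> i
            if val is None:
                a_free[i, j] = new_param(f"{src}->{dst}")
            else:
                a_fixed[i, j] = val
        explicit_var = {(s, d) for s, d, _ in covs}
        for src, dst, val in covs:
            i, j = sorted((idx[src], idx[dst]))
            if val is None:
                k = new_param(f"{src}~~{dst}")
                s_free[i, j] = k
                s_free[j, i] = k
            else:
                s_fixed[i, j] = s_fixed[j, i] = val
        for v in variables:
            if (v, v) not in explicit_var:
                i = idx[v]
                s_free[i, i] = new_param(f"{v}~~{v}")
        return cls(variables, [v for v in observed if v in names],
                   a_free, a_fixed, s_free, s_fixed, param_names)


def implied_covariance(spec: SemSpec, theta: np.ndarray) -> np.ndarray:
    """Sigma(theta) = F (I-A)^(-1) S (I-A)^(-T) F^T."""
    a, s = spec.matrices(np.asarray(theta, float))
    nv = len(spec.variables)
    ia = np.eye(nv) - a
    try:
        b = np.linalg.inv(ia)
    except np.linalg.LinAlgError as err:
        raise ValueError("(I - A) is singular") from err
    f = spec.filter_matrix()
    sigma = f @ b @ s @ b.T @ f.T
    return (sigma + sigma.T) / 2.0


@dataclass
class SemFit:
    spec: SemSpec
    theta: np.ndarray
    se: np.ndarray
    chi2: float
    df: int
    p_value: float
    n: int
    f_ml: float
    converged: bool
    heywood: bool
    standardized: dict[str, float] = field(default_factory=dict)

    def table(self) -> pd.DataFrame:
        z = self.theta / np.where(self.se > 0, self.se, np.nan)
        return pd.DataFrame(
            {
                "parameter": self.spec.param_names,
                "estimate": self.theta,
                "se": self.se,
                "z": z,
                "p": 2 * stats.norm.sf(np.abs(z)),
                "standardized": [
                    self.standardized.get(n, np.nan) for n in self.spec.param_names
                ],
            }
        )

    def path_estimate(self, src: str, dst: str) -> float:
        return float(self.theta[self.spec.param_names.index(f"{src}->{dst}")])


def _fml_and_grad(spec: SemSpec, theta, c, logdet_c):
    nv = len(spec.variables)
    p = c.shape[0]
    a, s = spec.matrices(theta)
    ia = np.eye(nv) - a
    try:
        b = np.linalg.inv(ia)
    except np.linalg.LinAlgError:
        return 1e10, np.zeros_like(theta)
    f = spec.filter_matrix()
    fb = f @ b
    sigma = fb @ s @ fb.T
    sigma = (sigma + sigma.T) / 2.0
    sign, logdet = np.linalg.slogdet(sigma)
    if sign <= 0:
        return 1e10, np.zeros_like(theta)
    sinv = np.linalg.inv(sigma)
    fml = logdet + float(np.trace(c @ sinv)) - logdet_c - p
    # dF = tr[(Sinv - Sinv C Sinv) dSigma] =: tr[M0 dSigma]
    m0 = sinv - sinv @ c @ sinv
    mb = b.T @ f.T @ m0 @ f @ b  # B^T F^T M0 F B, (nv, nv)
    grad = np.zeros_like(theta)
    # dF/dA_ij = 2 [B^T F^T M0 F B S B^T]_ij
    ga = 2.0 * mb @ s @ b.T
    mask_a = spec.a_free >= 0
    np.add.at(grad, spec.a_free[mask_a], ga[mask_a])
    # dF/dS_kk = [B^T M B]_kk ; dF/dS_kl (k != l) = 2 [B^T M B]_kl
    gs = mb.copy()
    gs = gs + gs.T - np.diag(np.diag(gs))  # doubles off-diagonals
    mask_s = spec.s_free >= 0
    iu = np.triu(mask_s)
    np.add.at(grad, spec.s_free[iu], gs[iu])
    return fml, grad


def fit_sem(
    spec: SemSpec,
    data: pd.DataFrame | None = None,
    sample_cov: np.ndarray | None = None,
    n: int | None = None,
    theta0: np.ndarray | None = None,
) -> SemFit:
    """Maximum-likelihood fit via L-BFGS with analytic gradient.

    Start values: free paths at 0, observed variances at half their sample
    variance, latent variances at 1, covariances at 0.  Standard errors come
    from the inverse numerical Hessian of F_ML scaled by 2/(n-1).
    """
    if data is not None:
        data = data[spec.observed]
        c = np.cov(data.to_numpy(float).T, ddof=1)
        n = len(data)
    else:
        if sample_cov is None or n is None:
            raise ValueError("provide data, or sample_cov and n")
        c = np.asarray(sample_cov, float)
    p = len(spec.observed)
    if n <= p:
        raise ValueError(f"need n > p ({n} <= {p})")
    sign, logdet_c = np.linalg.slogdet(c)
    if sign <= 0:
        raise ValueError("sample covariance is not positive definite")

    if theta0 is None:
        theta0 = np.zeros(spec.n_params)
        var_idx = {v: i for i, v in enumerate(spec.variables)}
        diag_c = {name: c[i, i] for i, name in enumerate(spec.observed)}
        for k, name in enumerate(spec.param_names):
            if "~~" in name:
                a, b_ = name.split("~~")
                if a == b_:
                    theta0[k] = 0.5 * diag_c.get(a, 2.0) if a in diag_c else 1.0
                else:
                    theta0[k] = 0.0
            else:
                theta0[k] = 0.1 if name.count("->") else 0.0

    res = optimize.minimize(
        lambda t: _fml_and_grad(spec, t, c, logdet_c),
        theta0,
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": 2000, "ftol": 1e-12, "gtol": 1e-9},
    )
    theta = res.x
    fml = float(res.fun)
    chi2 = (n - 1) * fml
    df = spec.degrees_of_freedom()
    p_value = float(stats.chi2.sf(chi2, df)) if df > 0 else 1.0

    # numerical Hessian of F_ML from the analytic gradient
    h = np.zeros((spec.n_params, spec.n_params))
    eps = 1e-5 * np.maximum(np.abs(theta), 1.0)
    for k in range(spec.n_params):
        tp, tm = theta.copy(), theta.copy()
        tp[k] += eps[k]
        tm[k] -= eps[k]
        gp = _fml_and_grad(spec, tp, c, logdet_c)[1]
        gm = _fml_and_grad(spec, tm, c, logdet_c)[1]
        h[k] = (gp - gm) / (2 * eps[k])
    h = (h + h.T) / 2.0
    try:
        acov = (2.0 / (n - 1)) * np.linalg.inv(h)
        se = np.sqrt(np.maximum(np.diag(acov), 0.0))
    except np.linalg.LinAlgError:
        se = np.full(spec.n_params, np.nan)

    a, s = spec.matrices(theta)
    heywood = bool(np.any(np.diag(s)[spec.s_free.diagonal() >= 0] < 0))
    nv = len(spec.variables)
    b = np.linalg.inv(np.eye(nv) - a)
    sigma_all = b @ s @ b.T
    sd_all = np.sqrt(np.maximum(np.diag(sigma_all), 1e-300))
    standardized = {}
    for k, name in enumerate(spec.param_names):
        if "->" in name:
            src, dst = name.split("->")
            i, j = spec.variables.index(dst), spec.variables.index(src)
            standardized[name] = float(theta[k] * sd_all[j] / sd_all[i])
        else:
            src, dst = name.split("~~")
            i, j = spec.variables.index(src), spec.variables.index(dst)
            standardized[name] = float(theta[k] / (sd_all[i] * sd_all[j]))
    return SemFit(spec, theta, se, float(chi2), df, p_value, int(n), fml,
                  bool(res.success), heywood, standardized)


def simulate_from_sem(
    spec: SemSpec, theta: np.ndarray, n: int, seed: int = 0
) -> pd.DataFrame:
    """Draw exogenous terms from N(0, S), propagate through (I - A)^(-1),
    and return the observed columns."""
    rng = np.random.default_rng(seed)
    a, s = spec.matrices(np.asarray(theta, float))
    nv = len(spec.variables)
    # PSD factor of S via eigendecomposition (S may be singular)
    w, v = np.linalg.eigh((s + s.T) / 2.0)
    if w.min() < -1e-8:
        raise ValueError("S is not positive semidefinite at these parameters")
    factor = v @ np.diag(np.sqrt(np.maximum(w, 0.0)))
    u = rng.standard_normal((n, nv)) @ factor.T
    x = np.linalg.solve(np.eye(nv) - a, u.T).T
    f = spec.filter_matrix()
    return pd.DataFrame(x @ f.T, columns=spec.observed)


def indirect_effect(fit: SemFit, chain: list[str]) -> float:
    """Product of path coefficients along a mediation chain [x, m, ..., y]."""
    est = 1.0
    for src, dst in zip(chain[:-1], chain[1:]):
        est *= fit.path_estimate(src, dst)
    return float(est)


def bootstrap_indirect(
    spec: SemSpec,
    data: pd.DataFrame,
    chain: list[str],
    n_boot: int = 2000,
    seed: int = 0,
    level: float = 0.95,
) -> dict:
    """Nonparametric bootstrap interval for an indirect effect."""
    fit = fit_sem(spec, data=data)
    point = indirect_effect(fit, chain)
    rng = np.random.default_rng(seed)
    n = len(data)
    draws = np.empty(n_boot)
    arr = data[spec.observed].to_numpy(float)
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        boot = pd.DataFrame(arr[idx], columns=spec.observed)
        bfit = fit_sem(spec, data=boot, theta0=fit.theta)
        draws[b] = indirect_effect(bfit, chain)
    lo, hi = np.quantile(draws, [(1 - level) / 2, 1 - (1 - level) / 2])
    return {"estimate": point, "ci": (float(lo), float(hi)),
            "n_boot": n_boot, "level": level}


def default_path_model() -> tuple[SemSpec, list[str]]:
    """The default mediation template: three upstream latents (severity of
    preterm birth, perinatal injuries, postnatal factors), BAI as manifest
    mediator, and a neurodevelopmental-outcome latent.  Returns the spec and
    its observed-variable list."""
    observed = [
        "ga_birth", "birthweight",
        "ivh", "vm", "pvl",
        "cld", "steroids", "hypotension",
        "bai",
        "cognitive", "language", "motor",
    ]
    lines = [
        "preterm -> ga_birth @1",
        "preterm -> birthweight",
        "injury -> ivh @1",
        "injury -> vm",
        "injury -> pvl",
        "postnatal -> cld @1",
        "postnatal -> steroids",
        "postnatal -> hypotension",
        "preterm -> bai",
        "injury -> bai",
        "postnatal -> bai",
        "preterm -> outcome",
        "injury -> outcome",
        "postnatal -> outcome",
        "bai -> outcome",
        "outcome -> cognitive @1",
        "outcome -> language",
        "outcome -> motor",
        "preterm ~~ injury",
        "preterm ~~ postnatal",
        "injury ~~ postnatal",
    ]
    return SemSpec.from_lines(lines, observed), observed
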