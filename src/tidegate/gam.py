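"""Penalized binomial additive models with per-tag random intercepts.

The three analysis tables (seasonal detection, seasonal roaming, intra-day
detection) are modelled with binomial GAMs:

    logit E[y] = intercept + factors + sum_j f_j(x_j) [+ by-factor smooths]
                 + random intercept per tag

Smooth terms use penalized regression splines: cubic P-splines (equally
spaced B-spline basis with a second-order difference penalty) for aperiodic
covariates, and cyclic cubic regression splines (value-based basis with the
exact integrated-squared-second-derivative penalty and f matching at the
period ends) for month and hour.  Random intercepts are the standard
GAMM-as-GAM device: one dummy per tag with a ridge penalty, so the tag
variance is just another smoothing parameter; "tag:sex" stratifies the
ridge block (and its smoothing parameter) by sex.

Fitting is penalized IRLS; smoothing parameters minimise the UBRE/GCV score
(deviance/n + 2*edf/n, binomial scale fixed at 1) by a derivative-free outer
search.  Effective degrees of freedom are tr[(X'WX + S)^-1 X'WX], per term
by block.  Model ranking uses AICc = AIC + 2k(k+1)/(n-k-1) with k = total
effective parameters; AICc values are backend-sensitive, so candidate sets
should be compared by ranking and recovery rather than against printed
values from other software.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline
from scipy.optimize import minimize
from scipy.special import expit, gammaln
from scipy.stats import chi2

__all__ = [
    "Smooth",
    "ModelSpec",
    "BinomialGAM",
    "GAMResults",
    "aicc",
    "aicc_rank",
]

_EPS = 1e-10


def _factor_values(data: pd.DataFrame, name: str) -> pd.Series:
    """Factor column; ``a:b`` builds the interaction of two categoricals."""
    if ":" in name:
        a, b = name.split(":", 1)
        return data[a].astype(str) + ":" + data[b].astype(str)
    return data[name].astype(str)


# ---------------------------------------------------------------------------
# spline bases


class PSplineBasis:
    """Cubic B-spline basis on equally spaced knots, 2nd-difference penalty."""

    def __init__(self, x: np.ndarray, df: int = 8, degree: int = 3):
        x = np.asarray(x, dtype=float)
        lo, hi = float(np.min(x)), float(np.max(x))
        if hi <= lo:
            hi = lo + 1.0
        self.degree = degree
        n_inner = df - degree + 1
        if n_inner < 2:
            raise ValueError(f"P-spline df={df} too small for degree {degree}")
        inner = np.linspace(lo, hi, n_inner)
        step = inner[1] - inner[0]
        self.knots = np.concatenate(
            [lo - step * np.arange(degree, 0, -1), inner,
             hi + step * np.arange(1, degree + 1)]
        )
        self.lo, self.hi = lo, hi
        self.n_coef = df
        D = np.diff(np.eye(df), n=2, axis=0)
        self.penalty = D.T @ D
        self.means = np.zeros(df)
        self.means = self.transform(x).mean(axis=0) + self.means

    def transform(self, x) -> np.ndarray:
        x = np.clip(np.asarray(x, dtype=float), self.lo, self.hi)
        B = BSpline.design_matrix(x, self.knots, self.degree).toarray()
        return B - self.means


class CyclicBasis:
    """Cyclic cubic regression spline on [lo, hi] with exact curvature penalty.

    Coefficients are the function values at the knots; the value and the
    first two derivatives match at the period ends, so predictions are
    periodic by construction.
    """

    def __init__(self, x: np.ndarray, df: int = 6, bounds: tuple | None = None):
        x = np.asarray(x, dtype=float)
        if bounds is None:
            bounds = (float(np.min(x)), float(np.max(x)))
        self.lo, self.hi = float(bounds[0]), float(bounds[1])
        self.period = self.hi - self.lo
        if self.period <= 0:
            raise ValueError("cyclic bounds must have hi > lo")
        k = df
        if k < 3:
            raise ValueError("cyclic basis needs df >= 3")
        self.knots = np.linspace(self.lo, self.hi, k + 1)[:-1]  # last knot == first
        h = np.full(k, self.period / k)
        self.h = h
        B = np.zeros((k, k))
        D = np.zeros((k, k))
        for i in range(k):
            im1 = (i - 1) % k
            ip1 = (i + 1) % k
            B[i, i] = (h[im1] + h[i]) / 3.0
            B[i, im1] += h[im1] / 6.0
            B[i, ip1] += h[i] / 6.0
            D[i, i] = -(1.0 / h[im1] + 1.0 / h[i])
            D[i, im1] += 1.0 / h[im1]
            D[i, ip1] += 1.0 / h[i]
        self.BinvD = np.linalg.solve(B, D)
        self.penalty = D.T @ self.BinvD  # integral of f''^2
        self.penalty = (self.penalty + self.penalty.T) / 2.0
        self.n_coef = k
        self.means = np.zeros(k)
        self.means = self.transform(x).mean(axis=0) + self.means

    def transform(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        k = self.n_coef
        u = (x - self.lo) % self.period
        i = np.minimum((u / (self.period / k)).astype(int), k - 1)
        ip1 = (i + 1) % k
        x_i = self.knots[i]
        h = self.period / k
        d_lo = u - x_i
        d_hi = h - d_lo
        a_minus = d_hi / h
        a_plus = d_lo / h
        c_minus = (d_hi**3 / h - h * d_hi) / 6.0
        c_plus = (d_lo**3 / h - h * d_lo) / 6.0
        n = len(x)
        F = np.zeros((n, k))
        F[np.arange(n), i] += a_minus
        F[np.arange(n), ip1] += a_plus
        F += c_minus[:, None] * self.BinvD[i, :]
        F += c_plus[:, None] * self.BinvD[ip1, :]
        return F - self.means


# ---------------------------------------------------------------------------
# model specification


@dataclass(frozen=True)
class Smooth:
    """One smooth term: f(var), optionally stratified by a factor level."""

    var: str
    basis: str = "ps"  # "ps" (cubic P-spline) | "cc" (cyclic)
    df: int = 8
    by: str | None = None  # factor column: one smooth block per level
    bounds: tuple | None = None  # cyclic period bounds, e.g. (0.5, 12.5)

    def label(self) -> str:
        return f"s({self.var})" if self.by is None else f"s({self.var}):{self.by}"


@dataclass(frozen=True)
class ModelSpec:
    """Formula for a binomial GAM on one of the analysis tables."""

    name: str
    response: str
    smooths: tuple = ()
    factors: tuple = ()  # unpenalized categorical terms
    linear: tuple = ()  # unpenalized continuous terms
    random: str | None = None  # None | "tag" | "tag:sex"
    trials: str | None = None  # column of binomial totals (None -> Bernoulli)
    random_var: str = "tag_id"
    sex_var: str = "sex"

    def describe(self) -> str:
        parts = list(self.factors) + list(self.linear)
        parts += [s.label() for s in self.smooths]
        rnd = f" + random({self.random})" if self.random else ""
        return f"{self.response} ~ " + " + ".join(parts) + rnd


@dataclass
class _Block:
    name: str
    sl: slice
    penalty: np.ndarray | None  # in block coordinates; None -> unpenalized
    lambda_index: int | None


# ---------------------------------------------------------------------------
# model


class BinomialGAM:
    """Penalized binomial additive model built from a tidy analysis table.

    Parameters
    ----------
    spec : ModelSpec
        Terms, response and random-effect structure.
    data : pandas.DataFrame
        One row per (tag, day) or (tag, hour); rows with missing values in
        any used column are dropped listwise (count recorded).
    """

    def __init__(self, spec: ModelSpec, data: pd.DataFrame):
        self.spec = spec
        used = [spec.response] + list(spec.linear) + [s.var for s in spec.smooths]
        for f in spec.factors:
            used += f.split(":")
        used += [s.by for s in spec.smooths if s.by is not None]
        if spec.trials:
            used.append(spec.trials)
        if spec.random:
            used.append(spec.random_var)
            if spec.random == "tag:sex":
                used.append(spec.sex_var)
        used = list(dict.fromkeys(used))
        complete = data[used].notna().all(axis=1)
        self.n_dropped = int((~complete).sum())
        self.data = data.loc[complete].reset_index(drop=True)
        self._build_design(self.data)

    # -- design ------------------------------------------------------------

    def _build_design(self, data: pd.DataFrame) -> None:
        spec = self.spec
        n = len(data)
        cols = [np.ones((n, 1))]
        blocks = [_Block("intercept", slice(0, 1), None, None)]
        self._factor_levels: dict[str, list] = {}
        self._bases: dict[str, object] = {}
        pos = 1
        lam_i = 0

        for f in spec.factors:
            vals = _factor_values(data, f)
            levels = sorted(pd.unique(vals))
            self._factor_levels[f] = levels
            for lev in levels[1:]:
                cols.append((vals == lev).to_numpy(float)[:, None])
                blocks.append(_Block(f"{f}[{lev}]", slice(pos, pos + 1), None, None))
                pos += 1

        for v in spec.linear:
            cols.append(data[v].to_numpy(float)[:, None])
            blocks.append(_Block(v, slice(pos, pos + 1), None, None))
            pos += 1

        for s in spec.smooths:
            x = data[s.var].to_numpy(float)
            if s.basis == "cc":
                basis = CyclicBasis(x, df=s.df, bounds=s.bounds)
            elif s.basis == "ps":
                basis = PSplineBasis(x, df=s.df)
            else:
                raise ValueError(f"unknown basis {s.basis!r}")
            self._bases[s.label()] = basis
            B = basis.transform(x)
            if s.by is None:
                cols.append(B)
                blocks.append(
                    _Block(s.label(), slice(pos, pos + B.shape[1]), basis.penalty, lam_i)
                )
                pos += B.shape[1]
                lam_i += 1
            else:
                levels = sorted(pd.unique(data[s.by].astype(str)))
                self._factor_levels.setdefault(s.by, levels)
                for lev in levels:
                    mask = (data[s.by].astype(str) == lev).to_numpy(float)[:, None]
                    cols.append(B * mask)
                    blocks.append(
                        _Block(
                            f"{s.label()}[{lev}]",
                            slice(pos, pos + B.shape[1]),
                            basis.penalty,
                            lam_i,
                        )
                    )
                    pos += B.shape[1]
                    lam_i += 1

        if spec.random:
            groups = data[spec.random_var].astype(str)
            levels = sorted(pd.unique(groups))
            self._factor_levels[spec.random_var] = levels
            dummies = (groups.to_numpy()[:, None] == np.array(levels)[None, :]).astype(
                float
            )
            if spec.random == "tag:sex":
                sex_of = (
                    data.groupby(groups)[spec.sex_var].first().astype(str).to_dict()
                )
                for sx in sorted(set(sex_of.values())):
                    idx = [i for i, t in enumerate(levels) if sex_of[t] == sx]
                    cols.append(dummies[:, idx])
                    blocks.append(
                        _Block(
                            f"random({spec.random_var}:{sx})",
                            slice(pos, pos + len(idx)),
                            np.eye(len(idx)),
                            lam_i,
                        )
                    )
                    pos += len(idx)
                    lam_i += 1
                self._random_levels = {"levels": levels, "by_sex": sex_of}
            elif spec.random == "tag":
                cols.append(dummies)
                blocks.append(
                    _Block(
                        f"random({spec.random_var})",
                        slice(pos, pos + len(levels)),
                        np.eye(len(levels)),
                        lam_i,
                    )
                )
                pos += len(levels)
                lam_i += 1
            else:
                raise ValueError(f"unknown random spec {spec.random!r}")

        self.X = np.concatenate(cols, axis=1)
        self.blocks = blocks
        self.n_lambda = lam_i
        y = data[spec.response].to_numpy(float)
        if spec.trials:
            trials = data[spec.trials].to_numpy(float)
            self.prior_weights = trials
            self.y = y / np.maximum(trials, 1.0)
        else:
            self.prior_weights = np.ones(n)
            self.y = y
        if ((self.y < 0) | (self.y > 1)).any():
            raise ValueError("binomial response outside [0, 1]")

    def _design_for(self, data: pd.DataFrame) -> np.ndarray:
        """Design matrix for new data using the frozen training bases/levels."""
        spec = self.spec
        n = len(data)
        cols = [np.ones((n, 1))]
        for f in spec.factors:
            vals = _factor_values(data, f)
            for lev in self._factor_levels[f][1:]:
                cols.append((vals == lev).to_numpy(float)[:, None])
        for v in spec.linear:
            cols.append(data[v].to_numpy(float)[:, None])
        for s in spec.smooths:
            B = self._bases[s.label()].transform(data[s.var].to_numpy(float))
            if s.by is None:
                cols.append(B)
            else:
                for lev in self._factor_levels[s.by]:
                    mask = (data[s.by].astype(str) == lev).to_numpy(float)[:, None]
                    cols.append(B * mask)
        if spec.random:
            levels = self._factor_levels[spec.random_var]
            groups = data[spec.random_var].astype(str).to_numpy()
            dummies = (groups[:, None] == np.array(levels)[None, :]).astype(float)
            if spec.random == "tag:sex":
                sex_of = self._random_levels["by_sex"]
                for sx in sorted(set(sex_of.values())):
                    idx = [i for i, t in enumerate(levels) if sex_of[t] == sx]
                    cols.append(dummies[:, idx])
            else:
                cols.append(dummies)
        return np.concatenate(cols, axis=1)

    # -- fitting -----------------------------------------------------------

    def _penalty_total(self, lam: np.ndarray) -> np.ndarray:
        p = self.X.shape[1]
        S = np.zeros((p, p))
        for b in self.blocks:
            if b.penalty is not None:
                S[b.sl, b.sl] += lam[b.lambda_index] * b.penalty
        return S

    def _pirls(self, lam, beta0=None, max_iter=100, tol=1e-8):
        X, y, w = self.X, self.y, self.prior_weights
        n, p = X.shape
        S = self._penalty_total(lam)
        beta = np.zeros(p) if beta0 is None else beta0.copy()
        eta = X @ beta
        if beta0 is None:
            mu0 = np.clip((w * y + 0.5) / (w + 1.0), _EPS, 1 - _EPS)
            eta = np.log(mu0 / (1 - mu0))
        dev_prev = np.inf
        converged = False
        for _ in range(max_iter):
            mu = np.clip(expit(eta), _EPS, 1 - _EPS)
            var = mu * (1 - mu)
            W = w * var
            z = eta + (y - mu) / var
            XtW = X.T * W
            A = XtW @ X + S
            A[np.diag_indices_from(A)] += 1e-9
            try:
                beta = np.linalg.solve(A, XtW @ z)
            except np.linalg.LinAlgError:
                break
            eta = X @ beta
            dev = self._deviance(self.y, np.clip(expit(eta), _EPS, 1 - _EPS))
            if abs(dev - dev_prev) < tol * (abs(dev) + 0.1):
                converged = True
                dev_prev = dev
                break
            dev_prev = dev
        mu = np.clip(expit(eta), _EPS, 1 - _EPS)
        W = self.prior_weights * mu * (1 - mu)
        XtWX = (X.T * W) @ X
        A = XtWX + S
        A[np.diag_indices_from(A)] += 1e-9
        Ainv = np.linalg.inv(A)
        F = Ainv @ XtWX
        return beta, dev_prev, F, Ainv, converged

    def _deviance(self, y, mu) -> float:
        w = self.prior_weights
        yy = np.clip(y, _EPS, 1 - _EPS)
        d = y * np.log(yy / mu) + (1 - y) * np.log((1 - yy) / (1 - mu))
        return float(2.0 * np.sum(w * d))

    def fit(
        self,
        lam: np.ndarray | float | None = None,
        select: bool = True,
        maxfev: int | None = None,
    ) -> "GAMResults":
        """Fit the model; smoothing parameters by UBRE unless ``lam`` given."""
        n = len(self.y)
        if self.n_lambda == 0:
            lam_vec = np.zeros(0)
            beta, dev, F, Ainv, conv = self._pirls(lam_vec)
            return self._results(beta, dev, F, Ainv, lam_vec, conv)
        if lam is not None:
            lam_vec = np.full(self.n_lambda, lam) if np.isscalar(lam) else np.asarray(lam)
            beta, dev, F, Ainv, conv = self._pirls(lam_vec)
            return self._results(beta, dev, F, Ainv, lam_vec, conv)

        state = {"beta": None}

        def ubre(rho):
            rho = np.clip(rho, -14.0, 14.0)
            beta, dev, F, _, _ = self._pirls(np.exp(rho), beta0=state["beta"])
            state["beta"] = beta
            edf = float(np.trace(F))
            return dev / n + 2.0 * edf / n

        rho0 = np.zeros(self.n_lambda)
        if maxfev is None:
            maxfev = 80 * self.n_lambda + 60
        simplex = np.vstack([rho0, rho0 + 3.0 * np.eye(self.n_lambda)])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = minimize(
                ubre,
                rho0,
                method="Nelder-Mead",
                options={
                    "maxfev": maxfev,
                    "xatol": 0.2,
                    "fatol": 1e-7,
                    "initial_simplex": simplex,
                },
            )
        lam_vec = np.exp(np.clip(res.x, -14.0, 14.0))
        beta, dev, F, Ainv, conv = self._pirls(lam_vec, beta0=state["beta"])
        return self._results(beta, dev, F, Ainv, lam_vec, conv)

    def _results(self, beta, dev, F, Ainv, lam, converged) -> "GAMResults":
        n = len(self.y)
        edf_by_term = {}
        diagF = np.diag(F)
        for b in self.blocks:
            edf_by_term[b.name] = float(np.sum(diagF[b.sl]))
        edf = float(np.trace(F))
        mu = np.clip(expit(self.X @ beta), _EPS, 1 - _EPS)
        # intercept-only null deviance (same weights)
        w = self.prior_weights
        mu0 = np.sum(w * self.y) / np.sum(w)
        null_dev = self._deviance(self.y, np.full(n, np.clip(mu0, _EPS, 1 - _EPS)))
        llf = self._loglik(mu)
        aic = -2.0 * llf + 2.0 * edf
        degenerate = bool(np.all(self.y == self.y[0]))
        return GAMResults(
            degenerate=degenerate,
            model=self,
            params=beta,
            lam=lam,
            edf=edf,
            edf_by_term=edf_by_term,
            deviance=dev,
            null_deviance=null_dev,
            llf=llf,
            aic=aic,
            aicc=aicc(aic, edf, n),
            nobs=n,
            cov_params=Ainv,
            converged=bool(converged),
        )

    def _loglik(self, mu) -> float:
        w = self.prior_weights
        k = w * self.y  # successes
        ll = (
            gammaln(w + 1)
            - gammaln(k + 1)
            - gammaln(w - k + 1)
            + k * np.log(mu)
            + (w - k) * np.log(1 - mu)
        )
        return float(np.sum(ll))


@dataclass
class GAMResults:
    """Fitted penalized binomial GAM: estimates, EDFs, information criteria."""

    model: BinomialGAM
    params: np.ndarray
    lam: np.ndarray
    edf: float
    edf_by_term: dict
    deviance: float
    null_deviance: float
    llf: float
    aic: float
    aicc: float
    nobs: int
    cov_params: np.ndarray
    converged: bool
    degenerate: bool = False  # constant response: intercept-only in disguise

    @property
    def deviance_explained(self) -> float:
        return 1.0 - self.deviance / self.null_deviance

    def predict(self, data: pd.DataFrame, linear: bool = False) -> np.ndarray:
        X = self.model._design_for(data)
        eta = X @ self.params
        return eta if linear else expit(eta)

    def smooth_values(self, label: str, x: np.ndarray, level: str | None = None):
        """Centered smooth f(x) on a grid, for plotting/recovery checks.

        ``label`` is the smooth's label (e.g. ``"s(month)"``); for by-factor
        smooths pass the block label or use ``level``.
        """
        smooth = next(s for s in self.model.spec.smooths if s.label() == label)
        basis = self.model._bases[label]
        B = basis.transform(np.asarray(x, dtype=float))
        name = label if level is None else f"{label}[{level}]"
        block = next(b for b in self.model.blocks if b.name == name)
        return B @ self.params[block.sl]

    def term_pvalue(self, name: str) -> float:
        """Approximate Wald chi-square p-value for one term block."""
        block = next(b for b in self.model.blocks if b.name == name)
        b = self.params[block.sl]
        V = self.cov_params[block.sl, block.sl]
        stat = float(b @ np.linalg.solve(V + 1e-12 * np.eye(len(b)), b))
        df = max(self.edf_by_term[name], 0.5)
        return float(chi2.sf(stat, df))

    def summary(self) -> str:
        lines = [
            f"Binomial GAM: {self.model.spec.describe()}",
            f"n = {self.nobs}   edf = {self.edf:.2f}   "
            f"deviance explained = {100 * self.deviance_explained:.1f}%",
            f"AIC = {self.aic:.1f}   AICc = {self.aicc:.1f}   "
            f"logLik = {self.llf:.1f}   converged = {self.converged}",
            "",
            f"{'term':<32}{'edf':>8}{'lambda':>12}",
        ]
        for b in self.model.blocks:
            lam = "" if b.lambda_index is None else f"{self.lam[b.lambda_index]:.3g}"
            lines.append(f"{b.name:<32}{self.edf_by_term[b.name]:>8.2f}{lam:>12}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# information criteria


def aicc(aic: float, k: float, n: int) -> float:
    """Small-sample corrected AIC: AIC + 2k(k+1)/(n-k-1); inf when n <= k+1."""
    if n - k - 1 <= 0:
        return float("inf")
    return float(aic + 2.0 * k * (k + 1.0) / (n - k - 1.0))


def aicc_rank(fits: dict[str, GAMResults]) -> pd.DataFrame:
    """Rank fitted candidates by AICc (ascending) with delta-AICc.

    Non-converged fits are excluded from the ranking with a warning.
    """
    rows = []
    for name, r in fits.items():
        if not r.converged or r.degenerate:
            warnings.warn(
                f"model {name!r} "
                + ("is degenerate (constant response)" if r.degenerate
                   else "did not converge")
                + "; excluded from ranking"
            )
            continue
        rows.append(
            {
                "model": name,
                "edf": r.edf,
                "aic": r.aic,
                "aicc": r.aicc,
                "deviance_explained": r.deviance_explained,
            }
        )
    if not rows:
        raise ValueError("no converged fits to rank")
    out = pd.DataFrame(rows).sort_values("aicc", kind="mergesort").reset_index(drop=True)
    out["delta_aicc"] = out["aicc"] - out["aicc"].iloc[0]
    return out
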