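"""Pseudolikelihood estimation of the liability threshold model.

`LiabilityThresholdModel` is a scikit-learn style estimator: construct it
with a model id (M1..M10) and integration settings, call ``fit`` on a
filtered cohort DataFrame, and read the fitted attributes
(``heritability_``, ``heritability_male_`` ..., ``aic_``).  The module
functions (`fit_model`, `heritability`, `model_ladder`) are thin wrappers.

Because overlapping grandparent groups make the objective a
pseudolikelihood rather than a likelihood, the parameter covariance is the
sandwich estimator: bread = inverse observed information of the objective,
meat = sum of outer products of per-group score contributions.
Heritability confidence intervals use the delta method on the logit scale
(kept inside (0, 1)); the male-female difference uses the plain delta
method with the full cross-sex parameter covariance.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import expit, logit, ndtri
from sklearn.base import BaseEstimator

from .descriptives import tetrachoric
from .model import (ModelSpec, ParamVector, PreparedData,
                    pattern_log_probs_multi, prepare, pseudo_loglik_multi,
                    pseudo_loglik_prepared)
from .mvn import QMCConfig

Z95 = 1.959963984540054


def h2_from_scales(sigma_A2: float, sigma_C2: float) -> float:
    """Narrow-sense liability heritability sigma_A^2/(1+sigma_A^2+sigma_C^2)."""
    return sigma_A2 / (1.0 + sigma_A2 + sigma_C2)


def _h2_and_grad(theta, n_beta, sex_specific, which):
    """h2 and its gradient w.r.t. the packed parameter vector.

    ``which``: 'overall' (shared scales), 'male' or 'female'.
    """
    k = 2 if sex_specific else 1
    i_a = n_beta + (0 if which != "female" else 1) if sex_specific else n_beta
    i_c = n_beta + k + ((0 if which != "female" else 1) if sex_specific else 0)
    u = math.exp(2.0 * theta[i_a])   # sigma_A^2
    v = math.exp(2.0 * theta[i_c])   # sigma_C^2
    denom = 1.0 + u + v
    h2 = u / denom
    g = np.zeros(len(theta))
    g[i_a] = 2.0 * u * (1.0 + v) / denom ** 2
    g[i_c] = -2.0 * u * v / denom ** 2
    return h2, g


def _logit_ci(h2, g, vcov):
    var = float(g @ vcov @ g)
    if var <= 0 or not (0.0 < h2 < 1.0):
        return (float("nan"), float("nan"))
    se_logit = math.sqrt(var) / (h2 * (1.0 - h2))
    lo = expit(logit(h2) - Z95 * se_logit)
    hi = expit(logit(h2) + Z95 * se_logit)
    return (float(lo), float(hi))


@dataclass
class FitResult:
    """Estimates, uncertainty and fit statistics of one model."""

    model_id: str
    params: ParamVector
    theta: np.ndarray
    vcov: np.ndarray | None
    loglik: float
    aic: float
    n_parameters: int
    n_individuals: int
    n_cases: int
    n_groups: int
    n_dropped_missing: int
    heritability: dict = field(default_factory=dict)
    difference: dict | None = None
    converged: bool = True
    boundary: bool = False
    message: str = ""

    def to_dict(self) -> dict:
        return {
            "model_id": self.model_id,
            "beta": list(map(float, self.params.beta)),
            "sigma_A": list(map(float, np.exp(np.atleast_1d(self.params.log_sigma_A)))),
            "sigma_C": list(map(float, np.exp(np.atleast_1d(self.params.log_sigma_C)))),
            "loglik": self.loglik,
            "minus2_loglik": -2.0 * self.loglik,
            "aic": self.aic,
            "n_parameters": self.n_parameters,
            "n_individuals": self.n_individuals,
            "n_cases": self.n_cases,
            "n_groups": self.n_groups,
            "n_dropped_missing": self.n_dropped_missing,
            "heritability": self.heritability,
            "difference": self.difference,
            "converged": self.converged,
            "boundary": self.boundary,
            "message": self.message,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)


class LiabilityThresholdModel(BaseEstimator):
    """Probit variance-components model over grandparent-couple groups.

    Parameters
    ----------
    model : str
        Model id M1..M10 (even ids have sex-specific scales).
    scheme : str or None
        Covariate categorization ('main_text' or 'alternative'); None picks
        the id's default.
    n_qmc, n_randomizations, qmc_seed : int
        Randomized quasi-Monte-Carlo budget for >=3-member groups.
    compute_vcov : bool
        Whether to compute the sandwich covariance (needed for CIs).
    start : array or None
        Optional starting parameter vector (packed).

    Fitted attributes (trailing underscore): ``params_``, ``theta_``,
    ``vcov_``, ``loglik_``, ``aic_``, ``heritability_`` (dict with
    'overall' or 'male'/'female' entries of (estimate, lo, hi)),
    ``difference_``, ``converged_``, ``result_``.
    """

    def __init__(self, model="M6", scheme=None, n_qmc=1024,
                 n_randomizations=4, qmc_seed=0, abs_tol=1e-6,
                 compute_vcov=True, gtol=1e-4, ftol=1e-9, max_iter=100,
                 scale_parameterization="sibcov", start=None):
        self.model = model
        self.scheme = scheme
        self.n_qmc = n_qmc
        self.n_randomizations = n_randomizations
        self.qmc_seed = qmc_seed
        self.abs_tol = abs_tol
        self.compute_vcov = compute_vcov
        self.gtol = gtol
        self.ftol = ftol
        self.max_iter = max_iter
        self.scale_parameterization = scale_parameterization
        self.start = start

    # -- internal -----------------------------------------------------------

    def _spec(self) -> ModelSpec:
        return ModelSpec.from_id(self.model, scheme=self.scheme)

    def _qmc(self) -> QMCConfig:
        return QMCConfig(n_samples=self.n_qmc,
                         n_randomizations=self.n_randomizations,
                         seed=self.qmc_seed, abs_tol=self.abs_tol)

    def _to_log_sigma(self, theta, n_beta):
        """Map the internal parameter vector to the (beta, log sigma) scale."""
        theta = np.asarray(theta, dtype=float)
        mode = self.scale_parameterization
        if mode == "log_sigma":
            return theta.copy()
        t = theta.copy()
        if mode == "log_sigma2":
            t[n_beta:] = t[n_beta:] / 2.0
            return t
        if mode == "sibcov":
            # theta holds [beta, log s, logit f] with s = 0.5 sigma_A^2 +
            # sigma_C^2 (full-sib liability covariance) and f the additive
            # share 0.5 sigma_A^2 / s.  This aligns the weakly identified
            # sigma_A-vs-sigma_C direction with a single coordinate.
            k = (len(theta) - n_beta) // 2
            s = np.exp(theta[n_beta:n_beta + k])
            f = expit(theta[n_beta + k:])
            sigma_a2 = np.maximum(2.0 * s * f, 1e-12)
            sigma_c2 = np.maximum(s * (1.0 - f), 1e-12)
            t[n_beta:n_beta + k] = 0.5 * np.log(sigma_a2)
            t[n_beta + k:] = 0.5 * np.log(sigma_c2)
            return t
        raise ValueError(f"unknown scale parameterization {mode!r}")

    def _objective(self, data: PreparedData, sex_specific: bool):
        n_beta = data.n_beta

        def unpack(theta):
            return ParamVector.unpack(self._to_log_sigma(theta, n_beta),
                                      n_beta, sex_specific)

        def negloglik(theta):
            return -pseudo_loglik_prepared(data, unpack(theta))

        def grad(theta):
            # Central differences, all 2k perturbations in one vectorized
            # pass over the de-duplicated patterns (common random numbers).
            theta = np.asarray(theta, dtype=float)
            h = 1e-5 * np.maximum(np.abs(theta), 1.0)
            pts = []
            for j in range(len(theta)):
                tp = theta.copy(); tp[j] += h[j]
                tm = theta.copy(); tm[j] -= h[j]
                pts.extend([unpack(tp), unpack(tm)])
            vals = pseudo_loglik_multi(data, pts)
            return -(vals[0::2] - vals[1::2]) / (2.0 * h)

        return negloglik, grad, unpack

    def _starting_values(self, cohort, data: PreparedData, sex_specific: bool):
        """Probit regression for beta; tetrachoric sibling correlation for
        the additive scale; small positive shared-environment scale."""
        import statsmodels.api as sm

        from .model import design_matrix
        X, keep = design_matrix(cohort, self._spec())
        y = cohort["diagnosis"].to_numpy()[keep]
        X = X[keep]
        try:
            res = sm.Probit(y, X).fit(disp=0, maxiter=100)
            beta_std = np.asarray(res.params)
        except Exception:
            beta_std = np.zeros(data.n_beta)
            beta_std[0] = ndtri(max(y.mean(), 1e-4))

        # Sibling and cousin tetrachorics from the accumulated pair tables.
        # r_sib estimates s/V and r_cousin estimates 0.25*s*f/V, so the
        # ratio 4*r_cousin/r_sib is a moment estimate of the additive share
        # f, and s follows from V = 1 + s*(1+f).
        def pair_r(rel, sps, default):
            tab = sum((data.pair_counts[(rel, sp)] for sp in sps), np.zeros(3))
            n11, nd, n00 = tab
            if n11 < 1 or n00 < 1 or nd < 1:
                return default
            r, _ = tetrachoric((n11, nd / 2, nd / 2, n00), ci=False)
            return float(r)

        groups_of = [["mm"], ["ff"]] if sex_specific else [["mm", "ff"]]
        r_sib = np.array([np.clip(pair_r("sib", sps, 0.3), 0.02, 0.6)
                          for sps in groups_of])
        r_cousin = np.array([pair_r("cousin", sps, rs / 4.0)
                             for sps, rs in zip(groups_of, r_sib)])
        f_data = np.clip(4.0 * r_cousin / r_sib, 0.10, 0.98)

        # The additive-share direction is weakly identified (only cousin
        # pairs separate sigma_A from sigma_C) and the surface is flat
        # along it, so the optimizer inherits its start: probe a few
        # candidate shares per sex in one batched likelihood evaluation
        # and start from the best.
        from itertools import product
        k = len(groups_of)
        f_options = [tuple(f_data)] + list(product(*[[0.95, 0.5]] * k))
        candidates = []
        for fs in f_options:
            f0 = np.asarray(fs, dtype=float)
            s0 = r_sib / np.maximum(1.0 - r_sib * (1.0 + f0), 0.15)
            sigma_a0 = np.sqrt(2.0 * s0 * f0)
            sigma_c0 = np.sqrt(np.maximum(s0 * (1.0 - f0), 1e-4))
            total_sd = math.sqrt(
                1.0 + float(np.mean(sigma_a0 ** 2 + sigma_c0 ** 2)))
            candidates.append((beta_std * total_sd, s0, f0, sigma_a0, sigma_c0))
        lls = pseudo_loglik_multi(data, [
            ParamVector(beta=b, log_sigma_A=np.log(sa), log_sigma_C=np.log(sc))
            for b, _, _, sa, sc in candidates])
        beta0, s0, f0, sigma_a0, sigma_c0 = candidates[int(np.argmax(lls))]

        mode = self.scale_parameterization
        if mode == "log_sigma":
            scales = np.concatenate([np.log(sigma_a0), np.log(sigma_c0)])
        elif mode == "log_sigma2":
            scales = 2.0 * np.concatenate([np.log(sigma_a0), np.log(sigma_c0)])
        else:  # sibcov
            scales = np.concatenate([np.log(s0), logit(f0)])
        return np.concatenate([beta0, scales])

    def _sandwich(self, data: PreparedData, unpack, theta_hat):
        """Sandwich covariance from numerical per-pattern scores."""
        k = len(theta_hat)
        h = 1e-5 * np.maximum(1.0, np.abs(theta_hat))
        counts = np.concatenate([b.counts for b in data.batches])

        def pattern_logs_multi(thetas):
            per_batch = pattern_log_probs_multi(data, [unpack(t) for t in thetas])
            return np.concatenate(per_batch, axis=1)      # (T, n_patterns)

        pts = []
        for j in range(k):
            tp = theta_hat.copy(); tp[j] += h[j]
            tm = theta_hat.copy(); tm[j] -= h[j]
            pts.extend([tp, tm])
        logs = pattern_logs_multi(pts)
        scores = ((logs[0::2] - logs[1::2]) / (2 * h[:, None])).T  # (patterns, k)
        meat = (scores * counts[:, None]).T @ scores

        # Observed information: central second differences of the total
        # log-pseudolikelihood (diagonal) and mixed partials (off-diagonal).
        def total(thetas):
            return pattern_logs_multi(thetas) @ counts

        f0 = float(total([theta_hat])[0])
        H = np.empty((k, k))
        pts, index = [], {}
        for i in range(k):
            for j in range(i, k):
                for si, sj in ((1, 1), (1, -1), (-1, 1), (-1, -1)):
                    t = theta_hat.copy()
                    t[i] += si * h[i]
                    t[j] += sj * h[j]
                    index[(i, j, si, sj)] = len(pts)
                    pts.append(t)
        vals = total(pts)
        for i in range(k):
            for j in range(i, k):
                v = lambda si, sj: vals[index[(i, j, si, sj)]]
                if i == j:
                    H[i, i] = (v(1, 1) - 2 * f0 + v(-1, -1)) / (2 * h[i]) ** 2
                else:
                    H[i, j] = H[j, i] = (
                        v(1, 1) - v(1, -1) - v(-1, 1) + v(-1, -1)
                    ) / (4 * h[i] * h[j])
        H = -H  # observed information of the negative log-likelihood sense
        try:
            bread = np.linalg.inv(H)
        except np.linalg.LinAlgError:
            bread = np.linalg.pinv(H)
        return bread @ meat @ bread.T

    # -- public -------------------------------------------------------------

    def fit(self, X: pd.DataFrame, y=None):
        """Fit the model to a filtered cohort table.

        ``X`` is a cohort DataFrame in the registry schema (after
        :func:`famh2.registry.apply_cohort_filters`); ``y`` optionally
        overrides the ``diagnosis`` column.
        """
        cohort = X.reset_index(drop=True)
        if y is not None:
            cohort = cohort.copy()
            cohort["diagnosis"] = np.asarray(y, dtype=int)
        spec = self._spec()
        data = prepare(cohort, spec, qmc=self._qmc())
        sex_specific = spec.sex_specific_scales
        negloglik, grad, unpack = self._objective(data, sex_specific)

        theta0 = (np.asarray(self.start, dtype=float) if self.start is not None
                  else self._starting_values(cohort, data, sex_specific))
        n_scale = len(theta0) - data.n_beta
        mode = self.scale_parameterization
        if mode == "sibcov":
            k = n_scale // 2
            scale_bounds = ([(math.log(1e-6), math.log(250.0))] * k +
                            [(-13.8, 13.8)] * k)
        else:
            mult = 2.0 if mode == "log_sigma2" else 1.0
            scale_bounds = [(mult * math.log(1e-3),
                             mult * math.log(20.0))] * n_scale
        bounds = [(-40.0, 40.0)] * data.n_beta + scale_bounds

        # The QMC point sets are fixed across evaluations (common random
        # numbers), so the objective is a smooth deterministic function and
        # quasi-Newton optimization with central-difference gradients
        # applies.  The scale surface has a soft sigma_A/sigma_C ridge, so
        # gradient accuracy matters more than a tight function tolerance.
        res = optimize.minimize(
            negloglik, theta0, jac=grad, method="L-BFGS-B", bounds=bounds,
            options={"maxiter": self.max_iter, "ftol": self.ftol,
                     "gtol": self.gtol},
        )
        # The additive-share coordinates are weakly identified (cousin pairs
        # only), and the surface flattens toward share 1, so a first fit can
        # stall on the wrong side of the ridge.  Probe the share-1 end with
        # a second optimization and keep the higher pseudolikelihood.
        if mode == "sibcov":
            k = n_scale // 2
            f_idx = np.arange(data.n_beta + k, data.n_beta + 2 * k)
            if np.any(res.x[f_idx] < 3.5):
                x0 = res.x.copy()
                x0[f_idx] = np.maximum(x0[f_idx], 4.6)
                res2 = optimize.minimize(
                    negloglik, x0, jac=grad, method="L-BFGS-B", bounds=bounds,
                    options={"maxiter": self.max_iter, "ftol": self.ftol,
                             "gtol": self.gtol},
                )
                if res2.fun < res.fun:
                    res = res2
        theta_hat = res.x
        params = unpack(theta_hat)
        loglik = -float(res.fun)
        n_par = len(theta_hat)
        aic = 2.0 * n_par - 2.0 * loglik

        # Express theta on the log-sigma scale for downstream formulas.
        theta_ls = self._to_log_sigma(theta_hat, data.n_beta)

        vcov = None
        if self.compute_vcov:
            vcov = self._sandwich(
                data, lambda t: ParamVector.unpack(t, data.n_beta, sex_specific),
                theta_ls)

        boundary = bool(np.any(theta_ls[data.n_beta:] < math.log(1e-3)))

        herit = {}
        if sex_specific:
            for which in ("male", "female"):
                h2, g = _h2_and_grad(theta_ls, data.n_beta, True, which)
                ci = _logit_ci(h2, g, vcov) if vcov is not None else (float("nan"),) * 2
                herit[which] = {"estimate": h2, "ci_low": ci[0], "ci_high": ci[1]}
            h2m, gm = _h2_and_grad(theta_ls, data.n_beta, True, "male")
            h2f, gf = _h2_and_grad(theta_ls, data.n_beta, True, "female")
            diff = h2m - h2f
            if vcov is not None:
                gd = gm - gf
                se = math.sqrt(max(float(gd @ vcov @ gd), 0.0))
                dci = (diff - Z95 * se, diff + Z95 * se)
            else:
                dci = (float("nan"), float("nan"))
            difference = {"estimate": diff, "ci_low": dci[0], "ci_high": dci[1]}
        else:
            h2, g = _h2_and_grad(theta_ls, data.n_beta, False, "overall")
            ci = _logit_ci(h2, g, vcov) if vcov is not None else (float("nan"),) * 2
            herit["overall"] = {"estimate": h2, "ci_low": ci[0], "ci_high": ci[1]}
            difference = None

        self.result_ = FitResult(
            model_id=spec.model_id,
            params=params,
            theta=theta_ls,
            vcov=vcov,
            loglik=loglik,
            aic=aic,
            n_parameters=n_par,
            n_individuals=data.n_individuals,
            n_cases=data.n_cases,
            n_groups=data.n_groups,
            n_dropped_missing=data.n_dropped_missing,
            heritability=herit,
            difference=difference,
            converged=bool(res.success),
            boundary=boundary,
            message=str(res.message),
        )
        self.params_ = params
        self.theta_ = theta_ls
        self.vcov_ = vcov
        self.loglik_ = loglik
        self.aic_ = aic
        self.heritability_ = herit
        self.difference_ = difference
        self.converged_ = bool(res.success)
        self.n_features_in_ = data.n_beta
        return self

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        """Marginal affection probability Phi(x'beta / total SD) per row."""
        from scipy.special import ndtr

        from .model import design_matrix
        Xd, keep = design_matrix(X, self._spec())
        male = (X["sex"] == "male").to_numpy()[keep]
        sa = self.params_.sigma_A(male if self.params_.sex_specific else None)
        sc = self.params_.sigma_C(male if self.params_.sex_specific else None)
        total_sd = np.sqrt(1.0 + np.asarray(sa) ** 2 + np.asarray(sc) ** 2)
        p1 = ndtr(Xd[keep] @ self.params_.beta / total_sd)
        return np.column_stack([1.0 - p1, p1])


# ---------------------------------------------------------------------------
# Functional wrappers

def fit_model(cohort: pd.DataFrame, model: str = "M6", **kwargs) -> FitResult:
    est = LiabilityThresholdModel(model=model, **kwargs)
    est.fit(cohort)
    return est.result_


def heritability(params: ParamVector, which: str = "overall",
                 vcov: np.ndarray | None = None, n_beta: int | None = None):
    """Point estimate (and CI when vcov given) of h2 for one sex or overall."""
    theta = params.pack()
    nb = len(np.atleast_1d(params.beta)) if n_beta is None else n_beta
    h2, g = _h2_and_grad(theta, nb, params.sex_specific,
                         which if params.sex_specific else "overall")
    if vcov is None:
        return h2, (float("nan"), float("nan"))
    return h2, _logit_ci(h2, g, vcov)


def heritability_difference(params: ParamVector, vcov: np.ndarray | None = None):
    """h2_male - h2_female with delta-method CI (sex-specific fits only)."""
    if not params.sex_specific:
        raise ValueError("difference requires a sex-specific fit")
    theta = params.pack()
    nb = len(np.atleast_1d(params.beta))
    h2m, gm = _h2_and_grad(theta, nb, True, "male")
    h2f, gf = _h2_and_grad(theta, nb, True, "female")
    diff = h2m - h2f
    if vcov is None:
        return diff, (float("nan"), float("nan"))
    gd = gm - gf
    se = math.sqrt(max(float(gd @ vcov @ gd), 0.0))
    return diff, (diff - Z95 * se, diff + Z95 * se)


def model_ladder(cohort: pd.DataFrame, models=("M1", "M2", "M3", "M4", "M5", "M6"),
                 **kwargs) -> pd.DataFrame:
    """Fit a sequence of models and tabulate -2 loglik, AIC and heritability.

    AIC differences are reported against the previous row, and omitted when
    two rows were fitted on different subsets (models that drop rows with
    missing gestational age are not comparable with the others).
    """
    rows = []
    prev_aic = None
    prev_subset = None
    for mid in models:
        res = fit_model(cohort, model=mid, **kwargs)
        subset = res.n_individuals
        delta = (res.aic - prev_aic) if (prev_aic is not None and
                                         subset == prev_subset) else float("nan")
        h = res.heritability
        rows.append({
            "model": mid,
            "n_individuals": res.n_individuals,
            "n_cases": res.n_cases,
            "n_parameters": res.n_parameters,
            "minus2_loglik": -2.0 * res.loglik,
            "aic": res.aic,
            "delta_aic": delta,
            "h2_overall": h.get("overall", {}).get("estimate", float("nan")),
            "h2_male": h.get("male", {}).get("estimate", float("nan")),
            "h2_female": h.get("female", {}).get("estimate", float("nan")),
            "difference": (res.difference or {}).get("estimate", float("nan")),
        })
        prev_aic = res.aic
        prev_subset = subset
    return pd.DataFrame(rows)
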