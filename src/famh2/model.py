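"""Probit liability model: design construction and pseudolikelihood.

The liability of child j in group i is
``eta_ij = x_ij' beta + sigma_A(s) A_ij + sigma_C(s) C_ij + eps_ij``
with A correlated 0.5 between full siblings and 0.125 between first
cousins, C correlated 1 between full siblings, eps iid standard normal,
and the child affected iff ``eta_ij >= 0``.  The scale parameters may be
shared or sex-specific; the residual variance is fixed at 1 for
identification, so the implied marginal prevalence is
``Phi(x'beta / sqrt(1 + sigma_A^2 + sigma_C^2))``.

The objective is a pseudolikelihood: the sum over grandparent-couple
groups of the log rectangle probability of the observed affection
pattern, in which a child with both grandparent couples known
contributes to two groups.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import ndtr

from .mvn import QMCConfig, bvn_cdf, mvn_cdf_qmc_batch, _sobol_points
from .registry import build_groups

# ---------------------------------------------------------------------------
# Model specification

#: Categorization of covariates.  "main_text" is the default; "alternative"
#: uses the alternative parental-age grouping.
SCHEMES = {
    "main_text": {
        "birth_year": [1986, 1989, 1991, 1994],   # 85-86|87-89|90-91|92-94|95-98
        "paternal_age": [28, 32],                 # <=28 | 29-32 | >=33
        "maternal_age": [25, 30],                 # <=25 | 26-30 | >=31
        "gestational_age": [36, 38],              # <37 | 37-38 | >38
    },
    "alternative": {
        "birth_year": [1986, 1989, 1991, 1994],
        "paternal_age": [34, 42],                 # <35 | 35-42 | >42
        "maternal_age": [31, 37],                 # <32 | 32-37 | >37
        "gestational_age": [36, 38],
    },
}

_TERM_SOURCES = {
    "birth_year_cat": "birth_year",
    "paternal_age_cat": "paternal_age",
    "maternal_age_cat": "maternal_age",
    "gestational_age_cat": "gestational_age_weeks",
}

_MODEL_TERMS = {
    "M1": ["intercept", "sex"],
    "M3": ["intercept", "sex", "birth_year_cat", "sex:birth_year_cat"],
    "M5": ["intercept", "sex", "birth_year_cat", "paternal_age_cat",
           "maternal_age_cat", "sex:birth_year_cat", "sex:paternal_age_cat",
           "sex:maternal_age_cat"],
    "M9": ["intercept", "sex", "birth_year_cat", "paternal_age_cat",
           "maternal_age_cat", "gestational_age_cat", "sex:birth_year_cat",
           "sex:paternal_age_cat", "sex:maternal_age_cat",
           "sex:gestational_age_cat"],
}


@dataclass(frozen=True)
class ModelSpec:
    """Which fixed effects enter the design, and whether scales are per sex.

    The model ladder: M1/M2 sex only; M3/M4 add birth-year and its sex
    interaction; M5/M6 add parental-age categories and interactions; M7/M8
    are M5/M6 under the alternative parental-age categorization; M9/M10 add
    gestational age.  Even-numbered models have sex-specific scales.
    """

    model_id: str = "M6"
    fixed_terms: tuple = ()
    sex_specific_scales: bool = True
    categorization_scheme: str = "main_text"

    @staticmethod
    def from_id(model_id: str, scheme: str | None = None) -> "ModelSpec":
        mid = model_id.upper()
        num = int(mid[1:])
        if mid[0] != "M" or not 1 <= num <= 10:
            raise ValueError(f"unknown model id {model_id!r}")
        base = {1: "M1", 2: "M1", 3: "M3", 4: "M3", 5: "M5", 6: "M5",
                7: "M5", 8: "M5", 9: "M9", 10: "M9"}[num]
        default_scheme = "alternative" if num in (7, 8) else "main_text"
        return ModelSpec(
            model_id=mid,
            fixed_terms=tuple(_MODEL_TERMS[base]),
            sex_specific_scales=(num % 2 == 0),
            categorization_scheme=scheme or default_scheme,
        )


@dataclass
class ParamVector:
    """Fixed-effect coefficients plus log scale parameters.

    ``log_sigma_A``/``log_sigma_C`` hold one value for shared-scale models
    and ``(male, female)`` pairs for sex-specific models.  Scales are
    recovered as ``exp(log_sigma)``.
    """

    beta: np.ndarray
    log_sigma_A: np.ndarray
    log_sigma_C: np.ndarray

    @property
    def sex_specific(self) -> bool:
        return np.size(self.log_sigma_A) == 2

    def sigma_A(self, sex_is_male=None):
        s = np.exp(np.atleast_1d(self.log_sigma_A))
        if not self.sex_specific:
            return s[0] if sex_is_male is None else np.full(np.shape(sex_is_male), s[0], dtype=float)
        if sex_is_male is None:
            raise ValueError("sex needed for sex-specific scales")
        return np.where(sex_is_male, s[0], s[1])

    def sigma_C(self, sex_is_male=None):
        s = np.exp(np.atleast_1d(self.log_sigma_C))
        if not self.sex_specific:
            return s[0] if sex_is_male is None else np.full(np.shape(sex_is_male), s[0], dtype=float)
        if sex_is_male is None:
            raise ValueError("sex needed for sex-specific scales")
        return np.where(sex_is_male, s[0], s[1])

    def pack(self) -> np.ndarray:
        return np.concatenate([
            np.atleast_1d(self.beta),
            np.atleast_1d(self.log_sigma_A),
            np.atleast_1d(self.log_sigma_C),
        ])

    @staticmethod
    def unpack(theta: np.ndarray, n_beta: int, sex_specific: bool) -> "ParamVector":
        theta = np.asarray(theta, dtype=float)
        k = 2 if sex_specific else 1
        return ParamVector(
            beta=theta[:n_beta],
            log_sigma_A=theta[n_beta:n_beta + k],
            log_sigma_C=theta[n_beta + k:n_beta + 2 * k],
        )


def _cut(values, edges):
    """0-based category index: value <= edges[0] -> 0, ... , > edges[-1] -> len(edges)."""
    return np.searchsorted(np.asarray(edges, dtype=float), np.asarray(values, dtype=float), side="left")


def term_columns(spec: ModelSpec):
    """Column labels of the design matrix, in order."""
    scheme = SCHEMES[spec.categorization_scheme]
    cols = []
    for term in spec.fixed_terms:
        if term == "intercept":
            cols.append("intercept")
        elif term == "sex":
            cols.append("sex_male")
        elif ":" in term:
            _, base = term.split(":")
            src = base.replace("_cat", "")
            for lev in range(1, len(scheme[src]) + 1):
                cols.append(f"sex_male:{src}_{lev}")
        else:
            src = term.replace("_cat", "")
            for lev in range(1, len(scheme[src]) + 1):
                cols.append(f"{src}_{lev}")
    return cols


def design_matrix(cohort: pd.DataFrame, spec: ModelSpec):
    """Design matrix for the fixed effects of ``spec``.

    Dummy coding with the first category as reference; sex coded male=1,
    female=0; interactions are products of the sex dummy with the category
    dummies.  Returns ``(X, keep_mask)`` where ``keep_mask`` flags rows with
    all required covariates present (rows with a missing gestational age are
    dropped for the models that use it).
    """
    scheme = SCHEMES[spec.categorization_scheme]
    n = len(cohort)
    male = (cohort["sex"] == "male").to_numpy().astype(float)
    keep = np.ones(n, dtype=bool)

    blocks = []
    for term in spec.fixed_terms:
        if term == "intercept":
            blocks.append(np.ones((n, 1)))
            continue
        if term == "sex":
            blocks.append(male[:, None])
            continue
        interact = ":" in term
        base = term.split(":")[-1]
        src = base.replace("_cat", "")
        col = _TERM_SOURCES[base]
        raw = pd.to_numeric(cohort[col], errors="coerce").to_numpy(dtype=float)
        missing = ~np.isfinite(raw)
        keep &= ~missing
        cat = _cut(np.where(missing, 0.0, raw), scheme[src])
        n_lev = len(scheme[src]) + 1
        dummies = (cat[:, None] == np.arange(1, n_lev)[None, :]).astype(float)
        if interact:
            dummies = dummies * male[:, None]
        blocks.append(dummies)
    X = np.concatenate(blocks, axis=1)
    return X, keep


def design_row(record, spec: ModelSpec) -> np.ndarray:
    """Covariate vector of one child (see :func:`design_matrix`)."""
    df = pd.DataFrame([dict(record)])
    X, keep = design_matrix(df, spec)
    if not keep[0]:
        raise ValueError("record is missing a covariate required by the model")
    return X[0]


# ---------------------------------------------------------------------------
# Covariance and group probability

def group_covariance(r_a: np.ndarray, r_c: np.ndarray, sex_is_male: np.ndarray,
                     params: ParamVector) -> np.ndarray:
    """Liability covariance matrix of one group.

    Diagonal ``1 + sigma_A(s)^2 + sigma_C(s)^2``; off-diagonal
    ``sigma_A(s_i) sigma_A(s_j) r_A + sigma_C(s_i) sigma_C(s_j) r_C``.
    """
    sa = params.sigma_A(sex_is_male)
    sc = params.sigma_C(sex_is_male)
    if not (np.all(np.isfinite(sa)) and np.all(np.isfinite(sc))):
        raise ValueError("non-finite scale parameters")
    cov = np.outer(sa, sa) * r_a + np.outer(sc, sc) * r_c
    np.fill_diagonal(cov, 1.0 + sa ** 2 + sc ** 2)
    return cov


# ---------------------------------------------------------------------------
# Prepared dataset with pattern de-duplication

@dataclass
class _PatternBatch:
    """Unique (design, pedigree, outcome) patterns of one group size."""

    n: int
    X: np.ndarray        # (G, n, p)
    y: np.ndarray        # (G, n)
    male: np.ndarray     # (G, n) boolean
    R_A: np.ndarray      # (G, n, n)
    R_C: np.ndarray      # (G, n, n)
    counts: np.ndarray   # (G,) multiplicity over groups


@dataclass
class PreparedData:
    """Cohort + groups + designs, ready for repeated likelihood evaluation.

    Group probabilities depend only on the members' design rows, outcomes,
    sexes and relatedness matrices, so identical patterns are collapsed with
    multiplicity counts (an exact rewrite of the sum over groups).  QMC point
    sets are drawn once per group size and reused across evaluations (common
    random numbers), making the objective a deterministic smooth function of
    the parameters.
    """

    spec: ModelSpec
    batches: list
    n_individuals: int
    n_cases: int
    n_groups: int
    n_dropped_missing: int
    n_beta: int
    qmc: QMCConfig = field(default_factory=QMCConfig)
    pair_counts: dict = field(default_factory=dict)
    _points: dict = field(default_factory=dict)

    def points_for(self, n: int) -> np.ndarray:
        if n not in self._points:
            cfg = replace(self.qmc, seed=self.qmc.seed + 7919 * n)
            self._points[n] = _sobol_points(max(n - 1, 1), cfg)
        return self._points[n]


def _canonical_order(sub_X, sub_y, sub_male, mothers, fathers):
    """Permutation making the group pattern independent of member labels:
    sort sibships by their (size, member signature), members within a
    sibship by their own signature.  Affected members sort first, which
    doubles as the integration-variable ordering (most restrictive
    coordinates first improves the sequential-conditioning accuracy)."""
    n = len(sub_y)
    sig = [(-int(sub_y[i]),) + tuple(sub_X[i]) + (bool(sub_male[i]),)
           for i in range(n)]
    sib_key = {}
    for i in range(n):
        sib_key.setdefault((mothers[i], fathers[i]), []).append(i)
    blocks = []
    for _, idx in sib_key.items():
        idx = sorted(idx, key=lambda i: sig[i])
        blocks.append((len(idx), [sig[i] for i in idx], idx))
    blocks.sort(key=lambda b: (b[0], b[1]))
    return [i for _, _, idx in blocks for i in idx]


def prepare(cohort: pd.DataFrame, spec: ModelSpec,
            qmc: QMCConfig | None = None, groups: list | None = None) -> PreparedData:
    """Build designs and de-duplicated group patterns for a filtered cohort."""
    cohort = cohort.reset_index(drop=True)
    X, keep = design_matrix(cohort, spec)
    n_dropped = int((~keep).sum())
    if n_dropped:
        cohort = cohort.loc[keep].reset_index(drop=True)
        X = X[keep]
        groups = None
    if groups is None:
        groups = build_groups(cohort)

    y = cohort["diagnosis"].to_numpy(dtype=np.int8)
    male = (cohort["sex"] == "male").to_numpy()
    mothers = cohort["mother_id"].to_numpy()
    fathers = cohort["father_id"].to_numpy()

    patterns: dict = {}
    for g in groups:
        idx = g.indices
        perm = _canonical_order(X[idx], y[idx], male[idx],
                                mothers[idx], fathers[idx])
        pidx = idx[perm]
        ra = g.R_A[np.ix_(perm, perm)]
        rc = g.R_C[np.ix_(perm, perm)]
        key = (len(idx), X[pidx].tobytes(), y[pidx].tobytes(),
               male[pidx].tobytes(), ra.tobytes(), rc.tobytes())
        if key in patterns:
            patterns[key][-1] += 1
        else:
            patterns[key] = [X[pidx], y[pidx], male[pidx], ra, rc, 1]

    by_size: dict = {}
    for key in sorted(patterns, key=lambda k: (k[0], k[1], k[2], k[3], k[4], k[5])):
        by_size.setdefault(key[0], []).append(patterns[key])
    batches = []
    for n in sorted(by_size):
        items = by_size[n]
        batches.append(_PatternBatch(
            n=n,
            X=np.stack([it[0] for it in items]),
            y=np.stack([it[1] for it in items]).astype(int),
            male=np.stack([it[2] for it in items]),
            R_A=np.stack([it[3] for it in items]),
            R_C=np.stack([it[4] for it in items]),
            counts=np.array([it[5] for it in items], dtype=float),
        ))
    return PreparedData(
        spec=spec,
        batches=batches,
        n_individuals=len(cohort),
        n_cases=int(y.sum()),
        n_groups=len(groups),
        n_dropped_missing=n_dropped,
        n_beta=X.shape[1],
        qmc=qmc or QMCConfig(),
        pair_counts=_pair_counts(batches),
    )


def _pair_counts(batches) -> dict:
    """Same-sex sibling/cousin pair 2x2 counts accumulated over groups.

    Keys (relationship, 'mm'|'ff') map to [both, discordant, neither]
    counts.  Sibling pairs in two groups are counted twice, which leaves
    the margin-based tetrachoric estimate unchanged; these tables feed the
    data-driven starting values of the fit.
    """
    out = {(rel, sp): np.zeros(3)
           for rel in ("sib", "cousin") for sp in ("mm", "ff")}
    for batch in batches:
        n = batch.n
        if n < 2:
            continue
        iu, ju = np.triu_indices(n, 1)
        for i, j in zip(iu, ju):
            same = batch.male[:, i] == batch.male[:, j]
            ra = batch.R_A[:, i, j]
            k = batch.y[:, i] + batch.y[:, j]
            for rel, rval in (("sib", 0.5), ("cousin", 0.125)):
                for sp, is_male in (("mm", True), ("ff", False)):
                    sel = same & (batch.male[:, i] == is_male) & (ra == rval)
                    if not sel.any():
                        continue
                    for slot, kk in ((0, 2), (1, 1), (2, 0)):
                        out[(rel, sp)][slot] += batch.counts[
                            sel & (k == kk)].sum()
    return out


def _batch_cov(batch: _PatternBatch, params: ParamVector):
    sa = params.sigma_A(batch.male)          # (G, n)
    sc = params.sigma_C(batch.male)
    cov = (sa[:, :, None] * sa[:, None, :]) * batch.R_A + \
          (sc[:, :, None] * sc[:, None, :]) * batch.R_C
    diag = 1.0 + sa ** 2 + sc ** 2
    ii = np.arange(batch.n)
    cov[:, ii, ii] = diag
    return cov


def _batch_pattern_probs(batch: _PatternBatch, params_list, points):
    """(T, G) pattern probabilities for T parameter vectors at once."""
    T = len(params_list)
    G = len(batch.counts)
    n = batch.n
    means = np.stack([np.einsum("gnp,p->gn", batch.X, pv.beta)
                      for pv in params_list])                 # (T, G, n)
    cov = np.stack([_batch_cov(batch, pv) for pv in params_list])
    d = (1.0 - 2.0 * batch.y)[None]
    ii = np.arange(n)
    sd = np.sqrt(cov[:, :, ii, ii])
    upper = -d * means / sd
    corr = (d[:, :, :, None] * d[:, :, None, :]) * cov / (
        sd[:, :, :, None] * sd[:, :, None, :])
    if n == 1:
        return ndtr(upper[:, :, 0])
    if n == 2:
        return bvn_cdf(upper[:, :, 0], upper[:, :, 1], corr[:, :, 0, 1])
    flat_corr = corr.reshape(T * G, n, n)
    try:
        chol = np.linalg.cholesky(flat_corr)
    except np.linalg.LinAlgError:
        chol = np.linalg.cholesky(flat_corr + 1e-10 * np.eye(n)[None])
    p, _ = mvn_cdf_qmc_batch(upper.reshape(T * G, n), chol, points)
    return p.reshape(T, G)


def pattern_log_probs_multi(data: PreparedData, params_list):
    """Per-batch (T, G) log pattern probabilities for several parameter
    vectors in one vectorized pass (used for finite-difference gradients
    and per-group scores with common random numbers)."""
    out = []
    for batch in data.batches:
        p = _batch_pattern_probs(batch, params_list, data.points_for(batch.n))
        out.append(np.log(np.maximum(p, 1e-300)))
    return out


def pattern_log_probs(data: PreparedData, params: ParamVector):
    """Log probability of each unique pattern, per batch."""
    return [lp[0] for lp in pattern_log_probs_multi(data, [params])]


def pseudo_loglik_multi(data: PreparedData, params_list) -> np.ndarray:
    """Log-pseudolikelihood for several parameter vectors at once."""
    logs = pattern_log_probs_multi(data, params_list)
    total = np.zeros(len(params_list))
    for batch, lp in zip(data.batches, logs):
        total += lp @ batch.counts
    return total


def pseudo_loglik_prepared(data: PreparedData, params: ParamVector) -> float:
    logs = pattern_log_probs(data, params)
    return math.fsum(
        float(np.dot(batch.counts, lp))
        for batch, lp in zip(data.batches, logs)
    )


def pseudo_loglik(cohort: pd.DataFrame, spec: ModelSpec, params: ParamVector,
                  qmc: QMCConfig | None = None) -> float:
    """Log-pseudolikelihood: sum over grandparent-couple groups of the log
    probability of the observed affection pattern.  Children appearing in
    two groups contribute to both terms."""
    data = prepare(cohort, spec, qmc=qmc)
    return pseudo_loglik_prepared(data, params)
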