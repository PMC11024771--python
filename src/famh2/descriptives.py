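"""Descriptive analyses: pair concordance tables, tetrachoric correlations,
correlation-to-heritability heuristics, and prevalence tables.

The tetrachoric correlation treats the two binary outcomes of a pair as
dichotomized bivariate-normal liabilities: thresholds come from the table
margins and the correlation maximizes the orthant likelihood.  Pairs are
unordered, so discordant counts are split evenly between the two
off-diagonal cells; all pairings within a sibship contribute (estimates
from overlapping pairs are descriptive, not independent).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import ndtri
from scipy.stats import chi2

from .mvn import bvn_cdf
from .registry import build_groups

SEX_PATTERNS = {"male": "male-male", "female": "female-female"}


@dataclass
class PairTable:
    """Unordered same-sex pair counts: (both, first-only, second-only, neither)."""

    relationship: str
    sex_pattern: str
    counts: tuple  # (n11, n10, n01, n00), off-diagonals symmetrized

    @property
    def n_pairs(self) -> float:
        return float(sum(self.counts))


def enumerate_pairs(cohort: pd.DataFrame) -> dict:
    """All unordered same-sex full-sibling and first-cousin pairs.

    Returns ``{(relationship, sex_pattern): PairTable}``.  Cousin pairs are
    found inside grandparent-couple groups and de-duplicated (a pair seen
    through both sides counts once).
    """
    cohort = cohort.reset_index(drop=True)
    sex = cohort["sex"].to_numpy()
    y = cohort["diagnosis"].to_numpy()

    cells = {(rel, sp): np.zeros(3)  # [concordant-affected, discordant, neither]
             for rel in ("full_sibling", "cousin")
             for sp in ("male-male", "female-female")}

    seen = set()
    for g in build_groups(cohort):
        idx = g.indices
        for a, b in combinations(range(len(idx)), 2):
            i, j = int(idx[a]), int(idx[b])
            if sex[i] != sex[j]:
                continue
            r_a = g.R_A[a, b]
            if r_a == 0.5:
                rel = "full_sibling"
            elif r_a == 0.125:
                rel = "cousin"
            else:
                continue
            key = (min(i, j), max(i, j), rel)
            if key in seen:
                continue
            seen.add(key)
            sp = SEX_PATTERNS[sex[i]]
            k = y[i] + y[j]
            cells[(rel, sp)][2 - k] += 1  # k=2 -> slot 0, k=1 -> 1, k=0 -> 2

    out = {}
    for key, (n11, nd, n00) in cells.items():
        out[key] = PairTable(relationship=key[0], sex_pattern=key[1],
                             counts=(n11, nd / 2.0, nd / 2.0, n00))
    return out


def tetrachoric(counts, ci: bool = True, level: float = 0.95):
    """Maximum-likelihood tetrachoric correlation of a symmetrized 2x2 table.

    ``counts`` is (n11, n10, n01, n00) or a :class:`PairTable`.  Thresholds
    are fixed at the margin quantiles; the correlation maximizes the
    bivariate-normal orthant likelihood.  The CI is profile-likelihood based
    (two-sided).  Returns ``(r, (lo, hi))``; with ``ci=False`` the interval
    is (nan, nan).
    """
    if isinstance(counts, PairTable):
        counts = counts.counts
    n11, n10, n01, n00 = (float(c) for c in counts)
    n = n11 + n10 + n01 + n00
    if n <= 0 or n11 + n10 + n01 == 0:
        raise ValueError("table has no informative cells")
    p_first = (n11 + n10) / n
    p_second = (n11 + n01) / n
    h = -ndtri(p_first)   # threshold: P(X > h) = margin
    k = -ndtri(p_second)

    def cell_probs(r):
        p11 = float(bvn_cdf(-h, -k, r))  # P(X>h, Y>k) by symmetry of the normal
        pX = 1.0 - float(_phi(h))
        pY = 1.0 - float(_phi(k))
        p10 = max(pX - p11, 1e-12)
        p01 = max(pY - p11, 1e-12)
        p00 = max(1.0 - pX - pY + p11, 1e-12)
        return max(p11, 1e-12), p10, p01, p00

    def loglik(r):
        p11, p10, p01, p00 = cell_probs(r)
        return (n11 * np.log(p11) + n10 * np.log(p10) +
                n01 * np.log(p01) + n00 * np.log(p00))

    res = optimize.minimize_scalar(lambda r: -loglik(r),
                                   bounds=(-0.999, 0.999), method="bounded",
                                   options={"xatol": 1e-8})
    r_hat = float(res.x)
    if not ci:
        return r_hat, (float("nan"), float("nan"))

    if n11 < 0.5 or n00 < 0.5:
        # Boundary table: estimate pinned near +/-1, CI not identified.
        return r_hat, (float("nan"), float("nan"))

    l_max = loglik(r_hat)
    crit = chi2.ppf(level, df=1) / 2.0

    def prof(r):
        return l_max - loglik(r) - crit

    lo = -0.999
    if prof(-0.999) > 0:
        lo = optimize.brentq(prof, -0.999, r_hat, xtol=1e-6)
    hi = 0.999
    if prof(0.999) > 0:
        hi = optimize.brentq(prof, r_hat, 0.999, xtol=1e-6)
    return r_hat, (float(lo), float(hi))


def _phi(x):
    from scipy.special import ndtr
    return ndtr(x)


def correlation_to_h2(r: float, relatedness: float):
    """Implied heritability r / relatedness, clipped to [0, 1].

    ``relatedness`` is 0.5 for full siblings and 0.125 for first cousins.
    Returns ``(h2, clipped)``; the flag marks estimates pinned at the
    boundary (a cousin correlation above 0.125 implies h2 > 1).
    """
    if relatedness not in (0.5, 0.125):
        raise ValueError("relatedness must be 0.5 (siblings) or 0.125 (cousins)")
    if not -1.0 < r < 1.0:
        raise ValueError("correlation must be in (-1, 1)")
    raw = r / relatedness
    h2 = min(max(raw, 0.0), 1.0)
    return h2, bool(h2 != raw)


def prevalence_table(cohort: pd.DataFrame, by: str = "sex",
                     cohort_bins=((1985, 1989), (1990, 1994), (1995, 1998))) -> pd.DataFrame:
    """Counts and prevalence proportions, overall and by stratum.

    ``by`` is 'sex', 'birth_cohort' or 'sex_x_birth_cohort'.  Empty strata
    get a missing proportion.  Proportions are reported in percent.
    """
    df = cohort.copy()
    if by in ("birth_cohort", "sex_x_birth_cohort"):
        labels = [f"{a}-{b}" for a, b in cohort_bins]
        edges = [a for a, _ in cohort_bins] + [cohort_bins[-1][1] + 1]
        df["birth_cohort"] = pd.cut(df["birth_year"], bins=edges, labels=labels,
                                    right=False)
    keys = {"sex": ["sex"], "birth_cohort": ["birth_cohort"],
            "sex_x_birth_cohort": ["sex", "birth_cohort"]}[by]
    grouped = df.groupby(keys, observed=False)["diagnosis"].agg(["size", "sum"])
    grouped.columns = ["n", "n_cases"]
    grouped["prevalence_pct"] = np.where(
        grouped["n"] > 0, 100.0 * grouped["n_cases"] / grouped["n"].replace(0, np.nan), np.nan)
    total = pd.DataFrame({
        "n": [len(df)], "n_cases": [int(df["diagnosis"].sum())],
        "prevalence_pct": [100.0 * df["diagnosis"].mean() if len(df) else np.nan],
    }, index=pd.Index(["all"], name="stratum"))
    out = grouped.reset_index()
    out["stratum"] = out[keys].astype(str).agg(":".join, axis=1)
    out = out[["stratum", "n", "n_cases", "prevalence_pct"]]
    return pd.concat([total.reset_index(), out], ignore_index=True)
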