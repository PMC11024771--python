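"""Exploratory scenario calculations for the heritability sex difference.

These reconstruct two thought experiments on the liability scale (residual
variance 1): (a) if male and female additive-genetic variances were really
equal, how much *extra* female-specific residual variance X would produce
the lower observed female heritability, and what share of female
prevalence that extra variance would account for; (b) if X came from a
single binary risk factor of prevalence p, how large a relative risk the
factor would need (an RR curve over p), and how far it would shift the
prevalence of the carrier subpopulation.

All relative-risk results use the threshold model with the factor's
liability shift mean-centered so the overall prevalence is preserved; an
un-centered variant with the threshold fixed at the no-factor baseline is
provided for the prevalence-shift illustration and labeled as such in the
output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize
from scipy.special import ndtr, ndtri


@dataclass
class ScenarioInput:
    """Variance components from a sex-specific fit plus a baseline female
    prevalence for the illustrations (the reference example uses 0.5%)."""

    sigma_A_male2: float
    sigma_A_female2: float
    sigma_C2: float = 0.0
    female_prevalence_baseline: float = 0.005

    def __post_init__(self):
        if min(self.sigma_A_male2, self.sigma_A_female2, self.sigma_C2) < 0:
            raise ValueError("variances must be non-negative")
        if not 0.0 < self.female_prevalence_baseline < 1.0:
            raise ValueError("baseline prevalence must be in (0, 1)")

    @property
    def h2_male(self) -> float:
        v = 1.0 + self.sigma_A_male2 + self.sigma_C2
        return self.sigma_A_male2 / v

    @property
    def h2_female(self) -> float:
        v = 1.0 + self.sigma_A_female2 + self.sigma_C2
        return self.sigma_A_female2 / v


def extra_female_variance(inp: ScenarioInput, method: str = "closed_form") -> float:
    """Extra female residual variance X reproducing the observed female
    heritability under male-valued genetic variance.

    Solves ``h2_female = sigma_A_male^2 / (1 + sigma_A_male^2 + sigma_C^2 + X)``.
    ``method`` 'closed_form' or 'numeric' (root finding); the two agree to
    high precision and exist as a cross-check of the algebra.
    """
    h2f = inp.h2_female
    if inp.h2_male < h2f:
        raise ValueError("scenario requires male heritability >= female")
    base = 1.0 + inp.sigma_A_male2 + inp.sigma_C2
    if method == "closed_form":
        x = inp.sigma_A_male2 / h2f - base
    elif method == "numeric":
        f = lambda x: inp.sigma_A_male2 / (base + x) - h2f
        hi = 10.0 * base + 10.0
        x = optimize.brentq(f, 0.0, hi, xtol=1e-12, rtol=1e-14) if f(0.0) > 0 else 0.0
    else:
        raise ValueError(f"unknown method {method!r}")
    if x < -1e-9:
        raise ValueError("inputs admit no non-negative extra variance")
    return max(float(x), 0.0)


def attributable_share(inp: ScenarioInput, x: float) -> float:
    """Share of female prevalence attributable to the extra residual X.

    The threshold is calibrated so that prevalence with X present equals
    the observed baseline; the share is 1 minus the ratio of the prevalence
    with X removed (threshold fixed) to the baseline.
    """
    p = inp.female_prevalence_baseline
    v_with = 1.0 + inp.sigma_A_male2 + inp.sigma_C2 + x
    v_without = v_with - x
    t = -ndtri(p) * np.sqrt(v_with)
    p_without = float(ndtr(-t / np.sqrt(v_without)))
    return 1.0 - p_without / p


def _delta_for_variance(p: float, x: float, method: str = "closed_form") -> float:
    """Liability shift delta of a Bernoulli(p) factor with variance
    p(1-p) delta^2 = X.  The numeric route cross-checks the closed form."""
    if method == "closed_form":
        return float(np.sqrt(x / (p * (1.0 - p))))
    f = lambda d: p * (1.0 - p) * d * d - x
    hi = np.sqrt(x / (p * (1.0 - p))) * 2 + 1.0
    return float(optimize.brentq(f, 0.0, hi, xtol=1e-12, rtol=1e-14))


def binary_factor_requirement(p: float, inp: ScenarioInput, x: float,
                              method: str = "closed_form") -> dict:
    """Required relative risk of a binary factor of prevalence p carrying
    the whole extra variance X.

    The factor adds delta to carriers' liability and is mean-centered
    (carriers +delta(1-p), non-carriers -delta p), so the overall female
    prevalence stays at the baseline; the threshold is re-calibrated under
    that constraint.  RR is the carrier/non-carrier risk ratio.
    """
    if not 0.0 < p < 1.0:
        raise ValueError("factor prevalence must be in (0, 1)")
    base_prev = inp.female_prevalence_baseline
    if x == 0.0:
        return {"p": p, "delta": 0.0, "rr": 1.0, "note": "X = 0: no factor needed"}
    delta = _delta_for_variance(p, x, method=method)
    s = np.sqrt(1.0 + inp.sigma_A_male2 + inp.sigma_C2)  # residual + genetic SD

    def prev(t):
        p1 = ndtr((-t + delta * (1.0 - p)) / s)
        p0 = ndtr((-t - delta * p) / s)
        return p * p1 + (1.0 - p) * p0

    lo, hi = -50.0 * s, 50.0 * s
    t = optimize.brentq(lambda tt: prev(tt) - base_prev, lo, hi, xtol=1e-12)
    p1 = float(ndtr((-t + delta * (1.0 - p)) / s))
    p0 = float(ndtr((-t - delta * p) / s))
    return {"p": p, "delta": delta, "rr": p1 / p0, "risk_carrier": p1,
            "risk_noncarrier": p0, "threshold": float(t), "variant": "centered"}


def prevalence_shift(p: float, delta: float, inp: ScenarioInput) -> dict:
    """Population and carrier prevalence with the factor active, threshold
    fixed at the no-factor baseline (un-centered illustration variant)."""
    if not 0.0 < p < 1.0:
        raise ValueError("factor prevalence must be in (0, 1)")
    s = np.sqrt(1.0 + inp.sigma_A_male2 + inp.sigma_C2)
    t = -ndtri(inp.female_prevalence_baseline) * s
    p1 = float(ndtr((-t + delta) / s))
    p0 = float(ndtr(-t / s))
    return {"p": p, "delta": delta,
            "population_prevalence": p * p1 + (1.0 - p) * p0,
            "carrier_prevalence": p1, "noncarrier_prevalence": p0,
            "variant": "uncentered"}


def rr_curve(inp: ScenarioInput, x: float, ps=None) -> list:
    """Required-RR curve over factor prevalences (for an eFigure-style plot)."""
    if ps is None:
        ps = np.concatenate([np.linspace(0.005, 0.1, 20), np.linspace(0.12, 0.5, 20)])
    return [binary_factor_requirement(float(p), inp, x) for p in ps]
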