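"""Synthetic two-generation registry generator.

Emulates the structure of a national birth / multi-generation register:
grandparent couples produce parent sibships (at most 3 children); parents
pair across families, so the grandchildren form full-sibling and
first-cousin clusters.  Outcomes are generated from the liability
threshold model with (possibly sex-specific) additive-genetic and
shared-environment scales, using the union pedigree: the additive effect
of a child is the mean of its parents' effects plus Mendelian segregation
noise, which yields correlations of exactly 0.5 between full siblings and
0.125 between first cousins while keeping every marginal standard normal.

The default configuration reproduces the study conditions of the Swedish
1985-1998 cohort this package models: 51.38% males, overall prevalence
1.17% (1.51% male / 0.80% female) and the strong birth-cohort trend
(0.46% in 1985-1989 births up to 2.36% in 1995-1998 births), with
sex-specific scales at the fitted sex-specific model values
(h2 male 0.870, h2 female 0.757, no shared environment).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.special import ndtr, ndtri

from .registry import REGISTRY_COLUMNS

# Fitted sex-specific variance components used as generator defaults:
# sigma_A^2 = h2 / (1 - h2) when sigma_C = 0.
H2_MALE_DEFAULT = 0.870
H2_FEMALE_DEFAULT = 0.757
SIGMA_A_MALE_DEFAULT = float(np.sqrt(H2_MALE_DEFAULT / (1 - H2_MALE_DEFAULT)))
SIGMA_A_FEMALE_DEFAULT = float(np.sqrt(H2_FEMALE_DEFAULT / (1 - H2_FEMALE_DEFAULT)))

#: Observed prevalences: overall, by sex, and by birth cohort.
PREV_OVERALL = 0.0117
PREV_MALE = 0.0151
PREV_FEMALE = 0.0080
COHORT_PREV = {(1985, 1989): 0.0046, (1990, 1994): 0.01217, (1995, 1998): 0.0236}
COHORT_WEIGHTS = {(1985, 1989): 0.3915, (1990, 1994): 0.3928, (1995, 1998): 0.2156}


def threshold_for_prevalence(target_prev: float, sigma_A: float, sigma_C: float) -> float:
    """Intercept beta0 with Phi(beta0 / sqrt(1 + sigma_A^2 + sigma_C^2)) = target."""
    if not 0.0 < target_prev < 1.0:
        raise ValueError("target prevalence must be in (0, 1)")
    total_sd = np.sqrt(1.0 + sigma_A ** 2 + sigma_C ** 2)
    return float(ndtri(target_prev) * total_sd)


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic registry.

    ``n_couples`` grandparent couples found the pedigree; each has 1-3
    children (``parent_sibship_dist``), and matched mother/father pairs have
    children per ``children_per_mother_dist``.  ``sigma_A``/``sigma_C`` are
    (male, female) scale pairs on the liability scale.  Prevalence targets
    are met exactly on the liability scale through
    :func:`threshold_for_prevalence`; when ``cohort_prevalences`` is set the
    linear predictor additionally varies by birth cohort (sex-by-cohort
    cells scale multiplicatively with the overall cohort trend).
    """

    n_couples: int = 1000
    parent_sibship_dist: dict = field(default_factory=lambda: {1: 0.25, 2: 0.45, 3: 0.30})
    children_per_mother_dist: dict = field(default_factory=lambda: {1: 0.25, 2: 0.45, 3: 0.30})
    twin_rate: float = 0.014
    sex_ratio_male: float = 0.5138
    birth_year_range: tuple = (1985, 1998)
    cohort_year_weights: dict | None = field(default_factory=lambda: dict(COHORT_WEIGHTS))
    maternal_age_mean: float = 28.5
    maternal_age_sd: float = 4.8
    paternal_age_mean: float = 31.0
    paternal_age_sd: float = 5.5
    gestational_age_mean: float = 39.4
    gestational_age_sd: float = 1.8
    gestational_missing_rate: float = 0.0
    swedish_fraction: float = 1.0
    prev_male: float = PREV_MALE
    prev_female: float = PREV_FEMALE
    cohort_prevalences: dict | None = field(default_factory=lambda: dict(COHORT_PREV))
    prev_overall: float = PREV_OVERALL
    sigma_A: tuple = (SIGMA_A_MALE_DEFAULT, SIGMA_A_FEMALE_DEFAULT)
    sigma_C: tuple = (0.0, 0.0)
    seed: int = 0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["cohort_prevalences"] = (
            {f"{a}-{b}": v for (a, b), v in self.cohort_prevalences.items()}
            if self.cohort_prevalences else None)
        d["cohort_year_weights"] = (
            {f"{a}-{b}": v for (a, b), v in self.cohort_year_weights.items()}
            if self.cohort_year_weights else None)
        return d

    @staticmethod
    def from_dict(d: dict) -> "GeneratorConfig":
        d = dict(d)
        for key in ("cohort_prevalences", "cohort_year_weights"):
            if d.get(key):
                d[key] = {tuple(int(x) for x in k.split("-")): v
                          for k, v in d[key].items()}
        for key in ("parent_sibship_dist", "children_per_mother_dist"):
            if key in d and d[key] is not None:
                d[key] = {int(k): v for k, v in d[key].items()}
        for key in ("sigma_A", "sigma_C", "birth_year_range"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return GeneratorConfig(**d)


def _sample_dist(rng, dist: dict, size: int) -> np.ndarray:
    ks = np.array(sorted(dist))
    ps = np.array([dist[k] for k in ks], dtype=float)
    ps = ps / ps.sum()
    return rng.choice(ks, size=size, p=ps)


def _linear_predictor(cfg: GeneratorConfig, male: np.ndarray,
                      birth_year: np.ndarray) -> np.ndarray:
    """Liability-scale fixed effect per child, calibrated so that the
    marginal prevalence in each sex (x cohort) cell equals its target."""
    sa_m, sa_f = cfg.sigma_A
    sc_m, sc_f = cfg.sigma_C
    out = np.empty(len(male), dtype=float)
    for is_male, sa, sc in ((True, sa_m, sc_m), (False, sa_f, sc_f)):
        sel = male == is_male
        base_prev = cfg.prev_male if is_male else cfg.prev_female
        if cfg.cohort_prevalences:
            for (y0, y1), pc in cfg.cohort_prevalences.items():
                cell = sel & (birth_year >= y0) & (birth_year <= y1)
                prev = base_prev * pc / cfg.prev_overall
                out[cell] = threshold_for_prevalence(prev, sa, sc)
        else:
            out[sel] = threshold_for_prevalence(base_prev, sa, sc)
    return out


def simulate_registry(cfg: GeneratorConfig) -> pd.DataFrame:
    """Generate a raw registry table (one row per child).

    Deterministic given ``cfg.seed``.  Returns a DataFrame in the registry
    CSV schema, including internal pedigree consistency (cousin clusters
    arise from sibling parents sharing a grandparent couple).
    """
    rng = np.random.default_rng(cfg.seed)
    if cfg.n_couples <= 0:
        return pd.DataFrame(columns=REGISTRY_COLUMNS)

    # Grandparent couples and the parent generation.
    n_parents_per = _sample_dist(rng, cfg.parent_sibship_dist, cfg.n_couples)
    couple_of_parent = np.repeat(np.arange(cfg.n_couples), n_parents_per)
    n_parents = len(couple_of_parent)
    parent_male = rng.random(n_parents) < 0.5

    fathers = np.nonzero(parent_male)[0]
    mothers = np.nonzero(~parent_male)[0]
    rng.shuffle(fathers)
    rng.shuffle(mothers)
    n_fam = min(len(fathers), len(mothers))
    fam_father = fathers[:n_fam]
    fam_mother = mothers[:n_fam]
    # Avoid pairing a parent with a full sibling (same grandparent couple).
    same = couple_of_parent[fam_father] == couple_of_parent[fam_mother]
    if same.any() and n_fam > 1:
        idx = np.nonzero(same)[0]
        fam_father[idx] = np.roll(fam_father[idx], 1)

    # Children per family.
    n_children_per = _sample_dist(rng, cfg.children_per_mother_dist, n_fam)
    fam_of_child = np.repeat(np.arange(n_fam), n_children_per)
    n_children = len(fam_of_child)
    if n_children == 0:
        return pd.DataFrame(columns=REGISTRY_COLUMNS)

    # Birth years (cohort-weighted), dates and twinning.
    y0, y1 = cfg.birth_year_range
    years = np.arange(y0, y1 + 1)
    if cfg.cohort_year_weights:
        w = np.zeros(len(years))
        for (a, b), cw in cfg.cohort_year_weights.items():
            m = (years >= a) & (years <= b)
            if m.any():
                w[m] = cw / m.sum()
    else:
        w = np.ones(len(years))
    w = w / w.sum()
    birth_year = rng.choice(years, size=n_children, p=w)
    day_of_year = rng.integers(1, 366, size=n_children)
    # Twins: a child shares the birth date of its previous sibling.
    twin = (rng.random(n_children) < cfg.twin_rate)
    first_of_fam = np.r_[True, fam_of_child[1:] != fam_of_child[:-1]]
    twin &= ~first_of_fam
    for i in np.nonzero(twin)[0]:
        birth_year[i] = birth_year[i - 1]
        day_of_year[i] = day_of_year[i - 1]
    birth_date = np.char.add(
        np.char.add(birth_year.astype(str), "-"),
        np.char.zfill(day_of_year.astype(str), 3))

    sex_male = rng.random(n_children) < cfg.sex_ratio_male

    # Parental ages at each child's birth, consistent within a parent.
    mother_birth_year = np.empty(n_fam)
    father_birth_year = np.empty(n_fam)
    first_year = np.full(n_fam, np.inf)
    np.minimum.at(first_year, fam_of_child, birth_year)
    mother_birth_year = first_year - np.clip(
        rng.normal(cfg.maternal_age_mean - 1.0, cfg.maternal_age_sd, n_fam), 16, 45)
    father_birth_year = first_year - np.clip(
        rng.normal(cfg.paternal_age_mean - 1.0, cfg.paternal_age_sd, n_fam), 16, 60)
    maternal_age = np.round(birth_year - mother_birth_year[fam_of_child], 0)
    paternal_age = np.round(birth_year - father_birth_year[fam_of_child], 0)

    gest = np.round(rng.normal(cfg.gestational_age_mean, cfg.gestational_age_sd,
                               n_children)).astype(int)
    gest = np.clip(gest, 24, 44).astype(float)
    if cfg.gestational_missing_rate > 0:
        gest[rng.random(n_children) < cfg.gestational_missing_rate] = np.nan

    swedish = rng.random(n_fam) < cfg.swedish_fraction

    # Identifiers.
    gm_id = np.array([f"GM{c}" for c in range(cfg.n_couples)])
    gf_id = np.array([f"GF{c}" for c in range(cfg.n_couples)])
    parent_id = np.array([f"P{p}" for p in range(n_parents)])
    mother_ids = parent_id[fam_mother][fam_of_child]
    father_ids = parent_id[fam_father][fam_of_child]
    m_couple = couple_of_parent[fam_mother][fam_of_child]
    f_couple = couple_of_parent[fam_father][fam_of_child]

    df = pd.DataFrame({
        "child_id": [f"C{i}" for i in range(n_children)],
        "sex": np.where(sex_male, "male", "female"),
        "birth_year": birth_year,
        "birth_date": birth_date,
        "mother_id": mother_ids,
        "father_id": father_ids,
        "maternal_grandmother_id": gm_id[m_couple],
        "maternal_grandfather_id": gf_id[m_couple],
        "paternal_grandmother_id": gm_id[f_couple],
        "paternal_grandfather_id": gf_id[f_couple],
        "maternal_age": maternal_age,
        "paternal_age": paternal_age,
        "gestational_age_weeks": gest,
        "parents_swedish": swedish[fam_of_child].astype(int),
        "diagnosis": 0,
    })

    # Latent effects over the union pedigree.
    a_gm = rng.standard_normal(cfg.n_couples)
    a_gf = rng.standard_normal(cfg.n_couples)
    a_parent = 0.5 * (a_gm[couple_of_parent] + a_gf[couple_of_parent]) + \
        np.sqrt(0.5) * rng.standard_normal(n_parents)
    a_child = 0.5 * (a_parent[fam_mother][fam_of_child] +
                     a_parent[fam_father][fam_of_child]) + \
        np.sqrt(0.5) * rng.standard_normal(n_children)
    c_fam = rng.standard_normal(n_fam)[fam_of_child]
    eps = rng.standard_normal(n_children)

    sa = np.where(sex_male, cfg.sigma_A[0], cfg.sigma_A[1])
    sc = np.where(sex_male, cfg.sigma_C[0], cfg.sigma_C[1])
    xb = _linear_predictor(cfg, sex_male, birth_year)
    eta = xb + sa * a_child + sc * c_fam + eps
    df["diagnosis"] = (eta >= 0).astype(int)
    # extra diagnostic column, not part of the registry CSV schema
    df["liability_latent"] = eta
    return df


def simulate_outcomes(cohort: pd.DataFrame, sigma_A, sigma_C, linear_predictor,
                      seed: int = 0, return_liability: bool = False):
    """Re-draw diagnosis indicators for an existing registry table.

    The latent additive effect is built over the union pedigree implied by
    the identifier columns (founders standard normal, children the mean of
    their parents plus segregation noise of variance 1/2), so children
    appearing in two grandparent groups are simulated once.  ``sigma_A`` and
    ``sigma_C`` are (male, female) pairs; ``linear_predictor`` is an array
    of x'beta per row.  Rows are processed in child_id order, so the result
    is invariant to the input row order.
    """
    rng = np.random.default_rng(seed)
    order = np.argsort(cohort["child_id"].to_numpy())
    df = cohort.iloc[order]

    effects: dict = {}

    def ancestor_effect(pid: str) -> float:
        if pid in effects:
            return effects[pid]
        effects[pid] = rng.standard_normal()
        return effects[pid]

    # Grandparents first (deterministic order), then parents, then children.
    a_child = np.empty(len(df))
    c_shared: dict = {}
    male = (df["sex"] == "male").to_numpy()
    for pos, (_, rec) in enumerate(df.iterrows()):
        parent_a = []
        for side, pid_col in (("maternal", "mother_id"), ("paternal", "father_id")):
            pid = rec[pid_col]
            if pid == "":
                parent_a.append(rng.standard_normal())
                continue
            if pid not in effects:
                gm = rec[f"{side}_grandmother_id"]
                gf = rec[f"{side}_grandfather_id"]
                if gm == "" and gf == "":
                    effects[pid] = rng.standard_normal()
                else:
                    am = ancestor_effect(gm) if gm else rng.standard_normal()
                    af = ancestor_effect(gf) if gf else rng.standard_normal()
                    effects[pid] = 0.5 * (am + af) + np.sqrt(0.5) * rng.standard_normal()
            parent_a.append(effects[pid])
        a_child[pos] = 0.5 * sum(parent_a) + np.sqrt(0.5) * rng.standard_normal()
        fam = (rec["mother_id"], rec["father_id"])
        if fam not in c_shared:
            c_shared[fam] = rng.standard_normal()

    c_child = np.array([c_shared[(m, f)] for m, f in
                        zip(df["mother_id"], df["father_id"])])
    eps = rng.standard_normal(len(df))
    sa = np.where(male, sigma_A[0], sigma_A[1])
    sc = np.where(male, sigma_C[0], sigma_C[1])
    lp = np.asarray(linear_predictor, dtype=float)[order]
    eta = lp + sa * a_child + sc * c_child + eps

    y = np.zeros(len(cohort), dtype=int)
    y[order] = (eta >= 0).astype(int)
    if return_liability:
        eta_out = np.empty(len(cohort))
        eta_out[order] = eta
        return y, eta_out
    return y
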