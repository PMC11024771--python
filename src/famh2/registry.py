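"""Cohort construction from registry-style tables.

The raw input is one row per child with identifiers linking it to its
parents and (maternal/paternal) grandparents, in the style of national
birth / multi-generation registers.  This module applies the analytic
cohort filters, computes pairwise additive-genetic and shared-environment
relatedness from the identifier graph, and partitions the cohort into
pseudolikelihood groups defined by grandparent couples.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Registry CSV schema.  Missing identifiers are encoded as the empty string.
REGISTRY_COLUMNS = [
    "child_id",
    "sex",
    "birth_year",
    "birth_date",
    "mother_id",
    "father_id",
    "maternal_grandmother_id",
    "maternal_grandfather_id",
    "paternal_grandmother_id",
    "paternal_grandfather_id",
    "maternal_age",
    "paternal_age",
    "gestational_age_weeks",
    "parents_swedish",
    "diagnosis",
]

ID_COLUMNS = [
    "child_id",
    "mother_id",
    "father_id",
    "maternal_grandmother_id",
    "maternal_grandfather_id",
    "paternal_grandmother_id",
    "paternal_grandfather_id",
]

#: Order in which the exclusion rules are applied; a row is counted against
#: the first rule that removes it.
FILTER_RULES = [
    "missing_parent_id",
    "outside_window",
    "twin",
    "non_swedish_parents",
    "not_first_partner",
    "birth_order_gt3",
    "no_known_grandparent",
]


def read_registry(path) -> pd.DataFrame:
    """Read a registry CSV, keeping identifiers as strings ('' = missing)."""
    df = pd.read_csv(
        path,
        dtype={c: str for c in ID_COLUMNS},
        keep_default_na=False,
        na_values={"maternal_age": [""], "paternal_age": [""],
                   "gestational_age_weeks": [""]},
    )
    missing = [c for c in REGISTRY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"registry file lacks columns: {missing}")
    for c in ID_COLUMNS:
        df[c] = df[c].astype(str).replace("nan", "")
    df["birth_year"] = df["birth_year"].astype(int)
    df["diagnosis"] = df["diagnosis"].astype(int)
    df["parents_swedish"] = df["parents_swedish"].astype(int).astype(bool)
    return df


def write_registry(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, columns=[c for c in REGISTRY_COLUMNS if c in df.columns])


def validate_registry(df: pd.DataFrame) -> None:
    missing = [c for c in REGISTRY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"registry table lacks columns: {missing}")
    if not df["sex"].isin(["male", "female"]).all():
        raise ValueError("sex must be 'male' or 'female' and non-missing")
    if not df["diagnosis"].isin([0, 1]).all():
        raise ValueError("diagnosis must be 0/1 and non-missing")


@dataclass
class FilterReport:
    """Per-rule removal counts, in application order."""

    counts: dict = field(default_factory=dict)
    n_input: int = 0
    n_output: int = 0

    def to_json(self) -> str:
        return json.dumps(
            {"n_input": self.n_input, "n_output": self.n_output,
             "removed": self.counts}, indent=2)


def apply_cohort_filters(df: pd.DataFrame, window=(1985, 1998)):
    """Apply the analytic-cohort exclusion rules sequentially.

    Rules, in order: rows with a missing parent identifier; births outside
    the cohort window; twins (two or more children of one mother sharing a
    birth date — zygosity is unavailable, so all multiple births go); children
    whose parents are not flagged as native-origin; children not belonging to
    each parent's first partnership (partner order = birth date of the
    parent's earliest child, ties broken by partner id); birth order > 3
    within the mother; and children with no known grandparent.

    Returns the filtered table and a :class:`FilterReport` whose counts
    attribute each removed row to the first rule that removed it.
    """
    validate_registry(df)
    report = FilterReport(n_input=len(df))
    for rule in FILTER_RULES:
        report.counts[rule] = 0
    out = df.copy()

    def drop(mask: pd.Series, rule: str):
        nonlocal out
        report.counts[rule] = int(mask.sum())
        out = out.loc[~mask]

    drop((out["mother_id"] == "") | (out["father_id"] == ""), "missing_parent_id")
    drop(~out["birth_year"].between(window[0], window[1]), "outside_window")
    # Twins: same mother, same birth date -> all children of that delivery.
    multi = out.groupby(["mother_id", "birth_date"])["child_id"].transform("size")
    drop(multi > 1, "twin")
    drop(~out["parents_swedish"].astype(bool), "non_swedish_parents")

    # First partner of each parent.  A parent's first partner is the other
    # parent of their earliest-born child (ties: smallest partner id).
    def first_partner(parent_col: str, partner_col: str) -> pd.Series:
        ordered = out.sort_values(["birth_date", partner_col, "child_id"])
        return ordered.groupby(parent_col)[partner_col].first()

    fp_mother = first_partner("mother_id", "father_id")
    fp_father = first_partner("father_id", "mother_id")
    bad = (out["father_id"] != out["mother_id"].map(fp_mother)) | (
        out["mother_id"] != out["father_id"].map(fp_father))
    drop(bad, "not_first_partner")

    order = (
        out.sort_values(["birth_date", "child_id"])
        .groupby("mother_id")
        .cumcount()
    )
    drop(order.reindex(out.index) >= 3, "birth_order_gt3")

    gp_cols = [
        "maternal_grandmother_id", "maternal_grandfather_id",
        "paternal_grandmother_id", "paternal_grandfather_id",
    ]
    drop((out[gp_cols] == "").all(axis=1), "no_known_grandparent")

    report.n_output = len(out)
    return out.reset_index(drop=True), report


def _couples(rec) -> set:
    """Known grandparent-couple keys of a child ('' members allowed if the
    other member is known)."""
    keys = set()
    for gm, gf in (
        (rec["maternal_grandmother_id"], rec["maternal_grandfather_id"]),
        (rec["paternal_grandmother_id"], rec["paternal_grandfather_id"]),
    ):
        if gm or gf:
            keys.add((gm, gf))
    return keys


def relatedness(a, b):
    """Additive-genetic and shared-environment relatedness of two children.

    Full siblings (same mother and father) -> (0.5, 1.0); first cousins
    (a shared grandparent couple through different parents) -> (0.125, 0.0);
    half siblings and everything else -> (0.0, 0.0).
    """
    if a["child_id"] == b["child_id"]:
        raise ValueError("relatedness of a child with itself is undefined")
    same_m = a["mother_id"] == b["mother_id"] and a["mother_id"] != ""
    same_f = a["father_id"] == b["father_id"] and a["father_id"] != ""
    if same_m and same_f:
        return 0.5, 1.0
    if same_m or same_f:
        # Half siblings carry no modeled correlation in this design.
        return 0.0, 0.0
    if _couples(a) & _couples(b):
        return 0.125, 0.0
    return 0.0, 0.0


def _relatedness_from_arrays(m, f, km, kp):
    """Pairwise relatedness matrices from mother/father ids and the two
    grandparent-couple key strings ('|' when both members are unknown)."""
    same_m = (m[:, None] == m[None, :]) & (m != "")[:, None]
    same_f = (f[:, None] == f[None, :]) & (f != "")[:, None]
    sib = same_m & same_f
    half = (same_m | same_f) & ~sib

    share_gp = np.zeros(sib.shape, dtype=bool)
    for ka in (km, kp):
        for kb in (km, kp):
            share_gp |= (ka[:, None] == kb[None, :]) & (ka != "|")[:, None]
    cousin = share_gp & ~sib & ~half

    r_a = np.where(sib, 0.5, np.where(cousin, 0.125, 0.0))
    r_c = np.where(sib, 1.0, 0.0)
    np.fill_diagonal(r_a, 1.0)
    np.fill_diagonal(r_c, 1.0)
    return r_a, r_c


def relatedness_matrices(sub: pd.DataFrame):
    """Vectorized pairwise relatedness for the children of one group."""
    def key(gm_col, gf_col):
        return (sub[gm_col].astype(str) + "|" + sub[gf_col].astype(str)).to_numpy()

    return _relatedness_from_arrays(
        sub["mother_id"].to_numpy(),
        sub["father_id"].to_numpy(),
        key("maternal_grandmother_id", "maternal_grandfather_id"),
        key("paternal_grandmother_id", "paternal_grandfather_id"),
    )


@dataclass
class PedigreeGroup:
    """Grandchildren of one grandparent couple: the pseudolikelihood unit.

    ``indices`` point into the cohort table; ``R_A``/``R_C`` are the
    additive-genetic and shared-environment relatedness matrices (diagonal 1
    by convention).
    """

    group_key: tuple
    members: list
    indices: np.ndarray
    R_A: np.ndarray
    R_C: np.ndarray

    def __len__(self):
        return len(self.members)


def build_groups(cohort: pd.DataFrame) -> list:
    """Partition a filtered cohort into grandparent-couple groups.

    One group per grandparent couple with at least one grandchild in the
    cohort.  A child belongs to every group defined by one of its known
    grandparent couples, hence appears in at most two groups (maternal and
    paternal side).  Within-group order is (birth_year, child_id) so that
    downstream evaluation is deterministic.
    """
    cohort = cohort.reset_index(drop=True)
    n = len(cohort)
    mothers = cohort["mother_id"].to_numpy(dtype=object)
    fathers = cohort["father_id"].to_numpy(dtype=object)
    child_ids = cohort["child_id"].to_numpy(dtype=object)
    birth_year = cohort["birth_year"].to_numpy()

    side_keys = []
    for side in ("maternal", "paternal"):
        gm = cohort[f"{side}_grandmother_id"].astype(str)
        gf = cohort[f"{side}_grandfather_id"].astype(str)
        side_keys.append((gm + "|" + gf).to_numpy(dtype=object))
    km, kp = side_keys

    # Within-group member order: (birth_year, child_id).
    rank = np.empty(n, dtype=np.int64)
    rank[np.lexsort((child_ids, birth_year))] = np.arange(n)

    idx_all = np.concatenate([np.arange(n), np.arange(n)])
    key_all = np.concatenate([km, kp])
    known = key_all != "|"
    idx_all, key_all = idx_all[known], key_all[known]
    codes, uniques = pd.factorize(key_all, sort=True)
    order = np.lexsort((rank[idx_all], codes))
    codes, idx_all = codes[order], idx_all[order]
    starts = np.r_[0, np.nonzero(np.diff(codes))[0] + 1, len(codes)]

    groups = []
    for g in range(len(starts) - 1):
        idx = idx_all[starts[g]:starts[g + 1]]
        gm_id, gf_id = uniques[codes[starts[g]]].split("|")
        r_a, r_c = _relatedness_from_arrays(mothers[idx], fathers[idx],
                                            km[idx], kp[idx])
        groups.append(PedigreeGroup(
            group_key=(gm_id, gf_id),
            members=list(child_ids[idx]),
            indices=idx.copy(),
            R_A=r_a,
            R_C=r_c,
        ))
    return groups
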