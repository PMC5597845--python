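"""Build the analysis table of anchors from a pedigree.

An *anchor* is a focal offspring whose paternal age is compared with that of
its full siblings.  This module applies completeness filters, derives the
paternal/maternal ages, the binned covariates, the selective-episode outcomes
(e1 infant survival, e2 juvenile survival, e3 marriage, e4 child count, e5
divorce where a flag exists), the within-family centering of paternal age,
and grandpaternal ages for the extended-family design.

Ages are decimal years; bins use completed years (floor).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .pedigree import Pedigree, assign_families

LOSS_BIN_EDGES = [(0, 1), (2, 5), (6, 10), (11, 15), (16, 20), (21, 25),
                  (26, 30), (31, 35), (36, 40), (41, 45)]
LOSS_BIN_LABELS = [f"{a}-{b}" for a, b in LOSS_BIN_EDGES] + ["45+", "unknown"]
OLDER_SIB_LABELS = ["0", "1", "2", "3", "4", "5", ">5"]
MATERNAL_BIN_LABELS = ["<=20", "21-34", "35+"]


class CohortError(ValueError):
    """Inconsistent records encountered while deriving outcomes."""


@dataclass(frozen=True)
class CohortFilter:
    """Window/completeness criteria for anchor inclusion.

    ``min_followup`` drops anchors whose records end (window upper bound)
    less than that many years after birth while their death is unrecorded,
    i.e. anchors whose life course is visibly censored.
    """

    birth_year_window: tuple[float, float] | None = None
    require_father: bool = True
    require_mother: bool = True
    require_known_birth: bool = True
    min_followup: float = 0.0
    drop_unknown_sex: bool = True

    def __post_init__(self):
        if self.birth_year_window is not None:
            lo, hi = self.birth_year_window
            if not lo < hi:
                raise ValueError("empty birth-year window")


def bin_maternal_age(ages) -> pd.Categorical:
    """Maternal age in completed years -> {<=20, 21-34, 35+}."""
    a = np.floor(np.asarray(ages, dtype=float))
    lab = np.where(a <= 20, "<=20", np.where(a < 35, "21-34", "35+"))
    return pd.Categorical(lab, categories=MATERNAL_BIN_LABELS)


def bin_cohort(birth_years, window: tuple[float, float], min_edge_n: int = 50) -> pd.Categorical:
    """Half-open 5-year birth-cohort bins aligned to the window start.

    Edge bins holding fewer than ``min_edge_n`` anchors are lumped with their
    inner neighbor (repeatedly, from both ends).
    """
    y = np.asarray(birth_years, dtype=float)
    lo = float(np.floor(window[0]))
    hi = float(max(np.max(y), window[1])) if len(y) else window[1]
    edges = [lo + 5.0 * k for k in range(int(np.ceil((hi - lo) / 5.0)) + 1)]
    edges[-1] = max(edges[-1], hi + 1e-9)
    idx = np.clip(np.searchsorted(edges, y, side="right") - 1, 0, len(edges) - 2)
    counts = np.bincount(idx, minlength=len(edges) - 1)
    # lump small edge bins inward
    lo_i, hi_i = 0, len(counts) - 1
    start = {}
    while lo_i < hi_i and counts[lo_i] < min_edge_n:
        counts[lo_i + 1] += counts[lo_i]
        lo_i += 1
    while hi_i > lo_i and counts[hi_i] < min_edge_n:
        counts[hi_i - 1] += counts[hi_i]
        hi_i -= 1
    mapped = np.clip(idx, lo_i, hi_i)
    labels = {}
    for k in range(lo_i, hi_i + 1):
        a = edges[0] if k == lo_i else edges[k]
        b = edges[-1] if k == hi_i else edges[k + 1]
        labels[k] = f"{int(a)}-{int(b) - 1}"
    cats = [labels[k] for k in range(lo_i, hi_i + 1)]
    return pd.Categorical([labels[k] for k in mapped], categories=cats)


def bin_parental_loss(age_at_loss) -> pd.Categorical:
    """Anchor's completed age at the parent's death -> loss bins.

    NaN (parent's death unrecorded) -> "unknown"; losses before birth are
    binned as 0-1; losses after the anchor's 46th year (and parents who
    outlived that point) -> "45+".
    """
    a = np.asarray(age_at_loss, dtype=float)
    out = np.full(a.shape, "unknown", dtype=object)
    known = np.isfinite(a)
    fa = np.floor(np.clip(a[known], 0.0, None))
    lab = np.full(fa.shape, "45+", dtype=object)
    for lo, hi in LOSS_BIN_EDGES:
        lab[(fa >= (0 if lo == 0 else lo)) & (fa <= hi)] = f"{lo}-{hi}"
    out[known] = lab
    return pd.Categorical(out, categories=LOSS_BIN_LABELS)


def bin_older_siblings(n) -> pd.Categorical:
    n = np.asarray(n, dtype=int)
    lab = np.where(n > 5, ">5", n.astype(str))
    return pd.Categorical(lab, categories=OLDER_SIB_LABELS)


def center_paternal_age(df: pd.DataFrame, col: str = "paternal_age",
                        family: str = "family_id") -> pd.DataFrame:
    """Attach the family mean and within-family deviation of ``col``.

    The mean is computed over the rows present (i.e. anchors that survived
    filtering), so per-family deviations always sum to zero; singleton
    families get deviation 0.
    """
    mean = df.groupby(family)[col].transform("mean")
    return df.assign(**{f"{col}_fam_mean": mean, f"{col}_dev": df[col] - mean})


def derive_episodes(df: pd.DataFrame) -> pd.DataFrame:
    """Selective-episode outcomes from vital/marriage data.

    e1 = survived the first year; e2 = survived to the 15th birthday (given
    e1); e3 = ever married (given e2); the e4 outcome is ``n_children``
    (episode models restrict to e3 = 1; the hurdle reproductive-success
    outcome uses it for *all* anchors, zero-coded for those who died young or
    never married).  A missing death year counts as survival.  e5 (divorce)
    is populated only where a divorce flag exists in the input.
    """
    age_death = df["death_year"] - df["birth_year"]
    n_marr = df["marriage_years"].map(len).to_numpy()

    first_marr = df["marriage_years"].map(lambda m: m[0] if m else np.nan).to_numpy()
    bad_marr = df["individual_id"][first_marr - df["birth_year"].to_numpy() < 10.0]
    if len(bad_marr):
        raise CohortError(f"married before age 10: {list(bad_marr[:10])}")

    e1 = np.where(age_death.isna(), 1, (age_death >= 1.0).astype(int))
    e2 = np.where(e1 == 0, np.nan,
                  np.where(age_death.isna(), 1, (age_death >= 15.0).astype(int)))
    e3 = np.where(e2 != 1, np.nan, (n_marr > 0).astype(float))
    e5 = df["divorced"].astype(float).where(e3 == 1) if "divorced" in df else np.where(e3 == 1, np.nan, np.nan)
    out = df.assign(e1=e1.astype(float), e2=e2, e3=e3, e5=e5,
                    n_spouses=np.where(e3 == 1, n_marr, 0))
    # hurdle outcome: zero for anyone who did not reach/complete reproduction
    out["n_children"] = out["n_children"].fillna(0).astype(int)
    out.loc[out["e3"] != 1, "n_children"] = 0
    return out


def add_grandpaternal_ages(anchors: pd.DataFrame, pedigree: Pedigree) -> pd.DataFrame:
    """Attach grandfather ages and the extended-family (cousin-group) id.

    Paternal-grandfather age is taken at the father's birth, maternal at the
    mother's; missing links yield missing values and the record is retained.
    The extended-family id groups anchors sharing a paternal grandfather.
    """
    ped = pedigree.df.set_index("individual_id")
    birth = ped["birth_year"]
    father_of = ped["father_id"]

    fa_birth = anchors["father_id"].map(birth)
    mo_birth = anchors["mother_id"].map(birth)
    pgf = anchors["father_id"].map(father_of)
    mgf = anchors["mother_id"].map(father_of)
    pgf_age = fa_birth - pgf.map(birth)
    mgf_age = mo_birth - mgf.map(birth)
    xfam = np.where(pgf.notna(), "xfam:" + pgf.astype(str),
                    "xsolo:" + anchors["family_id"].astype(str))
    return anchors.assign(pgf_age=pgf_age, mgf_age=mgf_age, extended_family_id=xfam)


def _dependent_siblings(anchors: pd.DataFrame) -> np.ndarray:
    """Siblings younger than 5 and alive at the anchor's birth."""
    sib = anchors[["family_id", "birth_year", "death_year"]].reset_index()
    pairs = sib.merge(sib, on="family_id", suffixes=("", "_s"))
    pairs = pairs[pairs["index"] != pairs["index_s"]]
    gap = pairs["birth_year"] - pairs["birth_year_s"]
    alive = pairs["death_year_s"].isna() | (pairs["death_year_s"] > pairs["birth_year"])
    dep = pairs[(gap > 0) & (gap < 5) & alive].groupby("index").size()
    out = np.zeros(len(anchors), dtype=int)
    out[dep.index.to_numpy()] = dep.to_numpy()
    return out


def build_anchor_table(pedigree: Pedigree, filt: CohortFilter | None = None,
                       min_edge_n: int = 50) -> pd.DataFrame:
    """One row per anchor passing the filter, with all derived fields.

    The returned frame's ``attrs["filter_log"]`` records the count removed by
    each criterion.  Family means are recomputed on included anchors only.
    """
    filt = filt or CohortFilter()
    if "family_id" not in pedigree.df.columns:
        assign_families(pedigree)
    ped = pedigree.df
    idx = ped.set_index("individual_id")
    birth = idx["birth_year"]
    death = idx["death_year"]

    df = ped.copy()
    log: dict[str, int] = {}

    def drop(mask_keep: np.ndarray, reason: str):
        nonlocal df
        n0 = len(df)
        df = df[mask_keep]
        log[reason] = n0 - len(df)

    father_known = df["father_id"].notna() & df["father_id"].map(birth).notna()
    if filt.require_father:
        drop(father_known.to_numpy(), "no_father")
    mother_known = df["mother_id"].notna() & df["mother_id"].map(birth).notna()
    if filt.require_mother:
        drop(mother_known.to_numpy(), "no_mother")
    if filt.require_known_birth:
        drop(df["birth_year"].notna().to_numpy(), "no_birth_year")
    if filt.birth_year_window is not None:
        lo, hi = filt.birth_year_window
        drop(((df["birth_year"] >= lo) & (df["birth_year"] < hi)).to_numpy(),
             "outside_window")
        if filt.min_followup > 0:
            censored = df["death_year"].isna() & (hi - df["birth_year"] < filt.min_followup)
            drop((~censored).to_numpy(), "insufficient_followup")
    if filt.drop_unknown_sex:
        drop((df["sex"] != "unknown").to_numpy(), "unknown_sex")

    if df.empty:
        warnings.warn("no anchors pass the cohort filter")
        out = pd.DataFrame()
        out.attrs["filter_log"] = log
        return out

    df = df.reset_index(drop=True)
    fa_birth = df["father_id"].map(birth).to_numpy()
    mo_birth = df["mother_id"].map(birth).to_numpy()
    if np.any(df["birth_year"].to_numpy() < fa_birth) or np.any(
        df["birth_year"].to_numpy() < mo_birth
    ):
        bad = df["individual_id"][df["birth_year"].to_numpy() < fa_birth]
        raise CohortError(f"child born before parent: {list(bad[:10])}")

    df = df.assign(
        anchor_id=df["individual_id"],
        paternal_age=df["birth_year"].to_numpy() - fa_birth,
        maternal_age=df["birth_year"].to_numpy() - mo_birth,
    )

    # child counts from the pedigree itself
    counts = pd.concat([ped["father_id"], ped["mother_id"]]).dropna().value_counts()
    df["n_children"] = df["individual_id"].map(counts).fillna(0).astype(int)

    df = derive_episodes(df)

    # birth order within family (ties broken by id), sibship covariates
    df = df.sort_values(["family_id", "birth_year", "individual_id"]).reset_index(drop=True)
    grp = df.groupby("family_id", sort=False)
    df["birth_order"] = grp.cumcount()
    size = grp["individual_id"].transform("size")
    df["n_siblings"] = size - 1
    df["n_older_siblings_bin"] = bin_older_siblings(df["birth_order"])
    df["born_last"] = (df["birth_order"] == size - 1).astype(int)
    df["n_dependent_siblings"] = _dependent_siblings(df)

    # first/last-born adult son within family
    adult_son = (df["sex"] == "male") & (df["e2"] == 1)
    bo = df["birth_order"].where(adult_son)
    df["first_adult_son"] = (bo == bo.groupby(df["family_id"]).transform("min")).fillna(False).astype(int)
    df["last_adult_son"] = (bo == bo.groupby(df["family_id"]).transform("max")).fillna(False).astype(int)

    # covariate bins
    window = filt.birth_year_window or (
        float(np.floor(df["birth_year"].min())), float(df["birth_year"].max()),
    )
    df["cohort_bin"] = bin_cohort(df["birth_year"], window, min_edge_n)
    df["maternal_age_bin"] = bin_maternal_age(df["maternal_age"])
    fa_death = df["father_id"].map(death).to_numpy()
    mo_death = df["mother_id"].map(death).to_numpy()
    df["father_loss_bin"] = bin_parental_loss(fa_death - df["birth_year"].to_numpy())
    df["mother_loss_bin"] = bin_parental_loss(mo_death - df["birth_year"].to_numpy())

    # father's age at his first recorded child (among included anchors)
    df["paternal_age_at_first_birth"] = grp["paternal_age"].transform("min")

    df = center_paternal_age(df)
    df = center_paternal_age(df, col="maternal_age")
    df = add_grandpaternal_ages(df, pedigree)

    keep = [
        "anchor_id", "family_id", "sex", "birth_year",
        "paternal_age", "paternal_age_fam_mean", "paternal_age_dev",
        "maternal_age", "maternal_age_fam_mean", "maternal_age_dev",
        "maternal_age_bin", "cohort_bin", "father_loss_bin", "mother_loss_bin",
        "n_siblings", "n_older_siblings_bin", "born_last", "birth_order",
        "n_dependent_siblings", "first_adult_son", "last_adult_son",
        "paternal_age_at_first_birth",
        "e1", "e2", "e3", "e5", "n_children", "n_spouses",
        "pgf_age", "mgf_age", "extended_family_id",
    ]
    out = df[keep].copy()
    out.attrs["filter_log"] = log
    return out
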