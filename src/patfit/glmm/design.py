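"""Declarative model specification and design-matrix construction.

``ModelSpec`` names the outcome, family, covariates and the form of the
paternal-age and group terms; ``build_design`` turns a spec plus an anchor
table into dense numeric matrices.  Categorical covariates expand into
indicator contrasts against their most frequent level; levels unobserved in
the data are dropped.  Prior scales for each column are returned alongside so
the weakly-informative priors act on approximately standardized predictors.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
import yaml

from .spline import SplineBasis

PA_TERMS = ("none", "linear_raw", "linear_dev_plus_mean", "spline_dev_plus_mean")
GROUP_TERMS = ("none", "family_intercept", "family_intercept_and_slope", "family_fixed")
MODEL_FAMILIES = (
    "poisson_log",
    "hurdle_poisson_log",
    "bernoulli_cauchit",
    "bernoulli_logit",
    "normal_identity",
)

#: covariate set of the baseline sibling-comparison model (m3)
DEFAULT_COVARIATES = (
    "cohort_bin",
    "maternal_age_bin",
    "father_loss_bin",
    "mother_loss_bin",
    "n_siblings",
    "n_older_siblings_bin",
    "born_last",
)


@dataclass(frozen=True)
class PriorSet:
    """Scales of the default weakly informative priors.

    Coefficient priors are normal with sd ``coef_scale`` on standardized
    predictors (internally rescaled by each column's sd); the family sd gets
    a half-normal prior.  ``flat=True`` switches all priors off (comparable
    with maximum likelihood).
    """

    coef_scale: float = 2.5
    intercept_scale: float = 10.0
    sigma_scale: float = 1.0
    flat: bool = False

    def __post_init__(self):
        if not self.flat and min(self.coef_scale, self.intercept_scale, self.sigma_scale) <= 0:
            raise ValueError("prior scales must be positive")


PRIOR_SETS = {
    "default": PriorSet(),
    "tight": PriorSet(coef_scale=1.0, intercept_scale=5.0, sigma_scale=0.5),
    "flat": PriorSet(flat=True),
}


@dataclass(frozen=True)
class ModelSpec:
    outcome: str = "n_children"
    family: str = "hurdle_poisson_log"
    fixed_terms: tuple[str, ...] = DEFAULT_COVARIATES
    paternal_age_term: str = "linear_dev_plus_mean"
    group_term: str = "family_intercept"
    group_col: str = "family_id"
    priors: str = "default"
    spline_df: int = 8
    interactions: tuple[tuple[str, str], ...] = ()
    tag: str = ""

    def __post_init__(self):
        if self.family not in MODEL_FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        if self.paternal_age_term not in PA_TERMS:
            raise ValueError(f"unknown paternal-age term {self.paternal_age_term!r}")
        if self.group_term not in GROUP_TERMS:
            raise ValueError(f"unknown group term {self.group_term!r}")
        if self.paternal_age_term == "spline_dev_plus_mean" and self.spline_df < 3:
            raise ValueError("spline df must be >= 3")
        if self.family == "hurdle_poisson_log" and self.outcome in ("e1", "e2", "e3", "e5"):
            raise ValueError("hurdle family requires a count outcome")

    def prior_set(self) -> PriorSet:
        if isinstance(self.priors, PriorSet):
            return self.priors
        return PRIOR_SETS[self.priors]

    def with_(self, **kw) -> "ModelSpec":
        return replace(self, **kw)

    def to_yaml(self) -> str:
        d = {
            "outcome": self.outcome,
            "family": self.family,
            "fixed_terms": list(self.fixed_terms),
            "paternal_age_term": self.paternal_age_term,
            "group_term": self.group_term,
            "group_col": self.group_col,
            "priors": self.priors if isinstance(self.priors, str) else vars(self.priors),
            "spline_df": self.spline_df,
            "interactions": [list(i) for i in self.interactions],
            "tag": self.tag,
        }
        return yaml.safe_dump(d, sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "ModelSpec":
        d = yaml.safe_load(text)
        d["fixed_terms"] = tuple(d.get("fixed_terms", DEFAULT_COVARIATES))
        d["interactions"] = tuple(tuple(i) for i in d.get("interactions", []))
        if isinstance(d.get("priors"), dict):
            d["priors"] = PriorSet(**d["priors"])
        return cls(**d)


@dataclass
class DesignInfo:
    """Numeric design built from a spec: X, column metadata, groups, outcome."""

    X: np.ndarray
    names: list[str]
    y: np.ndarray
    groups: np.ndarray  # integer codes; empty if group term is none
    n_groups: int
    prior_sd_scale: np.ndarray  # per-column divisor applied to coef_scale
    pa_dev_col: int | None
    pa_mean_col: int | None
    pa_raw_col: int | None
    spline_cols: list[int]
    spline: SplineBasis | None
    reference_row: np.ndarray
    pa_mean_reference: float
    n_obs: int

    def contrast_rows(self, pa_lo: float, pa_hi: float) -> tuple[np.ndarray, np.ndarray]:
        """Two design rows differing only in paternal age (reference covariates).

        Ages are absolute paternal ages; the family-mean term is held at its
        sample mean, the deviation term moves.
        """
        lo = self.reference_row.copy()
        hi = self.reference_row.copy()
        for row, age in ((lo, pa_lo), (hi, pa_hi)):
            if self.pa_raw_col is not None:
                row[self.pa_raw_col] = age
            if self.pa_dev_col is not None:
                row[self.pa_dev_col] = age - self.pa_mean_reference
            if self.pa_mean_col is not None:
                row[self.pa_mean_col] = self.pa_mean_reference
            if self.spline is not None:
                row[self.spline_cols] = self.spline.transform(
                    [age - self.pa_mean_reference]
                )[0]
        return lo, hi


def _expand_categorical(s: pd.Series, name: str):
    if isinstance(s.dtype, pd.CategoricalDtype):
        counts = s.value_counts()
        present = [c for c in s.cat.categories if counts.get(c, 0) > 0]
    else:
        counts = s.value_counts()
        present = list(counts.index)
    if len(present) < 2:
        return [], []
    ref = counts.idxmax()
    cols, names = [], []
    for lev in present:
        if lev == ref:
            continue
        cols.append((s == lev).to_numpy(dtype=float))
        names.append(f"{name}[{lev}]")
    return cols, names


def build_design(anchors: pd.DataFrame, spec: ModelSpec) -> DesignInfo:
    df = anchors
    needed = [spec.outcome, *spec.fixed_terms]
    for a, b in spec.interactions:
        needed += [a, b]
    if spec.paternal_age_term == "linear_raw":
        needed.append("paternal_age")
    elif spec.paternal_age_term != "none":
        needed += ["paternal_age_dev", "paternal_age_fam_mean"]
    if spec.group_term != "none":
        needed.append(spec.group_col)
    df = df.dropna(subset=[c for c in dict.fromkeys(needed) if c in df.columns])
    if df.empty:
        raise ValueError("no rows left after dropping missing outcome/covariates")

    n = len(df)
    cols: list[np.ndarray] = [np.ones(n)]
    names: list[str] = ["intercept"]
    scales: list[float] = [0.0]  # marker: intercept gets intercept_scale

    def add_numeric(vals: np.ndarray, name: str):
        sd = float(np.std(vals))
        cols.append(vals.astype(float))
        names.append(name)
        scales.append(sd if sd > 1e-12 else 1.0)

    for term in spec.fixed_terms:
        s = df[term]
        if isinstance(s.dtype, pd.CategoricalDtype) or s.dtype == object:
            cats, cnames = _expand_categorical(s, term)
            for c, cn in zip(cats, cnames):
                cols.append(c)
                names.append(cn)
                scales.append(1.0)
        else:
            vals = s.to_numpy(dtype=float)
            if np.std(vals) > 1e-12:
                add_numeric(vals, term)

    pa_dev_col = pa_mean_col = pa_raw_col = None
    spline_cols: list[int] = []
    spline = None
    if spec.paternal_age_term == "linear_raw":
        pa_raw_col = len(cols)
        add_numeric(df["paternal_age"].to_numpy(dtype=float), "paternal_age")
    elif spec.paternal_age_term in ("linear_dev_plus_mean", "spline_dev_plus_mean"):
        pa_dev_col = len(cols)
        add_numeric(df["paternal_age_dev"].to_numpy(dtype=float), "paternal_age_dev")
        pa_mean_col = len(cols)
        add_numeric(df["paternal_age_fam_mean"].to_numpy(dtype=float), "paternal_age_fam_mean")
        if spec.paternal_age_term == "spline_dev_plus_mean":
            spline = SplineBasis(df["paternal_age_dev"].to_numpy(dtype=float), df=spec.spline_df)
            B = spline.transform(df["paternal_age_dev"].to_numpy(dtype=float))
            for k, cn in enumerate(spline.column_names("pa_spline")):
                spline_cols.append(len(cols))
                cols.append(B[:, k])
                names.append(cn)
                scales.append(max(float(np.std(B[:, k])), 1e-12))

    for a, b in spec.interactions:
        # categorical first factor expands to indicator(s) for non-modal levels
        if isinstance(df[a].dtype, pd.CategoricalDtype) or df[a].dtype == object:
            cats, cnames = _expand_categorical(df[a], a)
        else:
            cats, cnames = [df[a].to_numpy(dtype=float)], [a]
        vb = df[b].to_numpy(dtype=float)
        for c, cn in zip(cats, cnames):
            add_numeric(np.asarray(c, dtype=float) * vb, f"{cn}:{b}")

    X = np.column_stack(cols)

    if spec.group_term in ("family_intercept", "family_intercept_and_slope"):
        codes, uniques = pd.factorize(df[spec.group_col], sort=True)
        groups = codes.astype(np.int64)
        n_groups = len(uniques)
    elif spec.group_term == "family_fixed":
        codes, uniques = pd.factorize(df[spec.group_col], sort=True)
        counts = np.bincount(codes)
        ref = int(np.argmax(counts))
        for g in range(len(uniques)):
            if g == ref:
                continue
            X = np.column_stack([X, (codes == g).astype(float)])
            names.append(f"family[{uniques[g]}]")
            scales.append(1.0)
        groups = np.array([], dtype=np.int64)
        n_groups = 0
    else:
        groups = np.array([], dtype=np.int64)
        n_groups = 0

    # reference row: continuous at mean, indicators at modal pattern (zeros =
    # reference levels); family fixed-effect dummies at zero
    ref_row = X.mean(axis=0)
    for j, nm in enumerate(names):
        if "[" in nm:  # indicator column -> reference level
            ref_row[j] = 0.0
    ref_row[0] = 1.0

    pa_mean_ref = (
        float(df["paternal_age_fam_mean"].mean())
        if "paternal_age_fam_mean" in df.columns
        else float(df["paternal_age"].mean()) if "paternal_age" in df.columns else 0.0
    )

    return DesignInfo(
        X=X,
        names=names,
        y=df[spec.outcome].to_numpy(dtype=float),
        groups=groups,
        n_groups=n_groups,
        prior_sd_scale=np.array(scales),
        pa_dev_col=pa_dev_col,
        pa_mean_col=pa_mean_col,
        pa_raw_col=pa_raw_col,
        spline_cols=spline_cols,
        spline=spline,
        reference_row=ref_row,
        pa_mean_reference=pa_mean_ref,
        n_obs=n,
    )
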