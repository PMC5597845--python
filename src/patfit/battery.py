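"""Configurable robustness battery around the baseline sibling-comparison model.

Each variant perturbs the baseline (m3) analysis in one documented way —
dropping or re-coding covariates, changing the grouping structure, swapping
the outcome family, or changing the priors — and reports the per-decade
paternal-age effect it yields.  The spread of estimates across variants is
itself the result of interest: it shows how much the estimate depends on
modelling assumptions.

Variants that require data features the input lacks (e.g. excluding
trisomy-like cases needs the simulator's truth table) raise before any
fitting, as do unknown variant names.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .effects import model_set_specs, per_decade_effect
from .glmm.design import DEFAULT_COVARIATES, ModelSpec
from .glmm.fit import fit_glmm
from .glmm.spline import SplineBasis


class BatteryError(ValueError):
    pass


_BASE_TERMS = list(DEFAULT_COVARIATES)


def _terms_without(*names: str) -> tuple[str, ...]:
    return tuple(t for t in _BASE_TERMS if t not in names)


def _loss_lt5(col: pd.Series) -> np.ndarray:
    return col.isin(["0-1", "2-5"]).to_numpy(dtype=float)


def _v_r2(anchors, base):
    return anchors, base.with_(fixed_terms=("cohort_bin",), tag="r2")


def _v_r3(anchors, base):
    terms = _terms_without("n_older_siblings_bin", "born_last") + ("birth_order",)
    return anchors, base.with_(fixed_terms=terms, tag="r3")


def _v_r4(anchors, base):
    terms = _terms_without("n_older_siblings_bin", "born_last") + ("n_dependent_siblings",)
    return anchors, base.with_(fixed_terms=terms, tag="r4")


def _v_r5(anchors, base):
    terms = _terms_without("n_older_siblings_bin") + ("birth_order",)
    return anchors, base.with_(
        fixed_terms=terms, interactions=(("birth_order", "n_siblings"),), tag="r5"
    )


def _v_r6(anchors, base):
    return anchors, base.with_(
        fixed_terms=_terms_without("n_older_siblings_bin", "born_last"), tag="r6"
    )


def _v_r7(anchors, base):
    a = anchors.assign(
        father_loss_lt5=_loss_lt5(anchors["father_loss_bin"]),
        mother_loss_lt5=_loss_lt5(anchors["mother_loss_bin"]),
    )
    terms = _terms_without("father_loss_bin", "mother_loss_bin") + (
        "father_loss_lt5", "mother_loss_lt5",
    )
    return a, base.with_(fixed_terms=terms, tag="r7")


def _v_r8(anchors, base):
    return anchors, base.with_(
        fixed_terms=tuple(_BASE_TERMS) + ("first_adult_son", "last_adult_son"), tag="r8"
    )


def _v_r9(anchors, base):
    y = anchors["birth_year"].to_numpy(dtype=float)
    df = min(8, max(3, len(np.unique(y)) - 2))
    sb = SplineBasis(y, df=df)
    B = sb.transform(y)
    a = anchors.assign(
        birth_year_c=y - y.mean(),
        **{f"by_spline_{k + 1}": B[:, k] for k in range(B.shape[1])},
    )
    terms = _terms_without("cohort_bin") + ("birth_year_c",) + tuple(
        f"by_spline_{k + 1}" for k in range(B.shape[1])
    )
    return a, base.with_(fixed_terms=terms, tag="r9")


def _v_r10(anchors, base):
    return anchors, base.with_(group_term="family_intercept_and_slope", tag="r10")


def _v_r11(anchors, base):
    a = anchors.assign(father_group=anchors["family_id"].str.split("|").str[0])
    return a, base.with_(group_col="father_group", tag="r11")


def _v_r12(anchors, base):
    return anchors, base.with_(
        fixed_terms=tuple(_BASE_TERMS) + ("sex",),
        interactions=(("sex", "paternal_age_dev"),),
        tag="r12",
    )


def _v_r13(anchors, base):
    return anchors, base.with_(
        fixed_terms=tuple(_BASE_TERMS) + ("paternal_age_at_first_birth",), tag="r13"
    )


def _v_r14(anchors, base, max_families: int = 1000):
    # per-family indicator contrasts make each Newton step cubic in the
    # number of families; on large inputs this variant runs on a family
    # subsample (deterministic: evenly spaced over the sorted family ids)
    fams = np.sort(anchors["family_id"].unique())
    if len(fams) > max_families:
        keep = fams[np.linspace(0, len(fams) - 1, max_families).astype(int)]
        anchors = anchors[anchors["family_id"].isin(keep)].copy()
    return anchors, base.with_(
        group_term="family_fixed", paternal_age_term="linear_raw", tag="r14"
    )


def _v_r17(anchors, base):
    if "trisomy" not in anchors.columns:
        raise BatteryError(
            "r17 needs a 'trisomy' column (join the simulator truth table)"
        )
    return anchors[~anchors["trisomy"].astype(bool)].copy(), base.with_(tag="r17")


def _v_r18(anchors, base):
    fam = "poisson_log" if base.family == "hurdle_poisson_log" else "hurdle_poisson_log"
    return anchors, base.with_(family=fam, tag="r18")


def _v_r19(anchors, base):
    return anchors, base.with_(family="normal_identity", tag="r19")


def _v_r20(anchors, base):
    return anchors, base.with_(fixed_terms=_terms_without("maternal_age_bin"), tag="r20")


def _v_r21(anchors, base):
    terms = _terms_without("maternal_age_bin") + ("maternal_age",)
    return anchors, base.with_(fixed_terms=terms, tag="r21")


def _v_r23(anchors, base):
    return anchors, base.with_(priors="tight", tag="r23")


def _v_r24(anchors, base):
    return anchors, base.with_(priors="flat", tag="r24")


def _v_r26(anchors, base):
    a = anchors.assign(teen_mother=(anchors["maternal_age"] < 20).astype(float))
    terms = _terms_without("maternal_age_bin") + (
        "maternal_age_dev", "maternal_age_fam_mean", "teen_mother",
    )
    return a, base.with_(fixed_terms=terms, tag="r26")


VARIANTS = {
    "r2": _v_r2, "r3": _v_r3, "r4": _v_r4, "r5": _v_r5, "r6": _v_r6,
    "r7": _v_r7, "r8": _v_r8, "r9": _v_r9, "r10": _v_r10, "r11": _v_r11,
    "r12": _v_r12, "r13": _v_r13, "r14": _v_r14, "r17": _v_r17, "r18": _v_r18,
    "r19": _v_r19, "r20": _v_r20, "r21": _v_r21, "r23": _v_r23, "r24": _v_r24,
    "r26": _v_r26,
}

DEFAULT_BATTERY = tuple(VARIANTS)


@dataclass(frozen=True)
class BatteryConfig:
    variants: tuple[str, ...] = DEFAULT_BATTERY
    base_spec: ModelSpec = field(default_factory=lambda: ModelSpec(tag="m3"))
    seed: int = 0
    n_nodes: int = 21
    n_draws: int = 4000

    def __post_init__(self):
        if len(set(self.variants)) != len(self.variants):
            raise BatteryError("duplicate variant names")
        known = set(VARIANTS) | {"m1", "m2", "m3", "m4"}
        bad = [v for v in self.variants if v not in known]
        if bad:
            raise BatteryError(f"unknown variants: {bad}; known: {sorted(known)}")


def _variant_inputs(name: str, anchors: pd.DataFrame, base: ModelSpec):
    if name in ("m1", "m2", "m3", "m4"):
        return anchors, model_set_specs(base)[name]
    return VARIANTS[name](anchors, base)


def robustness_battery(
    config: BatteryConfig,
    anchors: pd.DataFrame,
    truth: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Run the configured variants; returns one row per variant plus the
    m3 baseline, with the per-decade effect and its 95% interval, and a
    min/max spread summary in ``attrs["spread"]``."""
    a = anchors
    if truth is not None and "trisomy" not in a.columns:
        a = a.merge(
            truth[["individual_id", "trisomy"]].rename(
                columns={"individual_id": "anchor_id"}
            ),
            on="anchor_id",
            how="left",
        )
    # validate every variant before fitting anything
    names = list(dict.fromkeys(("m3",) + tuple(config.variants)))
    prepared = {}
    for name in names:
        prepared[name] = _variant_inputs(name, a, config.base_spec)

    rows = []
    for name in names:
        data, spec = prepared[name]
        fit = fit_glmm(spec, data, n_nodes=config.n_nodes)
        if name in ("m2", "m4"):
            # no linear age coefficient to summarize
            rows.append({"variant": name, "point": np.nan, "lo": np.nan,
                         "hi": np.nan, "n_obs": fit.n_obs,
                         "converged": fit.diagnostics.get("converged", True)})
            continue
        seed = (config.seed * 1000003 + zlib.crc32(name.encode())) % (2**31)
        eff = per_decade_effect(fit, n_draws=config.n_draws, seed=seed)
        rows.append({
            "variant": name, "point": eff.point, "lo": eff.lo, "hi": eff.hi,
            "n_obs": fit.n_obs,
            "converged": fit.diagnostics.get("converged", True),
        })
    out = pd.DataFrame(rows).set_index("variant")
    pts = out["point"].dropna()
    out.attrs["spread"] = (float(pts.min()), float(pts.max()))
    return out
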