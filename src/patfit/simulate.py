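"""Multi-generation pedigree simulator with a paternal-age-linked mutation load.

The generator emulates the family-structured demography of the four study
populations (see :mod:`patfit.presets`) together with the biological mechanism
under study: each child receives a Poisson number of de novo mutations whose
mean increases linearly with the father's age, every mutation multiplies the
child's relative fitness by ``(1 - s_bar)``, and that fitness loss is
partitioned across the selective episodes of the life course (infant survival,
juvenile survival, reproduction).

Three generations are produced:

* generation 0 — grandfather stubs (one per founder father/mother), so that
  grandpaternal ages are derivable; a configurable fraction of founder fathers
  are brothers, creating cousin groups for the within-extended-family design;
* generation 1 — founder couples with correlated reproductive ages;
* generation 2 — the *anchors*: the individuals whose paternal ages the
  downstream sibling comparison analyses; full life histories are generated;
* generation 3 — anchors' children as minimal records (identity and parent
  link only), which is all the reproductive-success outcome needs.

Between-family confounding is optional: a log-normal family latent quality
multiplies episode success, and a nonzero ``confounder_timing_coupling`` makes
high-quality families systematically reproduce at older (or younger) ages —
the scenario in which a naive (no-family-effect) model is biased while the
sibling comparison is not.

Within-family overdispersion of completed fertility is generated by a
family-level gamma frailty calibrated to the preset's fertility variance, so
the marginal distribution of married women's child counts is negative
binomial with exactly the preset mean and sd.  Presets whose fertility is
*under*-dispersed (twentieth-century Sweden) use a moment-matched binomial
instead.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .pedigree import Pedigree, assign_families
from .presets import PopulationPreset, load_preset

TRUTH_COLUMNS = [
    "individual_id",
    "family_id",
    "paternal_age",
    "denovo_count",
    "family_quality",
    "fertility_frailty",
    "mult_e1",
    "mult_e2",
    "mult_e4",
    "trisomy",
]


class MutationParamError(ValueError):
    pass


@dataclass(frozen=True)
class MutationParams:
    """De novo mutation-load mechanism.

    ``count_at_30`` anchors the expected mutation count for a 30-year-old
    father; ``slope_m`` adds mutations per year of paternal age.  Each
    mutation multiplies fitness by ``1 - s_bar``; ``partition`` says what
    fraction of the (log) fitness loss is expressed in infant survival (e1),
    juvenile survival (e2) and reproduction (e4).
    """

    slope_m: float = 2.0
    count_at_30: float = 60.0
    s_bar: float = 0.004
    partition: tuple[float, float, float] = (0.5, 0.1, 0.4)

    def __post_init__(self):
        if self.slope_m < 0:
            raise MutationParamError("slope_m must be >= 0")
        if not 0.0 <= self.s_bar < 1.0:
            raise MutationParamError("s_bar must be in [0, 1)")
        if abs(sum(self.partition) - 1.0) > 1e-9 or min(self.partition) < 0:
            raise MutationParamError("partition weights must be >= 0 and sum to 1")


@dataclass(frozen=True)
class SimulationConfig:
    preset: PopulationPreset | str = "historical_sweden"
    mutation: MutationParams = field(default_factory=MutationParams)
    n_families: int = 1000
    confounder_sd: float = 0.0
    confounder_timing_coupling: float = 0.0  # years of paternal age per sd of quality
    maternal_age_effect: float = 0.0  # trisomy-like risk for mothers 35+
    seed: int = 0
    grandfather_brother_prob: float = 0.3
    death_missing_prob: float = 0.03
    remarriage_prob: float = 0.1

    def resolved_preset(self) -> PopulationPreset:
        if isinstance(self.preset, str):
            return load_preset(self.preset)
        return self.preset

    def __post_init__(self):
        if self.n_families < 1:
            raise ValueError("n_families must be >= 1")
        if self.confounder_sd < 0:
            raise ValueError("confounder_sd must be >= 0")


@lru_cache(maxsize=64)
def _truncnorm_shape(target_mean: float, target_sd: float, lo: float, hi: float):
    """Underlying (mu, sigma) so the [lo, hi]-truncated normal has the target moments."""

    def resid(x):
        mu, lsig = x
        sig = np.exp(lsig)
        a, b = (lo - mu) / sig, (hi - mu) / sig
        m, v = stats.truncnorm.stats(a, b, loc=mu, scale=sig, moments="mv")
        return [m - target_mean, np.sqrt(v) - target_sd]

    sol = optimize.fsolve(resid, [target_mean, np.log(target_sd)], full_output=False)
    mu, sig = sol[0], float(np.exp(sol[1]))
    return mu, sig


def _draw_truncnorm(rng, n, mean, sd, lo, hi):
    mu, sig = _truncnorm_shape(round(mean, 6), round(sd, 6), lo, hi)
    a, b = (lo - mu) / sig, (hi - mu) / sig
    u = rng.uniform(size=n)
    return stats.truncnorm.ppf(u, a, b, loc=mu, scale=sig)


def draw_denovo_count(paternal_age, params: MutationParams, rng) -> np.ndarray:
    """Poisson de novo mutation count(s) with mean linear in paternal age.

    The mean is ``count_at_30 + slope_m * (age - 30)``, floored at 0.1 so the
    Poisson mean stays positive for implausibly young fathers.
    """
    age = np.asarray(paternal_age, dtype=float)
    mean = np.maximum(params.count_at_30 + params.slope_m * (age - 30.0), 0.1)
    return rng.poisson(mean)


def fitness_components(M, params: MutationParams) -> dict[str, np.ndarray]:
    """Multiplicative episode components of relative fitness w = (1-s̄)^M.

    Returns multipliers for e1 (infant survival), e2 (juvenile survival) and
    e4 (reproduction); their product equals ``(1 - s_bar) ** M``.
    """
    M = np.asarray(M, dtype=float)
    if np.any(M < 0):
        raise ValueError("mutation counts must be non-negative")
    log_w = M * np.log1p(-params.s_bar)
    w1, w2, w4 = (np.exp(p * log_w) for p in params.partition)
    return {"e1": w1, "e2": w2, "e4": w4}


def _fertility_sampler(preset: PopulationPreset):
    """Return (kind, params) for the completed-fertility draw.

    Over-dispersed presets use Poisson with a family gamma frailty (marginal
    negative binomial); under-dispersed ones a moment-matched binomial.
    """
    mu, var = preset.fertility_mean, preset.fertility_sd**2
    if var > mu * 1.0001:
        r = mu**2 / (var - mu)
        return "nb", {"frailty_shape": r}
    if var < mu * 0.9999:
        n_b = max(int(round(mu**2 / (mu - var))), 1)
        return "binom", {"n": n_b, "p": mu / n_b}
    return "poisson", {}


def _pad(arr, width):
    fmt = "{:0" + str(width) + "d}"
    return np.array([fmt.format(int(v)) for v in arr], dtype=str)


def simulate_pedigree(config: SimulationConfig) -> tuple[Pedigree, pd.DataFrame]:
    """Generate a pedigree and the per-anchor latent truth table.

    Returns ``(pedigree, truth)`` where ``truth`` has one row per anchor
    (generation-2 individual) with the true mutation count, latent family
    quality, fertility frailty and episode multipliers, joinable to the
    pedigree by ``individual_id``.
    """
    rng = np.random.default_rng(config.seed)
    preset = config.resolved_preset()
    mut = config.mutation
    F = config.n_families
    w0, w1_ = preset.birth_year_window

    # --- generation 1: founder couples -----------------------------------
    # family latent quality (mean-1 log-normal) and fertility frailty
    zq = rng.standard_normal(F)
    if config.confounder_sd > 0:
        Q = np.exp(config.confounder_sd * zq - 0.5 * config.confounder_sd**2)
    else:
        Q = np.ones(F)
    kind, fpar = _fertility_sampler(preset)
    if kind == "nb":
        # two independent family frailties: one for the founders' sibship
        # size, one shared by the anchors' own completed fertility.  Sharing a
        # single frailty would size-bias the anchors' fertility (large
        # sibships contribute more anchors), inflating its mean above the
        # preset value.
        r_sh = fpar["frailty_shape"]
        G_sib = rng.gamma(r_sh, 1.0 / r_sh, size=F)
        G = rng.gamma(r_sh, 1.0 / r_sh, size=F)
    else:
        G_sib = np.ones(F)
        G = np.ones(F)

    # founder fathers: brother pairs share a generation-0 grandfather
    lead = np.ones(F, dtype=bool)
    pair_with_prev = np.zeros(F, dtype=bool)
    coin = rng.uniform(size=F) < config.grandfather_brother_prob
    i = 1
    while i < F:
        if coin[i]:
            pair_with_prev[i] = True
            lead[i] = False
            i += 2
        else:
            i += 1
    father_birth = np.empty(F)
    father_birth[lead] = rng.uniform(
        w0 - preset.paternal_age_mean, w1_ - preset.paternal_age_mean, size=lead.sum()
    )
    idx_pair = np.where(pair_with_prev)[0]
    father_birth[idx_pair] = father_birth[idx_pair - 1] + rng.uniform(1, 8, size=len(idx_pair))

    # paternal grandfather per founder father (shared within brother pairs)
    pgf_group = np.cumsum(lead) - 1  # grandfather index per father
    n_pgf = pgf_group[-1] + 1
    pgf_age_lead = _draw_truncnorm(
        rng, n_pgf, preset.paternal_age_mean, preset.paternal_age_sd, 15.0, 80.0
    )
    pgf_birth = father_birth[lead] - pgf_age_lead  # anchored at the lead brother
    # maternal grandfather, one per founder mother
    mgf_age = _draw_truncnorm(
        rng, F, preset.paternal_age_mean, preset.paternal_age_sd, 15.0, 80.0
    )

    # --- generation 2: anchors -------------------------------------------
    mult = G_sib * Q
    if kind == "binom":
        sib_n = rng.binomial(fpar["n"], np.clip(fpar["p"] * mult, 0.0, 1.0))
    else:
        sib_n = rng.poisson(preset.fertility_mean * mult)
    sib_n = np.minimum(sib_n, 99)
    N = int(sib_n.sum())
    fam = np.repeat(np.arange(F), sib_n)

    pa = _draw_truncnorm(
        rng, N, preset.paternal_age_mean, preset.paternal_age_sd, 15.0, 80.0
    )
    if config.confounder_timing_coupling != 0.0:
        pa = np.clip(pa + config.confounder_timing_coupling * zq[fam], 15.0, 80.0)
    # birth order: sort paternal ages within family
    order = np.lexsort((pa, fam))
    pa = pa[order]
    # cap the within-family span of paternal ages at 34 years so the (single)
    # mother's implied reproductive span fits in [15, 50]; the squeeze is
    # symmetric about the family mid-range, which leaves the marginal mean
    # unbiased for normal draws
    fam_max = np.full(F, -np.inf)
    fam_min = np.full(F, np.inf)
    np.maximum.at(fam_max, fam, pa)
    np.minimum.at(fam_min, fam, pa)
    with np.errstate(invalid="ignore"):
        mid = np.where(np.isfinite(fam_max), 0.5 * (fam_max + fam_min), 0.0)
    pa = np.clip(pa, (mid - 17.0)[fam], (mid + 17.0)[fam])
    child_birth = father_birth[fam] + pa

    # mother's birth year: one per family, ages moving in lockstep with father's
    gap = rng.normal(preset.paternal_age_mean - preset.maternal_age_mean, 3.0, size=F)
    pa_min = np.full(F, np.inf)
    pa_max = np.full(F, -np.inf)
    np.minimum.at(pa_min, fam, pa)
    np.maximum.at(pa_max, fam, pa)
    has_kids = sib_n > 0
    lo_gap = np.where(has_kids, pa_max - 50.0, -np.inf)
    hi_gap = np.where(has_kids, pa_min - 15.0, np.inf)
    gap = np.clip(gap, lo_gap, np.maximum(hi_gap, lo_gap))
    mother_birth = father_birth + gap
    ma = pa - gap[fam]

    sex_female = rng.uniform(size=N) < 0.5
    M = draw_denovo_count(pa, mut, rng)
    comps = fitness_components(M, mut)
    Qc = Q[fam]
    Gc = G[fam]

    trisomy = np.zeros(N, dtype=bool)
    if config.maternal_age_effect > 0:
        trisomy = (ma >= 35.0) & (rng.uniform(size=N) < config.maternal_age_effect)

    base1 = np.where(sex_female, 1 - preset.infant_mortality_female, 1 - preset.infant_mortality_male)
    p1 = np.clip(base1 * comps["e1"] * Qc**0.5 * np.where(trisomy, 0.5, 1.0), 0, 1)
    e1 = rng.uniform(size=N) < p1
    p2 = np.clip((1 - preset.juvenile_mortality) * comps["e2"] * Qc**0.5 * np.where(trisomy, 0.5, 1.0), 0, 1)
    e2 = e1 & (rng.uniform(size=N) < p2)
    p3 = np.clip(preset.marriage_prob * Qc**0.5, 0, 1)
    e3 = e2 & (rng.uniform(size=N) < p3)

    fert_mult = Gc * Qc * comps["e4"] * np.where(trisomy, 0.0, 1.0)
    if kind == "binom":
        kids = rng.binomial(fpar["n"], np.clip(fpar["p"] * Qc * comps["e4"], 0, 1))
    else:
        kids = rng.poisson(preset.fertility_mean * fert_mult)
    kids = np.where(e3, np.minimum(kids, 99), 0)

    # vital events
    death_age = np.where(
        ~e1,
        rng.uniform(0.0, 1.0, size=N),
        np.where(~e2, rng.uniform(1.0, 15.0, size=N), rng.uniform(45.0, 90.0, size=N)),
    )
    anchor_death = child_birth + death_age
    marr_age = np.clip(rng.normal(25.0, 4.0, size=N), 16.0, None)
    anchor_marr = child_birth + marr_age
    remarry = e3 & (rng.uniform(size=N) < config.remarriage_prob)
    remarr_year = anchor_marr + rng.uniform(2.0, 15.0, size=N)

    # founder vital events
    first_birth = np.full(F, np.inf)
    np.minimum.at(first_birth, fam, child_birth)
    father_death = father_birth + np.maximum(rng.uniform(45, 90, size=F), np.where(has_kids, pa_max + 1, 45))
    mother_death = mother_birth + np.maximum(rng.uniform(40, 90, size=F), np.where(has_kids, pa_max - gap + 1, 40))
    couple_marr = np.where(
        has_kids, first_birth - rng.uniform(0.5, 2.0, size=F), father_birth + 25.0
    )
    couple_marr = np.maximum(
        couple_marr, np.maximum(father_birth, mother_birth) + 15.5
    )

    miss = lambda n: rng.uniform(size=n) < config.death_missing_prob

    # --- identifiers -------------------------------------------------------
    fam_pad = _pad(np.arange(F), 7)
    father_id = np.char.add("F", fam_pad)
    mother_id = np.char.add("M", fam_pad)
    pgf_id_all = np.char.add("A", _pad(pgf_group, 7))  # per founder father
    pgf_id = np.char.add("A", _pad(np.arange(n_pgf), 7))
    mgf_id = np.char.add("B", fam_pad)

    kth = np.concatenate([np.arange(n) for n in sib_n]) if N else np.array([], dtype=int)
    child_id = np.char.add(
        np.char.add(np.char.add("C", fam_pad[fam]), "x"), _pad(kth, 2)
    )

    # --- assemble records ---------------------------------------------------
    def block(ids, fid, mid, sex, birth, death, marr, region=None):
        return pd.DataFrame(
            {
                "individual_id": ids,
                "father_id": fid,
                "mother_id": mid,
                "sex": sex,
                "birth_year": birth,
                "death_year": death,
                "marriage_years": marr,
                "region": region,
            }
        )

    none_ = lambda n: np.full(n, None, dtype=object)
    empty_marr = lambda n: [() for _ in range(n)]

    gen0p = block(pgf_id, none_(n_pgf), none_(n_pgf), "male", pgf_birth,
                  np.where(miss(n_pgf), np.nan, pgf_birth + rng.uniform(45, 90, n_pgf)),
                  empty_marr(n_pgf))
    gen0m = block(mgf_id, none_(F), none_(F), "male", mother_birth - mgf_age,
                  np.where(miss(F), np.nan, mother_birth - mgf_age + rng.uniform(45, 90, F)),
                  empty_marr(F))
    gen1f = block(father_id, pgf_id_all, none_(F), "male", father_birth,
                  np.where(miss(F), np.nan, father_death),
                  [(y,) for y in couple_marr])
    gen1m = block(mother_id, mgf_id, none_(F), "female", mother_birth,
                  np.where(miss(F), np.nan, mother_death),
                  [(y,) for y in couple_marr])

    anchor_marrs = [
        ((m, r) if rm else (m,)) if flag else ()
        for flag, m, rm, r in zip(e3, anchor_marr, remarry, remarr_year)
    ]
    gen2 = block(child_id, father_id[fam], mother_id[fam],
                 np.where(sex_female, "female", "male"), child_birth,
                 np.where(e2 & miss(N), np.nan, anchor_death),
                 anchor_marrs)

    # --- generation 3: anchors' children as stubs ---------------------------
    kn = kids
    tot_kids = int(kn.sum())
    if tot_kids:
        parent_idx = np.repeat(np.arange(N), kn)
        j = np.concatenate([np.arange(n) for n in kn])
        kid_id = np.char.add(
            np.char.add(np.char.add("K", _pad(parent_idx, 8)), "x"), _pad(j, 2)
        )
        par_is_male = ~sex_female[parent_idx]
        kid_father = np.where(par_is_male, child_id[parent_idx], None)
        kid_mother = np.where(par_is_male, None, child_id[parent_idx])
        kid_birth = child_birth[parent_idx] + rng.uniform(18, 48, size=tot_kids)
        gen3 = block(kid_id, kid_father, kid_mother,
                     np.where(rng.uniform(size=tot_kids) < 0.5, "female", "male"),
                     kid_birth, np.full(tot_kids, np.nan), empty_marr(tot_kids))
    else:
        gen3 = block(np.array([], dtype=str), none_(0), none_(0),
                     np.array([], dtype=str), np.array([]), np.array([]), [])

    df = pd.concat([gen0p, gen0m, gen1f, gen1m, gen2, gen3], ignore_index=True)
    ped = Pedigree(df)
    assign_families(ped)

    fam_label = np.array(
        [f"fam:{f}|{m}" for f, m in zip(father_id[fam], mother_id[fam])], dtype=str
    )
    truth = pd.DataFrame(
        {
            "individual_id": child_id,
            "family_id": fam_label,
            "paternal_age": pa,
            "denovo_count": M,
            "family_quality": Qc,
            "fertility_frailty": Gc,
            "mult_e1": comps["e1"],
            "mult_e2": comps["e2"],
            "mult_e4": comps["e4"],
            "trisomy": trisomy,
        },
        columns=TRUTH_COLUMNS,
    )

    if N == 0:
        warnings.warn("simulation produced no anchors; increase n_families")
    return ped, truth
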