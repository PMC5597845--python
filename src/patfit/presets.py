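"""Population presets for the pedigree simulator.

Each preset packages the demographic descriptives of one study population:
the two German/Canadian church-register populations, the historical Swedish
church registers, and twentieth-century Sweden (national registers).  Mean/sd
paternal and maternal ages, sex-specific infant mortality, and completed
fertility of ever-married women are transcribed from the study's descriptive
table; juvenile mortality (between the 1st and 15th birthday) and the
probability of ever marrying are not tabulated there and are set to values
typical of the respective demographic regime (see docs/methods.md).
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import yaml


class PresetError(ValueError):
    """Unknown preset name or invalid preset file."""


@dataclass(frozen=True)
class PopulationPreset:
    name: str
    paternal_age_mean: float   # years, at anchor's birth
    paternal_age_sd: float
    maternal_age_mean: float
    maternal_age_sd: float
    infant_mortality_female: float  # P(death before 1st birthday)
    infant_mortality_male: float
    juvenile_mortality: float       # P(death in [1, 15) | survived infancy)
    marriage_prob: float            # P(ever married | survived to 15)
    fertility_mean: float           # completed fertility, ever-married women
    fertility_sd: float
    birth_year_window: tuple[float, float]

    def __post_init__(self):
        for p in (
            self.infant_mortality_female,
            self.infant_mortality_male,
            self.juvenile_mortality,
            self.marriage_prob,
        ):
            if not 0.0 <= p <= 1.0:
                raise PresetError(f"probability out of [0,1] in preset {self.name}")
        if self.paternal_age_sd <= 0 or self.maternal_age_sd <= 0 or self.fertility_sd <= 0:
            raise PresetError(f"sd fields must be positive in preset {self.name}")
        lo, hi = self.birth_year_window
        if not lo < hi:
            raise PresetError(f"empty birth-year window in preset {self.name}")


PRESETS: dict[str, PopulationPreset] = {
    "krummhorn": PopulationPreset(
        name="krummhorn",
        paternal_age_mean=35.23,
        paternal_age_sd=7.56,
        maternal_age_mean=31.53,
        maternal_age_sd=5.88,
        infant_mortality_female=0.111,
        infant_mortality_male=0.129,
        juvenile_mortality=0.10,
        marriage_prob=0.80,
        fertility_mean=3.66,
        fertility_sd=2.89,
        birth_year_window=(1720.0, 1835.0),
    ),
    "quebec": PopulationPreset(
        name="quebec",
        paternal_age_mean=36.28,
        paternal_age_sd=8.48,
        maternal_age_mean=29.58,
        maternal_age_sd=6.66,
        infant_mortality_female=0.190,
        infant_mortality_male=0.232,
        juvenile_mortality=0.15,
        marriage_prob=0.90,
        fertility_mean=7.71,
        fertility_sd=4.57,
        birth_year_window=(1670.0, 1740.0),
    ),
    "historical_sweden": PopulationPreset(
        name="historical_sweden",
        paternal_age_mean=34.37,
        paternal_age_sd=7.69,
        maternal_age_mean=31.54,
        maternal_age_sd=6.32,
        infant_mortality_female=0.120,
        infant_mortality_male=0.141,
        juvenile_mortality=0.12,
        marriage_prob=0.80,
        fertility_mean=3.6,
        fertility_sd=3.17,
        birth_year_window=(1737.0, 1850.0),
    ),
    "sweden20c": PopulationPreset(
        name="sweden20c",
        paternal_age_mean=31.84,
        paternal_age_sd=7.05,
        maternal_age_mean=28.34,
        maternal_age_sd=6.11,
        infant_mortality_female=0.005,
        infant_mortality_male=0.007,
        juvenile_mortality=0.004,
        marriage_prob=0.70,
        fertility_mean=2.15,
        fertility_sd=1.11,
        birth_year_window=(1947.0, 1959.0),
    ),
}


def load_preset(name: str) -> PopulationPreset:
    """Return a packaged preset by name, or load one from a YAML file path."""
    if name in PRESETS:
        return PRESETS[name]
    try:
        with open(name, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
    except OSError:
        raise PresetError(
            f"unknown preset {name!r}; packaged presets: {sorted(PRESETS)}"
        ) from None
    if not isinstance(raw, dict):
        raise PresetError(f"preset file {name!r} does not contain a mapping")
    want = {f.name for f in fields(PopulationPreset)}
    extra = set(raw) - want
    if extra:
        raise PresetError(f"unknown preset fields: {sorted(extra)}")
    raw["birth_year_window"] = tuple(raw["birth_year_window"])
    try:
        return PopulationPreset(**raw)
    except TypeError as exc:
        raise PresetError(str(exc)) from None
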