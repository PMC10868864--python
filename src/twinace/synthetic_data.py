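"""Synthetic twin-cohort generator.

Generates same-sex MZ/DZ twin pairs whose phenotypes follow a
liability-threshold ACE model: each member's latent liability is

    L_j = sqrt(a2) * A_j + sqrt(c2) * C + sqrt(e2) * E_j

with C shared within the pair, E_j independent, and the additive-genetic
deviations (A_1, A_2) standard bivariate normal with correlation 1 for
monozygotic and 0.5 for dizygotic pairs.  A binary trait is 1 when the
liability exceeds the threshold implied by its target prevalence; a
continuous trait is the liability rescaled to a requested mean/variance.

The default configuration mirrors the study conditions of the ABCD twin
hub baseline sample: ~60/40 DZ/MZ same-sex pairs, two binary alcohol
traits (intent among never-users, sips) with ~20-30% prevalence, sex- and
race/ethnicity-specific variance components, age ~121 months, and record
defects (missing zygosity, inconsistent zygosity, singleton families) to
exercise the exclusion filter.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy.stats import norm

SEXES = ("M", "F")
RACES = ("White", "Black", "Hispanic", "Other")

#: canonical cohort table columns (one row per individual)
BASE_COLUMNS = [
    "family_id",
    "member_index",
    "zygosity",
    "sex",
    "race_eth",
    "age_months",
    "heard_alcohol",
    "sipped",
    "curious",
    "try_soon",
    "friend_offer",
]

_TOL = 1e-9


class ConfigError(ValueError):
    """A SimulationConfig invariant is violated; the message names it."""


@dataclass(frozen=True)
class TrueComponents:
    """Generative variance proportions on the liability (binary) or
    phenotype (continuous) scale; must sum to one."""

    a2: float
    c2: float
    e2: float

    def validate(self, where: str = "") -> None:
        for name, v in (("a2", self.a2), ("c2", self.c2), ("e2", self.e2)):
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{where}{name}={v} outside [0, 1]")
        if abs(self.a2 + self.c2 + self.e2 - 1.0) > _TOL:
            raise ConfigError(
                f"{where}a2 + c2 + e2 = {self.a2 + self.c2 + self.e2} != 1"
            )

    @property
    def r_mz(self) -> float:
        return self.a2 + self.c2

    @property
    def r_dz(self) -> float:
        return 0.5 * self.a2 + self.c2


@dataclass(frozen=True)
class TraitSpec:
    """One simulated trait: binary (threshold at target prevalence) or
    continuous (liability rescaled to mean/variance)."""

    name: str
    kind: str = "binary"  # binary | continuous
    prevalence: float | None = None
    mean: float = 0.0
    variance: float = 1.0

    def validate(self) -> None:
        if self.kind not in ("binary", "continuous"):
            raise ConfigError(f"trait {self.name}: kind must be binary|continuous")
        if self.kind == "binary":
            if self.prevalence is None or not 0.0 < self.prevalence < 1.0:
                raise ConfigError(
                    f"trait {self.name}: binary trait needs prevalence in (0, 1)"
                )
        elif self.variance <= 0:
            raise ConfigError(f"trait {self.name}: variance must be positive")


def threshold_for_prevalence(prevalence: float) -> float:
    """Liability cut-point t with P(L > t) = prevalence, L ~ N(0,1)."""
    return float(norm.isf(prevalence))


@dataclass(frozen=True)
class StratumSpec:
    """A sex x race/ethnicity stratum with its sampling weight,
    per-trait variance components and optional prevalence overrides."""

    sex: str
    race: str
    weight: float
    components: dict[str, TrueComponents]
    prevalence: dict[str, float] = field(default_factory=dict)

    @property
    def label(self) -> str:
        return f"{self.sex}/{self.race}"


@dataclass(frozen=True)
class DefectRates:
    """Proportions of pairs hit by each record defect, injected after
    generation so the pristine truth is retained upstream."""

    missing_zygosity: float = 0.0
    inconsistent_zygosity: float = 0.0
    singleton: float = 0.0

    def validate(self) -> None:
        rates = dataclasses.asdict(self)
        for name, v in rates.items():
            if not 0.0 <= v < 1.0:
                raise ConfigError(f"defect rate {name}={v} outside [0, 1)")
        if sum(rates.values()) >= 1.0:
            raise ConfigError("defect rates jointly >= 1")


@dataclass(frozen=True)
class SimulationConfig:
    n_pairs: int
    traits: tuple[TraitSpec, ...]
    strata: tuple[StratumSpec, ...]
    dz_fraction: float = 0.604
    age_mean: float = 121.2
    age_sd: float = 6.7
    defect_rates: DefectRates = field(default_factory=DefectRates)
    seed: int = 0

    def validate(self) -> None:
        if self.n_pairs <= 0:
            raise ConfigError(f"n_pairs={self.n_pairs} must be positive")
        if not 0.0 <= self.dz_fraction <= 1.0:
            raise ConfigError(f"dz_fraction={self.dz_fraction} outside [0, 1]")
        if not self.traits:
            raise ConfigError("at least one trait is required")
        if not self.strata:
            raise ConfigError("at least one stratum is required")
        wsum = sum(s.weight for s in self.strata)
        if abs(wsum - 1.0) > _TOL:
            raise ConfigError(f"stratum weights sum to {wsum} != 1")
        for t in self.traits:
            t.validate()
        for s in self.strata:
            if s.sex not in SEXES:
                raise ConfigError(f"stratum sex {s.sex!r} not in {SEXES}")
            if s.race not in RACES:
                raise ConfigError(f"stratum race {s.race!r} not in {RACES}")
            for t in self.traits:
                if t.name not in s.components:
                    raise ConfigError(
                        f"stratum {s.label}: no components for trait {t.name}"
                    )
                s.components[t.name].validate(f"stratum {s.label}, trait {t.name}: ")
        self.defect_rates.validate()

    # -- flat key/value (YAML) serialization -------------------------------
    def to_dict(self) -> dict:
        return {
            "n_pairs": self.n_pairs,
            "dz_fraction": self.dz_fraction,
            "age_mean": self.age_mean,
            "age_sd": self.age_sd,
            "seed": self.seed,
            "defect_rates": dataclasses.asdict(self.defect_rates),
            "traits": [dataclasses.asdict(t) for t in self.traits],
            "strata": [
                {
                    "sex": s.sex,
                    "race": s.race,
                    "weight": s.weight,
                    "components": {k: dataclasses.asdict(v) for k, v in s.components.items()},
                    "prevalence": dict(s.prevalence),
                }
                for s in self.strata
            ],
        }

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        traits = tuple(TraitSpec(**t) for t in d["traits"])
        strata = tuple(
            StratumSpec(
                sex=s["sex"],
                race=s["race"],
                weight=s["weight"],
                components={k: TrueComponents(**v) for k, v in s["components"].items()},
                prevalence=dict(s.get("prevalence", {})),
            )
            for s in d["strata"]
        )
        return cls(
            n_pairs=d["n_pairs"],
            traits=traits,
            strata=strata,
            dz_fraction=d.get("dz_fraction", 0.604),
            age_mean=d.get("age_mean", 121.2),
            age_sd=d.get("age_sd", 6.7),
            defect_rates=DefectRates(**d.get("defect_rates", {})),
            seed=d.get("seed", 0),
        )

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


# ---------------------------------------------------------------------------
# Study-condition defaults
# ---------------------------------------------------------------------------

# Marginal prevalences (%) of the two traits in the emulated cohort:
# overall, by sex, by race/ethnicity.  Intent is defined among never-users.
_PREV = {
    "intent": {"all": 0.235, "M": 0.272, "F": 0.199,
               "White": 0.240, "Black": 0.190, "Hispanic": 0.254, "Other": 0.250},
    "sips": {"all": 0.254, "M": 0.284, "F": 0.223,
             "White": 0.286, "Black": 0.081, "Hispanic": 0.240, "Other": 0.293},
}

# Sex-specific generative variance components.
_COMPONENTS = {
    "intent": {"M": TrueComponents(0.38, 0.0, 0.62),
               "F": TrueComponents(0.39, 0.0, 0.61)},
    "sips": {"M": TrueComponents(0.09, 0.55, 0.36),
             "F": TrueComponents(0.03, 0.63, 0.34)},
}

_SEX_W = {"M": 0.511, "F": 0.489}
_RACE_W = {"White": 0.654, "Black": 0.139, "Hispanic": 0.108, "Other": 0.099}


def _stratum_prevalence(trait: str, sex: str, race: str) -> float:
    """Combine sex and race margins additively on the probit scale."""
    p = _PREV[trait]
    t_all = threshold_for_prevalence(p["all"])
    t = t_all + (threshold_for_prevalence(p[sex]) - t_all) \
        + (threshold_for_prevalence(p[race]) - t_all)
    return float(norm.sf(t))


def study_config(
    n_pairs: int = 886,
    seed: int = 0,
    defect_rates: DefectRates | None = None,
) -> SimulationConfig:
    """Configuration emulating the baseline twin-hub sample: ~60/40 DZ/MZ,
    sex x race strata, alcohol intent and sips with sex-specific components."""
    wtot = sum(_SEX_W[s] * _RACE_W[r] for s in SEXES for r in RACES)
    strata = tuple(
        StratumSpec(
            sex=s,
            race=r,
            weight=_SEX_W[s] * _RACE_W[r] / wtot,
            components={t: _COMPONENTS[t][s] for t in ("intent", "sips")},
            prevalence={t: _stratum_prevalence(t, s, r) for t in ("intent", "sips")},
        )
        for s in SEXES
        for r in RACES
    )
    traits = (
        TraitSpec("intent", "binary", prevalence=_PREV["intent"]["all"]),
        TraitSpec("sips", "binary", prevalence=_PREV["sips"]["all"]),
    )
    return SimulationConfig(
        n_pairs=n_pairs,
        traits=traits,
        strata=strata,
        defect_rates=defect_rates or DefectRates(),
        seed=seed,
    )


def single_trait_config(
    n_pairs: int,
    components: TrueComponents,
    kind: str = "continuous",
    prevalence: float = 0.25,
    dz_fraction: float = 0.5,
    seed: int = 0,
    name: str = "y",
) -> SimulationConfig:
    """Minimal one-stratum, one-trait configuration for recovery and
    power simulations."""
    trait = (
        TraitSpec(name, "binary", prevalence=prevalence)
        if kind == "binary"
        else TraitSpec(name, "continuous")
    )
    stratum = StratumSpec("M", "White", 1.0, components={name: components})
    return SimulationConfig(
        n_pairs=n_pairs, traits=(trait,), strata=(stratum,),
        dz_fraction=dz_fraction, seed=seed,
    )


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------

def simulate_cohort(config: SimulationConfig) -> pd.DataFrame:
    """Generate a cohort table (one row per individual) under *config*.

    Deterministic given ``config.seed``: all per-pair draws are made in a
    fixed order keyed by pair position, and defect injection uses a
    separate child stream, so the pristine pair draws never depend on the
    defect settings.
    """
    config.validate()
    ss_pairs, ss_defects = np.random.SeedSequence(config.seed).spawn(2)
    rng = np.random.default_rng(ss_pairs)
    n = config.n_pairs
    n_strata = len(config.strata)

    stratum_idx = rng.choice(n_strata, size=n, p=[s.weight for s in config.strata])
    is_dz = rng.random(n) < config.dz_fraction
    age = rng.normal(config.age_mean, config.age_sd, size=(n, 2))

    sex = np.array([s.sex for s in config.strata])[stratum_idx]
    race = np.array([s.race for s in config.strata])[stratum_idx]
    zyg = np.where(is_dz, "DZ", "MZ")

    trait_values: dict[str, np.ndarray] = {}  # name -> (n, 2)
    for trait in config.traits:
        a2 = np.empty(n)
        c2 = np.empty(n)
        e2 = np.empty(n)
        tau = np.empty(n)
        for i, s in enumerate(config.strata):
            mask = stratum_idx == i
            comp = s.components[trait.name]
            a2[mask], c2[mask], e2[mask] = comp.a2, comp.c2, comp.e2
            if trait.kind == "binary":
                prev = s.prevalence.get(trait.name, trait.prevalence)
                tau[mask] = threshold_for_prevalence(prev)
        z0 = rng.standard_normal(n)
        z1 = rng.standard_normal(n)
        a_dev = np.stack(
            [z0, np.where(is_dz, 0.5 * z0 + np.sqrt(0.75) * z1, z0)], axis=1
        )
        c_dev = rng.standard_normal(n)[:, None]
        e_dev = rng.standard_normal((n, 2))
        liab = (
            np.sqrt(a2)[:, None] * a_dev
            + np.sqrt(c2)[:, None] * c_dev
            + np.sqrt(e2)[:, None] * e_dev
        )
        if trait.kind == "binary":
            trait_values[trait.name] = (liab > tau[:, None]).astype(int)
        else:
            trait_values[trait.name] = trait.mean + np.sqrt(trait.variance) * liab

    frame = _assemble_frame(config, zyg, sex, race, age, trait_values)
    return _inject_defects_by_rate(frame, config.defect_rates,
                                   np.random.default_rng(ss_defects))


def _assemble_frame(config, zyg, sex, race, age, trait_values) -> pd.DataFrame:
    n = config.n_pairs
    fam = np.array([f"F{i:06d}" for i in range(n)])
    rows = {
        "family_id": np.repeat(fam, 2),
        "member_index": np.tile([1, 2], n),
        "zygosity": np.repeat(zyg, 2),
        "sex": np.repeat(sex, 2),
        "race_eth": np.repeat(race, 2),
        "age_months": np.round(age.ravel(), 1),
    }
    frame = pd.DataFrame(rows)

    trait_names = {t.name: t for t in config.traits}
    # Alcohol traits are rendered as the raw gated questionnaire items so
    # the phenotype-derivation step is exercised; any other trait becomes
    # a plain column.
    sips = trait_values.get("sips")
    intent = trait_values.get("intent")
    if sips is not None or intent is not None:
        sips_flat = sips.ravel() if sips is not None else np.zeros(2 * n, dtype=int)
        frame["heard_alcohol"] = "yes"
        frame["sipped"] = np.where(sips_flat == 1, "yes", "no")
        if intent is not None:
            intent_flat = intent.ravel()
            ever = sips_flat == 1
            frame["curious"] = np.where(
                ever, "", np.where(intent_flat == 1, "A little curious",
                                   "Not at all curious"))
            frame["try_soon"] = np.where(ever, "", "Definitely not")
            frame["friend_offer"] = np.where(ever, "", "Definitely not")
        else:
            frame["curious"] = ""
            frame["try_soon"] = ""
            frame["friend_offer"] = ""
    else:
        frame["heard_alcohol"] = ""
        frame["sipped"] = ""
        frame["curious"] = ""
        frame["try_soon"] = ""
        frame["friend_offer"] = ""

    for name, values in trait_values.items():
        if name not in ("sips", "intent"):
            frame[name] = values.ravel()
            if trait_names[name].kind == "binary":
                frame[name] = frame[name].astype(int)
    return frame


def _inject_defects_by_rate(frame: pd.DataFrame, rates: DefectRates,
                            rng: np.random.Generator) -> pd.DataFrame:
    fams = frame["family_id"].unique()
    n = len(fams)
    n_missing = int(round(rates.missing_zygosity * n))
    n_incons = int(round(rates.inconsistent_zygosity * n))
    n_single = int(round(rates.singleton * n))
    if n_missing + n_incons + n_single == 0:
        return frame
    chosen = rng.permutation(fams)[: n_missing + n_incons + n_single]
    return inject_defects(
        frame,
        missing=chosen[:n_missing],
        inconsistent=chosen[n_missing:n_missing + n_incons],
        singleton=chosen[n_missing + n_incons:],
    )


def inject_defects(frame: pd.DataFrame, missing=(), inconsistent=(),
                   singleton=()) -> pd.DataFrame:
    """Corrupt the listed families: blank zygosity for both members, flip
    member 2's zygosity label, or drop member 2's row."""
    frame = frame.copy()
    missing = set(missing)
    inconsistent = set(inconsistent)
    singleton = set(singleton)
    if (missing & inconsistent) or (missing & singleton) or (inconsistent & singleton):
        raise ValueError("defect family sets must be disjoint")
    frame.loc[frame["family_id"].isin(missing), "zygosity"] = ""
    flip = frame["family_id"].isin(inconsistent) & (frame["member_index"] == 2)
    frame.loc[flip, "zygosity"] = np.where(
        frame.loc[flip, "zygosity"] == "MZ", "DZ", "MZ")
    drop = frame["family_id"].isin(singleton) & (frame["member_index"] == 2)
    return frame.loc[~drop].reset_index(drop=True)


def exclusion_fixture(seed: int = 886) -> pd.DataFrame:
    """Deterministic 1,069-pair cohort with exactly 169 missing-zygosity
    pairs, 12 inconsistent-zygosity pairs and 2 singleton families, so the
    exclusion filter's survivor count (886 pairs) is checkable."""
    cfg = study_config(n_pairs=1069, seed=seed)
    frame = simulate_cohort(cfg)
    fams = frame["family_id"].unique()
    return inject_defects(
        frame,
        missing=fams[:169],
        inconsistent=fams[169:181],
        singleton=fams[181:183],
    )
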