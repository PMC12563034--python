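"""Synthetic ICSR line-list generator.

Emulates the statistical structure of a spontaneous-reporting extract so the
whole pipeline is testable offline: per-drug report volumes, multinomial SOC
profiles with planted similarity clusters (archetypes), per-reaction
seriousness and fatal-outcome probabilities, a reactions-per-case
distribution, and demographic categoricals. No pharmacological realism is
attempted (no dose, indication or concomitant drugs).

The default scenario mirrors the published oral-anticoagulant extract shrunk
by a factor of 100 (≈2,400 cases, ≈4,300 reactions): per-drug volumes and
seriousness/fatality rates follow the published per-drug aggregates, and two
profile archetypes (VKA-like vs NOAC-like) plant the cluster structure the
analysis is meant to recover.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .records import COLUMNS
from .vocab import DEFAULT_DRUGS, NOAC_DRUGS, VKA_DRUGS, soc_codes


class ConfigError(ValueError):
    """Invalid generative configuration (caught before any sampling)."""


def _as_prob_vector(values, length, what) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.shape != (length,):
        raise ConfigError(f"{what}: expected {length} probabilities, got shape {arr.shape}")
    if (arr < 0).any():
        raise ConfigError(f"{what}: negative probability")
    if abs(arr.sum() - 1.0) > 1e-12:
        raise ConfigError(f"{what}: probabilities sum to {arr.sum()!r}, not 1")
    return arr


@dataclass(frozen=True)
class SyntheticConfig:
    """Generative parameters for the ICSR simulator.

    ``drugs`` maps each drug to its target reaction volume n_d. Each drug's
    SOC profile is ``alpha * archetype + (1 - alpha) * global mean`` of the
    assigned archetypes, so ``alpha`` controls cluster tightness (1 = pure
    archetypes, 0 = a single shared profile).
    """

    drugs: dict[str, int]
    socs: tuple[str, ...]
    archetypes: tuple[tuple[float, ...], ...]
    assignment: dict[str, int]
    seriousness_prob: dict[str, float]
    fatal_prob: dict[str, float]
    alpha: float = 1.0
    adrs_per_icsr_mean: float = 1.77
    max_adrs_per_icsr: int = 10
    nonfatal_outcome_probs: dict[str, float] = field(default_factory=dict)
    age_probs: dict[str, float] = field(default_factory=dict)
    sex_probs: dict[str, float] = field(default_factory=dict)
    country_probs: dict[str, float] = field(default_factory=dict)
    seed: int = 0

    def validate(self) -> None:
        if not self.drugs:
            raise ConfigError("no drugs configured")
        for drug, n_d in self.drugs.items():
            if n_d < 1:
                raise ConfigError(f"target reaction volume for {drug!r} must be >= 1")
        if not 0.0 <= self.alpha <= 1.0:
            raise ConfigError("alpha must lie in [0, 1]")
        if self.adrs_per_icsr_mean < 1.0:
            raise ConfigError("mean reactions per case must be >= 1")
        if self.max_adrs_per_icsr < 1:
            raise ConfigError("max reactions per case must be >= 1")
        for k, arch in enumerate(self.archetypes):
            _as_prob_vector(arch, len(self.socs), f"archetype {k}")
        for drug in self.drugs:
            if drug not in self.assignment:
                raise ConfigError(f"no archetype assigned to {drug!r}")
            if not 0 <= self.assignment[drug] < len(self.archetypes):
                raise ConfigError(f"archetype index out of range for {drug!r}")
            for probs, what in (
                (self.seriousness_prob, "seriousness_prob"),
                (self.fatal_prob, "fatal_prob"),
            ):
                p = probs.get(drug)
                if p is None or not 0.0 <= p <= 1.0:
                    raise ConfigError(f"{what}[{drug!r}] must be a probability")
        for name in ("nonfatal_outcome_probs", "age_probs", "sex_probs", "country_probs"):
            dist = getattr(self, name)
            _as_prob_vector(list(dist.values()), len(dist), name)

    def drug_profiles(self) -> dict[str, np.ndarray]:
        """Per-drug SOC probability vectors after archetype mixing."""
        arch = [np.asarray(a, dtype=float) for a in self.archetypes]
        mean = np.mean([arch[self.assignment[d]] for d in self.drugs], axis=0)
        return {
            d: self.alpha * arch[self.assignment[d]] + (1.0 - self.alpha) * mean
            for d in self.drugs
        }


@dataclass(frozen=True)
class GroundTruth:
    """What the generator actually planted and realized, for recovery checks."""

    socs: tuple[str, ...]
    drugs: tuple[str, ...]
    counts: np.ndarray              # realized SOC × drug reaction counts
    assignment: dict[str, int]      # drug -> archetype label
    realized_seriousness: dict[str, float]
    realized_fatal: dict[str, float]

    def counts_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.socs), columns=list(self.drugs))


# --- default scenario --------------------------------------------------------

#: Baseline SOC reporting weights (relative, normalised at use). Gastro and
#: nervous-system disorders dominate, as in anticoagulant safety data; a thin
#: tail covers every class including social circumstances.
_BASE_WEIGHTS = {
    "Blood": 30, "Card": 50, "Cong": 4, "Ear": 8, "Endo": 5, "Eye": 12,
    "Gastr": 170, "Genrl": 100, "Hepato": 15, "Immun": 10, "Infec": 30,
    "Inj&P": 80, "Inv": 60, "Metab": 20, "Musc": 40, "Neopl": 20,
    "Nerv": 130, "Preg": 4, "Product": 5, "Psych": 30, "Renal": 30,
    "Repro": 5, "Resp": 60, "Skin": 40, "Surg": 20, "Vasc": 70, "Soc": 5,
}

#: Archetype 0 (VKA-like): monitoring-driven reporting — investigations,
#: pregnancy-related and injury/poisoning inflated. Archetype 1 (NOAC-like):
#: bleeding-site reporting — gastro and nervous-system inflated.
_VKA_BOOST = {"Inv": 3.0, "Preg": 6.0, "Inj&P": 1.6, "Psych": 1.5, "Endo": 1.5}
_NOAC_BOOST = {"Gastr": 1.7, "Nerv": 1.5, "Renal": 1.3, "Vasc": 1.2, "Surg": 1.4}

#: Per-drug reaction volumes: the published per-drug ADR totals divided by 100.
_DEFAULT_VOLUMES = {
    "warfarin": 811, "acenocumarol": 173, "dabigatran": 871,
    "rivaroxaban": 1726, "apixaban": 671, "edoxaban": 61,
}
#: Published per-drug serious and fatal reaction shares.
_DEFAULT_SERIOUS = {
    "warfarin": 0.910, "acenocumarol": 0.888, "dabigatran": 0.937,
    "rivaroxaban": 0.955, "apixaban": 0.909, "edoxaban": 0.709,
}
_DEFAULT_FATAL = {
    "warfarin": 0.084, "acenocumarol": 0.085, "dabigatran": 0.124,
    "rivaroxaban": 0.066, "apixaban": 0.088, "edoxaban": 0.060,
}
#: Non-fatal outcome mix and demographics from the published pooled totals.
_DEFAULT_NONFATAL = {
    "not_recovered": 36950, "not_specified": 2981, "recovered": 102724,
    "recovered_with_sequelae": 6195, "recovering": 49831, "unknown": 213820,
}
_DEFAULT_AGE = {
    "over_85": 0.146, "65_85": 0.477, "18_64": 0.165,
    "under_18": 0.002, "not_specified": 0.210,
}
_DEFAULT_SEX = {"F": 0.456, "M": 0.469, "not_specified": 0.075}
_DEFAULT_COUNTRY = {
    "FR": 0.24, "IT": 0.21, "DE": 0.17, "GB": 0.12, "ES": 0.08, "NL": 0.06, "": 0.12,
}


def _normalise(weights: dict[str, float], socs) -> tuple[float, ...]:
    w = np.array([weights[s] for s in socs], dtype=float)
    w = w / w.sum()
    w[-1] = 1.0 - w[:-1].sum()  # exact unit sum
    return tuple(w)


def default_config(seed: int = 0, alpha: float = 1.0, scale: float = 1.0) -> SyntheticConfig:
    """The default two-archetype oral-anticoagulant scenario.

    ``scale`` multiplies every per-drug reaction volume (1.0 ≈ the published
    extract divided by 100).
    """
    socs = soc_codes(include_social=True)
    vka = {s: _BASE_WEIGHTS[s] * _VKA_BOOST.get(s, 1.0) for s in socs}
    noac = {s: _BASE_WEIGHTS[s] * _NOAC_BOOST.get(s, 1.0) for s in socs}
    nonfatal_total = sum(_DEFAULT_NONFATAL.values())
    nonfatal = {k: v / nonfatal_total for k, v in _DEFAULT_NONFATAL.items()}
    config = SyntheticConfig(
        drugs={d: max(1, round(n * scale)) for d, n in _DEFAULT_VOLUMES.items()},
        socs=socs,
        archetypes=(_normalise(vka, socs), _normalise(noac, socs)),
        assignment={d: 0 if d in VKA_DRUGS else 1 for d in DEFAULT_DRUGS},
        seriousness_prob=dict(_DEFAULT_SERIOUS),
        fatal_prob=dict(_DEFAULT_FATAL),
        alpha=alpha,
        nonfatal_outcome_probs=nonfatal,
        age_probs=dict(_DEFAULT_AGE),
        sex_probs=dict(_DEFAULT_SEX),
        country_probs=dict(_DEFAULT_COUNTRY),
        seed=seed,
    )
    config.validate()
    return config


def generate(config: SyntheticConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Draw a synthetic line list and the ground truth behind it.

    For each drug, cases are drawn (truncated-geometric number of reactions
    each) until the drug's reaction volume is reached; the last case is
    trimmed to hit the volume exactly. Each reaction's SOC is multinomial
    from the drug's mixed profile; seriousness and fatal outcome are
    Bernoulli per reaction; demographics are case-level categoricals.
    Output is deterministic given the config (seed included).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    socs = tuple(config.socs)
    profiles = config.drug_profiles()
    geometric_p = 1.0 / config.adrs_per_icsr_mean

    nonfatal_levels = list(config.nonfatal_outcome_probs)
    nonfatal_p = np.array(list(config.nonfatal_outcome_probs.values()))
    age_levels, age_p = list(config.age_probs), np.array(list(config.age_probs.values()))
    sex_levels, sex_p = list(config.sex_probs), np.array(list(config.sex_probs.values()))
    ctry_levels = list(config.country_probs)
    ctry_p = np.array(list(config.country_probs.values()))

    frames = []
    counts = np.zeros((len(socs), len(config.drugs)), dtype=np.int64)
    realized_serious: dict[str, float] = {}
    realized_fatal: dict[str, float] = {}

    for j, (drug, n_d) in enumerate(config.drugs.items()):
        sizes = rng.geometric(geometric_p, size=n_d).clip(max=config.max_adrs_per_icsr)
        cum = np.cumsum(sizes)
        n_cases = int(np.searchsorted(cum, n_d)) + 1
        sizes = sizes[:n_cases]
        sizes[-1] -= cum[n_cases - 1] - n_d  # trim to the exact volume

        case_ids = np.array([f"{drug[:3].upper()}-{i:07d}" for i in range(n_cases)])
        age = rng.choice(age_levels, size=n_cases, p=age_p)
        sex = rng.choice(sex_levels, size=n_cases, p=sex_p)
        country = rng.choice(ctry_levels, size=n_cases, p=ctry_p)

        soc_idx = rng.choice(len(socs), size=n_d, p=profiles[drug])
        serious = rng.random(n_d) < config.seriousness_prob[drug]
        fatal = rng.random(n_d) < config.fatal_prob[drug]
        outcome = rng.choice(nonfatal_levels, size=n_d, p=nonfatal_p)
        outcome[fatal] = "fatal"

        frames.append(
            pd.DataFrame(
                {
                    "icsr_id": np.repeat(case_ids, sizes),
                    "drug": drug,
                    "soc": np.array(socs, dtype=object)[soc_idx],
                    "seriousness": np.where(serious, "serious", "non_serious"),
                    "outcome": outcome,
                    "age_band": np.repeat(age, sizes),
                    "sex": np.repeat(sex, sizes),
                    "country": np.repeat(country, sizes),
                },
                columns=list(COLUMNS),
            )
        )
        counts[:, j] = np.bincount(soc_idx, minlength=len(socs))
        realized_serious[drug] = float(serious.mean())
        realized_fatal[drug] = float(fatal.mean())

    line_list = pd.concat(frames, ignore_index=True)
    truth = GroundTruth(
        socs=socs,
        drugs=tuple(config.drugs),
        counts=counts,
        assignment=dict(config.assignment),
        realized_seriousness=realized_serious,
        realized_fatal=realized_fatal,
    )
    return line_list, truth


def scaled_config(config: SyntheticConfig, **overrides) -> SyntheticConfig:
    """Copy a config with field overrides (validated)."""
    new = replace(config, **overrides)
    new.validate()
    return new
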