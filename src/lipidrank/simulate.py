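"""Synthetic case-control lipidomics cohorts with known ground truth.

The generator emulates a serum lipidomics panel of 530 species in 34
classes measured on a small case-control cohort (22 cases / 30 controls by
default).  Concentrations are log-normal: each species' log-value is a
class baseline plus a species baseline plus, in cases, an additive log-scale
group effect (class-level and/or species-level), plus Gaussian noise.  Ages
and sexes are drawn to match a typical mid-life cohort.  Every run is fully
reproducible from its seed and serializes its ground truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .core import AbundanceMatrix, LipidTaxonomy, SubjectMetadata

#: The ten headline lipid classes and their species counts in the default
#: panel (jointly 176 species): glycerophosphatidylcholine (PC),
#: N-acylphosphatidylserine (NAPS), diradylglycerol (DG),
#: globotriaosylceramide (GB3), ceramide (Cer), monohexosylceramide (MhCer),
#: bis(monoacylglycero)phosphate (BMP), lysophosphatidylserine (LPS),
#: triradylglycerol (TG) and N-acylphosphatidylethanolamine (NAPE).
TOP_CLASS_SIZES: dict[str, int] = {
    "PC": 60, "TG": 40, "Cer": 20, "DG": 15, "MhCer": 12,
    "NAPE": 10, "NAPS": 7, "GB3": 5, "BMP": 4, "LPS": 3,
}

#: Remaining 24 classes of the 530-species panel (354 species).
OTHER_CLASS_SIZES: dict[str, int] = {
    "SM": 36, "PE": 36, "PI": 20, "PS": 18, "PG": 12, "PA": 12,
    "LPC": 15, "LPE": 12, "LPI": 8, "LPA": 6, "CE": 24, "FFA": 29,
    "DhCer": 10, "LacCer": 8, "Sph": 6, "S1P": 4, "CL": 12, "MG": 8,
    "CAR": 15, "GM3": 8, "PEp": 20, "PCe": 20, "GD3": 5, "Gb4": 10,
}

TOP_CLASSES: list[str] = list(TOP_CLASS_SIZES)

DEFAULT_N_CASE = 22
DEFAULT_N_CONTROL = 30


def _species_names(class_id: str, n: int) -> list[str]:
    """Dotted species names CLASS.carbons.doublebonds on a deterministic grid."""
    names = []
    for carbons in range(30, 74, 2):
        for db in range(0, 9):
            names.append(f"{class_id}.{carbons}.{db}")
            if len(names) == n:
                return names
    raise ValueError(f"cannot name {n} species for class {class_id}")


def make_default_taxonomy(seed: int = 0) -> LipidTaxonomy:
    """Build the default 530-species / 34-class panel.

    The ten headline classes jointly contain exactly 176 species.  The
    panel layout is a fixed fixture; it does not vary with the seed.
    """
    class_of: dict[str, str] = {}
    for cls, n in {**TOP_CLASS_SIZES, **OTHER_CLASS_SIZES}.items():
        for sp in _species_names(cls, n):
            class_of[sp] = cls
    return LipidTaxonomy(class_of)


@dataclass(frozen=True)
class EffectSpec:
    """Log-scale case-vs-control mean shifts.

    ``class_effects`` shifts every species of a class; ``species_effects``
    adds a species-specific shift on top.  The sign is the direction of
    effect (positive = higher in cases).  An empty spec is the null cohort.
    """

    class_effects: dict[str, float] = field(default_factory=dict)
    species_effects: dict[str, float] = field(default_factory=dict)

    def validate(self, tax: LipidTaxonomy) -> None:
        bad = set(self.class_effects) - set(tax.class_ids)
        if bad:
            raise ValueError(f"effect spec references unknown classes: {sorted(bad)}")
        bad = set(self.species_effects) - set(tax.species_ids)
        if bad:
            raise ValueError(f"effect spec references unknown species: {sorted(bad)}")

    @property
    def informative_classes(self) -> list[str]:
        return [c for c, e in self.class_effects.items() if e != 0]

    @property
    def informative_species(self) -> list[str]:
        return [s for s, e in self.species_effects.items() if e != 0]


def default_effect_spec(magnitude: float = 0.4) -> EffectSpec:
    """Demonstration effect template: PC, DG, TG up in cases; GB3, NAPS,
    NAPE down.  The magnitude is a free parameter."""
    return EffectSpec(class_effects={
        "PC": magnitude, "DG": magnitude, "TG": magnitude,
        "GB3": -magnitude, "NAPS": -magnitude, "NAPE": -magnitude,
    })


@dataclass
class GroundTruth:
    """Generator provenance stored alongside every simulated cohort."""

    effects: EffectSpec
    informative_classes: list[str]
    informative_species: list[str]
    seed: int
    params: dict

    def to_json(self, path: str | Path) -> None:
        payload = {
            "class_effects": self.effects.class_effects,
            "species_effects": self.effects.species_effects,
            "informative_classes": self.informative_classes,
            "informative_species": self.informative_species,
            "seed": self.seed,
            "params": self.params,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)


def simulate_cohort(
    tax: LipidTaxonomy,
    n_case: int = DEFAULT_N_CASE,
    n_control: int = DEFAULT_N_CONTROL,
    effects: EffectSpec | None = None,
    noise_sd: float = 1.0,
    missing_rate: float = 0.0,
    seed: int = 0,
) -> tuple[AbundanceMatrix, SubjectMetadata, GroundTruth]:
    """Draw a log-normal case-control cohort over the given panel.

    log-concentration = class baseline + species baseline
                        + case_indicator * (class effect + species effect)
                        + N(0, noise_sd)

    Ages ~ N(51, 12) truncated to [30, 85]; sex is Bernoulli per group
    (55% female in cases, 67% in controls).  ``missing_rate`` masks cells
    uniformly at random to emulate sporadic undetectable species.
    """
    if n_case < 2 or n_control < 2:
        raise ValueError("need at least 2 subjects per group")
    effects = effects or EffectSpec()
    effects.validate(tax)
    rng = np.random.default_rng(seed)

    species = tax.species_ids
    classes = tax.class_ids
    class_base = dict(zip(classes, rng.normal(2.0, 1.0, len(classes))))
    species_base = dict(zip(species, rng.normal(0.0, 0.5, len(species))))

    n = n_case + n_control
    subject_ids = [f"S{i:03d}" for i in range(n)]
    is_case = np.array([1] * n_case + [0] * n_control)

    shift = np.array([
        effects.class_effects.get(tax.class_of[s], 0.0)
        + effects.species_effects.get(s, 0.0)
        for s in species
    ])
    base = np.array([class_base[tax.class_of[s]] + species_base[s] for s in species])
    log_values = (
        base[None, :]
        + np.outer(is_case, shift)
        + rng.normal(0.0, noise_sd, size=(n, len(species)))
    )
    values = pd.DataFrame(np.exp(log_values), index=subject_ids, columns=species)
    if missing_rate > 0:
        mask = rng.random(values.shape) < missing_rate
        values = values.mask(mask)

    a, b = (30 - 51) / 12, (85 - 51) / 12
    ages = stats.truncnorm.rvs(a, b, loc=51, scale=12, size=n, random_state=rng)
    p_female = np.where(is_case == 1, 0.55, 0.67)
    sex = np.where(rng.random(n) < p_female, "female", "male")
    meta = SubjectMetadata(pd.DataFrame(
        {"group": np.where(is_case == 1, "case", "control"),
         "age": np.round(ages, 1), "sex": sex},
        index=pd.Index(subject_ids, name="subject_id"),
    ))

    truth = GroundTruth(
        effects=effects,
        informative_classes=effects.informative_classes,
        informative_species=effects.informative_species,
        seed=seed,
        params={"n_case": n_case, "n_control": n_control,
                "noise_sd": noise_sd, "missing_rate": missing_rate},
    )
    return AbundanceMatrix(values, level="species"), meta, truth


@dataclass
class RawPeakExperiment:
    """Log-scale raw peaks and internal-standard intensities with shared
    per-sample technical drift, plus the latent factor for testing."""

    raw_log: pd.DataFrame
    is_log: pd.DataFrame
    factor: pd.Series


def simulate_raw_peaks(
    m: AbundanceMatrix,
    n_is: int = 3,
    drift_sd: float = 0.5,
    meas_sd: float = 0.05,
    seed: int = 0,
) -> RawPeakExperiment:
    """Corrupt a clean abundance matrix with sample-level technical drift.

    Each sample gets a latent factor ~ N(0, drift_sd).  Every raw log-peak
    is the true log-value plus the factor (unit loading) plus measurement
    noise; each internal standard is its own constant plus the same factor
    plus noise.  With ``drift_sd=0`` the raw peaks equal the true values up
    to measurement noise.
    """
    if n_is < 1:
        raise ValueError("need at least one internal standard")
    rng = np.random.default_rng(seed)
    n = m.n_subjects
    factor = pd.Series(rng.normal(0.0, drift_sd, n) if drift_sd > 0 else np.zeros(n),
                       index=m.data.index, name="drift_factor")
    true_log = np.log(m.data)
    raw_log = (true_log.add(factor, axis=0)
               + rng.normal(0.0, meas_sd, size=m.data.shape))
    is_const = rng.normal(5.0, 1.0, n_is)
    is_log = pd.DataFrame(
        is_const[None, :] + factor.to_numpy()[:, None]
        + rng.normal(0.0, meas_sd, size=(n, n_is)),
        index=m.data.index,
        columns=[f"IS{j + 1}" for j in range(n_is)],
    )
    return RawPeakExperiment(raw_log, is_log, factor)
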