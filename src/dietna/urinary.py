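"""Urinary sodium methods.

Covers the reference method (24-h urinary sodium from a timed collection),
completeness screening of collections, and estimation of 24-h sodium
excretion from a single spot-urine sample via six published conversion
equations (Kawasaki, Tanaka, INTERSALT with and without potassium, and two
creatinine-ratio equations). Equation coefficients live in a versioned
plain-text registry (``data/equations.csv``) with per-coefficient
provenance, never inline in code.

Units follow clinical convention: urinary Na and K concentrations in
mmol/L, creatinine concentration in mg/dL, volume in litres, 24-h
excretions in mg/day.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable

import numpy as np
import pandas as pd

#: Molar mass of sodium used for the mmol <-> mg bridge. 23.0 is the
#: conventional rounded value; 22.9898 is available for exact work.
NA_MG_PER_MMOL = 23.0

#: Salt (NaCl) mass per unit sodium mass: 600 mg Na == 1.5 g salt.
SALT_TO_NA_RATIO = 2.5

#: Molar mass of creatinine (g/mol); bridges mg/dL to mmol/L.
CREATININE_MG_PER_MMOL = 113.12

SPOT_EQUATION_IDS = (
    "kawasaki",
    "tanaka",
    "intersalt_with_k",
    "intersalt_without_k",
    "mage",
    "toft",
)

# ---------------------------------------------------------------------------
# unit bridges


def na_mmol_to_mg(x, molar_mass: float = NA_MG_PER_MMOL):
    """Convert sodium mmol to mg."""
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("sodium amount must be non-negative (mmol)")
    out = x * molar_mass
    return float(out) if out.ndim == 0 else out


def na_mg_to_mmol(x, molar_mass: float = NA_MG_PER_MMOL):
    """Convert sodium mg to mmol (inverse of :func:`na_mmol_to_mg`)."""
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("sodium amount must be non-negative (mg)")
    out = x / molar_mass
    return float(out) if out.ndim == 0 else out


def na_mg_to_salt_g(x):
    """Convert mg of sodium to grams of salt (NaCl), ratio 2.5.

    600 mg Na corresponds to 1.5 g of salt.
    """
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("sodium amount must be non-negative (mg)")
    out = x * SALT_TO_NA_RATIO / 1000.0
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# records


@dataclass(frozen=True)
class UrineRecord:
    """One urine sample: either a full 24-h collection or a spot sample."""

    participant_id: str
    kind: str  # "collection_24h" | "spot"
    na_conc: float  # mmol/L
    k_conc: float = np.nan  # mmol/L
    creat_conc: float = np.nan  # mg/dL
    volume: float = np.nan  # litres; required for collection_24h

    def __post_init__(self):
        if self.kind not in ("collection_24h", "spot"):
            raise ValueError(f"unknown urine record kind {self.kind!r}")
        if self.na_conc < 0:
            raise ValueError("na_conc must be non-negative")
        if self.kind == "collection_24h" and not self.volume > 0:
            raise ValueError("volume must be positive for a 24-h collection")


@dataclass(frozen=True)
class ParticipantProfile:
    """Demographics and anthropometry driving sex/age-dependent equations."""

    participant_id: str
    age_y: float
    sex: str  # "M" | "F"
    weight_kg: float
    height_cm: float

    @property
    def bmi(self) -> float:
        return self.weight_kg / (self.height_cm / 100.0) ** 2


def compute_24h_urinary_na(record: UrineRecord, molar_mass: float = NA_MG_PER_MMOL) -> float:
    """24-h urinary sodium (mg/day) from a 24-h collection.

    concentration (mmol/L) x volume (L) -> mmol/day -> mg/day.
    """
    if record.kind != "collection_24h":
        raise ValueError("compute_24h_urinary_na requires a collection_24h record")
    return record.na_conc * record.volume * molar_mass


# ---------------------------------------------------------------------------
# completeness screening


@dataclass(frozen=True)
class CompletenessRules:
    """Screening rules for 24-h collection completeness.

    Defaults follow the criteria commonly used in the urinary-sodium
    literature: a minimum collected volume of 0.5 L and 24-h creatinine
    excretion per kg body weight within sex-specific physiological bounds.
    Each rule can be switched off independently via ``enabled_rules``.
    """

    min_volume: float = 0.5  # litres
    creat_per_kg_bounds_male: tuple[float, float] = (14.4, 33.6)  # mg/kg/day
    creat_per_kg_bounds_female: tuple[float, float] = (10.8, 25.2)
    enabled_rules: tuple[str, ...] = ("min_volume", "creatinine_range")

    def __post_init__(self):
        for name in ("creat_per_kg_bounds_male", "creat_per_kg_bounds_female"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ValueError(f"{name} must be a proper interval")
        unknown = set(self.enabled_rules) - {"min_volume", "creatinine_range"}
        if unknown:
            raise ValueError(f"unknown completeness rules: {sorted(unknown)}")


def screen_completeness(
    record: UrineRecord,
    profile: ParticipantProfile | None,
    rules: CompletenessRules,
) -> tuple[bool, list[str]]:
    """Return (complete, violated-rule names) for a 24-h collection.

    Pure function of its inputs; a record is complete iff no enabled rule
    is violated.
    """
    if record.kind != "collection_24h":
        raise ValueError("completeness screening applies to 24-h collections only")
    violations: list[str] = []
    if "min_volume" in rules.enabled_rules and record.volume < rules.min_volume:
        violations.append("min_volume")
    if "creatinine_range" in rules.enabled_rules:
        if profile is None or not np.isfinite(profile.weight_kg):
            raise ValueError(
                "creatinine_range rule requires a profile with sex and weight"
            )
        creat_mg_day = record.creat_conc * 10.0 * record.volume  # mg/dL -> mg/L
        per_kg = creat_mg_day / profile.weight_kg
        lo, hi = (
            rules.creat_per_kg_bounds_male
            if profile.sex == "M"
            else rules.creat_per_kg_bounds_female
        )
        if not lo <= per_kg <= hi:
            violations.append("creatinine_range")
    return (not violations, violations)


# ---------------------------------------------------------------------------
# spot-urine conversion equations


@dataclass(frozen=True)
class EquationSpec:
    """A spot-urine conversion equation materialised from the registry."""

    equation_id: str
    family: str  # "ratio_power" | "intersalt"
    output_unit: str  # always mmol/day internally
    coefficients: dict  # (sex, term) -> coefficient
    requires: tuple[str, ...]
    provenance: dict = field(default_factory=dict)

    def coef(self, sex: str, term: str, default: float | None = None) -> float:
        for key in ((sex, term), ("any", term)):
            if key in self.coefficients:
                return self.coefficients[key]
        if default is not None:
            return default
        raise KeyError(f"{self.equation_id}: no coefficient for {term!r} (sex {sex!r})")

    def has(self, sex: str, term: str) -> bool:
        return (sex, term) in self.coefficients or ("any", term) in self.coefficients


_RATIO_IDS = {"kawasaki", "tanaka", "mage", "toft"}

_REQUIRES = {
    "kawasaki": ("spot_na", "spot_creat", "age", "sex", "weight", "height"),
    "tanaka": ("spot_na", "spot_creat", "age", "weight", "height"),
    "intersalt_with_k": ("spot_na", "spot_k", "spot_creat", "age", "sex", "weight", "height"),
    "intersalt_without_k": ("spot_na", "spot_creat", "age", "sex", "weight", "height"),
    "mage": ("spot_na", "spot_creat", "sex", "weight", "height"),
    "toft": ("spot_na", "spot_creat", "sex", "weight"),
}


def load_equation_registry(path=None) -> dict[str, EquationSpec]:
    """Load the conversion-equation registry from its constants file."""
    if path is None:
        with resources.as_file(resources.files("dietna.data") / "equations.csv") as p:
            table = pd.read_csv(p)
    else:
        table = pd.read_csv(path)
    registry: dict[str, EquationSpec] = {}
    for eq_id, grp in table.groupby("equation_id", sort=False):
        coefs = {(r.sex, r.term): float(r.coefficient) for r in grp.itertuples()}
        prov = {(r.sex, r.term): r.provenance for r in grp.itertuples()}
        family = "ratio_power" if eq_id in _RATIO_IDS else "intersalt"
        registry[eq_id] = EquationSpec(
            equation_id=eq_id,
            family=family,
            output_unit="mmol/day",
            coefficients=coefs,
            requires=_REQUIRES[eq_id],
            provenance=prov,
        )
    return registry


_REGISTRY: dict[str, EquationSpec] | None = None


def equation_registry() -> dict[str, EquationSpec]:
    global _REGISTRY
    if _REGISTRY is None:
        _REGISTRY = load_equation_registry()
    return _REGISTRY


def _prcr_terms(spec: EquationSpec, sex, age, weight, height):
    """Predicted 24-h creatinine (mg/day) for one sex value (scalar sex)."""
    total = np.zeros(np.broadcast(np.asarray(age), np.asarray(weight)).shape)
    total = total + spec.coef(sex, "prcr_intercept", 0.0)
    if spec.has(sex, "prcr_age"):
        total = total + spec.coef(sex, "prcr_age") * age
    if spec.has(sex, "prcr_weight"):
        total = total + spec.coef(sex, "prcr_weight") * weight
    if spec.has(sex, "prcr_height"):
        total = total + spec.coef(sex, "prcr_height") * height
    if spec.has(sex, "prcr_w15sqrth"):
        total = total + spec.coef(sex, "prcr_w15sqrth") * weight**1.5 * np.sqrt(height)
    if spec.has(sex, "prcr_per_kg"):
        total = total + spec.coef(sex, "prcr_per_kg") * weight
    return total


def predicted_creatinine_24h(equation_id: str, profile: ParticipantProfile) -> float:
    """Predicted 24-h urinary creatinine (mg/day) for ratio-type equations."""
    registry = equation_registry()
    if equation_id not in registry:
        raise KeyError(f"unknown equation_id {equation_id!r}")
    spec = registry[equation_id]
    if spec.family != "ratio_power":
        raise ValueError(f"{equation_id} has no predicted-creatinine sub-model")
    missing = [
        name
        for name, value in (
            ("age", profile.age_y),
            ("weight", profile.weight_kg),
            ("height", profile.height_cm),
        )
        if not np.isfinite(value)
    ]
    if missing:
        raise ValueError(f"{equation_id}: missing covariates {missing}")
    return float(_prcr_terms(spec, profile.sex, profile.age_y, profile.weight_kg, profile.height_cm))


def estimate_spot_24h_na(
    equation_id: str,
    spot: UrineRecord,
    profile: ParticipantProfile,
    molar_mass: float = NA_MG_PER_MMOL,
) -> float:
    """Estimated 24-h sodium excretion (mg/day) from a spot sample.

    Evaluates the registry equation; mmol/day outputs are converted to
    mg/day. Negative linear-equation outputs are floored at 0 with a
    warning (excretion cannot be negative).
    """
    if spot.kind != "spot":
        raise ValueError("estimate_spot_24h_na requires a spot record")
    out = evaluate_spot_equation(
        equation_id,
        sex=profile.sex,
        age=profile.age_y,
        weight=profile.weight_kg,
        height=profile.height_cm,
        spot_na=spot.na_conc,
        spot_k=spot.k_conc,
        spot_creat=spot.creat_conc,
        molar_mass=molar_mass,
    )
    return float(out)


def evaluate_spot_equation(
    equation_id: str,
    *,
    sex,
    age,
    weight,
    height,
    spot_na,
    spot_k=np.nan,
    spot_creat=np.nan,
    molar_mass: float = NA_MG_PER_MMOL,
):
    """Vectorised evaluation of one conversion equation; returns mg/day.

    ``sex`` may be a scalar or an array of "M"/"F". All other inputs
    broadcast. Missing required inputs (NaN) raise with the field name for
    scalar inputs and propagate NaN for arrays.
    """
    registry = equation_registry()
    if equation_id not in registry:
        raise KeyError(f"unknown equation_id {equation_id!r}")
    spec = registry[equation_id]

    sex_arr = np.atleast_1d(np.asarray(sex, dtype=object))
    age = np.asarray(age, dtype=float)
    weight = np.asarray(weight, dtype=float)
    height = np.asarray(height, dtype=float)
    spot_na_a = np.asarray(spot_na, dtype=float)
    spot_k_a = np.asarray(spot_k, dtype=float)
    spot_creat_a = np.asarray(spot_creat, dtype=float)

    scalar = all(
        np.ndim(v) == 0 for v in (sex, age, weight, height, spot_na, spot_k, spot_creat)
    )
    if scalar:
        provided = {
            "spot_na": spot_na_a,
            "spot_k": spot_k_a,
            "spot_creat": spot_creat_a,
            "age": age,
            "weight": weight,
            "height": height,
        }
        for name in spec.requires:
            if name == "sex":
                continue
            if not np.isfinite(provided[name]):
                raise ValueError(f"{equation_id}: missing required input {name!r}")
        if np.any(spot_na_a < 0) or (np.isfinite(spot_creat_a) and spot_creat_a < 0):
            raise ValueError(f"{equation_id}: concentrations must be non-negative")

    shape = np.broadcast(sex_arr, age, weight, height, spot_na_a, spot_k_a, spot_creat_a).shape
    sex_b = np.broadcast_to(sex_arr, shape)
    out = np.full(shape, np.nan)

    if spec.family == "ratio_power":
        scale = spec.coef("any", "scale")
        exponent = spec.coef("any", "exponent")
        for s in ("M", "F"):
            mask = sex_b == s
            if not mask.any():
                continue
            prcr = np.broadcast_to(_prcr_terms(spec, s, age, weight, height), shape)[mask]
            creat_mg_l = np.broadcast_to(spot_creat_a, shape)[mask] * 10.0
            ratio = np.broadcast_to(spot_na_a, shape)[mask] / creat_mg_l * prcr
            out[mask] = scale * np.power(ratio, exponent)
    else:  # intersalt family: linear in concentrations and anthropometry
        bmi = weight / (height / 100.0) ** 2
        creat_mmol = spot_creat_a / CREATININE_MG_PER_MMOL * 10.0  # mg/dL -> mmol/L
        for s in ("M", "F"):
            mask = sex_b == s
            if not mask.any():
                continue
            val = (
                spec.coef(s, "intercept")
                + spec.coef(s, "spot_na") * np.broadcast_to(spot_na_a, shape)
                + spec.coef(s, "spot_creat_mmol") * np.broadcast_to(creat_mmol, shape)
                + spec.coef(s, "bmi") * np.broadcast_to(bmi, shape)
                + spec.coef(s, "age") * np.broadcast_to(age, shape)
            )
            if spec.has(s, "spot_k"):
                val = val + spec.coef(s, "spot_k") * np.broadcast_to(spot_k_a, shape)
            if spec.has(s, "age2"):
                val = val + spec.coef(s, "age2") * np.broadcast_to(age, shape) ** 2
            out[mask] = val[mask]

    out_mg = out * molar_mass
    negative = out_mg < 0
    if np.any(negative):
        warnings.warn(
            f"{equation_id}: {int(negative.sum())} negative estimate(s) floored at 0",
            RuntimeWarning,
            stacklevel=2,
        )
        out_mg = np.where(negative, 0.0, out_mg)
    return float(out_mg.reshape(-1)[0]) if scalar else out_mg


def estimate_all_spot_equations(
    spot: UrineRecord, profile: ParticipantProfile
) -> dict[str, float]:
    """Evaluate every registry equation on one spot sample."""
    return {
        eq: estimate_spot_24h_na(eq, spot, profile) for eq in SPOT_EQUATION_IDS
    }
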