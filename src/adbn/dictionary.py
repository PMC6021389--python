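"""Data dictionary: typed feature specifications for heterogeneous cohorts.

The default dictionary describes the 33-feature analysis set used throughout
the pipeline: 2 demographics, 10 medical-history flags, 13 blood measures
(including the ApoE genotype), 4 psychological/functional assessments
(including the CDR severity target) and 4 imaging summaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import yaml

from .errors import FeatureLookupError, ValidationError

KINDS = ("continuous", "ordinal", "categorical")
DOMAIN_BLOCKS = (
    "demographics",
    "medical_history",
    "blood",
    "psychological",
    "imaging",
    "target",
)

#: Canonical CDR scores; mild (1) and moderate (2) are merged downstream.
CDR_SCORES = (0.0, 0.5, 1.0, 2.0, 3.0)

#: ApoE allele combinations, ordered by increasing epsilon-4 load.
APOE_GENOTYPES = ("e3e2", "e3e3", "e4e2", "e4e3", "e4e4")

DIAGNOSES = ("HC", "MCI", "AD")
VISITS = ("BL", "M18", "M36", "M54")


@dataclass(frozen=True)
class FeatureSpec:
    """Type and provenance of a single cohort feature."""

    name: str
    kind: str
    categories: tuple | None = None
    unit: str = ""
    domain_block: str = "blood"

    def __post_init__(self):
        if self.kind not in KINDS:
            raise ValidationError(f"{self.name}: unknown kind {self.kind!r}")
        if self.domain_block not in DOMAIN_BLOCKS:
            raise ValidationError(
                f"{self.name}: unknown domain_block {self.domain_block!r}"
            )
        if self.kind == "continuous":
            if self.categories is not None:
                raise ValidationError(
                    f"{self.name}: continuous features list no categories"
                )
        else:
            if self.categories is None or len(self.categories) < 2:
                raise ValidationError(
                    f"{self.name}: {self.kind} features need >=2 categories"
                )
        if self.categories is not None:
            object.__setattr__(self, "categories", tuple(self.categories))


def validate_dictionary(specs: list[FeatureSpec]) -> None:
    names = [s.name for s in specs]
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise ValidationError(f"duplicate feature names: {dupes}")


def feature_map(specs: list[FeatureSpec]) -> dict[str, FeatureSpec]:
    return {s.name: s for s in specs}


def lookup(specs: list[FeatureSpec], name: str) -> FeatureSpec:
    for s in specs:
        if s.name == name:
            return s
    raise FeatureLookupError(name)


def _flag(name: str) -> FeatureSpec:
    return FeatureSpec(name, "categorical", ("no", "yes"),
                       domain_block="medical_history")


def _blood(name: str, unit: str) -> FeatureSpec:
    return FeatureSpec(name, "continuous", unit=unit, domain_block="blood")


def default_dictionary() -> list[FeatureSpec]:
    """The 33-feature analysis dictionary (32 predictors + CDR target)."""
    specs = [
        FeatureSpec("age", "continuous", unit="years",
                    domain_block="demographics"),
        FeatureSpec("sex", "categorical", ("F", "M"),
                    domain_block="demographics"),
        _flag("hypertension"),
        _flag("diabetes"),
        _flag("hypercholesterolemia"),
        _flag("stroke"),
        _flag("depression"),
        _flag("head_injury"),
        _flag("smoking"),
        _flag("cardiovascular_disease"),
        _flag("thyroid_disorder"),
        _flag("neurological_disorder"),
        FeatureSpec("apoe", "categorical", APOE_GENOTYPES,
                    domain_block="blood"),
        _blood("hemoglobin", "g/L"),
        _blood("glucose", "mmol/L"),
        _blood("cholesterol_total", "mmol/L"),
        _blood("hdl", "mmol/L"),
        _blood("ldl", "mmol/L"),
        _blood("triglycerides", "mmol/L"),
        _blood("vitamin_b12", "pmol/L"),
        _blood("folate", "nmol/L"),
        _blood("creatinine", "umol/L"),
        _blood("urea", "mmol/L"),
        _blood("albumin", "g/L"),
        _blood("platelets", "10^9/L"),
        FeatureSpec("mmse", "continuous", unit="points",
                    domain_block="psychological"),
        FeatureSpec("lmir", "continuous", unit="points",
                    domain_block="psychological"),
        FeatureSpec("lmdr", "continuous", unit="points",
                    domain_block="psychological"),
        FeatureSpec("cdr", "ordinal", CDR_SCORES, unit="score",
                    domain_block="target"),
        FeatureSpec("gm_volume", "continuous", unit="mL",
                    domain_block="imaging"),
        FeatureSpec("wm_volume", "continuous", unit="mL",
                    domain_block="imaging"),
        FeatureSpec("csf_volume", "continuous", unit="mL",
                    domain_block="imaging"),
        FeatureSpec("pib_pet_voxels", "continuous", unit="voxels",
                    domain_block="imaging"),
    ]
    validate_dictionary(specs)
    return specs


def save_dictionary(specs: list[FeatureSpec], path) -> None:
    doc = {
        s.name: {
            "kind": s.kind,
            "categories": list(s.categories) if s.categories else None,
            "unit": s.unit,
            "domain_block": s.domain_block,
        }
        for s in specs
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def load_dictionary(path) -> list[FeatureSpec]:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    specs = [
        FeatureSpec(
            name,
            entry["kind"],
            tuple(entry["categories"]) if entry.get("categories") else None,
            entry.get("unit", ""),
            entry.get("domain_block", "blood"),
        )
        for name, entry in doc.items()
    ]
    validate_dictionary(specs)
    return specs
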