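"""Single-patient risk computation for the decision-support interface.

Takes the five key predictors (age, county hospital quality, distance to
county hospital, township health-center quality, Chinese communication),
validates their ranges, and returns the delay probability, a banded risk
level and the signed per-feature attributions that explain the prediction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np

from ieto_automl.automl import ModelBundle
from ieto_automl.explain import shap_attributions

__all__ = ["PatientInput", "RiskOutput", "predict_risk", "KEY_FEATURES", "RISK_BANDS"]

KEY_FEATURES = (
    "age",
    "county_quality",
    "dist_county",
    "township_quality",
    "chinese_communication",
)

# documented interface defaults; the banding is a convenience, not a clinical claim
RISK_BANDS = {"low": (0.0, 0.3), "moderate": (0.3, 0.6), "high": (0.6, 1.0)}

_RANGES = {
    "age": (25.0, 72.0),
    "county_quality": (0.0, 10.0),
    "dist_county": (0.0, float("inf")),
    "township_quality": (0.0, 10.0),
    "chinese_communication": (0, 1),
}


@dataclass(frozen=True)
class PatientInput:
    age: float
    county_quality: float
    dist_county: float
    township_quality: float
    chinese_communication: int

    def __post_init__(self) -> None:
        bad = []
        for name in KEY_FEATURES:
            lo, hi = _RANGES[name]
            v = getattr(self, name)
            if not lo <= v <= hi:
                bad.append(f"{name}={v} outside [{lo}, {hi}]")
        if self.chinese_communication not in (0, 1):
            bad.append("chinese_communication must be 0 or 1")
        if bad:
            raise ValueError("invalid patient input: " + "; ".join(bad))


@dataclass
class RiskOutput:
    probability: float
    risk_band: str
    attributions: dict[str, float]
    base_value: float

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


def _band(probability: float) -> str:
    for name, (lo, hi) in RISK_BANDS.items():
        if lo <= probability < hi or (name == "high" and probability == hi):
            return name
    return "high"


def predict_risk(
    patient: PatientInput,
    bundle: ModelBundle,
    allow_superset: bool = False,
) -> RiskOutput:
    """Risk probability, band and per-feature attributions for one patient.

    The bundle must be trained on exactly the five key features (in any
    order); with ``allow_superset=True`` a bundle trained on more features
    accepts the patient with schema-default zeros for the absent ones.
    """
    selected = bundle.selected_features
    extra = [f for f in selected if f not in KEY_FEATURES]
    if extra and not allow_superset:
        raise ValueError(
            f"bundle uses features beyond the key-feature schema: {extra}; "
            "pass allow_superset=True to accept with defaults"
        )
    missing = [f for f in KEY_FEATURES if f not in bundle.feature_names]
    if missing:
        raise ValueError(f"bundle does not know key features: {missing}")
    row = np.zeros(len(bundle.feature_names))
    for name in KEY_FEATURES:
        row[bundle.feature_names.index(name)] = getattr(patient, name)
    prob = float(bundle.predict_proba(row[None, :])[0])
    attr = shap_attributions(bundle, row[None, :])
    contribs = dict(zip(attr.feature_names, attr.values[0].astype(float)))
    return RiskOutput(
        probability=prob,
        risk_band=_band(prob),
        attributions=contribs,
        base_value=attr.base_value,
    )
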