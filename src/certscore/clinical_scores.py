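"""Companion clinical scores: HOMA-IR, metabolic syndrome, Framingham risk.

HOMA-IR is the homeostatic model assessment of insulin resistance,
``insulin [µIU/mL] × glucose [mmol/L] / 22.5``.  Metabolic syndrome is
classified by an IDF-derived rule: positive when three or more of five
factors are present (abdominal obesity; hypertriglyceridemia; reduced
HDL-C; hypertension; hyperglycemia/T2DM), each factor also satisfied by
its specific treatment.  Cardiovascular risk uses the 2008 Framingham
general-CVD sex-specific Cox model over age, total cholesterol, HDL-C,
systolic blood pressure (treated or not), smoking and diabetes; vascular
age is the age at which a person with every other risk factor at a normal
level would carry the same predicted 10-year risk.

The Framingham coefficients are shipped as a versioned data table
(``data/framingham_2008.csv``); an integrity checksum and hand-verified
oracle values guard against accidental edits.
"""

from __future__ import annotations

import hashlib
import math
import warnings
from dataclasses import dataclass
from importlib import resources
from typing import NamedTuple

import pandas as pd
from scipy.optimize import brentq

from certscore.core_model import Sex, SubjectRecord, convert_glucose

__all__ = [
    "MetSThresholds",
    "MetSResult",
    "FrsResult",
    "NormalProfile",
    "homa_ir",
    "classify_mets",
    "frs_2008",
    "vascular_age",
    "frs_result",
    "FRS_AGE_RANGE",
    "VA_AGE_BRACKET",
]

#: Validity range of the published Framingham model (years).
FRS_AGE_RANGE = (30.0, 74.0)

#: Age bracket searched when inverting the risk curve for vascular age.
#: It extends below the model's validity range on purpose: vascular ages
#: younger than 30 are routinely reported for low-risk subjects.
VA_AGE_BRACKET = (5.0, 130.0)

_COEF_SHA256 = "2a727f775e6ae9498b7e845c50e25fa966be8141119e407f193555c9b9ec224a"


def homa_ir(insulin: float, glucose: float) -> float:
    """HOMA-IR from fasting insulin (µIU/mL) and glucose (mg/dL).

    Glucose is converted to mmol/L with the exact molar factor before the
    standard formula ``insulin × glucose / 22.5`` is applied.
    """
    if insulin <= 0 or glucose <= 0:
        raise ValueError(
            f"insulin and glucose must be strictly positive, got {insulin}, {glucose}"
        )
    return insulin * convert_glucose(glucose) / 22.5


# ---------------------------------------------------------------------------
# Metabolic syndrome
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MetSThresholds:
    """Cut-offs of the metabolic-syndrome rule (IDF consensus defaults).

    Waist circumference uses the Europid sex-specific cut-offs; lipids and
    glucose are in mg/dL, pressures in mmHg.  ``rule`` selects between the
    plain ``any_three_of_five`` count and the canonical IDF variant in which
    abdominal obesity is mandatory plus at least two of the remaining four.
    """

    wc_female: float = 80.0
    wc_male: float = 94.0
    tg: float = 150.0
    hdl_female: float = 50.0
    hdl_male: float = 40.0
    sbp: float = 130.0
    dbp: float = 85.0
    glucose: float = 100.0
    rule: str = "any_three_of_five"  # or "idf_central_obesity_mandatory"


class MetSResult(NamedTuple):
    """Five factor flags, their count, and the overall classification."""

    abdominal_obesity: bool
    hypertriglyceridemia: bool
    reduced_hdl: bool
    hypertension: bool
    hyperglycemia: bool
    count: int
    positive: bool


def classify_mets(
    record: SubjectRecord,
    thresholds: MetSThresholds | None = None,
) -> MetSResult:
    """Evaluate the five metabolic-syndrome factors for one subject.

    Treatment of a previously diagnosed abnormality satisfies the
    corresponding criterion (hypertension via ``treated_htn``, hyperglycemia
    via ``diabetes``).  Missing required measurements raise ``ValueError``
    naming the field.
    """
    th = thresholds or MetSThresholds()
    record.require("wc", "tg", "hdl", "sbp", "dbp", "glucose")
    treated_htn = bool(record.treated_htn)
    diabetes = bool(record.diabetes)

    wc_cut = th.wc_female if record.sex is Sex.F else th.wc_male
    hdl_cut = th.hdl_female if record.sex is Sex.F else th.hdl_male

    abdominal = record.wc >= wc_cut
    hypertg = record.tg >= th.tg
    low_hdl = record.hdl < hdl_cut
    htn = record.sbp >= th.sbp or record.dbp >= th.dbp or treated_htn
    hyperglyc = record.glucose >= th.glucose or diabetes

    flags = (abdominal, hypertg, low_hdl, htn, hyperglyc)
    count = sum(flags)
    if th.rule == "any_three_of_five":
        positive = count >= 3
    elif th.rule == "idf_central_obesity_mandatory":
        positive = abdominal and sum(flags[1:]) >= 2
    else:
        raise ValueError(f"unknown metabolic-syndrome rule {th.rule!r}")
    return MetSResult(*flags, count=count, positive=positive)


# ---------------------------------------------------------------------------
# Framingham 2008 general CVD risk and vascular age
# ---------------------------------------------------------------------------

def _load_coefficients() -> dict[str, dict[str, float]]:
    with resources.files("certscore.data").joinpath("framingham_2008.csv").open("rb") as fh:
        raw = fh.read()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != _COEF_SHA256:
        raise RuntimeError(
            "framingham_2008.csv failed its integrity check "
            f"(sha256 {digest}); the coefficient table must not be edited"
        )
    df = pd.read_csv(pd.io.common.BytesIO(raw))
    return {
        sex: dict(zip(sub["term"], sub["value"]))
        for sex, sub in df.groupby("sex")
    }


_COEFS = _load_coefficients()


@dataclass(frozen=True)
class NormalProfile:
    """Risk-factor levels taken as 'normal' when computing vascular age."""

    tc: float = 160.0
    hdl: float = 50.0
    sbp: float = 110.0
    treated_htn: bool = False
    smoking: bool = False
    diabetes: bool = False


class FrsResult(NamedTuple):
    """10-year general-CVD risk (percent) and the matching vascular age."""

    risk10y: float
    vascular_age: float
    sex: Sex
    extrapolated: bool
    va_clamped: bool


def frs_2008(
    sex: Sex | str,
    age: float,
    tc: float,
    hdl: float,
    sbp: float,
    treated_htn: bool,
    smoking: bool,
    diabetes: bool,
    out_of_range: str = "flag",
) -> float:
    """Sex-specific 10-year general-CVD risk, in percent.

    The linear predictor sums the published Cox coefficients over log age,
    log total cholesterol, log HDL-C, log SBP (separate coefficient when on
    antihypertensive treatment), smoking and diabetes; risk is
    ``1 - S0(10) ** exp(lp - mean_lp)``.

    ``out_of_range`` controls ages outside the published validity range
    (30-74 years): ``"flag"`` emits a warning and extrapolates, ``"error"``
    raises, ``"silent"`` extrapolates quietly (used internally by the
    vascular-age inversion).
    """
    sex = Sex(sex)
    if min(age, tc, hdl, sbp) <= 0:
        raise ValueError("age, TC, HDL-C and SBP must be strictly positive")
    if not FRS_AGE_RANGE[0] <= age <= FRS_AGE_RANGE[1]:
        if out_of_range == "error":
            raise ValueError(f"age {age} outside model validity range {FRS_AGE_RANGE}")
        if out_of_range == "flag":
            warnings.warn(
                f"age {age} outside the published validity range {FRS_AGE_RANGE}; "
                "risk is extrapolated",
                stacklevel=2,
            )
    c = _COEFS[sex.value]
    lp = (
        c["ln_age"] * math.log(age)
        + c["ln_tc"] * math.log(tc)
        + c["ln_hdl"] * math.log(hdl)
        + (c["ln_sbp_treated"] if treated_htn else c["ln_sbp_untreated"]) * math.log(sbp)
        + c["smoker"] * float(bool(smoking))
        + c["diabetes"] * float(bool(diabetes))
    )
    risk = 1.0 - c["baseline_survival_10y"] ** math.exp(lp - c["mean_linear_predictor"])
    return 100.0 * risk


def _normal_risk(age: float, sex: Sex, profile: NormalProfile) -> float:
    return frs_2008(
        sex,
        age,
        profile.tc,
        profile.hdl,
        profile.sbp,
        profile.treated_htn,
        profile.smoking,
        profile.diabetes,
        out_of_range="silent",
    )


class VascularAge(NamedTuple):
    years: float
    clamped: bool


def vascular_age(
    risk10y: float,
    sex: Sex | str,
    profile: NormalProfile | None = None,
    tol: float = 0.1,
) -> VascularAge:
    """Invert the all-normal risk curve: the age with the same predicted risk.

    Solved by monotone root-finding on age over ``VA_AGE_BRACKET`` to within
    *tol* years.  Risks below or above the achievable range of the
    all-normal curve are clamped to the bracket end and flagged.
    """
    sex = Sex(sex)
    profile = profile or NormalProfile()
    lo, hi = VA_AGE_BRACKET
    r_lo, r_hi = _normal_risk(lo, sex, profile), _normal_risk(hi, sex, profile)
    if risk10y <= r_lo:
        return VascularAge(lo, clamped=True)
    if risk10y >= r_hi:
        return VascularAge(hi, clamped=True)
    age = brentq(lambda a: _normal_risk(a, sex, profile) - risk10y, lo, hi, xtol=tol / 2)
    return VascularAge(float(age), clamped=False)


def frs_result(
    record: SubjectRecord,
    profile: NormalProfile | None = None,
    out_of_range: str = "flag",
) -> FrsResult:
    """Framingham risk and vascular age for one subject record."""
    record.require("age", "tc", "hdl", "sbp")
    if record.smoking is None:
        raise ValueError(f"subject {record.id!r}: smoking status is missing")
    extrapolated = not FRS_AGE_RANGE[0] <= record.age <= FRS_AGE_RANGE[1]
    risk = frs_2008(
        record.sex,
        record.age,
        record.tc,
        record.hdl,
        record.sbp,
        bool(record.treated_htn),
        record.smoking,
        bool(record.diabetes),
        out_of_range=out_of_range,
    )
    va = vascular_age(risk, record.sex, profile)
    return FrsResult(
        risk10y=risk,
        vascular_age=va.years,
        sex=record.sex,
        extrapolated=extrapolated,
        va_clamped=va.clamped,
    )
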