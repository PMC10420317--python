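"""CERT1 ceramide risk scoring with quartile cut-offs.

The score has six components: the plasma concentrations of Cer 16:0,
Cer 18:0 and Cer 24:1, and the three ratios of each scored-or-not ceramide
to Cer 24:0 (Cer 16:0/24:0, Cer 18:0/24:0, Cer 24:1/24:0).  Cer 24:0 itself
contributes only as the ratio denominator.  Each component earns 0 points
below the reference median, +1 in the third quartile and +2 in the fourth,
so the total ranges 0-12 and maps onto four risk categories:
low (0-2), moderate (3-6), increased (7-9), high (10-12).

Quartile membership uses half-open intervals: values exactly at the 75th
percentile belong to the fourth quartile (+2), values exactly at the median
to the third (+1).  Reference cut-offs default to linear-interpolation
quantiles of the analyzed cohort itself, but an external
:class:`QuartileReference` table may be supplied to score new individuals
against a fixed population.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from pathlib import Path
import numpy as np
import pandas as pd

from certscore.core_model import CohortFrame, SubjectRecord

__all__ = [
    "SCORING_VARIABLES",
    "RATIO_VARIABLES",
    "RiskCategory",
    "RatioSet",
    "QuartileReference",
    "Cert1Result",
    "compute_ratios",
    "add_ratio_columns",
    "fit_quartile_reference",
    "subscore",
    "cert1_score",
    "score_cohort",
    "categorize",
]

#: The six scored variables, in reporting order.
SCORING_VARIABLES: tuple[str, ...] = (
    "cer16",
    "cer18",
    "cer241",
    "r16_240",
    "r18_240",
    "r241_240",
)

RATIO_VARIABLES: tuple[str, ...] = ("r16_240", "r18_240", "r241_240")

#: Minimum number of complete ceramide panels needed to fit a reference.
MIN_REFERENCE_N = 8


class RiskCategory(str, enum.Enum):
    LOW = "low"
    MODERATE = "moderate"
    INCREASED = "increased"
    HIGH = "high"


class ReferenceSource(str, enum.Enum):
    SELF_COHORT = "self_cohort"
    EXTERNAL_TABLE = "external_table"


@dataclass(frozen=True)
class RatioSet:
    """The three ceramide/Cer 24:0 ratios of one subject (dimensionless)."""

    r16_240: float
    r18_240: float
    r241_240: float


@dataclass
class QuartileReference:
    """Per-variable (q25, q50, q75) cut-offs defining the scoring reference.

    ``cutoffs`` maps each of the six scoring variables to its quartile
    triple, in the variable's units (µmol/L for concentrations,
    dimensionless for ratios).
    """

    cutoffs: dict[str, tuple[float, float, float]]
    source: ReferenceSource = ReferenceSource.SELF_COHORT

    def __post_init__(self) -> None:
        for name, (q25, q50, q75) in self.cutoffs.items():
            if not (q25 <= q50 <= q75):
                raise ValueError(
                    f"non-monotone quartiles for {name!r}: ({q25}, {q50}, {q75})"
                )

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        rows = [
            {"variable": name, "q25": q[0], "q50": q[1], "q75": q[2], "source": self.source.value}
            for name, q in self.cutoffs.items()
        ]
        pd.DataFrame(rows).to_csv(path, index=False)
        return path

    @classmethod
    def from_csv(cls, path: str | Path) -> "QuartileReference":
        df = pd.read_csv(path)
        cutoffs = {
            str(r.variable): (float(r.q25), float(r.q50), float(r.q75))
            for r in df.itertuples()
        }
        source = ReferenceSource(df["source"].iloc[0]) if "source" in df else ReferenceSource.EXTERNAL_TABLE
        return cls(cutoffs=cutoffs, source=source)


@dataclass(frozen=True)
class Cert1Result:
    """Per-component subscores, total CERT1 score, and risk category."""

    subscores: tuple[int, int, int, int, int, int]
    total: int
    category: RiskCategory

    def __post_init__(self) -> None:
        if sum(self.subscores) != self.total:
            raise ValueError("total must equal the sum of the six subscores")


def compute_ratios(record: SubjectRecord) -> RatioSet:
    """Exact ceramide/Cer 24:0 quotients for one subject, no rounding.

    Raises ``ValueError`` if any of the four ceramides is missing (Cer 24:0
    positivity is enforced by the record itself).
    """
    record.require("cer16", "cer18", "cer241", "cer240")
    return RatioSet(
        r16_240=record.cer16 / record.cer240,
        r18_240=record.cer18 / record.cer240,
        r241_240=record.cer241 / record.cer240,
    )


def add_ratio_columns(df: pd.DataFrame) -> pd.DataFrame:
    """Return a copy of a cohort dataframe with the three ratio columns added."""
    out = df.copy()
    out["r16_240"] = out["cer16"] / out["cer240"]
    out["r18_240"] = out["cer18"] / out["cer240"]
    out["r241_240"] = out["cer241"] / out["cer240"]
    return out


def fit_quartile_reference(
    cohort: CohortFrame | pd.DataFrame,
    interpolation: str = "linear",
) -> QuartileReference:
    """Fit Q25/Q50/Q75 cut-offs for the six scoring variables on a pooled cohort.

    Quantiles use linear interpolation between order statistics by default
    (``interpolation`` accepts any numpy quantile ``method``).  At least
    eight subjects with complete ceramide panels are required.
    """
    df = cohort.to_dataframe() if isinstance(cohort, CohortFrame) else cohort
    panel = df[["cer16", "cer18", "cer241", "cer240"]].dropna()
    if len(panel) < MIN_REFERENCE_N:
        raise ValueError(
            f"insufficient data: {len(panel)} complete ceramide panels, "
            f"need at least {MIN_REFERENCE_N}"
        )
    scored = add_ratio_columns(panel)
    cutoffs = {}
    for name in SCORING_VARIABLES:
        q25, q50, q75 = np.quantile(scored[name].to_numpy(), [0.25, 0.5, 0.75], method=interpolation)
        cutoffs[name] = (float(q25), float(q50), float(q75))
    return QuartileReference(cutoffs=cutoffs, source=ReferenceSource.SELF_COHORT)


def subscore(value: float, cutoffs: tuple[float, float, float]) -> int:
    """Quartile-membership points for one variable: 0, +1 or +2.

    Below the median scores 0; the third quartile ``[q50, q75)`` scores +1;
    the fourth quartile ``[q75, inf)`` scores +2.
    """
    q25, q50, q75 = cutoffs
    if not (q25 <= q50 <= q75):
        raise ValueError(f"non-monotone cutoffs: ({q25}, {q50}, {q75})")
    if value >= q75:
        return 2
    if value >= q50:
        return 1
    return 0


def categorize(total: int) -> RiskCategory:
    """Map a total CERT1 score onto its risk category."""
    if not 0 <= total <= 12:
        raise ValueError(f"CERT1 total must lie in [0, 12], got {total}")
    if total <= 2:
        return RiskCategory.LOW
    if total <= 6:
        return RiskCategory.MODERATE
    if total <= 9:
        return RiskCategory.INCREASED
    return RiskCategory.HIGH


def cert1_score(record: SubjectRecord, reference: QuartileReference) -> Cert1Result:
    """Score one subject against a quartile reference.

    The six subscores follow the order of :data:`SCORING_VARIABLES`.
    """
    missing = set(SCORING_VARIABLES) - set(reference.cutoffs)
    if missing:
        raise ValueError(f"reference lacks cutoffs for: {sorted(missing)}")
    ratios = compute_ratios(record)
    values = {
        "cer16": record.cer16,
        "cer18": record.cer18,
        "cer241": record.cer241,
        "r16_240": ratios.r16_240,
        "r18_240": ratios.r18_240,
        "r241_240": ratios.r241_240,
    }
    subs = tuple(subscore(values[name], reference.cutoffs[name]) for name in SCORING_VARIABLES)
    total = int(sum(subs))
    return Cert1Result(subscores=subs, total=total, category=categorize(total))


def score_cohort(
    cohort: CohortFrame | pd.DataFrame,
    reference: QuartileReference | None = None,
) -> pd.DataFrame:
    """Score every subject of a cohort; vectorized.

    When *reference* is ``None`` the cut-offs are fit on the cohort itself
    (the default for a self-contained study analysis).  Returns a dataframe
    indexed like the cohort with the ratio columns, one ``score_<var>``
    column per component, ``cert1`` and ``category``.
    """
    df = cohort.to_dataframe() if isinstance(cohort, CohortFrame) else cohort.copy()
    if reference is None:
        reference = fit_quartile_reference(df)
    scored = add_ratio_columns(df)
    total = np.zeros(len(scored), dtype=int)
    for name in SCORING_VARIABLES:
        _, q50, q75 = reference.cutoffs[name]
        v = scored[name].to_numpy(dtype=float)
        pts = (v >= q50).astype(int) + (v >= q75).astype(int)
        scored[f"score_{name}"] = pts
        total += pts
    scored["cert1"] = total
    scored["category"] = [categorize(int(t)).value for t in total]
    return scored
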