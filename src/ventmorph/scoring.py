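"""mFI-11 frailty scoring and the MCID responder rule.

The modified Frailty Index-11 assigns one binary point per comorbidity; the
cumulative score (0-11) stratifies subjects into low (0-2) and high (>= 3)
frailty.  Responders to external lumbar drainage are subjects whose best
inpatient-domain improvement (gait, balance or cognition) reaches the minimal
clinically important difference of 10% *and* whose patient/caregiver-reported
functional improvement reaches 20%; both thresholds are inclusive.
"""
from __future__ import annotations

from dataclasses import dataclass, fields
from typing import Mapping

import pandas as pd

from .errors import VentmorphError

#: the canonical 11 items, in a fixed order
MFI11_ITEMS: tuple[str, ...] = (
    "diabetes_mellitus",
    "congestive_heart_failure",
    "hypertension",
    "myocardial_infarction",
    "pci_cardiac_surgery_angina",
    "peripheral_vascular_disease",
    "respiratory_disease",
    "impaired_sensorium",
    "tia_cva",
    "cva_with_deficit",
    "adl_dependent",
)

LOW_STRATUM = "0-2"
HIGH_STRATUM = ">=3"
RESPONDER = "Responder"
NON_RESPONDER = "Non-Responder"


@dataclass(frozen=True)
class ComorbidityRecord:
    """One subject's 11 binary mFI-11 items."""

    diabetes_mellitus: bool
    congestive_heart_failure: bool
    hypertension: bool
    myocardial_infarction: bool
    pci_cardiac_surgery_angina: bool
    peripheral_vascular_disease: bool
    respiratory_disease: bool
    impaired_sensorium: bool
    tia_cva: bool
    cva_with_deficit: bool
    adl_dependent: bool

    def as_dict(self) -> dict[str, bool]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def mfi11_score(record: ComorbidityRecord | Mapping, *, frailty_cut: int = 3) -> tuple[int, str]:
    """Cumulative mFI-11 score and frailty stratum.

    Every item must be present and boolean; missing items raise rather than
    being imputed.
    """
    items = record.as_dict() if isinstance(record, ComorbidityRecord) else dict(record)
    score = 0
    for name in MFI11_ITEMS:
        if name not in items or items[name] is None or (
            isinstance(items[name], float) and pd.isna(items[name])
        ):
            raise VentmorphError(f"mFI-11 item {name!r} is missing; no imputation is performed")
        score += int(bool(items[name]))
    return score, (LOW_STRATUM if score < frailty_cut else HIGH_STRATUM)


@dataclass(frozen=True)
class OutcomeScores:
    """Percent improvements; missing inpatient domains are allowed (None)."""

    gait: float | None = None
    balance: float | None = None
    cognitive: float | None = None
    functional: float | None = None


def classify_responder(
    scores: OutcomeScores,
    *,
    inpatient_threshold: float = 10.0,
    functional_threshold: float = 20.0,
) -> str:
    """MCID rule: >=10% in any inpatient domain AND >=20% functional improvement."""
    inpatient = [v for v in (scores.gait, scores.balance, scores.cognitive) if v is not None and not pd.isna(v)]
    if not inpatient:
        raise VentmorphError("no inpatient domain (gait/balance/cognitive) available")
    if scores.functional is None or pd.isna(scores.functional):
        raise VentmorphError("functional improvement report is missing")
    ok = max(inpatient) >= inpatient_threshold and scores.functional >= functional_threshold
    return RESPONDER if ok else NON_RESPONDER


def score_cohort(df: pd.DataFrame, *, frailty_cut: int = 3) -> pd.DataFrame:
    """Add mfi11_score/mfi11_stratum (and responder, when outcomes exist) columns."""
    out = df.copy()
    scores, strata = [], []
    for _, row in out.iterrows():
        s, st = mfi11_score({k: row[k] for k in MFI11_ITEMS if k in row.index}, frailty_cut=frailty_cut)
        scores.append(s)
        strata.append(st)
    out["mfi11_score"] = scores
    out["mfi11_stratum"] = strata
    outcome_cols = {"gait_improvement_pct", "functional_improvement_pct"}
    if outcome_cols <= set(out.columns):
        out["responder_classified"] = [
            classify_responder(
                OutcomeScores(
                    gait=row.get("gait_improvement_pct"),
                    balance=row.get("balance_improvement_pct"),
                    cognitive=row.get("cognitive_improvement_pct"),
                    functional=row.get("functional_improvement_pct"),
                )
            )
            for _, row in out.iterrows()
        ]
    return out
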