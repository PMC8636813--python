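"""Simulated cohorts drawn from published group-level distributions.

The patient-level imaging data behind the published group comparisons are not
deposited, so cohorts are *simulated* from the printed per-group means and
SDs: each subject's measures are drawn from a truncated multivariate normal
whose marginal moments are the published values, with an exchangeable
inter-measure correlation (default 0.5) and, for paired designs, a
within-subject pre/post correlation (default 0.9).  Comorbidities are
independent Bernoulli draws at the published prevalences.  Everything is
seed-deterministic.

Truncation keeps ratio indices in (0, 1), angles in (0, 180) degrees and
positive quantities positive by resampling invalid rows; at the published
parameter values the bounds sit several SDs from the means, so the induced
moment bias is negligible (documented in the methods note).
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ParameterInconsistencyError, VentmorphError
from .scoring import MFI11_ITEMS, NON_RESPONDER, RESPONDER
from .stats import mann_whitney

#: valid ranges per measure (open intervals)
MEASURE_BOUNDS: dict[str, tuple[float, float]] = {
    "ei": (0.0, 1.0),
    "bci": (0.0, 1.0),
    "z_evans": (0.0, 1.0),
    "ca_deg": (0.0, 180.0),
    "bvr_ac": (0.0, np.inf),
    "bvr_pc": (0.0, np.inf),
    "bvr_pc_brain_mm": (0.0, np.inf),
    "bvr_pc_ventricle_mm": (0.0, np.inf),
    "ventricular_volume_cm3": (0.0, np.inf),
}

CROSS_SECTIONAL = "cross_sectional"
LONGITUDINAL = "longitudinal"
SUBTYPE = "subtype"


@dataclass(frozen=True)
class CohortParams:
    """Registry of every published mean/SD/count used as generative defaults."""

    groups: dict
    longitudinal: dict
    comorbidity_counts: dict
    cohort_n: int
    responder_n: int
    classic_n: int
    rho_prepost: float
    rho_measures: float
    notes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not (0.0 <= self.rho_prepost < 1.0) or not (0.0 <= self.rho_measures < 1.0):
            raise VentmorphError("correlations must lie in [0, 1)")
        for name, count in self.comorbidity_counts.items():
            if not 0 <= count <= self.cohort_n:
                raise VentmorphError(f"comorbidity count {name}={count} outside [0, n]")
        for gname, g in self.groups.items():
            if g["n"] < 1:
                raise VentmorphError(f"group {gname} has size < 1")
            for m, (mean, sd) in g["measures"].items():
                if sd <= 0:
                    raise VentmorphError(f"SD must be positive for {gname}/{m}")

    # -- lookups ------------------------------------------------------------
    def lookup(self, group: str, measure: str, timepoint: str | None = None) -> tuple[float, float]:
        """(mean, SD) for a (group, measure[, timepoint]) key."""
        if timepoint is None:
            return tuple(self.groups[group]["measures"][measure])
        return tuple(self.longitudinal[group][timepoint][measure])

    @property
    def comorbidity_prevalence(self) -> dict[str, float]:
        return {k: v / self.cohort_n for k, v in self.comorbidity_counts.items()}

    @property
    def responder_fraction(self) -> float:
        return self.responder_n / self.cohort_n

    @classmethod
    def from_json(cls, path: str | Path) -> "CohortParams":
        payload = json.loads(Path(path).read_text())
        return cls._from_payload(payload)

    @classmethod
    def _from_payload(cls, payload: dict) -> "CohortParams":
        return cls(
            groups=payload["groups"],
            longitudinal=payload["longitudinal"],
            comorbidity_counts=payload["comorbidity_counts"],
            cohort_n=payload["cohort_n"],
            responder_n=payload["responder_n"],
            classic_n=payload["classic_n"],
            rho_prepost=payload["rho_prepost"],
            rho_measures=payload["rho_measures"],
            notes=tuple(payload.get("notes", ())),
        )


def default_published_params() -> CohortParams:
    """Load the checked-in registry of published parameters."""
    with resources.files("ventmorph.data").joinpath("published_params.json").open() as fh:
        return CohortParams._from_payload(json.load(fh))


# ---------------------------------------------------------------------------
# truncated multivariate sampling
# ---------------------------------------------------------------------------


def _exchangeable_corr(k: int, rho: float) -> np.ndarray:
    return (1 - rho) * np.eye(k) + rho * np.ones((k, k))


def truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, bounds: tuple[float, float], n: int
) -> np.ndarray:
    """Resample-until-valid scalar truncated normal draws."""
    return _truncated_mvn(rng, np.array([mean]), np.array([[sd**2]]), [bounds], n)[:, 0]


def _truncated_mvn(
    rng: np.random.Generator,
    mean: np.ndarray,
    cov: np.ndarray,
    bounds: list[tuple[float, float]],
    n: int,
    *,
    max_factor: int = 40,
) -> np.ndarray:
    """Multivariate normal rows resampled until every coordinate is in bounds.

    Signals parameter inconsistency when any single measure's marginal
    rejection rate exceeds 50%.
    """
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    chol = np.linalg.cholesky(cov + 1e-12 * np.eye(len(mean)))
    out = np.empty((n, len(mean)))
    filled = 0
    drawn = np.zeros(len(mean))
    rejected = np.zeros(len(mean))
    attempts = 0
    while filled < n:
        attempts += 1
        if attempts > max_factor:
            raise ParameterInconsistencyError("truncation rejected too many draws; check parameters")
        block = mean + rng.standard_normal((n, len(mean))) @ chol.T
        bad = (block <= lo) | (block >= hi)
        drawn += n
        rejected += bad.sum(axis=0)
        if np.any(rejected / drawn > 0.5) and drawn.max() >= 2 * n:
            raise ParameterInconsistencyError(
                "a measure's truncation rejection rate exceeds 50%: parameters inconsistent with bounds"
            )
        good = block[~bad.any(axis=1)]
        take = min(n - filled, good.shape[0])
        out[filled : filled + take] = good[:take]
        filled += take
    return out


def _assign_labels(rng: np.random.Generator, n: int, n_positive: int, positive: str, negative: str) -> np.ndarray:
    labels = np.array([positive] * n_positive + [negative] * (n - n_positive), dtype=object)
    return rng.permutation(labels)


def _sample_comorbidities(rng: np.random.Generator, prevalence: dict[str, float], n: int) -> pd.DataFrame:
    data = {item: rng.random(n) < prevalence.get(item, 0.0) for item in MFI11_ITEMS}
    return pd.DataFrame(data)


def _sample_outcomes(rng: np.random.Generator, responder: np.ndarray) -> pd.DataFrame:
    """Improvement percentages consistent with each subject's responder label.

    Draws avoid the exact 10%/20% MCID boundaries so the label is recoverable
    without ambiguity.
    """
    n = len(responder)
    gait = np.empty(n)
    balance = np.empty(n)
    cognitive = np.empty(n)
    functional = np.empty(n)
    for i, status in enumerate(responder):
        if status == RESPONDER:
            gait[i] = rng.uniform(10.5, 40.0)
            balance[i] = rng.uniform(-5.0, 25.0)
            cognitive[i] = rng.uniform(-5.0, 25.0)
            functional[i] = rng.uniform(20.5, 60.0)
        elif rng.random() < 0.5:  # fails the inpatient criterion
            gait[i] = rng.uniform(-10.0, 9.5)
            balance[i] = rng.uniform(-10.0, 9.5)
            cognitive[i] = rng.uniform(-10.0, 9.5)
            functional[i] = rng.uniform(-10.0, 60.0)
        else:  # fails the functional criterion
            gait[i] = rng.uniform(10.5, 40.0)
            balance[i] = rng.uniform(-10.0, 9.5)
            cognitive[i] = rng.uniform(-10.0, 9.5)
            functional[i] = rng.uniform(-10.0, 19.5)
    return pd.DataFrame(
        {
            "gait_improvement_pct": gait,
            "balance_improvement_pct": balance,
            "cognitive_improvement_pct": cognitive,
            "functional_improvement_pct": functional,
        }
    )


# ---------------------------------------------------------------------------
# cohort simulation
# ---------------------------------------------------------------------------


def simulate_cohort(
    params: CohortParams | None = None,
    *,
    design: str = CROSS_SECTIONAL,
    seed: int | None = None,
    truncate: bool = True,
) -> pd.DataFrame:
    """Simulate one cohort table (one row per subject x timepoint).

    Designs: ``cross_sectional`` (NPH/AD/HC at baseline), ``subtype``
    (Classic vs Complex at baseline), ``longitudinal`` (responder groups with
    paired pre/post rows, outcome scores and comorbidities).
    """
    params = params or default_published_params()
    rng = np.random.default_rng(seed)
    if design == CROSS_SECTIONAL:
        frames = [
            _simulate_baseline_group(rng, params, g, truncate)
            for g in ("NPH", "AD", "HC")
            if g in params.groups
        ]
    elif design == SUBTYPE:
        frames = [
            _simulate_baseline_group(rng, params, g, truncate)
            for g in ("NPH-Classic", "NPH-Complex")
            if g in params.groups
        ]
    elif design == LONGITUDINAL:
        frames = [
            _simulate_longitudinal_group(rng, params, g, truncate)
            for g in (RESPONDER, NON_RESPONDER)
            if g in params.longitudinal
        ]
    else:
        raise VentmorphError(f"unknown design {design!r}")
    df = pd.concat(frames, ignore_index=True)
    df.insert(0, "subject_id", [f"sub-{i:03d}" for i in _subject_numbers(df)])
    return df


def _subject_numbers(df: pd.DataFrame) -> np.ndarray:
    codes, _ = pd.factorize(df.pop("_subject_key"))
    return codes


def _simulate_baseline_group(
    rng: np.random.Generator, params: CohortParams, group: str, truncate: bool
) -> pd.DataFrame:
    g = params.groups[group]
    n = g["n"]
    measures = list(g["measures"])
    means = np.array([g["measures"][m][0] for m in measures])
    sds = np.array([g["measures"][m][1] for m in measures])
    corr = _exchangeable_corr(len(measures), params.rho_measures)
    cov = corr * np.outer(sds, sds)
    if truncate:
        bounds = [MEASURE_BOUNDS[m] for m in measures]
    else:
        bounds = [(-np.inf, np.inf)] * len(measures)
    draws = _truncated_mvn(rng, means, cov, bounds, n)
    df = pd.DataFrame(draws, columns=measures)
    df.insert(0, "timepoint", "baseline")
    df.insert(0, "group", group)
    is_nph = group.startswith("NPH")
    if is_nph:
        df = pd.concat([df, _sample_comorbidities(rng, params.comorbidity_prevalence, n)], axis=1)
        if group == "NPH":
            n_resp = round(n * params.responder_fraction)
            n_classic = round(n * params.classic_n / params.cohort_n)
            df["responder"] = _assign_labels(rng, n, n_resp, RESPONDER, NON_RESPONDER)
            df["subtype"] = _assign_labels(rng, n, n_classic, "Classic", "Complex")
    df["_subject_key"] = [f"{group}-{i}" for i in range(n)]
    return df


def _simulate_longitudinal_group(
    rng: np.random.Generator, params: CohortParams, group: str, truncate: bool
) -> pd.DataFrame:
    spec = params.longitudinal[group]
    n = spec["n"]
    measures = list(spec["pre"])
    k = len(measures)
    means = np.array([spec[tp][m][0] for tp in ("pre", "post") for m in measures])
    sds = np.array([spec[tp][m][1] for tp in ("pre", "post") for m in measures])
    corr = np.kron(_exchangeable_corr(2, params.rho_prepost), _exchangeable_corr(k, params.rho_measures))
    np.fill_diagonal(corr, 1.0)
    cov = corr * np.outer(sds, sds)
    if truncate:
        bounds = [MEASURE_BOUNDS[m] for _ in ("pre", "post") for m in measures]
    else:
        bounds = [(-np.inf, np.inf)] * (2 * k)
    draws = _truncated_mvn(rng, means, cov, bounds, n)
    comorb = _sample_comorbidities(rng, params.comorbidity_prevalence, n)
    outcomes = _sample_outcomes(rng, np.array([group] * n, dtype=object))
    rows = []
    for tp_i, tp in enumerate(("pre", "post")):
        block = pd.DataFrame(draws[:, tp_i * k : (tp_i + 1) * k], columns=measures)
        block.insert(0, "timepoint", tp)
        block.insert(0, "group", group)
        block["responder"] = group
        block = pd.concat([block, comorb.copy(), outcomes.copy()], axis=1)
        block["_subject_key"] = [f"{group}-{i}" for i in range(n)]
        rows.append(block)
    return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# headline contrast replication
# ---------------------------------------------------------------------------


def replicate_group_contrast(
    measure: str,
    group_a: str = "NPH",
    group_b: str = "AD",
    *,
    n_per_group: int = 21,
    n_replicates: int = 200,
    seed: int = 0,
    params: CohortParams | None = None,
) -> np.ndarray:
    """Two-sided Mann-Whitney p-values over seeded replicate cohorts.

    Each replicate draws ``n_per_group`` subjects per group from the
    registry's truncated normal for ``measure`` and tests the group contrast;
    the array of replicate p-values is returned.
    """
    params = params or default_published_params()
    mean_a, sd_a = params.lookup(group_a, measure)
    mean_b, sd_b = params.lookup(group_b, measure)
    bounds = MEASURE_BOUNDS[measure]
    pvals = np.empty(n_replicates)
    for i, child in enumerate(np.random.SeedSequence(seed).spawn(n_replicates)):
        rng = np.random.default_rng(child)
        a = truncated_normal(rng, mean_a, sd_a, bounds, n_per_group)
        b = truncated_normal(rng, mean_b, sd_b, bounds, n_per_group)
        pvals[i] = mann_whitney(a, b).pvalue
    return pvals
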