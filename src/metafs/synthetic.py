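"""Synthetic dialysis-like data for end-to-end testing of the pipeline.

The motivating clinical dataset — tens of thousands of hemodialysis
sessions with a ~71/29 split between sessions without and with
intradialytic hypotension (IDH), and 87 expanded features — is not public.
This module generates stand-ins with the same *structure* so every pipeline
stage can be exercised and verified:

- :func:`generate_feature_table` builds a processed feature matrix with an
  exactly controlled class imbalance, a planted subset of class-informative
  Gaussian columns among pure-noise columns, and optional one-hot-expanded
  categorical columns.  The ground-truth informative indices are returned
  so feature-recovery can be measured.
- :func:`generate_sessions` builds raw hourly systolic-blood-pressure (SBP)
  session records plus an irregular laboratory table, with patient
  covariates shifting the probability of a pressure drop.
- :func:`label_hypotension` applies the clinical labeling rule: IDH is
  present when the lowest SBP of Hours 2-4 is at least 20 mmHg below the
  highest SBP of Hours 0-1, and the drop magnitude (HYM) is that
  difference.
- :func:`join_nearest_prior` attaches to each session the same patient's
  most recent lab panel drawn on or before the session date.

Trajectories are drawn as noisy level curves, not a physiological model;
what passing tests show is that the pipeline recovers planted structure,
not that it would perform identically on real hemodynamics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SBP_HOURS = ["sbp_h0", "sbp_h1", "sbp_h2", "sbp_h3", "sbp_h4"]
IDH_DROP_MMHG = 20.0  # inclusive threshold


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of an emulated processed IDH feature table.

    Defaults echo the clinical dataset's shape: 68,574 sessions, minority
    fraction 0.2889, and 68 numeric + 3 categorical variables whose one-hot
    expansion (cardinalities 7, 6, 6) yields 87 columns.  The cardinalities
    of the real categorical variables are not published; these are a
    documented choice, not an assertion.
    """

    n_samples: int = 68574
    minority_fraction: float = 0.2889
    n_informative: int = 10
    n_noise: int = 58
    n_categorical: int = 3
    categorical_cardinalities: tuple[int, ...] = (7, 6, 6)
    effect_size: float = 1.0  # standardized class-mean separation
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.minority_fraction < 1.0):
            raise ValueError("minority_fraction must lie in (0, 1)")
        if self.n_samples < 2 or self.n_informative < 0 or self.n_noise < 0:
            raise ValueError("invalid sizes")
        if len(self.categorical_cardinalities) != self.n_categorical:
            raise ValueError("one cardinality per categorical column")
        if any(c < 2 for c in self.categorical_cardinalities):
            raise ValueError("categorical cardinalities must be >= 2")

    @property
    def n_expanded(self) -> int:
        return (self.n_informative + self.n_noise
                + sum(self.categorical_cardinalities))


def generate_feature_table(spec: SyntheticSpec):
    """Planted-signal feature table.

    Returns ``(X, y, informative_idx)`` where ``X`` is a DataFrame of the
    one-hot-expanded features, ``y`` the binary labels (minority class 1,
    exactly ``round(n * minority_fraction)`` of them), and
    ``informative_idx`` the column positions of the informative features.
    Informative columns are unit-variance Gaussians whose class means
    differ by ``effect_size``; noise and categorical columns are
    independent of the label.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_samples
    n_min = int(round(n * spec.minority_fraction))
    y = np.zeros(n, dtype=int)
    y[rng.choice(n, size=n_min, replace=False)] = 1

    cols: dict[str, np.ndarray] = {}
    for j in range(spec.n_informative):
        cols[f"inf_{j}"] = rng.normal(size=n) + spec.effect_size * y
    for j in range(spec.n_noise):
        cols[f"noise_{j}"] = rng.normal(size=n)
    for j, card in enumerate(spec.categorical_cardinalities):
        levels = rng.integers(0, card, size=n)
        for lvl in range(card):
            cols[f"cat_{j}_lvl{lvl}"] = (levels == lvl).astype(float)
    X = pd.DataFrame(cols)
    informative_idx = np.arange(spec.n_informative)
    return X, y, informative_idx


def label_hypotension(sbp_by_hour):
    """Apply the IDH labeling rule to one session's hourly SBP values.

    ``sbp_by_hour`` holds SBP (mmHg) at Hours 0-4.  The label is 1 iff
    ``min(Hours 2-4) <= max(Hours 0-1) - 20`` (the 20 mmHg threshold is
    inclusive), in which case HYM is that maximal drop; otherwise the label
    is 0 and HYM is None.  Sessions with a missing hour return
    ``(None, None)`` and are excluded downstream.
    """
    sbp = np.asarray(sbp_by_hour, dtype=float)
    if sbp.shape != (5,):
        raise ValueError("expected SBP values for Hours 0-4")
    if not np.all(np.isfinite(sbp)) or np.any(sbp <= 0):
        return None, None
    early_max = sbp[:2].max()
    late_min = sbp[2:].min()
    drop = early_max - late_min
    if drop >= IDH_DROP_MMHG:
        return 1, float(drop)
    return 0, None


def join_nearest_prior(sessions: pd.DataFrame, labs: pd.DataFrame) -> pd.DataFrame:
    """Attach each session's latest same-or-prior lab panel.

    Lab draws are irregular and not aligned to sessions, so each session
    receives the analyte values of the same patient's most recent lab with
    ``draw_date <= session_date``; sessions with no prior lab carry NaN
    analytes.  Duplicate same-day labs resolve to the latest by stable
    input order.
    """
    sessions = sessions.copy()
    labs = labs.drop(columns=["session_date"], errors="ignore").copy()
    sessions["session_date"] = pd.to_datetime(sessions["session_date"])
    labs["draw_date"] = pd.to_datetime(labs["draw_date"])
    ndup = int(labs.duplicated(["patient_id", "draw_date"]).sum())
    if ndup:
        warnings.warn(f"{ndup} duplicate same-day labs; keeping the latest "
                      "by input order", stacklevel=2)
    sessions["_order"] = np.arange(len(sessions))
    merged = pd.merge_asof(
        sessions.sort_values("session_date", kind="stable"),
        labs.sort_values("draw_date", kind="stable"),
        left_on="session_date",
        right_on="draw_date",
        by="patient_id",
        direction="backward",
        allow_exact_matches=True,
    )
    merged = merged.sort_values("_order").drop(columns="_order")
    return merged.reset_index(drop=True)


@dataclass(frozen=True)
class PropensityModel:
    """Logistic drop-propensity model on standardized patient covariates.

    The intercept is calibrated by bisection so the mean propensity over
    the drawn cohort matches ``target_prevalence``.
    """

    coefficients: dict = field(default_factory=lambda: {
        "age": 0.4, "diabetic": 0.5, "baseline_sbp": -0.3})
    target_prevalence: float = 0.289


def _calibrate_intercept(logits: np.ndarray, target: float) -> float:
    if target <= 0.0:
        return -np.inf
    if target >= 1.0:
        return np.inf
    lo, hi = -30.0, 30.0
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if np.mean(1.0 / (1.0 + np.exp(-(logits + mid)))) < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def generate_sessions(
    n_patients: int,
    sessions_per_patient: int,
    propensity: PropensityModel | None = None,
    seed: int = 0,
):
    """Raw session + lab tables with a planted, recoverable drop signal.

    Returns ``(sessions, labs)`` DataFrames.  Each patient carries
    covariates (age, diabetic and hypertensive flags, baseline SBP) that
    shift their per-session probability of an IDH pressure drop through the
    propensity model.  Trajectories are constructed so the drop indicator
    and the labeling rule coincide exactly: non-drop sessions never fall
    more than 15 mmHg below their early maximum, drop sessions reach
    exactly ``20 + Exp(8)`` mmHg below it.  ``idh_label`` and ``hym`` are
    always recomputed through :func:`label_hypotension`.
    """
    if n_patients < 1 or sessions_per_patient < 1:
        raise ValueError("counts must be positive")
    propensity = propensity or PropensityModel()
    rng = np.random.default_rng(seed)

    age = rng.normal(65.0, 12.0, n_patients)
    diabetic = rng.random(n_patients) < 0.4
    hypertensive = rng.random(n_patients) < 0.5
    baseline = rng.normal(135.0, 15.0, n_patients)
    cov = {"age": age, "diabetic": diabetic.astype(float),
           "hypertensive": hypertensive.astype(float),
           "baseline_sbp": baseline}

    logits = np.zeros(n_patients)
    for name, beta in propensity.coefficients.items():
        v = cov[name]
        sd = v.std()
        z = (v - v.mean()) / sd if sd > 0 else np.zeros_like(v)
        logits += beta * z
    b0 = _calibrate_intercept(logits, propensity.target_prevalence)
    with np.errstate(over="ignore"):
        p_drop = 1.0 / (1.0 + np.exp(-(logits + b0)))
    p_drop = np.nan_to_num(p_drop, nan=0.0)

    start = pd.Timestamp("2016-01-04")
    rows = []
    for i in range(n_patients):
        for s in range(sessions_per_patient):
            date = start + pd.Timedelta(days=int(3 * s + rng.integers(0, 2)))
            early = baseline[i] + rng.normal(0.0, 5.0, 2)
            early_max = early.max()
            if rng.random() < p_drop[i]:
                drop = IDH_DROP_MMHG + rng.exponential(8.0)
                late = early_max - drop * np.array([0.6, 1.0, 0.8]) \
                    - rng.uniform(0.0, 3.0, 3) * np.array([1.0, 0.0, 1.0])
                late[1] = early_max - drop  # nadir fixed at the full drop
            else:
                late = early_max - rng.uniform(-5.0, 15.0, 3)
                late = np.maximum(late, early_max - 15.0)
            sbp = np.concatenate([early, late])
            label, hym = label_hypotension(sbp)
            rows.append({
                "patient_id": i,
                "session_date": date,
                "age": age[i],
                "diabetic": int(diabetic[i]),
                "hypertensive": int(hypertensive[i]),
                **dict(zip(SBP_HOURS, sbp)),
                "idh_label": label,
                "hym": hym,
            })
    sessions = pd.DataFrame(rows)

    lab_rows = []
    for i in range(n_patients):
        day = -rng.integers(0, 20)
        horizon = 3 * sessions_per_patient + 10
        while day < horizon:
            lab_rows.append({
                "patient_id": i,
                "draw_date": start + pd.Timedelta(days=int(day)),
                "creatinine": 6.0 + 0.02 * (age[i] - 65.0) + rng.normal(0, 1.0),
                "albumin": 3.8 - 0.3 * diabetic[i] + rng.normal(0, 0.3),
                "hemoglobin": 11.0 + rng.normal(0, 1.2),
            })
            day += int(rng.integers(20, 41))
    labs = pd.DataFrame(lab_rows)
    return sessions, labs
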