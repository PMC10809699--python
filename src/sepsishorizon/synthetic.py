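"""Seeded synthetic ICU cohorts with the statistical structure the pipeline assumes.

Real sepsis cohorts live in credentialed databases, so the package ships a
generator that emulates the features the preprocessing and models rely on:

* irregular per-variable sampling — vitals on a minutes scale, labs on an
  hours scale, with exponentially jittered inter-observation gaps;
* AR(1) within-patient physiologic noise (so forward-fill imputation is a
  sensible estimator);
* a pre-onset signature: on a configurable subset of variables, sepsis
  patients drift linearly by a chosen number of baseline SDs over a lead
  window that ends at the diagnosis anchor;
* a control arm with no drift and a seeded synthetic anchor (>= 24 h after
  admission) so windows can be cut identically for both arms;
* whole channels missing at random, as in real extracts.

Everything is reproducible from ``CohortParams.seed``; per-patient streams are
spawned from a single SeedSequence so results do not depend on generation
order.  The injected signature variables are the ground truth that the
Shapley-ranking recovery tests check against.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .io import EventTable, PATIENT_COLUMNS

__all__ = [
    "VariableSpec", "SignatureSpec", "CohortParams",
    "default_variables", "default_signatures",
    "generate_cohort", "cohort_ground_truth",
]


@dataclass(frozen=True)
class VariableSpec:
    """Baseline behaviour of one clinical variable."""
    name: str
    baseline_mean: float
    baseline_sd: float
    sampling_interval_min: float  # mean gap between observations


@dataclass(frozen=True)
class SignatureSpec:
    """A pre-onset drift on one variable: `amplitude` baseline SDs,
    ramped linearly over the `lead_hours` ending at the onset anchor."""
    variable: str
    direction: str = "up"  # up | down
    amplitude: float = 2.0
    lead_hours: float = 14.0

    def __post_init__(self):
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if self.lead_hours <= 0:
            raise ValueError("lead_hours must be > 0")
        if self.direction not in ("up", "down"):
            raise ValueError("direction must be 'up' or 'down'")


def default_variables() -> list[VariableSpec]:
    """A 10-variable ICU panel: five vitals sampled on a minutes scale and
    five labs sampled on an hours scale (values in conventional units).

    Lab intervals (4-6 h) reflect an active sepsis-watch panel; they must sit
    comfortably below the signature lead time, or a pre-onset drift is simply
    never sampled on those channels for a large fraction of patients."""
    return [
        VariableSpec("heart_rate", 85.0, 12.0, 15.0),
        VariableSpec("respiration", 17.0, 3.0, 15.0),
        VariableSpec("sao2", 96.5, 2.0, 15.0),
        VariableSpec("map", 85.0, 11.0, 30.0),
        VariableSpec("temperature", 36.9, 0.5, 60.0),
        VariableSpec("wbc", 9.0, 3.0, 240.0),
        VariableSpec("lactate", 1.6, 0.8, 240.0),
        VariableSpec("platelets", 240.0, 70.0, 360.0),
        VariableSpec("bnp", 180.0, 90.0, 360.0),
        VariableSpec("ast", 38.0, 16.0, 360.0),
    ]


def default_signatures(amplitude: float = 2.0, lead_hours: float = 14.0) -> list[SignatureSpec]:
    """Signatures on the channels clinically tied to incipient sepsis:
    rising heart rate, respiration, BNP, AST and platelets; falling SaO2."""
    return [
        SignatureSpec("heart_rate", "up", amplitude, lead_hours),
        SignatureSpec("respiration", "up", amplitude, lead_hours),
        SignatureSpec("sao2", "down", amplitude, lead_hours),
        SignatureSpec("bnp", "up", amplitude, lead_hours),
        SignatureSpec("ast", "up", amplitude, lead_hours),
        SignatureSpec("platelets", "up", amplitude, lead_hours),
    ]


@dataclass
class CohortParams:
    """Generator settings.  Defaults give a balanced cohort with a 2-SD,
    14-hour pre-onset drift on six of ten channels."""
    n_patients: int = 200
    prevalence: float = 0.5
    variables: list[VariableSpec] = field(default_factory=default_variables)
    signatures: list[SignatureSpec] = field(default_factory=default_signatures)
    missing_channel_prob: float = 0.10
    min_stay_hours: float = 48.0
    mean_extra_stay_hours: float = 36.0
    ar_rho: float = 0.9
    seed: int = 0

    def __post_init__(self):
        if self.n_patients < 2:
            raise ValueError("n_patients must be >= 2")
        if not (0.0 < self.prevalence < 1.0):
            raise ValueError("prevalence must be in (0, 1)")
        if not (0.0 <= self.missing_channel_prob < 1.0):
            raise ValueError("missing_channel_prob must be in [0, 1)")
        if not (0.0 <= self.ar_rho < 1.0):
            raise ValueError("ar_rho must be in [0, 1)")
        if self.prevalence * self.n_patients < 1:
            raise ValueError("prevalence * n_patients < 1: no positive class")
        if self.prevalence > 0 and not self.signatures:
            raise ValueError("at least one signature required when prevalence > 0")
        names = {v.name for v in self.variables}
        for s in self.signatures:
            if s.variable not in names:
                raise ValueError(f"signature variable {s.variable!r} not in panel")


def cohort_ground_truth(params: CohortParams) -> list[str]:
    """The informative (signature) variable names — the oracle for
    attribution-recovery tests.  Independent of seed."""
    seen: list[str] = []
    for s in params.signatures:
        if s.variable not in seen:
            seen.append(s.variable)
    return seen


def _drift(times_min: np.ndarray, anchor_min: float, sig: SignatureSpec,
           baseline_sd: float) -> np.ndarray:
    lead_min = sig.lead_hours * 60.0
    ramp = np.clip((times_min - (anchor_min - lead_min)) / lead_min, 0.0, 1.0)
    sign = 1.0 if sig.direction == "up" else -1.0
    return sign * sig.amplitude * baseline_sd * ramp


def generate_cohort(params: CohortParams) -> tuple[pd.DataFrame, EventTable]:
    """Generate (patient table, event table) for one synthetic cohort.

    The sepsis arm gets an onset anchor well inside the stay and the
    signature drifts ending at it; controls get a seeded uniform anchor in
    [24 h, discharge] and no drift.  Exactly round(n * prevalence) patients
    (at least one) are sepsis cases, chosen by seeded permutation.
    """
    master = np.random.SeedSequence(params.seed)
    label_rng = np.random.default_rng(master.spawn(1)[0])
    n = params.n_patients
    n_sepsis = max(1, int(round(params.prevalence * n)))
    sepsis_idx = set(label_rng.permutation(n)[:n_sepsis].tolist())
    children = np.random.SeedSequence(params.seed + 1).spawn(n)

    width = max(4, len(str(n)))
    pat_rows = []
    ev_pid, ev_off, ev_var, ev_val = [], [], [], []

    for i in range(n):
        rng = np.random.default_rng(children[i])
        pid = f"p{i:0{width}d}"
        is_sepsis = i in sepsis_idx
        age = float(np.clip(rng.normal(65.0, 16.0), 18.0, 100.0))
        stay_h = params.min_stay_hours + rng.exponential(params.mean_extra_stay_hours)
        discharge = int(round(stay_h * 60.0))

        # Anchor far enough in for a 12 h horizon plus the drift lead, and at
        # least 4 h before discharge.  Controls draw from the SAME distribution
        # as cases (>= 24 h after admission): matched anchors keep window
        # length uninformative about the label, so classifiers can only use
        # the physiologic signal.
        lo = min(30 * 60, max(discharge // 2, 13 * 60))
        hi = max(lo + 1, discharge - 4 * 60)
        anchor = int(rng.integers(lo, hi))

        sig_by_var = ({s.variable: s for s in params.signatures} if is_sepsis else {})

        for var in params.variables:
            if params.missing_channel_prob > 0 and rng.random() < params.missing_channel_prob:
                continue  # whole channel absent for this patient
            # exponentially jittered observation times
            est = int(discharge / var.sampling_interval_min) + 8
            gaps = rng.exponential(var.sampling_interval_min, size=2 * est + 4)
            times = np.cumsum(np.concatenate(
                [[rng.uniform(0, var.sampling_interval_min)], gaps]))
            times = times[times <= discharge]
            while times.size and times[-1] < discharge - 4 * var.sampling_interval_min:
                more = np.cumsum(rng.exponential(var.sampling_interval_min, size=est)) + times[-1]
                times = np.concatenate([times, more[more <= discharge]])
                if more[-1] > discharge:
                    break
            if times.size == 0:
                times = np.array([rng.uniform(0, min(var.sampling_interval_min, discharge))])
            times = np.unique(np.round(times).astype(np.int64))
            times = times[(times >= 0) & (times <= discharge)]
            k = times.size
            if k == 0:
                continue

            # stationary AR(1) noise in event index
            eps = rng.normal(0.0, 1.0, size=k)
            s = np.empty(k)
            s[0] = eps[0]
            c = np.sqrt(1.0 - params.ar_rho ** 2)
            for j in range(1, k):
                s[j] = params.ar_rho * s[j - 1] + c * eps[j]
            values = var.baseline_mean + var.baseline_sd * s
            if var.name in sig_by_var:
                values = values + _drift(times.astype(float), float(anchor),
                                         sig_by_var[var.name], var.baseline_sd)

            ev_pid.append(np.full(k, pid))
            ev_off.append(times)
            ev_var.append(np.full(k, var.name))
            ev_val.append(values)

        pat_rows.append((pid, round(age, 1), "sepsis" if is_sepsis else "control",
                         anchor, discharge))

    patients = pd.DataFrame(pat_rows, columns=PATIENT_COLUMNS)
    if ev_pid:
        events = pd.DataFrame({
            "patient_id": np.concatenate(ev_pid),
            "offset_min": np.concatenate(ev_off),
            "variable": np.concatenate(ev_var),
            "value": np.concatenate(ev_val),
        })
    else:
        events = pd.DataFrame(columns=["patient_id", "offset_min", "variable", "value"])
    return patients, EventTable(events)
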