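"""Synthetic cohort and session-trace generator.

The study data this package analyses (55 participants x 7 VR
exposure-therapy sessions, with per-second heart rate and head-pose
velocity plus per-session summaries and FSQ pre/post scores) are not
publicly deposited, so this module generates cohorts with the statistical
structure the analysis assumes:

* per-second session traces whose innovations follow an AR(p) mean model
  with GARCH(1,1) conditional variance, preceded by a 120-s pre-exposure
  baseline segment at resting levels (so controller baselining is
  exercisable);
* participants x sessions summary tables (time-on-task, head-movement
  variability, heart rate) drawn around configurable per-session targets
  that default to the study's printed session means;
* FSQ pre/post scores by severity stratum (defaults 18/24/13 participants
  in the high / moderate / low-moderate bands) with a configurable
  pre-post correlation;
* post-session questionnaire (PSQ) response tables under calm / anxious /
  random respondent profiles.

Everything is driven by numpy Generator seeding: a fixed seed gives
bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SESSION_TARGETS",
    "FSQ_STRATA_DEFAULT",
    "TraceGenParams",
    "CohortConfig",
    "CohortDataset",
    "generate_garch_innovations",
    "generate_session_trace",
    "generate_cohort",
    "generate_psq_responses",
    "write_trace_csv",
    "read_trace_csv",
]

# Per-session target means/SDs for the three summary signals
# (time-on-task s, head movement deg/s, heart rate bpm), sessions 1..7.
SESSION_TARGETS = pd.DataFrame(
    {
        "session": [1, 2, 3, 4, 5, 6, 7],
        "time_mean": [56.56, 62.53, 68.33, 74.19, 80.05, 88.27, 97.331],
        "time_sd": [3.68, 2.83, 3.44, 3.77, 4.26, 6.58, 10.32],
        "hmv_mean": [171.47, 164.28, 158.04, 153.03, 145.98, 140.74, 135.93],
        "hmv_sd": [5.67, 6.36, 6.03, 5.91, 6.28, 6.91, 6.14],
        "hr_mean": [118.31, 110.33, 105.05, 99.80, 94.86, 90.6, 86.62],
        "hr_sd": [6.83, 6.94, 6.95, 7.54, 9.26, 9.400, 9.26],
    }
).set_index("session")

# (label, count, pre_mean, pre_sd, post_mean, post_sd) by FSQ severity band.
FSQ_STRATA_DEFAULT = [
    ("high", 18, 88.2, 4.5, 54.7, 6.2),
    ("moderate", 24, 67.8, 6.9, 46.2, 7.8),
    ("low_moderate", 13, 44.2, 3.2, 34.9, 4.1),
]

BASELINE_S = 120  # pre-exposure resting segment length
DEFAULT_DURATION_S = 600  # exposure block length (no value is reported; see docs)

TRACE_COLUMNS = ["t_s", "hr_bpm", "head_vel_dps", "scene", "difficulty"]


@dataclass
class TraceGenParams:
    """Parameters for one synthetic session trace.

    ``ar_coeffs`` are the mean-model AR coefficients; ``garch_delta``,
    ``garch_beta``, ``garch_gamma`` parametrise the innovation variance
    recursion sigma2_t = delta + beta*tau2_{t-1} + gamma*sigma2_{t-1}.
    ``innovations`` selects the shock distribution: "gaussian" (default),
    "t" (scaled Student-t with ``t_df`` d.f., unit variance) for
    leptokurtosis experiments, or "zero" for the degenerate noiseless case.
    """

    session_index: int = 1
    duration_s: int = DEFAULT_DURATION_S
    sample_hz: float = 1.0
    hr_mean_bpm: float = 118.31
    hmv_mean_dps: float = 171.47
    ar_coeffs: tuple = (0.5,)
    garch_delta: float = 0.4
    garch_beta: float = 0.15
    garch_gamma: float = 0.75
    seed: int = 0
    stationary: bool = True
    innovations: str = "gaussian"
    t_df: float = 6.0
    rest_hr_bpm: float = 72.0
    rest_hmv_scale: float = 0.3  # resting head velocity as a fraction of exposure mean

    def __post_init__(self):
        if self.duration_s <= 0 or self.sample_hz <= 0:
            raise ValueError("duration_s and sample_hz must be positive")
        if self.duration_s * self.sample_hz < 60:
            raise ValueError("duration too short: need >= 60 samples for baselining")
        if not 1 <= self.session_index <= 7:
            raise ValueError("session_index must be in 1..7")
        if self.garch_delta <= 0 or self.garch_beta < 0 or self.garch_gamma < 0:
            raise ValueError("require delta > 0 and beta, gamma >= 0")
        if self.stationary and self.garch_beta + self.garch_gamma >= 1:
            raise ValueError(
                "non-stationary GARCH parameters (beta + gamma >= 1) with "
                "stationary=True; set stationary=False to allow this"
            )
        if self.innovations not in {"gaussian", "t", "zero"}:
            raise ValueError(f"unknown innovation kind {self.innovations!r}")

    @classmethod
    def for_session(cls, session_index: int, seed: int = 0, **overrides) -> "TraceGenParams":
        """Defaults calibrated to the printed per-session cohort means."""
        row = SESSION_TARGETS.loc[session_index]
        kw = dict(
            session_index=session_index,
            hr_mean_bpm=float(row["hr_mean"]),
            hmv_mean_dps=float(row["hmv_mean"]),
            seed=seed,
        )
        kw.update(overrides)
        return cls(**kw)


def generate_garch_innovations(
    n: int,
    delta: float,
    beta: float,
    gamma: float,
    rng: np.random.Generator,
    innovations: str = "gaussian",
    t_df: float = 6.0,
) -> np.ndarray:
    """Simulate GARCH(1,1) innovations tau_t = sigma_t * eps_t.

    The variance recursion starts at the unconditional variance
    delta/(1-beta-gamma) when persistence < 1, else at delta.
    """
    if innovations == "zero":
        return np.zeros(n)
    if innovations == "gaussian":
        eps = rng.standard_normal(n)
    else:  # scaled t with unit variance
        if t_df <= 2:
            raise ValueError("t_df must exceed 2 for unit-variance scaling")
        eps = rng.standard_t(t_df, size=n) * np.sqrt((t_df - 2) / t_df)
    pers = beta + gamma
    sigma2 = delta / (1.0 - pers) if pers < 1 else delta
    tau = np.empty(n)
    for t in range(n):
        tau[t] = np.sqrt(sigma2) * eps[t]
        sigma2 = delta + beta * tau[t] ** 2 + gamma * sigma2
    return tau


def _ar_filter(tau: np.ndarray, coeffs) -> np.ndarray:
    """Apply the AR recursion to innovations, deviations starting at zero."""
    from scipy.signal import lfilter

    a = np.concatenate([[1.0], -np.asarray(coeffs, dtype=float)])
    return lfilter([1.0], a, tau)


def generate_session_trace(params: TraceGenParams) -> pd.DataFrame:
    """Generate one per-second session trace.

    Columns ``t_s, hr_bpm, head_vel_dps, scene, difficulty``; the first
    120 s carry scene ``baseline`` at resting levels, the remainder scene
    ``exposure`` with AR+GARCH-structured deviations around the session
    means.  Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(params.seed)
    hz = params.sample_hz
    n_base = int(round(BASELINE_S * hz))
    n_expo = int(round(params.duration_s * hz))

    # resting baseline: small iid wobble so baselining statistics are finite
    base_hr = params.rest_hr_bpm + 1.5 * rng.standard_normal(n_base)
    rest_hmv = params.rest_hmv_scale * params.hmv_mean_dps
    base_hmv = rest_hmv + 0.05 * rest_hmv * rng.standard_normal(n_base)

    def block(mean):
        tau = generate_garch_innovations(
            n_expo,
            params.garch_delta,
            params.garch_beta,
            params.garch_gamma,
            rng,
            innovations=params.innovations,
            t_df=params.t_df,
        )
        return mean + _ar_filter(tau, params.ar_coeffs)

    expo_hr = block(params.hr_mean_bpm)
    expo_hmv = block(params.hmv_mean_dps)

    n = n_base + n_expo
    t = np.arange(n) / hz
    return pd.DataFrame(
        {
            "t_s": t,
            "hr_bpm": np.concatenate([base_hr, expo_hr]),
            "head_vel_dps": np.concatenate([base_hmv, expo_hmv]),
            "scene": ["baseline"] * n_base + ["exposure"] * n_expo,
            "difficulty": 1,
        }
    )


@dataclass
class CohortConfig:
    """Cohort-level generation settings.

    ``session_mean_targets`` defaults to the printed per-session means/SDs;
    ``fsq_strata`` to the printed 18/24/13 severity split.  ``pre_post_rho``
    is the within-participant FSQ pre/post correlation (the printed paired
    t-statistics imply roughly 0.92).  ``participant_share`` is the fraction
    of each summary SD attributed to a stable participant intercept.
    ``session_trend`` flips the direction of the session-mean trajectories
    if set to "reversed" (the printed time-on-task table increases across
    sessions while the abstract reports a reduction; the default follows
    the printed table).
    """

    n_participants: int = 55
    n_sessions: int = 7
    session_mean_targets: pd.DataFrame = field(
        default_factory=lambda: SESSION_TARGETS.copy()
    )
    fsq_strata: list = field(default_factory=lambda: list(FSQ_STRATA_DEFAULT))
    seed: int = 0
    pre_post_rho: float = 0.92
    participant_share: float = 0.6
    session_trend: str = "printed"

    def __post_init__(self):
        counts = sum(c for _, c, *_ in self.fsq_strata)
        if counts != self.n_participants:
            raise ValueError(
                f"stratum counts sum to {counts}, not n_participants={self.n_participants}"
            )
        for label, _, pre_m, pre_sd, post_m, post_sd in self.fsq_strata:
            if pre_sd <= 0 or post_sd <= 0:
                raise ValueError(f"stratum {label!r} has non-positive SD")
        if not 1 <= self.n_sessions <= len(self.session_mean_targets):
            raise ValueError("n_sessions outside configured target table")
        if self.session_trend not in {"printed", "reversed"}:
            raise ValueError("session_trend must be 'printed' or 'reversed'")


@dataclass
class CohortDataset:
    """Participants x sessions summaries plus FSQ pre/post and raw PSQ items."""

    sessions: pd.DataFrame  # participant, session, time_s, hmv_dps, hr_bpm
    fsq: pd.DataFrame  # participant, stratum, fsq_pre, fsq_post
    psq: pd.DataFrame  # raw 15-item responses, one row per participant

    def session_series(self, signal: str, session: int) -> np.ndarray:
        """The cohort's per-participant values for one signal and session."""
        col = {"time": "time_s", "hmv": "hmv_dps", "hr": "hr_bpm"}[signal]
        sub = self.sessions[self.sessions["session"] == session]
        return sub.sort_values("participant")[col].to_numpy()


def generate_cohort(config: CohortConfig) -> CohortDataset:
    """Generate the cohort summary tables; reproducible by seed."""
    rng = np.random.default_rng(config.seed)
    n = config.n_participants
    targets = config.session_mean_targets.iloc[: config.n_sessions]
    if config.session_trend == "reversed":
        targets = targets.copy()
        for c in ("time_mean", "hmv_mean", "hr_mean"):
            targets[c] = targets[c].to_numpy()[::-1]

    a = config.participant_share
    b = float(np.sqrt(max(0.0, 1.0 - a**2)))
    u = rng.standard_normal((n, 3))  # stable participant intercepts per signal

    rows = []
    for s_idx, (session, row) in enumerate(targets.iterrows()):
        z = rng.standard_normal((n, 3))
        vals = {}
        for j, sig in enumerate(("time", "hmv", "hr")):
            mean, sd = row[f"{sig}_mean"], row[f"{sig}_sd"]
            vals[sig] = mean + sd * (a * u[:, j] + b * z[:, j])
        for i in range(n):
            rows.append(
                {
                    "participant": i + 1,
                    "session": int(session),
                    "time_s": vals["time"][i],
                    "hmv_dps": vals["hmv"][i],
                    "hr_bpm": vals["hr"][i],
                }
            )
    sessions = pd.DataFrame(rows)

    fsq_rows = []
    pid = 1
    for label, count, pre_m, pre_sd, post_m, post_sd in config.fsq_strata:
        zp = rng.standard_normal(count)
        zq = rng.standard_normal(count)
        rho = config.pre_post_rho
        pre = pre_m + pre_sd * zp
        post = post_m + post_sd * (rho * zp + np.sqrt(1 - rho**2) * zq)
        for k in range(count):
            fsq_rows.append(
                {
                    "participant": pid,
                    "stratum": label,
                    "fsq_pre": pre[k],
                    "fsq_post": post[k],
                }
            )
            pid += 1
    fsq = pd.DataFrame(fsq_rows)

    psq = generate_psq_responses(n, "random", seed=int(rng.integers(2**31)))
    psq.insert(0, "participant", np.arange(1, n + 1))
    return CohortDataset(sessions=sessions, fsq=fsq, psq=psq)


PSQ_LIKERT_ITEMS = [
    "AV1", "AV2", "AV3", "C1", "C2", "C3",
    "P1", "P2", "P3", "T1", "T2", "T3", "R1",
]
PSQ_COLUMNS = ["A1", "A2", *PSQ_LIKERT_ITEMS, "AE"]

_PSQ_PROFILES = {
    # (A-center, AV-center, C-center, P-center, T1/T3-center, T2-center,
    #  R1-center, AE probability)
    "calm": (10.0, 1.5, 6.5, 6.0, 6.5, 1.5, 6.0, 0.01),
    "anxious": (80.0, 6.0, 2.0, 5.0, 3.0, 4.5, 2.5, 0.15),
}


def generate_psq_responses(n: int, profile: str, seed: int = 0) -> pd.DataFrame:
    """Generate 15-item PSQ response tables.

    A1/A2 are 0-100 anxiety ratings; the remaining items are 1-7 Likert
    (T2 higher = worse) and AE is a binary adverse-event flag.
    """
    if profile not in {"calm", "anxious", "random"}:
        raise ValueError(f"unknown profile {profile!r}")
    if n < 0:
        raise ValueError("n must be non-negative")
    rng = np.random.default_rng(seed)
    if n == 0:
        return pd.DataFrame(columns=PSQ_COLUMNS)

    if profile == "random":
        data = {
            "A1": rng.integers(0, 101, n),
            "A2": rng.integers(0, 101, n),
            **{it: rng.integers(1, 8, n) for it in PSQ_LIKERT_ITEMS},
            "AE": rng.integers(0, 2, n),
        }
        return pd.DataFrame(data)[PSQ_COLUMNS]

    a_c, av_c, c_c, p_c, t_c, t2_c, r_c, ae_p = _PSQ_PROFILES[profile]

    def likert(center):
        return np.clip(np.rint(center + rng.normal(0, 0.7, n)), 1, 7).astype(int)

    data = {
        "A1": np.clip(np.rint(a_c + rng.normal(0, 8, n)), 0, 100).astype(int),
        "A2": np.clip(np.rint(a_c + 10 + rng.normal(0, 8, n)), 0, 100).astype(int),
        "AV1": likert(av_c), "AV2": likert(av_c), "AV3": likert(av_c),
        "C1": likert(c_c), "C2": likert(c_c), "C3": likert(c_c),
        "P1": likert(p_c), "P2": likert(p_c), "P3": likert(p_c),
        "T1": likert(t_c), "T2": likert(t2_c), "T3": likert(t_c),
        "R1": likert(r_c),
        "AE": (rng.random(n) < ae_p).astype(int),
    }
    return pd.DataFrame(data)[PSQ_COLUMNS]


def write_trace_csv(trace: pd.DataFrame, path) -> None:
    trace.to_csv(path, index=False)


def read_trace_csv(path) -> pd.DataFrame:
    trace = pd.read_csv(path)
    missing = set(TRACE_COLUMNS) - set(trace.columns)
    if missing:
        raise ValueError(f"trace file missing columns {sorted(missing)}")
    return trace
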