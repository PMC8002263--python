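"""Synthetic beat-annotated RR cohorts with a controllable NSR/CHF contrast.

Each subject's tachogram is a first-order autoregressive Gaussian process
around a class-specific mean RR with stationary standard deviation SDNN.
The CHF-like class encodes the clinical signature of heart failure —
shorter mean RR (faster resting rate) and strongly reduced beat-to-beat
variability — while the NSR-like class is slower and more variable, and an
AF-like class is highly irregular with almost no autocorrelation.  Ectopic
beats (annotated non-'N') and long pauses (> 2 s) are injected at small
per-beat rates so the preprocessing filters have work to do.

The generator emulates first and second moments and lag-1 autocorrelation
only; it makes no claim of physiological realism beyond that.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .preprocessing import BeatAnnotatedRR, CohortLabel

ECTOPIC_CODE = "V"
MIN_RR_SECONDS = 0.2


@dataclass(frozen=True)
class SubjectProfile:
    """Distributional parameters of one simulated subject class."""

    cohort_label: CohortLabel
    mean_rr: float  # seconds
    sdnn: float  # stationary beat-to-beat standard deviation, seconds
    ar_coefficient: float  # lag-1 autocorrelation, in [0, 1)
    ectopic_rate: float = 0.01  # per-beat probability of a non-'N' annotation
    pause_rate: float = 0.005  # per-beat probability of a > 2 s pause

    def __post_init__(self) -> None:
        if self.mean_rr <= 0 or self.sdnn < 0:
            raise ValueError("mean_rr must be positive and sdnn non-negative")
        if not 0.0 <= self.ar_coefficient < 1.0:
            raise ValueError("ar_coefficient must lie in [0, 1)")
        for rate in (self.ectopic_rate, self.pause_rate):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("rates must lie in [0, 1]")


DEFAULT_PROFILES: dict[CohortLabel, SubjectProfile] = {
    CohortLabel.NSR: SubjectProfile(CohortLabel.NSR, 0.9, 0.06, 0.9),
    CohortLabel.CHF: SubjectProfile(CohortLabel.CHF, 0.65, 0.015, 0.3),
    CohortLabel.AF: SubjectProfile(CohortLabel.AF, 0.75, 0.12, 0.05),
}


@dataclass(frozen=True)
class CohortConfig:
    """Cohort composition: subjects per class, beats per subject, master seed."""

    subjects_per_class: dict[CohortLabel, int] = field(
        default_factory=lambda: {CohortLabel.NSR: 10, CohortLabel.CHF: 10}
    )
    beats_per_subject: int = 1500
    seed: int = 0
    profiles: dict[CohortLabel, SubjectProfile] = field(
        default_factory=lambda: dict(DEFAULT_PROFILES)
    )

    def __post_init__(self) -> None:
        if self.beats_per_subject < 1:
            raise ValueError("beats_per_subject must be ≥ 1")
        if any(c < 0 for c in self.subjects_per_class.values()):
            raise ValueError("subject counts must be non-negative")


def generate_subject(
    profile: SubjectProfile, n_beats: int, seed: int, subject_id: str | None = None
) -> BeatAnnotatedRR:
    """Simulate one subject's beat-annotated tachogram.

    The RR series is AR(1): x_t = μ + φ(x_{t-1} − μ) + ε_t with
    ε_t ~ N(0, σ²(1 − φ²)) so the stationary standard deviation is exactly
    ``sdnn``; values are clipped below at 0.2 s.  Ectopic annotations and
    uniform (2, 3] s pauses are then injected at the profile rates.  Fully
    determined by ``seed``.
    """
    if n_beats < 1:
        raise ValueError("n_beats must be ≥ 1")
    rng = np.random.default_rng(seed)
    phi = profile.ar_coefficient
    innov_sd = profile.sdnn * np.sqrt(1.0 - phi ** 2)
    noise = rng.normal(0.0, 1.0, n_beats)
    x = np.empty(n_beats)
    x[0] = profile.mean_rr + profile.sdnn * noise[0]
    for t in range(1, n_beats):
        x[t] = profile.mean_rr + phi * (x[t - 1] - profile.mean_rr) \
            + innov_sd * noise[t]
    x = np.clip(x, MIN_RR_SECONDS, None)
    ectopic = rng.random(n_beats) < profile.ectopic_rate
    pause = rng.random(n_beats) < profile.pause_rate
    x[pause] = 2.0 + rng.random(int(pause.sum()))  # uniform in (2, 3]
    annotations = np.where(ectopic, ECTOPIC_CODE, "N")
    sid = subject_id or f"{profile.cohort_label.value.lower()}-{seed}"
    return BeatAnnotatedRR(
        subject_id=sid,
        cohort_label=profile.cohort_label,
        intervals=tuple(np.round(x, 6)),
        annotations=tuple(annotations),
    )


def generate_cohort(cfg: CohortConfig | None = None) -> list[BeatAnnotatedRR]:
    """Simulate a full cohort with unique ids and per-subject derived seeds."""
    cfg = cfg or CohortConfig()
    root = np.random.SeedSequence(cfg.seed)
    cohort: list[BeatAnnotatedRR] = []
    classes = sorted(cfg.subjects_per_class, key=lambda c: c.value)
    child_seeds = root.spawn(sum(cfg.subjects_per_class[c] for c in classes))
    idx = 0
    for label in classes:
        profile = cfg.profiles[label]
        for s in range(cfg.subjects_per_class[label]):
            seed = int(child_seeds[idx].generate_state(1)[0] % (2 ** 31))
            cohort.append(
                generate_subject(
                    profile,
                    cfg.beats_per_subject,
                    seed,
                    subject_id=f"{label.value.lower()}-{s:03d}",
                )
            )
            idx += 1
    return cohort
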