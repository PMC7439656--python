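"""Synthetic survey and outcome data emulating the study conditions.

Three generators make every other module testable without any download:

* :func:`gen_interval_survey` — interval/representative-point elicitations
  for one stratum, from a :class:`StratumProfile` of per-level perception
  centers (doctor and patient default profiles ship with the package);
* :func:`gen_qualitative_survey` — the inverse mapping: a uniform value in
  1-99 and a label chosen with probability decaying in the distance between
  the value and each level's center;
* :func:`gen_outcome_dataset` — a PROM-style regression table of 336 rows
  and 15 features (gender, age, intervention type, 3 continuous scores,
  9 ordinal items) whose ordinal labels discretise latent 0-100 severities
  through *non-uniformly spaced* cutpoints, while the target depends on the
  latent values.  Equally-spaced rank encoding is therefore misspecified
  exactly when the cutpoints are non-uniform.

All generators are pure functions of their parameters and the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .scale import OrdinalScale, SEVERITY
from .survey_io import IntervalResponse, QualitativeResponse
from .mlbench import FeatureTable


def _round_half_up(x: float) -> int:
    return int(math.floor(float(x) + 0.5))


def _clip_grid(x: float) -> int:
    return int(min(100, max(0, _round_half_up(x))))


@dataclass
class StratumProfile:
    """Generative profile of one stratum's perception of the scale levels.

    ``level_centers`` are the stratum's mean perceived locations (0-100, in
    scale order, non-decreasing); respondents scatter around them with sd
    ``center_sd``.  Interval half-widths are |Normal(half_width_mean,
    half_width_sd)| and representative points jitter around the respondent's
    center with sd ``rp_jitter_sd``.
    """

    stratum: str
    level_centers: dict[str, float]
    center_sd: float = 8.0
    half_width_mean: float = 10.0
    half_width_sd: float = 4.0
    rp_jitter_sd: float = 5.0

    def __post_init__(self) -> None:
        centers = list(self.level_centers.values())
        if any(b < a for a, b in zip(centers, centers[1:])):
            raise ValueError("level_centers must be non-decreasing in scale order")
        if not (self.center_sd >= 0 and self.half_width_mean > 0):
            raise ValueError("center_sd must be >= 0 and half_width_mean > 0")
        if self.half_width_sd < 0 or self.rp_jitter_sd < 0:
            raise ValueError("spread parameters must be >= 0")


# Default profiles emulating the two strata of the elicitation study:
# doctors place the extreme levels further out than laypeople do (who
# compress the upper half of the scale).  Centers are inspired by the
# reported per-level confidence bands; they are an emulation, not estimates.
DOCTOR_PROFILE = StratumProfile(
    stratum="doctor",
    level_centers={"Absent": 9.0, "Mild": 26.0, "Moderate": 47.0, "Severe": 67.5, "Extreme": 88.0},
)
PATIENT_PROFILE = StratumProfile(
    stratum="patient",
    level_centers={"Absent": 13.8, "Mild": 26.6, "Moderate": 41.3, "Severe": 58.0, "Extreme": 70.8},
)
DEFAULT_PROFILES = {"doctor": DOCTOR_PROFILE, "patient": PATIENT_PROFILE}


def gen_interval_survey(
    profile: StratumProfile,
    n_respondents: int,
    scale: OrdinalScale = SEVERITY,
    seed: int = 0,
) -> list[IntervalResponse]:
    """Simulate one stratum's interval elicitation survey.

    Per respondent and level: center ~ Normal(level_center, center_sd),
    half-width ~ |Normal(half_width_mean, half_width_sd)|, interval =
    clip(center +/- half-width) rounded to the integer grid, RP =
    clip(center + Normal(0, rp_jitter_sd)).  Clipping happens before the
    lower <= upper invariant is (trivially) satisfied; degenerate intervals
    can occur at the scale boundaries.
    """
    if n_respondents < 1:
        raise ValueError("n_respondents must be >= 1")
    missing = [v for v in scale if v not in profile.level_centers]
    if missing:
        raise ValueError(f"profile lacks centers for levels {missing}")
    rng = np.random.default_rng(seed)
    out: list[IntervalResponse] = []
    for i in range(n_respondents):
        rid = f"{profile.stratum[:1]}{i:05d}"
        for level in scale:
            center = rng.normal(profile.level_centers[level], profile.center_sd)
            half_width = abs(rng.normal(profile.half_width_mean, profile.half_width_sd))
            lower = _clip_grid(center - half_width)
            upper = _clip_grid(center + half_width)
            rp = _clip_grid(center + rng.normal(0.0, profile.rp_jitter_sd))
            out.append(
                IntervalResponse(
                    respondent_id=rid,
                    stratum=profile.stratum,
                    level=level,
                    lower=lower,
                    upper=upper,
                    representative_point=rp,
                )
            )
    return out


def gen_qualitative_survey(
    profiles: Mapping[str, StratumProfile],
    n: int,
    scale: OrdinalScale = SEVERITY,
    seed: int = 0,
) -> list[QualitativeResponse]:
    """Simulate the inverse-mapping survey.

    Each respondent receives a uniform integer value in 1-99 and chooses a
    label with probability proportional to
    ``exp(-(value - level_center)^2 / (2 * center_sd^2))`` under their
    stratum's profile (strata assigned uniformly at random).  As
    ``center_sd`` shrinks, the choice converges to the nearest-center label.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    strata = sorted(profiles)
    sexes = ("F", "M")
    ages = ("18-30", "31-50", "51-70", "71+")
    out: list[QualitativeResponse] = []
    for i in range(n):
        profile = profiles[strata[rng.integers(len(strata))]]
        value = int(rng.integers(1, 100))
        centers = np.array([profile.level_centers[v] for v in scale])
        sd = max(profile.center_sd, 1e-9)
        logw = -((value - centers) ** 2) / (2.0 * sd**2)
        w = np.exp(logw - logw.max())
        p = w / w.sum()
        level = scale.levels[rng.choice(len(scale), p=p)]
        out.append(
            QualitativeResponse(
                respondent_id=f"q{i:05d}",
                value=value,
                chosen_level=level,
                sex=sexes[rng.integers(2)],
                age_range=ages[rng.integers(4)],
            )
        )
    return out


#: Default non-uniform cutpoints on the latent 0-100 severity axis.  The
#: induced label bins [0,5), [5,15), [15,30), [30,60), [60,100] compress the
#: low-severity end and stretch the top — the floor/ceiling-like regime of
#: severity instruments where equally spaced rank encoding misstates the
#: metric structure that a perception-derived scalar encoding retains.
DEFAULT_CUTPOINTS = (5.0, 15.0, 30.0, 60.0)


@dataclass
class LatentOutcomeSpec:
    """Specification of the PROM-style latent-severity regression dataset.

    Each ordinal feature f has a per-row latent severity
    z_f ~ Normal(latent_mean_f, latent_sd) clipped to [0,100]; the recorded
    label is the cutpoint bin containing z_f.  The continuous target is a
    linear function of the latent severities (not the ranks), the continuous
    scores and the demographics, plus Normal(0, noise_sd) noise.
    """

    n_rows: int = 336
    scale: OrdinalScale = SEVERITY
    n_ordinal: int = 9
    n_continuous: int = 3
    cutpoints: tuple[float, ...] = DEFAULT_CUTPOINTS
    latent_means: tuple[float, ...] | None = None  # default: spread over [25, 75]
    latent_sd: float = 25.0
    ordinal_coef: float = 0.08
    continuous_coefs: tuple[float, ...] = (0.2, 0.1, 0.1)
    age_coef: float = -0.02
    gender_effect: float = 0.3
    intervention_effects: dict[str, float] = field(
        default_factory=lambda: {"hip": 0.0, "knee": 0.4, "spine": -0.3}
    )
    intercept: float = 10.0
    noise_sd: float = 0.5

    def __post_init__(self) -> None:
        if any(b <= a for a, b in zip(self.cutpoints, self.cutpoints[1:])):
            raise ValueError("cutpoints must be strictly increasing")
        if len(self.cutpoints) != len(self.scale) - 1:
            raise ValueError("need len(scale) - 1 cutpoints")
        if self.latent_means is None:
            object.__setattr__(
                self, "latent_means", tuple(np.linspace(25, 75, self.n_ordinal))
            )
        if len(self.latent_means) != self.n_ordinal:
            raise ValueError("latent_means must have one entry per ordinal feature")
        if len(self.continuous_coefs) != self.n_continuous:
            raise ValueError("continuous_coefs must have one entry per continuous score")

    @property
    def ordinal_features(self) -> list[str]:
        return [f"ord_{i + 1}" for i in range(self.n_ordinal)]

    @property
    def continuous_features(self) -> list[str]:
        return [f"score_{i + 1}" for i in range(self.n_continuous)]

    def label_for(self, z: float) -> str:
        """Cutpoint bin containing latent severity z."""
        idx = int(np.searchsorted(np.asarray(self.cutpoints), z, side="right"))
        return self.scale.levels[idx]

    def bin_midpoints(self) -> dict[str, float]:
        """Midpoint of each label's cutpoint bin on [0, 100]."""
        edges = [0.0, *self.cutpoints, 100.0]
        return {
            v: (edges[i] + edges[i + 1]) / 2.0 for i, v in enumerate(self.scale.levels)
        }

    def matched_profile(self, stratum: str = "doctor") -> StratumProfile:
        """Zero-noise elicitation profile whose level centers sit at the
        cutpoint-bin midpoints — a survey 'matched' to the latent scale."""
        return StratumProfile(
            stratum=stratum,
            level_centers=self.bin_midpoints(),
            center_sd=0.0,
            half_width_mean=1e-9,
            half_width_sd=0.0,
            rp_jitter_sd=0.0,
        )


def gen_outcome_dataset(spec: LatentOutcomeSpec, seed: int = 0) -> FeatureTable:
    """Generate the latent-severity regression table as a FeatureTable."""
    rng = np.random.default_rng(seed)
    n = spec.n_rows
    data: dict[str, object] = {}
    feature_spec: dict[str, str] = {}

    gender = np.where(rng.random(n) < 0.5, "F", "M")
    age = rng.normal(65.0, 10.0, n)
    interventions = sorted(spec.intervention_effects)
    intervention = np.asarray(interventions, dtype=object)[rng.integers(len(interventions), size=n)]
    data["gender"] = gender
    data["age"] = age
    data["intervention"] = intervention
    feature_spec.update({"gender": "categorical", "age": "continuous", "intervention": "categorical"})

    scores = {}
    for name in spec.continuous_features:
        scores[name] = rng.normal(0.0, 1.0, n)
        data[name] = scores[name]
        feature_spec[name] = "continuous"

    latents = {}
    for name, mu in zip(spec.ordinal_features, spec.latent_means):
        z = np.clip(rng.normal(mu, spec.latent_sd, n), 0.0, 100.0)
        latents[name] = z
        data[name] = [spec.label_for(zi) for zi in z]
        feature_spec[name] = "ordinal"

    target = np.full(n, spec.intercept, dtype=float)
    for name in spec.ordinal_features:
        target += spec.ordinal_coef * latents[name]
    for name, c in zip(spec.continuous_features, spec.continuous_coefs):
        target += c * scores[name]
    target += spec.age_coef * age
    target += np.where(gender == "M", spec.gender_effect, 0.0)
    target += np.asarray([spec.intervention_effects[t] for t in intervention])
    target += rng.normal(0.0, spec.noise_sd, n)
    data["improvement_6m"] = target

    df = pd.DataFrame(data)
    return FeatureTable(
        df=df,
        feature_spec=feature_spec,
        target="improvement_6m",
        scales={name: spec.scale for name in spec.ordinal_features},
    )
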