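"""Cohort/generator configuration.

The default profile (``paper_default``) encodes the study conditions the
synthetic cohort emulates: 140 very old decedents (age 92.0 +/- 5.4 years,
72.1% female), log-normal per-participant fibre counts (mean 5387,
SD 3436, clipped to the observed range 299-19892), a right-skewed
log-normal axon-diameter distribution, a continuous piecewise-linear
axon->myelin law (slope 0.5 um/um below 4 um, 0.125 um/um from 4-8 um,
flat above 8 um), and an age effect acting as a multiplicative shrinkage
of the axon-size scale with age-invariant fibre density.

The numeric constants marked "calibrated" below were obtained with
``scripts/calibrate_generator.py`` so that the pooled fibre marginals hit
the targets mean fibre diameter 4.9 um, mean axon diameter 2.0 um, mean
myelin thickness 1.4 um and mean g-ratio 0.45, the between-person SD of
mean fibre diameter is 0.9 um, and a sex-adjusted regression of
person-mean fibre diameter on age has expected slope -0.041 um/year.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .exceptions import ConfigurationError

__all__ = ["CohortConfig", "load_config", "save_config"]


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """Log-scale (mu, sigma) of a log-normal with the given mean and SD."""
    cv2 = (sd / mean) ** 2
    sigma2 = math.log1p(cv2)
    return math.log(mean) - sigma2 / 2.0, math.sqrt(sigma2)


# Derived once from mean 5387 / SD 3436 and mean 4993.4 / SD 2076.2.
_FC_LOGMEAN, _FC_LOGSD = _lognormal_params(5387.0, 3436.0)
_DENS_LOGSD = _lognormal_params(4993.4, 2076.2)[1]


@dataclass
class CohortConfig:
    """All parameters of the synthetic cohort and fibre generator.

    Units are stated per field; every SD must be positive and proportions
    must lie in [0, 1]. ``validate`` raises :class:`ConfigurationError`
    naming the first offending field.
    """

    # cohort
    n_participants: int = 140
    age_mean: float = 92.0          # years
    age_sd: float = 5.4             # years
    age_min: float = 65.0           # years, left truncation of the age law
    p_female: float = 0.721

    # per-participant fibre counts (log-normal, clipped)
    fibre_count_logmean: float = _FC_LOGMEAN
    fibre_count_logsd: float = _FC_LOGSD
    fibre_count_min: int = 299
    fibre_count_max: int = 19892

    # axon-diameter law: pooled log-normal split into a within-person part
    # and a between-person log-scale random effect (calibrated)
    axon_logmean: float = 0.525761          # log-um
    axon_logsd: float = 0.575409            # log-um, within person
    person_scale_logsd: float = 0.235       # between-person log-scale SD

    # age mechanism: axon scale multiplied by exp(-rate * (age - age_mean))
    tail_shrink_per_year: float = 0.011046  # 1/year (calibrated)

    # piecewise myelin law (um and um/um)
    myelin_intercept: float = 0.429983      # c0, um (calibrated)
    myelin_slopes: tuple[float, float] = (0.5, 0.125)
    myelin_breakpoints: tuple[float, float] = (4.0, 8.0)
    myelin_noise_sd: float = 0.633575       # um (calibrated)

    # density (fibres/mm^2), log-normal across participants, age-invariant
    density_target: float = 4993.4
    density_logsd: float = _DENS_LOGSD

    # covariates (independent of morphology)
    hypertension_prev: float = 0.671
    smoking_prev: float = 0.357
    bmi_mean: float = 25.5          # kg/m^2
    bmi_sd: float = 4.3
    gfr_mean: float = 59.9          # ml/min/1.73 m^2
    gfr_sd: float = 16.0
    vascular_p: float = 0.245       # per-disease probability, n out of 4

    seed: int = 0

    def validate(self) -> "CohortConfig":
        pos = [
            "age_sd", "fibre_count_logsd", "axon_logsd", "myelin_noise_sd",
            "density_logsd", "bmi_sd", "gfr_sd", "density_target",
        ]
        for name in pos:
            if not getattr(self, name) > 0:
                raise ConfigurationError(f"{name} must be > 0")
        for name in ("p_female", "hypertension_prev", "smoking_prev", "vascular_p"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1]")
        if self.n_participants < 1:
            raise ConfigurationError("n_participants must be >= 1")
        if self.fibre_count_min < 1:
            raise ConfigurationError("fibre_count_min must be >= 1")
        if self.fibre_count_max < self.fibre_count_min:
            raise ConfigurationError("fibre_count_max must be >= fibre_count_min")
        b1, b2 = self.myelin_breakpoints
        if not b1 < b2:
            raise ConfigurationError("myelin_breakpoints must satisfy b1 < b2")
        if self.tail_shrink_per_year < 0:
            raise ConfigurationError("tail_shrink_per_year must be >= 0")
        if self.person_scale_logsd < 0:
            raise ConfigurationError("person_scale_logsd must be >= 0")
        if self.age_min > self.age_mean:
            raise ConfigurationError("age_min must not exceed age_mean")
        return self

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["myelin_slopes"] = list(self.myelin_slopes)
        d["myelin_breakpoints"] = list(self.myelin_breakpoints)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CohortConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown config field(s): {sorted(unknown)}")
        d = dict(d)
        for key in ("myelin_slopes", "myelin_breakpoints"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d).validate()


def load_config(path: str | Path | None = None) -> CohortConfig:
    """Load a YAML cohort profile.

    ``path`` may be a YAML file, the name of a bundled profile
    (``"paper_default"``), or ``None`` for the built-in defaults (which
    equal the bundled ``paper_default`` profile).
    """
    if path is None:
        return CohortConfig().validate()
    if isinstance(path, str) and not Path(path).exists():
        bundled = Path(__file__).parent / "profiles" / f"{path}.yaml"
        if bundled.exists():
            path = bundled
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return CohortConfig.from_dict(data)


def save_config(config: CohortConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)
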