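"""Synthetic cohorts, fibre populations and rendered cross-sections.

The generator emulates a postmortem tibial-nerve morphometry study on very
old adults.  It produces three layers, each usable on its own:

1. a cohort table (ages, sex, vascular covariates, per-person density);
2. per-fibre ground truth (axon diameter, myelin thickness) drawn from a
   log-normal axon law combined with a continuous piecewise-linear
   axon->myelin relation plus truncated Gaussian noise;
3. rendered cross-section images: non-overlapping axon disks with myelin
   annuli, exact label masks, and a noisy grayscale rendition emulating a
   Toluidine-blue semithin section (dark myelin on a light background).

Ageing is modelled as axonal atrophy, not fibre loss: the axon-diameter
scale of a participant is multiplied by ``exp(-rate * (age - age_mean))``
while the fibre count and density laws do not depend on age.  Older
participants therefore have proportionally shrunken diameter tails but
unchanged numbers, which is the mechanism the analysis layer is designed
to detect.

``simulate_from_fitted_model`` is the model-based generator used by the
parameter-recovery machinery: it draws outcomes from exactly the
heteroscedastic random-intercept Gaussian model that
:func:`nervemorph.stat_models.fit_hetero_mixed` estimates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.draw import disk as _draw_disk

from .config import CohortConfig
from .exceptions import ConfigurationError, DesignError, PackingError

__all__ = [
    "RenderedSection",
    "sample_cohort",
    "piecewise_myelin_mean",
    "sample_fibres",
    "sample_cohort_fibres",
    "fibres_to_area_table",
    "render_section",
    "simulate_from_fitted_model",
]


@dataclass
class RenderedSection:
    """A synthetic nerve cross-section with exact segmentation masks.

    ``axon_mask`` and ``myelin_mask`` are same-shape uint16 label images
    sharing fibre labels (1..n); they are disjoint.  ``analysed_area_mm2``
    is the full field area, pixels * pixel_size^2 / 1e6.
    """

    image: np.ndarray
    axon_mask: np.ndarray
    myelin_mask: np.ndarray
    pixel_size_um: float
    analysed_area_mm2: float
    participant_id: str | None = None

    def __post_init__(self):
        if self.axon_mask.shape != self.image.shape or self.myelin_mask.shape != self.image.shape:
            raise ValueError("masks must have the same shape as the image")


def _rng_from(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def sample_cohort(config: CohortConfig, rng=None) -> pd.DataFrame:
    """Draw the participant table.

    Ages come from a normal law left-truncated at ``age_min`` (drawn by
    rejection; the truncation point sits several SDs below the mean so the
    acceptance rate is essentially 1).  Covariates are independent of each
    other and of the fibre morphology.  The latent ``person_log_scale``
    column is the between-person axon-size random effect consumed by
    :func:`sample_fibres`.

    Returns a DataFrame with one row per participant.
    """
    config.validate()
    rng = _rng_from(config.seed if rng is None else rng)
    n = config.n_participants

    ages = np.empty(n)
    need = np.ones(n, dtype=bool)
    while need.any():
        draw = config.age_mean + config.age_sd * rng.standard_normal(need.sum())
        ages[need] = draw
        need = ages < config.age_min

    sex = np.where(rng.random(n) < config.p_female, "female", "male")
    counts = np.exp(config.fibre_count_logmean
                    + config.fibre_count_logsd * rng.standard_normal(n))
    counts = np.clip(np.rint(counts), config.fibre_count_min,
                     config.fibre_count_max).astype(int)
    dens_mu = np.log(config.density_target) - config.density_logsd**2 / 2.0
    density = np.exp(dens_mu + config.density_logsd * rng.standard_normal(n))

    width = len(str(n))
    return pd.DataFrame({
        "participant_id": [f"P{i + 1:0{width}d}" for i in range(n)],
        "age_at_death": ages,
        "sex": sex,
        "hypertension": rng.random(n) < config.hypertension_prev,
        "smoking": rng.random(n) < config.smoking_prev,
        "bmi": config.bmi_mean + config.bmi_sd * rng.standard_normal(n),
        "n_vascular": rng.binomial(4, config.vascular_p, size=n),
        "gfr": config.gfr_mean + config.gfr_sd * rng.standard_normal(n),
        "n_fibres_true": counts,
        "density_true": density,
        "person_log_scale": config.person_scale_logsd * rng.standard_normal(n),
    })


def piecewise_myelin_mean(axon_diameter, config: CohortConfig | None = None):
    """Expected myelin thickness (um) at a given axon diameter (um).

    Continuous piecewise-linear law: slope ``s1`` up to breakpoint ``b1``,
    slope ``s2`` from ``b1`` to ``b2``, constant (plateau) beyond ``b2``:

        c0 + s1 * min(a, b1) + s2 * clip(a - b1, 0, b2 - b1)

    Accepts scalars or arrays; negative diameters raise ``ValueError``.
    """
    config = config or CohortConfig()
    a = np.asarray(axon_diameter, dtype=float)
    if np.any(a < 0):
        raise ValueError("axon_diameter must be >= 0")
    s1, s2 = config.myelin_slopes
    b1, b2 = config.myelin_breakpoints
    out = (config.myelin_intercept
           + s1 * np.minimum(a, b1)
           + s2 * np.clip(a - b1, 0.0, b2 - b1))
    return out.item() if np.isscalar(axon_diameter) else out


def sample_fibres(participant: pd.Series, config: CohortConfig, rng) -> pd.DataFrame:
    """Draw the ground-truth fibre population of one participant.

    Axon diameters are log-normal with the participant's latent log-scale
    shift plus the age-shrinkage term; myelin thickness is the piecewise
    law plus Gaussian noise clipped at zero (exactly-zero thickness stands
    in for fibres the segmentation sees as unmyelinated, g = 1).
    """
    rng = _rng_from(rng)
    n = int(participant["n_fibres_true"])
    log_scale = (float(participant.get("person_log_scale", 0.0))
                 - config.tail_shrink_per_year
                 * (float(participant["age_at_death"]) - config.age_mean))
    axon = np.exp(config.axon_logmean + log_scale
                  + config.axon_logsd * rng.standard_normal(n))
    myelin = np.maximum(
        0.0,
        piecewise_myelin_mean(axon, config)
        + config.myelin_noise_sd * rng.standard_normal(n),
    )
    return pd.DataFrame({
        "participant_id": participant["participant_id"],
        "axon_diameter_um": axon,
        "myelin_thickness_um": myelin,
    })


def sample_cohort_fibres(config: CohortConfig,
                         participants: pd.DataFrame | None = None,
                         rng=None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Sample a cohort and all its fibres in one call.

    Returns ``(participants, fibres)``.  Reproducible: the fibre stream of
    each participant is drawn from a child generator spawned in row order
    from the supplied seed/generator.
    """
    base = np.random.SeedSequence(config.seed) if rng is None else None
    if participants is None:
        participants = sample_cohort(
            config,
            np.random.default_rng(base.spawn(1)[0]) if rng is None else rng)
    if rng is None:
        children = base.spawn(len(participants) + 1)[1:]
        gens = [np.random.default_rng(c) for c in children]
    else:
        gens = [_rng_from(rng)] * len(participants)
    frames = [sample_fibres(row, config, g)
              for (_, row), g in zip(participants.iterrows(), gens)]
    return participants, pd.concat(frames, ignore_index=True)


def fibres_to_area_table(fibres: pd.DataFrame) -> pd.DataFrame:
    """Convert ground-truth diameters to the area table morphometry reads.

    axon_area = pi (a/2)^2, myelin_area = pi (f/2)^2 - axon_area with
    f = a + 2t, so the morphometric formulas invert it exactly.
    """
    a = fibres["axon_diameter_um"].to_numpy()
    f = a + 2.0 * fibres["myelin_thickness_um"].to_numpy()
    axon_area = np.pi * (a / 2.0) ** 2
    return pd.DataFrame({
        "participant_id": fibres["participant_id"].to_numpy(),
        "axon_area_um2": axon_area,
        "myelin_area_um2": np.pi * (f / 2.0) ** 2 - axon_area,
    })


def render_section(fibres: pd.DataFrame,
                   pixel_size_um: float,
                   field_um: tuple[float, float],
                   rng,
                   *,
                   background: float = 200.0,
                   axoplasm: float = 170.0,
                   myelin_shade: float = 60.0,
                   noise_sd: float = 8.0,
                   margin_um: float = 0.3,
                   max_attempts: int = 2000,
                   participant_id: str | None = None) -> tuple[RenderedSection, pd.DataFrame]:
    """Render fibres as non-overlapping disks with myelin annuli.

    Placement is rejection-sampled: each fibre's outer circle (plus
    ``margin_um``) must not intersect previously placed circles and must
    lie inside the field.  Raises :class:`PackingError` (reporting the
    achieved count) if a fibre cannot be placed within ``max_attempts``.

    Returns the section and a copy of ``fibres`` with centre coordinates
    (``centre_x_um``, ``centre_y_um``) appended.
    """
    if pixel_size_um <= 0:
        raise ValueError("pixel_size_um must be > 0")
    rng = _rng_from(rng)
    w_um, h_um = field_um
    shape = (int(round(h_um / pixel_size_um)), int(round(w_um / pixel_size_um)))
    axon_mask = np.zeros(shape, dtype=np.uint16)
    myelin_mask = np.zeros(shape, dtype=np.uint16)
    image = np.full(shape, background, dtype=float)

    a = fibres["axon_diameter_um"].to_numpy() if len(fibres) else np.empty(0)
    t = fibres["myelin_thickness_um"].to_numpy() if len(fibres) else np.empty(0)
    order = np.argsort(-(a + 2 * t))  # place big fibres first
    cx = np.full(len(fibres), np.nan)
    cy = np.full(len(fibres), np.nan)
    placed: list[tuple[float, float, float]] = []

    for label_idx, i in enumerate(order):
        r_out = (a[i] + 2 * t[i]) / 2.0
        r_guard = r_out + margin_um
        ok = False
        for _ in range(max_attempts):
            x = rng.uniform(r_guard, w_um - r_guard)
            y = rng.uniform(r_guard, h_um - r_guard)
            if all((x - px) ** 2 + (y - py) ** 2 >= (r_guard + pr) ** 2
                   for px, py, pr in placed):
                ok = True
                break
        if not ok:
            raise PackingError(
                f"could not place fibre {i} after {max_attempts} attempts",
                achieved=len(placed))
        placed.append((x, y, r_guard))
        cx[i], cy[i] = x, y
        label = i + 1  # stable label = input row + 1
        c_px = (y / pixel_size_um, x / pixel_size_um)
        rr_o, cc_o = _draw_disk(c_px, r_out / pixel_size_um, shape=shape)
        rr_a, cc_a = _draw_disk(c_px, a[i] / 2.0 / pixel_size_um, shape=shape)
        myelin_mask[rr_o, cc_o] = label
        image[rr_o, cc_o] = myelin_shade
        axon_mask[rr_a, cc_a] = label
        myelin_mask[rr_a, cc_a] = 0
        image[rr_a, cc_a] = axoplasm

    if noise_sd > 0:
        image = image + noise_sd * rng.standard_normal(shape)
    image = np.clip(image, 0, 255).astype(np.uint8)
    section = RenderedSection(
        image=image,
        axon_mask=axon_mask,
        myelin_mask=myelin_mask,
        pixel_size_um=pixel_size_um,
        analysed_area_mm2=shape[0] * shape[1] * pixel_size_um**2 / 1e6,
        participant_id=participant_id,
    )
    out = fibres.copy()
    out["centre_x_um"] = cx
    out["centre_y_um"] = cy
    return section, out


def simulate_from_fitted_model(X_mean: np.ndarray,
                               beta: np.ndarray,
                               Z_disp: np.ndarray,
                               gamma: np.ndarray,
                               groups: np.ndarray,
                               tau: float,
                               rng) -> np.ndarray:
    """Draw outcomes from the heteroscedastic random-intercept model.

        y = X beta + u[group] + eps,   u ~ N(0, tau^2),
        eps_i ~ N(0, exp(2 z_i' gamma))

    This is exactly the likelihood ``fit_hetero_mixed`` maximizes, so
    refitting simulated data is a clean parameter-recovery experiment.
    Dimension mismatches raise :class:`DesignError`.
    """
    X_mean = np.asarray(X_mean, float)
    Z_disp = np.asarray(Z_disp, float)
    beta = np.asarray(beta, float)
    gamma = np.asarray(gamma, float)
    groups = np.asarray(groups)
    n = X_mean.shape[0]
    if X_mean.shape[1] != beta.size:
        raise DesignError(
            f"beta has {beta.size} entries but X_mean has {X_mean.shape[1]} columns")
    if Z_disp.shape[0] != n or groups.shape[0] != n:
        raise DesignError("X_mean, Z_disp and groups must have equal row counts")
    if Z_disp.shape[1] != gamma.size:
        raise DesignError(
            f"gamma has {gamma.size} entries but Z_disp has {Z_disp.shape[1]} columns")
    if tau < 0:
        raise DesignError("tau must be >= 0")
    rng = _rng_from(rng)
    _, idx = np.unique(groups, return_inverse=True)
    u = tau * rng.standard_normal(idx.max() + 1)
    sd = np.exp(Z_disp @ gamma)
    return X_mean @ beta + u[idx] + sd * rng.standard_normal(n)
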