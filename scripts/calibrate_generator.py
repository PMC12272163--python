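"""Calibration of the default generator constants.

Re-derives the four calibrated numbers frozen in
``nervemorph.config.CohortConfig`` (axon_logmean, the pooled axon log-SD
that is split into within- and between-person parts, myelin_intercept,
myelin_noise_sd) together with tail_shrink_per_year and
person_scale_logsd.  Everything is computed from the generator's own
closed forms:

* pooled moments of myelin thickness under zero-clipped Gaussian noise
  use E[max(0, m + s e)] = m Phi(m/s) + s phi(m/s) integrated over the
  log-normal axon law by Gauss-Hermite quadrature;
* the pooled mean g-ratio has no closed form and is evaluated by a
  fixed-seed Monte-Carlo integral;
* the age-shrinkage rate solves, by 1-D root finding, for the value at
  which the population regression slope of expected person-mean fibre
  diameter on age equals the target -0.041 um/year (ages integrated over
  the truncated normal age law);
* the between-person log-scale SD is chosen so the SD of person-mean
  fibre diameter at fixed age is ~0.88 um, which together with the age
  effect gives a total person-level SD of ~0.9 um.

Run:  python scripts/calibrate_generator.py
"""

import numpy as np
from scipy import optimize, stats
from scipy.special import roots_hermitenorm

# targets for the pooled fibre marginals and the age association
TARGET_AXON_MEAN = 2.0       # um
TARGET_AXON_SD = 1.4         # um
TARGET_FIBRE_MEAN = 4.9      # um
TARGET_G_MEAN = 0.45
TARGET_VAR_EXPLAINED = 0.574  # share of myelin variance carried by axon size
TARGET_AGE_SLOPE = -0.041    # um/year, person-mean fibre diameter on age
TARGET_PERSON_SD = 0.88      # um, person-mean fibre SD at fixed age

B1, B2, S1, S2 = 4.0, 8.0, 0.5, 0.125
AGE_MEAN, AGE_SD, AGE_MIN = 92.0, 5.4, 65.0

z, w = roots_hermitenorm(201)
w = w / w.sum()


def piecewise(a, c0):
    return c0 + S1 * np.minimum(a, B1) + S2 * np.clip(a - B1, 0.0, B2 - B1)


def clipped_mean(f, s):
    r = f / s
    return f * stats.norm.cdf(r) + s * stats.norm.pdf(r)


def pooled_moments(mu, sig, c0, sn):
    a = np.exp(mu + sig * z)
    f = piecewise(a, c0)
    h = clipped_mean(f, sn)
    m2 = (f**2 + sn**2) * stats.norm.cdf(f / sn) + f * sn * stats.norm.pdf(f / sn)
    Ea, Ea2 = np.sum(w * a), np.sum(w * a * a)
    Em = np.sum(w * h)
    Vm = np.sum(w * m2) - Em**2
    Vh = np.sum(w * h * h) - Em**2
    return Ea, np.sqrt(Ea2 - Ea**2), Em, Vm, Vh


def g_mean(mu, sig, c0, sn, n=400_000, seed=12345):
    rng = np.random.default_rng(seed)
    a = np.exp(mu + sig * rng.standard_normal(n))
    m = np.maximum(0.0, piecewise(a, c0) + sn * rng.standard_normal(n))
    return float(np.mean(a / (a + 2 * m)))


def residuals(p):
    mu, sig, c0, sn = p
    Ea, SDa, Em, Vm, Vh = pooled_moments(mu, sig, c0, sn)
    return [
        2.0 * (Ea - TARGET_AXON_MEAN),
        1.0 * (SDa - TARGET_AXON_SD),
        3.0 * (Ea + 2 * Em - TARGET_FIBRE_MEAN),
        10.0 * (g_mean(mu, sig, c0, sn) - TARGET_G_MEAN),
        1.0 * (Vh / Vm - TARGET_VAR_EXPLAINED),
    ]


def solve_shrink_rate(mu, sig, c0, sn):
    aa = (AGE_MIN - AGE_MEAN) / AGE_SD
    ages = stats.truncnorm.ppf(np.linspace(5e-4, 1 - 5e-4, 400), aa, np.inf,
                               loc=AGE_MEAN, scale=AGE_SD)
    a_base = np.exp(mu + sig * z)

    def mean_fibre(age, k):
        a = a_base * np.exp(-k * (age - AGE_MEAN))
        return np.sum(w * (a + 2 * clipped_mean(piecewise(a, c0), sn)))

    def slope(k):
        mf = np.array([mean_fibre(ag, k) for ag in ages])
        return np.polyfit(ages, mf, 1)[0]

    return optimize.brentq(lambda k: slope(k) - TARGET_AGE_SLOPE, 1e-4, 0.1)


def solve_person_scale(mu, sig_tot, c0, sn):
    def person_sd(sp):
        sw = np.sqrt(sig_tot**2 - sp**2)
        rng = np.random.default_rng(3)
        us = sp * rng.standard_normal(4000)
        pm = [np.sum(w * (np.exp(mu + u + sw * z)
                          + 2 * clipped_mean(
                              piecewise(np.exp(mu + u + sw * z), c0), sn)))
              for u in us]
        return np.std(pm)

    return optimize.brentq(lambda sp: person_sd(sp) - TARGET_PERSON_SD,
                           0.05, 0.45)


if __name__ == "__main__":
    sol = optimize.least_squares(
        residuals, [0.5, 0.63, 0.45, 0.6],
        bounds=([-1, 0.2, 0.0, 0.1], [1.5, 1.2, 1.5, 1.5]))
    mu, sig_tot, c0, sn = sol.x
    Ea, SDa, Em, Vm, Vh = pooled_moments(mu, sig_tot, c0, sn)
    print(f"axon_logmean        = {mu:.6f}")
    print(f"pooled axon log-SD  = {sig_tot:.6f}")
    print(f"myelin_intercept    = {c0:.6f}")
    print(f"myelin_noise_sd     = {sn:.6f}")
    print(f"  pooled: axon {Ea:.3f} ({SDa:.3f}), myelin {Em:.3f}, "
          f"fibre {Ea + 2 * Em:.3f}, g {g_mean(mu, sig_tot, c0, sn, 2_000_000):.4f}, "
          f"explained {Vh / Vm:.3f}")
    k = solve_shrink_rate(mu, sig_tot, c0, sn)
    print(f"tail_shrink_per_year = {k:.6f}")
    sp = solve_person_scale(mu, sig_tot, c0, sn)
    print(f"person_scale_logsd  = {sp:.4f}")
    print(f"axon_logsd (within) = {np.sqrt(sig_tot**2 - sp**2):.6f}")
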