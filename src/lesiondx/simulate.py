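"""Synthetic cohort generation from published summary statistics.

Continuous features are modeled as truncated normal distributions on the
published range, with the parent location/scale calibrated numerically so
the *truncated* law attains the published mean and SD (closed-form
truncated-normal moments, two-equation solve).  The published mean/SD/range
triple is not always attainable within this family — the SD supremum on an
interval, given the mean, is reached in the exponential-tilt limit — so the
calibrator has two modes: strict (raise, naming the maximal feasible SD)
and relaxed (match the mean exactly, take the closest attainable SD).  The
cohort sampler uses the relaxed mode.

Categorical features are drawn from the published frequencies.  Distinct
features are drawn independently within a lesion (the source reports no
correlation structure and none is invented), except that the perilesional
ratios of one modality at 5/10/20 mm share a quantile (comonotone
coupling), so each marginal keeps its calibrated moments while the
within-lesion distance profile follows the published gradient.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from typing import Optional

import numpy as np
from scipy import optimize
from scipy.stats import truncnorm

from . import params
from .schema import Cohort, Lesion, Patient, SUBTYPES_BY_ENTITY

_REL_TOL = 1e-6


class CalibrationError(ValueError):
    """The target moment pair is not attainable on the truncation interval."""

    def __init__(self, message: str, max_feasible_sd: float):
        super().__init__(message)
        self.max_feasible_sd = max_feasible_sd


@dataclass(frozen=True)
class CalibratedLaw:
    """A truncated normal with parent (mu, sigma) and realized moments."""

    family: str
    mu: float
    sigma: float
    lower: float
    upper: float
    target_mean: float
    target_sd: float
    realized_mean: float
    realized_sd: float

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        a = (self.lower - self.mu) / self.sigma
        b = (self.upper - self.mu) / self.sigma
        return truncnorm.rvs(
            a, b, loc=self.mu, scale=self.sigma, size=size, random_state=rng
        )


def _moments(mu: float, sigma: float, lower: float, upper: float):
    a, b = (lower - mu) / sigma, (upper - mu) / sigma
    m, v = truncnorm.stats(a, b, loc=mu, scale=sigma, moments="mv")
    return float(m), float(np.sqrt(v))


def _trunc_mean(mu: float, sigma: float, lower: float, upper: float) -> float:
    m, _ = _moments(mu, sigma, lower, upper)
    if not np.isfinite(m):
        # far-tail saturation: virtually all mass at the nearer bound
        return lower if mu < 0.5 * (lower + upper) else upper
    return m


def _mean_matched_mu(sigma: float, target_mean: float, lower: float, upper: float):
    """mu such that the truncated mean equals target_mean (monotone in mu).

    The bracket is expanded geometrically: in the strong-truncation regime
    the required mu grows like sigma^2 (exponential-tilt limit), so no
    fixed multiple of sigma suffices.
    """

    def f(mu):
        return _trunc_mean(mu, sigma, lower, upper) - target_mean

    width = upper - lower
    cap = 1e9 * max(sigma, sigma**2 / width)
    lo, hi = lower, upper
    step = sigma
    while f(lo) > 0:
        lo -= step
        step *= 2.0
        if step > cap:
            raise RuntimeError("mean bracket expansion failed (low side)")
    step = sigma
    while f(hi) < 0:
        hi += step
        step *= 2.0
        if step > cap:
            raise RuntimeError("mean bracket expansion failed (high side)")
    return optimize.brentq(f, lo, hi, xtol=1e-12, rtol=1e-14)


def calibrate_truncated_normal(
    target_mean: float,
    target_sd: float,
    lower: float,
    upper: float,
    relax: bool = False,
) -> CalibratedLaw:
    """Solve for the parent (mu, sigma) of a truncated normal on
    [lower, upper] whose truncated mean and SD equal the targets.

    With ``relax=False`` an infeasible (mean, sd) pair raises
    :class:`CalibrationError` naming the maximal feasible SD at that mean;
    with ``relax=True`` the mean is matched exactly and sigma is pushed to
    the feasibility boundary, yielding the closest attainable SD.
    """
    if not (lower < target_mean < upper):
        raise ValueError("target_mean must lie strictly inside (lower, upper)")
    if target_sd <= 0:
        raise ValueError("target_sd must be positive")
    if not (np.isfinite(lower) and np.isfinite(upper)):
        raise ValueError("finite truncation bounds required")

    def residual(p):
        mu, log_sigma = p
        m, s = _moments(mu, np.exp(log_sigma), lower, upper)
        return [m - target_mean, s - target_sd]

    sol = optimize.root(residual, [target_mean, np.log(target_sd)], method="hybr")
    mu, sigma = float(sol.x[0]), float(np.exp(sol.x[1]))
    rm, rs = _moments(mu, sigma, lower, upper)
    tol_m = _REL_TOL * max(1.0, abs(target_mean))
    tol_s = _REL_TOL * max(1.0, abs(target_sd))
    if abs(rm - target_mean) <= tol_m and abs(rs - target_sd) <= tol_s:
        return CalibratedLaw(
            "truncated_normal", mu, sigma, lower, upper,
            target_mean, target_sd, rm, rs,
        )

    # Mean-matching manifold: sd is increasing in sigma, bounded above by
    # the exponential-tilt limit.  Bisect sigma for the target sd.
    width = upper - lower
    sigma_max = 20.0 * width

    def sd_at(sigma: float) -> float:
        mu = _mean_matched_mu(sigma, target_mean, lower, upper)
        return _moments(mu, sigma, lower, upper)[1]

    sd_sup = sd_at(sigma_max)
    if target_sd >= sd_sup:
        if not relax:
            raise CalibrationError(
                f"target sd {target_sd} infeasible on [{lower}, {upper}] at "
                f"mean {target_mean}; maximal feasible sd ~ {sd_sup:.6g}",
                max_feasible_sd=sd_sup,
            )
        sigma = sigma_max
    else:
        sigma = optimize.brentq(
            lambda s: sd_at(s) - target_sd, 1e-6 * width, sigma_max,
            xtol=1e-12, rtol=1e-14,
        )
    mu = _mean_matched_mu(sigma, target_mean, lower, upper)
    rm, rs = _moments(mu, sigma, lower, upper)
    if not relax and not (
        abs(rm - target_mean) <= tol_m and abs(rs - target_sd) <= tol_s
    ):
        raise CalibrationError(
            f"calibration did not converge for ({target_mean}, {target_sd}) "
            f"on [{lower}, {upper}]; maximal feasible sd ~ {sd_sup:.6g}",
            max_feasible_sd=sd_sup,
        )
    return CalibratedLaw(
        "truncated_normal", float(mu), float(sigma), lower, upper,
        target_mean, target_sd, rm, rs,
    )


@dataclass
class GeneratorConfig:
    """Per-entity sampling configuration; defaults come from
    :func:`default_config` and carry the published values."""

    entity: str
    n_patients: int
    lesion_count_law: tuple  # (mean, sd, min, max)
    continuous_laws: dict  # feature -> (mean, sd, lower, upper)
    morphology_probs: dict
    location_probs: dict
    subtype_probs: dict
    contrast_enhancing_prob: float
    flair_connected_prob: float
    perfusion_available_prob: float
    typical_curve_prob_given_perfusion: float
    rcbv_increased_prob: float
    swi_available_prob: float
    swi_hemorrhage_prob: float
    swi_vascularization_prob: float
    seed: int = 0

    def validate(self) -> None:
        if self.entity not in SUBTYPES_BY_ENTITY:
            raise ValueError(f"unknown entity {self.entity!r}")
        if self.n_patients <= 0:
            raise ValueError("n_patients must be positive")
        for name, table in (
            ("morphology_probs", self.morphology_probs),
            ("location_probs", self.location_probs),
            ("subtype_probs", self.subtype_probs),
        ):
            total = sum(table.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"{name} sums to {total}, not 1")
        laws = dict(self.continuous_laws)
        laws["lesion_count"] = self.lesion_count_law
        for name, (m, s, lo, hi) in laws.items():
            if not lo < hi:
                raise ValueError(f"{name}: lower must be < upper")
            if not lo < m < hi:
                raise ValueError(f"{name}: mean outside (lower, upper)")
            if s <= 0:
                raise ValueError(f"{name}: sd must be positive")


def default_config(
    entity: str, n_patients: Optional[int] = None, seed: int = 0
) -> GeneratorConfig:
    """Configuration whose every numeric field equals the published value
    for ``entity`` (probability tables renormalized to sum to 1)."""
    if entity not in params.CONTINUOUS_LAWS:
        raise ValueError(f"unknown entity {entity!r}")
    laws = dict(params.CONTINUOUS_LAWS[entity])
    count_law = laws.pop("lesion_count")
    morph_total = sum(params.MORPHOLOGY_COUNTS[entity].values())
    loc_total = sum(params.LOCATION_COUNTS[entity].values())
    bc = params.BINARY_COUNTS[entity]
    major = "multifocal" if entity == "mGB" else "PCNSL"
    minor = "multicentric" if entity == "mGB" else "SCNSL"
    key = f"subtype_{major}_patients"
    k, n = bc[key]
    return GeneratorConfig(
        entity=entity,
        n_patients=params.N_PATIENTS[entity] if n_patients is None else n_patients,
        lesion_count_law=count_law,
        continuous_laws=laws,
        morphology_probs={
            m: c / morph_total for m, c in params.MORPHOLOGY_COUNTS[entity].items()
        },
        location_probs={
            m: c / loc_total for m, c in params.LOCATION_COUNTS[entity].items()
        },
        subtype_probs={major: k / n, minor: (n - k) / n},
        contrast_enhancing_prob=_p(bc["contrast_enhancing"]),
        flair_connected_prob=_p(bc["flair_connected"]),
        perfusion_available_prob=_p(bc["perfusion_available_patients"]),
        typical_curve_prob_given_perfusion=_p(bc["typical_curve"]),
        rcbv_increased_prob=_p(bc["rcbv_increased"]),
        swi_available_prob=_p(bc["swi_available_patients"]),
        swi_hemorrhage_prob=_p(bc["swi_hemorrhage"]),
        swi_vascularization_prob=_p(bc["swi_vascularization"]),
        seed=seed,
    )


def _p(count_denominator: tuple[int, int]) -> float:
    k, n = count_denominator
    return k / n


_ADC_EDEMA = ("adc_ratio_edema_5mm", "adc_ratio_edema_10mm", "adc_ratio_edema_20mm")
_FLAIR_EDEMA = (
    "flair_ratio_edema_5mm", "flair_ratio_edema_10mm", "flair_ratio_edema_20mm"
)


def sample_cohort(config: GeneratorConfig) -> Cohort:
    """Draw a labeled cohort; deterministic for a given ``config.seed``."""
    config.validate()
    rng = np.random.default_rng(config.seed)

    cm, cs, cmin, cmax = config.lesion_count_law
    count_law = calibrate_truncated_normal(cm, cs, cmin, cmax, relax=True)
    laws = {
        name: calibrate_truncated_normal(*law, relax=True)
        for name, law in config.continuous_laws.items()
    }

    counts = np.clip(
        np.rint(count_law.sample(rng, config.n_patients)).astype(int), cmin, cmax
    )
    total = int(counts.sum())

    draws = {
        name: law.sample(rng, total)
        for name, law in laws.items()
        if name not in _ADC_EDEMA and name not in _FLAIR_EDEMA
    }
    # Perilesional ratios at 5/10/20 mm are drawn comonotonically (one
    # shared quantile per modality per lesion): every marginal keeps its
    # calibrated moments exactly, while within-lesion profiles follow the
    # published monotone-in-expectation distance gradients smoothly.
    for group in (_ADC_EDEMA, _FLAIR_EDEMA):
        u = rng.random(total)
        for name in group:
            law = laws[name]
            a = (law.lower - law.mu) / law.sigma
            b = (law.upper - law.mu) / law.sigma
            draws[name] = truncnorm.ppf(u, a, b, loc=law.mu, scale=law.sigma)

    morph_tokens = list(config.morphology_probs)
    morph = rng.choice(
        morph_tokens, size=total, p=[config.morphology_probs[t] for t in morph_tokens]
    )
    loc_tokens = list(config.location_probs)
    loc = rng.choice(
        loc_tokens, size=total, p=[config.location_probs[t] for t in loc_tokens]
    )
    enhancing = rng.random(total) < config.contrast_enhancing_prob
    connected = rng.random(total) < config.flair_connected_prob
    rcbv = rng.random(total) < config.rcbv_increased_prob
    typical = rng.random(total) < config.typical_curve_prob_given_perfusion
    hemorrhage = rng.random(total) < config.swi_hemorrhage_prob
    vascular = rng.random(total) < config.swi_vascularization_prob

    perf = rng.random(config.n_patients) < config.perfusion_available_prob
    swi = rng.random(config.n_patients) < config.swi_available_prob
    sub_tokens = list(config.subtype_probs)
    subtypes = rng.choice(
        sub_tokens,
        size=config.n_patients,
        p=[config.subtype_probs[t] for t in sub_tokens],
    )

    patients = []
    gi = 0
    for p_idx in range(config.n_patients):
        lesions = []
        for _ in range(counts[p_idx]):
            lesions.append(
                Lesion(
                    diameter_mm=float(draws["diameter_mm"][gi]),
                    morphology=str(morph[gi]),
                    location=str(loc[gi]),
                    edema_mm=float(draws["edema_mm"][gi]),
                    nearest_lesion_distance_mm=float(
                        draws["nearest_lesion_distance_mm"][gi]
                    ),
                    flair_connected=bool(connected[gi]),
                    adc_ratio_tumor=float(draws["adc_ratio_tumor"][gi]),
                    flair_ratio_tumor=float(draws["flair_ratio_tumor"][gi]),
                    contrast_enhancing=bool(enhancing[gi]),
                    adc_ratio_edema_5mm=float(draws["adc_ratio_edema_5mm"][gi]),
                    adc_ratio_edema_10mm=float(draws["adc_ratio_edema_10mm"][gi]),
                    adc_ratio_edema_20mm=float(draws["adc_ratio_edema_20mm"][gi]),
                    flair_ratio_edema_5mm=float(draws["flair_ratio_edema_5mm"][gi]),
                    flair_ratio_edema_10mm=float(draws["flair_ratio_edema_10mm"][gi]),
                    flair_ratio_edema_20mm=float(draws["flair_ratio_edema_20mm"][gi]),
                    rcbv_increased=bool(rcbv[gi]) if perf[p_idx] else None,
                    typical_curve=bool(typical[gi]) if perf[p_idx] else None,
                    swi_hemorrhage=bool(hemorrhage[gi]) if swi[p_idx] else None,
                    swi_vascularization=bool(vascular[gi]) if swi[p_idx] else None,
                )
            )
            gi += 1
        patients.append(
            Patient(
                entity=config.entity,
                subtype=str(subtypes[p_idx]),
                lesions=lesions,
                perfusion_available=bool(perf[p_idx]),
                swi_available=bool(swi[p_idx]),
            )
        )
    return Cohort(patients, provenance=f"synthetic seed {config.seed}")


def config_to_dict(config: GeneratorConfig) -> dict:
    return asdict(config)


def config_from_dict(doc: dict) -> GeneratorConfig:
    doc = dict(doc)
    doc["lesion_count_law"] = tuple(doc["lesion_count_law"])
    doc["continuous_laws"] = {
        k: tuple(v) for k, v in doc["continuous_laws"].items()
    }
    return GeneratorConfig(**doc)
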