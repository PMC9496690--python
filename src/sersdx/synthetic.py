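"""Synthetic SERS cohorts with the statistical structure the analysis assumes.

No CSF spectra are publicly deposited for this kind of study, so every
downstream stage is exercised on generated data instead.  A cohort is a set
of samples; each sample has a diagnostic class, a latent severity, one
sample-level amplitude effect shared by its replicate mappings, and a
clinical record whose covariate distributions follow the published
group-level means/SDs.  A mapping is ``spectra_per_mapping`` noisy spectra:

    I(v) = baseline(v) + sum_k A_k * m_k * e_k * L(v; c_k, w_k) + eps(v)

with L a unit-height Lorentzian, A_k the band's base amplitude, m_k the
class-template multiplier, e_k the sample effect (lognormal, CV =
``sample_cv``), and eps iid Gaussian noise.  The six bands emulated are the
CSF protein/lipid bands at 850 (alanine), 870 (glutamic acid/serine),
1000 (phenylalanine), 1171 (tyrosine), 1465 (lipid) and 1555 cm^-1
(tryptophan).

p-tau is generated from t-tau through the linear link

    P = 0.1134 * T + 35.28 + noise

with the noise SD calibrated so the pooled t-tau/p-tau Pearson correlation
matches the planted target r = 0.8883.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .spectra_io import (
    LABELS,
    ClinicalRecord,
    MappingGroup,
    Spectrum,
    canonical_grid,
)

__all__ = [
    "PeakModel",
    "ClassTemplate",
    "CohortDesign",
    "default_peaks",
    "diagnosis_templates",
    "replicate_study_design",
    "diagnosis_study_design",
    "simulate_spectrum",
    "simulate_clinical",
    "simulate_cohort",
    "calibrate_tau_link_noise",
    "TAU_SLOPE",
    "TAU_INTERCEPT",
    "TAU_TARGET_R",
    "CLINICAL_PROFILES",
]

#: Generative t-tau -> p-tau link (pg/mL): P = slope*T + intercept + noise.
TAU_SLOPE = 0.1134
TAU_INTERCEPT = 35.28
#: Planted pooled Pearson correlation between t-tau and p-tau.
TAU_TARGET_R = 0.8883


@dataclass(frozen=True)
class PeakModel:
    """One Raman band: Lorentzian center (cm^-1), HWHM width, base amplitude."""

    center: float
    width: float = 8.0
    base_amplitude: float = 1.0

    def __post_init__(self):
        if self.width <= 0:
            raise ValueError("peak width must be positive")


@dataclass(frozen=True)
class ClassTemplate:
    """Per-class multiplicative modulation of the band amplitudes."""

    label: str
    amplitude_multipliers: tuple[float, ...]

    def __post_init__(self):
        if any(m <= 0 for m in self.amplitude_multipliers):
            raise ValueError("amplitude multipliers must be positive")


def default_peaks() -> list[PeakModel]:
    """The six CSF bands, HWHM 8 cm^-1, phenylalanine strongest."""
    centers = (850.0, 870.0, 1000.0, 1171.0, 1465.0, 1555.0)
    amplitudes = (0.8, 0.7, 1.0, 0.6, 0.7, 0.9)
    return [PeakModel(c, 8.0, a) for c, a in zip(centers, amplitudes)]


# Group-level clinical covariate distributions (mean, SD), per diagnostic
# class: age (years), Aβ42 / t-tau (pg/mL), MMSE, CDRSUM, CDRGLOB, plus the
# male fraction and the FAD carriers' adjusted age (years to expected onset).
CLINICAL_PROFILES: dict[str, dict] = {
    "normal": dict(
        age=(76.6, 5.5), abeta42=(645.6, 353.0), t_tau=(364.9, 265.3),
        mmse=(29.9, 0.3), cdr_sum=(0.1, 0.2), cdr_glob=(0.1, 0.2),
        male_frac=3 / 10, adjusted_age=None,
    ),
    "dementia": dict(
        age=(79.0, 4.9), abeta42=(375.9, 305.8), t_tau=(570.6, 529.4),
        mmse=(19.6, 3.6), cdr_sum=(9.1, 2.0), cdr_glob=(1.44, 0.5),
        male_frac=4 / 9, adjusted_age=None,
    ),
    "fad_pos": dict(
        age=(36.0, 12.9), abeta42=(186.2, 60.4), t_tau=(516.9, 363.3),
        mmse=(25.0, 7.9), cdr_sum=(1.6, 3.0), cdr_glob=(0.2, 0.45),
        male_frac=3 / 5, adjusted_age=(-10.0, 10.6),
    ),
    "fad_neg": dict(
        age=(34.0, 14.8), abeta42=(418.8, 174.9), t_tau=(312.1, 266.8),
        mmse=(28.8, 0.5), cdr_sum=(0.25, 0.5), cdr_glob=(0.13, 0.25),
        male_frac=3 / 4, adjusted_age=None,
    ),
}


def diagnosis_templates() -> list[ClassTemplate]:
    """Default class templates for the four diagnostic classes.

    Dementia modulates every band by >=30% relative to normal.  FAD mutation
    carriers (fad_pos) sit most of the way toward the dementia pattern
    (pre-clinical disease biochemistry); non-carriers (fad_neg) sit close to
    normal.
    """
    normal = np.ones(6)
    dementia = np.array([1.5, 0.65, 1.6, 0.6, 1.45, 0.65])

    def blend(t):
        return tuple(normal + t * (dementia - normal))

    return [
        ClassTemplate("normal", tuple(normal)),
        ClassTemplate("dementia", tuple(dementia)),
        ClassTemplate("fad_pos", blend(0.75)),
        ClassTemplate("fad_neg", blend(0.05)),
    ]


@dataclass(frozen=True)
class CohortDesign:
    """Full specification of a synthetic cohort.

    ``samples_per_class`` is one count applied to every class, or a
    per-label mapping.  ``sample_cv`` is the relative SD of the lognormal
    sample-level amplitude effects (shared across a sample's replicates);
    ``spectrum_noise_sd`` the per-point Gaussian noise in intensity units.
    ``baseline_coeffs`` are polynomial coefficients in the scaled coordinate
    u = (v - 550)/1100, low order first.  ``t_tau_missing_rate`` blanks
    t-tau at random to exercise imputation.  A fixed ``seed`` makes the
    cohort fully reproducible.
    """

    classes: tuple[ClassTemplate, ...]
    samples_per_class: int | dict = 1
    replicates_per_sample: int = 1
    spectra_per_mapping: int = 80
    peaks: tuple[PeakModel, ...] = field(default_factory=lambda: tuple(default_peaks()))
    sample_cv: float = 0.02
    spectrum_noise_sd: float = 0.05
    baseline_coeffs: tuple[float, ...] = (0.05, 0.10, 0.05)
    t_tau_missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.spectra_per_mapping < 1:
            raise ValueError("spectra_per_mapping must be >= 1")
        if self.sample_cv < 0 or self.spectrum_noise_sd < 0:
            raise ValueError("sample_cv and spectrum_noise_sd must be >= 0")
        for t in self.classes:
            if len(t.amplitude_multipliers) != len(self.peaks):
                raise ValueError(f"template {t.label!r} needs one multiplier per peak")

    def n_samples_for(self, label: str) -> int:
        if isinstance(self.samples_per_class, dict):
            return int(self.samples_per_class[label])
        return int(self.samples_per_class)


def replicate_study_design(seed: int = 0, **overrides) -> CohortDesign:
    """The 5-samples x 3-replicates reproducibility design.

    Five distinct spectral classes (one sample each, three replicate
    mappings of >=80 spectra) whose band multipliers differ pairwise by at
    least a factor 1.3 on two or more bands.
    """
    patterns = {
        "s1": (1.0, 1.0, 1.0, 1.0, 1.0, 1.0),
        "s2": (1.4, 1.0, 0.7, 1.0, 1.4, 1.0),
        "s3": (0.7, 1.4, 1.0, 1.4, 0.7, 1.0),
        "s4": (1.0, 0.7, 1.4, 0.7, 1.0, 1.4),
        "s5": (1.4, 1.4, 0.7, 0.7, 1.4, 0.7),
    }
    classes = tuple(ClassTemplate(k, v) for k, v in patterns.items())
    kwargs = dict(
        classes=classes, samples_per_class=1, replicates_per_sample=3,
        spectra_per_mapping=80, seed=seed,
    )
    kwargs.update(overrides)
    return CohortDesign(**kwargs)


def diagnosis_study_design(seed: int = 0, **overrides) -> CohortDesign:
    """The 26-sample diagnosis cohort: 8 normal, 9 dementia, 5 FAD carriers
    and 4 FAD non-carriers, one mapping of 80 spectra per sample."""
    kwargs = dict(
        classes=tuple(diagnosis_templates()),
        samples_per_class={"normal": 8, "dementia": 9, "fad_pos": 5, "fad_neg": 4},
        replicates_per_sample=1,
        spectra_per_mapping=80,
        seed=seed,
    )
    kwargs.update(overrides)
    return CohortDesign(**kwargs)


# ---------------------------------------------------------------------------
# spectra

def _lorentzian(grid: np.ndarray, center: float, hwhm: float) -> np.ndarray:
    return hwhm**2 / ((grid - center) ** 2 + hwhm**2)


def _baseline(grid: np.ndarray, coeffs) -> np.ndarray:
    u = (grid - grid[0]) / (grid[-1] - grid[0])
    return np.polynomial.polynomial.polyval(u, np.asarray(coeffs, dtype=float))


def simulate_spectrum(
    template: ClassTemplate,
    peaks,
    sample_effect,
    noise_sd: float = 0.0,
    baseline_coeffs=(0.0,),
    rng: np.random.Generator | None = None,
    grid: np.ndarray | None = None,
    meta: dict | None = None,
) -> Spectrum:
    """Draw one noisy SERS spectrum from the generative model.

    intensity(v) = baseline(v)
                 + sum_k base_amplitude_k * multiplier_k * effect_k * L_k(v)
                 + eps(v),  eps ~ N(0, noise_sd^2) iid.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    grid = canonical_grid() if grid is None else np.asarray(grid, dtype=float)
    sample_effect = np.asarray(sample_effect, dtype=float)
    intensity = _baseline(grid, baseline_coeffs).copy()
    for peak, mult, eff in zip(peaks, template.amplitude_multipliers, sample_effect):
        intensity += peak.base_amplitude * mult * eff * _lorentzian(grid, peak.center, peak.width)
    if noise_sd > 0:
        if rng is None:
            raise ValueError("rng required when noise_sd > 0")
        intensity = intensity + rng.normal(0.0, noise_sd, size=grid.size)
    return Spectrum(grid, intensity, dict(meta or {}, label=template.label))


# ---------------------------------------------------------------------------
# clinical covariates

def calibrate_tau_link_noise(
    class_weights: dict[str, float], target_r: float = TAU_TARGET_R
) -> float:
    """Noise SD for the tau link giving pooled corr(T, P) = ``target_r``.

    With P = b*T + c + eps, r = b*sd(T) / sqrt(b^2 var(T) + var(eps)), so
    sd(eps) = b * sd(T) * sqrt(1/r^2 - 1).  var(T) is the mixture variance
    over the class mix (law of total variance on the per-class t-tau
    normals), ignoring the positivity clamp.
    """
    total = sum(class_weights.values())
    w = {k: v / total for k, v in class_weights.items()}
    mean_t = sum(w[k] * CLINICAL_PROFILES[k]["t_tau"][0] for k in w)
    var_t = sum(
        w[k] * (CLINICAL_PROFILES[k]["t_tau"][1] ** 2
                + (CLINICAL_PROFILES[k]["t_tau"][0] - mean_t) ** 2)
        for k in w
    )
    return TAU_SLOPE * math.sqrt(var_t) * math.sqrt(1.0 / target_r**2 - 1.0)


def _round_half(x: float) -> float:
    return round(x * 2.0) / 2.0


def simulate_clinical(
    label: str,
    severity: float,
    rng: np.random.Generator,
    sample_id: str = "S0",
    tau_link_noise_sd: float | None = None,
    t_tau_missing: bool = False,
) -> ClinicalRecord:
    """Draw one clinical record for a subject of class ``label``.

    ``severity`` in [0, 1] is the latent disease-burden score: the cognitive
    scores are deterministic monotone functions of it (MMSE decreasing,
    CDRSUM/CDRGLOB increasing) through the probit quantile of the class
    distribution, so a severity ~ Uniform(0,1) cohort reproduces the class
    means/SDs while keeping score-vs-severity correlations plantable.
    Biomarkers are drawn from the class Gaussians, clamped to >= 1 pg/mL;
    p-tau follows the linear t-tau link plus calibrated noise.
    """
    if label not in LABELS:
        raise ValueError(f"unknown label {label!r}")
    if not 0.0 <= severity <= 1.0:
        raise ValueError("severity must be in [0, 1]")
    prof = CLINICAL_PROFILES[label]
    if tau_link_noise_sd is None:
        tau_link_noise_sd = calibrate_tau_link_noise({label: 1.0})

    from scipy.stats import norm

    z = norm.ppf(np.clip(severity, 1e-4, 1 - 1e-4))
    mmse = int(np.clip(round(prof["mmse"][0] - prof["mmse"][1] * z), 0, 30))
    cdr_sum = float(np.clip(_round_half(prof["cdr_sum"][0] + prof["cdr_sum"][1] * z), 0, 18))
    cdr_glob = float(np.clip(_round_half(prof["cdr_glob"][0] + prof["cdr_glob"][1] * z), 0, 3))

    age = float(np.clip(rng.normal(*prof["age"]), 18, 100))
    abeta42 = float(np.maximum(rng.normal(*prof["abeta42"]), 1.0))
    t_tau = float(np.maximum(rng.normal(*prof["t_tau"]), 1.0))
    p_tau = float(
        np.maximum(TAU_SLOPE * t_tau + TAU_INTERCEPT + rng.normal(0.0, tau_link_noise_sd), 1.0)
    )
    adjusted_age = (
        float(rng.normal(*prof["adjusted_age"])) if prof["adjusted_age"] else None
    )
    sex = "M" if rng.random() < prof["male_frac"] else "F"

    return ClinicalRecord(
        sample_id=sample_id,
        label=label,
        sex=sex,
        age=age,
        adjusted_age=adjusted_age,
        abeta42=abeta42,
        t_tau=None if t_tau_missing else t_tau,
        p_tau=p_tau,
        mmse=mmse,
        cdr_sum=cdr_sum,
        cdr_glob=cdr_glob,
    )


# ---------------------------------------------------------------------------
# cohorts

def simulate_cohort(design: CohortDesign):
    """Generate a full cohort.

    Returns ``(groups, records, severities)``: one :class:`MappingGroup` per
    sample x replicate (sample_id, then ``sample_id + "_r<k>"`` when there
    are several replicates), one :class:`ClinicalRecord` per sample, and the
    per-sample latent severity (dict sample_id -> float) so tests can check
    recovery of planted structure.

    The per-sample amplitude-effect vector (one lognormal factor per band,
    CV = ``sample_cv``) is drawn once per sample and shared by all of its
    replicate mappings; spectra within a mapping differ only by noise.
    """
    rng = np.random.default_rng(design.seed)
    # abstract spectral classes (e.g. the blinded-replicate sets) have no
    # clinical profile of their own; their subjects draw covariates from the
    # normal profile
    clin_label = {
        t.label: (t.label if t.label in LABELS else "normal") for t in design.classes
    }
    weights: dict[str, float] = {}
    for t in design.classes:
        weights[clin_label[t.label]] = weights.get(clin_label[t.label], 0.0) + float(
            design.n_samples_for(t.label)
        )
    tau_noise = calibrate_tau_link_noise(weights)
    sigma = math.sqrt(math.log(1.0 + design.sample_cv**2)) if design.sample_cv > 0 else 0.0

    groups: list[MappingGroup] = []
    records: list[ClinicalRecord] = []
    severities: dict[str, float] = {}
    counter = 0
    for template in design.classes:
        for s in range(design.n_samples_for(template.label)):
            counter += 1
            sample_id = f"{template.label}_{s + 1:02d}"
            severity = float(rng.uniform())
            severities[sample_id] = severity
            effect = (
                rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=len(design.peaks))
                if sigma > 0
                else np.ones(len(design.peaks))
            )
            missing = bool(rng.random() < design.t_tau_missing_rate)
            records.append(
                simulate_clinical(
                    clin_label[template.label], severity, rng,
                    sample_id=sample_id,
                    tau_link_noise_sd=tau_noise,
                    t_tau_missing=missing,
                )
            )
            for r in range(design.replicates_per_sample):
                gid = (
                    sample_id
                    if design.replicates_per_sample == 1
                    else f"{sample_id}_r{r + 1}"
                )
                spectra = [
                    simulate_spectrum(
                        template, design.peaks, effect,
                        noise_sd=design.spectrum_noise_sd,
                        baseline_coeffs=design.baseline_coeffs,
                        rng=rng,
                        meta={"sample_id": gid, "site": k},
                    )
                    for k in range(design.spectra_per_mapping)
                ]
                groups.append(MappingGroup(gid, spectra))
    return groups, records, severities
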