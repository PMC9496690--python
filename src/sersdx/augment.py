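"""Training-set augmentation for grouped SERS spectra.

Three operators, applied only to training folds and always within one
mapping group:

(i)   random shift of a spectrum by one or two wavenumber steps (an integer
      index shift on the canonical 1 cm^-1 grid, edges replicated);
(ii)  additive Gaussian noise scaled to a fraction of the spectrum's own
      intensity SD;
(iii) random convex combinations of spectra drawn from the same mapping.

Every synthetic spectrum inherits its source group's label and group id and
carries provenance metadata (operator, parameters, source sites), so the
no-cross-group-mixing contract is auditable after the fact.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .spectra_io import MappingGroup, Spectrum

__all__ = [
    "AugmentConfig",
    "shift_spectrum",
    "add_noise",
    "combine_within_group",
    "augment_dataset",
    "GroupIntegrityError",
]


class GroupIntegrityError(ValueError):
    """Raised when an operation would mix spectra across mapping groups."""


@dataclass(frozen=True)
class AugmentConfig:
    """Augmentation tunables.

    max_shift
        Largest wavenumber shift in grid steps; shifts are drawn uniformly
        from {-max_shift, ..., -1, 1, ..., max_shift}.
    noise_sd_frac
        Noise SD as a fraction of each spectrum's intensity SD.
    combo_components
        Spectra entering each convex combination (weights ~ flat Dirichlet).
    augment_factor
        Output/input size ratio; 1 returns the originals only.
    convex_only
        If False, combination weights may be any reals summing to 1
        (general linear combinations) instead of convex ones.
    """

    max_shift: int = 2
    noise_sd_frac: float = 0.05
    combo_components: int = 2
    augment_factor: float = 2.0
    convex_only: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.max_shift < 1:
            raise ValueError("max_shift must be >= 1")
        if self.noise_sd_frac < 0:
            raise ValueError("noise_sd_frac must be >= 0")
        if self.combo_components < 2:
            raise ValueError("combo_components must be >= 2")
        if self.augment_factor < 1:
            raise ValueError("augment_factor must be >= 1")


def shift_spectrum(spectrum: Spectrum, shift: int, max_shift: int = 2) -> Spectrum:
    """Translate intensities by ``shift`` index positions on the grid.

    Positive shifts move features toward higher wavenumbers.  Vacated edge
    positions are filled by replicating the edge value, so no artificial
    zero-step appears at the range ends.
    """
    if abs(shift) > max_shift:
        raise ValueError(f"|shift| = {abs(shift)} exceeds max_shift = {max_shift}")
    y = spectrum.intensities
    if shift == 0:
        out = y.copy()
    elif shift > 0:
        out = np.concatenate([np.full(shift, y[0]), y[:-shift]])
    else:
        out = np.concatenate([y[-shift:], np.full(-shift, y[-1])])
    return spectrum.with_intensities(out, augment_op="shift", augment_shift=shift)


def add_noise(
    spectrum: Spectrum, noise_sd_frac: float, rng: np.random.Generator
) -> Spectrum:
    """Add iid Gaussian noise with SD = noise_sd_frac * SD(intensities)."""
    if noise_sd_frac < 0:
        raise ValueError("noise_sd_frac must be >= 0")
    if noise_sd_frac == 0:
        return spectrum.with_intensities(spectrum.intensities.copy(), augment_op="noise")
    sd = noise_sd_frac * float(np.std(spectrum.intensities))
    noisy = spectrum.intensities + rng.normal(0.0, sd, size=len(spectrum))
    return spectrum.with_intensities(noisy, augment_op="noise", augment_noise_sd=sd)


def combine_within_group(
    group: MappingGroup,
    weights: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
    n_components: int = 2,
    convex_only: bool = True,
) -> Spectrum:
    """Convex (or general linear) combination of spectra from ONE mapping.

    Components are sampled without replacement from the group; weights sum
    to 1, drawn from a flat Dirichlet when not given.  Combining spectra
    across groups is structurally impossible here — the operator takes a
    single :class:`MappingGroup`.
    """
    if weights is not None:
        weights = np.asarray(weights, dtype=float)
        n_components = weights.size
    if n_components > len(group):
        raise GroupIntegrityError(
            f"cannot draw {n_components} components from group of {len(group)}"
        )
    if weights is None:
        if rng is None:
            raise ValueError("rng required when weights are not given")
        if convex_only:
            weights = rng.dirichlet(np.ones(n_components))
        else:
            raw = rng.normal(1.0, 0.5, size=n_components)
            weights = raw / raw.sum()
    else:
        if convex_only and np.any(weights < 0):
            raise ValueError("convex combination requires nonnegative weights")
        if not np.isclose(weights.sum(), 1.0):
            raise ValueError("weights must sum to 1")
    if rng is None:
        idx = np.arange(n_components)
    else:
        idx = rng.choice(len(group), size=n_components, replace=False)
    mix = np.zeros_like(group.spectra[0].intensities)
    for w, i in zip(weights, idx):
        mix = mix + w * group.spectra[i].intensities
    return Spectrum(
        group.grid,
        mix,
        {
            "sample_id": group.sample_id,
            "augment_op": "combine",
            "augment_sources": tuple(int(i) for i in idx),
            "augment_weights": tuple(float(w) for w in weights),
        },
    )


def augment_dataset(
    groups: list[MappingGroup],
    labels: dict[str, str],
    config: AugmentConfig = AugmentConfig(),
):
    """Originals plus synthetic spectra, up to augment_factor x the input.

    For each synthetic spectrum one operator is chosen uniformly among
    shift / noise / within-group combination, applied to (spectra of) a
    uniformly chosen group.  Returns ``(spectra, spec_labels, group_ids)``
    aligned lists; synthetic spectra carry their source group's label/id and
    provenance metadata.
    """
    rng = np.random.default_rng(config.seed)
    spectra: list[Spectrum] = []
    spec_labels: list[str] = []
    group_ids: list[str] = []
    for g in groups:
        if g.sample_id not in labels:
            raise ValueError(f"no label for group {g.sample_id!r}")
        for s in g.spectra:
            spectra.append(s)
            spec_labels.append(labels[g.sample_id])
            group_ids.append(g.sample_id)
    n_original = len(spectra)
    n_extra = int(round((config.augment_factor - 1.0) * n_original))
    shifts = np.concatenate(
        [np.arange(-config.max_shift, 0), np.arange(1, config.max_shift + 1)]
    )
    for _ in range(n_extra):
        g = groups[int(rng.integers(len(groups)))]
        op = int(rng.integers(3))
        if op == 0:
            src = g.spectra[int(rng.integers(len(g)))]
            syn = shift_spectrum(src, int(rng.choice(shifts)), config.max_shift)
        elif op == 1:
            src = g.spectra[int(rng.integers(len(g)))]
            syn = add_noise(src, config.noise_sd_frac, rng)
        else:
            syn = combine_within_group(
                g, rng=rng,
                n_components=min(config.combo_components, len(g)),
                convex_only=config.convex_only,
            )
        syn = syn.with_intensities(syn.intensities, sample_id=g.sample_id, synthetic=True)
        spectra.append(syn)
        spec_labels.append(labels[g.sample_id])
        group_ids.append(g.sample_id)
    return spectra, spec_labels, group_ids
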