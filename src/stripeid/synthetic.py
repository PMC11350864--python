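"""Synthetic striped-individual generator.

Each synthetic individual carries a unique, pose-stable stripe texture: a
sum of 3-5 oriented sinusoidal bands, thresholded at zero, rendered as
dark stripes on an orange body mask over a textured background.  Three
part views are produced per individual — the left flank, the right flank
(the same pattern mirrored), and a face (the pattern at double frequency
inside a smaller circular mask) — each under per-image nuisance variation
(brightness, Gaussian blur, placement jitter).

Determinism: every record's nuisance stream is seeded by
``SeedSequence([master_seed, record_index])``, so datasets are
byte-identical across runs for a fixed master seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .preprocessing import PARTS, ImageRecord

__all__ = ["SyntheticConfig", "Individual", "make_individual", "render_part",
           "generate_dataset"]


@dataclass
class SyntheticConfig:
    n_individuals: int = 12
    images_per_part: int = 10
    image_size: int = 96
    stripe_frequency: tuple[float, float] = (4.0, 9.0)
    stripe_orientation: tuple[float, float] = (60.0, 120.0)  # degrees
    brightness_jitter: float = 0.15     # multiplicative, 1 +/- this
    blur_max: float = 0.8               # Gaussian sigma upper bound, pixels
    jitter: int = 3                     # body placement jitter, pixels
    noise_sigma: float = 4.0            # per-pixel sensor noise, gray levels
    seed: int = 0

    def __post_init__(self):
        if self.n_individuals < 2:
            raise ValueError("need at least 2 individuals")
        if self.images_per_part < 1:
            raise ValueError("images_per_part must be at least 1")
        if self.stripe_frequency[0] <= 0:
            raise ValueError("stripe frequencies must be positive")

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticConfig":
        unknown = set(d) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown synth config keys: {sorted(unknown)}")
        for key in ("stripe_frequency", "stripe_orientation"):
            if key in d:
                d = dict(d, **{key: tuple(d[key])})
        return cls(**d)


@dataclass
class Individual:
    """Stripe parameter set defining one individual's texture."""

    seed: int
    frequencies: np.ndarray   # cycles across the body, one per band system
    orientations: np.ndarray  # radians
    phases: np.ndarray
    amplitudes: np.ndarray
    body_aspect: float        # flank ellipse height/width ratio
    body_tone: np.ndarray     # base coat color, RGB in [0, 255]


def make_individual(individual_seed: int,
                    cfg: SyntheticConfig | None = None) -> Individual:
    """Deterministic stripe parameters for one individual."""
    cfg = cfg or SyntheticConfig()
    rng = np.random.default_rng(np.random.SeedSequence([2 ** 20, individual_seed]))
    n_waves = int(rng.integers(3, 6))
    f_lo, f_hi = cfg.stripe_frequency
    o_lo, o_hi = np.deg2rad(cfg.stripe_orientation)
    coat = np.array([210, 120, 30], dtype=float) + rng.uniform(-25, 25, size=3)
    return Individual(
        seed=individual_seed,
        frequencies=rng.uniform(f_lo, f_hi, size=n_waves),
        orientations=rng.uniform(o_lo, o_hi, size=n_waves),
        phases=rng.uniform(0, 2 * np.pi, size=n_waves),
        amplitudes=rng.uniform(0.5, 1.0, size=n_waves),
        body_aspect=float(rng.uniform(0.55, 0.75)),
        body_tone=np.clip(coat, 0, 255),
    )


def _stripe_field(ind: Individual, u, v):
    """Signed band field; stripes are the field's negative set."""
    s = np.zeros_like(u)
    for f, th, ph, a in zip(ind.frequencies, ind.orientations, ind.phases,
                            ind.amplitudes):
        s += a * np.sin(2 * np.pi * f * (u * np.cos(th) + v * np.sin(th)) + ph)
    return s


def render_part(ind: Individual, part: str, nuisance_seed=None,
                cfg: SyntheticConfig | None = None) -> ImageRecord:
    """Render one 8-bit RGB part view of an individual.

    ``nuisance_seed=None`` renders the noiseless canonical view — a pure
    function of (individual, part).
    """
    cfg = cfg or SyntheticConfig()
    if part not in PARTS:
        raise ValueError(f"part must be one of {PARTS}, got {part!r}")
    n = cfg.image_size
    rng = (np.random.default_rng(nuisance_seed)
           if nuisance_seed is not None else None)

    dx = dy = 0.0
    if rng is not None and cfg.jitter > 0:
        dx, dy = rng.uniform(-cfg.jitter, cfg.jitter, size=2) / n

    yy, xx = np.meshgrid(np.linspace(0, 1, n), np.linspace(0, 1, n),
                         indexing="ij")
    u, v = xx - 0.5 - dx, yy - 0.5 - dy
    if part == "right":        # mirrored flank view of the same pattern
        u = -u
    if part == "face":         # distinct masked region, finer texture
        mask = u ** 2 + v ** 2 <= 0.33 ** 2
        field = _stripe_field(ind, 2 * u, 2 * v)
    else:
        mask = (u / 0.46) ** 2 + (v / (0.46 * ind.body_aspect)) ** 2 <= 1.0
        field = _stripe_field(ind, u, v)
    stripes = mask & (field < -0.25)

    # textured background from the individual-independent part of the seed
    bg_rng = np.random.default_rng(np.random.SeedSequence([2 ** 21, ind.seed,
                                                           PARTS.index(part)]))
    bg = 150 + 40 * gaussian_filter(bg_rng.standard_normal((n, n)), 4.0)
    img = np.repeat(bg[:, :, None], 3, axis=2)
    img[:, :, 1] *= 0.95   # slightly green-grey backdrop
    img[mask] = ind.body_tone
    img[stripes] = (25.0, 20.0, 15.0)

    if rng is not None:
        if cfg.noise_sigma > 0:
            img += rng.normal(0, cfg.noise_sigma, size=img.shape)
        factor = 1.0 + rng.uniform(-cfg.brightness_jitter, cfg.brightness_jitter)
        img *= factor
        sigma = rng.uniform(0.0, cfg.blur_max)
        if sigma > 0.05:
            img = np.stack([gaussian_filter(img[..., c], sigma)
                            for c in range(3)], axis=-1)
    pixels = np.clip(np.round(img), 0, 255).astype(np.uint8)
    return ImageRecord(pixels=pixels, individual_id=f"ind{ind.seed:03d}",
                       part=part, source="synthetic")


def generate_dataset(cfg: SyntheticConfig) -> list[ImageRecord]:
    """n_individuals x 3 parts x images_per_part records, fully seeded."""
    individuals = [make_individual(i, cfg) for i in range(cfg.n_individuals)]
    records = []
    index = 0
    for ind in individuals:
        for part in PARTS:
            for _ in range(cfg.images_per_part):
                seed = np.random.SeedSequence([cfg.seed, index])
                records.append(render_part(ind, part, nuisance_seed=seed,
                                           cfg=cfg))
                index += 1
    return records
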