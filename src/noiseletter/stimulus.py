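"""Synthesis of luminance-modulated (LM) and contrast-modulated (CM) noise letters.

A stimulus is one of the optotypes H, O, T, V, drawn on a 5x5 stroke grid
(stroke width = one fifth of letter height) and embedded in a binary +/-1
check-noise carrier.  Every rendered pixel obeys

    I(x, y) = I_mean * [1 + n*N(x,y) + l*L(x,y) + m*n*M(x,y)*N(x,y)]

where ``N`` is the noise check value (-1 or +1), ``L`` and ``M`` are the
square-wave luminance- and contrast-modulation supports of the letter, ``n``
is the carrier (noise) contrast, ``l`` the luminance amplitude (non-zero only
for LM letters) and ``m`` the contrast amplitude (non-zero only for CM
letters).  An LM letter differs from its background in mean luminance; a CM
letter has the same expected luminance as the background everywhere and is
defined purely by a local-contrast increment: inside the letter the carrier
contrast is ``n*(1+m)`` instead of ``n``.

Noise is refreshed independently on every movie frame, so any single-frame
luminance clumping averages out over time.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "LETTERS",
    "StimulusSpec",
    "LetterTemplate",
    "NoiseField",
    "StimulusFrame",
    "StimulusMovie",
    "LuminanceReport",
    "make_letter_template",
    "sample_noise",
    "render_frame",
    "render_movie",
    "check_mean_luminance",
    "quantize_8bit",
    "save_frame_png",
]

#: Fixed response-alternative order; ties in any argmax are broken this way.
LETTERS = ("H", "O", "T", "V")

# Canonical 5x5 stroke grids (1 = ink).  Row 0 is the top of the letter.
# These are square-grid letterforms in the Sloan tradition: stroke width is
# exactly one cell, i.e. one fifth of the letter's height and width.
_STROKE_GRIDS: dict[str, tuple[tuple[int, ...], ...]] = {
    "H": (
        (1, 0, 0, 0, 1),
        (1, 0, 0, 0, 1),
        (1, 1, 1, 1, 1),
        (1, 0, 0, 0, 1),
        (1, 0, 0, 0, 1),
    ),
    "O": (
        (1, 1, 1, 1, 1),
        (1, 0, 0, 0, 1),
        (1, 0, 0, 0, 1),
        (1, 0, 0, 0, 1),
        (1, 1, 1, 1, 1),
    ),
    "T": (
        (1, 1, 1, 1, 1),
        (0, 0, 1, 0, 0),
        (0, 0, 1, 0, 0),
        (0, 0, 1, 0, 0),
        (0, 0, 1, 0, 0),
    ),
    "V": (
        (1, 0, 0, 0, 1),
        (1, 0, 0, 0, 1),
        (0, 1, 0, 1, 0),
        (0, 1, 0, 1, 0),
        (0, 0, 1, 0, 0),
    ),
}


@dataclass(frozen=True)
class StimulusSpec:
    """Physical parameters of a noise-letter stimulus.

    Parameters
    ----------
    mean_luminance : float
        Mean (background) luminance ``I``.  Images are generated in
        normalized linear luminance, so the default is 1.0 and all pixels lie
        in ``[0, 2*I]``.
    noise_contrast : float
        Carrier contrast ``n`` in [0, 1]; 0.2 by default.
    luminance_amplitude : float
        ``l``; must be 0 for CM stimuli.
    contrast_amplitude : float
        ``m``; must be 0 for LM stimuli.
    stimulus_type : str
        ``"LM"`` or ``"CM"``.
    bipolar_modulation : bool
        If True the square waves L, M take values -1 (background) / +1
        (letter) instead of 0 / +1.  Off by default: the unipolar convention
        keeps the background statistics identical for LM and CM stimuli.
    """

    stimulus_type: str
    mean_luminance: float = 1.0
    noise_contrast: float = 0.2
    luminance_amplitude: float = 0.0
    contrast_amplitude: float = 0.0
    bipolar_modulation: bool = False

    def __post_init__(self) -> None:
        if self.stimulus_type not in ("LM", "CM"):
            raise ValueError(
                f"stimulus_type must be 'LM' or 'CM', got {self.stimulus_type!r}"
            )
        if self.mean_luminance <= 0:
            raise ValueError("mean_luminance must be positive")
        if not 0.0 <= self.noise_contrast <= 1.0:
            raise ValueError(
                f"noise_contrast must lie in [0, 1], got {self.noise_contrast}"
            )
        if self.stimulus_type == "LM" and self.contrast_amplitude != 0.0:
            raise ValueError("LM stimuli require contrast_amplitude m = 0")
        if self.stimulus_type == "CM" and self.luminance_amplitude != 0.0:
            raise ValueError("CM stimuli require luminance_amplitude l = 0")
        l, n, m = self.luminance_amplitude, self.noise_contrast, self.contrast_amplitude
        if abs(l) + n * (1.0 + abs(m)) > 1.0 + 1e-12:
            raise ValueError(
                "luminance out of gamut: require |l| + n*(1+|m|) <= 1, got "
                f"l={l}, n={n}, m={m}"
            )

    @classmethod
    def lm(cls, luminance_amplitude: float = 0.3, **kwargs) -> "StimulusSpec":
        """A luminance-modulated spec with the default amplitude l = 0.3."""
        return cls("LM", luminance_amplitude=luminance_amplitude, **kwargs)

    @classmethod
    def cm(cls, contrast_amplitude: float = 1.0, **kwargs) -> "StimulusSpec":
        """A contrast-modulated spec with the default amplitude m = 1.0."""
        return cls("CM", contrast_amplitude=contrast_amplitude, **kwargs)


@dataclass(frozen=True)
class LetterTemplate:
    """Binary support of an optotype on the stroke grid and at check resolution."""

    letter: str
    stroke_grid: np.ndarray
    check_grid: np.ndarray
    checks_per_stroke: int

    @property
    def side_checks(self) -> int:
        return self.check_grid.shape[0]

    @property
    def ink_fraction(self) -> float:
        return float(self.check_grid.mean())


@dataclass(frozen=True)
class NoiseField:
    """A binary +/-1 check field; each check renders as a constant square block."""

    values: np.ndarray
    check_size_px: int
    seed: object
    frame_index: int = 0

    @property
    def shape_checks(self) -> tuple[int, int]:
        return self.values.shape

    def to_pixels(self) -> np.ndarray:
        cs = self.check_size_px
        return np.kron(self.values, np.ones((cs, cs)))


@dataclass(frozen=True)
class StimulusFrame:
    """One rendered frame: pixel luminances plus everything needed to rebuild it."""

    image: np.ndarray
    spec: StimulusSpec
    template: LetterTemplate
    noise: NoiseField
    check_image: np.ndarray
    letter_mask: np.ndarray  # bool, check resolution: True inside letter ink

    @property
    def check_size_px(self) -> int:
        return self.noise.check_size_px


@dataclass(frozen=True)
class StimulusMovie:
    """An ordered sequence of frames sharing spec and template."""

    frames: tuple[StimulusFrame, ...]
    frame_rate_hz: float = 60.0

    @property
    def spec(self) -> StimulusSpec:
        return self.frames[0].spec

    @property
    def template(self) -> LetterTemplate:
        return self.frames[0].template

    def __len__(self) -> int:
        return len(self.frames)


def make_letter_template(letter: str, checks_per_stroke: int = 3) -> LetterTemplate:
    """Build the binary support of an optotype.

    The letter is drawn on a 5x5 stroke grid (stroke width one fifth of
    letter size) and expanded by nearest-neighbour replication so that each
    stroke cell becomes a ``checks_per_stroke`` x ``checks_per_stroke`` block
    of noise checks (default 3, i.e. a 15x15-check letter).
    """
    if letter not in _STROKE_GRIDS:
        raise ValueError(f"unknown letter {letter!r}; valid letters are {LETTERS}")
    if checks_per_stroke < 1:
        raise ValueError("checks_per_stroke must be >= 1")
    stroke = np.array(_STROKE_GRIDS[letter], dtype=np.int8)
    check = np.kron(stroke, np.ones((checks_per_stroke, checks_per_stroke), dtype=np.int8))
    stroke.setflags(write=False)
    check.setflags(write=False)
    return LetterTemplate(letter, stroke, check, checks_per_stroke)


def sample_noise(
    n_checks_y: int, n_checks_x: int, check_size_px: int = 1, seed=0, frame_index: int = 0
) -> NoiseField:
    """Draw an i.i.d. equiprobable +/-1 check field; same seed, same field."""
    if n_checks_y < 1 or n_checks_x < 1:
        raise ValueError("noise field dimensions must be >= 1")
    if check_size_px < 1:
        raise ValueError("check_size_px must be >= 1")
    rng = np.random.default_rng(seed)
    values = rng.integers(0, 2, size=(n_checks_y, n_checks_x)).astype(np.int8) * 2 - 1
    values.setflags(write=False)
    return NoiseField(values, check_size_px, seed, frame_index)


def _support_maps(template: LetterTemplate, noise: NoiseField, bipolar: bool):
    """Letter modulation support L (= M) on the full noise-check grid."""
    ny, nx = noise.shape_checks
    ly, lx = template.check_grid.shape
    if ny < ly or nx < lx:
        raise ValueError(
            f"noise field {ny}x{nx} checks is smaller than the letter "
            f"({ly}x{lx} checks); enlarge the field"
        )
    oy, ox = (ny - ly) // 2, (nx - lx) // 2
    mask = np.zeros((ny, nx), dtype=bool)
    mask[oy : oy + ly, ox : ox + lx] = template.check_grid.astype(bool)
    support = np.where(mask, 1.0, -1.0 if bipolar else 0.0)
    return support, mask


def render_frame(
    spec: StimulusSpec, template: LetterTemplate, noise: NoiseField
) -> StimulusFrame:
    """Render one frame: ``I * (1 + n*N + l*L + m*n*M*N)`` pixel by pixel.

    The letter is centred in the noise field; surrounding checks are
    carrier-only background.
    """
    support, mask = _support_maps(template, noise, spec.bipolar_modulation)
    I = spec.mean_luminance
    n = spec.noise_contrast
    l = spec.luminance_amplitude
    m = spec.contrast_amplitude
    N = noise.values.astype(float)
    check_image = I * (1.0 + n * N + l * support + m * n * support * N)
    lo, hi = check_image.min(), check_image.max()
    if lo < -1e-12 or hi > 2.0 * I + 1e-12:
        raise ValueError(
            f"rendered luminance outside [0, 2I]: range [{lo:.6g}, {hi:.6g}] "
            f"for (l={l}, n={n}, m={m})"
        )
    cs = noise.check_size_px
    image = np.kron(check_image, np.ones((cs, cs)))
    image.setflags(write=False)
    check_image.setflags(write=False)
    mask.setflags(write=False)
    return StimulusFrame(image, spec, template, noise, check_image, mask)


def render_movie(
    spec: StimulusSpec,
    template: LetterTemplate,
    n_frames: int,
    seed=0,
    frame_rate_hz: float = 60.0,
    field_checks: tuple[int, int] | None = None,
    check_size_px: int = 1,
) -> StimulusMovie:
    """Render a dynamic-noise movie: frames differ only in their noise field.

    Per-frame noise seeds are spawned deterministically from ``seed`` so that
    frames are mutually independent yet the whole movie is reproducible.  By
    default the noise field side is twice the letter side (in checks).
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    if field_checks is None:
        side = 2 * template.side_checks
        field_checks = (side, side)
    root = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    frames = []
    for i, child in enumerate(root.spawn(n_frames)):
        noise = sample_noise(field_checks[0], field_checks[1], check_size_px, child, i)
        frames.append(render_frame(spec, template, noise))
    return StimulusMovie(tuple(frames), frame_rate_hz)


@dataclass(frozen=True)
class LuminanceReport:
    """Spatio-temporal mean luminance inside and outside the letter support."""

    letter_region_mean: float
    background_mean: float
    expected_letter: float
    expected_background: float
    se_letter: float
    se_background: float
    tolerance_pass: bool


def check_mean_luminance(movie: StimulusMovie, k: float = 3.0) -> LuminanceReport:
    """Mean-luminance artefact check.

    Averages luminance over checks and frames, separately for the letter
    support and the background, and compares each with its ensemble
    expectation (``I`` for CM everywhere; ``I*(1+l)`` in the letter for LM).
    Statistical units are independent check-frame samples, so the standard
    error uses the per-check sample s.d., not the (correlated) pixel count.
    """
    spec = movie.spec
    I = spec.mean_luminance
    s_letter = 1.0
    s_background = -1.0 if spec.bipolar_modulation else 0.0
    expected_letter = I * (1.0 + spec.luminance_amplitude * s_letter)
    expected_background = I * (1.0 + spec.luminance_amplitude * s_background)

    letter_samples = np.concatenate(
        [f.check_image[f.letter_mask] for f in movie.frames]
    )
    background_samples = np.concatenate(
        [f.check_image[~f.letter_mask] for f in movie.frames]
    )

    def _mean_se(x: np.ndarray) -> tuple[float, float]:
        se = float(x.std(ddof=1) / np.sqrt(x.size)) if x.size > 1 else 0.0
        return float(x.mean()), se

    m_let, se_let = _mean_se(letter_samples)
    m_bg, se_bg = _mean_se(background_samples)
    ok = abs(m_let - expected_letter) <= k * se_let + 1e-12 and abs(
        m_bg - expected_background
    ) <= k * se_bg + 1e-12
    return LuminanceReport(m_let, m_bg, expected_letter, expected_background, se_let, se_bg, ok)


def quantize_8bit(image: np.ndarray, mean_luminance: float = 1.0) -> np.ndarray:
    """Optional 8-bit quantization: round to the nearest of 256 levels on [0, 2I]."""
    levels = np.rint(np.clip(image / (2.0 * mean_luminance), 0.0, 1.0) * 255.0)
    return levels.astype(np.uint8)


def save_frame_png(frame: StimulusFrame, path: str | Path, metadata: bool = True) -> Path:
    """Write an 8-bit grayscale PNG plus a JSON sidecar with the generation metadata."""
    from PIL import Image

    path = Path(path)
    img = quantize_8bit(frame.image, frame.spec.mean_luminance)
    Image.fromarray(img, mode="L").save(path)
    if metadata:
        meta = {
            "stimulus_type": frame.spec.stimulus_type,
            "mean_luminance": frame.spec.mean_luminance,
            "noise_contrast": frame.spec.noise_contrast,
            "luminance_amplitude": frame.spec.luminance_amplitude,
            "contrast_amplitude": frame.spec.contrast_amplitude,
            "bipolar_modulation": frame.spec.bipolar_modulation,
            "letter": frame.template.letter,
            "checks_per_stroke": frame.template.checks_per_stroke,
            "check_size_px": frame.noise.check_size_px,
            "seed": repr(frame.noise.seed),
            "frame_index": frame.noise.frame_index,
        }
        path.with_suffix(".json").write_text(json.dumps(meta, indent=2))
    return path
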