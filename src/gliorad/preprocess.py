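"""Channel derivation, intensity quantization, and VOI validation.

Raw T1, T2 and Gd-enhanced T1 volumes are turned into the five analysis
channels (T1, T2, GdT1, T2Edge, Gdzscore), each re-allocated to 256 gray
levels, and bundled with the core / edema masks into a validated
:class:`Study` ready for feature extraction.

Quantization follows the acquisition protocol of the source analysis:
T2 is rescaled over its full intensity range; T1 and GdT1 first have their
top 0.1% of intensities clipped as high-signal noise.  The two derived
channels are constructions chosen for their names' plain meaning — T2Edge
is the spacing-aware gradient magnitude of T2, Gdzscore the whole-volume
z-score of GdT1 — and are isolated here so they can be swapped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

CHANNELS = ("T1", "T2", "GdT1", "T2Edge", "Gdzscore")
VOIS = ("core", "edema")

N_GRAY_LEVELS = 256


class ValidationError(ValueError):
    """Raised when a volume or mask fails study-level validation."""


@dataclass
class RawChannel:
    """A real-valued 3D volume with voxel spacing in mm."""

    values: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    modality: str = "T2"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3 or self.values.size == 0:
            raise ValidationError("channel must be a nonempty 3D array")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("channel contains non-finite voxels")
        if any(s <= 0 for s in self.spacing):
            raise ValidationError("voxel spacing must be positive")


@dataclass
class QuantizedVolume:
    """Integer volume on gray levels 0..255 plus the range used to rescale."""

    levels: np.ndarray
    channel: str
    source_range: tuple[float, float]

    def __post_init__(self) -> None:
        lv = np.asarray(self.levels)
        if lv.min(initial=0) < 0 or lv.max(initial=0) > N_GRAY_LEVELS - 1:
            raise ValidationError("levels outside 0..255")


@dataclass
class VoiMask:
    """Binary volume of interest; ``label`` is ``core`` or ``edema``."""

    mask: np.ndarray
    label: str = "core"

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 3:
            raise ValidationError(f"mask '{self.label}' must be 3D")

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


def _rescale_to_levels(values: np.ndarray) -> tuple[np.ndarray, tuple[float, float]]:
    lo = float(values.min())
    hi = float(values.max())
    if hi == lo:
        # degenerate (constant) volume: map to level 0 rather than erroring,
        # so flat synthetic cases stay runnable
        return np.zeros(values.shape, dtype=np.int16), (lo, hi)
    levels = np.floor((N_GRAY_LEVELS - 1) * (values - lo) / (hi - lo))
    return np.clip(levels, 0, N_GRAY_LEVELS - 1).astype(np.int16), (lo, hi)


def normalize_full_range(channel: RawChannel) -> QuantizedVolume:
    """Rescale the full intensity range to 256 gray levels.

    ``level = floor(255 * (v - min) / (max - min))``, clamped to [0, 255].
    A constant volume maps to all-zero levels.
    """
    levels, rng = _rescale_to_levels(channel.values)
    return QuantizedVolume(levels=levels, channel=channel.modality, source_range=rng)


def normalize_clip_top(channel: RawChannel, clip_fraction: float = 0.001) -> QuantizedVolume:
    """Clip the top ``clip_fraction`` of intensities, then rescale to 256 levels.

    Intensities strictly above the ``1 - clip_fraction`` sample quantile
    (lower order statistic, over all voxels of the volume) are set to that
    quantile value before the full-range rescale, so the clipped voxels land
    exactly on the brightest retained intensity.  ``clip_fraction=0`` is
    identical to :func:`normalize_full_range`.
    """
    if not 0 <= clip_fraction < 1:
        raise ValidationError("clip_fraction must be in [0, 1)")
    values = channel.values
    if clip_fraction > 0:
        cap = float(np.quantile(values, 1.0 - clip_fraction, method="lower"))
        values = np.minimum(values, cap)
    levels, rng = _rescale_to_levels(values)
    return QuantizedVolume(levels=levels, channel=channel.modality, source_range=rng)


def derive_t2edge(t2: RawChannel) -> RawChannel:
    """T2Edge channel: spacing-aware 3D gradient magnitude of T2.

    Central differences in the interior, one-sided at the faces (numpy
    gradient convention), divided by the voxel spacing per axis.
    """
    grads = np.gradient(t2.values, *t2.spacing)
    mag = np.sqrt(sum(g * g for g in grads))
    return RawChannel(values=mag, spacing=t2.spacing, modality="T2Edge")


def derive_gdzscore(gd: RawChannel, reference: VoiMask | None = None) -> RawChannel:
    """Gdzscore channel: voxelwise z-score of GdT1 against a reference region.

    The reference defaults to the whole volume; its mean and SD (population)
    standardize every voxel.  A zero-variance reference is an error.
    """
    ref = gd.values[reference.mask] if reference is not None else gd.values.ravel()
    if ref.size < 2:
        raise ValidationError("z-score reference needs at least 2 voxels")
    mu = float(ref.mean())
    sd = float(ref.std())
    if sd == 0:
        raise ValidationError("z-score reference has zero variance")
    return RawChannel(values=(gd.values - mu) / sd, spacing=gd.spacing, modality="Gdzscore")


@dataclass
class Study:
    """Validated per-patient bundle: 5 quantized channels x 2 VOI masks.

    ``atlas`` is an optional co-registered integer label volume used by the
    location features.  ``valid`` is False when any validation error was
    recorded; such studies feed listwise deletion downstream.
    """

    patient_id: str
    channels: dict[str, QuantizedVolume]
    masks: dict[str, VoiMask]
    spacing: tuple[float, float, float]
    atlas: np.ndarray | None = None
    errors: list[str] = field(default_factory=list)

    @property
    def valid(self) -> bool:
        return not self.errors

    def combos(self) -> list[tuple[str, str]]:
        """The 10 channel-VOI combinations feature extraction iterates over."""
        return [(ch, voi) for ch in CHANNELS for voi in VOIS]


def build_study(
    patient_id: str,
    t1: RawChannel,
    t2: RawChannel,
    gd: RawChannel,
    core: VoiMask,
    edema: VoiMask,
    atlas: np.ndarray | None = None,
    clip_fraction: float = 0.001,
) -> Study:
    """Derive and quantize the five channels and validate VOIs into a Study.

    Validation problems (empty mask, grid mismatch) are recorded on the study
    rather than raised, so a cohort run can continue and drop the patient via
    listwise deletion.
    """
    t2edge = derive_t2edge(t2)
    gdz = derive_gdzscore(gd)
    channels = {
        "T1": normalize_clip_top(t1, clip_fraction),
        "T2": normalize_full_range(t2),
        "GdT1": normalize_clip_top(gd, clip_fraction),
        "T2Edge": normalize_full_range(t2edge),
        "Gdzscore": normalize_full_range(gdz),
    }
    study = Study(
        patient_id=patient_id,
        channels=channels,
        masks={"core": core, "edema": edema},
        spacing=t2.spacing,
        atlas=atlas,
    )
    validate_vois(study)
    return study


def validate_vois(study: Study) -> Study:
    """Check masks are nonempty and on the channel grid; record failures."""
    shape = next(iter(study.channels.values())).levels.shape
    for name, voi in study.masks.items():
        if voi.mask.shape != shape:
            study.errors.append(
                f"mask '{name}' grid {voi.mask.shape} does not match channel grid {shape}"
            )
        elif voi.n_voxels == 0:
            study.errors.append(f"mask '{name}' is empty")
    if study.atlas is not None and study.atlas.shape != shape:
        study.errors.append("atlas grid does not match channel grid")
    return study
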