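"""Synthetic radiograph phantoms, longitudinal series and exact-dimension fixtures.

Real periapical radiographs of implant patients cannot be redistributed, so
this module supplies three kinds of stand-in with known ground truth:

* trabecular-bone-like phantoms — fractional-Brownian surfaces whose
  roughness is set by a Hurst exponent (lower Hurst = rougher texture =
  higher downstream fractal dimension), optionally with a radiopaque
  threaded implant silhouette;
* longitudinal series — per patient, a baseline plus follow-up visits of the
  *same* phantom with controlled drift in texture complexity, rigid
  misalignment jitter and brightness jitter between visits, mirroring how
  serial intraoral films differ in practice;
* exact fractal fixtures — point, line, filled rectangle and Sierpinski
  carpet masks whose theoretical box-counting dimensions are known in closed
  form, used to validate the estimator.

All generators are pure functions of their parameter blocks including the
seed: identical inputs give bit-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .datatypes import Radiograph, RigidTransform
from .errors import ConfigurationError, SizingError

__all__ = [
    "ImplantGeometry",
    "TrabecularPhantomParams",
    "LongitudinalScenario",
    "DEFAULT_STUDY_PANEL",
    "make_phantom",
    "make_series",
    "make_exact_fractal",
    "fbm_surface",
    "simulate_fd_records",
]

#: Visit-incidence pattern of an unbalanced retrospective implant follow-up
#: panel: blocks of (number of patients, visit months).  77 patients and
#: 215 visit records, with per-month counts 77 / 31 / 64 / 43 at months
#: 0 / 3 / 6 / 12.
DEFAULT_STUDY_PANEL: tuple[tuple[int, tuple[int, ...]], ...] = (
    (25, (0, 3, 6)),
    (34, (0, 6, 12)),
    (8, (0, 12)),
    (5, (0, 3)),
    (4, (0, 6)),
    (1, (0, 3, 6, 12)),
)


@dataclass(frozen=True)
class ImplantGeometry:
    """Geometry of the rendered implant silhouette (pixels).

    The implant is a near-saturated vertical profile with a sinusoidal
    thread: at row ``y`` below ``top_row`` the half-width is
    ``radius + thread_depth * sin(2*pi*(y - top_row)/thread_pitch)``.
    ``first_thread_row`` is the row of the first thread crest — the landmark
    the mesial/distal ROIs are anchored to.
    """

    axis_x: int
    top_row: int
    radius: int = 8
    thread_pitch: int = 12
    thread_depth: int = 2

    @property
    def first_thread_row(self) -> int:
        return self.top_row + self.thread_pitch // 4

    def half_width(self, rows: np.ndarray) -> np.ndarray:
        phase = 2.0 * np.pi * (rows - self.top_row) / self.thread_pitch
        return self.radius + self.thread_depth * np.sin(phase)

    def render(self, shape: tuple[int, int], level: int = 250) -> np.ndarray:
        """Boolean silhouette mask and the gray level used to draw it."""
        h, w = shape
        rows = np.arange(h)
        hw = np.where(rows >= self.top_row, self.half_width(rows), -1.0)
        cols = np.arange(w)
        mask = np.abs(cols[None, :] - self.axis_x) <= hw[:, None]
        return mask

    def to_dict(self) -> dict:
        return {
            "axis_x": self.axis_x,
            "top_row": self.top_row,
            "radius": self.radius,
            "thread_pitch": self.thread_pitch,
            "thread_depth": self.thread_depth,
            "first_thread_row": self.first_thread_row,
        }


@dataclass(frozen=True)
class TrabecularPhantomParams:
    """Parameters of one trabecular phantom.

    ``hurst`` in (0, 1) sets texture roughness: the fractional-Brownian
    surface has spectral density ``~ f**-(2*hurst + 2)``, so a lower Hurst
    exponent leaves more high-frequency energy and a more complex (higher-FD)
    trabecular pattern.  ``psf_sigma`` is the imaging-system point-spread
    blur (focal spot + film/scanner MTF) in pixels — it band-limits the
    texture so trabecular grain spans several pixels, as it does on a
    300-dpi scan of real film.  ``mean_gray`` and ``contrast`` set the
    8-bit brightness scale; ``noise_sd`` adds white acquisition noise.
    """

    width: int = 128
    height: int = 128
    hurst: float = 0.5
    mean_gray: float = 120.0
    contrast: float = 35.0
    psf_sigma: float = 1.5
    implant: Optional[ImplantGeometry] = None
    noise_sd: float = 2.0
    seed: int = 0

    def validate(self) -> None:
        if not (0.0 < self.hurst < 1.0):
            raise ConfigurationError("hurst must lie strictly in (0, 1)")
        if self.width < 96 or self.height < 96:
            raise SizingError(
                "phantom must be at least 96x96 px so mesial and distal "
                "10x30 ROIs fit beside the implant"
            )


def _white_noise_spectrum(shape: tuple[int, int], seed: int) -> np.ndarray:
    """FFT of a unit white-noise field.  Separated out so that a series of
    images for one patient can share spectral phases (same seed) while the
    spectral exponent — hence texture complexity — drifts between visits."""
    rng = np.random.default_rng(seed)
    return np.fft.fft2(rng.standard_normal(shape))


def fbm_surface(
    shape: tuple[int, int],
    hurst: float,
    seed: int,
    *,
    spectrum: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Fractional-Brownian surface by spectral synthesis, zero mean, unit SD.

    Filters a white-noise field with the power-law amplitude ``f**-(hurst+1)``
    (power spectral density ``f**-(2*hurst+2)``).  Passing a precomputed
    ``spectrum`` reuses the same phases across different Hurst exponents.
    """
    h, w = shape
    if spectrum is None:
        spectrum = _white_noise_spectrum(shape, seed)
    fy = np.fft.fftfreq(h)[:, None]
    fx = np.fft.fftfreq(w)[None, :]
    f = np.sqrt(fx * fx + fy * fy)
    amp = np.zeros_like(f)
    nz = f > 0
    amp[nz] = f[nz] ** (-(hurst + 1.0))
    field_ = np.real(np.fft.ifft2(spectrum * amp))
    field_ -= field_.mean()
    sd = field_.std()
    if sd > 0:
        field_ /= sd
    return field_


def _render_scene(
    params: TrabecularPhantomParams,
    *,
    hurst: Optional[float] = None,
    spectrum: Optional[np.ndarray] = None,
    shape: Optional[tuple[int, int]] = None,
    implant_offset: tuple[int, int] = (0, 0),
) -> np.ndarray:
    """Noiseless float scene (texture + implant), unclipped brightness."""
    from scipy import ndimage

    h, w = shape if shape is not None else (params.height, params.width)
    hu = params.hurst if hurst is None else hurst
    if params.contrast > 0:
        texture = fbm_surface((h, w), hu, params.seed, spectrum=spectrum)
        img = params.mean_gray + params.contrast * texture
        if params.psf_sigma > 0:
            img = ndimage.gaussian_filter(img, params.psf_sigma, mode="reflect")
    else:
        img = np.full((h, w), params.mean_gray, dtype=float)
    if params.implant is not None:
        dx, dy = implant_offset
        geo = ImplantGeometry(
            axis_x=params.implant.axis_x + dx,
            top_row=params.implant.top_row + dy,
            radius=params.implant.radius,
            thread_pitch=params.implant.thread_pitch,
            thread_depth=params.implant.thread_depth,
        )
        img = np.where(geo.render((h, w)), 250.0, img)
    return img


def _finish(params: TrabecularPhantomParams, scene: np.ndarray,
            brightness_offset: float = 0.0, noise_seed_offset: int = 0) -> np.ndarray:
    """Acquisition step: brightness jitter, detector noise, clip to [0, 255]."""
    img = scene + brightness_offset
    if params.noise_sd > 0:
        rng = np.random.default_rng((params.seed, 0x5EED, noise_seed_offset))
        img = img + params.noise_sd * rng.standard_normal(img.shape)
    return np.clip(img, 0.0, 255.0)


def make_phantom(params: TrabecularPhantomParams, **meta) -> Radiograph:
    """Render one trabecular phantom as an 8-bit radiograph.

    Deterministic: the same parameter block (including seed) reproduces the
    image bit-for-bit.
    """
    params.validate()
    img = _finish(params, _render_scene(params))
    return Radiograph(pixels=np.round(img).astype(np.uint8), **meta)


def make_jittered_view(
    params: TrabecularPhantomParams,
    transform: RigidTransform,
    *,
    hurst: Optional[float] = None,
    spectrum: Optional[np.ndarray] = None,
    brightness_offset: float = 0.0,
    noise_seed_offset: int = 0,
    pad: int = 24,
    **meta,
) -> Radiograph:
    """Render the phantom seen through a rigid misalignment.

    The scene is rendered on a canvas padded by ``pad`` px, rigidly warped
    about its center, and center-cropped back to the requested size — so
    texture flows in from beyond the crop instead of a black wedge, exactly
    as bone extends beyond the field of a repositioned intraoral film.  The
    crop and padded canvas share a center, so ``transform`` is also the
    ground-truth transform in the cropped frame.  Acquisition noise and
    brightness jitter are applied after the warp, on the detector.
    """
    from scipy import ndimage as ndi

    from .register import _sample_coords

    params.validate()
    h, w = params.height, params.width
    big = (h + 2 * pad, w + 2 * pad)
    if spectrum is not None and spectrum.shape != big:
        raise ConfigurationError("spectrum shape must match the padded canvas")
    scene = _render_scene(
        params, hurst=hurst, spectrum=spectrum, shape=big, implant_offset=(pad, pad)
    )
    if not transform.is_identity(tol=1e-12):
        src = _sample_coords(big, transform)
        scene = ndi.map_coordinates(
            scene, [src[..., 1], src[..., 0]], order=1, mode="reflect"
        )
    scene = scene[pad : pad + h, pad : pad + w]
    img = _finish(params, scene, brightness_offset, noise_seed_offset)
    return Radiograph(pixels=np.round(img).astype(np.uint8), **meta)


@dataclass(frozen=True)
class LongitudinalScenario:
    """Design of a synthetic longitudinal study.

    ``panel`` is a sequence of ``(n_patients, visit_months)`` blocks; every
    schedule must contain the baseline (month 0) and at least one follow-up.
    ``complexity_trajectory`` maps visit month to an offset subtracted from
    the patient's Hurst exponent (positive offset = rougher texture = higher
    FD), which is how remodeling-driven complexity drift is injected without
    touching brightness.  ``jaw_hurst_effect`` is subtracted from the Hurst
    exponent of mandible patients.  ``misalignment_sd`` is ``(pixels,
    degrees)`` of rigid inter-visit jitter; ``brightness_jitter_sd`` is in
    gray levels.
    """

    n_patients: int = 8
    panel: tuple[tuple[int, tuple[int, ...]], ...] = ()
    complexity_trajectory: dict = field(default_factory=dict)
    jaw_hurst_effect: float = 0.0
    base_hurst: float = 0.5
    hurst_sd: float = 0.05
    misalignment_sd: tuple[float, float] = (3.0, 2.0)
    brightness_jitter_sd: float = 5.0
    image_size: tuple[int, int] = (128, 128)
    mean_gray: float = 120.0
    contrast: float = 35.0
    noise_sd: float = 2.0
    with_implant: bool = True
    seed: int = 0

    def schedules(self) -> list[tuple[int, ...]]:
        """One visit schedule per patient, expanded from the panel blocks
        (or ``n_patients`` copies of the default 0/6/12 schedule)."""
        if self.panel:
            out: list[tuple[int, ...]] = []
            for n, months in self.panel:
                out.extend([tuple(sorted(months))] * n)
        else:
            out = [(0, 6, 12)] * self.n_patients
        for sched in out:
            if not sched:
                raise ConfigurationError("empty visit schedule")
            if sched[0] != 0:
                raise ConfigurationError("every patient needs the baseline (month 0) visit")
            if len(sched) < 2:
                raise ConfigurationError("every patient needs at least one follow-up visit")
        return out


def make_series(
    scenario: LongitudinalScenario,
) -> tuple[list[Radiograph], pd.DataFrame]:
    """Generate a longitudinal radiograph series plus its ground-truth table.

    Each patient gets one spectral phase field on a padded canvas;
    follow-up visits re-render it with the visit's Hurst offset applied,
    rigidly warped by the visit's misalignment jitter (texture flowing in
    from beyond the crop, no empty border) and brightness-jittered.  The
    ground-truth table records, per visit, the covariates and the applied
    offsets (``true_hurst``, ``true_offset``, ``applied_dx``,
    ``applied_dy``, ``applied_theta``, ``applied_brightness``) so recovery
    tests can compare estimates against truth.
    """
    schedules = scenario.schedules()
    rng = np.random.default_rng(scenario.seed)
    h, w = scenario.image_size
    pad = 24
    images: list[Radiograph] = []
    truth_rows: list[dict] = []
    for pidx, sched in enumerate(schedules):
        patient_id = f"P{pidx + 1:03d}"
        jaw = "mandible" if rng.random() < 0.62 else "maxilla"
        sex = "female" if rng.random() < 0.48 else "male"
        age = float(rng.integers(25, 75))
        base_hurst = float(
            np.clip(
                scenario.base_hurst
                + scenario.hurst_sd * rng.standard_normal()
                - (scenario.jaw_hurst_effect if jaw == "mandible" else 0.0),
                0.05,
                0.95,
            )
        )
        implant = (
            ImplantGeometry(axis_x=w // 2, top_row=h // 6)
            if scenario.with_implant
            else None
        )
        phantom_seed = int(rng.integers(0, 2**31 - 1))
        params = TrabecularPhantomParams(
            width=w, height=h, hurst=base_hurst, mean_gray=scenario.mean_gray,
            contrast=scenario.contrast, implant=implant,
            noise_sd=scenario.noise_sd, seed=phantom_seed,
        )
        params.validate()
        spectrum = _white_noise_spectrum((h + 2 * pad, w + 2 * pad), phantom_seed)
        for vidx, month in enumerate(sched):
            offset = float(scenario.complexity_trajectory.get(month, 0.0))
            hurst_v = float(np.clip(base_hurst - offset, 0.05, 0.95))
            if month == 0:
                dx = dy = theta = 0.0
                bright = 0.0
            else:
                sd_px, sd_deg = scenario.misalignment_sd
                dx = float(sd_px * rng.standard_normal())
                dy = float(sd_px * rng.standard_normal())
                theta = float(sd_deg * rng.standard_normal())
                bright = float(scenario.brightness_jitter_sd * rng.standard_normal())
            radiograph = make_jittered_view(
                params,
                RigidTransform(dx=dx, dy=dy, theta=theta),
                hurst=hurst_v,
                spectrum=spectrum,
                brightness_offset=bright,
                noise_seed_offset=vidx,
                pad=pad,
                patient_id=patient_id, timepoint=month, jaw=jaw, sex=sex, age=age,
            )
            images.append(radiograph)
            truth_rows.append({
                "patient_id": patient_id, "timepoint_months": month, "jaw": jaw,
                "sex": sex, "age": age, "true_hurst": hurst_v, "true_offset": offset,
                "applied_dx": dx, "applied_dy": dy, "applied_theta": theta,
                "applied_brightness": bright,
            })
    return images, pd.DataFrame(truth_rows)


def _sierpinski_carpet(level: int) -> np.ndarray:
    mask = np.ones((1, 1), dtype=bool)
    for _ in range(level):
        mask = np.block([
            [mask, mask, mask],
            [mask, np.zeros_like(mask), mask],
            [mask, mask, mask],
        ])
    return mask


def make_exact_fractal(kind: str, size: int, level: int | None = None):
    """Binary fixture with a known theoretical box-counting dimension.

    Returns ``(SkeletonMask, theoretical_dimension)``.  Kinds: ``point``
    (dimension 0), ``line`` (1), ``filled_rect`` (2), ``sierpinski_carpet``
    (log 8 / log 3, requires ``size == 3**level``).
    """
    from .datatypes import SkeletonMask

    if size < 1:
        raise SizingError("fixture size must be positive")
    if kind == "point":
        mask = np.zeros((size, size), dtype=bool)
        mask[size // 2, size // 2] = True
        dim = 0.0
    elif kind == "line":
        mask = np.zeros((size, size), dtype=bool)
        mask[size // 2, :] = True
        dim = 1.0
    elif kind == "filled_rect":
        mask = np.ones((size, size), dtype=bool)
        dim = 2.0
    elif kind == "sierpinski_carpet":
        if level is None or size != 3**level:
            raise SizingError("sierpinski_carpet requires size == 3**level")
        mask = _sierpinski_carpet(level)
        dim = math.log(8) / math.log(3)
    else:
        raise ConfigurationError(f"unknown fixture kind: {kind!r}")
    return SkeletonMask(pixels=mask, provenance=["exact_fixture"], params={"kind": kind}), dim


def downstream_fd(
    hurst: float,
    seed: int,
    *,
    patch_size: int = 64,
    noise_sd: float = 2.0,
    psf_sigma: float = 1.5,
) -> float:
    """Fractal dimension of one synthetic trabecular patch run through the
    full chain + box-counting estimator.

    The texture-validation study: renders an implant-free phantom, crops a
    ``patch_size`` x ``patch_size`` patch (large enough that the tile-size
    ladder is not window-limited), and returns the pipeline FD.  Used to
    check that FD decreases monotonically in the Hurst exponent and stays
    inside the plausible trabecular range.
    """
    from .fractal import box_count
    from .preprocess import run_chain

    side = max(96, patch_size)
    params = TrabecularPhantomParams(
        width=side, height=side, hurst=hurst, seed=seed,
        noise_sd=noise_sd, psf_sigma=psf_sigma,
    )
    img = make_phantom(params)
    patch = img.pixels[:patch_size, :patch_size]
    return box_count(run_chain(patch)).fd


def simulate_fd_records(
    panel: Sequence[tuple[int, Sequence[int]]],
    *,
    time_effects: Optional[dict] = None,
    jaw_effect: float = 0.0,
    sex_effect: float = 0.0,
    baseline_mean: float = 1.55,
    between_sd: float = 0.15,
    within_sd: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate an FD analysis table directly at the record level.

    Draws per-patient random intercepts (``between_sd``) around
    ``baseline_mean``, adds fixed time/jaw/sex effects and within-patient
    noise (``within_sd``).  This is the generator used for statistical
    calibration studies, where simulating full images for hundreds of
    replicates would add nothing: the mixed model sees only the FD table.
    """
    rng = np.random.default_rng(seed)
    time_effects = dict(time_effects or {})
    rows = []
    pidx = 0
    for n, months in panel:
        for _ in range(n):
            pidx += 1
            pid = f"S{pidx:03d}"
            jaw = "mandible" if rng.random() < 0.62 else "maxilla"
            sex = "female" if rng.random() < 0.48 else "male"
            age = float(rng.integers(25, 75))
            intercept = baseline_mean + between_sd * rng.standard_normal()
            for month in months:
                mu = (
                    intercept
                    + time_effects.get(month, 0.0)
                    + (jaw_effect if jaw == "mandible" else 0.0)
                    + (sex_effect if sex == "male" else 0.0)
                )
                fd = mu + within_sd * rng.standard_normal()
                rows.append({
                    "patient_id": pid, "timepoint_months": int(month), "jaw": jaw,
                    "sex": sex, "age": age, "fd_mean": fd,
                })
    return pd.DataFrame(rows)
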