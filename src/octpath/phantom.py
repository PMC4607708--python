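"""Synthetic B-scan phantoms with known ground truth.

The phantom emulates the features of a macular line scan that matter to
shortest-path segmentation: the layered reflectivity stack (dark
vitreous, brighter inner retina, dark outer nuclear layer, bright IS/OS
band, a dimmer gap, the bright RPE band, dimmer choroid), a Gaussian
foveal pit, an optionally detached posterior hyaloid, multiplicative
single-look speckle (unit-mean exponential), frame averaging with the
boundaries held fixed, and per-column axial jitter emulating eye motion.
Two device geometries are provided as templates: 512 A-scans over 6 mm
(single frame) and 768 A-scans over 8.7 mm (100-frame averaging).

Ground-truth boundary rows are stored as floats in the coordinates of the
generated image (jitter included), so a segmentation of the phantom can
be compared directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .core_io import BScan, Calibration
from .errors import ValidationError

DEVICE_A = "deviceA"  # 512 A-scans / 6 mm, no averaging
DEVICE_B = "deviceB"  # 768 A-scans / 8.7 mm, 100-frame averaging


@dataclass
class PhantomSpec:
    """Geometry, anatomy and noise parameters of one synthetic B-scan.

    Depths are micrometres measured from the top of the image (vitreous
    side).  The anatomy: the ILM descends into a Gaussian pit of depth
    ``pit_depth_um`` (FWHM ``pit_width_mm``); the RPE outer border is flat
    at ``ilm_base_um + retina_periph_um``; the RPE band occupies the
    ``rpe_band_um`` above it; the IS/OS top sits ``rpeos`` above the outer
    border, where the IS/OS→RPE-outer complex thickness interpolates from
    ``rpeos_periph_um`` peripherally to ``rpeos_fovea_um`` at the pit
    (foveally thicker, as measured in adults).

    Defaults give a central point thickness of
    ``retina_periph_um − pit_depth_um`` = 226 μm and a foveal RPE+OS
    complex of 76 μm, in the range measured in healthy adult eyes.
    """

    rows: int = 160
    n_ascans: int = 512
    axial_scale: float = 3.87  # μm per pixel
    scan_length_mm: float = 6.0
    # anatomy (μm unless noted)
    ilm_base_um: float = 120.0
    pit_depth_um: float = 94.0
    pit_width_mm: float = 1.8  # FWHM of the Gaussian pit
    pit_center_mm: float = 0.0  # relative to scan center
    retina_periph_um: float = 320.0
    rpeos_fovea_um: float = 76.0
    rpeos_periph_um: float = 62.0
    rpe_band_um: float = 20.0
    isos_band_um: float = 15.0  # thickness of the bright IS/OS band
    onl_um: float = 80.0  # dark outer nuclear layer above the IS/OS
    # reflectivity levels, display scale in [0, 1]
    level_vitreous: float = 0.05
    level_inner: float = 0.35
    level_onl: float = 0.15
    level_isos: float = 0.8
    level_gap: float = 0.3
    level_rpe: float = 0.9
    level_choroid: float = 0.25
    # posterior hyaloid (faint detached line in the vitreous)
    hyaloid: bool = False
    hyaloid_contrast: float = 0.2  # fraction of the ILM contrast
    hyaloid_offset_um: float = 60.0  # above the ILM
    hyaloid_band_um: float = 8.0
    # noise model
    speckle: bool = True
    n_frames: int = 1
    jitter_max_px: int = 3

    def __post_init__(self):
        levels = [
            self.level_vitreous, self.level_inner, self.level_onl,
            self.level_isos, self.level_gap, self.level_rpe, self.level_choroid,
        ]
        if any(not (0 <= v <= 1) for v in levels):
            raise ValidationError("reflectivity levels must lie in [0, 1]")
        if self.rpeos_fovea_um < self.rpeos_periph_um:
            raise ValidationError("foveal RPE+OS must be >= peripheral RPE+OS")
        if self.pit_depth_um >= self.retina_periph_um:
            raise ValidationError("pit deeper than the retina")
        if self.n_frames < 1 or self.jitter_max_px < 0:
            raise ValidationError("n_frames >= 1 and jitter_max_px >= 0 required")
        # the full stack must fit in the image with the ordering intact
        depth = self.ilm_base_um + self.retina_periph_um
        if depth / self.axial_scale >= self.rows - 1:
            raise ValidationError("RPE outer border falls below the image")
        if self.isos_band_um + self.rpe_band_um >= self.rpeos_periph_um:
            raise ValidationError("IS/OS and RPE bands overlap (gap vanishes)")

    @property
    def calibration(self) -> Calibration:
        return Calibration(
            axial_scale=self.axial_scale,
            scan_length_mm=self.scan_length_mm,
            n_ascans=self.n_ascans,
        )


def device_a_spec(**overrides) -> PhantomSpec:
    """512 A-scans over 6 mm, single frame (no averaging)."""
    kw = dict(n_ascans=512, scan_length_mm=6.0, n_frames=1)
    kw.update(overrides)
    return PhantomSpec(**kw)


def device_b_spec(**overrides) -> PhantomSpec:
    """768 A-scans over 8.7 mm with 100-frame averaging."""
    kw = dict(n_ascans=768, scan_length_mm=8.7, n_frames=100)
    kw.update(overrides)
    return PhantomSpec(**kw)


@dataclass
class PhantomResult:
    """A generated scan plus everything a test needs to score against.

    ``truth`` maps layer names to float boundary rows in the coordinates
    of the generated image (jitter included).  ``truth_retina_um`` and
    ``truth_rpeos_um`` are the jitter-free per-column thickness profiles.
    """

    scan: BScan
    truth: dict
    fovea_col: int
    truth_retina_um: np.ndarray
    truth_rpeos_um: np.ndarray
    jitter: np.ndarray
    spec: PhantomSpec


def _boundary_depths(spec: PhantomSpec) -> dict[str, np.ndarray]:
    """Boundary depths in μm per column, jitter-free."""
    n = spec.n_ascans
    lateral_um = spec.calibration.lateral_scale
    x_mm = ((np.arange(n) + 0.5) * lateral_um) / 1000.0 - spec.scan_length_mm / 2.0
    sigma = spec.pit_width_mm / 2.355  # FWHM → σ
    pit = np.exp(-((x_mm - spec.pit_center_mm) ** 2) / (2.0 * sigma**2))

    ilm = spec.ilm_base_um + spec.pit_depth_um * pit
    rpe_outer = np.full(n, spec.ilm_base_um + spec.retina_periph_um)
    rpeos = spec.rpeos_periph_um + (spec.rpeos_fovea_um - spec.rpeos_periph_um) * pit
    isos = rpe_outer - rpeos
    depths = {
        "ILM": ilm,
        "ONL_TOP": isos - spec.onl_um,
        "ISOS": isos,
        "ISOS_BOTTOM": isos + spec.isos_band_um,
        "RPE_TOP": rpe_outer - spec.rpe_band_um,
        "RPE_OUTER": rpe_outer,
    }
    order = ["ILM", "ONL_TOP", "ISOS", "ISOS_BOTTOM", "RPE_TOP", "RPE_OUTER"]
    stack = np.vstack([depths[k] for k in order])
    if np.any(np.diff(stack, axis=0) < 0):
        raise ValidationError("phantom spec produces unordered boundaries")
    return depths


def _composite(spec: PhantomSpec, depths: dict[str, np.ndarray]) -> np.ndarray:
    """Noise-free reflectivity image from the boundary depths."""
    d = (np.arange(spec.rows) + 0.5)[:, None] * spec.axial_scale  # pixel centers, μm
    img = np.full((spec.rows, spec.n_ascans), spec.level_vitreous)

    def put(level, top, bottom):
        sel = (d >= top[None, :]) & (d < bottom[None, :])
        img[sel] = level

    inf = np.full(spec.n_ascans, np.inf)
    put(spec.level_inner, depths["ILM"], depths["ONL_TOP"])
    put(spec.level_onl, depths["ONL_TOP"], depths["ISOS"])
    put(spec.level_isos, depths["ISOS"], depths["ISOS_BOTTOM"])
    put(spec.level_gap, depths["ISOS_BOTTOM"], depths["RPE_TOP"])
    put(spec.level_rpe, depths["RPE_TOP"], depths["RPE_OUTER"])
    put(spec.level_choroid, depths["RPE_OUTER"], inf)
    if spec.hyaloid:
        ilm_contrast = spec.level_inner - spec.level_vitreous
        level = spec.level_vitreous + spec.hyaloid_contrast * ilm_contrast
        top = depths["ILM"] - spec.hyaloid_offset_um
        put(level, top, top + spec.hyaloid_band_um)
    return img


def generate_phantom(spec: PhantomSpec, seed: int = 0) -> PhantomResult:
    """Render one synthetic B-scan, deterministically given (spec, seed).

    Compositing order: layered reflectivity → multiplicative unit-mean
    exponential speckle, averaged over ``n_frames`` independent
    realizations with the boundaries held fixed → per-column integer
    jitter drawn uniformly in ``[−jitter_max_px, +jitter_max_px]``.
    """
    rng = np.random.default_rng(seed)
    depths = _boundary_depths(spec)
    img = _composite(spec, depths)

    if spec.speckle:
        acc = np.zeros_like(img)
        for _ in range(spec.n_frames):
            acc += img * rng.exponential(1.0, size=img.shape)
        img = acc / spec.n_frames

    jitter = np.zeros(spec.n_ascans, dtype=np.int64)
    if spec.jitter_max_px > 0:
        jitter = rng.integers(
            -spec.jitter_max_px, spec.jitter_max_px + 1, size=spec.n_ascans
        )
        out = np.full_like(img, spec.level_vitreous)
        n_rows = spec.rows
        for c, j in enumerate(jitter):
            j = int(j)
            if j == 0:
                out[:, c] = img[:, c]
            elif j > 0:  # column displaced downward by j
                out[j:, c] = img[: n_rows - j, c]
            else:
                out[: n_rows + j, c] = img[-j:, c]
        img = out

    scan = BScan(
        image=img, calibration=spec.calibration, scan_id=f"phantom-{seed}"
    )
    # float boundary rows at the boundary's row-center coordinate, in the
    # coordinates of the generated (jittered) image
    truth = {
        name: depths[name] / spec.axial_scale - 0.5 + jitter
        for name in ("ILM", "ISOS", "RPE_OUTER")
    }
    truth["RPE_CENTER"] = (
        (depths["RPE_TOP"] + depths["RPE_OUTER"]) / 2.0 / spec.axial_scale
        - 0.5 + jitter
    )
    lateral_um = spec.calibration.lateral_scale
    fovea_x = spec.scan_length_mm / 2.0 + spec.pit_center_mm
    fovea_col = int(round(fovea_x * 1000.0 / lateral_um - 0.5))
    return PhantomResult(
        scan=scan,
        truth=truth,
        fovea_col=fovea_col,
        truth_retina_um=depths["RPE_OUTER"] - depths["ILM"],
        truth_rpeos_um=depths["RPE_OUTER"] - depths["ISOS"],
        jitter=jitter,
        spec=spec,
    )


def generate_cohort(
    n_eyes: int = 37,
    device_specs: tuple[PhantomSpec, PhantomSpec] | None = None,
    bias_um: float = 0.0,
    between_eye_sd_um: float = 17.0,
    seed: int = 0,
) -> tuple[list[dict], pd.DataFrame]:
    """Paired scans of ``n_eyes`` synthetic eyes under two device geometries.

    Each eye draws one latent anatomy (peripheral retinal thickness, pit
    depth and width, IS/OS–RPE-outer complex, axial position, fixation
    offset) and is rendered under both device templates.  Device B's outer
    boundary is displaced ``bias_um`` deeper — the averaging-related
    thickening a frame-averaging device can show at a weak posterior edge
    — which thickens both the retina and the RPE+OS complex by the same
    amount.  ``between_eye_sd_um`` scales the eye-to-eye variation of the
    peripheral retinal thickness; the other anatomy SDs are fixed at
    values in the range measured across healthy adult eyes.

    Returns the per-eye records and a tidy ground-truth thickness table
    (``eye_id, device, layer_pair, offset_mm, thickness_um``).
    """
    if n_eyes < 2:
        raise ValidationError("need at least 2 eyes")
    if device_specs is None:
        device_specs = (device_a_spec(), device_b_spec())
    spec_a, spec_b = device_specs
    rng = np.random.default_rng(seed)
    eyes, truth_rows = [], []
    offsets = np.round(np.arange(-3.0, 3.01, 0.5), 2)
    for i in range(n_eyes):
        def draw(base, sd):  # clip at 3 SD so tails cannot break ordering
            return float(base + np.clip(rng.normal(0.0, sd), -3 * sd, 3 * sd))

        anatomy = dict(
            retina_periph_um=draw(spec_a.retina_periph_um, between_eye_sd_um),
            pit_depth_um=draw(spec_a.pit_depth_um, 8.0),
            pit_width_mm=spec_a.pit_width_mm * float(rng.uniform(0.9, 1.1)),
            rpeos_fovea_um=draw(spec_a.rpeos_fovea_um, 5.0),
            rpeos_periph_um=draw(spec_a.rpeos_periph_um, 3.0),
            ilm_base_um=draw(spec_a.ilm_base_um, 8.0),
            pit_center_mm=float(np.clip(rng.normal(0.0, 0.1), -0.3, 0.3)),
        )
        anatomy["rpeos_fovea_um"] = max(
            anatomy["rpeos_fovea_um"], anatomy["rpeos_periph_um"]
        )
        eye_a = replace(spec_a, **anatomy)
        anatomy_b = dict(
            anatomy,
            retina_periph_um=anatomy["retina_periph_um"] + bias_um,
            rpeos_fovea_um=anatomy["rpeos_fovea_um"] + bias_um,
            rpeos_periph_um=anatomy["rpeos_periph_um"] + bias_um,
        )
        eye_b = replace(spec_b, **anatomy_b)
        seed_a = int(rng.integers(0, 2**31 - 1))
        seed_b = int(rng.integers(0, 2**31 - 1))
        res_a = generate_phantom(eye_a, seed_a)
        res_b = generate_phantom(eye_b, seed_b)
        eye_id = f"eye{i:02d}"
        res_a.scan.scan_id = f"{eye_id}-{DEVICE_A}"
        res_b.scan.scan_id = f"{eye_id}-{DEVICE_B}"
        eyes.append({"eye_id": eye_id, DEVICE_A: res_a, DEVICE_B: res_b})
        for device, res in ((DEVICE_A, res_a), (DEVICE_B, res_b)):
            lat_mm = res.spec.calibration.lateral_scale / 1000.0
            for off in offsets:
                col = int(round(res.fovea_col + off / lat_mm))
                if not (0 <= col < res.spec.n_ascans):
                    continue
                for pair, prof in (
                    ("RETINA", res.truth_retina_um),
                    ("RPEOS", res.truth_rpeos_um),
                ):
                    truth_rows.append(
                        (eye_id, device, pair, float(off), float(prof[col]))
                    )
    truth = pd.DataFrame(
        truth_rows,
        columns=["eye_id", "device", "layer_pair", "offset_mm", "thickness_um"],
    )
    return eyes, truth


def generate_repeat_visits(
    n_eyes: int = 12,
    spec: PhantomSpec | None = None,
    within_eye_sd_um: float = 2.3,
    between_eye_sd_um: float = 17.0,
    seed: int = 0,
) -> list[dict]:
    """Two visits per eye on one device, for test–retest repeatability.

    The second visit re-renders the same eye with fresh speckle and
    jitter, plus a small axial re-measurement perturbation of the outer
    boundary (SD ``within_eye_sd_um``), emulating session-to-session
    variability.
    """
    if spec is None:
        spec = device_a_spec()
    rng = np.random.default_rng(seed)
    eyes = []
    for i in range(n_eyes):
        base = replace(
            spec,
            retina_periph_um=spec.retina_periph_um
            + rng.normal(0.0, between_eye_sd_um),
            pit_depth_um=spec.pit_depth_um + rng.normal(0.0, 8.0),
        )
        delta = rng.normal(0.0, within_eye_sd_um)
        revisit = replace(
            base,
            retina_periph_um=base.retina_periph_um + delta,
            rpeos_fovea_um=base.rpeos_fovea_um + delta,
            rpeos_periph_um=base.rpeos_periph_um + delta,
        )
        v1 = generate_phantom(base, int(rng.integers(0, 2**31 - 1)))
        v2 = generate_phantom(revisit, int(rng.integers(0, 2**31 - 1)))
        eye_id = f"eye{i:02d}"
        v1.scan.scan_id = f"{eye_id}-visit1"
        v2.scan.scan_id = f"{eye_id}-visit2"
        eyes.append({"eye_id": eye_id, "visit1": v1, "visit2": v2})
    return eyes
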