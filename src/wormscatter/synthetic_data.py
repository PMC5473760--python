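"""Ground-truthed synthetic scenes for every pipeline stage.

Scenes emulate the qualitative features of dark-field worm micrographs:
a sinusoidal capsule-shaped body brighter than the background, discrete
bright puncta (lysosome-related organelles), rim-bright circular lipid
droplets, diffuse background, Poisson–Gaussian camera noise, optional
multiplicative vignetting, and matched flat-field phantom frames with a
dark registration scratch.  Every scene carries a GroundTruth record from
which each pipeline output can be computed in closed form in the
noiseless limit.

All randomness flows from explicit integer seeds; the same seed yields a
bit-identical scene.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .illumination import GeometryError, PhantomRecord
from .image_io import Image


@dataclass
class SceneSpec:
    """Parameters of one synthetic worm scene.

    Geometry is in pixels; intensities in a.u. on a 16-bit scale.  The
    body is a capsule of half-width ``body_half_width_px`` around a
    sinusoidal centerline.  ``background_sd`` is the additive (read)
    noise sd; ``shot_noise_gain`` scales the signal-proportional variance
    term.  Defaults give a body/background ratio of 7.5 (a clean
    dark-field frame) with mild camera noise.
    """

    shape: tuple[int, int] = (128, 256)
    pixel_size_um: float = 1.0
    margin_px: float = 14.0
    body_amplitude_px: float = 10.0
    body_wavelength_px: float = 140.0
    body_half_width_px: float = 9.0
    body_base_intensity: float = 60.0
    background_mean: float = 8.0
    background_sd: float = 2.0
    shot_noise_gain: float = 0.5
    n_droplets: int = 0
    droplet_radius_px: tuple[float, float] = (2.0, 4.0)
    interior_gain: float = 2.5     # droplet interior = interior_gain * body base
    rim_gain: float = 1.6          # rim = rim_gain * interior
    droplet_intensity: float | None = None  # absolute interior a.u.; overrides interior_gain
    n_puncta: int = 0
    puncta_intensity: float = 150.0
    puncta_radius_px: float = 1.5
    vignette: float = 0.0
    bit_depth: int = 16
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("body_base_intensity", "background_mean", "puncta_intensity"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.background_sd < 0 or self.shot_noise_gain < 0:
            raise ValueError("noise parameters must be non-negative")


@dataclass
class GroundTruth:
    """What the generator actually drew, for closed-form validation."""

    body_mask: np.ndarray
    droplet_centers: np.ndarray  # (n, 2) row, col
    droplet_radii: np.ndarray
    puncta_centers: np.ndarray   # (n, 2)
    latent_fat: float            # mean added scattering per body pixel (a.u./px)
    arc_length_um: float         # centerline arc length
    mean_body_intensity: float   # noiseless in-body mean (base + latent_fat)


def _centerline(spec: SceneSpec) -> tuple[np.ndarray, np.ndarray, float]:
    """Fine-sampled sinusoidal centerline and its arc length in pixels."""
    rows, cols = spec.shape
    c0, c1 = spec.margin_px, cols - 1 - spec.margin_px
    if c1 - c0 < 2:
        raise GeometryError("frame too small for the requested margin")
    cs = np.arange(c0, c1 + 1e-9, 0.25)
    omega = 2 * math.pi / spec.body_wavelength_px
    rs = rows / 2.0 + spec.body_amplitude_px * np.sin(omega * (cs - c0))
    if (rs.min() - spec.body_half_width_px < 1
            or rs.max() + spec.body_half_width_px > rows - 2):
        raise GeometryError("body does not fit in frame")
    # arc length by quadrature of sqrt(1 + r'(c)^2)
    fine = np.arange(c0, c1, 0.01)
    deriv = spec.body_amplitude_px * omega * np.cos(omega * (fine - c0))
    arc = float(np.trapezoid(np.sqrt(1 + deriv ** 2), fine))
    return rs, cs, arc


def _body_mask(spec: SceneSpec) -> tuple[np.ndarray, float]:
    rs, cs, arc = _centerline(spec)
    canvas = np.ones(spec.shape, dtype=bool)
    rr = np.clip(np.round(rs).astype(int), 0, spec.shape[0] - 1)
    cc = np.clip(np.round(cs).astype(int), 0, spec.shape[1] - 1)
    canvas[rr, cc] = False
    dist = ndimage.distance_transform_edt(canvas)
    return dist <= spec.body_half_width_px, arc


def _place_disjoint(rng: np.random.Generator, allowed: np.ndarray, radii: np.ndarray,
                    pad: float = 1.0, max_tries: int = 20000) -> np.ndarray:
    """Rejection-sample disjoint disk centers from the allowed pixel set."""
    coords = np.argwhere(allowed)
    if len(coords) == 0:
        raise GeometryError("no room inside the body for the requested objects")
    centers: list[np.ndarray] = []
    tries = 0
    for i, r in enumerate(radii):
        while True:
            tries += 1
            if tries > max_tries:
                raise GeometryError(
                    f"could not place {len(radii)} disjoint objects (placed {i})"
                )
            cand = coords[rng.integers(len(coords))].astype(float)
            ok = all(np.hypot(*(cand - c)) > r + radii[j] + pad
                     for j, c in enumerate(centers))
            if ok:
                centers.append(cand)
                break
    return np.array(centers).reshape(-1, 2)


def render_scene(spec: SceneSpec) -> tuple[Image, GroundTruth]:
    """Render one scene deterministically from its spec (and spec.seed)."""
    rng = np.random.default_rng(spec.seed)
    rows, cols = spec.shape
    body, arc_px = _body_mask(spec)

    clean = np.full(spec.shape, float(spec.background_mean))
    clean[body] = spec.body_base_intensity

    interior = (spec.droplet_intensity if spec.droplet_intensity is not None
                else spec.interior_gain * spec.body_base_intensity)
    rim_val = spec.rim_gain * interior
    rim_w = 1.2

    # containment: a disk of radius r fits iff its center is deeper than r
    depth = ndimage.distance_transform_edt(body)
    r_lo, r_hi = spec.droplet_radius_px
    droplet_radii = rng.uniform(r_lo, r_hi, size=spec.n_droplets)
    droplet_centers = (_place_disjoint(rng, depth > r_hi + 0.5, droplet_radii)
                       if spec.n_droplets else np.empty((0, 2)))
    rr_idx, cc_idx = np.ogrid[:rows, :cols]
    for (cr, cc0), rad in zip(droplet_centers, droplet_radii):
        d = np.hypot(rr_idx - cr, cc_idx - cc0)
        clean[(d > rad - rim_w) & (d <= rad)] = rim_val
        clean[d <= rad - rim_w] = interior

    puncta_centers = (_place_disjoint(
        rng, depth > spec.puncta_radius_px + 0.5,
        np.full(spec.n_puncta, spec.puncta_radius_px))
        if spec.n_puncta else np.empty((0, 2)))
    for cr, cc0 in puncta_centers:
        d = np.hypot(rr_idx - cr, cc_idx - cc0)
        clean[d <= spec.puncta_radius_px] = spec.puncta_intensity

    mean_body = float(clean[body].mean())
    latent = mean_body - spec.body_base_intensity

    img = clean
    if spec.background_sd > 0 or spec.shot_noise_gain > 0:
        sd = np.sqrt(spec.background_sd ** 2 + spec.shot_noise_gain * clean)
        img = clean + rng.standard_normal(spec.shape) * sd
    if spec.vignette > 0:
        dcent = np.hypot(rr_idx - (rows - 1) / 2, cc_idx - (cols - 1) / 2)
        img = img * (1 - spec.vignette * (dcent / dcent.max()) ** 2)
    img = np.clip(img, 0, 2 ** spec.bit_depth - 1)

    image = Image(pixels=img, bit_depth=spec.bit_depth, modality="darkfield",
                  pixel_size_um=spec.pixel_size_um)
    truth = GroundTruth(
        body_mask=body, droplet_centers=droplet_centers,
        droplet_radii=droplet_radii, puncta_centers=puncta_centers,
        latent_fat=latent, arc_length_um=arc_px * spec.pixel_size_um,
        mean_body_intensity=mean_body,
    )
    return image, truth


def render_phantom(mean_level: float, mark_center: tuple[float, float] | None = None,
                   shape: tuple[int, int] = (128, 128), noise_sd_frac: float = 0.01,
                   seed: int = 0, roi_inner_px: float = 5.0, roi_outer_px: float = 25.0,
                   session_id: str = "") -> tuple[Image, PhantomRecord]:
    """Flat-field phantom frame with a dark registration scratch at the mark.

    The scratch lies inside the annulus' inner radius, so the annulus mean
    concentrates on ``mean_level`` (exactly, at zero noise).
    """
    if mean_level <= 0:
        raise ValueError("mean_level must be positive")
    rng = np.random.default_rng(seed)
    if mark_center is None:
        mark_center = ((shape[0] - 1) / 2, (shape[1] - 1) / 2)
    px = np.full(shape, float(mean_level))
    if noise_sd_frac > 0:
        px = px + rng.standard_normal(shape) * (noise_sd_frac * mean_level)
    # scratch: short dark horizontal segment, half-length < roi_inner_px
    half = min(3, int(roi_inner_px) - 1)
    r0 = int(round(mark_center[0]))
    c0 = int(round(mark_center[1]))
    px[r0, max(0, c0 - half):c0 + half + 1] = 0.2 * mean_level
    px = np.clip(px, 0, 65535)
    frame = Image(pixels=px, bit_depth=16, modality="darkfield",
                  meta={"session_id": session_id} if session_id else {})
    record = PhantomRecord(frame=frame, mark_center=mark_center,
                           roi_inner_px=roi_inner_px, roi_outer_px=roi_outer_px,
                           session_id=session_id)
    return frame, record


def generate_validation_study(n_conditions: int = 23, worms_per_condition: int = 15,
                              latent_fat_range: tuple[float, float] = (1.0, 3.0),
                              scatter_gain: float = 1.0, oro_gain: float = 1.0,
                              noise_cv: float = 0.10, seed: int = 0):
    """Split-cohort validation study: disjoint worm sets per measurement.

    Each condition has a latent fat level drawn uniformly from
    ``latent_fat_range``; each worm's measurement is
    ``gain * latent * (1 + eps)`` with ``eps ~ N(0, noise_cv)``.  The
    scattering and staining cohorts are independent draws — never the same
    worms — mirroring the real design in which staining requires fixation.

    Returns ``(scatter_cohorts, oro_cohorts, truth)`` where the cohorts are
    condition -> array mappings and truth is a DataFrame of latent levels.
    """
    if n_conditions < 3:
        raise ValueError("need at least 3 conditions")
    if worms_per_condition < 2:
        raise ValueError("need at least 2 worms per condition")
    if noise_cv < 0:
        raise ValueError("noise_cv must be non-negative")
    rng = np.random.default_rng(seed)
    lo, hi = latent_fat_range
    latents = rng.uniform(lo, hi, size=n_conditions)
    scatter: dict[str, np.ndarray] = {}
    oro: dict[str, np.ndarray] = {}
    for i, mu in enumerate(latents):
        cond = f"cond_{i:02d}"
        eps_s = rng.normal(0, noise_cv, size=worms_per_condition) if noise_cv else np.zeros(worms_per_condition)
        eps_o = rng.normal(0, noise_cv, size=worms_per_condition) if noise_cv else np.zeros(worms_per_condition)
        scatter[cond] = scatter_gain * mu * (1 + eps_s)
        oro[cond] = oro_gain * mu * (1 + eps_o)
    truth = pd.DataFrame({"condition": [f"cond_{i:02d}" for i in range(n_conditions)],
                          "latent_fat": latents})
    return scatter, oro, truth


def generate_fasting_cohort(n_worms: int = 55, baseline_density: float = 100.0,
                            loss_range: tuple[float, float] = (0.10, 0.40),
                            noise_cv: float = 0.02, spread_cv: float = 0.15,
                            seed: int = 0):
    """Paired before/after densities for a fasting experiment.

    Each worm has its own true density (lognormal-ish spread around the
    baseline); fasting removes a fraction drawn from ``loss_range``; both
    measurements carry multiplicative noise of CV ``noise_cv``.  With the
    default 10–40% loss and 2% measurement noise, essentially every worm
    shows a decrease; with ``loss_range=(0, 0)`` the decrease fraction is
    ~0.5 by symmetry of the noise.
    """
    rng = np.random.default_rng(seed)
    true = baseline_density * (1 + rng.normal(0, spread_cv, n_worms))
    true = np.clip(true, baseline_density * 0.2, None)
    loss = rng.uniform(*loss_range, size=n_worms)
    before = true * (1 + rng.normal(0, noise_cv, n_worms))
    after = true * (1 - loss) * (1 + rng.normal(0, noise_cv, n_worms))
    ids = [f"worm_{i:03d}" for i in range(n_worms)]
    return (list(zip(ids, before.tolist())), list(zip(ids, after.tolist())))


def coloc_scene_spec(seed: int = 0, n_puncta: int = 60) -> SceneSpec:
    """Scene spec for an L1-like punctate frame used in colocalization work."""
    return SceneSpec(shape=(128, 256), body_base_intensity=30.0,
                     background_mean=5.0, background_sd=2.0, shot_noise_gain=0.3,
                     n_puncta=n_puncta, puncta_intensity=150.0,
                     puncta_radius_px=2.0, body_half_width_px=10.0, seed=seed)


def render_coloc_pair(seed: int = 0, mode: str = "coincident",
                      n_puncta: int = 60) -> tuple[Image, Image, GroundTruth]:
    """Dark-field + fluorescence channel pair over one body.

    ``mode="coincident"`` places the fluorescent puncta at exactly the
    dark-field puncta positions (the L1 situation: scatterers are the
    stained organelles); ``mode="independent"`` places them independently
    (the no-colocalization null).  Channel noise is always independent.
    """
    if mode not in ("coincident", "independent"):
        raise ValueError("mode must be 'coincident' or 'independent'")
    spec_df = coloc_scene_spec(seed=seed, n_puncta=n_puncta)
    df_img, truth = render_scene(spec_df)
    rng = np.random.default_rng(seed + 1_000_003)
    rows, cols = spec_df.shape
    body = truth.body_mask
    clean = np.full(spec_df.shape, 2.0)
    clean[body] = 15.0  # faint diffuse body fluorescence
    if mode == "coincident":
        centers = truth.puncta_centers
    else:
        depth = ndimage.distance_transform_edt(body)
        centers = _place_disjoint(rng, depth > spec_df.puncta_radius_px + 0.5,
                                  np.full(n_puncta, spec_df.puncta_radius_px))
    rr_idx, cc_idx = np.ogrid[:rows, :cols]
    for cr, cc0 in centers:
        d = np.hypot(rr_idx - cr, cc_idx - cc0)
        clean[d <= spec_df.puncta_radius_px] = 160.0
    sd = np.sqrt(spec_df.background_sd ** 2 + spec_df.shot_noise_gain * clean)
    fl = np.clip(clean + rng.standard_normal(spec_df.shape) * sd, 0, 65535)
    fluor = Image(pixels=fl, bit_depth=16, modality="fluor_red",
                  pixel_size_um=spec_df.pixel_size_um)
    return df_img, fluor, truth


# --- developmental time course -------------------------------------------

#: (time hr, target mean body scattering density a.u./px, worm length µm).
#: Emulates the qualitative developmental trajectory: nearly flat through
#: the L1 stage, a rapid rise for ~7 hr starting near the L1–L2 transition,
#: then a modest further increase.
DEFAULT_STAGE_PROFILE: list[tuple[float, float, float]] = [
    (4.0, 24.0, 250.0),
    (10.0, 25.0, 280.0),
    (17.0, 26.0, 310.0),
    (24.0, 28.0, 355.0),
    (27.0, 45.0, 400.0),
    (31.0, 68.0, 460.0),
    (38.0, 78.0, 545.0),
    (44.0, 84.0, 625.0),
    (50.0, 88.0, 700.0),
]

#: Simulated objectives: pixel size (µm) and relative light-collection gain.
OBJECTIVES = {"40x": {"pixel_size_um": 1.6, "gain": 1.0},
              "20x": {"pixel_size_um": 3.2, "gain": 0.45}}

BODY_BASE_TIMECOURSE = 20.0      # non-fat tissue floor, a.u./px
DROPLET_INTENSITY_TC = 420.0     # droplet interior, a.u. (at 40x gain)


@dataclass
class SceneRecord:
    timepoint_hr: float
    objective: str
    worm_index: int
    image: Image
    truth: GroundTruth


@dataclass
class TimecourseStudy:
    records: list[SceneRecord]
    profile: pd.DataFrame           # timepoint_hr, latent_density, length_um
    shared_t: float
    objectives: dict[str, dict] = field(default_factory=lambda: dict(OBJECTIVES))


def _spec_for_worm(latent_density: float, length_um: float, objective: str,
                   seed: int) -> SceneSpec:
    """Build a scene spec hitting a target body length and mean density."""
    obj = OBJECTIVES[objective]
    px = obj["pixel_size_um"]
    gain = obj["gain"]
    length_px = length_um / px
    half_width_px = max(3.0, 0.035 * length_px)
    amp = 0.05 * length_px
    # solve the horizontal extent so the sinusoid's arc length equals length_px
    extent = length_px
    for _ in range(3):
        omega = 2 * math.pi / (extent / 1.5)
        fine = np.linspace(0, extent, 400)
        deriv = amp * omega * np.cos(omega * fine)
        arc = float(np.trapezoid(np.sqrt(1 + deriv ** 2), fine))
        extent *= length_px / arc
    margin = 12.0
    cols = int(math.ceil(extent + 2 * margin)) + 2
    rows = int(math.ceil(2 * (amp + half_width_px) + 2 * margin)) + 2
    base = BODY_BASE_TIMECOURSE * gain
    interior = DROPLET_INTENSITY_TC * gain
    target_added = (latent_density - BODY_BASE_TIMECOURSE) * gain
    if target_added < 0:
        raise ValueError("latent density below the body base intensity")
    r_lo, r_hi = 2.0, 3.5
    rim_w = 1.2
    r_mean = (r_lo + r_hi) / 2
    interior_area = math.pi * (r_mean - rim_w) ** 2
    rim_area = math.pi * (r_mean ** 2 - (r_mean - rim_w) ** 2)
    per_droplet = (interior_area * (interior - base)
                   + rim_area * (1.6 * interior - base))
    # body area of a capsule around the centerline
    body_area = 2 * half_width_px * length_px + math.pi * half_width_px ** 2
    n_droplets = int(round(target_added * body_area / per_droplet)) if target_added > 0 else 0
    return SceneSpec(
        shape=(rows, cols), pixel_size_um=px, margin_px=margin,
        body_amplitude_px=amp, body_wavelength_px=extent / 1.5,
        body_half_width_px=half_width_px,
        body_base_intensity=base, background_mean=5.0 * gain,
        background_sd=2.0, shot_noise_gain=0.2,
        n_droplets=n_droplets, droplet_radius_px=(r_lo, r_hi),
        droplet_intensity=interior, rim_gain=1.6, seed=seed,
    )


def generate_timecourse(stage_profile: list[tuple[float, float, float]] | None = None,
                        worms_per_point: int = 6, shared_t: float = 31.0,
                        seed: int = 0) -> TimecourseStudy:
    """Render a two-objective developmental study with a shared timepoint.

    Timepoints up to ``shared_t`` are imaged at 40x, from ``shared_t`` on
    at 20x; the shared timepoint is rendered through both, providing the
    stitching anchor.  The latent fat curve (target mean in-body density
    at the 40x scale) and worm lengths are taken from ``stage_profile``.
    """
    profile = stage_profile if stage_profile is not None else DEFAULT_STAGE_PROFILE
    times = [p[0] for p in profile]
    if any(b <= a for a, b in zip(times, times[1:])):
        raise ValueError("profile times must be strictly increasing")
    if not any(abs(t - shared_t) < 1e-9 for t in times):
        raise ValueError(f"profile must contain the shared timepoint {shared_t}")
    records: list[SceneRecord] = []
    sub = 0
    for t, latent, length in profile:
        objs = []
        if t <= shared_t + 1e-9:
            objs.append("40x")
        if t >= shared_t - 1e-9:
            objs.append("20x")
        for objective in objs:
            for w in range(worms_per_point):
                sub += 1
                spec = _spec_for_worm(latent, length, objective,
                                      seed=(seed * 1_000_003 + sub) % (2 ** 31))
                img, truth = render_scene(spec)
                img.meta.update({"timepoint_hr": repr(t), "objective": objective})
                records.append(SceneRecord(t, objective, w, img, truth))
    prof_df = pd.DataFrame(profile, columns=["timepoint_hr", "latent_density", "length_um"])
    return TimecourseStudy(records=records, profile=prof_df, shared_t=shared_t)


def step_profile(fold: float = 2.0, t_step: float = 24.0,
                 base_density: float = 40.0) -> list[tuple[float, float, float]]:
    """Flat-then-step latent profile: density jumps by ``fold`` at ``t_step``.

    Useful for testing fold-change recovery through stitching and
    normalization; the step lands on the shared timepoint side boundary
    only if placed there, so default times keep it strictly inside the
    40x range.
    """
    pre = [(4.0, base_density, 260.0), (12.0, base_density, 300.0),
           (20.0, base_density, 340.0)]
    post = [(t_step + 4.0, base_density * fold, 420.0),
            (31.0, base_density * fold, 470.0),
            (40.0, base_density * fold, 560.0),
            (50.0, base_density * fold, 660.0)]
    return pre + post
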