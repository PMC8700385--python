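"""Synthetic data generation for the histology-MRI fusion / IVIM pipeline.

Everything downstream (registration, fitting, statistics) is testable
without any acquisition: this module builds 2-D prostate phantoms with a
transitional zone (TZ), peripheral zone (PZ) and an optional lesion,
renders multi-b-value DWI stacks from the biexponential IVIM model with
Rician noise, fabricates histology/T2WI scene pairs related by a known
planar transform, and simulates subject cohorts whose ground-truth
parameters carry the age trends and lesion effects the statistics layer is
meant to detect.

Default region parameter values are prostate-typical central tendencies:
TZ (f = 38.8%, D = 0.80e-3, D* = 4.41e-3 mm^2/s), PZ (f = 37.4%,
D = 0.82e-3, D* = 5.80e-3) and lesion (f = 42.7%, D = 0.51e-3,
D* = 3.73e-3).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .core import AcquisitionScheme, IVIMParameterMap, ivim_signal
from .registration import ControlPointSet, PlanarTransform, ROIMask

__all__ = [
    "RegionParams",
    "Ellipse",
    "PhantomSpec",
    "NoiseModel",
    "SyntheticCohortSpec",
    "GroundTruthScene",
    "make_phantom",
    "phantom_masks",
    "simulate_signal",
    "add_rician_noise",
    "make_scene",
    "simulate_cohort",
    "render_subject_study",
]


@dataclass(frozen=True)
class RegionParams:
    """IVIM parameter values of one piecewise-constant phantom region.

    ``f`` is a fraction in [0, 1]; ``d`` and ``dstar`` in mm^2/s.
    """

    f: float
    d: float
    dstar: float
    s0: float = 100.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.f <= 1.0:
            raise ValueError(f"f must be in [0, 1], got {self.f}")
        if self.d <= 0:
            raise ValueError("D must be positive")
        if self.f > 0 and self.dstar <= self.d:
            raise ValueError("D* must exceed D when f > 0")
        if self.s0 <= 0:
            raise ValueError("S0 must be positive")


@dataclass(frozen=True)
class Ellipse:
    """Axis-aligned ellipse in pixel coordinates (x = column, y = row)."""

    cx: float
    cy: float
    rx: float
    ry: float

    def mask(self, shape: tuple[int, int]) -> np.ndarray:
        ny, nx = shape
        gx, gy = np.meshgrid(np.arange(nx) + 0.5, np.arange(ny) + 0.5)
        return ((gx - self.cx) / self.rx) ** 2 + ((gy - self.cy) / self.ry) ** 2 <= 1.0


# Central-tendency defaults for the three tissue regions.
TZ_DEFAULT = RegionParams(f=0.388, d=0.80e-3, dstar=4.41e-3)
PZ_DEFAULT = RegionParams(f=0.374, d=0.82e-3, dstar=5.80e-3)
LESION_DEFAULT = RegionParams(f=0.427, d=0.51e-3, dstar=3.73e-3)
BACKGROUND_DEFAULT = RegionParams(f=0.05, d=1.6e-3, dstar=8.0e-3, s0=30.0)


@dataclass
class PhantomSpec:
    """Geometry and tissue parameters of a single-slice prostate phantom.

    The prostate is an ellipse containing a transitional-zone ellipse; the
    peripheral zone is the remainder.  An optional lesion ellipse must sit
    entirely inside exactly one zone.
    """

    grid_shape: tuple[int, int] = (64, 64)
    pixel_size: float = 3.05
    prostate: Ellipse = field(default_factory=lambda: Ellipse(32, 34, 26, 20))
    tz: Ellipse = field(default_factory=lambda: Ellipse(32, 30, 14, 10))
    lesion: Ellipse | None = field(default_factory=lambda: Ellipse(18, 42, 5, 4))
    tz_params: RegionParams = TZ_DEFAULT
    pz_params: RegionParams = PZ_DEFAULT
    lesion_params: RegionParams = LESION_DEFAULT
    background_params: RegionParams = BACKGROUND_DEFAULT

    @property
    def midline_x(self) -> float:
        return self.prostate.cx


def phantom_masks(spec: PhantomSpec) -> dict[str, np.ndarray]:
    """Boolean region masks (prostate, tz, pz, lesion) for a phantom spec.

    Validates the geometric invariants: the TZ lies inside the prostate and
    the lesion, if present, lies entirely inside exactly one zone.
    """
    shape = spec.grid_shape
    prostate = spec.prostate.mask(shape)
    tz = spec.tz.mask(shape)
    if np.any(tz & ~prostate):
        raise ValueError("transitional zone extends outside the prostate")
    pz = prostate & ~tz
    masks = {"prostate": prostate, "tz": tz, "pz": pz, "lesion": np.zeros(shape, bool)}
    if spec.lesion is not None:
        lesion = spec.lesion.mask(shape)
        if not lesion.any():
            raise ValueError("lesion ellipse covers no pixels")
        if np.any(lesion & ~prostate):
            raise ValueError("lesion crosses the prostate boundary")
        in_tz = np.any(lesion & tz)
        in_pz = np.any(lesion & pz)
        if in_tz and in_pz:
            raise ValueError("lesion straddles the TZ/PZ boundary")
        masks["lesion"] = lesion
        masks["lesion_zone"] = "tz" if in_tz else "pz"
    return masks


def make_phantom(spec: PhantomSpec) -> IVIMParameterMap:
    """Piecewise-constant IVIM parameter map from a phantom spec."""
    masks = phantom_masks(spec)
    shape = spec.grid_shape
    maps = {k: np.empty(shape) for k in ("f", "d", "dstar", "s0")}
    regions = [
        (~masks["prostate"], spec.background_params),
        (masks["tz"], spec.tz_params),
        (masks["pz"], spec.pz_params),
    ]
    if spec.lesion is not None:
        regions.append((masks["lesion"], spec.lesion_params))
    for mask, params in regions:
        maps["f"][mask] = params.f
        maps["d"][mask] = params.d
        maps["dstar"][mask] = params.dstar
        maps["s0"][mask] = params.s0
    return IVIMParameterMap(
        f=maps["f"], d=maps["d"], dstar=maps["dstar"], s0=maps["s0"],
        pixel_size=spec.pixel_size,
    )


def simulate_signal(params: IVIMParameterMap, scheme: AcquisitionScheme) -> np.ndarray:
    """Noise-free DWI stack, shape (ny, nx, n_b), from a parameter map.

    Per pixel and b: S(b) = S0 * (f exp[-b (D* + D)] + (1 - f) exp(-b D)).
    """
    params.validate()
    b = scheme.array[None, None, :]
    return ivim_signal(
        b, params.f[..., None], params.d[..., None],
        params.dstar[..., None], params.s0[..., None],
    )


@dataclass(frozen=True)
class NoiseModel:
    """Rician magnitude-image noise.

    ``snr`` is the ratio of a reference signal S0 to the complex Gaussian
    noise sigma; ``snr = inf`` means no noise.  ``s0_ref = None`` uses the
    maximum b = 0 signal of the stack being corrupted.
    """

    snr: float = 50.0
    seed: int = 0
    kind: str = "rician"
    s0_ref: float | None = None

    def __post_init__(self) -> None:
        if not self.snr > 0:
            raise ValueError("snr must be positive")
        if self.kind != "rician":
            raise ValueError(f"unsupported noise kind: {self.kind!r}")


def add_rician_noise(stack: np.ndarray, noise: NoiseModel) -> np.ndarray:
    """Corrupt a signal stack with Rician noise.

    Each value S is replaced by sqrt((S + e1)^2 + e2^2) with e1, e2
    independent N(0, sigma^2) and sigma = s0_ref / snr.  Deterministic for
    a fixed seed.
    """
    stack = np.asarray(stack, dtype=float)
    if not np.isfinite(noise.snr):
        return stack.copy()
    s0_ref = noise.s0_ref if noise.s0_ref is not None else float(stack.max())
    sigma = s0_ref / noise.snr
    if sigma == 0:
        return stack.copy()
    rng = np.random.default_rng(noise.seed)
    e1 = rng.normal(0.0, sigma, stack.shape)
    e2 = rng.normal(0.0, sigma, stack.shape)
    return np.sqrt((stack + e1) ** 2 + e2**2)


# ---------------------------------------------------------------------------
# Histology / T2WI scene with a known ground-truth transform


@dataclass
class GroundTruthScene:
    """A synthetic T2WI/histology pair with known registration truth."""

    t2_image: np.ndarray
    histology_image: np.ndarray
    true_transform: PlanarTransform
    control_points: ControlPointSet
    lesion_mask_histology: ROIMask
    pixel_size: float = 0.76
    jitter_sigma: float = 0.0


def _t2_anatomy(shape: tuple[int, int], spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    """Textured anatomical image on the fine (T2) grid from the phantom
    geometry, scaled up from the DWI grid."""
    ny, nx = shape
    scale = ny / spec.grid_shape[0]
    prostate = Ellipse(
        spec.prostate.cx * scale, spec.prostate.cy * scale,
        spec.prostate.rx * scale, spec.prostate.ry * scale,
    ).mask(shape)
    tz = Ellipse(
        spec.tz.cx * scale, spec.tz.cy * scale,
        spec.tz.rx * scale, spec.tz.ry * scale,
    ).mask(shape)
    img = np.full(shape, 0.15)
    img[prostate] = 0.55
    img[tz] = 0.75
    texture = ndimage.gaussian_filter(rng.normal(0, 1, shape), 6.0)
    img += 0.12 * texture * prostate
    # urethra: small dark disc near the TZ center
    urethra = Ellipse(spec.tz.cx * scale, spec.tz.cy * scale, 2.5 * scale / 4, 2.5 * scale / 4).mask(shape)
    img[urethra] = 0.2
    return np.clip(img, 0, 1)


def _true_transform(family: str, shape: tuple[int, int], rng: np.random.Generator) -> PlanarTransform:
    """Random, mildly non-trivial moving -> fixed transform centered on the
    image so it stays invertible on the domain."""
    ny, nx = shape
    cx, cy = nx / 2, ny / 2
    angle = rng.uniform(-8, 8) * math.pi / 180
    s = rng.uniform(0.95, 1.08)
    tx, ty = rng.uniform(-8, 8, 2)
    ca, sa = s * math.cos(angle), s * math.sin(angle)
    # rotate/scale about the center, then translate
    a0 = cx - ca * cx + sa * cy + tx
    b0 = cy - sa * cx - ca * cy + ty
    aff = np.array([[a0, ca, -sa], [b0, sa, ca]])
    if family == "affine":
        return PlanarTransform("affine", aff)
    if family != "polynomial-2":
        raise ValueError(f"unknown transform family: {family!r}")
    coef = np.zeros((2, 6))
    coef[:, :3] = aff
    # small quadratic warp, a few pixels across the field of view
    mag = 4.0 / max(nx, ny) ** 2
    coef[:, 3:] = rng.uniform(-mag, mag, (2, 3))
    return PlanarTransform("polynomial-2", coef)


def make_scene(
    family: str = "polynomial-2",
    n_points: int = 7,
    jitter_sigma: float = 0.0,
    seed: int = 0,
    shape: tuple[int, int] = (256, 256),
    phantom: PhantomSpec | None = None,
    transform: PlanarTransform | None = None,
) -> GroundTruthScene:
    """Build a histology/T2WI pair linked by a known planar transform.

    Control points (5-8 by default, >= the family minimum: 3 for affine, 6
    for polynomial-2) are placed on the prostate boundary and internal
    landmarks in the histology frame; their fixed-frame mates are the
    forward-mapped positions plus optional Gaussian jitter of standard
    deviation ``jitter_sigma`` pixels.
    """
    if jitter_sigma < 0:
        raise ValueError("jitter sigma must be non-negative")
    min_pts = {"affine": 3, "polynomial-2": 6}.get(family)
    if min_pts is None:
        raise ValueError(f"unknown transform family: {family!r}")
    if n_points < min_pts:
        raise ValueError(
            f"{family} transform is under-determined with {n_points} points "
            f"(needs >= {min_pts})"
        )
    rng = np.random.default_rng(seed)
    spec = phantom or PhantomSpec()
    t2 = _t2_anatomy(shape, spec, rng)
    tf = transform or _true_transform(family, shape, rng)

    # histology = T2 anatomy observed through the forward transform plus an
    # appearance change (stain-like gamma + contrast)
    ny, nx = shape
    gx, gy = np.meshgrid(np.arange(nx, dtype=float), np.arange(ny, dtype=float))
    mapped = tf(np.column_stack([gx.ravel(), gy.ravel()]))
    hist = ndimage.map_coordinates(
        t2, np.stack([mapped[:, 1].reshape(shape), mapped[:, 0].reshape(shape)]),
        order=1, mode="constant", cval=0.0, prefilter=False,
    )
    hist = np.clip(hist, 0, 1) ** 0.7 * 0.9 + 0.05

    # control points on the prostate boundary + interior landmarks, in the
    # moving (histology) frame; kept away from the image edge
    scale = ny / spec.grid_shape[0]
    cx, cy = spec.prostate.cx * scale, spec.prostate.cy * scale
    rx, ry = spec.prostate.rx * scale * 0.95, spec.prostate.ry * scale * 0.95
    angles = np.sort(rng.uniform(0, 2 * math.pi, n_points))
    moving = np.column_stack([cx + rx * np.cos(angles), cy + ry * np.sin(angles)])
    # one interior landmark (urethra) replaces the last boundary point
    moving[-1] = (spec.tz.cx * scale, spec.tz.cy * scale)
    fixed = tf(moving)
    if jitter_sigma > 0:
        fixed = fixed + rng.normal(0, jitter_sigma, fixed.shape)
    points = ControlPointSet(moving=moving, fixed=fixed)

    # lesion in the histology frame is the pre-image of the fixed-frame
    # lesion: histology pixel x shows the anatomy at T(x), so x is lesion
    # tissue iff T(x) falls inside the fixed-frame lesion ellipse
    lesion_spec = spec.lesion or Ellipse(18, 42, 5, 4)
    lcx, lcy = lesion_spec.cx * scale, lesion_spec.cy * scale
    lrx, lry = lesion_spec.rx * scale, lesion_spec.ry * scale
    mx = mapped[:, 0].reshape(shape) + 0.5
    my = mapped[:, 1].reshape(shape) + 0.5
    lesion_hist = ((mx - lcx) / lrx) ** 2 + ((my - lcy) / lry) ** 2 <= 1.0
    lesion_zone = "pz"
    if phantom is not None and spec.lesion is not None:
        lesion_zone = phantom_masks(spec).get("lesion_zone", "pz")
    lesion_mask = ROIMask(lesion_hist, pixel_size=1.0, label="lesion", zone=lesion_zone)

    return GroundTruthScene(
        t2_image=t2,
        histology_image=hist,
        true_transform=tf,
        control_points=points,
        lesion_mask_histology=lesion_mask,
        jitter_sigma=jitter_sigma,
    )


# ---------------------------------------------------------------------------
# Cohort simulation


@dataclass
class SyntheticCohortSpec:
    """Population model for a synthetic study cohort.

    Controls (healthy volunteers) and patients (one lesion each) get
    per-zone ground-truth IVIM parameters built from linear age trends plus
    Gaussian between-subject variation.  Sign conventions follow the
    age-physiology the analysis is meant to detect: the perfusion fraction
    rises with age (benign hyperplasia angiogenesis), the pseudo-diffusion
    coefficient falls, and molecular diffusion is age-flat.  Lesions lower
    D relative to the subject's own contralateral normal tissue; lesion
    effects on f and D* default to zero.

    All f values are fractions (not percent); D and D* in mm^2/s; slopes
    are per year of age relative to ``ref_age``.
    """

    n_patients: int = 16
    n_controls: int = 22
    patient_age_range: tuple[float, float] = (50.0, 84.0)
    control_age_range: tuple[float, float] = (24.0, 49.0)
    ref_age: float = 35.0
    # per-zone baselines at ref_age: (f, D, D*)
    tz_baseline: tuple[float, float, float] = (0.388, 0.80e-3, 4.41e-3)
    pz_baseline: tuple[float, float, float] = (0.374, 0.82e-3, 5.80e-3)
    f_slope: float = 0.003          # fraction / year (positive)
    d_slope: float = 0.0            # mm^2/s / year (flat)
    dstar_slope: float = -0.05e-3   # mm^2/s / year (negative)
    f_sd: float = 0.08
    d_sd: float = 0.12e-3
    dstar_sd: float = 1.2e-3
    # lesion = subject's normal-zone value + effect + N(0, sd)
    lesion_d_effect: float = -0.29e-3
    lesion_f_effect: float = 0.0
    lesion_dstar_effect: float = 0.0
    lesion_d_sd: float = 0.15e-3
    lesion_f_sd: float = 0.06
    lesion_dstar_sd: float = 1.0e-3
    pz_lesion_fraction: float = 0.7
    s0: float = 100.0
    snr: float = 50.0
    seed: int = 0
    max_redraws: int = 100

    def zone_mean(self, zone: str, age: float) -> tuple[float, float, float]:
        base = self.tz_baseline if zone == "tz" else self.pz_baseline
        da = age - self.ref_age
        return (
            base[0] + self.f_slope * da,
            base[1] + self.d_slope * da,
            base[2] + self.dstar_slope * da,
        )


def _draw_valid(
    rng: np.random.Generator,
    mean: tuple[float, float, float],
    sd: tuple[float, float, float],
    max_redraws: int,
) -> tuple[float, float, float]:
    """Draw (f, D, D*) from independent Gaussians, redrawing until the
    parameter-map invariants hold (f in (0,1), D > 0, D* > D)."""
    for _ in range(max_redraws):
        f = rng.normal(mean[0], sd[0])
        d = rng.normal(mean[1], sd[1])
        ds = rng.normal(mean[2], sd[2])
        if 0.0 < f < 1.0 and d > 0.0 and ds > d:
            return f, d, ds
    raise RuntimeError(
        "could not draw valid IVIM parameters within the redraw cap; "
        "the cohort spec's means/SDs are inconsistent with the invariants"
    )


def simulate_cohort(spec: SyntheticCohortSpec, render: bool = False):
    """Simulate a study cohort of patients and healthy controls.

    Returns a ``pandas.DataFrame`` of per-subject ground truth (one row per
    subject: age, group, per-zone f/D/D*, lesion zone and parameters,
    Gleason group, enhancement label) and, when ``render=True``, a dict of
    subject id -> rendered noisy DWI study (stack, phantom spec, masks).

    Deterministic for a fixed seed.
    """
    import pandas as pd

    rng = np.random.default_rng(spec.seed)
    rows = []
    studies = {}
    n = spec.n_patients + spec.n_controls
    # Gleason split mirrors a 10:6 ratio of score-7 vs 8-9 lesions;
    # enhancement 11 yes / 4 no / rest unknown out of each 16.
    gleason_pool = ["<=7"] * round(spec.n_patients * 10 / 16)
    gleason_pool += [">7"] * (spec.n_patients - len(gleason_pool))
    rng.shuffle(gleason_pool)
    n_enh_yes = round(spec.n_patients * 11 / 16)
    n_enh_no = round(spec.n_patients * 4 / 16)
    enhanced_pool = ["yes"] * n_enh_yes + ["no"] * n_enh_no
    enhanced_pool += ["none"] * (spec.n_patients - len(enhanced_pool))
    rng.shuffle(enhanced_pool)

    sd = (spec.f_sd, spec.d_sd, spec.dstar_sd)
    lesion_sd = (spec.lesion_f_sd, spec.lesion_d_sd, spec.lesion_dstar_sd)
    for i in range(n):
        is_patient = i < spec.n_patients
        lo, hi = spec.patient_age_range if is_patient else spec.control_age_range
        age = float(rng.uniform(lo, hi))
        row = {
            "subject_id": f"S{i:03d}",
            "group": "patient" if is_patient else "control",
            "age": age,
        }
        zone_vals = {}
        for zone in ("tz", "pz"):
            f, d, ds = _draw_valid(rng, spec.zone_mean(zone, age), sd, spec.max_redraws)
            zone_vals[zone] = (f, d, ds)
            row[f"f_{zone}"], row[f"d_{zone}"], row[f"dstar_{zone}"] = f, d, ds
        if is_patient:
            zone = "pz" if rng.uniform() < spec.pz_lesion_fraction else "tz"
            nf, nd, nds = zone_vals[zone]
            lf, ld, lds = _draw_valid(
                rng,
                (
                    nf + spec.lesion_f_effect,
                    nd + spec.lesion_d_effect,
                    nds + spec.lesion_dstar_effect,
                ),
                lesion_sd,
                spec.max_redraws,
            )
            row.update(
                lesion_zone=zone, f_lesion=lf, d_lesion=ld, dstar_lesion=lds,
                gleason_group=gleason_pool[i], enhanced=enhanced_pool[i],
            )
        else:
            row.update(
                lesion_zone="", f_lesion=np.nan, d_lesion=np.nan,
                dstar_lesion=np.nan, gleason_group="none", enhanced="none",
            )
        rows.append(row)
        if render:
            studies[row["subject_id"]] = render_subject_study(
                row, spec, seed=int(rng.integers(0, 2**31 - 1))
            )
    df = pd.DataFrame(rows)
    return (df, studies) if render else df


def render_subject_study(row: dict, spec: SyntheticCohortSpec, seed: int) -> dict:
    """Render one subject's noisy DWI study from their ground-truth row."""
    tz_p = RegionParams(row["f_tz"], row["d_tz"], row["dstar_tz"], spec.s0)
    pz_p = RegionParams(row["f_pz"], row["d_pz"], row["dstar_pz"], spec.s0)
    lesion_ell = None
    lesion_p = LESION_DEFAULT
    if row.get("lesion_zone"):
        lesion_p = RegionParams(
            row["f_lesion"], row["d_lesion"], row["dstar_lesion"], spec.s0
        )
        lesion_ell = (
            Ellipse(18, 42, 5, 4) if row["lesion_zone"] == "pz" else Ellipse(26, 28, 4, 3)
        )
    pspec = PhantomSpec(
        lesion=lesion_ell, tz_params=tz_p, pz_params=pz_p, lesion_params=lesion_p
    )
    truth = make_phantom(pspec)
    scheme = AcquisitionScheme()
    clean = simulate_signal(truth, scheme)
    noisy = add_rician_noise(
        clean, NoiseModel(snr=spec.snr, seed=seed, s0_ref=spec.s0)
    )
    return {
        "phantom_spec": pspec,
        "truth": truth,
        "scheme": scheme,
        "stack": noisy,
        "masks": phantom_masks(pspec),
    }
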