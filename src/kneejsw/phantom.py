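"""Synthetic knee phantoms with known joint-space ground truth.

The phantom models the tibiofemoral joint as two single-valued bone-surface
height fields over a shared mediolateral/anteroposterior (x, y) grid: the
tibial plateau ``z_t(x, y)`` below and the femoral condylar surface
``z_f(x, y)`` above, each carrying a cartilage thickness map (mm).  The
radiolucent joint space is the bone-to-bone gap ``z_f - z_t``; the true
cartilage thickness is ``c_t + c_f``.  This is the geometric substrate on
which all four measurement techniques of the package operate:

* weight-bearing projectional JSW  — loaded phantom, 2D silhouette gap;
* non-weight-bearing projectional JSW — unloaded phantom, same code path;
* 3D perpendicular median JSW — unloaded phantom, surface ray casting;
* MRI-style mean cartilage thickness — unloaded phantom, thickness maps.

Weight bearing is modelled as a rigid settling of the femur that closes the
residual (non-contact) gap, plus a multiplicative compression of the
cartilage layers governed by a per-subject deformability coefficient.  A
meniscus is represented only by the fraction of load it carries, which
attenuates cartilage compression; more extruded menisci carry less load.

Axis convention: x mediolateral (medial at low x), y anteroposterior
(posterior at low y), z inferosuperior.  All lengths in millimetres.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ValidationError
from .volume import Volume3D

logger = logging.getLogger(__name__)

#: Fraction of joint load carried by the meniscus at each extrusion grade
#: (0 = no extrusion ... 3 = severe); an extruded meniscus unloads less.
MENISCAL_LOAD_SHARE = {0: 0.4, 1: 0.3, 2: 0.2, 3: 0.1}

MEDIAL, INTERCONDYLAR, LATERAL = "medial", "intercondylar", "lateral"


def _default_noise() -> dict[str, float]:
    # Per-modality measurement noise (mm, 1 sd) applied to cohort observations.
    return {"xray": 0.4, "ct2d": 0.25, "ct3d": 0.15, "mri": 0.1}


@dataclass
class PhantomSpec:
    """Parameters defining one synthetic knee.

    Thicknesses and gaps in mm; ``deformability`` is the fractional
    cartilage compression under full standard load (0 <= delta < 1).
    """

    extent_x: float = 70.0
    extent_y: float = 50.0
    step: float = 1.0
    cartilage_tibial: dict[str, float] = field(
        default_factory=lambda: {MEDIAL: 2.0, LATERAL: 2.6}
    )
    cartilage_femoral: dict[str, float] = field(
        default_factory=lambda: {MEDIAL: 2.0, LATERAL: 2.6}
    )
    condyle_radius: float = 0.0  # 0 = flat femoral surface
    plateau_tilt_deg: float = 0.0
    residual_gap: float = 0.4
    deformability: float = 0.15
    extrusion_grade: int = 0
    meniscal_load_share: float | None = None  # None -> by extrusion grade
    noise_sd: dict[str, float] = field(default_factory=_default_noise)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.step <= 0:
            raise ValidationError(f"grid step must be > 0, got {self.step}")
        if self.extent_x <= 0 or self.extent_y <= 0:
            raise ValidationError("grid extents must be positive")
        for maps in (self.cartilage_tibial, self.cartilage_femoral):
            for comp, c in maps.items():
                if c < 0:
                    raise ValidationError(f"negative cartilage thickness for {comp}: {c}")
        if not 0 <= self.deformability < 1:
            raise ValidationError(
                f"deformability must be in [0, 1), got {self.deformability}"
            )
        if self.residual_gap < 0:
            raise ValidationError("residual gap must be >= 0")
        if self.extrusion_grade not in (0, 1, 2, 3):
            raise ValidationError(
                f"meniscal extrusion grade must be 0-3, got {self.extrusion_grade}"
            )
        for name, sd in self.noise_sd.items():
            if sd < 0:
                raise ValidationError(f"negative noise sd for {name}")

    @property
    def load_share(self) -> float:
        if self.meniscal_load_share is not None:
            return self.meniscal_load_share
        return MENISCAL_LOAD_SHARE[self.extrusion_grade]


@dataclass
class KneePhantom:
    """Realized knee geometry on an (x, y) grid; all fields in mm."""

    x: np.ndarray  # (nx,) mediolateral coordinates
    y: np.ndarray  # (ny,) anteroposterior coordinates
    z_tibia: np.ndarray  # (nx, ny) tibial superior bone surface
    z_femur: np.ndarray  # (nx, ny) femoral inferior bone surface
    c_tibia: np.ndarray  # (nx, ny) tibial cartilage thickness
    c_femur: np.ndarray  # (nx, ny) femoral cartilage thickness
    compartments: np.ndarray  # (nx, ny) labels: medial | intercondylar | lateral
    loaded: bool = False
    spec: PhantomSpec | None = None

    @property
    def gap(self) -> np.ndarray:
        """Bone-to-bone distance map (mm)."""
        return self.z_femur - self.z_tibia

    def validate(self) -> None:
        total = self.c_tibia + self.c_femur
        if np.any(self.gap + 1e-9 < total):
            raise ValidationError("bone-to-bone gap smaller than cartilage stack")


def make_phantom(spec: PhantomSpec) -> KneePhantom:
    """Build an unloaded phantom from a spec.

    The femoral surface is the tibial surface offset by the cartilage stack
    plus the residual gap, with an optional spherical condylar sagitta so
    the gap widens away from each condyle apex.  Compartments are assigned
    by mediolateral thirds (medial | intercondylar | lateral).
    """
    x = np.arange(0.0, spec.extent_x + spec.step / 2, spec.step)
    y = np.arange(0.0, spec.extent_y + spec.step / 2, spec.step)
    xx, yy = np.meshgrid(x, y, indexing="ij")

    comp = np.full(xx.shape, INTERCONDYLAR, dtype="<U13")
    comp[xx < spec.extent_x / 3] = MEDIAL
    comp[xx > 2 * spec.extent_x / 3] = LATERAL

    c_t = np.empty_like(xx)
    c_f = np.empty_like(xx)
    mid_t = 0.5 * (spec.cartilage_tibial[MEDIAL] + spec.cartilage_tibial[LATERAL])
    mid_f = 0.5 * (spec.cartilage_femoral[MEDIAL] + spec.cartilage_femoral[LATERAL])
    for comp_name, t_val, f_val in (
        (MEDIAL, spec.cartilage_tibial[MEDIAL], spec.cartilage_femoral[MEDIAL]),
        (LATERAL, spec.cartilage_tibial[LATERAL], spec.cartilage_femoral[LATERAL]),
        (INTERCONDYLAR, mid_t, mid_f),
    ):
        sel = comp == comp_name
        c_t[sel] = t_val
        c_f[sel] = f_val

    z_t = np.tan(np.deg2rad(spec.plateau_tilt_deg)) * (xx - spec.extent_x / 2)

    sagitta = np.zeros_like(xx)
    if spec.condyle_radius > 0:
        R = spec.condyle_radius
        apex_y = spec.extent_y / 2
        sag = []
        for apex_x in (spec.extent_x / 6, 5 * spec.extent_x / 6):
            r = np.hypot(xx - apex_x, yy - apex_y)
            r_eff = np.minimum(r, 0.95 * R)  # flatten the rim: keep z_f finite
            sag.append(R - np.sqrt(R**2 - r_eff**2))
        sagitta = np.minimum(*sag)

    z_f = z_t + c_t + c_f + spec.residual_gap + sagitta
    ph = KneePhantom(x, y, z_t, z_f, c_t, c_f, comp, loaded=False, spec=spec)
    ph.validate()
    return ph


def apply_load(
    phantom: KneePhantom,
    load_fraction: float,
    deformability: float | None = None,
    meniscal_load_share: float | None = None,
) -> KneePhantom:
    """Return the weight-bearing state of an unloaded phantom.

    Cartilage maps shrink multiplicatively by
    ``1 - delta * load_fraction * (1 - meniscal load share)`` and the femur
    settles rigidly so the gap closes onto the compressed cartilage stack at
    the contact point (the residual gap collapses).  Bone surface shape is
    unchanged.  At zero load the geometry is returned unchanged.
    """
    if phantom.loaded:
        raise ValidationError("phantom is already loaded")
    if not 0 <= load_fraction <= 1:
        raise ValidationError(f"load_fraction must be in [0, 1], got {load_fraction}")
    spec = phantom.spec
    if deformability is None:
        deformability = spec.deformability if spec is not None else 0.0
    if meniscal_load_share is None:
        meniscal_load_share = spec.load_share if spec is not None else 0.0
    attenuation = 1.0 - meniscal_load_share
    compression = deformability * load_fraction * attenuation
    if deformability * load_fraction >= 1:
        raise ValidationError("deformability * load_fraction must be < 1")

    if load_fraction == 0:
        return replace(phantom, loaded=True)

    factor = 1.0 - compression
    c_t = phantom.c_tibia * factor
    c_f = phantom.c_femur * factor
    slack = phantom.z_femur - phantom.z_tibia - (c_t + c_f)
    settlement = float(np.nanmin(slack))
    z_f = phantom.z_femur - settlement
    out = replace(phantom, z_femur=z_f, c_tibia=c_t, c_femur=c_f, loaded=True)
    out.validate()
    return out


def render_ct(
    phantom: KneePhantom,
    spacing: float | tuple[float, float, float] = (0.5, 0.5, 0.5),
    noise_sd: float = 0.0,
    bone_intensity: float = 1000.0,
    bone_thickness: float = 8.0,
    seed: int | None = None,
) -> Volume3D:
    """Render a CT-like intensity volume of the phantom.

    Bone (below the tibial surface, above the femoral surface) is bright;
    cartilage and joint space are radiolucent (zero), as on CT.  Voxel
    intensities use partial-volume fractions at the bone surfaces so that
    sub-voxel surface positions are recoverable by interpolation.  Additive
    Gaussian noise with the given sd and seed.
    """
    if np.isscalar(spacing):
        spacing = (float(spacing),) * 3  # type: ignore[assignment]
    spacing = tuple(float(s) for s in spacing)  # type: ignore[arg-type]
    if any(s <= 0 for s in spacing):
        raise ValidationError(f"spacing must be positive, got {spacing}")
    min_gap = float(np.nanmin(phantom.gap))
    if max(spacing) > min_gap / 2:
        logger.warning(
            "voxel spacing %s coarser than half the minimum gap (%.2f mm): "
            "JSW may be unresolvable",
            spacing,
            min_gap,
        )

    sx, sy, sz = spacing
    xg = np.arange(phantom.x[0], phantom.x[-1] + sx / 2, sx)
    yg = np.arange(phantom.y[0], phantom.y[-1] + sy / 2, sy)
    z_lo = float(np.nanmin(phantom.z_tibia)) - bone_thickness
    z_hi = float(np.nanmax(phantom.z_femur)) + bone_thickness
    zg = np.arange(z_lo, z_hi + sz / 2, sz)

    from scipy.interpolate import RegularGridInterpolator

    pts = np.stack(np.meshgrid(xg, yg, indexing="ij"), axis=-1)
    z_t = RegularGridInterpolator(
        (phantom.x, phantom.y), phantom.z_tibia, bounds_error=False, fill_value=None
    )(pts)
    z_f = RegularGridInterpolator(
        (phantom.x, phantom.y), phantom.z_femur, bounds_error=False, fill_value=None
    )(pts)

    zc = zg[None, None, :]
    # fraction of each voxel slab occupied by bone (partial volume)
    occ_t = np.clip((z_t[..., None] - (zc - sz / 2)) / sz, 0.0, 1.0)
    occ_f = np.clip(((zc + sz / 2) - z_f[..., None]) / sz, 0.0, 1.0)
    data = bone_intensity * (occ_t + occ_f)

    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        data = data + rng.normal(0.0, noise_sd, size=data.shape)

    return Volume3D(
        data,
        spacing,
        origin=(float(phantom.x[0]), float(phantom.y[0]), float(zg[0])),
        meta={"loaded": phantom.loaded, "bone_intensity": bone_intensity},
    )


def observe_mri_thickness(
    phantom: KneePhantom, noise_sd: float = 0.0, seed: int | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Noisy MRI-style observation of the cartilage thickness maps.

    MRI is acquired non-weight-bearing: observing a loaded phantom is a
    contract violation.  Returns (tibial, femoral) maps with i.i.d.
    Gaussian noise, clipped at zero.
    """
    if phantom.loaded:
        raise ValidationError("MRI thickness observation requires an unloaded phantom")
    if noise_sd < 0:
        raise ValidationError(f"noise sd must be >= 0, got {noise_sd}")
    if noise_sd == 0:
        return phantom.c_tibia.copy(), phantom.c_femur.copy()
    rng = np.random.default_rng(seed)
    c_t = np.clip(phantom.c_tibia + rng.normal(0, noise_sd, phantom.c_tibia.shape), 0, None)
    c_f = np.clip(phantom.c_femur + rng.normal(0, noise_sd, phantom.c_femur.shape), 0, None)
    return c_t, c_f


@dataclass
class SubjectRecord:
    """One subject at one timepoint, with ground truth attached."""

    subject: int
    timepoint: str  # "baseline" | "2yr"
    unloaded: KneePhantom
    loaded: KneePhantom
    true_thickness: dict[str, float]  # per-compartment pooled mean cartilage thickness
    true_mac: str
    deformability: float


def simulate_cohort(
    n: int,
    effect_mean: float = 0.2,
    effect_sd: float = 0.1,
    delta_mean: float = 0.15,
    delta_sd: float = 0.08,
    delta_drift_sd: float = 0.08,
    thickness_mean: float = 2.0,
    thickness_sd: float = 0.9,
    base_spec: PhantomSpec | None = None,
    seed: int = 0,
) -> list[SubjectRecord]:
    """Simulate a two-timepoint cohort with a small treatment effect.

    Per subject: baseline most-affected-compartment cartilage thickness is
    drawn (truncated below at 0.3 mm), the 2-year thickness adds a subject
    treatment effect (mm, applied to both cartilage plates so the pooled
    mean thickness changes by the effect), and the deformability coefficient
    is drawn at baseline and drifts independently over the 2 years — the
    mechanism that decouples weight-bearing change from thickness change.
    Returns two records (baseline, 2yr) per subject.
    """
    if n < 2:
        raise ValidationError(f"cohort size must be >= 2, got {n}")
    rng = np.random.default_rng(seed)
    base = base_spec if base_spec is not None else PhantomSpec()
    records: list[SubjectRecord] = []
    n_truncated = 0
    for i in range(n):
        t0 = rng.normal(thickness_mean, thickness_sd)
        if t0 < 0.3:
            t0 = 0.3
            n_truncated += 1
        effect = rng.normal(effect_mean, effect_sd)
        d0 = float(np.clip(rng.normal(delta_mean, delta_sd), 0.0, 0.5))
        d1 = float(np.clip(d0 + rng.normal(0.0, delta_drift_sd), 0.0, 0.5))
        grade = int(rng.integers(0, 4))
        for timepoint, thick, delta in (("baseline", t0, d0), ("2yr", t0 + effect, d1)):
            thick = max(thick, 0.0)
            if thick == 0.0:
                n_truncated += 1
            spec = replace(
                base,
                cartilage_tibial={MEDIAL: thick, LATERAL: thick + 1.0},
                cartilage_femoral={MEDIAL: thick, LATERAL: thick + 1.0},
                deformability=delta,
                extrusion_grade=grade,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            unloaded = make_phantom(spec)
            loaded = apply_load(unloaded, 1.0)
            records.append(
                SubjectRecord(
                    subject=i,
                    timepoint=timepoint,
                    unloaded=unloaded,
                    loaded=loaded,
                    true_thickness={MEDIAL: thick, LATERAL: thick + 1.0},
                    true_mac=MEDIAL,
                    deformability=delta,
                )
            )
    if n_truncated:
        logger.info("truncated %d negative thickness draws at the floor", n_truncated)
    return records
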