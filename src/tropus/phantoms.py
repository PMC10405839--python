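"""Digital cross-section phantoms and synthetic study cohorts.

Every group of the fatty-liver study is encoded as a :class:`CohortSpec`
whose parameters are the published group statistics: liver speed of sound
(control 1538+-18 m/s, NAFLD-24w 1475+-34, NAFLD-36w 1473+-26 in vivo;
control 1525+-15, NAFLD 1495+-12 ex vivo), cross-sectional body area
(control 333+-21 mm^2, NAFLD 562+-29 / 598+-25 mm^2), group mean body
weights (30.7 / 42.3 / 42.9 g) and the liver lipid contrast of the disease
groups (+47% ex vivo, +16% and +37% in vivo).  A phantom is a 2D section:
an elliptical body (or agarose cylinder for excised samples), a smooth
liver blob with its own speed of sound and lipid load, blood vessels, a
pigmented skin rim, and acoustic scatterers for pulse-echo imaging.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .containers import Grid
from .spectra import CHROMOPHORES

__all__ = [
    "Phantom",
    "CohortSpec",
    "STUDY_GROUPS",
    "default_study_specs",
    "generate_phantom",
    "generate_cohort",
    "WATER_SOS",
    "TISSUE_SOS",
]

#: Coupling-water speed of sound at the 34 C operating temperature (m/s).
WATER_SOS = 1523.0
#: Default non-liver soft-tissue speed of sound (m/s).
TISSUE_SOS = 1540.0
#: Agarose embedding medium for excised samples (m/s).
AGAROSE_SOS = 1520.0

# Relative chromophore concentrations (a.u.).  The in-body lipid baseline is
# the "non-distinct absorption background" that the lipid metric subtracts;
# the control liver carries a lipid excess over that baseline, and disease
# groups scale the excess by the group's lipid contrast.
_INVIVO_BASE = {"hb": 0.30, "hbo2": 0.50, "melanin": 0.02, "lipid": 0.30}
_EXVIVO_BASE = {"hb": 0.05, "hbo2": 0.05, "melanin": 0.005, "lipid": 0.02}
# Liver blood is venous-dominated, so Hb outweighs HbO2; the lipid excess
# over the in-body baseline is what the disease contrast factor scales.
_LIVER_HB = 1.20
_LIVER_HBO2 = 0.15
_LIVER_LIPID_EXCESS = 0.06


@dataclass(frozen=True)
class CohortSpec:
    """Generating parameters of one study group."""

    group: str
    liver_sos_mean: float
    liver_sos_std: float
    area_mean: float
    area_std: float
    weight_mean: float
    lipid_contrast: float = 1.0
    n_sections: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.liver_sos_mean, self.area_mean, self.weight_mean) <= 0:
            raise ValueError("group means must be positive")
        if min(self.liver_sos_std, self.area_std) < 0:
            raise ValueError("standard deviations must be non-negative")
        if self.group.startswith("nafld") or self.group.endswith("nafld"):
            if self.lipid_contrast < 1.0:
                raise ValueError("disease groups require lipid_contrast >= 1")

    @property
    def ex_vivo(self) -> bool:
        return self.group.startswith("exvivo")


#: Published group parameters of the study (means/STDs as printed).
STUDY_GROUPS: dict[str, CohortSpec] = {
    "control": CohortSpec(
        group="control",
        liver_sos_mean=1538.0,
        liver_sos_std=18.0,
        area_mean=333.0,
        area_std=21.0,
        weight_mean=30.7,
        lipid_contrast=1.0,
        n_sections=20,
    ),
    "nafld_24w": CohortSpec(
        group="nafld_24w",
        liver_sos_mean=1475.0,
        liver_sos_std=34.0,
        area_mean=562.0,
        area_std=29.0,
        weight_mean=42.3,
        lipid_contrast=1.16,
        n_sections=20,
    ),
    "nafld_36w": CohortSpec(
        group="nafld_36w",
        liver_sos_mean=1473.0,
        liver_sos_std=26.0,
        area_mean=598.0,
        area_std=25.0,
        weight_mean=42.9,
        lipid_contrast=1.37,
        n_sections=20,
    ),
    # Excised livers embedded in a 20 mm agarose cylinder (area ~ pi*10^2).
    "exvivo_control": CohortSpec(
        group="exvivo_control",
        liver_sos_mean=1525.0,
        liver_sos_std=15.0,
        area_mean=314.16,
        area_std=8.0,
        weight_mean=1.2,
        lipid_contrast=1.0,
        n_sections=6,
    ),
    "exvivo_nafld": CohortSpec(
        group="exvivo_nafld",
        liver_sos_mean=1495.0,
        liver_sos_std=12.0,
        area_mean=314.16,
        area_std=8.0,
        weight_mean=1.3,
        lipid_contrast=1.47,
        n_sections=6,
    ),
}


def default_study_specs(seed: int = 0) -> list[CohortSpec]:
    """The three in vivo groups (20 sections each — the 60-image layout)."""
    return [
        replace(STUDY_GROUPS[g], seed=seed) for g in ("control", "nafld_24w", "nafld_36w")
    ]


@dataclass
class Phantom:
    """One 2D digital cross-section.

    ``concentration_maps`` is ``(4, ny, nx)`` in :data:`CHROMOPHORES` order;
    ``scatterers`` is ``(n, 3)`` columns (x mm, y mm, reflectivity a.u.);
    ``vessels`` is ``(n, 3)`` columns (x mm, y mm, radius mm).
    """

    grid: Grid
    sos_map: np.ndarray
    concentration_maps: np.ndarray
    scatterers: np.ndarray
    body_mask: np.ndarray
    liver_mask: np.ndarray
    water_sos: float = WATER_SOS
    vessels: np.ndarray = field(default_factory=lambda: np.zeros((0, 3)))
    liver_sos: float = float("nan")

    def __post_init__(self) -> None:
        if self.concentration_maps.shape != (len(CHROMOPHORES), *self.grid.shape):
            raise ValueError("concentration_maps must be (4, ny, nx)")
        if np.any(self.liver_mask & ~self.body_mask):
            raise ValueError("liver_mask must be contained in body_mask")
        if np.any(self.concentration_maps < 0):
            raise ValueError("concentrations must be non-negative")
        outside = ~self.body_mask
        if np.any(self.concentration_maps[:, outside] != 0):
            raise ValueError("concentrations must vanish outside the body")
        if not np.allclose(self.sos_map[outside], self.water_sos):
            raise ValueError("speed of sound outside the body must equal water")

    def concentration(self, name: str) -> np.ndarray:
        return self.concentration_maps[CHROMOPHORES.index(name)]

    @property
    def body_area_mm2(self) -> float:
        return float(self.body_mask.sum()) * self.grid.pixel_size**2


def _phantom_rng(spec: CohortSpec, section_index: int, seed: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), int(spec.seed), int(section_index)])
    )


def _ellipse_mask(grid: Grid, cx, cy, a, b, theta) -> np.ndarray:
    xx, yy = grid.meshgrid()
    ct, st = np.cos(theta), np.sin(theta)
    u = (xx - cx) * ct + (yy - cy) * st
    v = -(xx - cx) * st + (yy - cy) * ct
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def _blob_mask(grid: Grid, cx, cy, r0, aspect, theta, harmonics) -> np.ndarray:
    """Smooth star-convex blob: radius modulated by low-order harmonics."""
    xx, yy = grid.meshgrid()
    ct, st = np.cos(theta), np.sin(theta)
    u = (xx - cx) * ct + (yy - cy) * st
    v = -(xx - cx) * st + (yy - cy) * ct
    phi = np.arctan2(v / aspect, u)
    rr = np.hypot(u, v / aspect)
    mod = np.ones_like(phi)
    for k, (amp, phase) in harmonics.items():
        mod += amp * np.cos(k * phi + phase)
    return rr <= r0 * mod


def _mask_boundary_points(mask: np.ndarray, grid: Grid, spacing_mm: float, rng) -> np.ndarray:
    """Points along a mask boundary, approximately uniformly spaced."""
    from skimage import measure

    contours = measure.find_contours(mask.astype(float), 0.5)
    if not contours:
        return np.zeros((0, 2))
    contour = max(contours, key=len)  # rows are (iy, ix)
    xy = np.column_stack(
        [grid.origin[0] + contour[:, 1] * grid.pixel_size,
         grid.origin[1] + contour[:, 0] * grid.pixel_size]
    )
    seg = np.linalg.norm(np.diff(xy, axis=0), axis=1)
    arclen = np.concatenate([[0.0], np.cumsum(seg)])
    if arclen[-1] <= 0:
        return np.zeros((0, 2))
    n_pts = max(int(arclen[-1] / spacing_mm), 8)
    targets = np.linspace(0.0, arclen[-1], n_pts, endpoint=False)
    targets = (targets + rng.uniform(0, spacing_mm)) % arclen[-1]
    return np.column_stack(
        [np.interp(targets, arclen, xy[:, 0]), np.interp(targets, arclen, xy[:, 1])]
    )


def _smooth_field(shape, rng, sigma_px: float = 6.0) -> np.ndarray:
    """Unit-variance smooth Gaussian random field."""
    from scipy.ndimage import gaussian_filter

    f = gaussian_filter(rng.standard_normal(shape), sigma_px)
    return f / max(f.std(), 1e-12)


def generate_phantom(
    spec: CohortSpec,
    section_index: int,
    seed: int,
    grid: Grid | None = None,
    water_sos: float = WATER_SOS,
    tissue_sos: float | None = None,
    tissue_sos_heterogeneity: float | None = None,
) -> Phantom:
    """Draw one deterministic phantom from a group model.

    The body is an ellipse with area ~ N(area_mean, area_std^2); the liver
    is a smooth blob occupying 15-30% of the body with speed of sound
    ~ N(liver_sos_mean, liver_sos_std^2), constant within the liver.
    Identical ``(spec, section_index, seed)`` always yields the identical
    phantom.
    """
    if grid is None:
        grid = Grid.centered(96, 0.5)
    if tissue_sos is None:
        tissue_sos = AGAROSE_SOS if spec.ex_vivo else TISSUE_SOS
    if tissue_sos_heterogeneity is None:
        tissue_sos_heterogeneity = 0.0 if spec.ex_vivo else 8.0
    rng = _phantom_rng(spec, section_index, seed)

    area = rng.normal(spec.area_mean, spec.area_std)
    attempts = 0
    while area <= 0:
        attempts += 1
        if attempts >= 10:
            raise ValueError("sampled body area remained non-positive after 10 attempts")
        import warnings

        warnings.warn("sampled non-positive body area; resampling", stacklevel=2)
        area = rng.normal(spec.area_mean, spec.area_std)

    aspect = rng.uniform(0.9, 1.0) if spec.ex_vivo else rng.uniform(0.72, 0.92)
    theta = rng.uniform(0.0, np.pi)
    a = np.sqrt(area / (np.pi * aspect))
    b = aspect * a
    jitter = 0.5 if spec.ex_vivo else 1.5
    cx, cy = rng.uniform(-jitter, jitter, size=2)
    fov_x = (grid.nx - 1) / 2.0 * grid.pixel_size
    fov_y = (grid.ny - 1) / 2.0 * grid.pixel_size
    if a + max(abs(cx), abs(cy)) > min(fov_x, fov_y):
        raise ValueError(
            f"grid half-extent {min(fov_x, fov_y):.1f} mm cannot contain the "
            f"sampled body (semi-axis {a:.1f} mm)"
        )
    body = _ellipse_mask(grid, cx, cy, a, b, theta)

    # Liver: smooth blob, 15-30% of the body area, offset from the centre.
    frac = rng.uniform(0.15, 0.30)
    r_liver = np.sqrt(frac * area / np.pi)
    off_phi = rng.uniform(0.0, 2 * np.pi)
    off_r = rng.uniform(0.15, 0.35) * b
    lx = cx + off_r * np.cos(off_phi)
    ly = cy + off_r * np.sin(off_phi)
    harmonics = {
        k: (rng.uniform(0.0, 0.08), rng.uniform(0.0, 2 * np.pi)) for k in (2, 3, 4)
    }
    liver = _blob_mask(grid, lx, ly, r_liver, rng.uniform(0.85, 1.0), rng.uniform(0, np.pi), harmonics)
    liver &= body

    liver_sos = float(rng.normal(spec.liver_sos_mean, spec.liver_sos_std))
    sos = np.full(grid.shape, water_sos)
    sos[body] = tissue_sos
    if tissue_sos_heterogeneity > 0:
        het = _smooth_field(grid.shape, rng) * tissue_sos_heterogeneity
        sos[body] += het[body]
    sos[liver] = liver_sos

    base = _EXVIVO_BASE if spec.ex_vivo else _INVIVO_BASE
    conc = np.zeros((len(CHROMOPHORES), *grid.shape))
    for j, name in enumerate(CHROMOPHORES):
        conc[j][body] = base[name]
    liver_lipid = base["lipid"] + _LIVER_LIPID_EXCESS * spec.lipid_contrast
    conc[CHROMOPHORES.index("hb")][liver] = _LIVER_HB
    conc[CHROMOPHORES.index("hbo2")][liver] = _LIVER_HBO2
    conc[CHROMOPHORES.index("lipid")][liver] = liver_lipid

    # Pigmented skin rim (in vivo only): melanin band inside the body edge.
    if not spec.ex_vivo:
        rim = body & ~_ellipse_mask(grid, cx, cy, a - 0.6, b - 0.6, theta)
        conc[CHROMOPHORES.index("melanin")][rim] = 0.8

    # Blood vessels: small high-hemoglobin disks inside the body.
    n_vessels = rng.integers(2, 6) if not spec.ex_vivo else rng.integers(1, 3)
    vessels = []
    host = liver if spec.ex_vivo else body
    hy, hx = np.nonzero(host)
    # excised tissue deoxygenates, so ex vivo vessels are Hb-dominated
    v_hb, v_hbo2 = (2.0, 0.3) if spec.ex_vivo else (1.2, 1.8)
    for _ in range(int(n_vessels)):
        i = rng.integers(hy.size)
        vx = grid.origin[0] + hx[i] * grid.pixel_size
        vy = grid.origin[1] + hy[i] * grid.pixel_size
        vr = rng.uniform(0.5, 1.2)
        disk = _ellipse_mask(grid, vx, vy, vr, vr, 0.0) & body
        conc[CHROMOPHORES.index("hb")][disk] = v_hb
        conc[CHROMOPHORES.index("hbo2")][disk] = v_hbo2
        vessels.append((vx, vy, vr))

    # Scatterers: a dense reflective skin/agarose interface, a weaker liver
    # capsule, and 200-1000 random sub-resolution scatterers in the body.
    body_pts = _mask_boundary_points(body, grid, 0.35, rng)
    liver_pts = _mask_boundary_points(liver, grid, 0.5, rng)
    n_rand = int(rng.integers(200, 1001))
    by, bx = np.nonzero(body)
    idx = rng.integers(0, by.size, size=n_rand)
    rand_xy = np.column_stack(
        [grid.origin[0] + bx[idx] * grid.pixel_size + rng.uniform(-0.25, 0.25, n_rand),
         grid.origin[1] + by[idx] * grid.pixel_size + rng.uniform(-0.25, 0.25, n_rand)]
    )
    scatterers = np.vstack(
        [
            np.column_stack([body_pts, np.full(len(body_pts), 1.0) * rng.uniform(0.8, 1.2, len(body_pts))]),
            np.column_stack([liver_pts, rng.uniform(0.2, 0.4, len(liver_pts))]),
            np.column_stack([rand_xy, rng.uniform(0.02, 0.10, n_rand)]),
        ]
    )

    return Phantom(
        grid=grid,
        sos_map=sos,
        concentration_maps=conc,
        scatterers=scatterers,
        body_mask=body,
        liver_mask=liver,
        water_sos=water_sos,
        vessels=np.asarray(vessels, dtype=float).reshape(-1, 3),
        liver_sos=liver_sos,
    )


def generate_cohort(
    specs: list[CohortSpec],
    seed: int = 0,
    grid: Grid | None = None,
    sections_per_mouse: int = 5,
) -> tuple[list[Phantom], pd.DataFrame]:
    """Generate all phantoms of a study plus the ground-truth table.

    Returns the phantoms (spec order, section-major) and a DataFrame with
    columns ``section_id, group, mouse_id, liver_sos, lipid_metric, area,
    weight`` holding the generating ground truth per section.  Weights are
    drawn per mouse from a normal with 10% coefficient of variation around
    the group mean.
    """
    labels = [s.group for s in specs]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate group labels in cohort specs")
    phantoms: list[Phantom] = []
    rows = []
    for spec in specs:
        if spec.n_sections < 1:
            raise ValueError(f"group {spec.group}: n_sections must be >= 1")
        group_tag = zlib.crc32(spec.group.encode()) % 100_000
        weight_rng = np.random.default_rng(
            np.random.SeedSequence([int(seed), int(spec.seed), 10_000 + group_tag])
        )
        n_mice = int(np.ceil(spec.n_sections / sections_per_mouse))
        weights = weight_rng.normal(spec.weight_mean, 0.1 * spec.weight_mean, size=n_mice)
        for k in range(spec.n_sections):
            ph = generate_phantom(spec, k, seed, grid=grid)
            phantoms.append(ph)
            mouse = k // sections_per_mouse
            rows.append(
                {
                    "section_id": f"{spec.group}_{k:03d}",
                    "group": spec.group,
                    "mouse_id": f"{spec.group}_m{mouse}",
                    "liver_sos": ph.liver_sos,
                    "lipid_metric": _LIVER_LIPID_EXCESS * spec.lipid_contrast,
                    "area": ph.body_area_mm2,
                    "weight": float(weights[mouse]),
                }
            )
    return phantoms, pd.DataFrame(rows)
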