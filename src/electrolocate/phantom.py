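"""Synthetic head phantoms.

Generates everything the localization pipeline consumes — a postimplant
CT with electrode artifacts, gray/white tissue-probability maps, a toy
MNI-space atlas with its label table, forward and inverse deformation
fields, and the ground truth of every planted quantity — so the full
pipeline is testable without patient data.

The head is an ellipsoidal brain (white-matter core wrapped in a gray
shell) inside a bright skull shell; electrode contacts are isotropic
Gaussian blobs at metal-artifact intensity placed along depth-lead or
grid geometries.  The phantom's "MNI" space is the patient grid under a
known affine, so deformation-field operations have a closed-form oracle.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .geometry import GridSpec, LeadSpec
from .labeling import AtlasVolume, DeformationField
from .volumes import Volume

AIR_HU = -1000.0
SOFT_TISSUE_HU = 40.0

# octant label names, indexed 1..8 by (x>0) + 2*(y>0) + 4*(z>0) + 1
OCTANT_NAMES = {
    1: "left_posterior_inferior",
    2: "right_posterior_inferior",
    3: "left_anterior_inferior",
    4: "right_anterior_inferior",
    5: "left_posterior_superior",
    6: "right_posterior_superior",
    7: "left_anterior_superior",
    8: "right_anterior_superior",
}


@dataclass
class LeadPlacement:
    """A depth lead in the phantom: spec + tip position + outward unit
    direction (from the deepest contact toward the skull entry)."""

    spec: LeadSpec
    tip_mm: np.ndarray
    out_direction: np.ndarray

    def __post_init__(self) -> None:
        self.tip_mm = np.asarray(self.tip_mm, dtype=float)
        d = np.asarray(self.out_direction, dtype=float)
        self.out_direction = d / np.linalg.norm(d)


@dataclass
class GridPlacement:
    """An ECoG grid/strip: spec + plane center + outward plane normal."""

    spec: GridSpec
    center_mm: np.ndarray
    normal: np.ndarray
    name: str = "G"

    def __post_init__(self) -> None:
        self.center_mm = np.asarray(self.center_mm, dtype=float)
        n = np.asarray(self.normal, dtype=float)
        self.normal = n / np.linalg.norm(n)


def _default_leads() -> list:
    # three leads spanning white core and gray shell, mutually > 4 mm apart
    return [
        LeadPlacement(LeadSpec.regular("LA", 8, 3.5), (-16.0, -4.0, 2.0), (0.97, 0.2, 0.15)),
        LeadPlacement(LeadSpec.regular("RB", 8, 3.5), (14.0, 8.0, -6.0), (-0.9, -0.3, 0.4)),
        LeadPlacement(
            LeadSpec("LC", 10, [3.5] * 4 + [7.0] + [3.5] * 4),
            (4.3, -19.3, -3.9),
            (-0.22, 0.95, -0.23),
        ),
    ]


@dataclass
class PhantomSpec:
    """Study conditions for one synthetic head.

    Defaults: 0.4-mm isotropic voxels (the pipeline's working
    resolution), a compact ellipsoidal brain, skull at 1500 HU and
    electrode artifacts peaking at 3000 HU — comfortably above the CT's
    99th intensity percentile so the detection threshold sweep brackets
    them.  ``seed`` makes the output bit-reproducible.
    """

    grid_shape: tuple = (128, 128, 112)
    voxel_mm: float = 0.4
    brain_radii_mm: tuple = (22.0, 24.0, 20.0)
    gray_shell_mm: float = 6.0
    skull_gap_mm: float = 4.0
    skull_thickness_mm: float = 2.5
    skull_hu: float = 1500.0
    electrode_hu: float = 3000.0
    contact_radius_mm: float = 1.3
    noise_sigma_hu: float = 0.0
    leads: list = field(default_factory=_default_leads)
    grids: list = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.brain_radii_mm) - self.gray_shell_mm <= 0:
            raise ValueError("gray shell thicker than the brain ellipsoid")


@dataclass
class PhantomTruth:
    """Everything planted in the phantom, for oracle-style checks."""

    contacts: list  # dicts: group, index, position_mm, tissue, atlas info
    mni_affine: np.ndarray
    optimal_intensity_hu: float

    @property
    def positions_mm(self) -> np.ndarray:
        return np.array([c["position_mm"] for c in self.contacts]).reshape(-1, 3)

    def to_json(self) -> str:
        def conv(o):
            if isinstance(o, np.ndarray):
                return o.tolist()
            if isinstance(o, (np.floating, np.integer)):
                return o.item()
            raise TypeError(type(o))

        return json.dumps(
            {
                "contacts": self.contacts,
                "mni_affine": self.mni_affine,
                "optimal_intensity_hu": self.optimal_intensity_hu,
            },
            default=conv,
            indent=2,
        )


# ---------------------------------------------------------------------------
# Geometry helpers


def make_lead_positions(tip_mm, direction, spec: LeadSpec) -> np.ndarray:
    """Contact centers of a lead, deepest first.

    ``tip_mm`` is the deepest contact; ``direction`` is the unit vector
    from the tip toward the skull entry; successive contacts sit at the
    cumulative gap spacings along it.
    """
    direction = np.asarray(direction, dtype=float)
    direction = direction / np.linalg.norm(direction)
    offsets = np.concatenate([[0.0], np.cumsum(spec.gap_spacings_mm)])
    return np.asarray(tip_mm, dtype=float) + offsets[:, None] * direction


def make_grid_positions(spec: GridSpec, center_mm, normal):
    """Planar row-major lattice of rows x cols contacts at the grid
    pitch, in the plane perpendicular to ``normal``; returns (positions,
    labels) with labels 'R{row}C{col}'."""
    normal = np.asarray(normal, dtype=float)
    normal = normal / np.linalg.norm(normal)
    e = np.eye(3)[int(np.argmin(np.abs(normal)))]
    u = np.cross(normal, e)
    u /= np.linalg.norm(u)
    v = np.cross(normal, u)
    center = np.asarray(center_mm, dtype=float)
    positions = []
    labels = []
    for r in range(spec.rows):
        for c in range(spec.cols):
            du = (r - (spec.rows - 1) / 2.0) * spec.pitch_mm
            dv = (c - (spec.cols - 1) / 2.0) * spec.pitch_mm
            positions.append(center + du * u + dv * v)
            labels.append(f"R{r + 1}C{c + 1}")
    return np.array(positions), labels


def random_leads(
    rng: np.random.Generator,
    brain_radii_mm,
    n_leads: int,
    n_contacts: int = 10,
    spacing_mm: float = 3.5,
    max_rho: float = 0.85,
    min_clearance_mm: float = 4.0,
    max_tries: int = 2000,
) -> list:
    """Sample non-intersecting depth-lead placements inside the brain.

    Leads are straight chords whose contacts all lie within ``max_rho``
    of the normalized ellipsoid radius and at least ``min_clearance_mm``
    from every contact of previously placed leads.
    """
    radii = np.asarray(brain_radii_mm, dtype=float)
    for _restart in range(30):  # greedy placement can wedge; restart fresh
        placed: list = []
        existing: list = []
        for _try in range(max_tries):
            if len(placed) == n_leads:
                return placed
            spec = LeadSpec.regular(f"L{len(placed) + 1}", n_contacts, spacing_mm)
            tip = rng.uniform(-0.7, 0.7, size=3) * radii
            # aim roughly through the brain center so long chords fit
            d = rng.uniform(-0.25, 0.25, size=3) * radii - tip
            norm = np.linalg.norm(d)
            if norm < 1e-6:
                continue
            d /= norm
            pts = make_lead_positions(tip, d, spec)
            if np.sqrt(((pts / radii) ** 2).sum(axis=1)).max() > max_rho:
                continue
            if existing:
                dmin = np.linalg.norm(
                    pts[:, None, :] - np.vstack(existing)[None, :, :], axis=2
                ).min()
                if dmin < min_clearance_mm:
                    continue
            placed.append(LeadPlacement(spec, tip, d))
            existing.append(pts)
        if len(placed) == n_leads:
            return placed
    raise RuntimeError(f"could not place {n_leads} leads of {n_contacts} contacts")


# ---------------------------------------------------------------------------
# Volume synthesis


def _centered_affine(shape, voxel_mm: float) -> np.ndarray:
    affine = np.eye(4)
    affine[:3, :3] *= voxel_mm
    affine[:3, 3] = -voxel_mm * (np.asarray(shape) - 1) / 2.0
    return affine


def _world_coords(shape, affine) -> np.ndarray:
    """(X, Y, Z, 3) array of world-mm voxel-center coordinates."""
    i = np.arange(shape[0])[:, None, None]
    j = np.arange(shape[1])[None, :, None]
    k = np.arange(shape[2])[None, None, :]
    out = np.empty(tuple(shape) + (3,), dtype=float)
    for a in range(3):
        out[..., a] = affine[a, 0] * i + affine[a, 1] * j + affine[a, 2] * k + affine[a, 3]
    return out


def _ellipsoid_rho(world: np.ndarray, radii) -> np.ndarray:
    """Normalized ellipsoidal radius (1.0 on the ellipsoid surface)."""
    return np.sqrt(
        (world[..., 0] / radii[0]) ** 2
        + (world[..., 1] / radii[1]) ** 2
        + (world[..., 2] / radii[2]) ** 2
    )


def _add_blob(ct, affine, inv_affine, center_mm, peak_hu, sigma_mm, voxel_mm):
    cvox = inv_affine[:3, :3] @ center_mm + inv_affine[:3, 3]
    half = int(np.ceil(4 * sigma_mm / voxel_mm))
    lo = np.maximum(0, np.floor(cvox).astype(int) - half)
    hi = np.minimum(np.array(ct.shape), np.floor(cvox).astype(int) + half + 1)
    if np.any(lo >= hi):
        raise ValueError(f"contact outside grid: {center_mm}")
    sub = np.meshgrid(*(np.arange(l, h) for l, h in zip(lo, hi)), indexing="ij")
    d2 = sum(((g - c) * voxel_mm) ** 2 for g, c in zip(sub, cvox))
    blob = peak_hu * np.exp(-d2 / (2.0 * sigma_mm**2))
    region = ct[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]]
    np.maximum(region, blob, out=region)


def _tissue_class_of(rho: float, spec: PhantomSpec, margin_mm: float = 2.0) -> str:
    """Planted tissue class with a safety margin from interfaces."""
    r_min = min(spec.brain_radii_mm)
    inner = 1.0 - spec.gray_shell_mm / r_min  # conservative core bound
    m = margin_mm / r_min
    if rho <= inner - m:
        return "white"
    if inner + m <= rho <= 1.0 - m:
        return "gray"
    if rho > 1.0 + m:
        return "unknown"
    return "boundary"


def make_head_phantom(spec: PhantomSpec):
    """Build one synthetic head.

    Returns ``(ct, gm, wm, atlas, (forward_field, inverse_field), truth)``
    where the forward field maps patient -> MNI (an affine by
    construction) and the inverse field maps MNI -> patient.
    """
    rng = np.random.default_rng(spec.seed)
    shape = tuple(int(s) for s in spec.grid_shape)
    affine = _centered_affine(shape, spec.voxel_mm)
    inv_affine = np.linalg.inv(affine)

    patient_world = _world_coords(shape, affine)
    rho = _ellipsoid_rho(patient_world, spec.brain_radii_mm)
    radii = np.asarray(spec.brain_radii_mm)
    r_min = float(radii.min())

    # ---- CT -------------------------------------------------------------
    ct = np.full(shape, AIR_HU)
    ct[rho <= 1.0 + (spec.skull_gap_mm + spec.skull_thickness_mm) / r_min] = SOFT_TISSUE_HU
    skull_lo = 1.0 + spec.skull_gap_mm / r_min
    skull_hi = skull_lo + spec.skull_thickness_mm / r_min
    ct[(rho >= skull_lo) & (rho <= skull_hi)] = spec.skull_hu

    # ---- tissue probability maps ---------------------------------------
    inner = 1.0 - spec.gray_shell_mm / r_min
    wm_hard = (rho <= inner).astype(float)
    gm_hard = ((rho > inner) & (rho <= 1.0)).astype(float)
    smooth_vox = max(0.5, 0.8 / spec.voxel_mm)
    gm_map = ndimage.gaussian_filter(gm_hard, smooth_vox)
    wm_map = ndimage.gaussian_filter(wm_hard, smooth_vox)
    gm = Volume(gm_map, affine, space_tag="patient")
    wm = Volume(wm_map, affine, space_tag="patient")

    # ---- contacts -------------------------------------------------------
    sigma_mm = 2.0 * spec.contact_radius_mm / 2.355  # FWHM = 2 x contact radius
    mni_affine = _mni_affine()
    contacts = []

    def plant(group, positions, labels=None, kind="lead"):
        for i, p in enumerate(positions):
            _add_blob(ct, affine, inv_affine, p, spec.electrode_hu, sigma_mm, spec.voxel_mm)
            rho_p = float(np.sqrt(np.sum((p / radii) ** 2)))
            mni_p = mni_affine[:3, :3] @ p + mni_affine[:3, 3]
            octant = _octant_label(mni_p)
            contacts.append(
                {
                    "group": group,
                    "index": i,
                    "label": labels[i] if labels else f"{group}{i + 1}",
                    "position_mm": p.tolist(),
                    "mni_mm": mni_p.tolist(),
                    "tissue": _tissue_class_of(rho_p, spec),
                    "atlas_label": OCTANT_NAMES[octant],
                    "atlas_index": octant,
                    "atlas_interior": _octant_interior(mni_p, margin_mm=2.0),
                    "kind": kind,
                }
            )

    for lp in spec.leads:
        plant(lp.spec.name, make_lead_positions(lp.tip_mm, lp.out_direction, lp.spec))
    for gp in spec.grids:
        positions, labels = make_grid_positions(gp.spec, gp.center_mm, gp.normal)
        plant(gp.name, positions, labels=labels, kind="grid")

    if spec.noise_sigma_hu > 0:
        ct = ct + rng.normal(0.0, spec.noise_sigma_hu, size=shape)

    ct_vol = Volume(ct, affine, space_tag="patient")

    # ---- toy atlas and deformation fields -------------------------------
    forward, inverse = make_affine_fields(shape, affine, mni_affine, patient_world)
    # the phantom's MNI grid is the patient grid under the known affine,
    # so the atlas labels can be read off the forward field's values
    atlas = _octant_atlas_from_world(forward.values, mni_affine @ affine)

    truth = PhantomTruth(
        contacts=contacts,
        mni_affine=mni_affine,
        optimal_intensity_hu=float(spec.electrode_hu),
    )
    return ct_vol, gm, wm, atlas, (forward, inverse), truth


def _mni_affine() -> np.ndarray:
    """Fixed, invertible patient->MNI affine (scale + shear-free rotation
    + translation) used by every phantom so field tests have a closed
    form."""
    a = np.eye(4)
    a[:3, :3] = np.diag([1.05, 0.95, 1.02])
    a[:3, 3] = [2.0, -3.0, 1.5]
    return a


def _octant_label(mni_p: np.ndarray) -> int:
    return 1 + int(mni_p[0] > 0) + 2 * int(mni_p[1] > 0) + 4 * int(mni_p[2] > 0)


def _octant_interior(mni_p: np.ndarray, margin_mm: float = 2.0) -> bool:
    return bool(np.all(np.abs(mni_p) >= margin_mm))


def make_octant_atlas(shape, mni_grid_affine) -> AtlasVolume:
    """Blockwise toy atlas on an MNI-space grid: labels 1..8 by
    coordinate-sign octant."""
    world = _world_coords(tuple(int(s) for s in shape), np.asarray(mni_grid_affine, float))
    return _octant_atlas_from_world(world, mni_grid_affine)


def _octant_atlas_from_world(mni_world: np.ndarray, mni_grid_affine) -> AtlasVolume:
    labels = (
        1
        + (mni_world[..., 0] > 0).astype(np.int32)
        + 2 * (mni_world[..., 1] > 0).astype(np.int32)
        + 4 * (mni_world[..., 2] > 0).astype(np.int32)
    )
    vol = Volume(labels, np.asarray(mni_grid_affine, dtype=float), space_tag="mni")
    return AtlasVolume(vol, dict(OCTANT_NAMES), name="octants")


def make_affine_fields(shape, patient_affine, mni_affine, patient_world=None):
    """Forward (patient->MNI) and exact inverse (MNI->patient)
    deformation fields for a known affine, in the absolute-coordinate
    convention.

    The phantom's MNI grid is the patient grid carried through the
    affine, so the inverse field's values are exactly the patient voxel
    coordinates.
    """
    patient_affine = np.asarray(patient_affine, dtype=float)
    mni_affine = np.asarray(mni_affine, dtype=float)
    if patient_world is None:
        patient_world = _world_coords(tuple(int(s) for s in shape), patient_affine)
    flat = patient_world.reshape(-1, 3)
    mni_world = (flat @ mni_affine[:3, :3].T + mni_affine[:3, 3]).reshape(
        patient_world.shape
    )
    forward = DeformationField(mni_world, patient_affine, direction="patient_to_mni")
    mni_grid_affine = mni_affine @ patient_affine
    inverse = DeformationField(
        patient_world.copy(), mni_grid_affine, direction="mni_to_patient"
    )
    return forward, inverse


# ---------------------------------------------------------------------------
# Disk output


def write_phantom(spec: PhantomSpec, outdir) -> None:
    """Write a full phantom dataset: CT.nii, MRGray.nii, MRWhite.nii,
    iy_MR.nii / y_MR.nii deformation fields, the toy atlas with its
    label table, and truth.json."""
    import pathlib

    import nibabel as nib

    outdir = pathlib.Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ct, gm, wm, atlas, (forward, inverse), truth = make_head_phantom(spec)
    from .volumes import save_volume

    save_volume(ct, outdir / "CT.nii")
    save_volume(gm, outdir / "MRGray.nii")
    save_volume(wm, outdir / "MRWhite.nii")
    nib.save(nib.Nifti1Image(forward.values, forward.affine), outdir / "iy_MR.nii")
    nib.save(nib.Nifti1Image(inverse.values, inverse.affine), outdir / "y_MR.nii")
    save_volume(atlas.labels, outdir / "octants.nii")
    from .labeling import save_atlas_table

    save_atlas_table(atlas.table, outdir / "octants.txt")
    (outdir / "truth.json").write_text(truth.to_json())
    (outdir / "manifest.json").write_text(
        json.dumps({"seed": spec.seed, "voxel_mm": spec.voxel_mm}, indent=2)
    )
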