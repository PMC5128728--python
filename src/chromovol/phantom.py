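"""Synthetic SBF-SEM-like volumes of mitotic chromosomes, with ground truth.

The generator emulates the imaging regime of a serial block-face SEM stack
of a mitotic cell: dark tubular chromosomes on a lighter cytoplasmic
background, an optional perichromosomal shell of intermediate gray, a
nucleolus that is lighter than the condensed chromatin, a thin
nuclear-envelope shell, and additive Gaussian noise on an 8-bit scale.
Chromosomes are drawn as tubes around smooth random space curves;
prophase-style objects add a band-limited radial perturbation ("lumps"),
metaphase-style objects are smooth with a larger, tighter diameter
distribution (1.15 +/- 0.12 um for a paired-chromatid unit versus
0.64 +/- 0.19 um at prophase).

Every voxel of every object is known exactly, so the downstream
segmentation, morphometry and accounting stages are testable end to end
without any acquired dataset.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import interpolate, ndimage
from scipy.spatial import cKDTree

from chromovol.volume_io import NM_PER_UM, LabelVolume, VoxelGrid
from chromovol.proteomics import ProteinIntensityTable


class PackingError(RuntimeError):
    """Requested tube count/volume cannot be placed in the image volume."""


@dataclass(frozen=True)
class GrayLevels:
    """Mean 8-bit intensities of the phantom compartments.

    Chromatin is darker than the nucleolus by the observed ~36% contrast
    (chromatin = 0.64 x nucleolus by default).
    """

    background: float = 200.0
    chromatin: float = 80.0
    periphery: float = 120.0
    nucleolus: float = 125.0
    envelope: float = 50.0

    def validate(self) -> None:
        if not self.chromatin < self.nucleolus:
            raise ValueError("chromatin gray level must be below (darker than) the nucleolus")


@dataclass(frozen=True)
class Tube:
    """One explicit tube: a polyline centerline plus a diameter.

    ``points_um`` is (N, 3) in (z, y, x) order, micrometres. Straight
    two-point tubes may request flat caps so the closed-form cylinder
    volume pi r^2 h holds exactly.
    """

    points_um: np.ndarray
    diameter_um: float
    flat_caps: bool = False

    @staticmethod
    def straight(start_um, end_um, diameter_um: float, flat_caps: bool = True) -> "Tube":
        pts = np.asarray([start_um, end_um], dtype=float)
        return Tube(points_um=pts, diameter_um=float(diameter_um), flat_caps=flat_caps)


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of a synthetic chromosome-complement volume.

    Defaults describe a scaled-down metaphase complement: 46 smooth tubes
    with diameters ~N(1.15, 0.12) um summing to 175.9 um^3, coated by a
    150 nm periphery shell, at (120, 48, 48) nm voxel pitch.
    """

    image_shape: tuple[int, int, int] = (150, 256, 256)
    spacing_nm: tuple[float, float, float] = (120.0, 48.0, 48.0)
    n_chromosomes: int = 46
    tube_diameter_um: tuple[float, float] = (1.15, 0.12)  # mean, sd
    total_volume_um3: float = 175.9
    periphery_thickness_nm: float = 150.0
    gray_levels: GrayLevels = field(default_factory=GrayLevels)
    nucleolus_radius_um: float = 0.0
    envelope_radius_um: float = 0.0
    envelope_thickness_nm: float = 120.0
    seed_on_envelope: bool = False
    stage: str = "metaphase"
    lump_amplitude: float = 0.25     # relative radius perturbation, prophase only
    lump_scale_um: float = 0.35      # correlation length of the perturbation
    clumped: bool = False            # allow tubes to touch/overlap (periphery-loss analogue)
    noise_sd: float = 0.0
    seed: int = 0
    tubes: tuple[Tube, ...] | None = None  # explicit geometry overrides random placement

    def validate(self) -> None:
        if any(s <= 0 for s in self.spacing_nm):
            raise ValueError("all spacings must be > 0")
        if self.n_chromosomes < 0:
            raise ValueError("n_chromosomes must be >= 0")
        if self.periphery_thickness_nm < 0:
            raise ValueError("periphery_thickness_nm must be >= 0")
        if self.stage not in ("prophase", "metaphase"):
            raise ValueError("stage must be 'prophase' or 'metaphase'")
        self.gray_levels.validate()


@dataclass
class PhantomTruth:
    """Voxel-exact ground truth for one generated phantom.

    ``volume_um3`` is the voxel count of each label times the voxel
    volume; surface areas are the analytic capsule/cylinder values of the
    generating tube (curvature corrections are negligible at the gentle
    curvatures drawn).
    """

    labels: LabelVolume
    volume_um3: np.ndarray
    surface_um2: np.ndarray
    length_um: np.ndarray
    diameter_um: np.ndarray
    midpoint_um: np.ndarray          # (n, 3) in (z, y, x)
    nucleolus_volume_um3: float = 0.0
    nucleolus_mask: np.ndarray | None = None
    periphery_mask: np.ndarray | None = None
    envelope_mask: np.ndarray | None = None


# ---------------------------------------------------------------------------
# geometry helpers
# ---------------------------------------------------------------------------

def _resample_curve(points_um: np.ndarray, step_um: float) -> np.ndarray:
    """Cubic-spline-resample a polyline to ~uniform arclength steps."""
    pts = np.asarray(points_um, dtype=float)
    if len(pts) < 2:
        return pts
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    total = seg.sum()
    n_out = max(int(np.ceil(total / step_um)) + 1, 2)
    if len(pts) < 4:
        t = np.concatenate([[0.0], np.cumsum(seg)]) / total
        tt = np.linspace(0.0, 1.0, n_out)
        return np.column_stack([np.interp(tt, t, pts[:, k]) for k in range(3)])
    tck, _ = interpolate.splprep(pts.T, s=0.0, k=3)
    tt = np.linspace(0.0, 1.0, n_out)
    return np.asarray(interpolate.splev(tt, tck)).T


def _arclength(points_um: np.ndarray) -> np.ndarray:
    seg = np.linalg.norm(np.diff(points_um, axis=0), axis=1)
    return np.concatenate([[0.0], np.cumsum(seg)])


def _bandlimited_noise(n: int, corr_steps: float, rng: np.random.Generator) -> np.ndarray:
    """Smoothed, unit-variance noise series (band-limited radial lumps)."""
    w = rng.standard_normal(n + 1)
    s = ndimage.gaussian_filter1d(w, sigma=max(corr_steps, 1.0), mode="reflect")
    sd = s.std()
    return s / sd if sd > 0 else s


def _rasterize_tube(
    tube: Tube,
    spacing_nm: np.ndarray,
    image_shape: tuple[int, int, int],
    shell_nm: float,
    margin_nm: float,
    radius_profile: np.ndarray | None = None,
):
    """Voxelize one tube inside its padded bounding box.

    Returns (bbox slices, chromatin mask, shell mask, claim mask) in bbox
    coordinates, or None when the tube leaves the image. ``claim`` is the
    tube dilated by shell + margin and is used to enforce the
    one-background-voxel separation between objects.
    """
    spacing_um = spacing_nm / NM_PER_UM
    fine = _resample_curve(tube.points_um, step_um=float(spacing_um.min()) / 2.0)
    r_um = tube.diameter_um / 2.0
    r_max_um = r_um * (1.0 + (radius_profile.max() if radius_profile is not None else 0.0))
    pad_um = r_max_um + (shell_nm + margin_nm) / NM_PER_UM

    lo = np.floor((fine.min(axis=0) - pad_um) / spacing_um).astype(int) - 1
    hi = np.ceil((fine.max(axis=0) + pad_um) / spacing_um).astype(int) + 2
    if (lo < 0).any() or (hi > np.asarray(image_shape)).any():
        return None
    sl = tuple(slice(int(a), int(b)) for a, b in zip(lo, hi))
    box_shape = tuple(int(b - a) for a, b in zip(lo, hi))

    # exact Euclidean distance from every bbox voxel center to the
    # centerline samples (sampled at half the finest pitch, so the chord
    # error is well below one voxel)
    axes = [(np.arange(lo[k], hi[k]) + 0.0) * spacing_um[k] for k in range(3)]
    zz, yy, xx = np.meshgrid(*axes, indexing="ij")
    pts = np.column_stack([zz.ravel(), yy.ravel(), xx.ravel()])
    dist_um, nearest = cKDTree(fine).query(pts, k=1)
    dist = (dist_um * NM_PER_UM).reshape(box_shape)
    nearest = nearest.reshape(box_shape)

    if radius_profile is None:
        local_r = np.full(box_shape, r_um * NM_PER_UM, dtype=np.float64)
    else:
        prof = np.asarray(radius_profile, dtype=float)
        prof_at = prof[np.minimum(nearest, len(prof) - 1)]
        local_r = r_um * (1.0 + prof_at) * NM_PER_UM

    chromatin = dist <= local_r
    if tube.flat_caps and len(tube.points_um) == 2:
        # clip to the slab between the endpoints -> a flat-ended cylinder
        a, b = np.asarray(tube.points_um, dtype=float)
        axis = (b - a) / np.linalg.norm(b - a)
        t = (zz - a[0]) * axis[0] + (yy - a[1]) * axis[1] + (xx - a[2]) * axis[2]
        chromatin &= (t >= 0) & (t <= np.linalg.norm(b - a))
    shell = (dist <= local_r + shell_nm) & ~chromatin if shell_nm > 0 else np.zeros_like(chromatin)
    claim = dist <= local_r + shell_nm + margin_nm
    return sl, chromatin, shell, claim, fine


def _random_walk(
    rng: np.random.Generator,
    start: np.ndarray,
    direction: np.ndarray,
    length_um: float,
    lo_um: np.ndarray,
    hi_um: np.ndarray,
    step_um: float = 0.4,
    wiggle_rad: float = 0.18,
    sphere_center_um: np.ndarray | None = None,
    sphere_radius_um: float = 0.0,
) -> np.ndarray | None:
    """Gently curving random walk; None when it leaves the allowed box.

    The per-step direction change is kept small so the curvature radius
    stays well above the tube radius — kinks would put spurious maxima on
    the separation landscape and break the one-marker-per-chromosome
    property downstream. A walk that would leave the box is rejected
    (the caller retries a fresh placement) rather than reflected.
    """
    n_steps = max(int(np.ceil(length_um / step_um)), 1)
    # long tubes drift less per step, or they loop back onto themselves
    wiggle_rad = wiggle_rad * min(1.0, 3.0 / max(length_um, 1e-6))
    pts = [start.copy()]
    d = direction / np.linalg.norm(direction)
    for _ in range(n_steps):
        d = d + wiggle_rad * rng.standard_normal(3)
        if sphere_center_um is not None:
            # smooth inward steering near the sphere boundary; a hard
            # reflection would kink the centerline and corrupt the
            # separation landscape downstream
            rel = pts[-1] - sphere_center_um
            rho = np.linalg.norm(rel)
            if rho > 0.8 * sphere_radius_um and rho > 0:
                pull = (rho - 0.8 * sphere_radius_um) / (0.2 * sphere_radius_um)
                d = d - 0.35 * pull * (rel / rho)
        d /= np.linalg.norm(d)
        nxt = pts[-1] + d * step_um
        if (nxt < lo_um).any() or (nxt > hi_um).any():
            return None
        if sphere_center_um is not None and np.linalg.norm(nxt - sphere_center_um) > sphere_radius_um:
            return None
        pts.append(nxt)
    pts = np.asarray(pts)
    # rescale about the start to the exact requested arclength
    s = _arclength(pts)
    if s[-1] > 0:
        pts = pts[0] + (pts - pts[0]) * (length_um / s[-1])
    if (pts < lo_um).any() or (pts > hi_um).any():
        return None
    if sphere_center_um is not None and (
        np.linalg.norm(pts - sphere_center_um, axis=1) > sphere_radius_um
    ).any():
        return None
    return pts


def _capsule_volume_um3(r: float, length: float, flat: bool) -> float:
    if flat:
        return np.pi * r * r * length
    return np.pi * r * r * length + 4.0 / 3.0 * np.pi * r**3


def _capsule_area_um2(r: float, length: float, flat: bool) -> float:
    if flat:
        return 2.0 * np.pi * r * length + 2.0 * np.pi * r * r
    return 2.0 * np.pi * r * length + 4.0 * np.pi * r * r


# ---------------------------------------------------------------------------
# main generator
# ---------------------------------------------------------------------------

def generate_phantom(spec: PhantomSpec) -> tuple[VoxelGrid, PhantomTruth]:
    """Generate a grayscale volume and its voxel-exact ground truth.

    Chromosome voxels carry the chromatin gray level, shell voxels the
    periphery level; noise is added last. Objects are separated by at
    least one background voxel unless ``spec.clumped`` requests the
    periphery-loss (chromosome clumping) analogue. Identical spec + seed
    give bit-identical output.

    Raises
    ------
    PackingError
        When the requested tubes cannot be placed in the image volume.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    spacing_nm = np.asarray(spec.spacing_nm, dtype=float)
    spacing_um = spacing_nm / NM_PER_UM
    shape = tuple(int(n) for n in spec.image_shape)
    voxvol = float(np.prod(spacing_um))
    extent_um = np.asarray(shape) * spacing_um

    labels = np.zeros(shape, dtype=np.int32)
    periphery = np.zeros(shape, dtype=bool)
    claimed = np.zeros(shape, dtype=bool)
    margin_nm = 0.0 if spec.clumped else float(spacing_nm.max())
    shell_nm = float(spec.periphery_thickness_nm)

    # --- tube geometry -----------------------------------------------------
    if spec.tubes is not None:
        tubes = list(spec.tubes)
        n = len(tubes)
        radii = np.array([t.diameter_um / 2.0 for t in tubes])
        profiles = [None] * n
    else:
        n = spec.n_chromosomes
        mean_d, sd_d = spec.tube_diameter_um
        radii = np.maximum(rng.normal(mean_d, sd_d, size=n), 0.3) / 2.0
        # choose lengths so the summed analytic capsule volume hits the
        # target; length shares are clamped to [3r, 0.55 x smallest field
        # extent] (placeable range), redistributing the volume difference
        # over the unclamped tubes
        per_tube = spec.total_volume_um3 / n if n else 0.0
        caps = 4.0 / 3.0 * np.pi * radii**3
        areas = np.pi * radii**2
        lengths = (per_tube - caps) / areas
        floors = 3.0 * radii
        extent_tmp = np.asarray(spec.image_shape) * np.asarray(spec.spacing_nm) / NM_PER_UM
        ceil_len = 0.55 * float(extent_tmp.min())
        for _ in range(5):
            clamped = (lengths <= floors) | (lengths >= ceil_len)
            lengths = np.clip(lengths, floors, ceil_len)
            excess = float(np.sum(areas * lengths) + caps.sum() - spec.total_volume_um3)
            free = ~clamped
            if abs(excess) < 1e-9 or not free.any():
                break
            lengths[free] -= excess / areas[free].sum()
        # place the longest (hardest-to-fit) tubes first; label order is
        # arbitrary, so the sort costs nothing downstream
        order = np.argsort(-lengths, kind="stable")
        radii = radii[order]
        lengths = lengths[order]
        tubes = [None] * n
        profiles = [None] * n

    lump = spec.lump_amplitude if spec.stage == "prophase" else 0.0
    center_um = extent_um / 2.0
    shell_um = shell_nm / NM_PER_UM
    margin_um = margin_nm / NM_PER_UM
    # half-voxel slack keeps voxelized surfaces >= 1 background voxel apart
    slack_um = float(np.linalg.norm(spacing_um)) / 2.0

    # centerline samples of already-placed tubes, for fast clearance checks
    placed_pts: list[np.ndarray] = []
    placed_reff: list[np.ndarray] = []  # per-sample effective radius

    # the nucleolus is placed first (it is by far the largest single
    # object); tubes then keep clear of it via the same KD-tree test,
    # with the sphere represented exactly as one center point + radius
    nucleolus = np.zeros(shape, dtype=bool)
    if spec.nucleolus_radius_um > 0:
        r_nuc = spec.nucleolus_radius_um
        if (extent_um < 2 * r_nuc).any():
            raise PackingError("nucleolus does not fit inside the image volume")
        zz, yy, xx = np.meshgrid(
            *[(np.arange(shape[k]) + 0.0) * spacing_um[k] for k in range(3)], indexing="ij"
        )
        c = center_um + 0.25 * (rng.uniform(-1, 1, 3) * (extent_um / 2 - r_nuc - margin_um))
        nucleolus = (zz - c[0]) ** 2 + (yy - c[1]) ** 2 + (xx - c[2]) ** 2 <= r_nuc**2
        claimed |= nucleolus
        placed_pts.append(c[None, :])
        # pad the nucleolus clearance for the worst-case lump excursion so
        # lumpy tubes cannot shave its surface
        placed_reff.append(np.array([r_nuc + 0.15]))

    def _clear_of_others(pts: np.ndarray, r_eff: float) -> bool:
        if not placed_pts:
            return True
        tree = cKDTree(np.vstack(placed_pts))
        d, j = tree.query(pts, k=1)
        req = r_eff + np.concatenate(placed_reff)[j] + margin_um + slack_um
        return bool(np.all(d > req))

    def _no_loop_back(pts: np.ndarray, r_eff: float) -> bool:
        # two stretches of the same centerline closer than their combined
        # tube+shell width would bridge the mask and corrupt the
        # separation landscape; genuine neighbours along a gently curved
        # arc satisfy arclength ~ chord, so a large arc/chord ratio flags
        # a loop-back
        d_crit = 2 * r_eff + margin_um
        tree = cKDTree(pts)
        step = _arclength(pts)[-1] / max(len(pts) - 1, 1)
        for a, b in tree.query_pairs(d_crit):
            if abs(a - b) * step > 1.5 * d_crit:
                return False
        return True

    for i in range(n):
        if spec.tubes is not None:
            tube = tubes[i]
            prof = None
            placed = _rasterize_tube(tube, spacing_nm, shape, shell_nm, margin_nm, prof)
            if placed is None:
                raise PackingError(f"explicit tube {i} does not fit inside the image volume")
            sl, chrom, shell, claim, fine = placed
            if not spec.clumped and (claimed[sl] & claim).any():
                raise PackingError(f"explicit tube {i} overlaps a previously placed object")
        else:
            r = radii[i]
            r_eff = r * (1 + lump) + shell_um
            pad = r_eff + margin_um + 2 * spacing_um.max()
            lo_um = np.full(3, 0.0) + pad
            hi_um = extent_um - pad
            if (hi_um <= lo_um).any():
                raise PackingError("image volume smaller than one tube diameter plus margins")
            placed = None
            rejects = {"walk": 0, "loop": 0, "clearance": 0, "raster": 0}
            for attempt in range(6000):
                if spec.seed_on_envelope and spec.envelope_radius_um > 0:
                    u = rng.standard_normal(3)
                    u /= np.linalg.norm(u)
                    # start so the tube surface pokes ~50 nm into the
                    # envelope shell: contact survives voxelization
                    start = center_um + u * (spec.envelope_radius_um - r + 0.05)
                    start = np.clip(start, lo_um, hi_um)
                    d0 = rng.standard_normal(3)
                    d0 -= (d0 @ u) * u  # tangential component
                    d0 /= np.linalg.norm(d0)
                    # tilt inward so the near-straight walk runs as a chord
                    # of the envelope sphere instead of exiting immediately
                    phi = rng.uniform(0.1, 0.6)
                    d0 = d0 * np.cos(phi) - u * np.sin(phi)
                elif spec.clumped:
                    u = rng.standard_normal(3)
                    u /= np.linalg.norm(u)
                    start = center_um + u * rng.uniform(0, 0.35 * extent_um.min())
                    start = np.clip(start, lo_um, hi_um)
                    d0 = rng.standard_normal(3)
                else:
                    start = rng.uniform(lo_um, hi_um)
                    d0 = rng.standard_normal(3)
                pts = _random_walk(
                    rng, start, d0, lengths[i], lo_um, hi_um,
                    sphere_center_um=center_um if spec.envelope_radius_um > 0 else None,
                    # 0.15 um slack lets envelope-seeded walks hug the shell
                    sphere_radius_um=max(spec.envelope_radius_um - r, 0.0) + 0.15,
                )
                if pts is None:
                    rejects["walk"] += 1
                    continue
                samples = _resample_curve(pts, step_um=0.2)
                if not _no_loop_back(samples, r_eff):
                    rejects["loop"] += 1
                    continue
                if not spec.clumped and not _clear_of_others(samples, r_eff):
                    rejects["clearance"] += 1
                    continue
                tube = Tube(points_um=pts, diameter_um=2 * r)
                if lump > 0:
                    fine_n = int(np.ceil(_arclength(pts)[-1] / (spacing_um.min() / 2.0))) + 1
                    prof = lump * np.clip(
                        _bandlimited_noise(fine_n, spec.lump_scale_um / (spacing_um.min() / 2.0), rng),
                        -2.0, 2.0,
                    )[:fine_n]
                    # taper the perturbation to zero at both ends so the
                    # end caps keep the nominal radius (an envelope-seeded
                    # end stays in contact with the envelope)
                    n_t = max(int(np.ceil(0.3 / (spacing_um.min() / 2.0))), 1)
                    ramp = np.minimum(np.arange(fine_n) / n_t, 1.0)
                    prof = prof * np.minimum(ramp, ramp[::-1])
                    # normalize so the expected cross-section (hence the
                    # volume share) matches the smooth tube of radius r
                    prof = (1.0 + prof) / np.sqrt(1.0 + np.mean(prof**2)) - 1.0
                else:
                    prof = None
                cand = _rasterize_tube(tube, spacing_nm, shape, shell_nm, margin_nm, prof)
                if cand is None:
                    rejects["raster"] += 1
                    continue
                placed = cand
                break
            if placed is None:
                raise PackingError(
                    f"could not place tube {i + 1}/{n} after 6000 attempts "
                    f"(rejections: {rejects}); requested total volume / count "
                    "does not fit this image_shape"
                )
            sl, chrom, shell, claim, fine = placed
            tubes[i] = tube
            profiles[i] = prof
            new_samples = _resample_curve(np.asarray(tube.points_um), 0.2)
            placed_pts.append(new_samples)
            placed_reff.append(np.full(len(new_samples), r_eff))

        region = labels[sl]
        free = chrom & (region == 0)
        region[free] = i + 1
        labels[sl] = region
        periphery[sl] |= shell & (labels[sl] == 0)
        claimed[sl] |= claim

    periphery &= labels == 0
    # compositing paints chromatin/periphery over grazing nucleolus voxels;
    # keep the truth mask consistent with the final image
    nucleolus &= (labels == 0) & ~periphery

    # --- nuclear envelope ---------------------------------------------------
    envelope = np.zeros(shape, dtype=bool)
    if spec.envelope_radius_um > 0:
        zz = (np.arange(shape[0]) + 0.0) * spacing_um[0] - center_um[0]
        yy = (np.arange(shape[1]) + 0.0) * spacing_um[1] - center_um[1]
        xx = (np.arange(shape[2]) + 0.0) * spacing_um[2] - center_um[2]
        rr = np.sqrt(zz[:, None, None] ** 2 + yy[None, :, None] ** 2 + xx[None, None, :] ** 2)
        t_um = spec.envelope_thickness_nm / NM_PER_UM
        envelope = (rr >= spec.envelope_radius_um) & (rr < spec.envelope_radius_um + t_um)

    # --- composite grayscale ------------------------------------------------
    g = spec.gray_levels
    img = np.full(shape, g.background, dtype=np.float32)
    img[envelope] = g.envelope
    img[nucleolus] = g.nucleolus
    img[periphery] = g.periphery
    img[labels > 0] = g.chromatin
    if spec.noise_sd > 0:
        img += rng.normal(0.0, spec.noise_sd, size=shape).astype(np.float32)
    img = np.clip(np.round(img), 0, 255).astype(np.uint8)

    # --- truth --------------------------------------------------------------
    counts = np.bincount(labels.ravel(), minlength=n + 1)[1:]
    vol = counts * voxvol
    length = np.zeros(n)
    diam = np.zeros(n)
    area = np.zeros(n)
    mid = np.zeros((n, 3))
    for i in range(n):
        tube = tubes[i]
        fine = _resample_curve(np.asarray(tube.points_um, dtype=float), spacing_um.min() / 2.0)
        s = _arclength(fine)
        length[i] = s[-1]
        diam[i] = tube.diameter_um
        r = tube.diameter_um / 2.0
        area[i] = _capsule_area_um2(r, s[-1], flat=tube.flat_caps)
        mid[i] = fine[np.searchsorted(s, s[-1] / 2.0)]

    truth = PhantomTruth(
        labels=LabelVolume(labels=labels, spacing_nm=tuple(spacing_nm)),
        volume_um3=vol,
        surface_um2=area,
        length_um=length,
        diameter_um=diam,
        midpoint_um=mid,
        nucleolus_volume_um3=float(nucleolus.sum()) * voxvol,
        nucleolus_mask=nucleolus if spec.nucleolus_radius_um > 0 else None,
        periphery_mask=periphery,
        envelope_mask=envelope if spec.envelope_radius_um > 0 else None,
    )
    grid = VoxelGrid(data=img, spacing_nm=tuple(spacing_nm))
    return grid, truth


# ---------------------------------------------------------------------------
# canonical study-condition specs
# ---------------------------------------------------------------------------

def metaphase_spec(seed: int = 0, **overrides) -> PhantomSpec:
    """The scaled-down metaphase complement: 46 smooth shelled tubes.

    46 tubes, diameters ~N(1.15, 0.12) um, summed volume 175.9 um^3,
    150 nm periphery shell, noise sd 5 (8-bit), voxel pitch (120, 48, 48) nm.
    """
    spec = PhantomSpec(seed=seed, noise_sd=5.0)
    return replace(spec, **overrides) if overrides else spec


def prophase_spec(seed: int = 0, **overrides) -> PhantomSpec:
    """Scaled-down prophase: 43 lumpy, thinner tubes, no periphery shell.

    43 separable units with diameters ~N(0.64, 0.19) um summing to
    109.8 um^3, a nucleolus, and no shell, mirroring the early-prophase
    state before nucleolar disassembly.
    """
    spec = PhantomSpec(
        image_shape=(150, 340, 340),
        n_chromosomes=43,
        tube_diameter_um=(0.64, 0.19),
        total_volume_um3=109.8,
        periphery_thickness_nm=0.0,
        nucleolus_radius_um=2.35,  # sphere of ~54.4 um^3
        envelope_radius_um=7.5,
        seed_on_envelope=True,
        stage="prophase",
        noise_sd=5.0,
        seed=seed,
    )
    return replace(spec, **overrides) if overrides else spec


def ki67_depleted_spec(seed: int = 0, **overrides) -> PhantomSpec:
    """Periphery-loss analogue: shell removed and tubes allowed to clump."""
    spec = PhantomSpec(
        periphery_thickness_nm=0.0,
        clumped=True,
        total_volume_um3=170.0,
        noise_sd=5.0,
        seed=seed,
    )
    return replace(spec, **overrides) if overrides else spec


# ---------------------------------------------------------------------------
# synthetic iBAQ tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ProteinBlock:
    """One annotation block of the synthetic protein-intensity table."""

    name: str
    mass_fraction: float
    rho: float = 0.9          # within-block between-experiment correlation
    n_proteins: int | None = None


DEFAULT_BLOCKS = (
    ProteinBlock("histone", 0.20, rho=0.9),
    ProteinBlock("periphery", 0.33, rho=0.9),
    ProteinBlock("other", 0.47, rho=0.0),
)


def generate_intensity_table(
    n_proteins: int,
    blocks=DEFAULT_BLOCKS,
    n_experiments: int = 8,
    noise_sd: float = 0.1,
    seed: int = 0,
) -> ProteinIntensityTable:
    """Generate a synthetic iBAQ (mass-proportional) intensity table.

    Each block's proteins share a per-experiment latent factor so that the
    pairwise correlation of log-intensities within a block equals
    ``rho``, while cross-block correlations are ~0. Per-protein baseline
    masses are scaled so each block's share of the total mass equals its
    requested ``mass_fraction`` exactly before noise, and each block is
    rescaled by one constant afterwards so its aggregate share across all
    experiments is exact after noise as well (a constant per block leaves
    the correlation structure untouched). ``noise_sd`` is the total
    per-protein log10 standard deviation; correlation depends only on the
    factor/noise variance ratio, so shares stay stable at rho near 1.
    """
    if n_experiments < 3:
        raise ValueError("need at least 3 experiments for correlation analysis")
    fractions = sum(b.mass_fraction for b in blocks)
    if fractions > 1.0 + 1e-9:
        raise ValueError(f"block mass fractions sum to {fractions:.3f} > 1")
    rng = np.random.default_rng(seed)

    sizes = []
    unspecified = [b for b in blocks if b.n_proteins is None]
    fixed = sum(b.n_proteins for b in blocks if b.n_proteins is not None)
    remaining = n_proteins - fixed
    if remaining < len(unspecified):
        raise ValueError("n_proteins too small for the requested blocks")
    for b in blocks:
        if b.n_proteins is not None:
            sizes.append(b.n_proteins)
        else:
            sizes.append(remaining // len(unspecified))
    # give any division remainder to the last unspecified block
    deficit = n_proteins - sum(sizes)
    for j in range(len(blocks) - 1, -1, -1):
        if blocks[j].n_proteins is None:
            sizes[j] += deficit
            break

    ids, groups, rows = [], [], []
    total_mass = 1e9
    for b, size in zip(blocks, sizes):
        base = 10.0 ** rng.normal(6.0, 0.8, size=size)
        base *= (b.mass_fraction * total_mass) / base.sum()
        factor = rng.standard_normal(n_experiments)
        # centering the shared factor keeps the block's mean log-mass
        # fixed across the experiment set without touching Pearson
        # correlations (which center each series anyway)
        factor -= factor.mean()
        eps = rng.standard_normal((size, n_experiments))
        rho = min(max(b.rho, 0.0), 1.0)
        logs = noise_sd * (np.sqrt(rho) * factor[None, :] + np.sqrt(1.0 - rho) * eps)
        block_rows = base[:, None] * 10.0**logs
        # one constant per block: exact aggregate mass share after noise
        target = b.mass_fraction * total_mass * n_experiments
        block_rows *= target / block_rows.sum()
        rows.append(block_rows)
        ids.extend(f"{b.name}_{k + 1}" for k in range(size))
        groups.extend([b.name] * size)

    intensities = np.vstack(rows) if rows else np.empty((0, n_experiments))
    return ProteinIntensityTable.from_arrays(
        intensities=intensities,
        protein_ids=ids,
        groups=groups,
        experiment_ids=[f"exp_{j + 1}" for j in range(n_experiments)],
    )
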