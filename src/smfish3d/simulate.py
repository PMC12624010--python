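"""Synthetic widefield smFISH field generator with full ground truth.

Emulates two-color smFISH of small round suspension T cells on a 100x/1.4NA
widefield system: 65 nm lateral pixels, 200 nm z-steps over a 12 um optical
range (61 planes), diffraction-limited mRNA spots rendered as anisotropic 3D
Gaussians, transcription sites as superposed multi-RNA emitters inside the
nucleus, DAPI-stained nuclei, diffuse cytoplasmic autofluorescence (the cue
real cell outlines are drawn from), dim wide autofluorescent granules as
distractors, and an sCMOS noise model (Poisson shot noise plus Gaussian read
noise).

Every emitted object is recorded in a :class:`GroundTruth` table so each
downstream stage -- detection, segmentation, localization, transcription-site
calling, cell QC -- can be scored against known answers.  A given
(config, seed) pair reproduces the field bit-identically.

Ground-truth spots are placed at least one voxel away from the nuclear
surface (on either side) so that the voxel-resolution compartment label of
every truth spot is unambiguous.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .config import planes_for_range
from .detect import ImageStack

log = logging.getLogger("smfish3d")

CHANNELS = ("DAPI", "RNA1", "RNA2")
RNA_CHANNELS = ("RNA1", "RNA2")


class PlacementError(RuntimeError):
    """Field too small to place the requested cells without overlap."""


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class IntDistribution:
    """A small family of nonnegative integer draw laws.

    law: 'constant' (params: value), 'poisson' (params: lam) or
    'uniform' (params: low, high; inclusive).
    """

    law: str
    params: dict

    def __post_init__(self) -> None:
        if self.law not in ("constant", "poisson", "uniform"):
            raise ValueError(f"unknown draw law {self.law!r}")

    def draw(self, rng: np.random.Generator, size: int | None = None):
        if self.law == "constant":
            v = int(self.params["value"])
            return v if size is None else np.full(size, v, dtype=int)
        if self.law == "poisson":
            return rng.poisson(self.params["lam"], size=size)
        return rng.integers(self.params["low"], self.params["high"] + 1, size=size)


def _default_cyto() -> IntDistribution:
    return IntDistribution("poisson", {"lam": 22})


def _default_nuclear() -> IntDistribution:
    return IntDistribution("poisson", {"lam": 6})


def _default_nascent() -> IntDistribution:
    return IntDistribution("uniform", {"low": 2, "high": 20})


@dataclass
class SimulationConfig:
    """All knobs of the synthetic field generator.

    Geometry defaults follow the emulated acquisition (200/65/65 nm voxels,
    61 planes over 12 um); cell and nucleus diameters are typical of effector
    T cells.  ``unit_spot_photons`` sets the integrated intensity of one mRNA;
    at the defaults the peak-amplitude-to-background-noise ratio is ~12.
    """

    field_shape_voxels: tuple[int, int, int] = (
        planes_for_range(12.0, 200.0), 384, 384)
    voxel_size_nm: tuple[float, float, float] = (200.0, 65.0, 65.0)
    n_cells: int = 4
    cell_diameter_um: float = 9.0
    nucleus_diameter_um: float = 6.0
    spots_per_cell_nuclear: IntDistribution = field(default_factory=_default_nuclear)
    spots_per_cell_cyto: IntDistribution = field(default_factory=_default_cyto)
    tsx_probs: tuple[float, float, float] = (0.35, 0.40, 0.25)  # P(0,1,2 TsX)
    nascent_per_tsx: IntDistribution = field(default_factory=_default_nascent)
    psf_sigma_nm: tuple[float, float, float] = (350.0, 130.0, 130.0)
    unit_spot_photons: float = 5000.0
    intensity_jitter_cv: float = 0.2  # lognormal CV of per-spot brightness
    background_level: float = 10.0
    read_noise_sd: float = 2.0
    granule_density: float = 0.2        # distractors per 100 um^3 per RNA channel
    granule_intensity_factor: float = 2.0
    granule_sigma_factor: float = 2.0
    fraction_dividing: float = 0.1
    fraction_edge: float = 0.1
    dapi_photons: float = 200.0
    autofluor_photons: float = 8.0      # diffuse cell-body signal in RNA channels
    apply_noise: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if any(int(n) <= 0 for n in self.field_shape_voxels):
            raise ValueError("field dimensions must be positive")
        if any(v <= 0 for v in self.voxel_size_nm):
            raise ValueError("voxel sizes must be positive")
        if self.n_cells < 0:
            raise ValueError("n_cells must be >= 0")
        if self.nucleus_diameter_um >= self.cell_diameter_um:
            raise ValueError("nucleus must fit inside its cell")
        if abs(sum(self.tsx_probs) - 1.0) > 1e-9:
            raise ValueError("tsx_probs must sum to 1")
        if not 0 <= self.fraction_dividing <= 1 or not 0 <= self.fraction_edge <= 1:
            raise ValueError("fractions must be in [0, 1]")
        if self.background_level < 0 or self.read_noise_sd < 0:
            raise ValueError("background and read noise must be nonnegative")


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

@dataclass
class _Ellipsoid:
    """Axis order (z, y, x) in voxel units; ``theta`` rotates the lateral axes."""

    center: tuple[float, float, float]
    semiaxes: tuple[float, float, float]  # (z, long-lateral, short-lateral)
    theta: float = 0.0

    def _local(self, z, y, x):
        cz, cy, cx = self.center
        c, s = math.cos(self.theta), math.sin(self.theta)
        dy, dx = y - cy, x - cx
        return z - cz, dy * c + dx * s, -dy * s + dx * c

    def contains(self, z, y, x, margin_vox=(0.0, 0.0, 0.0)):
        dz, dl, ds = self._local(z, y, x)
        az = self.semiaxes[0] + margin_vox[0]
        al = self.semiaxes[1] + margin_vox[1]
        ash = self.semiaxes[2] + margin_vox[2]
        return (dz / az) ** 2 + (dl / al) ** 2 + (ds / ash) ** 2 <= 1.0

    def sample(self, rng: np.random.Generator, margin_vox=(0.0, 0.0, 0.0)):
        v = rng.normal(size=3)
        v /= np.linalg.norm(v)
        r = rng.uniform() ** (1.0 / 3.0)
        az = self.semiaxes[0] + margin_vox[0]
        al = self.semiaxes[1] + margin_vox[1]
        ash = self.semiaxes[2] + margin_vox[2]
        dz, dl, ds = r * v[0] * az, r * v[1] * al, r * v[2] * ash
        c, s = math.cos(self.theta), math.sin(self.theta)
        cz, cy, cx = self.center
        return cz + dz, cy + dl * c - ds * s, cx + dl * s + ds * c

    def max_lateral_extent(self) -> float:
        return max(self.semiaxes[1], self.semiaxes[2])

    def fill(self, canvas: np.ndarray, value: float) -> None:
        """Add ``value`` inside the ellipsoid, clipped to the canvas."""
        nz, ny, nx = canvas.shape
        cz, cy, cx = self.center
        ez = self.semiaxes[0]
        el = self.max_lateral_extent()
        z0, z1 = max(0, int(cz - ez) - 1), min(nz, int(cz + ez) + 2)
        y0, y1 = max(0, int(cy - el) - 1), min(ny, int(cy + el) + 2)
        x0, x1 = max(0, int(cx - el) - 1), min(nx, int(cx + el) + 2)
        if z0 >= z1 or y0 >= y1 or x0 >= x1:
            return
        zz, yy, xx = np.meshgrid(
            np.arange(z0, z1, dtype=float),
            np.arange(y0, y1, dtype=float),
            np.arange(x0, x1, dtype=float),
            indexing="ij",
        )
        mask = self.contains(zz, yy, xx)
        canvas[z0:z1, y0:y1, x0:x1][mask] += value

    def volume_voxels(self) -> float:
        az, al, ash = self.semiaxes
        return 4.0 / 3.0 * math.pi * az * al * ash


@dataclass
class _Cell:
    cell_id: int
    body: _Ellipsoid
    nuclei: list
    is_dividing: bool
    touches_edge: bool


# ---------------------------------------------------------------------------
# ground truth
# ---------------------------------------------------------------------------

@dataclass
class GroundTruth:
    """Truth tables keyed to every synthetic spot, site, cell and granule."""

    spots: pd.DataFrame     # field_id, cell_id, channel, z, y, x, compartment,
    #                         is_tsx_member, intensity
    tsx: pd.DataFrame       # field_id, cell_id, channel, z, y, x, nascent_count,
    #                         allele_index, intensity
    cells: pd.DataFrame     # field_id, cell_id, centroid_*, is_dividing,
    #                         touches_edge, nucleus_volume_voxels
    granules: pd.DataFrame  # field_id, channel, z, y, x, intensity
    geometry: list = field(default_factory=list, repr=False)

    def nuclear_label_mask(self, shape: tuple[int, int, int]) -> np.ndarray:
        """Render the ground-truth nuclei as a 3D label image (label = cell_id)."""
        labels = np.zeros(shape, dtype=np.int32)
        for cell in self.geometry:
            for nuc in cell.nuclei:
                tmp = np.zeros(shape, dtype=float)
                nuc.fill(tmp, 1.0)
                labels[tmp > 0] = cell.cell_id
        return labels


_SPOT_COLS = ["field_id", "cell_id", "channel", "z", "y", "x",
              "compartment", "is_tsx_member", "intensity"]
_TSX_COLS = ["field_id", "cell_id", "channel", "z", "y", "x",
             "nascent_count", "allele_index", "intensity"]
_CELL_COLS = ["field_id", "cell_id", "centroid_z", "centroid_y", "centroid_x",
              "is_dividing", "touches_edge", "nucleus_volume_voxels"]
_GRANULE_COLS = ["field_id", "channel", "z", "y", "x", "intensity"]


# ---------------------------------------------------------------------------
# rendering primitives
# ---------------------------------------------------------------------------

def render_spot(
    canvas: np.ndarray,
    position: tuple[float, float, float],
    integrated_intensity: float,
    psf_sigma_nm: tuple[float, float, float],
    voxel_size_nm: tuple[float, float, float],
) -> np.ndarray:
    """Add a diffraction-limited emitter as a separable anisotropic 3D Gaussian.

    The Gaussian is sampled at voxel centers and normalized per axis so its
    discrete sum equals ``integrated_intensity`` up to window truncation
    (+-4 sigma) and field clipping.  Two calls add; intensity 0 is a no-op,
    negative intensity is an error.
    """
    if integrated_intensity < 0:
        raise ValueError("integrated intensity must be nonnegative")
    if integrated_intensity == 0:
        return canvas
    pos = tuple(float(p) for p in position)
    if any(p < 0 or p > n - 1 for p, n in zip(pos, canvas.shape)):
        raise ValueError(f"position {pos} outside canvas {canvas.shape}")
    sig_vox = [s / v for s, v in zip(psf_sigma_nm, voxel_size_nm)]
    axes = []
    slices = []
    for p, sig, n in zip(pos, sig_vox, canvas.shape):
        half = int(math.ceil(4.0 * sig)) + 1
        lo, hi = max(0, int(p) - half), min(n, int(p) + half + 1)
        idx = np.arange(lo, hi, dtype=float)
        g = np.exp(-0.5 * ((idx - p) / sig) ** 2) / (math.sqrt(2.0 * math.pi) * sig)
        axes.append(g)
        slices.append(slice(lo, hi))
    gz, gy, gx = axes
    canvas[tuple(slices)] += (
        integrated_intensity * gz[:, None, None] * gy[None, :, None] * gx[None, None, :]
    )
    return canvas


def add_noise(
    canvas: np.ndarray,
    background_level: float,
    read_noise_sd: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """sCMOS noise model: Poisson(canvas + background) + N(0, read_noise_sd), clipped at 0."""
    if background_level < 0 or read_noise_sd < 0:
        raise ValueError("background and read noise must be nonnegative")
    if np.any(canvas < 0):
        raise ValueError("canvas must be nonnegative before noise")
    out = rng.poisson(canvas + background_level).astype(float)
    if read_noise_sd > 0:
        out += rng.normal(0.0, read_noise_sd, size=out.shape)
    return np.clip(out, 0.0, None)


# ---------------------------------------------------------------------------
# cell placement
# ---------------------------------------------------------------------------

def _place_cells(cfg: SimulationConfig, rng: np.random.Generator) -> list:
    nz, ny, nx = cfg.field_shape_voxels
    vz, vy, vx = cfg.voxel_size_nm
    r_lat = cfg.cell_diameter_um * 1000.0 / 2.0 / vy
    r_z = cfg.cell_diameter_um * 1000.0 / 2.0 / vz
    nuc_lat = cfg.nucleus_diameter_um * 1000.0 / 2.0 / vy
    nuc_z = cfg.nucleus_diameter_um * 1000.0 / 2.0 / vz
    margin = 4.0  # voxels between neighboring cell bodies

    n = cfg.n_cells
    side = int(math.ceil(math.sqrt(n)))
    pitch_y, pitch_x = ny / side, nx / side
    # the widest body is the elongated dividing cell
    max_ext = 1.35 * r_lat
    if min(pitch_y, pitch_x) < 2.0 * r_lat + margin:
        raise PlacementError(
            f"field {ny}x{nx} too small for {n} cells of "
            f"{cfg.cell_diameter_um} um without overlap"
        )

    slots = [(iy, ix) for iy in range(side) for ix in range(side)]
    rng.shuffle(slots)
    slots = slots[:n]

    dividing = rng.random(n) < cfg.fraction_dividing
    edge = rng.random(n) < cfg.fraction_edge

    cells = []
    for i, (iy, ix) in enumerate(slots):
        is_div = bool(dividing[i])
        is_edge = bool(edge[i])
        ext = max_ext if is_div else r_lat

        # slot-constrained center range per lateral axis
        def slot_range(idx, pitch, nlen, extent):
            lo = idx * pitch + extent + margin / 2.0
            hi = (idx + 1) * pitch - extent - margin / 2.0
            lo = max(lo, extent + 1.0)
            hi = min(hi, nlen - 1.0 - extent - 1.0)
            return lo, hi

        ylo, yhi = slot_range(iy, pitch_y, ny, ext)
        xlo, xhi = slot_range(ix, pitch_x, nx, ext)
        if ylo > yhi or xlo > xhi:
            raise PlacementError(
                f"cell {i}: no room in grid slot ({iy},{ix}) for extent {ext:.0f} vox"
            )
        cy = rng.uniform(ylo, yhi)
        cx = rng.uniform(xlo, xhi)
        if is_edge:
            # push the body across the nearest field border of this slot
            depth = rng.uniform(0.2, 0.6) * ext
            if iy in (0, side - 1):
                cy = depth if iy == 0 else ny - 1 - depth
            elif ix in (0, side - 1):
                cx = depth if ix == 0 else nx - 1 - depth
            else:
                is_edge = False  # interior slot: cannot touch the border
        cz = nz / 2.0 + rng.uniform(-2.5, 2.5)

        theta = rng.uniform(0.0, math.pi)
        if is_div:
            body = _Ellipsoid((cz, cy, cx), (r_z, 1.35 * r_lat, 0.8 * r_lat), theta)
            sep = 5.0 * 1000.0 / 2.0 / vy  # +-2.5 um along the long axis
            scale = 0.7
            c, s = math.cos(theta), math.sin(theta)
            nuclei = [
                _Ellipsoid(
                    (cz, cy + d * c, cx + d * s),
                    (scale * nuc_z, scale * nuc_lat, scale * nuc_lat),
                )
                for d in (-sep, sep)
            ]
        else:
            body = _Ellipsoid((cz, cy, cx), (r_z, r_lat, r_lat), theta)
            slack = max(r_lat - nuc_lat - 3.0, 0.0)
            ang = rng.uniform(0.0, 2.0 * math.pi)
            rr = rng.uniform(0.0, 0.6 * slack)
            dz = rng.uniform(-0.4, 0.4) * max(r_z - nuc_z - 1.0, 0.0)
            nuclei = [
                _Ellipsoid(
                    (cz + dz, cy + rr * math.cos(ang), cx + rr * math.sin(ang)),
                    (nuc_z, nuc_lat, nuc_lat),
                )
            ]
        cells.append(_Cell(i + 1, body, nuclei, is_div, is_edge))
    return cells


# ---------------------------------------------------------------------------
# field simulation
# ---------------------------------------------------------------------------

def _in_field(pos, shape) -> bool:
    z, y, x = pos
    nz, ny, nx = shape
    return 1 <= z <= nz - 2 and 1 <= y <= ny - 2 and 1 <= x <= nx - 2


def _sample_cyto(rng, cell: _Cell, shape, margin) -> tuple | None:
    for _ in range(400):
        pos = cell.body.sample(rng, margin_vox=tuple(-m for m in margin))
        if not _in_field(pos, shape):
            continue
        if any(nuc.contains(*pos, margin_vox=margin) for nuc in cell.nuclei):
            continue
        return pos
    return None


def _sample_in(rng, ell: _Ellipsoid, shape, margin_vox) -> tuple | None:
    for _ in range(400):
        pos = ell.sample(rng, margin_vox=margin_vox)
        if _in_field(pos, shape):
            return pos
    return None


def simulate_field(config: SimulationConfig):
    """Render one synthetic field.

    Returns ``(stacks, truth)`` where ``stacks`` maps channel name (DAPI,
    RNA1, RNA2) to an :class:`ImageStack` and ``truth`` is the complete
    :class:`GroundTruth`.  Identical config (including seed) gives
    bit-identical output.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    shape = tuple(int(n) for n in cfg.field_shape_voxels)
    vs = cfg.voxel_size_nm
    margin = (1.0, 1.0, 1.0)  # one voxel per axis around the nuclear surface

    cells = _place_cells(cfg, rng) if cfg.n_cells > 0 else []

    canvases = {ch: np.zeros(shape, dtype=float) for ch in CHANNELS}

    # diffuse structures first: DAPI nuclei and cytoplasmic autofluorescence
    for cell in cells:
        for nuc in cell.nuclei:
            nuc.fill(canvases["DAPI"], cfg.dapi_photons)
        if cfg.autofluor_photons > 0:
            for ch in RNA_CHANNELS:
                cell.body.fill(canvases[ch], cfg.autofluor_photons)
    for ch in CHANNELS:
        if canvases[ch].any():
            canvases[ch] = ndimage.gaussian_filter(canvases[ch], sigma=(1.0, 2.0, 2.0))

    ln_sigma = math.sqrt(math.log(1.0 + cfg.intensity_jitter_cv ** 2))

    def jitter(size=None):
        if cfg.intensity_jitter_cv <= 0:
            return 1.0 if size is None else np.ones(size)
        return rng.lognormal(-0.5 * ln_sigma ** 2, ln_sigma, size=size)

    spot_rows, tsx_rows, cell_rows, granule_rows = [], [], [], []

    for cell in cells:
        for ch in RNA_CHANNELS:
            n_cyto = int(cfg.spots_per_cell_cyto.draw(rng))
            n_nuc = int(cfg.spots_per_cell_nuclear.draw(rng))
            for _ in range(n_cyto):
                pos = _sample_cyto(rng, cell, shape, margin)
                if pos is None:
                    continue
                inten = cfg.unit_spot_photons * float(jitter())
                render_spot(canvases[ch], pos, inten, cfg.psf_sigma_nm, vs)
                spot_rows.append((0, cell.cell_id, ch, *pos, "cytoplasmic",
                                  False, inten))
            for _ in range(n_nuc):
                nuc = cell.nuclei[int(rng.integers(len(cell.nuclei)))]
                pos = _sample_in(rng, nuc, shape,
                                 tuple(-m for m in margin))
                if pos is None:
                    continue
                inten = cfg.unit_spot_photons * float(jitter())
                render_spot(canvases[ch], pos, inten, cfg.psf_sigma_nm, vs)
                spot_rows.append((0, cell.cell_id, ch, *pos, "nuclear",
                                  False, inten))
            n_tsx = int(rng.choice(3, p=cfg.tsx_probs))
            for allele in range(n_tsx):
                nuc = cell.nuclei[int(rng.integers(len(cell.nuclei)))]
                # sites sit well inside the nucleus (chromatin, not lamina)
                pos = _sample_in(rng, nuc, shape,
                                 tuple(-0.2 * a for a in nuc.semiaxes))
                if pos is None:
                    continue
                k = max(1, int(cfg.nascent_per_tsx.draw(rng)))
                inten = cfg.unit_spot_photons * float(np.sum(jitter(k)))
                render_spot(canvases[ch], pos, inten, cfg.psf_sigma_nm, vs)
                tsx_rows.append((0, cell.cell_id, ch, *pos, k, allele, inten))
                spot_rows.append((0, cell.cell_id, ch, *pos, "nuclear", True, inten))
        cell_rows.append((
            0, cell.cell_id, *cell.body.center, cell.is_dividing,
            cell.touches_edge, sum(n.volume_voxels() for n in cell.nuclei),
        ))

    # autofluorescent granules: dim, twice the PSF width
    if cfg.granule_density > 0:
        vol_um3 = float(np.prod(shape)) * float(np.prod(vs)) / 1e9  # nm^3 -> um^3
        lam = cfg.granule_density * vol_um3 / 100.0
        g_sigma = tuple(cfg.granule_sigma_factor * s for s in cfg.psf_sigma_nm)
        for ch in RNA_CHANNELS:
            n_gran = int(rng.poisson(lam))
            for _ in range(n_gran):
                pos = tuple(rng.uniform(2, n - 3) for n in shape)
                inten = cfg.granule_intensity_factor * cfg.unit_spot_photons * float(jitter())
                render_spot(canvases[ch], pos, inten, g_sigma, vs)
                granule_rows.append((0, ch, *pos, inten))

    if cfg.apply_noise:
        for ch in CHANNELS:
            canvases[ch] = add_noise(
                canvases[ch], cfg.background_level, cfg.read_noise_sd, rng)

    stacks = {
        ch: ImageStack(canvases[ch], vs, channel_name=ch) for ch in CHANNELS
    }
    truth = GroundTruth(
        spots=pd.DataFrame(spot_rows, columns=_SPOT_COLS),
        tsx=pd.DataFrame(tsx_rows, columns=_TSX_COLS),
        cells=pd.DataFrame(cell_rows, columns=_CELL_COLS),
        granules=pd.DataFrame(granule_rows, columns=_GRANULE_COLS),
        geometry=cells,
    )
    return stacks, truth
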