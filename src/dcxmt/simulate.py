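"""Synthetic 2D projection images of decorated microtubule segments.

This is the data-generating stage of the pipeline: it renders orthographic
projections of the pseudo-helical lattices built by :mod:`dcxmt.lattice`,
with every tubulin monomer contributing an isotropic Gaussian blob, every
Bernoulli-decorated vertex site contributing a (weaker) blob on the outer
wall, and additive Gaussian noise on top.  Ground truth (architecture,
occupancy, per-site decoration mask, per-segment seed) travels with every
image, which is what makes the downstream statistics testable.

No contrast-transfer-function or defocus model is applied: the layer-line
ratio and projection-matching statistics exercised downstream do not need
an optics model, and real-image reconstruction is out of scope.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, asdict, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from . import __version__
from .errors import GeometryError, ParameterError, FormatError
from .lattice import (LatticeParams, SubunitLattice, DecorationSiteSet,
                      build_lattice, decoration_sites)

__all__ = ["RenderParams", "SegmentStack", "render_segment", "make_dataset",
           "lattice_for_box", "desk_params", "save_png"]


@dataclass(frozen=True)
class RenderParams:
    """Rendering conditions for one segment or one stack.

    Defaults mirror a typical high-magnification cryo-EM acquisition
    geometry (1.39 Angstrom pixels, 652 px boxes); :func:`desk_params`
    returns the faster desk-scale geometry used throughout the test-suite.

    Grey values are projected densities per Angstrom^2 (each blob integrates
    to its amplitude in those units), so they do not depend on the pixel
    size.  ``noise_sigma`` is the s.d. of the additive Gaussian noise in the
    same units; the default 0.001 matches the whole-box RMS of a noiseless
    default segment, i.e. a per-pixel signal-to-noise ratio near 1
    (moderate noise - raw cryo-EM frames are noisier, class averages less
    so).  ``decor_amp`` defaults to half ``tubulin_amp``: the relative
    decoration contrast is not known, so it is an explicit, configurable
    choice.  ``view_axis`` is 'x', 'y' or an azimuth in degrees about the
    MT axis.
    """

    pixel_size: float = 1.39          # Angstrom / px
    box: int | tuple[int, int] = 652  # px, int or (ny, nx) = (axial, lateral)
    psf_sigma: float = 8.0            # blob width, Angstrom
    tubulin_amp: float = 1.0
    decor_amp: float = 0.5
    decor_radial_offset: float = 25.0  # Angstrom outward from the wall vertex
    noise_sigma: float = 0.001
    occupancy_p: float = 0.5
    seed: int = 0
    view_axis: str | float = "x"

    def __post_init__(self):
        if not (0.0 <= self.occupancy_p <= 1.0):
            raise ParameterError(f"occupancy_p={self.occupancy_p} outside [0, 1]")
        if self.pixel_size <= 0:
            raise ParameterError(f"pixel_size={self.pixel_size} must be positive")
        ny, nx = self.shape
        if ny <= 0 or nx <= 0:
            raise ParameterError(f"box={self.box} must be positive")
        if self.noise_sigma < 0:
            raise ParameterError(f"noise_sigma={self.noise_sigma} must be >= 0")

    @property
    def shape(self) -> tuple[int, int]:
        """(ny, nx) image shape; rows run along the MT axis."""
        if isinstance(self.box, (tuple, list)):
            ny, nx = self.box
            return int(ny), int(nx)
        return int(self.box), int(self.box)


def desk_params(**kw) -> RenderParams:
    """Desk-scale rendering defaults: 160 px boxes at 2.78 Angstrom/px."""
    base = dict(pixel_size=2.78, box=160)
    base.update(kw)
    return RenderParams(**base)


def lattice_for_box(n_pf: int, rp: RenderParams, margin_layers: int = 2,
                    **lattice_kw) -> tuple[SubunitLattice, DecorationSiteSet]:
    """Build a lattice (and its seam-excluded sites) tall enough to fill the
    axial extent of ``rp``'s box, plus *margin_layers* dimer layers."""
    ny, _ = rp.shape
    c = lattice_kw.pop("dimer_repeat_c", 80.0)
    layers = max(2, int(np.ceil(ny * rp.pixel_size / c)) + margin_layers)
    params = LatticeParams(n_pf=n_pf, n_dimer_layers=layers, **lattice_kw)
    lat = build_lattice(params)
    return lat, decoration_sites(lat, exclude_seam=True)


def _project(xyz: np.ndarray, view_axis) -> np.ndarray:
    """Project 3D points to (axial, lateral) image-plane coordinates."""
    if isinstance(view_axis, str):
        if view_axis == "x":
            lateral = xyz[:, 1]
        elif view_axis == "y":
            lateral = xyz[:, 0]
        else:
            raise ParameterError(f"view_axis={view_axis!r} must be 'x', 'y' or degrees")
    else:
        ang = np.radians(float(view_axis))
        # rotate the lattice by -ang about z, then project along x
        lateral = -np.sin(ang) * xyz[:, 0] + np.cos(ang) * xyz[:, 1]
    return np.column_stack([xyz[:, 2], lateral])


def _splat(img: np.ndarray, rows: np.ndarray, cols: np.ndarray,
           amps: np.ndarray) -> None:
    """Bilinear deposition of point weights onto the image grid (in place)."""
    r0 = np.floor(rows).astype(int)
    c0 = np.floor(cols).astype(int)
    fr = rows - r0
    fc = cols - c0
    ny, nx = img.shape
    for dr, dc, w in ((0, 0, (1 - fr) * (1 - fc)), (0, 1, (1 - fr) * fc),
                      (1, 0, fr * (1 - fc)), (1, 1, fr * fc)):
        rr, cc = r0 + dr, c0 + dc
        ok = (rr >= 0) & (rr < ny) & (cc >= 0) & (cc < nx)
        np.add.at(img, (rr[ok], cc[ok]), (amps * w)[ok])


def render_segment(lat: SubunitLattice, sites: DecorationSiteSet,
                   rp: RenderParams,
                   rng: np.random.Generator | None = None,
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Render one segment; returns ``(image, decorated_site_mask)``.

    Each monomer contributes a Gaussian blob of integral ``tubulin_amp``;
    each vertex site contributes a blob of integral ``decor_amp`` iff its
    seeded Bernoulli(``occupancy_p``) draw succeeds, placed
    ``decor_radial_offset`` Angstrom outside the wall.  Blobs are summed in
    orthographic projection along ``view_axis``; Gaussian noise is added
    last.  Identical inputs and seed give bit-identical images.
    """
    if rng is None:
        rng = np.random.default_rng(rp.seed)
    ny, nx = rp.shape
    px = rp.pixel_size
    rho = lat.params.radius_rho
    if 2.0 * (rho + rp.decor_radial_offset) + 6.0 * rp.psf_sigma > nx * px:
        raise GeometryError(
            f"box: lattice diameter {2 * rho:.0f} A (+ decoration and blob margin) "
            f"exceeds the {nx * px:.0f} A lateral box extent")

    # Bernoulli decoration draw first so the noise stream depends on it only
    # through the documented draw order.
    mask = rng.random(sites.n_sites) < rp.occupancy_p

    z0 = float(lat.xyz[:, 2].mean())
    img = np.zeros((ny, nx), dtype=np.float64)

    mono = _project(lat.xyz, rp.view_axis)
    rows = (mono[:, 0] - z0) / px + (ny - 1) / 2.0
    cols = mono[:, 1] / px + (nx - 1) / 2.0
    _splat(img, rows, cols, np.full(len(rows), rp.tubulin_amp / px ** 2))

    if mask.any():
        sxyz = sites.xyz[mask]
        radial = sxyz[:, :2] / np.linalg.norm(sxyz[:, :2], axis=1, keepdims=True)
        outer = sxyz.copy()
        outer[:, :2] += rp.decor_radial_offset * radial
        dec = _project(outer, rp.view_axis)
        _splat(img, (dec[:, 0] - z0) / px + (ny - 1) / 2.0,
               dec[:, 1] / px + (nx - 1) / 2.0,
               np.full(mask.sum(), rp.decor_amp / px ** 2))

    ndimage.gaussian_filter(img, sigma=rp.psf_sigma / px, output=img,
                            mode="constant", truncate=4.0)
    if rp.noise_sigma > 0:
        img += rng.normal(0.0, rp.noise_sigma, size=img.shape)
    return img.astype(np.float32), mask


@dataclass
class SegmentStack:
    """An ordered stack of segment images with per-image ground truth.

    ``truth`` has one row per image: ``n_pf``, ``occupancy_p``, ``seed``
    (the per-segment child seed), ``n_sites`` and ``n_decorated``.
    ``masks`` holds the per-image decorated-site Bernoulli outcomes.
    """

    images: np.ndarray            # (n, ny, nx) float32
    truth: pd.DataFrame
    params: RenderParams
    masks: list[np.ndarray] | None = None

    def __post_init__(self):
        if self.images.ndim != 3:
            raise GeometryError("images must be a (n, ny, nx) array")
        if len(self.truth) != len(self.images):
            raise FormatError("ground truth must cover every image")

    def __len__(self) -> int:
        return len(self.images)

    @property
    def shape(self) -> tuple[int, int]:
        return self.images.shape[1:]

    def subset(self, idx) -> "SegmentStack":
        idx = np.asarray(idx)
        masks = [self.masks[i] for i in idx] if self.masks is not None else None
        return SegmentStack(images=self.images[idx],
                            truth=self.truth.iloc[idx].reset_index(drop=True),
                            params=self.params, masks=masks)

    # -- persistence: MRC (mode 2) + JSON sidecar ---------------------------

    def write(self, path) -> None:
        """Write the images as an MRC/CCP4 mode-2 stack with a JSON sidecar
        carrying ground truth, render parameters, package version and a
        config hash.  The round trip is lossless (float32 preserved)."""
        import gemmi

        path = Path(path)
        m = gemmi.Ccp4Map()
        m.grid = gemmi.FloatGrid(np.ascontiguousarray(self.images, dtype=np.float32))
        m.grid.unit_cell = gemmi.UnitCell(
            len(self) * self.params.pixel_size,
            self.shape[0] * self.params.pixel_size,
            self.shape[1] * self.params.pixel_size, 90, 90, 90)
        m.update_ccp4_header()
        m.write_ccp4_map(str(path))

        rp = asdict(self.params)
        if isinstance(rp["box"], tuple):
            rp["box"] = list(rp["box"])
        side = {
            "dcxmt_version": __version__,
            "render_params": rp,
            "config_hash": hashlib.sha256(
                json.dumps(rp, sort_keys=True).encode()).hexdigest(),
            "truth": self.truth.to_dict(orient="list"),
            "truth_columns": list(self.truth.columns),
            "masks": ([m_.astype(int).tolist() for m_ in self.masks]
                      if self.masks is not None else None),
        }
        path.with_suffix(path.suffix + ".json").write_text(
            json.dumps(side, sort_keys=True))

    @classmethod
    def read(cls, path) -> "SegmentStack":
        import gemmi

        path = Path(path)
        m = gemmi.read_ccp4_map(str(path))
        images = np.array(m.grid, copy=True).astype(np.float32)
        sidecar = path.with_suffix(path.suffix + ".json")
        if not sidecar.exists():
            raise FormatError(f"missing ground-truth sidecar {sidecar}")
        side = json.loads(sidecar.read_text())
        rp = dict(side["render_params"])
        if isinstance(rp["box"], list):
            rp["box"] = tuple(rp["box"])
        masks = side.get("masks")
        truth = pd.DataFrame(side["truth"])
        if "truth_columns" in side:
            truth = truth[side["truth_columns"]]
        return cls(images=images, truth=truth,
                   params=RenderParams(**rp),
                   masks=([np.asarray(m_, dtype=bool) for m_ in masks]
                          if masks is not None else None))


def save_png(stack: "SegmentStack", index: int, path) -> None:
    """Export one segment image as a grayscale PNG (for docs/diagnostics)."""
    from matplotlib.image import imsave

    img = stack.images[index]
    imsave(path, img, cmap="gray", origin="lower",
           vmin=float(img.min()), vmax=float(img.max()))


def make_dataset(mixture: list[tuple[int, float, float]], n_segments: int,
                 rp: RenderParams, **lattice_kw) -> SegmentStack:
    """Render a stack of segments drawn from an architecture mixture.

    ``mixture`` is a list of ``(n_pf, fraction, occupancy_p)``; fractions
    must sum to 1 within 1e-9.  Per-segment architectures are a seeded
    categorical draw from ``rp.seed``; each segment then renders from its
    own spawned child seed, so the stack is reproducible segment by segment.
    """
    if not mixture:
        raise ParameterError("mixture: empty specification")
    if n_segments < 1:
        raise ParameterError(f"n_segments={n_segments} must be >= 1")
    fracs = np.array([m[1] for m in mixture], dtype=float)
    if (fracs < 0).any():
        raise ParameterError("mixture: negative fractions")
    if abs(fracs.sum() - 1.0) > 1e-9:
        raise ParameterError(f"mixture: fractions sum to {fracs.sum()!r}, not 1")

    root = np.random.SeedSequence(rp.seed)
    rng = np.random.default_rng(root)
    arch_idx = rng.choice(len(mixture), size=n_segments, p=fracs)
    children = root.spawn(n_segments)

    cache: dict[tuple[int, float], tuple[SubunitLattice, DecorationSiteSet]] = {}
    images = np.empty((n_segments, *rp.shape), dtype=np.float32)
    masks: list[np.ndarray] = []
    rows = []
    for s in range(n_segments):
        n_pf, _, p = mixture[arch_idx[s]]
        key = (n_pf, p)
        if key not in cache:
            cache[key] = lattice_for_box(n_pf, rp, **lattice_kw)
        lat, sites = cache[key]
        child_seed = int(children[s].generate_state(1)[0] % (2 ** 31))
        seg_rp = replace(rp, occupancy_p=p, seed=child_seed)
        img, mask = render_segment(lat, sites, seg_rp)
        images[s] = img
        masks.append(mask)
        rows.append({"n_pf": n_pf, "occupancy_p": p, "seed": child_seed,
                     "n_sites": sites.n_sites, "n_decorated": int(mask.sum())})
    return SegmentStack(images=images, truth=pd.DataFrame(rows),
                        params=rp, masks=masks)
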