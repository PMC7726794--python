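"""Parametric pseudo-helical microtubule lattices.

A microtubule (MT) is modelled as a B-lattice of alpha/beta-tubulin monomers
on a cylinder: N protofilaments (PFs) run axially with a 4 nm monomer repeat
(8 nm dimer repeat), adjacent PFs are staggered by the lateral rise r, and the
cylinder closes through a single heterotypic (alpha-beta) boundary, the seam.
For the canonical 13-PF, 3-start architecture the closure constraint
S*a = N*r fixes r = 3*40/13 ~ 9.231 Angstrom and the PFs are exactly parallel
to the MT axis.  For other PF numbers the lateral rise is kept at the 13-PF
value and the closure mismatch is absorbed into a PF skew (supertwist) angle

    tan(theta_N) = (S*a - N*r) / (2*pi*rho_N),

which is zero for N = 13 and gives the slow winding of PFs responsible for
moire patterns in projection images of non-13-PF MTs.

Decoration sites are the vertices between four tubulin dimers (two adjacent
PFs x two dimer layers) where a doublecortin DC domain binds; the seam vertex
is excluded by default because DC domains do not bind across the seam.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import ParameterError

__all__ = [
    "LatticeParams",
    "SubunitLattice",
    "DecorationSiteSet",
    "build_lattice",
    "decoration_sites",
    "supertwist_deg",
    "moire_period",
    "moire_beat_period",
    "lattice_to_csv",
    "lattice_to_pdb",
]

#: reference radius of a 13-PF microtubule, Angstrom (centre of the wall)
RHO_13 = 115.0


def default_radius(n_pf: int) -> float:
    """Lattice radius for *n_pf* protofilaments, keeping the inter-PF arc
    spacing equal to the 13-PF value (rho = 115 * N / 13 Angstrom)."""
    return RHO_13 * n_pf / 13.0


def supertwist_deg(n_pf: int, *, monomer_repeat_a: float = 40.0,
                   start_number_s: int = 3, radius: float | None = None,
                   lateral_rise: float | None = None, sign: int = 1) -> float:
    """PF skew (supertwist) angle in degrees for an N-PF lattice.

    Solves the cylinder-closure equation with the lateral rise frozen at the
    13-PF value: tan(theta) = (S*a - N*r) / (2*pi*rho).  theta_13 == 0
    exactly.  ``sign`` flips the handedness (the helical family of non-13-PF
    MTs is a free convention here).
    """
    a = monomer_repeat_a
    r = lateral_rise if lateral_rise is not None else start_number_s * a / 13.0
    rho = radius if radius is not None else default_radius(n_pf)
    mismatch = start_number_s * a - n_pf * r
    if abs(mismatch) < 1e-9:   # closure already exact (canonical 13-PF)
        return 0.0
    return sign * math.degrees(math.atan2(mismatch, 2.0 * math.pi * rho))


def moire_period(n_pf: int, *, monomer_repeat_a: float = 40.0,
                 start_number_s: int = 3, radius: float | None = None,
                 lateral_rise: float | None = None) -> float:
    """Axial beat (moire) period of a skewed lattice, Angstrom.

    The projected PF pattern repeats when the lattice has rotated by one PF
    spacing (2*pi/N), i.e. after an axial distance

        L_N = (2*pi*rho)**2 / (N * |S*a - N*r|).

    Returns ``math.inf`` for unskewed lattices (N = 13 with defaults).
    """
    a = monomer_repeat_a
    r = lateral_rise if lateral_rise is not None else start_number_s * a / 13.0
    rho = radius if radius is not None else default_radius(n_pf)
    mismatch = abs(start_number_s * a - n_pf * r)
    if mismatch < 1e-9:
        return math.inf
    return (2.0 * math.pi * rho) ** 2 / (n_pf * mismatch)


def moire_beat_period(n_pf: int, **kw) -> float:
    """Axial beat period of the *projected* PF-stripe envelope, Angstrom.

    An orthographic projection superposes the front and back walls of the
    cylinder, and the row-wise stripe power is insensitive to the lateral
    mirror, so the projected envelope repeats when the lattice has rotated
    by half a PF spacing (pi/N): half of :func:`moire_period`.  This is the
    quantity the image-based moire estimator measures.
    """
    return moire_period(n_pf, **kw) / 2.0


@dataclass(frozen=True)
class LatticeParams:
    """Geometry of an N-PF pseudo-helical microtubule lattice.

    Parameters
    ----------
    n_pf:
        Protofilament count N.  11-16 covers the architectures seen in
        vitro; 2-20 is accepted.
    monomer_repeat_a:
        Axial monomer spacing a, Angstrom (the "4 nm" tubulin repeat).
    dimer_repeat_c:
        Axial dimer spacing c = 2a, Angstrom (the "8 nm" repeat that bound
        MAPs such as DC domains follow).
    start_number_s:
        Monomer helix start number S (3 for the canonical B-lattice).
    radius_rho:
        Cylinder radius, Angstrom.  Defaults to 115 * N / 13 so the inter-PF
        arc spacing is N-independent.
    lateral_rise_r:
        Axial stagger between laterally bonded monomers, Angstrom.  Frozen at
        the 13-PF value S*a/13 for every N; the closure mismatch goes into
        the supertwist.
    supertwist_deg:
        PF skew angle theta_N, degrees; solved from the closure equation by
        default.  0 for N = 13.
    supertwist_sign:
        Handedness convention for non-13-PF architectures (+1 or -1).
    seam_index:
        PF boundary (between PF ``seam_index`` and PF ``(seam_index+1) % N``)
        carrying the heterotypic contacts.  Default: the wrap boundary
        N-1 -> 0.
    n_dimer_layers:
        Axial extent, in 8 nm dimer layers.
    """

    n_pf: int = 13
    monomer_repeat_a: float = 40.0
    dimer_repeat_c: float = field(default=None)  # type: ignore[assignment]
    start_number_s: int = 3
    radius_rho: float = field(default=None)  # type: ignore[assignment]
    lateral_rise_r: float = field(default=None)  # type: ignore[assignment]
    supertwist_theta: float = field(default=None)  # type: ignore[assignment]
    supertwist_sign: int = 1
    seam_index: int = field(default=None)  # type: ignore[assignment]
    n_dimer_layers: int = 6

    def __post_init__(self):
        if not (2 <= self.n_pf <= 20):
            raise ParameterError(f"n_pf={self.n_pf} outside the supported range 2-20")
        if self.monomer_repeat_a <= 0:
            raise ParameterError(f"monomer_repeat_a={self.monomer_repeat_a} must be positive")
        if self.n_dimer_layers < 2:
            raise ParameterError(f"n_dimer_layers={self.n_dimer_layers} must be >= 2")
        if self.supertwist_sign not in (1, -1):
            raise ParameterError(f"supertwist_sign={self.supertwist_sign} must be +1 or -1")
        a = self.monomer_repeat_a
        if self.dimer_repeat_c is None:
            object.__setattr__(self, "dimer_repeat_c", 2.0 * a)
        if self.dimer_repeat_c <= 0:
            raise ParameterError(f"dimer_repeat_c={self.dimer_repeat_c} must be positive")
        if self.lateral_rise_r is None:
            object.__setattr__(self, "lateral_rise_r", self.start_number_s * a / 13.0)
        if self.radius_rho is None:
            object.__setattr__(self, "radius_rho", RHO_13 * self.n_pf / 13.0)
        if self.radius_rho <= 0:
            raise ParameterError(f"radius_rho={self.radius_rho} must be positive")
        if self.supertwist_theta is None:
            object.__setattr__(
                self, "supertwist_theta",
                supertwist_deg(self.n_pf, monomer_repeat_a=a,
                               start_number_s=self.start_number_s,
                               radius=self.radius_rho,
                               lateral_rise=self.lateral_rise_r,
                               sign=self.supertwist_sign))
        if self.seam_index is None:
            object.__setattr__(self, "seam_index", self.n_pf - 1)
        if not (0 <= self.seam_index < self.n_pf):
            raise ParameterError(f"seam_index={self.seam_index} outside 0..{self.n_pf - 1}")

    @property
    def seam_rise(self) -> float:
        """Axial rise of the seam bond: S*a - (N-1)*r, Angstrom.

        The same-kind (dimer-register) offset across the seam is this value
        plus one monomer repeat's worth of identity stagger; for N = 13 it
        equals r and the same-kind offset is r + a.
        """
        return (self.start_number_s * self.monomer_repeat_a
                - (self.n_pf - 1) * self.lateral_rise_r)

    def with_(self, **kw) -> "LatticeParams":
        """Return a copy with the given fields replaced (derived fields are
        re-solved unless given explicitly)."""
        solved = {"dimer_repeat_c", "radius_rho", "lateral_rise_r",
                  "supertwist_theta", "seam_index"}
        base = {k: (None if k in solved and k not in kw else v)
                for k, v in self.__dict__.items()}
        base.update(kw)
        return LatticeParams(**base)


@dataclass(frozen=True)
class SubunitLattice:
    """Explicit monomer poses of one MT lattice.

    Arrays are parallel, one entry per monomer: ``pf`` (0-based PF index),
    ``layer`` (0-based monomer layer along the PF; two layers per dimer),
    ``kind`` ('A' for alpha, 'B' for beta), ``xyz`` (N, 3) positions in
    Angstrom (MT axis = +z, right-handed frame) and ``axis`` (N, 3) unit
    vectors along the local PF direction.
    """

    params: LatticeParams
    pf: np.ndarray
    layer: np.ndarray
    kind: np.ndarray
    xyz: np.ndarray
    axis: np.ndarray

    @property
    def n_monomers(self) -> int:
        return len(self.pf)

    def lateral_offsets(self) -> list[tuple[int, float, bool]]:
        """Axial offset and homotypic flag for each lateral bond boundary.

        Returns a list of ``(boundary_index, rise, homotypic)``; boundary i
        connects PF i to PF (i+1) % N.  The seam boundary is the single
        heterotypic one; its rise is S*a - (N-1)*r.
        """
        p = self.params
        out = []
        for b in range(p.n_pf):
            if b == p.seam_index:
                out.append((b, p.seam_rise, False))
            else:
                out.append((b, p.lateral_rise_r, True))
        return out


def build_lattice(params: LatticeParams) -> SubunitLattice:
    """Place every monomer of an N-PF pseudo-helical lattice.

    PF ``i`` carries monomers at z = m*a + i*r (m = 0..2L-1) with azimuth
    phi = 2*pi*i/N + tan(theta)*z/rho; the kind alternates with the monomer
    layer (alpha on even layers).  With an odd start number this B-lattice
    convention yields homotypic lateral bonds at every boundary except the
    wrap, which is the seam.  Deterministic; no randomness.
    """
    p = params
    n, L = p.n_pf, p.n_dimer_layers
    a, r = p.monomer_repeat_a, p.lateral_rise_r
    rho = p.radius_rho
    drift = math.tan(math.radians(p.supertwist_theta)) / rho  # rad per Angstrom of z

    pf_idx, layer_idx = np.meshgrid(np.arange(n), np.arange(2 * L), indexing="ij")
    pf_idx = pf_idx.ravel()
    layer_idx = layer_idx.ravel()
    # measure PF offsets from the seam boundary so PF seam_index+1..N-1..
    # wrap order matches an arbitrary seam placement
    step = (pf_idx - (p.seam_index + 1)) % n
    z = layer_idx * a + step * r
    phi = 2.0 * math.pi * step / n + drift * z
    xyz = np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])

    # local PF direction: helix tangent (unit), identical handedness per PF
    tang = np.column_stack([-rho * drift * np.sin(phi),
                            rho * drift * np.cos(phi),
                            np.ones_like(phi)])
    tang /= np.linalg.norm(tang, axis=1, keepdims=True)

    kind = np.where(layer_idx % 2 == 0, "A", "B")
    return SubunitLattice(params=p, pf=pf_idx, layer=layer_idx,
                          kind=kind, xyz=xyz, axis=tang)


@dataclass(frozen=True)
class DecorationSiteSet:
    """Vertex decoration sites of a lattice.

    One site per PF pair per interior dimer-layer boundary, at the centroid
    of the four flanking tubulin dimers; the seam pair is omitted when
    ``exclude_seam`` is set (DC domains do not bind across the seam).
    """

    lattice: SubunitLattice
    pair: np.ndarray       # PF-pair (boundary) index per site
    dimer_layer: np.ndarray  # lower dimer-layer index per site
    xyz: np.ndarray        # (n_sites, 3) centroid positions, Angstrom
    exclude_seam: bool

    @property
    def n_sites(self) -> int:
        return len(self.pair)

    @property
    def sites_per_layer(self) -> int:
        n = self.lattice.params.n_pf
        return n - 1 if self.exclude_seam else n


def decoration_sites(lat: SubunitLattice, exclude_seam: bool = True) -> DecorationSiteSet:
    """Enumerate the inter-PF vertex sites of *lat*.

    The vertex between PFs (i, i+1) and dimer layers (l, l+1) is the corner
    of four tubulin dimers; its position is the centroid of the eight
    monomers making up those dimers.
    """
    p = lat.params
    n, L = p.n_pf, p.n_dimer_layers
    # monomer positions indexed [pf, layer]
    pos = np.full((n, 2 * L, 3), np.nan)
    pos[lat.pf, lat.layer] = lat.xyz
    dimer = 0.5 * (pos[:, 0::2] + pos[:, 1::2])  # [pf, dimer_layer, 3]

    pairs, layers, cents = [], [], []
    for b in range(n):
        if exclude_seam and b == p.seam_index:
            continue
        i, j = b, (b + 1) % n
        for l in range(L - 1):
            c = 0.25 * (dimer[i, l] + dimer[i, l + 1] + dimer[j, l] + dimer[j, l + 1])
            pairs.append(b)
            layers.append(l)
            cents.append(c)
    return DecorationSiteSet(lattice=lat, pair=np.asarray(pairs, dtype=int),
                             dimer_layer=np.asarray(layers, dtype=int),
                             xyz=np.asarray(cents, dtype=float),
                             exclude_seam=exclude_seam)


def lattice_to_csv(lat: SubunitLattice, path) -> None:
    """Write monomer poses as CSV with columns pf, layer, kind, x, y, z."""
    import pandas as pd

    pd.DataFrame({
        "pf": lat.pf, "layer": lat.layer, "kind": lat.kind,
        "x": lat.xyz[:, 0], "y": lat.xyz[:, 1], "z": lat.xyz[:, 2],
    }).to_csv(path, index=False, float_format="%.4f")


def lattice_to_pdb(lat: SubunitLattice, path) -> None:
    """Write one pseudo-atom (CA) per monomer for visual inspection.

    Alpha monomers become ALA, beta monomers GLY; the chain id cycles over
    PFs.  Purely diagnostic output.
    """
    chains = "ABCDEFGHIJKLMNOPQRST"
    with open(path, "w") as fh:
        for idx in range(lat.n_monomers):
            x, y, z = lat.xyz[idx]
            res = "ALA" if lat.kind[idx] == "A" else "GLY"
            fh.write(
                "ATOM  {serial:>5d}  CA  {res} {ch}{resseq:>4d}    "
                "{x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{b:6.2f}          "
                " C\n".format(serial=(idx + 1) % 100000, res=res,
                              ch=chains[lat.pf[idx] % len(chains)],
                              resseq=int(lat.layer[idx]) + 1,
                              x=x, y=y, z=z, occ=1.0, b=0.0))
        fh.write("END\n")
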