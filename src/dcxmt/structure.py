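"""Coordinate-model container, parsing, and atom selections.

Models are parsed with gemmi (PDB or mmCIF), hydrogens are dropped, and only
the highest-occupancy alternate location of each atom is kept.  Chains are
optionally tagged with *roles* - free-form labels such as ``"DC"`` for the
doublecortin domain and ``"alpha1" / "beta1" / "alpha2" / "beta2"`` for the
four tubulin subunits flanking the binding vertex - which the interface
operations use to group and report residues.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import FormatError, SelectionError

__all__ = ["StructureModel", "ContactParams", "Selection", "read_structure",
           "resolve_group"]


@dataclass(frozen=True)
class ContactParams:
    """Distance and surface parameters of the interface measurements.

    ``d_contact`` is the heavy-atom footprint cutoff (4 Angstrom: a residue
    belongs to the binding footprint when any of its heavy atoms comes this
    close to the partner).  ``d_polar`` bounds hydrogen-bond donor-acceptor
    N/O distances, ``d_salt`` charged-group nitrogen-carboxylate distances.
    ``probe_r`` and ``n_sphere_points`` parameterise the Shrake-Rupley
    solvent-accessible surface; ``radii_set`` names the vdW table in use so
    reports are reproducible.  ``his_charged`` treats histidine as
    positively charged for salt bridges (conservative default).
    """

    d_contact: float = 4.0
    d_polar: float = 3.5
    d_salt: float = 4.0
    probe_r: float = 1.4
    radii_set: str = "protor-like element defaults, v1"
    n_sphere_points: int = 960
    his_charged: bool = True

    def __post_init__(self):
        for name in ("d_contact", "d_polar", "d_salt", "probe_r"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_sphere_points < 10:
            raise ValueError("n_sphere_points must be at least 10")

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in
                ("d_contact", "d_polar", "d_salt", "probe_r", "radii_set",
                 "n_sphere_points", "his_charged")}


@dataclass
class StructureModel:
    """Heavy atoms of one coordinate model, as parallel arrays.

    ``chain_roles`` maps chain ids to role labels; atoms of chains without
    a role keep role ``""``.
    """

    chain: np.ndarray      # str per atom
    resnum: np.ndarray     # int per atom
    icode: np.ndarray      # str per atom ('' if none)
    resname: np.ndarray    # str per atom
    atname: np.ndarray     # str per atom
    element: np.ndarray    # str per atom
    xyz: np.ndarray        # (n, 3) float, Angstrom
    occ: np.ndarray        # float per atom
    chain_roles: dict[str, str] = field(default_factory=dict)
    name: str = ""

    def __post_init__(self):
        if not np.isfinite(self.xyz).all():
            raise FormatError("non-finite coordinates in model")

    @property
    def n_atoms(self) -> int:
        return len(self.resnum)

    @property
    def role(self) -> np.ndarray:
        return np.array([self.chain_roles.get(c, "") for c in self.chain])

    def residue_key(self) -> np.ndarray:
        """Per-atom residue identifier '<chain>:<resnum><icode>'."""
        return np.array([f"{c}:{n}{i}" for c, n, i in
                         zip(self.chain, self.resnum, self.icode)])

    def take(self, idx) -> "StructureModel":
        idx = np.asarray(idx)
        return StructureModel(
            chain=self.chain[idx], resnum=self.resnum[idx],
            icode=self.icode[idx], resname=self.resname[idx],
            atname=self.atname[idx], element=self.element[idx],
            xyz=self.xyz[idx], occ=self.occ[idx],
            chain_roles=dict(self.chain_roles), name=self.name)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray
                    ) -> "StructureModel":
        out = self.take(np.arange(self.n_atoms))
        out.xyz = self.xyz @ np.asarray(rotation).T + np.asarray(translation)
        return out


@dataclass(frozen=True)
class Selection:
    """Declarative atom selection.

    Any combination of chain ids, role labels, atom names, a residue-number
    range (inclusive) and explicit residue numbers; ``None`` means "no
    constraint".  ``mask`` combines the constraints conjunctively.
    """

    chains: tuple[str, ...] | None = None
    roles: tuple[str, ...] | None = None
    atom_names: tuple[str, ...] | None = None
    res_range: tuple[int, int] | None = None
    resnums: tuple[int, ...] | None = None

    @classmethod
    def make(cls, sel) -> "Selection":
        if isinstance(sel, Selection):
            return sel
        if isinstance(sel, dict):
            kw = {k: (tuple(v) if isinstance(v, (list, tuple, set)) else v)
                  for k, v in sel.items()}
            if kw.get("res_range") is not None:
                kw["res_range"] = tuple(kw["res_range"])
            return cls(**kw)
        raise SelectionError(f"cannot interpret selection {sel!r}")

    def mask(self, model: StructureModel) -> np.ndarray:
        m = np.ones(model.n_atoms, dtype=bool)
        if self.chains is not None:
            m &= np.isin(model.chain, list(self.chains))
        if self.roles is not None:
            m &= np.isin(model.role, list(self.roles))
        if self.atom_names is not None:
            m &= np.isin(model.atname, list(self.atom_names))
        if self.res_range is not None:
            lo, hi = self.res_range
            m &= (model.resnum >= lo) & (model.resnum <= hi)
        if self.resnums is not None:
            m &= np.isin(model.resnum, list(self.resnums))
        return m


def resolve_group(model: StructureModel, group) -> np.ndarray:
    """Resolve a group argument to atom indices.

    Accepts a role label, a chain id, an iterable of chain ids, a
    :class:`Selection` / dict, or a boolean mask / index array.  Raises
    :class:`SelectionError` when the group is empty.
    """
    if isinstance(group, np.ndarray):
        idx = np.flatnonzero(group) if group.dtype == bool else group
    elif isinstance(group, (Selection, dict)):
        idx = np.flatnonzero(Selection.make(group).mask(model))
    elif isinstance(group, str):
        roles = model.role
        if (roles == group).any():
            idx = np.flatnonzero(roles == group)
        else:
            idx = np.flatnonzero(model.chain == group)
    else:
        idx = np.flatnonzero(np.isin(model.chain, list(group)))
    idx = np.asarray(idx)
    if idx.size == 0:
        raise SelectionError(f"group {group!r} selects no atoms")
    return idx


def read_structure(path, chain_roles: dict[str, str] | None = None,
                   keep_waters: bool = False) -> StructureModel:
    """Parse a PDB or mmCIF file into a :class:`StructureModel`.

    Hydrogens are ignored; when alternate locations are present only the
    highest-occupancy one of each atom is retained (ties: first wins).
    ``chain_roles`` maps chain ids to role labels; naming a chain absent
    from the file is an error.
    """
    import gemmi

    path = Path(path)
    try:
        st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    if len(st) == 0:
        raise FormatError(f"{path} contains no models")
    st.setup_entities()
    model = st[0]

    rows = []
    for chain in model:
        for res in chain:
            if not keep_waters and res.is_water():
                continue
            best: dict[str, tuple[float, object]] = {}
            for atom in res:
                if atom.element.is_hydrogen:
                    continue
                prev = best.get(atom.name)
                if prev is None or atom.occ > prev[0]:
                    best[atom.name] = (atom.occ, atom)
            for _, atom in best.values():
                rows.append((chain.name, res.seqid.num,
                             (res.seqid.icode or " ").strip(), res.name,
                             atom.name, atom.element.name.upper(),
                             atom.pos.x, atom.pos.y, atom.pos.z, atom.occ))
    if not rows:
        raise FormatError(f"{path}: no heavy atoms parsed")
    cols = list(zip(*rows))
    sm = StructureModel(
        chain=np.array(cols[0]), resnum=np.array(cols[1], dtype=int),
        icode=np.array(cols[2]), resname=np.array(cols[3]),
        atname=np.array(cols[4]), element=np.array(cols[5]),
        xyz=np.column_stack([cols[6], cols[7], cols[8]]).astype(float),
        occ=np.array(cols[9], dtype=float),
        chain_roles=dict(chain_roles or {}), name=path.stem)
    if chain_roles:
        present = set(sm.chain)
        missing = [c for c in chain_roles if c not in present]
        if missing:
            raise FormatError(
                f"{path}: declared chains absent from file: {missing}")
    return sm
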