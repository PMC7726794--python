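"""Deterministic fixtures: toy structures and tiny segment stacks.

The toy complex is a synthetic stand-in for a MAP-domain/tubulin-vertex
model: a four-residue "DC domain" chain D facing four single-residue
"tubulin subunit" chains (roles alpha1/beta1/alpha2/beta2), built with
designed geometry so every footprint residue and polar contact is known by
construction:

* D LYS 1 NZ  -- A GLU 10 OE1 at 3.0 A  -> salt bridge (and footprint);
* D SER 2 OG  -- B ASN 20 OD1 at 3.2 A  -> hydrogen bond (and footprint);
* D VAL 3 CG1 -- C ALA 30 CB  at 3.8 A  -> apolar footprint contact only;
* D ARG 4 and chain E LEU 40 are >10 A from any partner (no contacts).

Everything here is generated programmatically; ``generate_fixtures`` writes
the files with a manifest of SHA-256 checksums so regeneration is
verifiable.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np

from . import __version__
from .errors import ParameterError
from .simulate import RenderParams, desk_params, make_dataset
from .structure import StructureModel

__all__ = ["toy_complex_model", "toy_domain_model", "write_model_pdb",
           "generate_fixtures"]

# (chain, resnum, resname, atname, element, x, y, z)
_TOY_COMPLEX_ATOMS = [
    # D LYS 1 -- salt-bridge donor cluster
    ("D", 1, "LYS", "N",   "N", -3.8,  1.0, 0.0),
    ("D", 1, "LYS", "CA",  "C", -3.0,  0.0, 0.0),
    ("D", 1, "LYS", "C",   "C", -3.8, -1.2, 0.0),
    ("D", 1, "LYS", "O",   "O", -4.9, -1.6, 0.0),
    ("D", 1, "LYS", "CB",  "C", -1.5,  0.0, 0.0),
    ("D", 1, "LYS", "NZ",  "N",  0.0,  0.0, 0.0),
    # A GLU 10 -- carboxylate partner: OE1 3.0 A from NZ
    ("A", 10, "GLU", "OE1", "O",  3.0,  0.0, 0.0),
    ("A", 10, "GLU", "OE2", "O",  4.4,  1.0, 0.0),
    ("A", 10, "GLU", "CD",  "C",  4.1,  0.1, 0.0),
    ("A", 10, "GLU", "CA",  "C",  6.5,  0.0, 0.0),
    ("A", 10, "GLU", "N",   "N",  7.3,  1.0, 0.0),
    ("A", 10, "GLU", "C",   "C",  7.3, -1.2, 0.0),
    ("A", 10, "GLU", "O",   "O",  8.4, -1.6, 0.0),
    # D SER 2 -- hydrogen-bond cluster at y = 20
    ("D", 2, "SER", "N",   "N", -3.7, 21.0, 0.0),
    ("D", 2, "SER", "CA",  "C", -2.9, 20.0, 0.0),
    ("D", 2, "SER", "C",   "C", -3.7, 18.8, 0.0),
    ("D", 2, "SER", "O",   "O", -4.8, 18.4, 0.0),
    ("D", 2, "SER", "CB",  "C", -1.4, 20.0, 0.0),
    ("D", 2, "SER", "OG",  "O",  0.0, 20.0, 0.0),
    # B ASN 20 -- amide partner: OD1 3.2 A from OG
    ("B", 20, "ASN", "OD1", "O",  3.2, 20.0, 0.0),
    ("B", 20, "ASN", "ND2", "N",  4.0, 21.2, 0.0),
    ("B", 20, "ASN", "CG",  "C",  4.3, 20.5, 0.0),
    ("B", 20, "ASN", "CA",  "C",  5.8, 20.3, 0.0),
    ("B", 20, "ASN", "N",   "N",  6.6, 21.3, 0.0),
    ("B", 20, "ASN", "C",   "C",  6.6, 19.1, 0.0),
    ("B", 20, "ASN", "O",   "O",  7.7, 18.7, 0.0),
    # D VAL 3 -- apolar contact cluster at y = 40
    ("D", 3, "VAL", "N",   "N", -3.8, 41.0, 0.0),
    ("D", 3, "VAL", "CA",  "C", -3.0, 40.0, 0.0),
    ("D", 3, "VAL", "C",   "C", -3.8, 38.8, 0.0),
    ("D", 3, "VAL", "O",   "O", -4.9, 38.4, 0.0),
    ("D", 3, "VAL", "CB",  "C", -1.5, 40.0, 0.0),
    ("D", 3, "VAL", "CG1", "C",  0.0, 40.0, 0.0),
    # C ALA 30 -- methyl partner: CB 3.8 A from CG1
    ("C", 30, "ALA", "CB",  "C",  3.8, 40.0, 0.0),
    ("C", 30, "ALA", "CA",  "C",  5.3, 40.0, 0.0),
    ("C", 30, "ALA", "N",   "N",  6.1, 41.0, 0.0),
    ("C", 30, "ALA", "C",   "C",  6.1, 38.8, 0.0),
    ("C", 30, "ALA", "O",   "O",  7.2, 38.4, 0.0),
    # D ARG 4 -- no partner within 10 A
    ("D", 4, "ARG", "N",   "N", -0.8, 61.0, 0.0),
    ("D", 4, "ARG", "CA",  "C",  0.0, 60.0, 0.0),
    ("D", 4, "ARG", "C",   "C", -0.8, 58.8, 0.0),
    ("D", 4, "ARG", "O",   "O", -1.9, 58.4, 0.0),
    ("D", 4, "ARG", "CB",  "C",  1.4, 60.0, 0.0),
    ("D", 4, "ARG", "NH1", "N",  3.0, 60.5, 0.0),
    # E LEU 40 -- distant subunit, no contacts
    ("E", 40, "LEU", "N",   "N", 14.2, 61.0, 0.0),
    ("E", 40, "LEU", "CA",  "C", 15.0, 60.0, 0.0),
    ("E", 40, "LEU", "C",   "C", 14.2, 58.8, 0.0),
    ("E", 40, "LEU", "O",   "O", 13.1, 58.4, 0.0),
    ("E", 40, "LEU", "CB",  "C", 16.4, 60.0, 0.0),
    ("E", 40, "LEU", "CD1", "C", 17.8, 60.0, 0.0),
]

TOY_CHAIN_ROLES = {"D": "DC", "A": "alpha1", "B": "beta1",
                   "C": "alpha2", "E": "beta2"}

#: designed ground truth of the toy complex
TOY_FOOTPRINT = {"alpha1": [("D", 1, "LYS")], "beta1": [("D", 2, "SER")],
                 "alpha2": [("D", 3, "VAL")]}
TOY_N_POLAR = 2
TOY_N_IONIC = 1


def _model_from_rows(rows, chain_roles, name) -> StructureModel:
    cols = list(zip(*rows))
    return StructureModel(
        chain=np.array(cols[0]), resnum=np.array(cols[1], dtype=int),
        icode=np.array([""] * len(rows)), resname=np.array(cols[2]),
        atname=np.array(cols[3]), element=np.array(cols[4]),
        xyz=np.column_stack([cols[5], cols[6], cols[7]]).astype(float),
        occ=np.ones(len(rows)), chain_roles=dict(chain_roles), name=name)


def toy_complex_model() -> StructureModel:
    """The designed DC-domain/tubulin-vertex toy complex (synthetic)."""
    return _model_from_rows(_TOY_COMPLEX_ATOMS, TOY_CHAIN_ROLES, "toy_complex")


def toy_domain_model() -> StructureModel:
    """Chain D of the toy complex alone (the 'isolated domain')."""
    rows = [r for r in _TOY_COMPLEX_ATOMS if r[0] == "D"]
    return _model_from_rows(rows, {"D": "DC"}, "toy_domain")


def write_model_pdb(model: StructureModel, path) -> None:
    """Write a StructureModel as minimal fixed-format PDB."""
    with open(path, "w") as fh:
        for i in range(model.n_atoms):
            x, y, z = model.xyz[i]
            fh.write(
                "ATOM  {serial:>5d} {name:<4s} {res:>3s} {ch}{resseq:>4d}    "
                "{x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{b:6.2f}          "
                "{el:>2s}\n".format(
                    serial=(i + 1) % 100000,
                    name=(" " + model.atname[i] if len(model.atname[i]) < 4
                          else model.atname[i]),
                    res=model.resname[i], ch=model.chain[i],
                    resseq=int(model.resnum[i]), x=x, y=y, z=z,
                    occ=float(model.occ[i]), b=0.0, el=model.element[i]))
        fh.write("END\n")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def generate_fixtures(out_dir, seed: int = 0,
                      archs=(11, 12, 13, 14, 15, 16),
                      rp: RenderParams | None = None) -> dict:
    """Write the fixture set and return its checksum manifest.

    Produces the toy complex/domain PDBs, one tiny two-segment stack per
    architecture (seeded from *seed*), a 10-row mutation CSV sampled from
    the packaged synthetic table, and ``manifest.json`` with SHA-256
    checksums, the seed and the package version.
    """
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise ParameterError(f"out_dir {out}: not writable ({exc})") from exc

    files: list[Path] = []
    write_model_pdb(toy_complex_model(), out / "toy_complex.pdb")
    write_model_pdb(toy_domain_model(), out / "toy_domain.pdb")
    files += [out / "toy_complex.pdb", out / "toy_domain.pdb"]

    base = rp or desk_params()
    for k, n in enumerate(archs):
        stack_rp = RenderParams(**{**base.__dict__,
                                   "seed": (seed * 1000 + k) % (2 ** 31)})
        stk = make_dataset([(n, 1.0, 0.5)], 2, stack_rp)
        p = out / f"stack_{n}pf.mrc"
        stk.write(p)
        files += [p, p.with_suffix(p.suffix + ".json")]

    from .mutations import packaged_mutation_table

    rng = np.random.default_rng(seed)
    table = packaged_mutation_table()
    pick = rng.choice(len(table), size=10, replace=False)
    with open(out / "mutations_10.csv", "w") as fh:
        fh.write("residue,wt_aa,mut_aa,domain\n")
        for i in sorted(pick):
            r = table[i]
            fh.write(f"{r.resnum},{r.wt_aa},{r.mut_aa},{r.domain}\n")
    files.append(out / "mutations_10.csv")

    manifest = {"seed": seed, "dcxmt_version": __version__,
                "files": {p.name: _sha256(p) for p in sorted(files)}}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1,
                                                  sort_keys=True))
    return manifest
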