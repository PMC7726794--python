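"""Pathogenic missense-mutation mapping onto the DC domains.

Doublecortin carries two homologous microtubule-binding DC domains, NDC and
CDC, and most disease-linked DCX missense mutations fall inside them.  Each
mutation site is classified structurally:

* ``interface`` - the residue belongs to the 4 Angstrom tubulin-contact
  footprint of the MT-bound complex;
* ``core`` - otherwise, its relative side-chain accessibility in the
  isolated domain falls below ``tau_core`` (default 0.20), i.e. it helps
  form the fold;
* ``unassigned-surface`` - solvent-exposed but not at the mapped interface;
* ``unclassified`` - the residue is missing from the model.

The interface class has a sharp quantitative definition (the 4 Angstrom
cutoff); the core/surface split is a declared accessibility criterion, not
a published number.  Residue numbering follows human DCX isoform 2
(360 residues); offsets for the 365/366-residue isoforms are provided.

The table shipped with the package
(``data/dcx_mutations_synthetic.csv``) is a synthetic stand-in whose
marginal counts match the published census of pathogenic DCX missense
mutations (78 total, 73 in the DC domains over 65 unique sites, 33 NDC +
32 CDC, 5 outside); the individual substitutions are constructed, not
clinical records.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ParameterError, SelectionError
from .sasa import MAX_SASA_TRIPEPTIDE, radii_for, shrake_rupley
from .structure import ContactParams, StructureModel
from .interface import contact_footprint

__all__ = ["MutationRecord", "DomainDefinition", "DEFAULT_DOMAINS",
           "ISOFORM_OFFSETS", "pairwise_identity", "relative_accessibility",
           "classify_mutation_sites", "summarize_counts",
           "load_mutation_table", "packaged_mutation_table"]

AA1 = set("ACDEFGHIKLMNPQRSTVWY")

#: residue-number offsets of the longer DCX isoforms relative to isoform 2
#: (positions past the splice divergence shift by the length difference)
ISOFORM_OFFSETS = {"isoform2_360": 0, "isoform1_365": 5, "isoform_366": 6}


@dataclass(frozen=True)
class DomainDefinition:
    """A DC domain as a residue window in isoform-2 numbering."""

    name: str
    start: int
    end: int
    sequence: str | None = None

    def __post_init__(self):
        if self.end < self.start:
            raise ParameterError(f"domain {self.name}: empty range "
                                 f"{self.start}-{self.end}")
        if self.sequence is not None and \
                len(self.sequence) != self.end - self.start + 1:
            raise ParameterError(
                f"domain {self.name}: sequence length {len(self.sequence)} "
                f"does not match range {self.start}-{self.end}")

    def __contains__(self, resnum: int) -> bool:
        return self.start <= resnum <= self.end


#: default DC-domain windows, isoform-2 numbering.  The NDC window starts
#: at the residue-48 construct boundary; both windows include the short
#: flanking stretches resolved in MT-bound maps.
DEFAULT_DOMAINS = (DomainDefinition("NDC", 48, 153),
                   DomainDefinition("CDC", 170, 260))


@dataclass
class MutationRecord:
    """One pathogenic missense substitution in isoform-2 numbering."""

    resnum: int
    wt_aa: str
    mut_aa: str
    domain: str = "outside"         # NDC | CDC | outside
    classification: str | None = None

    def __post_init__(self):
        if self.wt_aa not in AA1 or self.mut_aa not in AA1:
            raise ParameterError(
                f"residue {self.resnum}: invalid amino acids "
                f"{self.wt_aa!r}>{self.mut_aa!r}")


def assign_domains(records: list[MutationRecord],
                   domains=DEFAULT_DOMAINS) -> list[MutationRecord]:
    """Set each record's domain from the domain windows (first match wins)."""
    for rec in records:
        rec.domain = next((d.name for d in domains if rec.resnum in d),
                          "outside")
    return records


def load_mutation_table(path, domains=DEFAULT_DOMAINS) -> list[MutationRecord]:
    """Read a mutation CSV (columns residue, wt_aa, mut_aa[, domain]).

    When the domain column is absent it is assigned from the domain
    windows.
    """
    df = pd.read_csv(path, comment="#")
    need = {"residue", "wt_aa", "mut_aa"}
    if not need.issubset(df.columns):
        raise ParameterError(f"mutation table must have columns {sorted(need)}")
    records = [MutationRecord(int(r.residue), str(r.wt_aa), str(r.mut_aa))
               for r in df.itertuples()]
    if "domain" in df.columns:
        for rec, d in zip(records, df["domain"]):
            rec.domain = str(d)
    else:
        assign_domains(records, domains)
    return records


def packaged_mutation_table() -> list[MutationRecord]:
    """The synthetic stand-in mutation table shipped with the package."""
    with resources.as_file(resources.files("dcxmt.data")
                           / "dcx_mutations_synthetic.csv") as p:
        return load_mutation_table(p)


# -- sequence identity ------------------------------------------------------


def pairwise_identity(seq_a: str, seq_b: str, open_gap: float = -10.0,
                      extend_gap: float = -0.5,
                      matrix: str = "BLOSUM62") -> float:
    """Percent identity from a global protein alignment.

    Global (Needleman-Wunsch) alignment with a standard substitution
    matrix and affine gaps (defaults frozen: BLOSUM62, -10/-0.5); identity
    is the number of identical columns over all alignment columns
    (dual-gap columns cannot occur in a pairwise alignment), times 100.
    """
    from Bio import Align
    from Bio.Align import substitution_matrices

    for name, s in (("seq_a", seq_a), ("seq_b", seq_b)):
        if not s:
            raise ParameterError(f"{name} is empty")
        bad = set(s.upper()) - AA1
        if bad:
            raise ParameterError(f"{name}: invalid characters {sorted(bad)}")
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    aligner.open_gap_score = open_gap
    aligner.extend_gap_score = extend_gap
    aln = aligner.align(seq_a.upper(), seq_b.upper())[0]
    a, b = str(aln[0]), str(aln[1])
    cols = [(x, y) for x, y in zip(a, b) if not (x == "-" and y == "-")]
    matches = sum(1 for x, y in cols if x == y and x != "-")
    return 100.0 * matches / len(cols)


# -- accessibility and classification ---------------------------------------


def relative_accessibility(domain_model: StructureModel, chain: str,
                           resnum: int,
                           cp: ContactParams | None = None) -> float:
    """Residue SASA in the isolated domain over its Gly-X-Gly maximum.

    Values near 1 mean fully exposed (slightly above 1 is possible for
    unusual conformations); near 0, buried in the fold.
    """
    cp = cp or ContactParams()
    sel = (domain_model.chain == chain) & (domain_model.resnum == resnum)
    if not sel.any():
        raise SelectionError(f"residue {chain}:{resnum} absent from model")
    resname = domain_model.resname[sel][0]
    ref = MAX_SASA_TRIPEPTIDE.get(resname)
    if ref is None:
        raise SelectionError(f"no reference SASA for residue type {resname}")
    areas = shrake_rupley(domain_model.xyz,
                          radii_for(domain_model.element),
                          probe=cp.probe_r, n_points=cp.n_sphere_points)
    return float(areas[sel].sum() / ref)


def classify_mutation_sites(records: list[MutationRecord],
                            isolated_domain_model: StructureModel,
                            complex_model: StructureModel,
                            dc_group="DC", tubulin_group="tubulin",
                            cp: ContactParams | None = None,
                            tau_core: float = 0.20,
                            domain_chain: str | None = None,
                            ) -> tuple[list[MutationRecord], pd.DataFrame]:
    """Classify mutation sites as interface / core / unassigned-surface.

    A site is ``interface`` when its residue lies in the 4 Angstrom
    footprint of the DC group against tubulin in *complex_model*;
    otherwise ``core`` when its relative accessibility in
    *isolated_domain_model* is below ``tau_core``; otherwise
    ``unassigned-surface``.  Records whose residue is absent from the
    models are marked ``unclassified`` with a warning and the run
    continues.  Returns the records (mutated in place) and a per-domain /
    per-class summary of unique sites.
    """
    cp = cp or ContactParams()
    fp = contact_footprint(complex_model, dc_group, tubulin_group, cp)
    interface_resnums = set(fp.residue_numbers)
    if domain_chain is None:
        domain_chain = str(isolated_domain_model.chain[0])
    model_resnums = set(int(n) for n in
                        isolated_domain_model.resnum[
                            isolated_domain_model.chain == domain_chain])

    rel_cache: dict[int, float] = {}
    for rec in records:
        if rec.resnum in interface_resnums:
            rec.classification = "interface"
            continue
        if rec.resnum not in model_resnums:
            warnings.warn(f"residue {rec.resnum} absent from models; "
                          "record left unclassified", stacklevel=2)
            rec.classification = "unclassified"
            continue
        if rec.resnum not in rel_cache:
            rel_cache[rec.resnum] = relative_accessibility(
                isolated_domain_model, domain_chain, rec.resnum, cp)
        rec.classification = ("core" if rel_cache[rec.resnum] < tau_core
                              else "unassigned-surface")

    rows = []
    for dom in sorted({r.domain for r in records}):
        sub = [r for r in records if r.domain == dom]
        for cls in ("interface", "core", "unassigned-surface", "unclassified"):
            sites = {r.resnum for r in sub if r.classification == cls}
            rows.append({"domain": dom, "classification": cls,
                         "n_sites": len(sites),
                         "n_mutations": sum(r.classification == cls
                                            for r in sub)})
    return records, pd.DataFrame(rows)


def summarize_counts(records: list[MutationRecord]) -> dict:
    """Census arithmetic over a mutation table.

    Returns totals, per-domain mutation and unique-site counts, and the
    outside-domain bucket; unique sites are distinct residue numbers per
    domain.
    """
    in_domain = [r for r in records if r.domain != "outside"]
    per_domain: dict[str, dict] = {}
    for dom in sorted({r.domain for r in in_domain}):
        sub = [r for r in in_domain if r.domain == dom]
        per_domain[dom] = {"n_mutations": len(sub),
                           "n_unique_sites": len({r.resnum for r in sub})}
    return {
        "n_total": len(records),
        "n_in_domains": len(in_domain),
        "n_outside": len(records) - len(in_domain),
        "n_unique_sites_in_domains": len({(r.domain, r.resnum)
                                          for r in in_domain}),
        "per_domain": per_domain,
    }
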