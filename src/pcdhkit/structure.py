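"""Macromolecular coordinate model: reading/writing, selection, calcium stoichiometry.

The in-memory model is a thin, explicit hierarchy (structure -> chains ->
residues -> atoms) that preserves author numbering and insertion codes exactly
as read.  Parsing and serialisation of the PDB and mmCIF dialects are delegated
to gemmi; everything downstream (superposition, surface areas, interface
analysis) consumes only this model.

Conventions
-----------
* Alternate locations are resolved at load time: for each (residue, atom name)
  the highest-occupancy conformer is kept, ties broken by file order.
* Hydrogens are dropped (the crystal structures this package targets do not
  include them).
* Waters are flagged hetero and excluded from polymer operations.
* EC-domain annotations (EC1..EC6 residue intervals per chain) are supplied by
  configuration, never inferred from coordinates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np
import pandas as pd

from .errors import AnnotationError, EmptyStructureError, FormatError, SelectionError

WATER_NAMES = {"HOH", "WAT", "DOD"}

# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AtomRecord:
    serial: int
    name: str
    element: str
    alt_loc: str
    coords: tuple[float, float, float]
    occupancy: float = 1.0
    b_factor: float = 0.0
    is_hetero: bool = False

    def __post_init__(self):
        if not all(math.isfinite(c) for c in self.coords):
            raise FormatError(f"atom {self.serial} {self.name}: non-finite coordinates")
        if not 0.0 <= self.occupancy <= 1.0:
            raise FormatError(
                f"atom {self.serial} {self.name}: occupancy {self.occupancy} outside [0,1]"
            )


@dataclass
class ResidueRecord:
    chain_id: str
    author_seq_number: int
    residue_name: str
    atoms: list[AtomRecord] = field(default_factory=list)
    insertion_code: str = ""

    @property
    def seq_key(self) -> tuple[int, str]:
        # insertion codes sort after their base number ('' < 'A' < 'B' ...)
        return (self.author_seq_number, self.insertion_code)

    @property
    def is_water(self) -> bool:
        return self.residue_name in WATER_NAMES

    @property
    def is_hetero(self) -> bool:
        return all(a.is_hetero for a in self.atoms)

    def atom(self, name: str) -> AtomRecord | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    @property
    def ca(self) -> AtomRecord | None:
        return self.atom("CA") if not self.is_hetero else None


@dataclass
class StructureModel:
    id: str
    chains: dict[str, list[ResidueRecord]] = field(default_factory=dict)
    source_format: str = "pdb"

    # -- basic views --------------------------------------------------------

    @property
    def chain_ids(self) -> list[str]:
        return list(self.chains)

    def residues(self, chain_id: str | None = None) -> list[ResidueRecord]:
        if chain_id is not None:
            if chain_id not in self.chains:
                raise SelectionError(f"unknown chain {chain_id!r} in {self.id}")
            return list(self.chains[chain_id])
        return [r for ch in self.chains.values() for r in ch]

    def polymer_residues(self, chain_id: str | None = None) -> list[ResidueRecord]:
        return [r for r in self.residues(chain_id) if not r.is_hetero and not r.is_water]

    def atoms(self, include_hetero: bool = True) -> list[AtomRecord]:
        out = []
        for r in self.residues():
            if not include_hetero and (r.is_hetero or r.is_water):
                continue
            out.extend(r.atoms)
        return out

    def coords(self, include_hetero: bool = True) -> np.ndarray:
        ats = self.atoms(include_hetero=include_hetero)
        if not ats:
            return np.zeros((0, 3))
        return np.array([a.coords for a in ats], dtype=float)

    def ca_coords(self, chain_id: str | None = None) -> np.ndarray:
        cas = [r.ca for r in self.polymer_residues(chain_id) if r.ca is not None]
        if not cas:
            return np.zeros((0, 3))
        return np.array([a.coords for a in cas], dtype=float)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "StructureModel":
        """Return a rigid-motion copy (rotation then translation)."""
        R = np.asarray(rotation, dtype=float)
        t = np.asarray(translation, dtype=float)
        new_chains: dict[str, list[ResidueRecord]] = {}
        for cid, residues in self.chains.items():
            new_res = []
            for r in residues:
                new_atoms = [
                    replace(a, coords=tuple((R @ np.asarray(a.coords)) + t)) for a in r.atoms
                ]
                new_res.append(
                    ResidueRecord(r.chain_id, r.author_seq_number, r.residue_name,
                                  new_atoms, r.insertion_code)
                )
            new_chains[cid] = new_res
        return StructureModel(self.id, new_chains, self.source_format)

    def renamed_chains(self, mapping: dict[str, str]) -> "StructureModel":
        new_chains = {}
        for cid, residues in self.chains.items():
            nid = mapping.get(cid, cid)
            new_chains[nid] = [
                ResidueRecord(nid, r.author_seq_number, r.residue_name, list(r.atoms),
                              r.insertion_code)
                for r in residues
            ]
        if len(new_chains) != len(self.chains):
            raise SelectionError("chain renaming collapsed two chains onto one id")
        return StructureModel(self.id, new_chains, self.source_format)


@dataclass(frozen=True)
class DomainAnnotation:
    """EC-domain intervals (inclusive, author numbering) for one chain."""

    chain_id: str
    domains: tuple[tuple[str, int, int], ...]  # (label, start, end)

    def __post_init__(self):
        seen: list[tuple[int, int]] = []
        for label, start, end in self.domains:
            if end < start:
                raise AnnotationError(f"{label}: end {end} < start {start}")
            for s, e in seen:
                if start <= e and s <= end:
                    raise AnnotationError(f"{label}: overlapping interval on {self.chain_id}")
            seen.append((start, end))
        labels = [d[0] for d in self.domains]
        order = sorted(labels, key=lambda s: int(s[2:]) if s[2:].isdigit() else 0)
        if labels != order:
            raise AnnotationError(f"domain labels out of sequence order: {labels}")

    @property
    def labels(self) -> list[str]:
        return [d[0] for d in self.domains]

    def interval(self, label: str) -> tuple[int, int]:
        for lab, s, e in self.domains:
            if lab == label:
                return (s, e)
        raise AnnotationError(f"label {label!r} not annotated on chain {self.chain_id}")

    def label_of(self, seq_number: int) -> str | None:
        for lab, s, e in self.domains:
            if s <= seq_number <= e:
                return lab
        return None


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def _resolve_altlocs(residue: gemmi.Residue) -> list[gemmi.Atom]:
    """Keep the highest-occupancy conformer per atom name; ties -> first in file."""
    by_name: dict[str, gemmi.Atom] = {}
    for atom in residue:
        prev = by_name.get(atom.name)
        if prev is None or atom.occ > prev.occ:
            by_name[atom.name] = atom
    # preserve original order of the retained atoms
    retained = set(id(a) for a in by_name.values())
    return [a for a in residue if id(a) in retained]


def load_structure(path: str | Path, fmt: str | None = None) -> StructureModel:
    """Read a PDB or mmCIF file into a StructureModel.

    ``fmt`` may be "pdb" or "mmcif"; when omitted it is inferred from the
    file suffix.  Hydrogens are dropped and alternate locations resolved to
    the highest-occupancy conformer.
    """
    path = Path(path)
    if fmt is None:
        fmt = "mmcif" if path.suffix.lower() in {".cif", ".mmcif"} else "pdb"
    if fmt not in {"pdb", "mmcif"}:
        raise FormatError(f"unknown format {fmt!r}")
    try:
        if fmt == "pdb":
            st = gemmi.read_pdb(str(path))
        else:
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Mmcif)
    except (RuntimeError, ValueError, OSError) as exc:
        raise FormatError(f"could not parse {path}: {exc}") from exc

    st.setup_entities()
    model = st[0]
    out = StructureModel(id=st.name or path.stem, source_format=fmt)
    serial = 0
    for chain in model:
        residues: list[ResidueRecord] = []
        for res in chain:
            is_het = res.het_flag == "H" or res.name in WATER_NAMES
            atoms: list[AtomRecord] = []
            for atom in _resolve_altlocs(res):
                element = atom.element.name.upper()
                if element in {"H", "D"}:
                    continue
                serial += 1
                atoms.append(
                    AtomRecord(
                        serial=serial,
                        name=atom.name,
                        element=element,
                        alt_loc=atom.altloc if atom.altloc else "",
                        coords=(atom.pos.x, atom.pos.y, atom.pos.z),
                        occupancy=min(max(atom.occ, 0.0), 1.0),
                        b_factor=atom.b_iso,
                        is_hetero=is_het,
                    )
                )
            if atoms:
                residues.append(
                    ResidueRecord(
                        chain_id=chain.name,
                        author_seq_number=res.seqid.num,
                        residue_name=res.name,
                        atoms=atoms,
                        insertion_code=(res.seqid.icode or "").strip(),
                    )
                )
        if residues:
            out.chains[chain.name] = residues
    n_poly = sum(len(r.atoms) for r in out.polymer_residues())
    if n_poly == 0:
        raise EmptyStructureError(f"{path}: no polymer atoms")
    return out


def _to_gemmi(structure: StructureModel) -> gemmi.Structure:
    st = gemmi.Structure()
    st.name = structure.id
    model = gemmi.Model("1")
    for cid, residues in structure.chains.items():
        chain = gemmi.Chain(cid)
        for r in residues:
            res = gemmi.Residue()
            res.name = r.residue_name
            res.seqid = gemmi.SeqId(r.author_seq_number, r.insertion_code or " ")
            res.het_flag = "H" if (r.is_hetero or r.is_water) else "A"
            for a in r.atoms:
                atom = gemmi.Atom()
                atom.name = a.name
                atom.element = gemmi.Element(a.element.capitalize())
                atom.pos = gemmi.Position(*a.coords)
                atom.occ = a.occupancy
                atom.b_iso = a.b_factor
                atom.altloc = a.alt_loc or "\0"
                res.add_atom(atom)
            chain.add_residue(res)
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    return st


def write_structure(structure: StructureModel, path: str | Path, fmt: str | None = None) -> None:
    """Write a StructureModel as PDB or mmCIF (inferred from suffix by default)."""
    path = Path(path)
    if fmt is None:
        fmt = "mmcif" if path.suffix.lower() in {".cif", ".mmcif"} else "pdb"
    st = _to_gemmi(structure)
    if fmt == "pdb":
        st.write_pdb(str(path))
    elif fmt == "mmcif":
        st.make_mmcif_document().write_file(str(path))
    else:
        raise FormatError(f"unknown format {fmt!r}")


# ---------------------------------------------------------------------------
# Selection
# ---------------------------------------------------------------------------


def select(
    structure: StructureModel,
    chain_id: str | None = None,
    domain_labels: Sequence[str] | None = None,
    seq_range: tuple[int, int] | None = None,
    annotation: dict[str, DomainAnnotation] | None = None,
    include_hetero: bool = True,
) -> StructureModel:
    """Sub-structure containing exactly the requested residues, numbering unchanged.

    Either ``domain_labels`` (requires ``annotation``) or an inclusive author-
    numbering ``seq_range`` may be given; with neither, whole chains are kept.
    """
    if domain_labels is not None and annotation is None:
        raise AnnotationError("domain_labels selection requires an annotation")
    chain_ids = [chain_id] if chain_id is not None else structure.chain_ids
    out = StructureModel(structure.id, source_format=structure.source_format)
    for cid in chain_ids:
        if cid not in structure.chains:
            raise SelectionError(f"unknown chain {cid!r} in {structure.id}")
        intervals: list[tuple[int, int]] = []
        if domain_labels is not None:
            ann = annotation.get(cid) if annotation else None
            if ann is None:
                raise AnnotationError(f"no annotation for chain {cid!r}")
            for lab in domain_labels:
                intervals.append(ann.interval(lab))
        if seq_range is not None:
            intervals.append(tuple(seq_range))
        kept = []
        for r in structure.chains[cid]:
            if not include_hetero and (r.is_hetero or r.is_water):
                continue
            if intervals and not any(s <= r.author_seq_number <= e for s, e in intervals):
                continue
            kept.append(r)
        if kept:
            out.chains[cid] = kept
    return out


# ---------------------------------------------------------------------------
# Calcium stoichiometry at EC-EC junctions
# ---------------------------------------------------------------------------


def count_linker_calcium(
    structure: StructureModel,
    annotation: dict[str, DomainAnnotation],
    cutoff: float = 6.0,
    linker_residues: int = 5,
) -> pd.DataFrame:
    """Count calcium ions at each EC-EC junction.

    The linker region of a junction (ECi, ECi+1) is the last ``linker_residues``
    residues of ECi plus the first ``linker_residues`` of ECi+1.  A calcium ion
    (hetero atom with element CA) is assigned to a junction when it lies within
    ``cutoff`` angstroms of any protein atom of that linker region.  Counting is
    invariant under rigid motion of the structure.

    Returns a DataFrame with columns chain, junction, n_ca.
    """
    rows = []
    ca_ions = [
        a
        for r in structure.residues()
        if r.is_hetero and not r.is_water
        for a in r.atoms
        if a.element == "CA"
    ]
    ion_xyz = np.array([a.coords for a in ca_ions], dtype=float) if ca_ions else np.zeros((0, 3))
    for cid in structure.chain_ids:
        ann = annotation.get(cid)
        if ann is None:
            poly = structure.polymer_residues(cid)
            if poly:
                raise AnnotationError(f"no annotation for chain {cid!r}")
            continue
        labels = ann.labels
        poly = structure.polymer_residues(cid)
        for lab_a, lab_b in zip(labels, labels[1:]):
            sa, ea = ann.interval(lab_a)
            sb, eb = ann.interval(lab_b)
            in_a = sorted(
                (r for r in poly if sa <= r.author_seq_number <= ea), key=lambda r: r.seq_key
            )
            in_b = sorted(
                (r for r in poly if sb <= r.author_seq_number <= eb), key=lambda r: r.seq_key
            )
            linker = in_a[-linker_residues:] + in_b[:linker_residues]
            pts = np.array([a.coords for r in linker for a in r.atoms], dtype=float)
            if len(pts) == 0 or len(ion_xyz) == 0:
                n = 0
            else:
                d2 = ((ion_xyz[:, None, :] - pts[None, :, :]) ** 2).sum(axis=2)
                n = int((d2.min(axis=1) <= cutoff**2).sum())
            rows.append({"chain": cid, "junction": f"{lab_a}-{lab_b}", "n_ca": n})
    return pd.DataFrame(rows, columns=["chain", "junction", "n_ca"])


# ---------------------------------------------------------------------------
# Domain-annotation config
# ---------------------------------------------------------------------------


def read_domain_config(path: str | Path) -> dict[str, dict[str, DomainAnnotation]]:
    """Read a domain-boundary table (columns pdb_id, chain, domain, start, end).

    Returns {pdb_id: {chain: DomainAnnotation}}.
    """
    df = pd.read_csv(path, comment="#")
    required = {"pdb_id", "chain", "domain", "start", "end"}
    if not required.issubset(df.columns):
        raise AnnotationError(f"domain config missing columns {required - set(df.columns)}")
    out: dict[str, dict[str, DomainAnnotation]] = {}
    for (pdb_id, chain), grp in df.groupby(["pdb_id", "chain"], sort=False):
        domains = tuple(
            (row.domain, int(row.start), int(row.end)) for row in grp.itertuples()
        )
        out.setdefault(str(pdb_id), {})[str(chain)] = DomainAnnotation(str(chain), domains)
    return out


def annotation_from_ranges(
    chain_ids: Iterable[str], ranges: Sequence[tuple[str, int, int]]
) -> dict[str, DomainAnnotation]:
    """Convenience: apply one (label, start, end) list to several chains."""
    return {cid: DomainAnnotation(cid, tuple(ranges)) for cid in chain_ids}
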