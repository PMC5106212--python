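"""Solvent-accessible and buried surface areas, interface residues, contacts.

SASA follows the Shrake–Rupley point-sampling construction: each atom is
expanded by the probe radius and covered with a deterministic Fibonacci-
lattice point set; the accessible fraction is the fraction of points outside
every expanded neighbour sphere.  The point lattice is a fixed function of
``n_points`` only, so areas are bit-reproducible.

Buried surface area (BSA) of a complex is the decrease in accessible area
summed over both protomers: ASA(protomer A alone) + ASA(protomer B alone)
- ASA(complex), accumulated per residue.  A residue's percent-buried uses
its ASA in the isolated protomer as denominator.  Cross-interface contact
pairs are residue pairs from opposite protomers with Cα–Cα distance strictly
below a cutoff (default 10 Å).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .errors import ParameterError, RadiiError, SelectionError
from .structure import ResidueRecord, StructureModel

# Van der Waals radii (Å) by element; a pragmatic protein-centric set.
DEFAULT_RADII = {
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
    "SE": 1.90,
    "CA": 1.97,  # calcium ion
    "MG": 1.73,
    "ZN": 1.39,
    "F": 1.47,
    "CL": 1.75,
}

DEFAULT_PROBE = 1.4
DEFAULT_N_POINTS = 960


@dataclass
class SasaResult:
    per_atom_area: np.ndarray  # Å², aligned with the atom list used
    probe_radius: float
    n_sphere_points: int
    radii_set_name: str = "default"

    @property
    def total(self) -> float:
        return float(self.per_atom_area.sum())


@dataclass
class ResidueBsa:
    chain_id: str
    seq_number: int
    residue_name: str
    asa_free: float
    asa_complex: float
    missing_atoms: bool = False

    @property
    def bsa(self) -> float:
        return max(self.asa_free - self.asa_complex, 0.0)

    @property
    def percent_buried(self) -> float:
        if self.asa_free <= 0.0:
            return 0.0
        return float(np.clip(100.0 * self.bsa / self.asa_free, 0.0, 100.0))


@dataclass
class InterfaceReport:
    structure_id: str
    total_bsa: float
    residues_a: list[ResidueBsa] = field(default_factory=list)
    residues_b: list[ResidueBsa] = field(default_factory=list)
    contact_pairs: list[tuple[ResidueRecord, ResidueRecord, float]] = field(default_factory=list)
    interface_threshold: float = 0.1

    @property
    def interfacial_residues(self) -> list[ResidueBsa]:
        return [
            r for r in self.residues_a + self.residues_b if r.bsa > self.interface_threshold
        ]

    @property
    def n_contacts(self) -> int:
        return len(self.contact_pairs)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for side, residues in (("A", self.residues_a), ("B", self.residues_b)):
            for r in residues:
                rows.append(
                    {
                        "protomer": side,
                        "chain": r.chain_id,
                        "seq_number": r.seq_number,
                        "residue": r.residue_name,
                        "asa_free": r.asa_free,
                        "asa_complex": r.asa_complex,
                        "bsa": r.bsa,
                        "percent_buried": r.percent_buried,
                        "missing_atoms": r.missing_atoms,
                    }
                )
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Shrake-Rupley SASA
# ---------------------------------------------------------------------------


def _fibonacci_sphere(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit-sphere lattice (golden-angle spiral)."""
    i = np.arange(n, dtype=float)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    z = 1.0 - 2.0 * (i + 0.5) / n
    rho = np.sqrt(np.clip(1.0 - z * z, 0.0, 1.0))
    return np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])


def _analysis_residues(structure: StructureModel, include_hetero: bool):
    """Residues entering SASA/BSA: waters always out, hetero only on request."""
    out = []
    for res in structure.residues():
        if res.is_water:
            continue
        if res.is_hetero and not include_hetero:
            continue
        out.append(res)
    return out


def _analysis_atoms(structure: StructureModel, include_hetero: bool):
    return [a for res in _analysis_residues(structure, include_hetero) for a in res.atoms]


def _local_frame(xyz: np.ndarray, i: int, occluders: list[int]) -> np.ndarray:
    """Rotation-covariant lattice orientation for atom i.

    The sampling lattice is expressed in a frame built from the atom's
    occluding neighbours (mean neighbour direction + nearest neighbour), so
    per-atom areas are exactly invariant under any proper rigid motion of the
    whole structure - in particular, the two protomers of an exactly
    symmetric dimer receive identical areas.
    """
    if not occluders:
        return np.eye(3)
    vecs = xyz[occluders] - xyz[i]
    dists = np.linalg.norm(vecs, axis=1)
    z = (vecs / dists[:, None]).sum(axis=0)
    nz = np.linalg.norm(z)
    if nz < 1e-10:
        z = vecs[int(np.argmin(dists))] / dists.min()
    else:
        z = z / nz
    x = None
    for j in np.argsort(dists, kind="stable"):
        u = vecs[j]
        cand = u - (u @ z) * z
        if np.linalg.norm(cand) > 1e-8:
            x = cand / np.linalg.norm(cand)
            break
    if x is None:
        # all occluders along z: any transverse axis gives the same area set
        x = np.array([z[1] - z[2], z[2] - z[0], z[0] - z[1]])
        n = np.linalg.norm(x)
        x = x / n if n > 1e-10 else np.array([1.0, 0.0, 0.0])
    y = np.cross(z, x)
    return np.column_stack([x, y, z])


def _atom_radii(
    atoms, radii: dict[str, float], fallback_radius: float | None
) -> np.ndarray:
    out = np.empty(len(atoms))
    for i, a in enumerate(atoms):
        r = radii.get(a.element)
        if r is None:
            if fallback_radius is None:
                raise RadiiError(f"no radius for element {a.element!r} and no fallback set")
            r = fallback_radius
        out[i] = r
    return out


def compute_sasa(
    structure: StructureModel,
    probe: float = DEFAULT_PROBE,
    n_points: int = DEFAULT_N_POINTS,
    radii: dict[str, float] | None = None,
    radii_set_name: str = "default",
    fallback_radius: float | None = 1.70,
    include_hetero: bool = False,
) -> SasaResult:
    """Per-atom solvent-accessible surface area of a structure.

    Waters are always excluded; hetero atoms (glycans, ions) are excluded by
    default and included with ``include_hetero=True``.
    """
    radii = DEFAULT_RADII if radii is None else radii
    atoms = _analysis_atoms(structure, include_hetero)
    if not atoms:
        raise SelectionError("structure has no atoms after filtering")
    xyz = np.array([a.coords for a in atoms], dtype=float)
    rad = _atom_radii(atoms, radii, fallback_radius) + probe
    sphere = _fibonacci_sphere(n_points)
    tree = cKDTree(xyz)
    max_r = rad.max()
    areas = np.zeros(len(atoms))
    for i in range(len(atoms)):
        neighbours = tree.query_ball_point(xyz[i], rad[i] + max_r)
        neighbours = [j for j in neighbours if j != i]
        # keep only genuine occluders
        occluders = [
            j for j in neighbours
            if np.linalg.norm(xyz[j] - xyz[i]) < rad[i] + rad[j]
        ]
        frame = _local_frame(xyz, i, occluders)
        pts = xyz[i] + rad[i] * (sphere @ frame.T)
        accessible = np.ones(n_points, dtype=bool)
        for j in occluders:
            d2 = ((pts - xyz[j]) ** 2).sum(axis=1)
            accessible &= d2 > rad[j] ** 2
            if not accessible.any():
                break
        areas[i] = 4.0 * np.pi * rad[i] ** 2 * accessible.mean()
    return SasaResult(areas, probe, n_points, radii_set_name)


# residues where any non-backbone heavy atom is expected but absent
_EXPECTED_SIDECHAIN = {
    "GLY": 0, "ALA": 1, "SER": 2, "CYS": 2, "THR": 3, "VAL": 3, "PRO": 3,
    "ASP": 4, "ASN": 4, "ILE": 4, "LEU": 4, "MET": 4, "GLU": 5, "GLN": 5,
    "LYS": 5, "HIS": 6, "ARG": 7, "PHE": 7, "TYR": 8, "TRP": 10,
}
_BACKBONE = {"N", "CA", "C", "O", "OXT"}


def _missing_sidechain(residue: ResidueRecord) -> bool:
    expected = _EXPECTED_SIDECHAIN.get(residue.residue_name)
    if expected is None:
        return False
    n_side = sum(1 for a in residue.atoms if a.name not in _BACKBONE)
    return n_side < expected


# ---------------------------------------------------------------------------
# Interface analysis
# ---------------------------------------------------------------------------


def _per_residue_areas(structure: StructureModel, sasa: SasaResult,
                       include_hetero: bool) -> dict[tuple[str, int, str], float]:
    keyed: dict[tuple[str, int, str], float] = {}
    idx = 0
    for res in _analysis_residues(structure, include_hetero):
        key = (res.chain_id, res.author_seq_number, res.insertion_code)
        for _ in res.atoms:
            keyed[key] = keyed.get(key, 0.0) + sasa.per_atom_area[idx]
            idx += 1
    assert idx == len(sasa.per_atom_area)
    return keyed


def _protomer(structure: StructureModel, chain_ids: list[str]) -> StructureModel:
    sub = StructureModel(structure.id, source_format=structure.source_format)
    for cid in chain_ids:
        if cid not in structure.chains:
            raise SelectionError(f"unknown chain {cid!r}")
        sub.chains[cid] = structure.chains[cid]
    return sub


def compute_interface(
    complex_structure: StructureModel,
    sel_a: list[str],
    sel_b: list[str],
    probe: float = DEFAULT_PROBE,
    n_points: int = DEFAULT_N_POINTS,
    contact_cutoff: float = 10.0,
    interface_threshold: float = 0.1,
    include_hetero: bool = False,
) -> InterfaceReport:
    """Buried surface area and contacts between two protomer selections.

    ``sel_a`` and ``sel_b`` are disjoint chain-id lists.  ASA of each protomer
    is computed in isolation, then on the assembled pair; the per-residue
    difference (clamped at 0) is the residue BSA.  Contact pairs are all
    inter-protomer residue pairs with Cα–Cα distance strictly below
    ``contact_cutoff`` (ties at exactly the cutoff are excluded).
    """
    if set(sel_a) & set(sel_b):
        raise SelectionError(f"selections overlap: {set(sel_a) & set(sel_b)}")
    prot_a = _protomer(complex_structure, sel_a)
    prot_b = _protomer(complex_structure, sel_b)
    both = _protomer(complex_structure, sel_a + sel_b)

    kwargs = dict(probe=probe, n_points=n_points, include_hetero=include_hetero)
    asa_a = _per_residue_areas(prot_a, compute_sasa(prot_a, **kwargs), include_hetero)
    asa_b = _per_residue_areas(prot_b, compute_sasa(prot_b, **kwargs), include_hetero)
    asa_c = _per_residue_areas(both, compute_sasa(both, **kwargs), include_hetero)

    def residue_list(prot: StructureModel, free: dict) -> list[ResidueBsa]:
        out = []
        for res in _analysis_residues(prot, include_hetero):
            key = (res.chain_id, res.author_seq_number, res.insertion_code)
            out.append(
                ResidueBsa(
                    chain_id=res.chain_id,
                    seq_number=res.author_seq_number,
                    residue_name=res.residue_name,
                    asa_free=free.get(key, 0.0),
                    asa_complex=asa_c.get(key, 0.0),
                    missing_atoms=_missing_sidechain(res),
                )
            )
        return out

    residues_a = residue_list(prot_a, asa_a)
    residues_b = residue_list(prot_b, asa_b)
    total_bsa = sum(r.bsa for r in residues_a + residues_b)

    # contacts: strict < cutoff on Cα-Cα distance, across the interface only
    res_a = [r for r in prot_a.polymer_residues() if r.ca is not None]
    res_b = [r for r in prot_b.polymer_residues() if r.ca is not None]
    contacts: list[tuple[ResidueRecord, ResidueRecord, float]] = []
    if res_a and res_b:
        xyz_a = np.array([r.ca.coords for r in res_a])
        xyz_b = np.array([r.ca.coords for r in res_b])
        tree_b = cKDTree(xyz_b)
        for i, hits in enumerate(tree_b.query_ball_point(xyz_a, contact_cutoff)):
            for j in hits:
                d = float(np.linalg.norm(xyz_a[i] - xyz_b[j]))
                if d < contact_cutoff:
                    contacts.append((res_a[i], res_b[j], d))
    contacts.sort(key=lambda c: (c[0].seq_key, c[1].seq_key))

    return InterfaceReport(
        structure_id=complex_structure.id,
        total_bsa=total_bsa,
        residues_a=residues_a,
        residues_b=residues_b,
        contact_pairs=contacts,
        interface_threshold=interface_threshold,
    )


# ---------------------------------------------------------------------------
# %BSA binning and per-position profiles
# ---------------------------------------------------------------------------


def bin_percent_bsa(
    report: InterfaceReport, bin_edges: list[float] | None = None
) -> pd.DataFrame:
    """Histogram of interfacial residues by percent buried surface area.

    Default edges run every 10% from 0 to 100; the last bin is closed so a
    fully buried residue (100%) counts in it.
    """
    edges = np.asarray(bin_edges if bin_edges is not None else np.arange(0, 101, 10), float)
    if len(edges) < 2 or np.any(np.diff(edges) <= 0):
        raise ParameterError("bin edges must be strictly increasing")
    values = [r.percent_buried for r in report.interfacial_residues]
    counts, _ = np.histogram(values, bins=edges)
    return pd.DataFrame(
        {
            "bin_low": edges[:-1],
            "bin_high": edges[1:],
            "count": counts.astype(int),
        }
    )


def per_position_bsa_profile(
    reports: list[InterfaceReport],
    numbering_maps: dict[str, dict[tuple[str, int], int]],
) -> pd.DataFrame:
    """Long-format per-residue %BSA table on a shared reference numbering.

    ``numbering_maps[structure_id]`` maps (chain_id, author number) to the
    reference position.  Interfacial residues that cannot be mapped raise a
    MappingError listing the offenders.
    """
    from .errors import MappingError

    rows = []
    offenders = []
    for report in reports:
        nmap = numbering_maps.get(report.structure_id)
        if nmap is None:
            raise MappingError(
                f"no numbering map for {report.structure_id!r}", [report.structure_id]
            )
        for r in report.interfacial_residues:
            ref = nmap.get((r.chain_id, r.seq_number))
            if ref is None:
                offenders.append((report.structure_id, r.chain_id, r.seq_number))
                continue
            rows.append(
                {
                    "reference_position": ref,
                    "structure_id": report.structure_id,
                    "percent_buried": r.percent_buried,
                }
            )
    if offenders:
        raise MappingError(f"unmapped interfacial residues: {offenders}", offenders)
    df = pd.DataFrame(rows, columns=["reference_position", "structure_id", "percent_buried"])
    return df.sort_values(["reference_position", "structure_id"]).reset_index(drop=True)
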