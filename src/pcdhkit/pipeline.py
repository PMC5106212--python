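"""Config-driven orchestration: structure, specificity, and AUC reports.

A run is described by a RunConfig (validated up front; unknown keys are
rejected) and produces a ReportBundle: a directory of CSV/JSON artifacts
plus a manifest recording inputs, parameters, package version, and seeds,
sufficient to re-run the bundle bit-compatibly.  Failures are isolated per
input: one bad structure or scan set is reported in the manifest and does
not abort the remaining analyses.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Optional

import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

from . import __version__
from .errors import ConfigError, PcdhkitError
from . import auc as auc_mod
from . import conservation as cons
from . import geometry, interface, specificity
from .structure import load_structure, read_domain_config, select

log = logging.getLogger("pcdhkit")


# ---------------------------------------------------------------------------
# Configuration schema
# ---------------------------------------------------------------------------


class StructureEntry(BaseModel):
    model_config = ConfigDict(extra="forbid")
    id: str
    path: Optional[str] = None  # explicit file path...
    accession: Optional[str] = None  # ...or an id resolved from cache_dir
    chains: list[str] = Field(default_factory=list)  # dimer chain pair, in order


class SequenceSet(BaseModel):
    model_config = ConfigDict(extra="forbid")
    isoform: str
    alignment_path: str  # FASTA alignment of orthologs
    reference_id: Optional[str] = None  # defaults to first record
    reference_start: int = 1


class AucFragment(BaseModel):
    model_config = ConfigDict(extra="forbid")
    name: str
    scan_paths: list[str]
    monomer_mass: float
    vbar: float = 0.73
    solvent_density: float = 1.005
    extinction: float = 50000.0
    path_length: float = 1.2


class RunConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    structures: list[StructureEntry] = Field(default_factory=list)
    domain_config: Optional[str] = None  # CSV: pdb_id, chain, domain, start, end
    cache_dir: Optional[str] = None  # local structure cache for accession entries
    sequence_sets: list[SequenceSet] = Field(default_factory=list)
    contact_positions: list[list[int]] = Field(default_factory=list)  # reference pairs
    face_positions: list[int] = Field(default_factory=list)
    group_a: list[str] = Field(default_factory=list)  # isoform names for face diff
    group_b: list[str] = Field(default_factory=list)
    auc_fragments: list[AucFragment] = Field(default_factory=list)
    trim_cycles: int = 5
    trim_cutoff: float = 2.0
    contact_cutoff: float = 10.0
    sasa_points: int = 960
    purity_threshold: float = 0.8
    out_dir: str = "pcdhkit_out"
    seed: int = 0

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text())
        try:
            return cls.model_validate(raw)
        except Exception as exc:
            raise ConfigError(f"invalid run config {path}: {exc}") from exc


class ReportBundle:
    """Output directory with per-analysis artifacts and a manifest."""

    def __init__(self, out_dir: str | Path, config: RunConfig, analysis: str):
        self.out_dir = Path(out_dir)
        self.out_dir.mkdir(parents=True, exist_ok=True)
        self.manifest = {
            "analysis": analysis,
            "version": __version__,
            "seed": config.seed,
            "parameters": json.loads(config.model_dump_json()),
            "artifacts": [],
            "failures": [],
            "timers_s": {},
        }

    def add_frame(self, name: str, df: pd.DataFrame) -> Path:
        path = self.out_dir / f"{name}.csv"
        df.to_csv(path, index=False)
        self.manifest["artifacts"].append(
            {"name": name, "path": path.name, "sha256": _sha256(path)}
        )
        return path

    def add_json(self, name: str, payload) -> Path:
        path = self.out_dir / f"{name}.json"
        path.write_text(json.dumps(payload, indent=2, default=str))
        self.manifest["artifacts"].append(
            {"name": name, "path": path.name, "sha256": _sha256(path)}
        )
        return path

    def fail(self, item: str, error: Exception) -> None:
        log.warning("%s failed: %s", item, error)
        self.manifest["failures"].append({"item": item, "error": str(error)})

    def finish(self) -> Path:
        path = self.out_dir / "manifest.json"
        path.write_text(json.dumps(self.manifest, indent=2))
        return path

    @property
    def checksums(self) -> dict[str, str]:
        return {a["name"]: a["sha256"] for a in self.manifest["artifacts"]}


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _timer(bundle: ReportBundle, name: str):
    class _T:
        def __enter__(self):
            self.t0 = time.perf_counter()
            return self

        def __exit__(self, *exc):
            bundle.manifest["timers_s"][name] = round(time.perf_counter() - self.t0, 3)

    return _T()


# ---------------------------------------------------------------------------
# Structure report
# ---------------------------------------------------------------------------


def _resolve_structure(entry: StructureEntry, config: RunConfig):
    if entry.path:
        return load_structure(entry.path)
    if entry.accession:
        if not config.cache_dir:
            raise ConfigError(f"{entry.id}: accession given but no cache_dir configured")
        cache = Path(config.cache_dir)
        for suffix in (".pdb", ".cif", ".ent"):
            candidate = cache / f"{entry.accession.lower()}{suffix}"
            if candidate.exists():
                return load_structure(candidate)
            candidate = cache / f"{entry.accession.upper()}{suffix}"
            if candidate.exists():
                return load_structure(candidate)
        raise ConfigError(
            f"{entry.id}: accession {entry.accession} not found in cache {cache} "
            "(populate it with scripts/fetch_depositions.py)"
        )
    raise ConfigError(f"{entry.id}: neither path nor accession given")


def run_structure_report(config: RunConfig) -> ReportBundle:
    """Pairwise protomer/dimer RMSD matrices, bend angles, BSA, contacts."""
    bundle = ReportBundle(Path(config.out_dir) / "structure", config, "structure-report")
    annotations = read_domain_config(config.domain_config) if config.domain_config else {}

    loaded = {}
    with _timer(bundle, "load"):
        for entry in config.structures:
            try:
                loaded[entry.id] = (entry, _resolve_structure(entry, config))
            except (PcdhkitError, OSError) as exc:
                bundle.fail(entry.id, exc)
    if config.structures and not loaded:
        bundle.finish()
        return bundle

    ids = list(loaded)

    # protomer pairwise RMSD matrix (first chain of each entry)
    with _timer(bundle, "protomer_rmsd"):
        proto = pd.DataFrame(index=ids, columns=ids, dtype=object)
        for i, a in enumerate(ids):
            proto.loc[a, a] = "0.00 (n/a)"
            for b in ids[i + 1:]:
                try:
                    ea, sa = loaded[a]
                    eb, sb = loaded[b]
                    ca = sa if not ea.chains else select(sa, ea.chains[0])
                    cb = sb if not eb.chains else select(sb, eb.chains[0])
                    res = geometry.trimmed_align(
                        ca, cb, max_cycles=config.trim_cycles,
                        reject_cutoff=config.trim_cutoff,
                    )
                    cell = f"{res.rmsd:.2f} ({res.n_aligned})"
                except PcdhkitError as exc:
                    bundle.fail(f"protomer {a} vs {b}", exc)
                    cell = "failed"
                proto.loc[a, b] = proto.loc[b, a] = cell
        bundle.add_frame("protomer_rmsd", proto.reset_index(names="structure"))

    # dimer pairwise RMSD matrix for two-chain entries
    dimer_ids = [i for i in ids if len(loaded[i][0].chains) == 2]
    with _timer(bundle, "dimer_rmsd"):
        dim = pd.DataFrame(index=dimer_ids, columns=dimer_ids, dtype=object)
        for i, a in enumerate(dimer_ids):
            dim.loc[a, a] = "0.00 (n/a)"
            for b in dimer_ids[i + 1:]:
                try:
                    ea, sa = loaded[a]
                    eb, sb = loaded[b]
                    da = _two_chain(sa, ea.chains)
                    db = _two_chain(sb, eb.chains)
                    res = geometry.compare_dimers(
                        da, db, max_cycles=config.trim_cycles,
                        reject_cutoff=config.trim_cutoff,
                    )
                    cell = f"{res.rmsd:.2f} ({res.n_aligned})"
                except PcdhkitError as exc:
                    bundle.fail(f"dimer {a} vs {b}", exc)
                    cell = "failed"
                dim.loc[a, b] = dim.loc[b, a] = cell
        if dimer_ids:
            bundle.add_frame("dimer_rmsd", dim.reset_index(names="structure"))

    # interdomain angles
    with _timer(bundle, "angles"):
        rows = []
        for sid, (entry, st) in loaded.items():
            ann = annotations.get(entry.accession or sid) or annotations.get(sid)
            if not ann:
                continue
            for cid in st.chain_ids:
                ca = ann.get(cid)
                if ca is None:
                    continue
                labels = ca.labels
                for la, lb in zip(labels, labels[1:]):
                    try:
                        bend = geometry.interdomain_angle(st, ca, (la, lb), chain_id=cid)
                        rows.append(
                            {"structure": sid, "chain": cid,
                             "junction": f"{la}-{lb}",
                             "deviation_deg": round(bend.deviation_deg, 1)}
                        )
                    except PcdhkitError as exc:
                        bundle.fail(f"angle {sid} {cid} {la}-{lb}", exc)
        if rows:
            bundle.add_frame("interdomain_angles", pd.DataFrame(rows))

    # interface BSA + contacts + %BSA histogram per two-chain entry
    with _timer(bundle, "interfaces"):
        summary, hist_rows = [], []
        for sid in dimer_ids:
            entry, st = loaded[sid]
            try:
                report = interface.compute_interface(
                    st, [entry.chains[0]], [entry.chains[1]],
                    n_points=config.sasa_points, contact_cutoff=config.contact_cutoff,
                )
                summary.append(
                    {"structure": sid, "total_bsa_A2": round(report.total_bsa, 1),
                     "n_interfacial": len(report.interfacial_residues),
                     "n_contacts": report.n_contacts}
                )
                hist = interface.bin_percent_bsa(report)
                hist["structure"] = sid
                hist_rows.append(hist)
            except PcdhkitError as exc:
                bundle.fail(f"interface {sid}", exc)
        if summary:
            bundle.add_frame("interface_summary", pd.DataFrame(summary))
        if hist_rows:
            bundle.add_frame("percent_bsa_histogram", pd.concat(hist_rows, ignore_index=True))

    bundle.finish()
    return bundle


def _two_chain(st, chain_pair):
    from .structure import StructureModel

    if len(chain_pair) != 2:
        raise ConfigError(f"{st.id}: dimer analyses need exactly two chains")
    out = StructureModel(st.id, source_format=st.source_format)
    for cid in chain_pair:
        out.chains[cid] = st.chains[cid]
    return out


# ---------------------------------------------------------------------------
# Specificity report
# ---------------------------------------------------------------------------


def run_specificity_report(config: RunConfig) -> ReportBundle:
    """Variability classes, specificity calls, subfamily face differences."""
    bundle = ReportBundle(Path(config.out_dir) / "specificity", config, "specificity-report")
    logos: dict[str, cons.IsoformLogo] = {}
    with _timer(bundle, "logos"):
        for sset in config.sequence_sets:
            try:
                msa = cons.read_fasta(sset.alignment_path)
                ref = sset.reference_id or msa[0].id
                logos[sset.isoform] = cons.build_logo(
                    msa, ref, isoform=sset.isoform, reference_start=sset.reference_start
                )
            except (PcdhkitError, OSError) as exc:
                bundle.fail(sset.isoform, exc)
    if logos:
        frames = []
        for iso, logo in logos.items():
            df = logo.to_frame()
            df.insert(0, "isoform", iso)
            frames.append(df)
        bundle.add_frame("logos", pd.concat(frames, ignore_index=True))

    contacts = [
        specificity.ResiduePairContact(a, b, "configured", float("nan"))
        for a, b in config.contact_positions
    ]
    with _timer(bundle, "calls"):
        if logos and contacts:
            try:
                positions = sorted({p for c in config.contact_positions for p in c})
                classes = cons.classify_positions(
                    logos, positions, purity_threshold=config.purity_threshold
                )
                bundle.add_frame(
                    "variability_classes",
                    pd.DataFrame(
                        [
                            {"position": v.position, "class": v.variability,
                             **{f"consensus_{k}": r for k, r in v.consensus.items()}}
                            for v in classes
                        ]
                    ),
                )
                calls = specificity.scan_heterodimers(logos, contacts)
                bundle.add_frame("specificity_calls", specificity.calls_to_frame(calls))
                candidates = [c for c in calls if c.specificity_candidate]
                bundle.add_json(
                    "specificity_candidates",
                    [
                        {"isoforms": [c.isoform_x, c.isoform_y],
                         "positions": [c.contact.position_a, c.contact.position_b],
                         "hetero": c.hetero}
                        for c in candidates
                    ],
                )
            except PcdhkitError as exc:
                bundle.fail("specificity scan", exc)
        elif logos and not contacts:
            bundle.add_frame("specificity_calls", specificity.calls_to_frame([]))

    with _timer(bundle, "face_diff"):
        if config.face_positions and config.group_a and config.group_b:
            try:
                ga = {k: logos[k] for k in config.group_a}
                gb = {k: logos[k] for k in config.group_b}
                diff = specificity.subfamily_face_diff(
                    ga, gb, config.face_positions, purity_threshold=config.purity_threshold
                )
                bundle.add_json("face_differences", {"positions": diff, "n": len(diff)})
            except (KeyError, PcdhkitError) as exc:
                bundle.fail("face diff", exc)

    bundle.finish()
    return bundle


# ---------------------------------------------------------------------------
# AUC report
# ---------------------------------------------------------------------------


def run_auc_report(config: RunConfig) -> ReportBundle:
    """Per-fragment association-model fits and oligomeric-state table."""
    bundle = ReportBundle(Path(config.out_dir) / "auc", config, "auc-report")
    rows = []
    with _timer(bundle, "fits"):
        for frag in config.auc_fragments:
            try:
                scans = [auc_mod.read_scan(p) for p in frag.scan_paths]
                species = auc_mod.SpeciesParams(
                    frag.monomer_mass, frag.vbar, frag.solvent_density,
                    frag.extinction, frag.path_length,
                )
                fits = {}
                for kind in ("single", "monomer_dimer", "isodesmic",
                             "monomer_dimer_tetramer"):
                    fits[kind] = auc_mod.global_fit(
                        scans, kind, species, seed=config.seed
                    )
                label, ratio = auc_mod.classify_oligomer(
                    fits["monomer_dimer"], fits["isodesmic"],
                    fit_tetramer=fits["monomer_dimer_tetramer"],
                    fit_single=fits["single"],
                )
                chosen = {
                    "monomer": fits["single"],
                    "dimer": fits["monomer_dimer"],
                    "non-specific": fits["monomer_dimer"],
                    "tetramer": fits["monomer_dimer_tetramer"],
                }[label]
                rows.append(auc_mod.fit_report_row(frag.name, label, chosen, ratio))
            except (PcdhkitError, OSError) as exc:
                bundle.fail(frag.name, exc)
                rows.append({"fragment": frag.name, "oligomeric_state": "error",
                             "kd_uM": None, "k24_uM": None, "ki_uM": None,
                             "rms_AU": None, "ki_over_kd": None})
    bundle.add_frame("oligomeric_states", pd.DataFrame(
        rows, columns=["fragment", "oligomeric_state", "kd_uM", "k24_uM",
                       "ki_uM", "rms_AU", "ki_over_kd"]))
    bundle.finish()
    return bundle
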