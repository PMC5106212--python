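"""Rule-based specificity calls for interacting interface residue pairs.

The analysis combines structural contacts (reference-numbered residue pairs
across a trans or cis interface) with per-isoform consensus residues from
ortholog logos.  For every ordered isoform pair and contact, the residue
combination seen in each homodimer and in both orientations of the
hypothetical heterodimer is classified as favorable, electrostatic clash,
steric clash, or neutral:

* opposite formal charges -> favorable (salt bridge);
* like charges -> electrostatic clash, with histidine counted positive;
* a hetero pair whose combined side-chain volume exceeds the larger homo
  pair's combined volume by more than a threshold -> steric clash;
* anything else -> neutral.

A contact is a specificity candidate for an isoform pair when both homodimer
combinations are favorable or neutral while the worst heterodimer orientation
clashes.  These are qualitative, rule-based flags - no energies are computed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .errors import CoverageError, MappingError, RulesError
from .conservation import IsoformLogo
from .interface import InterfaceReport

CHARGE = {
    "K": +1, "R": +1, "H": +1,  # histidine counted positive for clash detection
    "D": -1, "E": -1,
}

# Residue volumes (Å³), standard published mean residue volume table.
RESIDUE_VOLUME = {
    "A": 88.6, "R": 173.4, "N": 114.1, "D": 111.1, "C": 108.5,
    "Q": 143.8, "E": 138.4, "G": 60.1, "H": 153.2, "I": 166.7,
    "L": 166.7, "K": 168.6, "M": 162.9, "F": 189.9, "P": 112.7,
    "S": 89.0, "T": 116.1, "W": 227.8, "Y": 193.6, "V": 140.0,
}

FAVORABLE = "favorable"
ELECTROSTATIC_CLASH = "electrostatic_clash"
STERIC_CLASH = "steric_clash"
NEUTRAL = "neutral"
CLASHES = {ELECTROSTATIC_CLASH, STERIC_CLASH}


@dataclass(frozen=True)
class CompatibilityRuleSet:
    charge: dict[str, int] = field(default_factory=lambda: dict(CHARGE))
    volume: dict[str, float] = field(default_factory=lambda: dict(RESIDUE_VOLUME))
    steric_delta_volume: float = 40.0  # Å³ allowance over the homo reference pair

    def charge_of(self, aa: str) -> int:
        if aa not in self.volume:
            raise RulesError(f"noncanonical residue {aa!r}")
        return self.charge.get(aa, 0)

    def volume_of(self, aa: str) -> float:
        if aa not in self.volume:
            raise RulesError(f"noncanonical residue {aa!r}")
        return self.volume[aa]


DEFAULT_RULES = CompatibilityRuleSet()


@dataclass(frozen=True)
class ResiduePairContact:
    position_a: int
    position_b: int
    interface_zone: str  # e.g. "EC1:EC4", "EC2:EC3", "EC6-cis"
    min_ca_distance: float


@dataclass
class SpecificityCall:
    contact: ResiduePairContact
    isoform_x: str
    isoform_y: str
    residues_x: tuple[str, str]
    residues_y: tuple[str, str]
    homo_x: str
    homo_y: str
    hetero: str
    specificity_candidate: bool
    rationale: str


# ---------------------------------------------------------------------------
# Structural contacts -> reference numbering
# ---------------------------------------------------------------------------


def contacts_to_reference(
    report: InterfaceReport,
    numbering_map: dict[tuple[str, int], int],
    zone_of: dict[int, str] | None = None,
) -> list[ResiduePairContact]:
    """Re-express an interface report's contacts in reference numbering.

    ``numbering_map`` maps (chain_id, author number) -> reference position;
    ``zone_of`` optionally maps a reference position to its EC-domain label,
    from which the interface zone string (e.g. "EC2:EC3") is built.
    """
    contacts = []
    offenders = []
    for res_a, res_b, dist in report.contact_pairs:
        ka = (res_a.chain_id, res_a.author_seq_number)
        kb = (res_b.chain_id, res_b.author_seq_number)
        pa, pb = numbering_map.get(ka), numbering_map.get(kb)
        if pa is None:
            offenders.append(ka)
        if pb is None:
            offenders.append(kb)
        if pa is None or pb is None:
            continue
        if zone_of is not None:
            za, zb = zone_of.get(pa, "?"), zone_of.get(pb, "?")
            zone = f"{za}:{zb}"
        else:
            zone = "?"
        contacts.append(ResiduePairContact(pa, pb, zone, dist))
    if offenders:
        raise MappingError(f"unmapped contact residues: {sorted(set(offenders))}", offenders)
    # collapse to unique position pairs, keeping the minimum distance
    best: dict[tuple[int, int, str], ResiduePairContact] = {}
    for c in contacts:
        key = (c.position_a, c.position_b, c.interface_zone)
        if key not in best or c.min_ca_distance < best[key].min_ca_distance:
            best[key] = c
    return sorted(best.values(), key=lambda c: (c.position_a, c.position_b))


# ---------------------------------------------------------------------------
# Pair evaluation
# ---------------------------------------------------------------------------


def evaluate_pair(
    residue_a: str,
    residue_b: str,
    rules: CompatibilityRuleSet = DEFAULT_RULES,
    reference_volume: float | None = None,
) -> str:
    """Classify one interacting residue combination.

    ``reference_volume`` is the combined volume of the corresponding homodimer
    pair against which a steric clash is judged; without it only the charge
    logic applies.  Symmetric in its arguments.
    """
    a, b = residue_a.upper(), residue_b.upper()
    qa, qb = rules.charge_of(a), rules.charge_of(b)
    if qa and qb:
        return FAVORABLE if qa * qb < 0 else ELECTROSTATIC_CLASH
    if reference_volume is not None:
        if rules.volume_of(a) + rules.volume_of(b) > reference_volume + rules.steric_delta_volume:
            return STERIC_CLASH
    return NEUTRAL


_RANK = {NEUTRAL: 0, FAVORABLE: 0, ELECTROSTATIC_CLASH: 1, STERIC_CLASH: 1}


def _worst(classes: list[str]) -> str:
    # prefer reporting a clash; among clashes electrostatic listed first
    for cls in (ELECTROSTATIC_CLASH, STERIC_CLASH):
        if cls in classes:
            return cls
    return FAVORABLE if FAVORABLE in classes and all(
        c in (FAVORABLE, NEUTRAL) for c in classes
    ) else NEUTRAL


# ---------------------------------------------------------------------------
# Heterodimer scan
# ---------------------------------------------------------------------------


def scan_heterodimers(
    logos: dict[str, IsoformLogo],
    contacts: list[ResiduePairContact],
    rules: CompatibilityRuleSet = DEFAULT_RULES,
) -> list[SpecificityCall]:
    """Specificity calls for every unordered isoform pair and contact.

    For a contact (a, b) and isoforms x, y with consensus residues x_a, x_b,
    y_a, y_b: the homodimers place (x_a, x_b) and (y_a, y_b) across the
    interface; the hypothetical heterodimer places (x_a, y_b) and (y_a, x_b).
    The call records the worst heterodimer orientation; the candidate flag is
    set when both homo classes are favorable/neutral and the hetero class is
    a clash.  Self-interacting positions (a == b) across the two-fold axis
    are handled identically, with x_a facing y_a.
    """
    # coverage check up front
    missing = []
    for iso, logo in logos.items():
        covered = {p.reference_number for p in logo.positions if p.frequencies}
        for c in contacts:
            for pos in (c.position_a, c.position_b):
                if pos not in covered:
                    missing.append((iso, pos))
    if missing:
        raise CoverageError(f"logo coverage gaps: {sorted(set(missing))}", missing)

    isoforms = sorted(logos)
    calls: list[SpecificityCall] = []
    for i, iso_x in enumerate(isoforms):
        for iso_y in isoforms[i + 1:]:
            for contact in contacts:
                a, b = contact.position_a, contact.position_b
                xa, _ = logos[iso_x].consensus(a)
                xb, _ = logos[iso_x].consensus(b)
                ya, _ = logos[iso_y].consensus(a)
                yb, _ = logos[iso_y].consensus(b)
                vol_homo = max(
                    rules.volume_of(xa) + rules.volume_of(xb),
                    rules.volume_of(ya) + rules.volume_of(yb),
                )
                homo_x = evaluate_pair(xa, xb, rules)
                homo_y = evaluate_pair(ya, yb, rules)
                het1 = evaluate_pair(xa, yb, rules, reference_volume=vol_homo)
                het2 = evaluate_pair(ya, xb, rules, reference_volume=vol_homo)
                hetero = _worst([het1, het2])
                candidate = (
                    homo_x in (FAVORABLE, NEUTRAL)
                    and homo_y in (FAVORABLE, NEUTRAL)
                    and hetero in CLASHES
                )
                rationale = (
                    f"homo {iso_x}:{xa}{a}-{xb}{b} {homo_x}; "
                    f"homo {iso_y}:{ya}{a}-{yb}{b} {homo_y}; "
                    f"hetero {xa}{a}-{yb}{b}={het1}, {ya}{a}-{xb}{b}={het2}"
                )
                calls.append(
                    SpecificityCall(
                        contact, iso_x, iso_y, (xa, xb), (ya, yb),
                        homo_x, homo_y, hetero, candidate, rationale,
                    )
                )
    return calls


_CALL_COLUMNS = [
    "isoform_x", "isoform_y", "position_a", "position_b", "zone",
    "residues_x", "residues_y", "homo_x", "homo_y", "hetero",
    "specificity_candidate", "rationale",
]


def calls_to_frame(calls: list[SpecificityCall]) -> pd.DataFrame:
    if not calls:
        return pd.DataFrame(columns=_CALL_COLUMNS)
    rows = []
    for c in calls:
        rows.append(
            {
                "isoform_x": c.isoform_x,
                "isoform_y": c.isoform_y,
                "position_a": c.contact.position_a,
                "position_b": c.contact.position_b,
                "zone": c.contact.interface_zone,
                "residues_x": "".join(c.residues_x),
                "residues_y": "".join(c.residues_y),
                "homo_x": c.homo_x,
                "homo_y": c.homo_y,
                "hetero": c.hetero,
                "specificity_candidate": c.specificity_candidate,
                "rationale": c.rationale,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Subfamily face comparison (cis face of the membrane-proximal domain)
# ---------------------------------------------------------------------------


def subfamily_face_diff(
    logo_group_a: dict[str, IsoformLogo],
    logo_group_b: dict[str, IsoformLogo],
    face_positions: list[int],
    purity_threshold: float = 0.8,
) -> list[int]:
    """Positions on a configured interface face whose group consensus differs.

    Each group must be internally consistent at the position (every member
    logo's consensus identical and at/above the purity threshold) for the
    position to be comparable; a position where either group is internally
    mixed is not reported as differing.
    """

    def group_consensus(group: dict[str, IsoformLogo], pos: int) -> str | None:
        residues = set()
        for logo in group.values():
            aa, freq = logo.consensus(pos)
            if freq < purity_threshold:
                return None
            residues.add(aa)
        return residues.pop() if len(residues) == 1 else None

    differing = []
    for pos in face_positions:
        ca = group_consensus(logo_group_a, pos)
        cb = group_consensus(logo_group_b, pos)
        if ca is not None and cb is not None and ca != cb:
            differing.append(pos)
    return differing
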