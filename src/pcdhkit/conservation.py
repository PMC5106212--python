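"""Ortholog filtering, reference-numbered sequence logos, variability classes.

The ortholog filter emulates the classic BLAST-based "one isoform" rule for
building per-isoform alignments of clustered-protocadherin orthologs: a
candidate sequence from another species is accepted for the mouse isoform it
scores best against, but only when that best score clearly separates from the
runner-up.  Scores are global pairwise alignment scores under a standard
substitution matrix, which keeps the filter deterministic and database-free;
the margin on the second/best score ratio (default 0.95) is the declared
surrogate for "significant similarity to more than one isoform".

Logos are tabular: per reference position, residue frequencies over the
non-gap symbols and information content in bits, log2(20) - H(column).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import Align, SeqIO
from Bio.Align import substitution_matrices

from .errors import AlignmentError, CoverageError, ParameterError

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
GAP_CHARS = {"-", "."}
MAX_BITS = math.log2(20)


@dataclass(frozen=True)
class SequenceRecord:
    id: str
    species: str
    sequence: str

    def __post_init__(self):
        if not self.sequence:
            raise ParameterError(f"{self.id}: empty sequence")
        bad = set(self.sequence.upper()) - set(AMINO_ACIDS) - {"X"} - GAP_CHARS
        if bad:
            raise ParameterError(f"{self.id}: non amino-acid symbols {sorted(bad)}")


@dataclass(frozen=True)
class OrthologAssignment:
    candidate_id: str
    best_isoform: str
    best_score: float
    second_score: float
    accepted: bool


@dataclass
class LogoPosition:
    reference_number: int
    frequencies: dict[str, float]  # over the 20 canonical residues, sums to 1
    gap_fraction: float
    information_bits: float
    n_sequences: int


@dataclass
class IsoformLogo:
    isoform: str
    positions: list[LogoPosition] = field(default_factory=list)

    def position(self, reference_number: int) -> LogoPosition:
        for p in self.positions:
            if p.reference_number == reference_number:
                return p
        raise CoverageError(
            f"position {reference_number} absent from logo {self.isoform!r}",
            [reference_number],
        )

    def consensus(self, reference_number: int) -> tuple[str, float]:
        """Modal residue and its frequency; ties break lexicographically."""
        p = self.position(reference_number)
        if not p.frequencies:
            raise CoverageError(
                f"position {reference_number} of {self.isoform!r} is all-gap",
                [reference_number],
            )
        best = max(sorted(p.frequencies), key=lambda aa: p.frequencies[aa])
        return best, p.frequencies[best]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for p in self.positions:
            row = {"position": p.reference_number, "gap_fraction": p.gap_fraction,
                   "information_bits": p.information_bits, "n_sequences": p.n_sequences}
            for aa in AMINO_ACIDS:
                row[aa] = p.frequencies.get(aa, 0.0)
            rows.append(row)
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class VariabilityClass:
    position: int
    variability: str  # "constant" | "variable"
    consensus: dict[str, str]  # isoform -> consensus residue
    tie_flagged: bool = False


# ---------------------------------------------------------------------------
# Ortholog assignment
# ---------------------------------------------------------------------------


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.5
    return aligner


def _score(aligner: Align.PairwiseAligner, a: str, b: str) -> float:
    return float(aligner.score(a.upper().replace("X", "A"), b.upper().replace("X", "A")))


def assign_orthologs(
    candidates: list[SequenceRecord],
    mouse_isoforms: dict[str, str],
    margin: float = 0.95,
) -> list[OrthologAssignment]:
    """Assign each candidate ortholog to at most one mouse isoform.

    A candidate is scored by global pairwise alignment against every mouse
    isoform sequence and accepted for its best-scoring isoform only when
    second_score / best_score < margin (and the best score is positive).
    An empty candidate list yields an empty result.
    """
    if len(mouse_isoforms) < 2:
        raise ParameterError("need at least two mouse isoforms to disambiguate")
    aligner = _make_aligner()
    out: list[OrthologAssignment] = []
    for cand in candidates:
        scores = {
            iso: _score(aligner, cand.sequence, seq) for iso, seq in mouse_isoforms.items()
        }
        ranked = sorted(scores, key=lambda k: (-scores[k], k))
        best, second = ranked[0], ranked[1]
        best_score, second_score = scores[best], scores[second]
        accepted = best_score > 0 and (second_score / best_score) < margin
        out.append(
            OrthologAssignment(cand.id, best, best_score, second_score, accepted)
        )
    return out


# ---------------------------------------------------------------------------
# Logos
# ---------------------------------------------------------------------------


def column_information_bits(frequencies: dict[str, float]) -> float:
    """log2(20) minus the Shannon entropy of a residue-frequency column."""
    h = 0.0
    for f in frequencies.values():
        if f > 0:
            h -= f * math.log2(f)
    return max(MAX_BITS - h, 0.0)


def build_logo(
    msa: list[SequenceRecord],
    reference_id: str,
    isoform: str | None = None,
    reference_start: int = 1,
    gap_flag_fraction: float = 0.5,
) -> IsoformLogo:
    """Per-position frequency/information logo on the reference's numbering.

    All sequences must be aligned (equal length) and include the reference.
    Columns where the reference has a gap are dropped; remaining columns are
    numbered consecutively from ``reference_start`` along the reference.
    Frequencies are over observed non-gap canonical residues (X ignored).
    """
    if not msa:
        raise AlignmentError("empty alignment")
    lengths = {len(s.sequence) for s in msa}
    if len(lengths) != 1:
        raise AlignmentError(f"aligned sequences have unequal lengths: {sorted(lengths)}")
    ref = next((s for s in msa if s.id == reference_id), None)
    if ref is None:
        raise AlignmentError(f"reference {reference_id!r} not present in the alignment")
    logo = IsoformLogo(isoform or reference_id)
    refnum = reference_start - 1
    for col in range(len(ref.sequence)):
        if ref.sequence[col] in GAP_CHARS:
            continue
        refnum += 1
        counts: dict[str, int] = {}
        gaps = 0
        for s in msa:
            aa = s.sequence[col].upper()
            if aa in GAP_CHARS:
                gaps += 1
            elif aa in AMINO_ACIDS:
                counts[aa] = counts.get(aa, 0) + 1
        n_obs = sum(counts.values())
        freqs = {aa: c / n_obs for aa, c in counts.items()} if n_obs else {}
        logo.positions.append(
            LogoPosition(
                reference_number=refnum,
                frequencies=freqs,
                gap_fraction=gaps / len(msa),
                information_bits=column_information_bits(freqs) if freqs else 0.0,
                n_sequences=len(msa),
            )
        )
    return logo


# ---------------------------------------------------------------------------
# Variability classes across isoforms
# ---------------------------------------------------------------------------


def classify_positions(
    logos: dict[str, IsoformLogo],
    positions: list[int],
    purity_threshold: float = 0.8,
) -> list[VariabilityClass]:
    """Classify interface positions as constant or variable across isoforms.

    A position is constant when every isoform's consensus residue is identical
    AND each consensus frequency reaches the purity threshold; otherwise
    variable.  Consensus ties break lexicographically and are flagged.
    """
    out = []
    for pos in positions:
        consensus: dict[str, str] = {}
        pure = True
        tie = False
        for iso, logo in logos.items():
            aa, freq = logo.consensus(pos)
            p = logo.position(pos)
            top = max(p.frequencies.values())
            if sum(1 for f in p.frequencies.values() if f == top) > 1:
                tie = True
            consensus[iso] = aa
            if freq < purity_threshold:
                pure = False
        constant = pure and len(set(consensus.values())) == 1
        out.append(
            VariabilityClass(pos, "constant" if constant else "variable", consensus, tie)
        )
    return out


# ---------------------------------------------------------------------------
# Pairwise identity
# ---------------------------------------------------------------------------


def pairwise_identity(seq_a: str, seq_b: str) -> float:
    """Percent identity from a global alignment, gap columns excluded."""
    aligner = _make_aligner()
    sa, sb = seq_a.upper(), seq_b.upper()
    aln = aligner.align(sa.replace("X", "A"), sb.replace("X", "A"))[0]
    matches = 0
    aligned_cols = 0
    for (a0, a1), (b0, b1) in zip(*aln.aligned):
        for i, j in zip(range(a0, a1), range(b0, b1)):
            aligned_cols += 1
            if sa[i] == sb[j]:
                matches += 1
    if aligned_cols == 0:
        return 0.0
    return 100.0 * matches / aligned_cols


def pairwise_identity_matrix(
    seqs: dict[str, str],
) -> tuple[pd.DataFrame, float]:
    """Symmetric percent-identity matrix and the average over unordered pairs.

    Callers select the region of interest (e.g. an EC6 domain via annotation)
    before passing sequences in.
    """
    names = list(seqs)
    if len(names) < 2:
        raise ParameterError("identity average undefined for fewer than 2 sequences")
    mat = pd.DataFrame(100.0, index=names, columns=names, dtype=float)
    pair_values = []
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            ident = pairwise_identity(seqs[a], seqs[b])
            mat.loc[a, b] = mat.loc[b, a] = ident
            pair_values.append(ident)
    return mat, float(np.mean(pair_values))


# ---------------------------------------------------------------------------
# FASTA I/O helpers
# ---------------------------------------------------------------------------


def read_fasta(path, species_from_header: bool = True) -> list[SequenceRecord]:
    """Read sequences; species parsed from a 'species=' tag or second token."""
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        species = ""
        desc = rec.description or ""
        for token in desc.split():
            if token.startswith("species="):
                species = token.split("=", 1)[1]
        if not species and species_from_header:
            tokens = desc.split()
            if len(tokens) > 1:
                species = tokens[1]
        out.append(SequenceRecord(rec.id, species, str(rec.seq)))
    return out


def write_fasta(records: list[SequenceRecord], path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            tag = f" species={rec.species}" if rec.species else ""
            fh.write(f">{rec.id}{tag}\n")
            for i in range(0, len(rec.sequence), 60):
                fh.write(rec.sequence[i : i + 60] + "\n")
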