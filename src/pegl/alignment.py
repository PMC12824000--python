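"""Aligned DNA matrices and FASTA I/O.

An alignment is a taxa-by-columns character matrix over the nucleotide
alphabet {A, C, G, T}, the gap character ``-`` and the IUPAC ambiguity
codes.  Gaps, ``?`` and ``N`` are all treated as fully ambiguous
observations (every state compatible), never as a fifth state.  Columns
are numbered 1-based throughout the package, matching the "site"
convention of the phylogenetics literature.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

BASES = "ACGT"
GAP = "-"

#: IUPAC code -> compatibility vector over (A, C, G, T).
IUPAC_PARTIALS: dict[str, tuple[float, float, float, float]] = {
    "A": (1, 0, 0, 0),
    "C": (0, 1, 0, 0),
    "G": (0, 0, 1, 0),
    "T": (0, 0, 0, 1),
    "R": (1, 0, 1, 0),
    "Y": (0, 1, 0, 1),
    "S": (0, 1, 1, 0),
    "W": (1, 0, 0, 1),
    "K": (0, 0, 1, 1),
    "M": (1, 1, 0, 0),
    "B": (0, 1, 1, 1),
    "D": (1, 0, 1, 1),
    "H": (1, 1, 0, 1),
    "V": (1, 1, 1, 0),
    "N": (1, 1, 1, 1),
    "?": (1, 1, 1, 1),
    GAP: (1, 1, 1, 1),
}

ALPHABET = frozenset(IUPAC_PARTIALS)


class AlignmentError(ValueError):
    """Raised for malformed alignments (ragged rows, bad labels/characters)."""


@dataclass(frozen=True)
class DnaAlignment:
    """Immutable taxa × sites nucleotide alignment.

    Parameters
    ----------
    taxa:
        Ordered, unique, non-empty sequence labels.
    matrix:
        ``(n_taxa, n_sites)`` array of single uppercase characters from
        the allowed alphabet.
    frame:
        Optional codon phase (1, 2 or 3) of column 1, used for
        codon-position bookkeeping downstream.
    """

    taxa: tuple[str, ...]
    matrix: np.ndarray = field(repr=False)
    frame: int | None = None

    def __post_init__(self) -> None:
        taxa = tuple(self.taxa)
        object.__setattr__(self, "taxa", taxa)
        if len(taxa) == 0:
            raise AlignmentError("alignment needs at least one taxon")
        if any(not t for t in taxa):
            raise AlignmentError("empty taxon label")
        if len(set(taxa)) != len(taxa):
            dupes = sorted({t for t in taxa if taxa.count(t) > 1})
            raise AlignmentError(f"duplicate taxon labels: {dupes}")
        mat = np.asarray(self.matrix, dtype="<U1")
        if mat.ndim != 2 or mat.shape[0] != len(taxa):
            raise AlignmentError(
                f"matrix shape {mat.shape} does not match {len(taxa)} taxa"
            )
        if mat.shape[1] < 1:
            raise AlignmentError("alignment needs at least one column")
        bad = ~np.isin(mat, list(ALPHABET))
        if bad.any():
            r, c = np.argwhere(bad)[0]
            raise AlignmentError(
                f"illegal character {mat[r, c]!r} in taxon {taxa[r]!r}, "
                f"column {c + 1}"
            )
        mat.setflags(write=False)
        object.__setattr__(self, "matrix", mat)
        if self.frame is not None and self.frame not in (1, 2, 3):
            raise AlignmentError(f"frame must be 1, 2 or 3, got {self.frame}")

    # -- construction helpers ------------------------------------------------

    @classmethod
    def from_sequences(
        cls,
        sequences: Mapping[str, str] | Iterable[tuple[str, str]],
        frame: int | None = None,
    ) -> "DnaAlignment":
        """Build an alignment from (label, sequence) pairs.

        Sequences are uppercased and RNA ``U`` is mapped to ``T``.
        Rows of unequal length raise :class:`AlignmentError` naming the
        offending taxon.
        """
        items = list(sequences.items()) if isinstance(sequences, Mapping) else list(sequences)
        if not items:
            raise AlignmentError("no sequences provided")
        cleaned = [(label, seq.upper().replace("U", "T")) for label, seq in items]
        n = len(cleaned[0][1])
        for label, seq in cleaned:
            if len(seq) != n:
                raise AlignmentError(
                    f"sequence {label!r} has length {len(seq)}, expected {n}"
                )
        taxa = tuple(label for label, _ in cleaned)
        mat = np.array([list(seq) for _, seq in cleaned], dtype="<U1")
        return cls(taxa=taxa, matrix=mat, frame=frame)

    # -- basic accessors -----------------------------------------------------

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_sites(self) -> int:
        """Number of alignment columns (the *n* of PEGL/n)."""
        return int(self.matrix.shape[1])

    def sequence(self, taxon: str) -> str:
        return "".join(self.matrix[self.taxa.index(taxon)])

    def column(self, site: int) -> str:
        """Column at 1-based position ``site``."""
        if not 1 <= site <= self.n_sites:
            raise IndexError(f"site {site} outside 1..{self.n_sites}")
        return "".join(self.matrix[:, site - 1])

    def partials(self) -> dict[str, np.ndarray]:
        """Per-taxon ``(n_sites, 4)`` tip compatibility vectors."""
        lut = np.zeros((128, 4))
        for ch, vec in IUPAC_PARTIALS.items():
            lut[ord(ch)] = vec
        codes = self.matrix.view(np.uint32).reshape(self.n_taxa, self.n_sites)
        return {t: lut[codes[i]] for i, t in enumerate(self.taxa)}

    def subset(self, taxa: Sequence[str], frame: int | None = None) -> "DnaAlignment":
        """Row subset keeping every column (coordinates preserved)."""
        missing = [t for t in taxa if t not in self.taxa]
        if missing:
            raise AlignmentError(f"unknown taxa: {missing}")
        idx = [self.taxa.index(t) for t in taxa]
        return DnaAlignment(
            taxa=tuple(taxa),
            matrix=self.matrix[idx].copy(),
            frame=self.frame if frame is None else frame,
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, DnaAlignment):
            return NotImplemented
        return (
            self.taxa == other.taxa
            and self.frame == other.frame
            and np.array_equal(self.matrix, other.matrix)
        )

    def __hash__(self) -> int:  # pragma: no cover - identity hashing only
        return hash((self.taxa, self.frame, self.matrix.tobytes()))


def read_fasta(path: str | Path, frame: int | None = None) -> DnaAlignment:
    """Read an aligned FASTA file into a :class:`DnaAlignment`.

    Characters are uppercased and ``U`` mapped to ``T``.  Unequal row
    lengths, duplicate labels and illegal characters raise
    :class:`AlignmentError`.
    """
    path = Path(path)
    records = [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]
    if not records:
        raise AlignmentError(f"no sequences found in {path}")
    return DnaAlignment.from_sequences(records, frame=frame)


def write_fasta(alignment: DnaAlignment, path: str | Path) -> Path:
    """Write an alignment to FASTA; ``read_fasta`` round-trips it exactly."""
    path = Path(path)
    records = [
        SeqRecord(Seq(alignment.sequence(t)), id=t, description="")
        for t in alignment.taxa
    ]
    with open(path, "w") as handle:
        SeqIO.write(records, handle, "fasta-2line")
    return path
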