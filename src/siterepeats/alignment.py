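"""Multiple sequence alignments of DNA with bitmask state encoding.

Nucleotide states use the one-hot encoding A=1, C=2, G=4, T=8.  IUPAC
ambiguity codes are the bitwise OR of their constituent bases (e.g. R = A|G
= 5), and gaps, '?' and 'N' all encode to 15 (complete uncertainty over the
four bases).  Encoded values therefore always lie in [1, 15], and the tip
conditional likelihood of a state follows directly from its bit pattern.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO


class AlignmentError(ValueError):
    """Raised for malformed alignment input or unknown characters."""


#: one-hot bases and IUPAC unions; U is treated as T, and '-', '?', 'N' as
#: complete uncertainty.
IUPAC_CODES: dict[str, int] = {
    "A": 1, "C": 2, "G": 4, "T": 8, "U": 8,
    "M": 1 | 2, "R": 1 | 4, "W": 1 | 8,
    "S": 2 | 4, "Y": 2 | 8, "K": 4 | 8,
    "V": 1 | 2 | 4, "H": 1 | 2 | 8, "D": 1 | 4 | 8, "B": 2 | 4 | 8,
    "N": 15, "-": 15, "?": 15,
}

# canonical character for each encoded value (15 prints as a gap)
CODE_TO_CHAR: dict[int, str] = {
    1: "A", 2: "C", 4: "G", 8: "T",
    3: "M", 5: "R", 9: "W", 6: "S", 10: "Y", 12: "K",
    7: "V", 11: "H", 13: "D", 14: "B", 15: "-",
}


def encode_state(c: str) -> int:
    """Encode one IUPAC DNA character (case-insensitive) as a 4-bit mask."""
    try:
        return IUPAC_CODES[c.upper()]
    except KeyError:
        raise AlignmentError(f"unknown nucleotide character {c!r}") from None


@dataclass
class Alignment:
    """An encoded alignment of ``m`` taxa by ``n`` site patterns.

    Parameters
    ----------
    taxa
        Ordered taxon labels (one per row of ``data``).
    data
        Integer matrix of encoded states, shape ``(m, n)``, values in [1, 15].
    weights
        Per-site positive integer multiplicities.  All ones for a raw
        alignment; after :func:`compress_patterns` they record how many
        original columns each pattern stands for, so their sum is always the
        pre-compression site count.
    """

    taxa: list[str]
    data: np.ndarray
    weights: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.int64)
        if self.data.ndim != 2:
            raise AlignmentError("alignment data must be a 2-D matrix")
        m, n = self.data.shape
        if m < 2:
            raise AlignmentError(f"alignment needs at least two sequences, got {m}")
        if n < 1:
            raise AlignmentError("alignment needs at least one site")
        if len(self.taxa) != m:
            raise AlignmentError("taxon list does not match number of rows")
        if len(set(self.taxa)) != m:
            raise AlignmentError("duplicate taxon labels")
        if self.data.min() < 1 or self.data.max() > 15:
            raise AlignmentError("encoded states must lie in [1, 15]")
        if self.weights is None:
            self.weights = np.ones(n, dtype=np.int64)
        else:
            self.weights = np.asarray(self.weights, dtype=np.int64)
            if self.weights.shape != (n,) or (self.weights < 1).any():
                raise AlignmentError("weights must be positive, one per site")

    @property
    def n_taxa(self) -> int:
        return self.data.shape[0]

    @property
    def n_sites(self) -> int:
        """Number of stored site patterns (columns of ``data``)."""
        return self.data.shape[1]

    @property
    def total_sites(self) -> int:
        """Pre-compression site count (sum of weights)."""
        return int(self.weights.sum())

    def row(self, taxon: str) -> np.ndarray:
        """Encoded states for one taxon."""
        try:
            return self.data[self.taxa.index(taxon)]
        except ValueError:
            raise AlignmentError(f"unknown taxon {taxon!r}") from None

    def sequences(self) -> dict[str, str]:
        """Decode back to IUPAC character strings (15 prints as '-')."""
        return {
            t: "".join(CODE_TO_CHAR[int(c)] for c in self.data[i])
            for i, t in enumerate(self.taxa)
        }

    @classmethod
    def from_sequences(cls, named: list[tuple[str, str]]) -> "Alignment":
        """Encode (label, sequence-string) pairs into an Alignment."""
        if not named:
            raise AlignmentError("no sequences")
        lengths = {len(s) for _, s in named}
        if len(lengths) != 1:
            raise AlignmentError(
                "sequences have unequal lengths: "
                + ", ".join(f"{t}:{len(s)}" for t, s in named)
            )
        rows = []
        for label, seq in named:
            row = []
            for pos, c in enumerate(seq):
                try:
                    row.append(encode_state(c))
                except AlignmentError:
                    raise AlignmentError(
                        f"unknown character {c!r} in sequence {label!r} "
                        f"at position {pos + 1}"
                    ) from None
            rows.append(row)
        return cls(taxa=[t for t, _ in named], data=np.array(rows))


def _read_relaxed_phylip(path: str) -> list[tuple[str, str]]:
    with open(path) as fh:
        lines = [ln.rstrip() for ln in fh if ln.strip()]
    if not lines:
        raise AlignmentError(f"empty PHYLIP file {path!r}")
    header = lines[0].split()
    if len(header) != 2:
        raise AlignmentError(f"bad PHYLIP header {lines[0]!r}")
    try:
        m, n = int(header[0]), int(header[1])
    except ValueError:
        raise AlignmentError(f"bad PHYLIP header {lines[0]!r}") from None
    if len(lines) - 1 != m:
        raise AlignmentError(
            f"PHYLIP header declares {m} sequences but file has {len(lines) - 1}"
        )
    named = []
    for ln in lines[1:]:
        parts = ln.split()
        if len(parts) < 2:
            raise AlignmentError(f"bad PHYLIP record {ln!r}")
        named.append((parts[0], "".join(parts[1:])))
    for label, seq in named:
        if len(seq) != n:
            raise AlignmentError(
                f"sequence {label!r} has length {len(seq)}, header declares {n}"
            )
    return named


def read_alignment(path: str, format: str | None = None) -> Alignment:
    """Read a FASTA or relaxed sequential PHYLIP alignment.

    ``format`` is ``"fasta"`` or ``"phylip"``; when omitted it is guessed
    from the file extension (``.phy``/``.phylip`` vs anything else).
    """
    if format is None:
        ext = os.path.splitext(path)[1].lower()
        format = "phylip" if ext in (".phy", ".phylip") else "fasta"
    if format == "fasta":
        named = [(rec.id, str(rec.seq)) for rec in SeqIO.parse(path, "fasta")]
        if not named:
            raise AlignmentError(f"no FASTA records in {path!r}")
    elif format == "phylip":
        named = _read_relaxed_phylip(path)
    else:
        raise AlignmentError(f"unknown alignment format {format!r}")
    return Alignment.from_sequences(named)


def write_fasta(alignment: Alignment, path: str) -> None:
    with open(path, "w") as fh:
        for taxon, seq in alignment.sequences().items():
            fh.write(f">{taxon}\n{seq}\n")


def compress_patterns(alignment: Alignment) -> Alignment:
    """Collapse identical full-height columns into weighted patterns (aliasing).

    Distinct columns are kept in order of first occurrence; the weight of
    each output pattern is the summed weight of the input columns it
    replaces, so the total site count is preserved.  Idempotent.
    """
    cols = alignment.data.T  # (n, m)
    _, first_idx, inverse = np.unique(
        cols, axis=0, return_index=True, return_inverse=True
    )
    # np.unique sorts patterns; remap to first-occurrence order
    order = np.argsort(first_idx, kind="stable")
    rank = np.empty_like(order)
    rank[order] = np.arange(len(order))
    pattern_of_col = rank[inverse]
    n_patterns = len(first_idx)
    weights = np.zeros(n_patterns, dtype=np.int64)
    np.add.at(weights, pattern_of_col, alignment.weights)
    data = alignment.data[:, np.sort(first_idx)]
    return Alignment(taxa=list(alignment.taxa), data=data, weights=weights)
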