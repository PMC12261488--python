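"""Conversions between CDR3β amino-acid sequences, nucleotides, and one-hot matrices.

Amino acids are back-translated with one fixed codon per residue (the most
frequently used human codon, shipped as a package resource and overridable),
and nucleotides are one-hot encoded over channels (A, T, G, C) into a
zero-padded fixed-length matrix suitable for the diffusion model. Decoding a
real-valued (denoised) matrix back to a sequence uses an arg-max rule with a
padding threshold and in-frame truncation.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
from Bio.Seq import Seq

__all__ = [
    "STANDARD_AA",
    "NT_CHANNELS",
    "CodonTable",
    "NucleotideOneHot",
    "load_codon_table",
    "back_translate",
    "translate",
    "one_hot_encode",
    "one_hot_decode",
    "read_fasta",
    "write_fasta",
    "DEFAULT_L_MAX",
]

STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"
NT_CHANNELS = "ATGC"  # channel order of the one-hot encoding
_NT_INDEX = {nt: i for i, nt in enumerate(NT_CHANNELS)}

#: 24 amino acids (the upper CDR3β length bound) at 3 nt per codon.
DEFAULT_L_MAX = 72


class InvalidResidueError(ValueError):
    pass


class FrameError(ValueError):
    pass


@dataclass(frozen=True)
class CodonTable:
    """One codon per standard amino acid.

    Every codon must translate back to its amino acid under the standard
    genetic code, and no stop codon may appear (enforced at construction).
    """

    codons: dict[str, str]

    def __post_init__(self):
        missing = set(STANDARD_AA) - set(self.codons)
        if missing:
            raise ValueError(f"codon table missing amino acids: {sorted(missing)}")
        for aa, codon in self.codons.items():
            if len(codon) != 3 or any(c not in _NT_INDEX for c in codon):
                raise ValueError(f"bad codon {codon!r} for {aa!r}")
            back = str(Seq(codon).translate())
            if back == "*":
                raise ValueError(f"stop codon {codon!r} assigned to {aa!r}")
            if back != aa:
                raise ValueError(f"codon {codon!r} translates to {back!r}, not {aa!r}")

    def __getitem__(self, aa: str) -> str:
        return self.codons[aa]


def load_codon_table(path: str | None = None) -> CodonTable:
    """Load the shipped most-frequent-human-codon table, or a user TSV.

    The TSV has a header row ``amino_acid\\tcodon`` and 20 data rows.
    """
    if path is None:
        text = resources.files("tcrdiff.data").joinpath("codon_table.tsv").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    codons: dict[str, str] = {}
    lines = [ln for ln in text.splitlines() if ln.strip()]
    for line in lines[1:]:  # skip header
        aa, codon = line.split("\t")
        codons[aa.strip()] = codon.strip().upper()
    return CodonTable(codons)


_DEFAULT_TABLE: CodonTable | None = None


def _default_table() -> CodonTable:
    global _DEFAULT_TABLE
    if _DEFAULT_TABLE is None:
        _DEFAULT_TABLE = load_codon_table()
    return _DEFAULT_TABLE


def back_translate(peptide: str, table: CodonTable | None = None) -> str:
    """Map an amino-acid sequence to nucleotides, one codon per residue."""
    if not peptide:
        raise InvalidResidueError("empty peptide")
    table = table or _default_table()
    parts = []
    for i, aa in enumerate(peptide):
        if aa not in table.codons:
            raise InvalidResidueError(f"invalid residue {aa!r} at position {i}")
        parts.append(table[aa])
    return "".join(parts)


def translate(nt: str) -> tuple[str, bool]:
    """Translate frame-1 nucleotides to amino acids under the standard code.

    Returns ``(peptide, ok)``; a stop codon truncates the peptide and sets
    ``ok`` to False.
    """
    if not nt:
        raise FrameError("empty nucleotide sequence")
    if len(nt) % 3:
        raise FrameError(f"length {len(nt)} not divisible by 3")
    bad = set(nt) - set(NT_CHANNELS)
    if bad:
        raise InvalidResidueError(f"invalid nucleotide(s): {sorted(bad)}")
    peptide = str(Seq(nt).translate())
    if "*" in peptide:
        return peptide[: peptide.index("*")], False
    return peptide, True


@dataclass
class NucleotideOneHot:
    """L_max×4 one-hot matrix over (A, T, G, C) with zero-row padding."""

    matrix: np.ndarray
    length: int

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise ValueError("matrix must be L_max x 4")
        if not 0 < self.length <= self.matrix.shape[0]:
            raise ValueError("length out of range")


def one_hot_encode(nt: str, l_max: int = DEFAULT_L_MAX) -> NucleotideOneHot:
    """Encode nucleotides into an L_max×4 basis-vector matrix, zero-padded."""
    if len(nt) > l_max:
        raise ValueError(f"sequence length {len(nt)} exceeds L_max={l_max}")
    bad = set(nt) - set(NT_CHANNELS)
    if bad:
        raise InvalidResidueError(f"invalid nucleotide(s): {sorted(bad)}")
    m = np.zeros((l_max, 4))
    for i, c in enumerate(nt):
        m[i, _NT_INDEX[c]] = 1.0
    return NucleotideOneHot(matrix=m, length=len(nt))


def one_hot_decode(matrix: np.ndarray, pad_threshold: float = 0.5) -> str:
    """Decode a real-valued L×4 matrix back to a nucleotide string.

    Positions are scanned left to right; the first row whose maximum channel
    value falls below ``pad_threshold`` terminates the sequence. Ties take the
    earliest channel in (A, T, G, C) order. The result is truncated down to a
    whole number of codons.
    """
    matrix = np.asarray(matrix, dtype=np.float64)
    if not np.all(np.isfinite(matrix)):
        raise ValueError("matrix must be finite")
    chars = []
    for row in matrix:
        if row.max() < pad_threshold:
            break
        chars.append(NT_CHANNELS[int(np.argmax(row))])
    n = len(chars) - len(chars) % 3
    return "".join(chars[:n])


def read_fasta(path: str) -> list[tuple[str, str]]:
    """Read (id, sequence) pairs from a FASTA file."""
    from Bio import SeqIO

    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(path, "fasta")]


def write_fasta(records: list[tuple[str, str]], path: str) -> None:
    from Bio.Seq import Seq as _Seq
    from Bio.SeqRecord import SeqRecord
    from Bio import SeqIO

    SeqIO.write(
        [SeqRecord(_Seq(seq), id=name, description="") for name, seq in records],
        path,
        "fasta",
    )
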