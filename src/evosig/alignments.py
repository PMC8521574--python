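"""Protein and codon alignment containers plus codon threading.

A :class:`ProteinAlignment` is a taxa-by-columns character matrix over the 20
amino acids plus ``-`` (gap) and ``X`` (unknown). A :class:`CodonAlignment`
stores integer indices into the 61 sense codons (``-1`` = gap) and always
translates column-for-column to its protein counterpart.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .codons import (
    CODON_AA_ARRAY,
    CODON_INDEX,
    CODONS,
    GAP,
    STOP_CODONS,
    UNKNOWN,
)


@dataclass
class ProteinAlignment:
    """Aligned amino-acid matrix with an optional per-column analysis mask."""

    taxa: list[str]
    matrix: np.ndarray  # (n_taxa, n_cols) of '<U1'
    mask: np.ndarray | None = None  # True = column excluded from analysis

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype="<U1")
        if self.matrix.ndim != 2 or self.matrix.shape[0] != len(self.taxa):
            raise ValueError("matrix shape does not match taxa list")
        if len(set(self.taxa)) != len(self.taxa):
            raise ValueError("duplicate taxon names")
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != (self.matrix.shape[1],):
                raise ValueError("mask length must equal column count")

    @property
    def n_taxa(self) -> int:
        return self.matrix.shape[0]

    @property
    def width(self) -> int:
        return self.matrix.shape[1]

    def row(self, taxon: str) -> np.ndarray:
        return self.matrix[self.taxa.index(taxon)]

    def sequence(self, taxon: str, ungapped: bool = False) -> str:
        r = self.row(taxon)
        if ungapped:
            r = r[r != GAP]
        return "".join(r)

    def copy(self) -> "ProteinAlignment":
        return ProteinAlignment(
            list(self.taxa),
            self.matrix.copy(),
            None if self.mask is None else self.mask.copy(),
        )

    @classmethod
    def from_fasta(cls, path) -> "ProteinAlignment":
        taxa, rows = [], []
        for rec in SeqIO.parse(str(path), "fasta"):
            taxa.append(rec.id)
            rows.append(list(str(rec.seq).upper()))
        if not taxa:
            raise ValueError(f"no sequences in {path}")
        widths = {len(r) for r in rows}
        if len(widths) != 1:
            raise ValueError(f"unequal row lengths in {path}")
        return cls(taxa, np.array(rows, dtype="<U1"))

    def to_fasta(self, path) -> None:
        recs = [
            SeqRecord(Seq("".join(row)), id=t, description="")
            for t, row in zip(self.taxa, self.matrix)
        ]
        SeqIO.write(recs, str(path), "fasta")


@dataclass
class CodonAlignment:
    """Codon-index matrix over the 61 sense codons; -1 marks a gap column
    cell. Width equals the protein alignment width (one codon per residue)."""

    taxa: list[str]
    codons: np.ndarray  # (n_taxa, n_cols) int16, -1 = gap

    def __post_init__(self):
        self.codons = np.asarray(self.codons, dtype=np.int16)
        if self.codons.ndim != 2 or self.codons.shape[0] != len(self.taxa):
            raise ValueError("codon matrix shape does not match taxa list")
        if self.codons.max(initial=-1) >= len(CODONS) or self.codons.min(initial=0) < -1:
            raise ValueError("codon indices out of range")

    @property
    def n_taxa(self) -> int:
        return self.codons.shape[0]

    @property
    def width(self) -> int:
        return self.codons.shape[1]

    def copy(self) -> "CodonAlignment":
        return CodonAlignment(list(self.taxa), self.codons.copy())

    def to_protein(self) -> ProteinAlignment:
        mat = np.full(self.codons.shape, GAP, dtype="<U1")
        present = self.codons >= 0
        mat[present] = CODON_AA_ARRAY[self.codons[present]]
        return ProteinAlignment(list(self.taxa), mat)

    def cds(self, taxon: str) -> str:
        """Ungapped coding sequence for one taxon."""
        row = self.codons[self.taxa.index(taxon)]
        return "".join(CODONS[i] for i in row if i >= 0)

    def nucleotide_row(self, taxon: str) -> str:
        """Gapped nucleotide row (3 characters per codon column)."""
        row = self.codons[self.taxa.index(taxon)]
        return "".join(CODONS[i] if i >= 0 else "---" for i in row)

    def write_cds_fasta(self, path) -> None:
        recs = [
            SeqRecord(Seq(self.cds(t)), id=t, description="") for t in self.taxa
        ]
        SeqIO.write(recs, str(path), "fasta")


def read_cds_fasta(path) -> dict[str, str]:
    """Read unaligned coding sequences keyed by record id."""
    seqs = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise ValueError(f"duplicate CDS id {rec.id!r} in {path}")
        seqs[rec.id] = str(rec.seq).upper()
    return seqs


def thread_codons(
    protein_alignment: ProteinAlignment, cds_by_taxon: dict[str, str]
) -> CodonAlignment:
    """Thread unaligned CDS through a protein alignment.

    Each taxon's CDS must translate exactly to its ungapped protein row (a
    terminal stop codon is allowed and stripped). Protein gaps become codon
    gaps; internal stop codons are an error.
    """
    n_cols = protein_alignment.width
    out = np.full((protein_alignment.n_taxa, n_cols), -1, dtype=np.int16)
    for ti, taxon in enumerate(protein_alignment.taxa):
        try:
            cds = cds_by_taxon[taxon].upper().replace("U", "T")
        except KeyError:
            raise ValueError(f"no CDS provided for taxon {taxon!r}") from None
        if len(cds) % 3 != 0:
            raise ValueError(f"CDS length for {taxon!r} is not a multiple of 3")
        codons = [cds[k : k + 3] for k in range(0, len(cds), 3)]
        if codons and codons[-1] in STOP_CODONS:
            codons = codons[:-1]
        prot_row = protein_alignment.matrix[ti]
        residue_cols = np.nonzero(prot_row != GAP)[0]
        if len(codons) != len(residue_cols):
            raise ValueError(
                f"CDS/protein length mismatch for {taxon!r}: "
                f"{len(codons)} codons vs {len(residue_cols)} residues"
            )
        for col, codon in zip(residue_cols, codons):
            if codon in STOP_CODONS:
                raise ValueError(
                    f"internal stop codon in {taxon!r} at protein column {col + 1}"
                )
            aa = prot_row[col]
            if aa == UNKNOWN:
                out[ti, col] = -1  # unknown residue: treat as missing
                continue
            try:
                idx = CODON_INDEX[codon]
            except KeyError:
                raise ValueError(
                    f"unrecognised codon {codon!r} in {taxon!r} at column {col + 1}"
                ) from None
            if CODON_AA_ARRAY[idx] != aa:
                raise ValueError(
                    f"translation mismatch for {taxon!r} at protein column "
                    f"{col + 1}: codon {codon} translates to "
                    f"{CODON_AA_ARRAY[idx]}, alignment has {aa}"
                )
            out[ti, col] = idx
    return CodonAlignment(list(protein_alignment.taxa), out)
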