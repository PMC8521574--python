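"""Focal-species unique amino-acid substitutions with functional-impact
scoring.

A unique substitution is an alignment column where every background species
carries one identical residue and the focal species differs. Columns near
alignment gaps are unreliable, so any column containing a gap in any taxon —
and a symmetric flank of ``flank`` columns around it (default 10) — is masked
out before calling; unknown residues ('X') are treated like gaps because they
cannot certify background identity.

Because running SIFT against an external protein database is out of reach for
a self-contained pipeline, functional impact is scored with a SIFT-style
normalized position-specific probability computed from the orthogroup
alignment itself (method label ``sift_like``); externally supplied SIFT calls
can be passed through instead (label ``external``). A substitution is
impactful when its normalized probability falls below SIFT's canonical 0.05
cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .alignments import ProteinAlignment
from .codons import AMINO_ACIDS, GAP, UNKNOWN

SIFT_CUTOFF = 0.05
DEFAULT_FLANK = 10


@dataclass
class UniqueSubstitutionCall:
    orthogroup: str
    column: int  # 1-based, reported coordinate
    focal_residue: str
    background_residue: str
    score: float
    impact: bool
    method: str = "sift_like"

    def __post_init__(self):
        if self.focal_residue == self.background_residue:
            raise ValueError("focal residue must differ from background")


def compute_gap_mask(alignment: ProteinAlignment, flank: int = DEFAULT_FLANK) -> np.ndarray:
    """True for columns excluded from analysis: any-taxon gap or 'X', plus
    ``flank`` columns on each side of such a column."""
    if flank < 0:
        raise ValueError("flank must be >= 0")
    bad = np.any((alignment.matrix == GAP) | (alignment.matrix == UNKNOWN), axis=0)
    if flank == 0 or not bad.any():
        return bad
    structure = np.ones(2 * flank + 1, dtype=bool)
    return ndimage.binary_dilation(bad, structure=structure)


def impact_score(
    alignment: ProteinAlignment,
    column: int,
    focal_residue: str,
    focal: str,
    pseudocount: float = 1.0,
) -> float:
    """Normalized probability of the focal residue at one (0-based) column.

    With c(a) the count of residue a among the N non-focal rows,
    ``p(a) = (c(a) + pseudocount/20) / (N + pseudocount)`` and the score is
    ``p(focal_residue) / max_a p(a)`` — 1 when the focal residue is (one of)
    the most common background residues, small when the column is conserved
    and the focal residue unseen.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    if alignment.mask is not None and alignment.mask[column]:
        raise ValueError(f"column {column + 1} is masked")
    fi = alignment.taxa.index(focal)
    residues = np.delete(alignment.matrix[:, column], fi)
    n = residues.size
    counts = {a: 0 for a in AMINO_ACIDS}
    for r in residues:
        if r in counts:
            counts[r] += 1
    probs = {
        a: (c + pseudocount / len(AMINO_ACIDS)) / (n + pseudocount)
        for a, c in counts.items()
    }
    p_focal = probs.get(focal_residue)
    if p_focal is None:
        raise ValueError(f"not an amino acid: {focal_residue!r}")
    return p_focal / max(probs.values())


def find_unique_substitutions(
    alignment: ProteinAlignment,
    focal: str,
    orthogroup_id: str = "",
    flank: int = DEFAULT_FLANK,
    pseudocount: float = 1.0,
    cutoff: float = SIFT_CUTOFF,
) -> list[UniqueSubstitutionCall]:
    """Call focal-unique substitutions at unmasked columns.

    A column is called when all non-focal residues are identical to one
    another and the focal residue differs. Each call carries the sift-like
    impact score and flag.
    """
    if focal not in alignment.taxa:
        raise ValueError(f"focal taxon {focal!r} not in alignment")
    if alignment.n_taxa < 3:
        raise ValueError("need the focal taxon plus >= 2 background taxa")
    if alignment.mask is None:
        alignment.mask = compute_gap_mask(alignment, flank=flank)
    fi = alignment.taxa.index(focal)
    mat = alignment.matrix
    others = np.delete(mat, fi, axis=0)
    bg_identical = np.all(others == others[0], axis=0)
    differs = mat[fi] != others[0]
    callable_cols = np.nonzero(~alignment.mask & bg_identical & differs)[0]
    calls = []
    for col in callable_cols:
        score = impact_score(
            alignment, int(col), str(mat[fi, col]), focal, pseudocount
        )
        calls.append(
            UniqueSubstitutionCall(
                orthogroup=orthogroup_id,
                column=int(col) + 1,
                focal_residue=str(mat[fi, col]),
                background_residue=str(others[0, col]),
                score=float(score),
                impact=bool(score < cutoff),
            )
        )
    return calls


def unique_substitution_signature(calls: list[UniqueSubstitutionCall]) -> bool:
    """A gene carries the signature iff at least one call is impactful."""
    return any(c.impact for c in calls)


def calls_to_frame(calls: list[UniqueSubstitutionCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "orthogroup": c.orthogroup,
                "column": c.column,
                "focal_aa": c.focal_residue,
                "background_aa": c.background_residue,
                "score": c.score,
                "impact": c.impact,
                "method": c.method,
            }
            for c in calls
        ],
        columns=[
            "orthogroup",
            "column",
            "focal_aa",
            "background_aa",
            "score",
            "impact",
            "method",
        ],
    )
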