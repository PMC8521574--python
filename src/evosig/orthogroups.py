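"""Orthogroup tables, filters and the concatenated supermatrix.

The analyses run on orthogroups (sets of genes across a species panel that
descend from one ancestral gene). This module reads an OrthoFinder-style
membership table, keeps orthogroups represented in every panel species,
selects the "fuzzy one-to-one" subset (most species single-copy, none above a
small copy cap), picks one representative gene per species (the longest), and
builds the trimmed, concatenated supermatrix used for species-tree work.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import skbio

from .alignments import ProteinAlignment
from .codons import GAP, UNKNOWN
from .trees import PhyloTree


@dataclass(frozen=True)
class SpeciesPanel:
    """The species under comparison, with the focal species and outgroup."""

    species: tuple[str, ...]
    focal: str
    outgroup: str

    def __post_init__(self):
        if len(set(self.species)) != len(self.species):
            raise ValueError("species names must be unique")
        if self.focal == self.outgroup:
            raise ValueError("focal and outgroup must differ")
        for name in (self.focal, self.outgroup):
            if name not in self.species:
                raise ValueError(f"{name!r} is not in the species panel")

    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def background(self) -> tuple[str, ...]:
        return tuple(s for s in self.species if s != self.focal)


@dataclass
class Orthogroup:
    id: str
    members: dict[str, list[str]]  # species -> gene IDs
    sequences: dict[str, str] = field(default_factory=dict)  # gene -> protein
    cds: dict[str, str] = field(default_factory=dict)  # gene -> CDS

    def gene_count(self, species: str) -> int:
        return len(self.members.get(species, []))

    def all_genes(self) -> list[str]:
        return [g for genes in self.members.values() for g in genes]


def parse_orthogroup_table(path, panel: SpeciesPanel) -> list[Orthogroup]:
    """Read an OrthoFinder-style TSV: column 1 = orthogroup ID, one column
    per species, cells empty or comma-separated gene IDs."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if df.shape[1] < 2:
        raise ValueError("orthogroup table needs an ID column plus species columns")
    species_cols = list(df.columns[1:])
    for col in species_cols:
        if col not in panel.species:
            raise ValueError(f"species column {col!r} is not in the panel")
    for sp in panel.species:
        if sp not in species_cols:
            raise ValueError(f"panel species {sp!r} missing from the table header")
    seen: set[str] = set()
    out = []
    for _, row in df.iterrows():
        members = {}
        for sp in species_cols:
            cell = row[sp].strip()
            genes = [g.strip() for g in cell.split(",") if g.strip()] if cell else []
            for g in genes:
                if g in seen:
                    raise ValueError(f"duplicate gene ID {g!r} across orthogroups")
                seen.add(g)
            members[sp] = genes
        out.append(Orthogroup(id=row.iloc[0], members=members))
    return out


def filter_all_species(
    orthogroups: list[Orthogroup], panel: SpeciesPanel
) -> list[Orthogroup]:
    """Keep orthogroups with at least one gene in every panel species."""
    return [
        og
        for og in orthogroups
        if all(og.gene_count(sp) >= 1 for sp in panel.species)
    ]


def select_fuzzy_one_to_one(
    orthogroups: list[Orthogroup],
    panel: SpeciesPanel,
    fuzziness: float = 0.75,
    max_copies: int = 3,
) -> list[Orthogroup]:
    """Fuzzy one-to-one selection: at least ``fuzziness`` of the species are
    exactly single-copy and no species exceeds ``max_copies`` genes.

    Assumes the input already passed :func:`filter_all_species`.
    """
    if not (0 <= fuzziness <= 1):
        raise ValueError("fuzziness must lie in [0, 1]")
    if max_copies < 1:
        raise ValueError("max_copies must be >= 1")
    kept = []
    for og in orthogroups:
        counts = [og.gene_count(sp) for sp in panel.species]
        if any(c < 1 or c > max_copies for c in counts):
            continue
        single = sum(1 for c in counts if c == 1)
        if single / len(counts) >= fuzziness:
            kept.append(og)
    return kept


def pick_representatives(
    orthogroup: Orthogroup, panel: SpeciesPanel
) -> dict[str, str]:
    """One gene per species: the longest protein, ties to the
    lexicographically smallest gene ID."""
    reps = {}
    for sp in panel.species:
        genes = orthogroup.members.get(sp, [])
        if not genes:
            raise ValueError(
                f"orthogroup {orthogroup.id}: species {sp!r} has no gene"
            )
        missing = [g for g in genes if g not in orthogroup.sequences]
        if missing:
            raise ValueError(
                f"orthogroup {orthogroup.id}: no sequence for {missing[0]!r}"
            )
        reps[sp] = min(
            genes, key=lambda g: (-len(orthogroup.sequences[g]), g)
        )
    return reps


@dataclass
class Supermatrix:
    alignment: ProteinAlignment
    partitions: list[tuple[int, int]]  # 0-based half-open column ranges


def build_supermatrix(
    alignments: list[ProteinAlignment], panel: SpeciesPanel
) -> Supermatrix:
    """Drop all-gap columns per alignment, then concatenate in input order.

    Every input must carry exactly one row per panel species (rows named by
    species).
    """
    order = list(panel.species)
    blocks, partitions = [], []
    start = 0
    for k, aln in enumerate(alignments):
        if sorted(aln.taxa) != sorted(order):
            raise ValueError(f"alignment {k} rows do not match the species panel")
        mat = np.vstack([aln.row(sp) for sp in order])
        keep = ~np.all(mat == GAP, axis=0)
        trimmed = mat[:, keep]
        blocks.append(trimmed)
        partitions.append((start, start + trimmed.shape[1]))
        start += trimmed.shape[1]
    matrix = (
        np.hstack(blocks) if blocks else np.empty((len(order), 0), dtype="<U1")
    )
    return Supermatrix(ProteinAlignment(order, matrix), partitions)


# ---------------------------------------------------------------------------
# neighbor-joining fallback tree


def poisson_distance_matrix(alignment: ProteinAlignment) -> np.ndarray:
    """Poisson-corrected pairwise protein distances d = -ln(1 - p), with p
    the mismatch fraction over mutually ungapped, non-X sites."""
    mat = alignment.matrix
    valid = (mat != GAP) & (mat != UNKNOWN)
    n = alignment.n_taxa
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = valid[i] & valid[j]
            m = both.sum()
            if m == 0:
                raise ValueError(
                    f"no mutually ungapped sites between "
                    f"{alignment.taxa[i]!r} and {alignment.taxa[j]!r}"
                )
            p = np.sum(mat[i, both] != mat[j, both]) / m
            if p >= 1.0:
                raise ValueError(
                    f"saturated pair {alignment.taxa[i]!r}/{alignment.taxa[j]!r} "
                    "(p = 1): Poisson distance undefined; consider capping p"
                )
            d[i, j] = d[j, i] = -np.log(1.0 - p)
    return d


def nj_from_distances(dm: np.ndarray, ids: list[str]) -> PhyloTree:
    """Neighbor joining on a distance matrix; negative branch lengths are
    clamped to zero. Returns an (arbitrarily rooted) tree."""
    sk = skbio.DistanceMatrix(dm, ids=ids)
    tree = skbio.tree.nj(sk)
    buf = io.StringIO()
    tree.write(buf, format="newick")
    phylo = PhyloTree.from_newick(buf.getvalue())
    for e in phylo._tree.preorder_edge_iter():
        if e.tail_node is not None and (e.length or 0.0) < 0:
            e.length = 0.0
    return phylo


def nj_tree(alignment: ProteinAlignment, panel: SpeciesPanel) -> PhyloTree:
    """NJ gene tree from Poisson-corrected protein distances, rooted on the
    panel outgroup. Used only when no tree is supplied."""
    if alignment.n_taxa < 3:
        raise ValueError("need at least 3 sequences for NJ")
    if panel.outgroup not in alignment.taxa:
        raise ValueError(f"outgroup {panel.outgroup!r} absent from alignment")
    d = poisson_distance_matrix(alignment)
    tree = nj_from_distances(d, list(alignment.taxa))
    tree.outgroup = panel.outgroup
    return tree.rerooted_on_outgroup()
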