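"""Root-to-tip divergence: flag focal genes evolving faster than the rest of
the panel.

For each orthogroup a rooted gene tree (supplied, or the NJ fallback built
from the orthogroup alignment) yields one root-to-tip distance per species —
the summed branch lengths from the root to that leaf. A focal gene is flagged
as divergent when its distance is comparatively higher than the other
species': by default strictly greater than the maximum non-focal distance
(optionally scaled by a ratio), with a z-score rule as an alternative.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .alignments import ProteinAlignment
from .orthogroups import SpeciesPanel, nj_tree
from .trees import PhyloTree


@dataclass
class DivergenceRecord:
    orthogroup: str
    distances: dict[str, float]
    focal_distance: float
    statistic: float
    flagged: bool
    mode: str


def root_to_tip_distances(tree: PhyloTree) -> dict[str, float]:
    """Distance from the root to every leaf (sum of branch lengths).

    Re-roots on the tree's named outgroup first when one is set.
    """
    if tree.outgroup is not None:
        tree = tree.rerooted_on_outgroup()
    return tree.root_to_tip()


def flag_divergent(
    distances: dict[str, float],
    focal: str,
    mode: str = "max",
    ratio: float = 1.0,
    z: float = 2.0,
) -> tuple[float, bool]:
    """Decide whether the focal species' root-to-tip distance is elevated.

    mode="max": flag iff focal > ratio * max(non-focal distances); the
    statistic is focal / max(non-focal) (inf if that max is 0 and focal > 0).
    mode="zscore": flag iff (focal - mean) / sd > z over non-focal distances;
    with sd = 0 the statistic is an infinity sentinel and the flag reduces to
    focal > mean.
    """
    if focal not in distances:
        raise ValueError(f"focal species {focal!r} missing from distances")
    others = [d for sp, d in distances.items() if sp != focal]
    if len(others) < 3:
        raise ValueError("need at least 3 non-focal species")
    fd = distances[focal]
    if mode == "max":
        mx = max(others)
        statistic = fd / mx if mx > 0 else (math.inf if fd > 0 else 1.0)
        return statistic, fd > ratio * mx
    if mode == "zscore":
        n = len(others)
        mean = sum(others) / n
        var = sum((x - mean) ** 2 for x in others) / (n - 1)
        sd = math.sqrt(var)
        if sd == 0:
            return (math.inf if fd > mean else -math.inf), fd > mean
        statistic = (fd - mean) / sd
        return statistic, statistic > z
    raise ValueError(f"unknown mode {mode!r}")


def gene_tree(alignment: ProteinAlignment, panel: SpeciesPanel) -> PhyloTree:
    """Per-orthogroup tree: NJ on Poisson-corrected protein distances, rooted
    on the panel outgroup (used when no tree is supplied)."""
    return nj_tree(alignment, panel)


def divergence_record(
    orthogroup_id: str,
    tree: PhyloTree,
    focal: str,
    mode: str = "max",
    ratio: float = 1.0,
    z: float = 2.0,
) -> DivergenceRecord:
    distances = root_to_tip_distances(tree)
    statistic, flagged = flag_divergent(distances, focal, mode=mode, ratio=ratio, z=z)
    return DivergenceRecord(
        orthogroup=orthogroup_id,
        distances=distances,
        focal_distance=distances[focal],
        statistic=statistic,
        flagged=flagged,
        mode=mode,
    )
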