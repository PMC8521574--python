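"""Synthetic orthogroup generator.

Emulates the data the comparative analysis consumes: codon alignments evolved
along a species tree under the branch-site (Model A) class structure, with
optional planted focal-unique amino-acid substitutions, a rate-accelerated
focal terminal branch, and injected gaps — plus ground-truth labels so every
downstream detector can be scored against what was planted.

Sequence evolution is simulated by Gillespie event sampling along each branch
(never by drawing from matrix exponentials), so exact per-branch, per-site
substitution event counts exist and serve as an independent oracle in tests.
Branch lengths are expected substitutions per codon site for a neutral
(omega = 1) site; omega classes run proportionally faster or slower by their
relative GY94 rate — the same convention the likelihood engine uses.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np

from .alignments import CodonAlignment, ProteinAlignment
from .codons import (
    AMINO_ACIDS,
    CODON_AA,
    CODON_AA_ARRAY,
    GAP,
    N_CODONS,
    codon_rate_matrix,
    f3x4_frequencies,
    relative_rate,
    uniform_frequencies,
    validate_frequencies,
)
from .trees import PhyloTree

SITE_CLASS_LABELS = ("0", "1", "2a", "2b")


@dataclass
class SimConfig:
    """Conditions for one synthetic orthogroup.

    Defaults mirror the study setting this generator stands in for: a
    17-species panel with one focal species and one outgroup, ~300-codon
    genes, mostly purifying selection (class 0) with a neutral fraction.
    """

    n_species: int = 17
    n_codons: int = 300
    tree_source: str | None = None  # newick; None = simulate a random tree
    mean_depth: float = 0.5
    focal_species: str = "sp01"
    outgroup_species: str = "sp17"
    p0: float = 0.75
    p1: float = 0.15
    omega0: float = 0.2
    omega2: float = 1.0
    kappa: float = 2.0
    codon_frequencies: object = "uniform"  # "uniform" | "f3x4" | vector
    n_planted_unique_sites: int = 0
    focal_rate_multiplier: float = 1.0
    gap_rate: float = 0.0
    gap_flank_clearance: int = 10
    seed: int = 0

    def __post_init__(self):
        if self.p0 < 0 or self.p1 < 0 or self.p0 + self.p1 > 1 + 1e-12:
            raise ValueError("need p0, p1 >= 0 and p0 + p1 <= 1")
        if not (0 < self.omega0 <= 1):
            raise ValueError("omega0 must lie in (0, 1]")
        if self.omega2 <= 0 or self.kappa <= 0:
            raise ValueError("omega2 and kappa must be > 0")
        if not (0 <= self.gap_rate < 1):
            raise ValueError("gap_rate must lie in [0, 1)")
        if self.focal_rate_multiplier < 1:
            raise ValueError("focal_rate_multiplier must be >= 1")
        if self.focal_species == self.outgroup_species:
            raise ValueError("focal and outgroup species must differ")

    def class_proportions(self) -> np.ndarray:
        """(p0, p1, p2a, p2b) with the Model A split of the selected mass."""
        p2 = max(0.0, 1.0 - self.p0 - self.p1)
        if p2 > 0 and self.p0 + self.p1 == 0:
            raise ValueError("p0 + p1 = 0 leaves the 2a/2b split undefined")
        if p2 == 0:
            return np.array([self.p0, self.p1, 0.0, 0.0])
        denom = self.p0 + self.p1
        return np.array(
            [self.p0, self.p1, p2 * self.p0 / denom, p2 * self.p1 / denom]
        )

    def resolve_frequencies(self, rng: np.random.Generator) -> np.ndarray:
        if isinstance(self.codon_frequencies, str):
            if self.codon_frequencies == "uniform":
                return uniform_frequencies()
            if self.codon_frequencies == "f3x4":
                # one Dirichlet draw of nucleotide frequencies per codon position
                pos = rng.dirichlet(np.full(4, 10.0), size=3)
                return f3x4_frequencies(pos)
            raise ValueError(
                f"unknown codon_frequencies {self.codon_frequencies!r}"
            )
        return validate_frequencies(np.asarray(self.codon_frequencies, float))


@dataclass
class SyntheticTruth:
    """Ground truth for one simulated orthogroup."""

    site_classes: list[str]  # one of SITE_CLASS_LABELS per codon column
    planted_columns: list[int]  # 0-based protein columns
    rate_accelerated: bool
    params: dict
    seed: int
    branch_events: dict = field(default_factory=dict)
    # branch label -> {"events": per-site counts, "nonsyn": per-site counts}

    def to_json(self) -> str:
        d = {
            "site_classes": self.site_classes,
            "planted_columns": [int(c) for c in self.planted_columns],
            "rate_accelerated": bool(self.rate_accelerated),
            "params": self.params,
            "seed": int(self.seed),
            "branch_events": {
                k: {kk: [int(x) for x in vv] for kk, vv in v.items()}
                for k, v in self.branch_events.items()
            },
        }
        return json.dumps(d, indent=1, sort_keys=True)


# ---------------------------------------------------------------------------
# tree simulation


def simulate_tree(
    n_species: int,
    seed: int,
    mean_depth: float = 0.5,
    names: list[str] | None = None,
    outgroup: str | None = None,
    focal: str | None = None,
) -> PhyloTree:
    """Random rooted binary tree with the outgroup attached at the root.

    A species tree should be roughly clock-like, so the ingroup is built as
    an ultrametric coalescent-style topology (random pairwise joins with
    exponential waiting times, rescaled to ``mean_depth``) and every branch
    then gets mild lognormal rate jitter — root-to-tip depths vary around
    ``mean_depth`` by ~15% rather than being exactly equal. Deterministic for
    a fixed seed.

    When ``focal`` is named, its lineage joins the ingroup only among the
    last few coalescences, giving it a long terminal branch — emulating a
    focal species with no close relative in the panel.
    """
    if n_species < 3:
        raise ValueError("too few taxa: need n_species >= 3")
    if names is None:
        names = [f"sp{i + 1:02d}" for i in range(n_species)]
    if len(names) != n_species or len(set(names)) != n_species:
        raise ValueError("need n_species unique leaf names")
    if outgroup is None:
        outgroup = names[-1]
    if outgroup not in names:
        raise ValueError(f"outgroup {outgroup!r} not among leaf names")

    rng = np.random.default_rng(seed)
    taxa = dendropy.TaxonNamespace()
    ingroup = [n for n in names if n != outgroup]
    clusters = []  # (node, height)
    focal_idx = None
    for k, name in enumerate(ingroup):
        node = dendropy.Node()
        node.taxon = taxa.new_taxon(name)
        clusters.append((node, 0.0))
        if focal is not None and name == focal:
            focal_idx = k
    height = 0.0
    while len(clusters) > 1:
        height += float(rng.exponential(1.0 / len(clusters)))
        if focal_idx is not None and len(clusters) > 3:
            pool = [k for k in range(len(clusters)) if k != focal_idx]
        else:
            pool = list(range(len(clusters)))
        i, j = sorted(rng.choice(pool, size=2, replace=False))
        parent = dendropy.Node()
        (ni, hi), (nj, hj) = clusters[i], clusters[j]
        parent.add_child(ni)
        parent.add_child(nj)
        ni.edge.length = height - hi
        nj.edge.length = height - hj
        merged_has_focal = focal_idx in (i, j)
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)]
        clusters.append((parent, height))
        if focal_idx is not None:
            if merged_has_focal:
                focal_idx = len(clusters) - 1
            else:
                focal_idx -= sum(1 for k in (i, j) if k < focal_idx)
    ingroup_root, ingroup_height = clusters[0]
    # rescale so every ingroup leaf sits mean_depth below the root
    factor = mean_depth / ingroup_height if ingroup_height > 0 else 1.0
    root = dendropy.Node()
    og_node = dendropy.Node()
    og_node.taxon = taxa.new_taxon(outgroup)
    root.add_child(ingroup_root)
    root.add_child(og_node)
    ingroup_root.edge.length = 0.1 * mean_depth / factor  # root stem
    og_node.edge.length = (ingroup_height + 0.1 * mean_depth / factor)

    tree = dendropy.Tree(taxon_namespace=taxa)
    tree.seed_node = root
    for edge in tree.preorder_edge_iter():
        if edge.tail_node is None:
            continue
        jitter = float(np.exp(rng.normal(0.0, 0.15)))
        edge.length = max(float(edge.length) * factor * jitter, 0.005)
    return PhyloTree(tree, outgroup=outgroup)


# ---------------------------------------------------------------------------
# codon evolution


def _branch_labels(tree: PhyloTree) -> dict[int, str]:
    """Stable labels for every branch (child-node keyed): leaf name for
    terminal branches, 'innerN' in postorder for internal ones."""
    labels = {}
    k = 0
    for node in tree._tree.postorder_node_iter():
        if node.parent_node is None:
            continue
        if node.is_leaf():
            labels[id(node)] = node.taxon.label
        else:
            labels[id(node)] = f"inner{k}"
            k += 1
    return labels


def _gillespie_branch(states, t, rates, jump_cum, rng):
    """Evolve each site's codon state for time ``t``.

    Returns ``(new_states, n_events, n_nonsyn)`` per site. ``rates`` is the
    per-state total exit rate and ``jump_cum`` the per-state cumulative jump
    distribution of the (scaled) generator in force on this branch.
    """
    aa = CODON_AA_ARRAY
    out = states.copy()
    events = np.zeros(states.shape[0], dtype=np.int64)
    nonsyn = np.zeros(states.shape[0], dtype=np.int64)
    for s in range(out.shape[0]):
        state = int(out[s])
        remaining = t
        while True:
            total = rates[state]
            if total <= 0:
                break
            dt = rng.exponential(1.0 / total)
            if dt > remaining:
                break
            remaining -= dt
            new = int(np.searchsorted(jump_cum[state], rng.random(), side="right"))
            events[s] += 1
            if aa[new] != aa[state]:
                nonsyn[s] += 1
            state = new
        out[s] = state
    return out, events, nonsyn


def simulate_orthogroup(
    config: SimConfig, tree: PhyloTree | None = None
) -> tuple[CodonAlignment, ProteinAlignment, SyntheticTruth]:
    """Evolve one orthogroup along ``tree`` under the Model A class structure.

    Site classes: 0 (omega0 everywhere), 1 (neutral everywhere), 2a/2b
    (background omega0 / 1, foreground omega2 on the focal terminal branch).
    The focal terminal branch additionally gets ``focal_rate_multiplier``
    times its length (overall rate acceleration, all classes). Planted unique
    substitutions and gaps are applied after evolution, with planted columns
    protected from gaps.
    """
    rng = np.random.default_rng(config.seed)
    if tree is None:
        tree = simulate_tree(
            config.n_species,
            seed=int(rng.integers(2**31 - 1)),
            mean_depth=config.mean_depth,
            outgroup=config.outgroup_species,
            focal=config.focal_species,
        ) if config.tree_source is None else PhyloTree.from_newick(
            config.tree_source, outgroup=config.outgroup_species
        )
    leaves = set(tree.leaf_names)
    if config.focal_species not in leaves or config.outgroup_species not in leaves:
        raise ValueError("tree must contain the focal and outgroup species")

    pi = config.resolve_frequencies(rng)
    props = config.class_proportions()
    n = config.n_codons
    site_class = rng.choice(4, size=n, p=props)

    # per-omega scaled generators, with jump-distribution tables for Gillespie
    omegas = {"w0": config.omega0, "w1": 1.0, "w2": config.omega2}
    rates, jumps, rel = {}, {}, {}
    for key, w in omegas.items():
        Q = codon_rate_matrix(config.kappa, w, pi)
        r = -np.diag(Q).copy()
        off = Q.copy()
        np.fill_diagonal(off, 0.0)
        with np.errstate(invalid="ignore", divide="ignore"):
            jump = np.cumsum(off / np.where(r[:, None] > 0, r[:, None], 1.0), axis=1)
        rates[key], jumps[key] = r, jump
        # branch lengths are neutral-site units; omega classes run faster or
        # slower by their relative total rate
        rel[key] = relative_rate(config.kappa, w, pi)

    # background/foreground omega key per class
    bg_key = np.array(["w0", "w1", "w0", "w1"])[site_class]
    fg_key = np.array(["w0", "w1", "w2", "w2"])[site_class]

    labels = _branch_labels(tree)
    root_states = rng.choice(N_CODONS, size=n, p=pi)
    states_at = {id(tree._tree.seed_node): root_states}
    leaf_states = {}
    branch_events: dict[str, dict[str, np.ndarray]] = {}

    for node in tree._tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        parent_states = states_at[id(node.parent_node)]
        states = parent_states.copy()
        is_fg = node.is_leaf() and node.taxon.label == config.focal_species
        t = (node.edge.length or 0.0) * (
            config.focal_rate_multiplier if is_fg else 1.0
        )
        ev = np.zeros(n, dtype=np.int64)
        ns = np.zeros(n, dtype=np.int64)
        keys = fg_key if is_fg else bg_key
        for key in ("w0", "w1", "w2"):
            sel = np.nonzero(keys == key)[0]
            if sel.size == 0:
                continue
            new_states, sub_ev, sub_ns = _gillespie_branch(
                states[sel], float(t) * rel[key], rates[key], jumps[key], rng
            )
            states[sel] = new_states
            ev[sel] = sub_ev
            ns[sel] = sub_ns
        states_at[id(node)] = states
        branch_events[labels[id(node)]] = {"events": ev, "nonsyn": ns}
        if node.is_leaf():
            leaf_states[node.taxon.label] = states

    taxa = sorted(leaf_states)
    codons = CodonAlignment(
        taxa, np.vstack([leaf_states[t] for t in taxa]).astype(np.int16)
    )

    truth = SyntheticTruth(
        site_classes=[SITE_CLASS_LABELS[c] for c in site_class],
        planted_columns=[],
        rate_accelerated=config.focal_rate_multiplier > 1.0,
        params={
            "kappa": config.kappa,
            "omega0": config.omega0,
            "omega2": config.omega2,
            "p0": config.p0,
            "p1": config.p1,
            "focal_rate_multiplier": config.focal_rate_multiplier,
            "pi": [float(x) for x in pi],
        },
        seed=config.seed,
        branch_events=branch_events,
    )

    if config.n_planted_unique_sites > 0:
        codons, planted = plant_unique_substitutions(
            codons,
            config.focal_species,
            config.n_planted_unique_sites,
            seed=int(rng.integers(2**31 - 1)),
        )
        truth.planted_columns = sorted(int(c) for c in planted)

    if config.gap_rate > 0:
        protect = set()
        for c in truth.planted_columns:
            lo = max(0, c - config.gap_flank_clearance)
            hi = min(n - 1, c + config.gap_flank_clearance)
            protect.update(range(lo, hi + 1))
        codons = inject_gaps(
            codons,
            config.gap_rate,
            seed=int(rng.integers(2**31 - 1)),
            protect_columns=protect,
        )

    return codons, codons.to_protein(), truth


# ---------------------------------------------------------------------------
# planted signals and gaps


def _protein_view(alignment) -> ProteinAlignment:
    if isinstance(alignment, CodonAlignment):
        return alignment.to_protein()
    return alignment


def eligible_unique_columns(alignment, focal: str) -> np.ndarray:
    """Columns gap-free in all taxa where every non-focal residue is
    identical (candidates for planting a focal-unique substitution)."""
    prot = _protein_view(alignment)
    if focal not in prot.taxa:
        raise ValueError(f"focal taxon {focal!r} not in alignment")
    fi = prot.taxa.index(focal)
    mat = prot.matrix
    others = np.delete(mat, fi, axis=0)
    clean = ~np.any((mat == GAP) | (mat == "X"), axis=0)
    invariant_bg = np.all(others == others[0], axis=0)
    return np.nonzero(clean & invariant_bg)[0]


def plant_unique_substitutions(alignment, focal: str, n_sites: int, seed: int):
    """Force ``n_sites`` focal-unique substitutions into eligible columns.

    Works on a protein or codon alignment (codon planting picks a sense codon
    whose translation differs from the background residue, keeping the
    protein/codon views consistent). Returns ``(alignment', planted_columns)``.
    """
    if n_sites < 0:
        raise ValueError("n_sites must be >= 0")
    if n_sites == 0:
        return alignment.copy(), np.array([], dtype=int)
    rng = np.random.default_rng(seed)
    eligible = eligible_unique_columns(alignment, focal)
    if eligible.size < n_sites:
        raise ValueError(
            f"insufficient eligible columns: need {n_sites}, found {eligible.size}"
        )
    chosen = np.sort(rng.choice(eligible, size=n_sites, replace=False))
    out = alignment.copy()
    prot = _protein_view(alignment)
    fi = prot.taxa.index(focal)
    for col in chosen:
        bg_rows = np.delete(prot.matrix[:, col], fi)
        bg = bg_rows[0]
        if isinstance(out, CodonAlignment):
            candidates = [i for i, aa in enumerate(CODON_AA) if aa != bg]
            out.codons[fi, col] = candidates[rng.integers(len(candidates))]
        else:
            candidates = [a for a in AMINO_ACIDS if a != bg]
            out.matrix[fi, col] = candidates[rng.integers(len(candidates))]
    return out, chosen


def inject_gaps(alignment, gap_rate: float, seed: int, protect_columns=()):
    """Independently gap each (taxon, column) cell with probability
    ``gap_rate``, leaving protected columns untouched."""
    if not (0 <= gap_rate < 1):
        raise ValueError("gap_rate must lie in [0, 1)")
    out = alignment.copy()
    if gap_rate == 0:
        return out
    rng = np.random.default_rng(seed)
    if isinstance(out, CodonAlignment):
        shape = out.codons.shape
    else:
        shape = out.matrix.shape
    cells = rng.random(shape) < gap_rate
    protect = np.zeros(shape[1], dtype=bool)
    idx = np.asarray(sorted(protect_columns), dtype=int)
    if idx.size:
        protect[idx] = True
    cells[:, protect] = False
    if isinstance(out, CodonAlignment):
        out.codons[cells] = -1
    else:
        out.matrix[cells] = GAP
    return out


# ---------------------------------------------------------------------------
# fixture sets


def write_fixture_set(
    configs: list[SimConfig],
    out_dir,
    species_tree: PhyloTree | None = None,
    tree_seed: int = 0,
) -> dict:
    """Materialise a directory of synthetic orthogroups.

    Writes, per orthogroup: aligned protein FASTA, unaligned CDS FASTA, the
    true gene tree (species tree with the focal terminal branch scaled by the
    orthogroup's rate multiplier), and a truth JSON; plus one orthogroup TSV,
    one species-tree newick and a manifest listing every file.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if not configs:
        raise ValueError("no configurations supplied")
    base = configs[0]
    if species_tree is None:
        if base.tree_source is not None:
            species_tree = PhyloTree.from_newick(
                base.tree_source, outgroup=base.outgroup_species
            )
        else:
            species_tree = simulate_tree(
                base.n_species,
                seed=tree_seed,
                mean_depth=base.mean_depth,
                outgroup=base.outgroup_species,
                focal=base.focal_species,
            )
    species = sorted(species_tree.leaf_names)
    tree_path = out_dir / "species_tree.nwk"
    tree_path.write_text(species_tree.newick())

    manifest = {"species_tree": tree_path.name, "orthogroups": {}}
    table_rows = []
    for k, cfg in enumerate(configs):
        og = f"OG{k + 1:07d}"
        codons, prot, truth = simulate_orthogroup(cfg, species_tree)
        gene_ids = {sp: f"{og}_{sp}" for sp in codons.taxa}
        prot_named = ProteinAlignment(
            [gene_ids[t] for t in prot.taxa], prot.matrix.copy()
        )
        prot_path = out_dir / f"{og}.prot.fasta"
        prot_named.to_fasta(prot_path)
        cds_path = out_dir / f"{og}.cds.fasta"
        renamed = CodonAlignment([gene_ids[t] for t in codons.taxa], codons.codons)
        renamed.write_cds_fasta(cds_path)
        gene_tree = species_tree.copy()
        if cfg.focal_rate_multiplier != 1.0:
            t = gene_tree._tree
            for lf in t.leaf_node_iter():
                if lf.taxon.label == cfg.focal_species:
                    lf.edge.length = (lf.edge.length or 0.0) * cfg.focal_rate_multiplier
        gtree_path = out_dir / f"{og}.nwk"
        gtree_path.write_text(gene_tree.newick())
        truth_path = out_dir / f"{og}.truth.json"
        truth_path.write_text(truth.to_json())
        manifest["orthogroups"][og] = {
            "protein": prot_path.name,
            "cds": cds_path.name,
            "gene_tree": gtree_path.name,
            "truth": truth_path.name,
        }
        table_rows.append(
            [og] + [gene_ids.get(sp, "") for sp in species]
        )

    table_path = out_dir / "orthogroups.tsv"
    with open(table_path, "w") as fh:
        fh.write("Orthogroup\t" + "\t".join(species) + "\n")
        for row in table_rows:
            fh.write("\t".join(row) + "\n")
    manifest["orthogroup_table"] = table_path.name
    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
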