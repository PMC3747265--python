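"""Synthetic 16S-like data: random trees, block-structured alignments with
conserved primer sites alternating with fast-evolving variable regions, and
clade-derived taxonomy.

The substitution kernel is Jukes-Cantor with a per-block rate multiplier;
no indels are introduced by default, so the alignment column space is the
ungapped coordinate space.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .io import RANKS, SequenceLibrary, SequenceRecord
from .primers import IUPAC_SETS, PrimerSpec, DEFAULT_PRIMERS, \
    reverse_complement
from .tree import Clade, PhyloTree

__all__ = [
    "RegionBlock", "RegionMap", "SimulationConfig", "default_region_map",
    "simulate_tree", "evolve_alignment", "simulate_library",
    "simulate_genus_library",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1")

#: depth fractions at which the rooted tree is cut per rank (phylum..genus)
CLADE_CUT_FRACTIONS = {
    "phylum": 0.15, "class": 0.30, "order": 0.45,
    "family": 0.60, "genus": 0.75,
}


@dataclass(frozen=True)
class RegionBlock:
    kind: str                      # "conserved" | "variable"
    length: int                    # alignment columns
    rate: float                    # relative substitution rate
    primer: Optional[PrimerSpec] = None
    primer_offset: int = 0         # offset of the planted site in the block

    def __post_init__(self):
        if self.kind not in {"conserved", "variable"}:
            raise ValueError(f"unknown block kind {self.kind!r}")
        if self.length <= 0:
            raise ValueError("block length must be positive")
        if self.rate < 0:
            raise ValueError("block rate must be >= 0")
        if self.primer is not None:
            if self.primer_offset < 0 or \
                    self.primer_offset + len(self.primer) > self.length:
                raise ValueError(
                    f"primer {self.primer.name} does not fit in its block")


@dataclass(frozen=True)
class RegionMap:
    blocks: tuple[RegionBlock, ...]
    #: rate multiplier for planted primer-site columns; 0.0 makes the sites
    #: invariant, mirroring how universal-primer sites behave in real 16S
    site_rate: float = 0.0

    @property
    def alignment_length(self) -> int:
        return sum(b.length for b in self.blocks)

    def rates(self) -> np.ndarray:
        rates = np.concatenate(
            [np.full(b.length, b.rate) for b in self.blocks])
        for primer, start in self.planted_sites():
            rates[start:start + len(primer)] *= self.site_rate
        return rates

    def column_kinds(self) -> np.ndarray:
        return np.concatenate([np.full(b.length, b.kind == "variable")
                               for b in self.blocks])

    def planted_sites(self) -> list[tuple[PrimerSpec, int]]:
        """(primer, alignment start column) of every planted site."""
        sites, offset = [], 0
        for b in self.blocks:
            if b.primer is not None:
                sites.append((b.primer, offset + b.primer_offset))
            offset += b.length
        return sites


def default_region_map(conserved_rate: float = 0.25,
                       variable_rate: float = 4.0) -> RegionMap:
    """~1500 columns: 10 conserved blocks alternating with 9 variable ones.

    The five primer loci (each shared by a forward/reverse primer pair) are
    planted inside conserved blocks at columns mimicking their E. coli
    coordinates; forward-orientation sequences are planted, so reverse
    primers match on the '-' strand.
    """
    by_name = {p.name: p for p in DEFAULT_PRIMERS}
    c, v = conserved_rate, variable_rate

    def cons(length, primer=None, offset=0):
        return RegionBlock("conserved", length, c, primer, offset)

    def var(length):
        return RegionBlock("variable", length, v)

    blocks = (
        cons(100),                              # 0-100
        var(150),                               # 100-250   V1
        cons(150, by_name["338f"], 88),         # 250-400   site at 338
        var(100),                               # 400-500   V2
        cons(60, by_name["518f"], 26),          # 500-560   site at 526
        var(120),                               # 560-680   V3
        cons(130, by_name["799f"], 101),        # 680-810   site at 781
        var(90),                                # 810-900   V4
        cons(60, by_name["926f"], 8),           # 900-960   site at 908
        var(80),                                # 960-1040  V5
        cons(60, by_name["1062f"], 24),         # 1040-1100 site at 1064
        var(80),                                # 1100-1180 V6
        cons(50),                               # 1180-1230
        var(70),                                # 1230-1300 V7
        cons(50),                               # 1300-1350
        var(70),                                # 1350-1420 V8
        cons(40),                               # 1420-1460
        var(20),                                # 1460-1480 V9
        cons(20),                               # 1480-1500
    )
    return RegionMap(blocks)


@dataclass
class SimulationConfig:
    n_taxa: int = 50
    seed: int = 0
    tree_model: str = "yule"        # "yule" | "coalescent"
    mean_branch_length: float = 0.02
    region_map: RegionMap = field(default_factory=default_region_map)
    taxonomy_ranks: tuple[str, ...] = RANKS

    def __post_init__(self):
        if self.n_taxa < 3:
            raise ValueError("n_taxa must be >= 3")
        if self.tree_model not in {"yule", "coalescent"}:
            raise ValueError(f"unknown tree model {self.tree_model!r}")
        if self.mean_branch_length <= 0:
            raise ValueError("mean branch length must be positive")
        unknown = set(self.taxonomy_ranks) - set(RANKS)
        if unknown:
            raise ValueError(f"unknown ranks {sorted(unknown)}")


# --------------------------------------------------------------------------
# trees
# --------------------------------------------------------------------------

def _yule_tree(n: int, rng: np.random.Generator) -> Clade:
    root = Clade()
    birth = {id(root): 0.0}
    active = [root]
    t = 0.0
    while len(active) < n:
        t += rng.exponential(1.0 / len(active))
        k = int(rng.integers(len(active)))
        node = active.pop(k)
        node.length = t - birth[id(node)]
        for _ in range(2):
            child = Clade()
            birth[id(child)] = t
            node.add(child)
            active.append(child)
    t += rng.exponential(1.0 / n)
    for node in active:
        node.length = t - birth[id(node)]
    return root


def _coalescent_tree(n: int, rng: np.random.Generator) -> Clade:
    active = [Clade() for _ in range(n)]
    height = {id(node): 0.0 for node in active}
    t = 0.0
    while len(active) > 1:
        k = len(active)
        t += rng.exponential(2.0 / (k * (k - 1)))
        i, j = sorted(rng.choice(k, size=2, replace=False))
        b = active.pop(int(j))
        a = active.pop(int(i))
        for node in (a, b):
            node.length = t - height[id(node)]
        parent = Clade(children=[a, b])
        height[id(parent)] = t
        active.append(parent)
    return active[0]


def simulate_tree(config: SimulationConfig) -> PhyloTree:
    """Random binary tree, derooted to 2n-3 edges, mean length rescaled.

    Fully determined by (config, config.seed).
    """
    rng = np.random.default_rng(config.seed)
    build = _yule_tree if config.tree_model == "yule" else _coalescent_tree
    root = build(config.n_taxa, rng)
    tree = PhyloTree(root)
    # name leaves in the order the simulator created them
    for k, leaf in enumerate(tree.leaves()):
        leaf.name = f"t{k + 1:04d}"
    tree.deroot()
    lengths = [n.length for n in tree.preorder() if n.parent is not None]
    mean = float(np.mean(lengths))
    if mean > 0:
        scale = config.mean_branch_length / mean
        for node in tree.preorder():
            if node.parent is not None:
                node.length *= scale
    return tree


# --------------------------------------------------------------------------
# sequence evolution
# --------------------------------------------------------------------------

def _root_sequence(region_map: RegionMap,
                   rng: np.random.Generator) -> np.ndarray:
    seq = rng.integers(0, 4, size=region_map.alignment_length)
    for primer, start in region_map.planted_sites():
        template = primer.iupac_seq if primer.direction == "forward" else \
            reverse_complement(primer.iupac_seq)
        for k, code in enumerate(template):
            choices = sorted(IUPAC_SETS[code])
            base = choices[int(rng.integers(len(choices)))]
            seq[start + k] = "ACGT".index(base)
    return seq


def _jc_sub_prob(t: float, rates: np.ndarray) -> np.ndarray:
    return 0.75 * (1.0 - np.exp(-4.0 / 3.0 * rates * t))


def evolve_alignment(tree: PhyloTree, region_map: RegionMap,
                     seed: int = 0) -> SequenceLibrary:
    """Evolve one root sequence down the tree (JC, per-block rates).

    Taxonomy labels are attached per clade at the configured depth cuts;
    the domain rank is constant ("Bacteria").
    """
    rng = np.random.default_rng(seed)
    rates = region_map.rates()
    L = region_map.alignment_length
    root_seq = _root_sequence(region_map, rng)
    seqs: dict[int, np.ndarray] = {id(tree.root): root_seq}
    for node in tree.preorder():
        if node.parent is None:
            continue
        parent_seq = seqs[id(node.parent)]
        p = _jc_sub_prob(node.length, rates)
        mask = rng.random(L) < p
        child_seq = parent_seq.copy()
        if mask.any():
            shift = rng.integers(1, 4, size=int(mask.sum()))
            child_seq[mask] = (child_seq[mask] + shift) % 4
        seqs[id(node)] = child_seq
    taxonomy = assign_clade_taxonomy(tree)
    records = []
    for leaf in tree.leaves():
        text = _BASES[seqs[id(leaf)]].tobytes().decode()
        records.append(SequenceRecord(leaf.name, text, taxonomy[leaf.name]))
    return SequenceLibrary(records)


def assign_clade_taxonomy(
    tree: PhyloTree,
    ranks: tuple[str, ...] = RANKS,
) -> dict[str, list[tuple[str, str]]]:
    """Label leaves by the first ancestor crossing each rank's depth cut.

    Every label therefore names the full subtree below one node, so labels
    induce connected subtrees and successive ranks nest.
    """
    depth: dict[int, float] = {id(tree.root): 0.0}
    number: dict[int, int] = {}
    for k, node in enumerate(tree.preorder()):
        number[id(node)] = k
        if node.parent is not None:
            depth[id(node)] = depth[id(node.parent)] + node.length
    max_depth = max(depth[id(lf)] for lf in tree.leaves()) or 1.0

    out: dict[str, list[tuple[str, str]]] = {}
    for leaf in tree.leaves():
        path = []
        node = leaf
        while node is not None:
            path.append(node)
            node = node.parent
        path.reverse()  # root -> leaf
        lineage: list[tuple[str, str]] = []
        for rank in ranks:
            if rank == "domain":
                lineage.append(("domain", "Bacteria"))
                continue
            if rank not in CLADE_CUT_FRACTIONS:
                continue
            cut = CLADE_CUT_FRACTIONS[rank] * max_depth
            crossing = path[-1]
            for node in path:
                if depth[id(node)] >= cut:
                    crossing = node
                    break
            lineage.append((rank, f"{rank[0]}{number[id(crossing)]:04d}"))
        out[leaf.name] = lineage
    return out


def simulate_library(
    config: SimulationConfig,
) -> tuple[PhyloTree, SequenceLibrary]:
    """Convenience: tree plus evolved library from one config."""
    tree = simulate_tree(config)
    library = evolve_alignment(tree, config.region_map, seed=config.seed + 1)
    return tree, library


# --------------------------------------------------------------------------
# well-separated genus libraries (classifier benchmarks)
# --------------------------------------------------------------------------

def simulate_genus_library(
    n_genera: int = 10,
    n_per_genus: int = 5,
    length: int = 600,
    intra_p: float = 0.03,
    seed: int = 0,
) -> SequenceLibrary:
    """Genera drawn independently (inter-genus p ~ 0.75 >> intra).

    Members of a genus differ from its centroid at floor(intra_p/2 * length)
    positions, so intra-genus pairwise p-distance is at most ``intra_p``.
    """
    rng = np.random.default_rng(seed)
    n_mut = int(np.floor(intra_p / 2.0 * length))
    records = []
    for g in range(n_genera):
        centroid = rng.integers(0, 4, size=length)
        lineage = [("domain", "Bacteria"),
                   ("phylum", f"p{g % 3:02d}"),
                   ("class", f"c{g % 3:02d}"),
                   ("order", f"o{g:02d}"),
                   ("family", f"f{g:02d}"),
                   ("genus", f"g{g:02d}")]
        for m in range(n_per_genus):
            seq = centroid.copy()
            pos = rng.choice(length, size=n_mut, replace=False)
            seq[pos] = (seq[pos] + rng.integers(1, 4, size=n_mut)) % 4
            text = _BASES[seq].tobytes().decode()
            records.append(SequenceRecord(f"g{g:02d}_s{m:02d}", text,
                                          lineage))
    return SequenceLibrary(records)
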