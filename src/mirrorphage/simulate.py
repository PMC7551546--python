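"""Synthetic partial-genome simulator with known coevolution structure.

The generator emulates a collection of phage contigs in which a *core* of
gene families shares one species tree (so their gene trees mirror each
other) while *accessory* families each follow an independent random tree
(genome mosaicism).  On top of the clean histories it implants the
irregularities the downstream pipeline must detect: gene duplications,
one intron-split gene (two complementary pieces flanking an inserted
marker ORF), and contig truncation (each genome retains only a contiguous
window of the full gene order, as partial assemblies do).

Sequences evolve indel-free under a 20-state equal-rates (Poisson)
substitution process: along a branch of length ``t`` expected
substitutions/site each site is redrawn uniformly over the 20 residues
with probability ``1 - exp(-(20/19) t)``, giving the classic expected
p-distance ``(19/20) (1 - exp(-(20/19) t))`` between two sequences at
total path length ``t``.
"""

from __future__ import annotations

import copy
import os
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError, DataError
from .records import AMINO_ACIDS, CATEGORIES, OrfRecord, orf_id_for

_REDRAW_RATE = 20.0 / 19.0  # uniform-redraw rate giving 1 substitution/site/unit t


# ---------------------------------------------------------------------------
# trees
# ---------------------------------------------------------------------------

@dataclass
class TreeNode:
    """Rooted tree node; ``length`` is the branch above this node."""

    name: str | None = None
    length: float = 0.0
    children: list["TreeNode"] = field(default_factory=list)

    def leaves(self) -> list["TreeNode"]:
        if not self.children:
            return [self]
        out: list[TreeNode] = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def leaf_names(self) -> list[str]:
        return [l.name for l in self.leaves()]

    def n_edges(self) -> int:
        return sum(1 + c.n_edges() for c in self.children)

    def newick(self) -> str:
        return self._newick_node() + ";"

    def _newick_node(self) -> str:
        if not self.children:
            return f"{self.name}:{self.length:.10g}"
        inner = ",".join(c._newick_node() for c in self.children)
        return f"({inner}):{self.length:.10g}"


def generate_tree(
    n_leaves: int,
    mean_branch_length: float,
    seed: int,
    labels: list[str] | None = None,
) -> TreeNode:
    """Random rooted bifurcating tree with exponential branch lengths.

    The topology is built by random sequential joins (uniform over labelled
    topologies); every branch length is an independent exponential draw
    with the given mean (expected substitutions/site).  Identical arguments
    give identical trees.
    """
    if n_leaves < 2:
        raise ConfigError("a tree needs at least 2 leaves")
    if mean_branch_length <= 0:
        raise ConfigError("mean_branch_length must be positive")
    if labels is None:
        labels = [f"g{i:03d}" for i in range(1, n_leaves + 1)]
    if len(labels) != n_leaves or len(set(labels)) != n_leaves:
        raise ConfigError("labels must be unique and match n_leaves")
    rng = np.random.default_rng(seed)
    nodes = [TreeNode(name=lab) for lab in labels]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        right = nodes.pop(j)
        left = nodes.pop(i)
        left.length = float(rng.exponential(mean_branch_length))
        right.length = float(rng.exponential(mean_branch_length))
        nodes.append(TreeNode(children=[left, right]))
    root = nodes[0]
    root.length = 0.0
    return root


# ---------------------------------------------------------------------------
# sequence evolution
# ---------------------------------------------------------------------------

def _evolve_along(seq: np.ndarray, t: float, rng: np.random.Generator) -> np.ndarray:
    """Evolve an integer-encoded sequence along a branch of length ``t``."""
    if t < 0:
        raise DataError("negative branch length in evolution")
    keep = rng.random(seq.size) < np.exp(-_REDRAW_RATE * t)
    out = seq.copy()
    n_redraw = int((~keep).sum())
    if n_redraw:
        out[~keep] = rng.integers(0, 20, size=n_redraw)
    return out


def _decode(seq: np.ndarray) -> str:
    return "".join(AMINO_ACIDS[i] for i in seq)


def evolve_family(
    tree: TreeNode, length: int, rate_scale: float, seed: int
) -> dict[str, str]:
    """Simulate one protein family over a tree; returns leaf name -> sequence.

    Indel-free, so the returned sequences are trivially aligned (all have
    the requested length).  The root sequence is uniform over the 20
    residues; substitutions follow the equal-rates model described in the
    module docstring, with every branch length multiplied by ``rate_scale``.
    """
    if length < 1:
        raise ConfigError("family length must be >= 1")
    if rate_scale < 0:
        raise ConfigError("rate_scale must be >= 0")
    rng = np.random.default_rng(seed)
    root_seq = rng.integers(0, 20, size=length)
    out: dict[str, str] = {}
    stack = [(tree, root_seq)]
    while stack:
        node, seq = stack.pop()
        if not node.children:
            out[node.name] = _decode(seq)
            continue
        # branch draws happen in child order, so the rng stream is reproducible
        for child in node.children:
            child_seq = _evolve_along(seq, child.length * rate_scale, rng)
            stack.append((child, child_seq))
    return out


# ---------------------------------------------------------------------------
# configuration and ground truth
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DuplicationTruth:
    family: int
    genome_id: str
    divergence: float
    retained: bool = True


@dataclass
class SplitTruth:
    family: int
    genome_ids: list[str]
    breakpoint: int
    marker_length: int
    retained: dict[str, bool] = field(default_factory=dict)


@dataclass
class TruthTable:
    """Ground truth written alongside every synthetic dataset."""

    family_tree: dict[int, str]            # family -> "shared" | "indep-<i>"
    coevolving: dict[int, bool]            # True for shared-tree families
    category: dict[int, str]
    windows: dict[str, tuple[int, int]]    # genome -> retained [start, end) gene slots
    duplications: list[DuplicationTruth] = field(default_factory=list)
    split: SplitTruth | None = None


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic collection of partial genomes.

    Defaults describe a moderately diverged clade of 40 partial genomes:
    12 core families mirroring one species tree plus 6 accessory families
    with independent histories, 200-residue proteins, exponential branch
    lengths with mean 0.1 substitutions/site, contigs truncated to a
    random 40-90% window of the gene order, three implanted duplications
    and one intron-split gene.
    """

    n_genomes: int = 40
    n_core_families: int = 12
    n_accessory_families: int = 6
    family_lengths: list[int] | None = None
    family_rate_scales: list[float] | None = None
    mean_branch_length: float = 0.1
    truncation: tuple[float, float] = (0.4, 0.9)
    duplications: tuple[tuple[int, int, float], ...] = (
        (1, 5, 0.05),
        (3, 12, 0.05),
        (3, 17, 0.05),
    )
    split_gene: tuple[int, tuple[int, ...], int, int] | None = (4, (6, 9), 90, 60)
    seed: int = 0
    categories: dict[int, str] | None = None

    @property
    def n_families(self) -> int:
        return self.n_core_families + self.n_accessory_families

    def resolved_lengths(self) -> list[int]:
        if self.family_lengths is None:
            return [200] * self.n_families
        return list(self.family_lengths)

    def resolved_rate_scales(self) -> list[float]:
        if self.family_rate_scales is None:
            return [1.0] * self.n_families
        return list(self.family_rate_scales)

    def resolved_categories(self) -> dict[int, str]:
        if self.categories is not None:
            return dict(self.categories)
        return {f: CATEGORIES[f % len(CATEGORIES)] for f in range(self.n_families)}

    def validate(self) -> None:
        if self.n_genomes < 2:
            raise ConfigError("n_genomes must be >= 2")
        if self.n_core_families < 0 or self.n_accessory_families < 0:
            raise ConfigError("family counts must be >= 0")
        if self.n_families < 1:
            raise ConfigError("at least one family required")
        lengths = self.resolved_lengths()
        scales = self.resolved_rate_scales()
        if len(lengths) != self.n_families or len(scales) != self.n_families:
            raise ConfigError(
                "family_lengths and family_rate_scales must match the family count"
            )
        if any(l < 1 for l in lengths) or any(s <= 0 for s in scales):
            raise ConfigError("family lengths must be >=1 and rate scales positive")
        lo, hi = self.truncation
        if not (0 < lo <= hi <= 1):
            raise ConfigError("truncation bounds must satisfy 0 < min <= max <= 1")
        for fam, gen, div in self.duplications:
            if not (0 <= fam < self.n_families) or not (0 <= gen < self.n_genomes):
                raise ConfigError(f"duplication ({fam},{gen}) out of range")
            if div < 0:
                raise ConfigError("duplication divergence must be >= 0")
        if self.split_gene is not None:
            fam, genomes, bp, mlen = self.split_gene
            if not 0 <= fam < self.n_families:
                raise ConfigError("split_gene family out of range")
            if any(not 0 <= g < self.n_genomes for g in genomes):
                raise ConfigError("split_gene genome index out of range")
            if not 0 < bp < lengths[fam]:
                raise ConfigError("split_gene breakpoint outside the gene")
            if mlen < 1:
                raise ConfigError("split_gene marker length must be >= 1")
        cats = self.resolved_categories()
        if set(cats) != set(range(self.n_families)):
            raise ConfigError("categories must cover every family index exactly")


@dataclass
class SyntheticDataset:
    """Materialised genomes plus the parallel ground-truth bookkeeping.

    ``gene_slots[g]`` holds, for each ORF of genome ``g`` in gene order,
    the family index it belongs to (``None`` for inserted marker ORFs).
    """

    genome_ids: list[str]
    reference_id: str
    sequences: dict[str, list[str]]          # genome -> protein per gene slot
    gene_slots: dict[str, list[int | None]]  # genome -> family index per slot
    truth: TruthTable
    trees: dict[str, TreeNode]

    def orfs(self, genome_id: str) -> list[OrfRecord]:
        return [
            OrfRecord(orf_id_for(genome_id, i + 1), genome_id, i + 1, seq)
            for i, seq in enumerate(self.sequences[genome_id])
        ]

    def all_orfs(self) -> list[OrfRecord]:
        out: list[OrfRecord] = []
        for g in self.genome_ids:
            out.extend(self.orfs(g))
        return out

    def reference_orfs(self) -> list[OrfRecord]:
        return self.orfs(self.reference_id)

    def reference_orf_for_family(self, family: int) -> str:
        slots = self.gene_slots[self.reference_id]
        for i, fam in enumerate(slots):
            if fam == family:
                return orf_id_for(self.reference_id, i + 1)
        raise DataError(f"reference genome lacks family {family}")

    def copy(self) -> "SyntheticDataset":
        return SyntheticDataset(
            genome_ids=list(self.genome_ids),
            reference_id=self.reference_id,
            sequences={g: list(s) for g, s in self.sequences.items()},
            gene_slots={g: list(s) for g, s in self.gene_slots.items()},
            truth=copy.deepcopy(self.truth),
            trees=self.trees,
        )


# ---------------------------------------------------------------------------
# dataset assembly and mutations
# ---------------------------------------------------------------------------

def _genome_labels(n: int) -> list[str]:
    # genome index 0 is the complete reference genome, kept untruncated
    return ["ref"] + [f"g{i:03d}" for i in range(1, n)]


def inject_duplication(
    dataset: SyntheticDataset,
    family: int,
    genome: int | str,
    divergence: float,
    seed: int,
) -> SyntheticDataset:
    """Insert a second, diverged copy of a gene adjacent to the original."""
    ds = dataset.copy()
    gid = genome if isinstance(genome, str) else ds.genome_ids[genome]
    slots = ds.gene_slots[gid]
    try:
        pos = slots.index(family)
    except ValueError:
        raise ConfigError(f"genome {gid} does not carry family {family}") from None
    rng = np.random.default_rng(seed)
    original = ds.sequences[gid][pos]
    encoded = np.array([AMINO_ACIDS.index(a) for a in original])
    dup = _decode(_evolve_along(encoded, divergence, rng))
    ds.sequences[gid].insert(pos + 1, dup)
    ds.gene_slots[gid].insert(pos + 1, family)
    ds.truth.duplications.append(DuplicationTruth(family, gid, divergence))
    return ds


def inject_split_gene(
    dataset: SyntheticDataset,
    family: int,
    genomes: list[int | str],
    breakpoint: int,
    marker_length: int,
    seed: int = 0,
) -> SyntheticDataset:
    """Split a gene into N-/C-terminal pieces flanking an inserted marker ORF.

    The same marker sequence (the mobile element) is inserted in every
    listed genome.
    """
    ds = dataset.copy()
    rng = np.random.default_rng(seed)
    marker = _decode(rng.integers(0, 20, size=marker_length))
    gids = [g if isinstance(g, str) else ds.genome_ids[g] for g in genomes]
    if gids:
        length = None
        for gid in gids:
            slots = ds.gene_slots[gid]
            try:
                pos = slots.index(family)
            except ValueError:
                raise ConfigError(
                    f"genome {gid} does not carry family {family}"
                ) from None
            seq = ds.sequences[gid][pos]
            if length is None:
                length = len(seq)
            if not 0 < breakpoint < len(seq):
                raise ConfigError(
                    f"breakpoint {breakpoint} outside gene of length {len(seq)}"
                )
            ds.sequences[gid][pos : pos + 1] = [
                seq[:breakpoint],
                marker,
                seq[breakpoint:],
            ]
            ds.gene_slots[gid][pos : pos + 1] = [family, None, family]
        ds.truth.split = SplitTruth(
            family=family,
            genome_ids=gids,
            breakpoint=breakpoint,
            marker_length=marker_length,
            retained={g: True for g in gids},
        )
    return ds


def truncate_genomes(
    dataset: SyntheticDataset,
    truncation: tuple[float, float],
    seed: int,
    keep_full: tuple[str, ...] = (),
) -> SyntheticDataset:
    """Keep one uniformly placed contiguous window of each genome's gene order.

    The retained fraction is drawn uniformly in ``[min, max]`` per genome.
    Genomes in ``keep_full`` (typically the reference) keep everything.
    Ground-truth windows and the retained flags of implanted events are
    updated accordingly.
    """
    lo, hi = truncation
    if not (0 < lo <= hi <= 1):
        raise ConfigError("truncation bounds must satisfy 0 < min <= max <= 1")
    ds = dataset.copy()
    rng = np.random.default_rng(seed)
    for gid in ds.genome_ids:
        n = len(ds.sequences[gid])
        if gid in keep_full or (lo == hi == 1.0):
            ds.truth.windows[gid] = (0, n)
            continue
        frac = float(rng.uniform(lo, hi))
        k = max(1, round(frac * n))
        start = int(rng.integers(0, n - k + 1))
        ds.sequences[gid] = ds.sequences[gid][start : start + k]
        ds.gene_slots[gid] = ds.gene_slots[gid][start : start + k]
        ds.truth.windows[gid] = (start, start + k)
    # update retained flags for implanted events
    ds.truth.duplications = [
        DuplicationTruth(
            d.family,
            d.genome_id,
            d.divergence,
            retained=ds.gene_slots[d.genome_id].count(d.family) >= 2,
        )
        for d in ds.truth.duplications
    ]
    if ds.truth.split is not None:
        sp = ds.truth.split
        for gid in sp.genome_ids:
            slots = ds.gene_slots[gid]
            ok = any(
                slots[i] == sp.family
                and slots[i + 1] is None
                and slots[i + 2] == sp.family
                for i in range(len(slots) - 2)
            )
            sp.retained[gid] = ok
    return ds


def simulate(config: SimulationConfig) -> SyntheticDataset:
    """Run the full generator: trees, families, implants, truncation."""
    config.validate()
    master = np.random.default_rng(config.seed)
    seeds = master.integers(0, 2**31 - 1, size=4 + config.n_families
                            + config.n_accessory_families
                            + len(config.duplications))
    seed_iter = iter(int(s) for s in seeds)

    labels = _genome_labels(config.n_genomes)
    shared = generate_tree(
        config.n_genomes, config.mean_branch_length, next(seed_iter), labels=labels
    )
    trees: dict[str, TreeNode] = {"shared": shared}
    family_tree: dict[int, str] = {}
    for f in range(config.n_core_families):
        family_tree[f] = "shared"
    for i in range(config.n_accessory_families):
        tid = f"indep-{i:02d}"
        trees[tid] = generate_tree(
            config.n_genomes, config.mean_branch_length, next(seed_iter), labels=labels
        )
        family_tree[config.n_core_families + i] = tid

    lengths = config.resolved_lengths()
    scales = config.resolved_rate_scales()
    families: list[dict[str, str]] = []
    for f in range(config.n_families):
        families.append(
            evolve_family(
                trees[family_tree[f]], lengths[f], scales[f], next(seed_iter)
            )
        )

    sequences = {g: [families[f][g] for f in range(config.n_families)] for g in labels}
    gene_slots = {g: list(range(config.n_families)) for g in labels}
    truth = TruthTable(
        family_tree=family_tree,
        coevolving={f: family_tree[f] == "shared" for f in range(config.n_families)},
        category=config.resolved_categories(),
        windows={},
    )
    ds = SyntheticDataset(
        genome_ids=labels,
        reference_id=labels[0],
        sequences=sequences,
        gene_slots=gene_slots,
        truth=truth,
        trees=trees,
    )

    for fam, gen, div in config.duplications:
        ds = inject_duplication(ds, fam, gen, div, next(seed_iter))
    if config.split_gene is not None:
        fam, genomes, bp, mlen = config.split_gene
        ds = inject_split_gene(ds, fam, list(genomes), bp, mlen, next(seed_iter))
    ds = truncate_genomes(
        ds, config.truncation, next(seed_iter), keep_full=(ds.reference_id,)
    )
    return ds


# ---------------------------------------------------------------------------
# serialisation
# ---------------------------------------------------------------------------

def write_dataset(dataset: SyntheticDataset, out_dir: str) -> dict[str, str]:
    """Write genomes (FASTA), ground truth (TSV) and trees (Newick).

    Returns a map of logical names to the paths written.  FASTA headers use
    the ``<genome_id>_<orf_index>`` dialect with a 1-based ORF index.
    """
    os.makedirs(out_dir, exist_ok=True)
    genome_dir = os.path.join(out_dir, "genomes")
    tree_dir = os.path.join(out_dir, "trees")
    os.makedirs(genome_dir, exist_ok=True)
    os.makedirs(tree_dir, exist_ok=True)
    paths: dict[str, str] = {}

    from .io import write_orf_fasta  # local import to avoid a cycle

    for gid in dataset.genome_ids:
        p = os.path.join(genome_dir, f"{gid}.faa")
        write_orf_fasta(dataset.orfs(gid), p)
        paths[f"genome:{gid}"] = p
    ref_path = os.path.join(out_dir, "reference.faa")
    write_orf_fasta(dataset.reference_orfs(), ref_path)
    paths["reference"] = ref_path

    tt = dataset.truth
    fam_path = os.path.join(out_dir, "families.tsv")
    with open(fam_path, "w") as fh:
        fh.write("family_id\ttree_id\tcoevolving\tcategory\treference_orf_id\n")
        for f in sorted(tt.family_tree):
            fh.write(
                f"{f}\t{tt.family_tree[f]}\t{tt.coevolving[f]}\t"
                f"{tt.category[f]}\t{dataset.reference_orf_for_family(f)}\n"
            )
    paths["families"] = fam_path

    cat_path = os.path.join(out_dir, "categories.tsv")
    with open(cat_path, "w") as fh:
        fh.write("reference_orf_id\tcategory\n")
        for f in sorted(tt.family_tree):
            fh.write(f"{dataset.reference_orf_for_family(f)}\t{tt.category[f]}\n")
    paths["categories"] = cat_path

    win_path = os.path.join(out_dir, "windows.tsv")
    with open(win_path, "w") as fh:
        fh.write("genome_id\tstart\tend\n")
        for g in dataset.genome_ids:
            s, e = tt.windows.get(g, (0, len(dataset.sequences[g])))
            fh.write(f"{g}\t{s}\t{e}\n")
    paths["windows"] = win_path

    dup_path = os.path.join(out_dir, "duplications.tsv")
    with open(dup_path, "w") as fh:
        fh.write("family_id\tgenome_id\tdivergence\tretained\n")
        for d in tt.duplications:
            fh.write(f"{d.family}\t{d.genome_id}\t{d.divergence}\t{d.retained}\n")
    paths["duplications"] = dup_path

    split_path = os.path.join(out_dir, "split_gene.tsv")
    with open(split_path, "w") as fh:
        fh.write("family_id\tgenome_id\tbreakpoint\tmarker_length\tretained\n")
        if tt.split is not None:
            sp = tt.split
            for g in sp.genome_ids:
                fh.write(
                    f"{sp.family}\t{g}\t{sp.breakpoint}\t{sp.marker_length}\t"
                    f"{sp.retained[g]}\n"
                )
    paths["split_gene"] = split_path

    for tid, tree in dataset.trees.items():
        p = os.path.join(tree_dir, f"{tid}.nwk")
        with open(p, "w") as fh:
            fh.write(tree.newick() + "\n")
        paths[f"tree:{tid}"] = p
    return paths
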