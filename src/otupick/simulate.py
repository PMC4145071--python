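"""Synthetic amplicon benchmarks with planted ground truth.

The generator emulates the three roles reads play in open-reference OTU
picking on real marker-gene surveys:

* reads from *reference* lineages, which match the reference collection;
* reads from *novel* lineages, which are real marker-gene sequence absent
  from the reference (these drive the new-reference / clean-up tiers);
* *contaminant* reads (e.g., host genomic sequence), uniform-random DNA
  verified to match no reference centroid at even 60% identity.

Lineage centroids are evolved from a random ancestor along a random
bifurcating tree under an independent-site (Jukes-Cantor-like) substitution
model; the planted between-lineage divergence is far above ``1 - s`` while
reads diverge from their lineage centroid far below it, so the planted
partition is recoverable at the default threshold s = 0.97. Samples fall
into a few groups with distinct lognormal abundance profiles, mimicking the
strong community structure (soil pH gradients, body sites) of the studies
this kind of evaluation is run on.

All randomness flows from ``SimConfig.seed``; identical configs produce
byte-identical benchmark bundles.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from skbio import TreeNode

from .align import pairwise_identity
from .io import (SampleAssignment, SequenceRecord, write_fasta,
                 write_newick, write_taxonomy)

__all__ = [
    "SimConfig",
    "LineageUniverse",
    "GroundTruth",
    "Benchmark",
    "generate_reference_set",
    "simulate_reads",
    "extend_tree_with_new_otus",
    "make_benchmark",
]

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic benchmark.

    Defaults define the standard benchmark: 60 reference and 20 novel
    lineages at 20% planted divergence, 12 samples x 2000 reads of length
    150 in 3 sample groups, 0.5% per-base read error (~1% read-to-read
    divergence within a lineage), and 2% contaminant reads drawn from 40
    fixed uniform-random source sequences.
    """

    n_reference_lineages: int = 60
    n_novel_lineages: int = 20
    n_contaminants: int = 40
    contaminant_fraction: float = 0.02
    read_length: int = 150
    substitution_rate: float = 0.005
    n_samples: int = 12
    reads_per_sample: int = 2000
    n_sample_groups: int = 3
    abundance_mu: float = 0.0
    abundance_sigma: float = 2.0
    within_group_sigma: float = 0.6
    lineage_divergence: float = 0.20
    graft_branch_length: float = 0.01
    seed: int = 42

    def __post_init__(self):
        if self.n_reference_lineages < 1:
            raise ValueError("need at least one reference lineage")
        if not 0 <= self.contaminant_fraction <= 1:
            raise ValueError("contaminant_fraction must be in [0, 1]")
        if self.contaminant_fraction > 0 and self.n_contaminants < 1:
            raise ValueError("contaminant reads requested but no "
                             "contaminant sources configured")
        if not 0 <= self.substitution_rate < 0.5 * self.lineage_divergence:
            raise ValueError("read error rate must sit well below the "
                             "between-lineage divergence")


@dataclass
class LineageUniverse:
    """All planted lineages: centroids, kinds, true tree and taxonomy."""

    centroids: dict[str, str]
    kinds: dict[str, str]
    tree: TreeNode
    taxonomy: dict[str, str]

    @property
    def reference(self) -> list[SequenceRecord]:
        return [SequenceRecord(lid, seq) for lid, seq in self.centroids.items()
                if self.kinds[lid] == "reference"]

    @property
    def lineage_ids(self) -> list[str]:
        return list(self.centroids)


@dataclass
class GroundTruth:
    """Planted origin of every read, plus the true tree and taxonomy."""

    read_lineage: dict[str, str]
    lineage_kind: dict[str, str]
    tree: TreeNode
    taxonomy: dict[str, str]

    def partition(self, read_ids=None) -> frozenset[frozenset[str]]:
        """Label-free planted partition (restrictable to a read subset)."""
        groups: dict[str, set[str]] = {}
        universe = (set(read_ids) if read_ids is not None
                    else set(self.read_lineage))
        for rid, lid in self.read_lineage.items():
            if rid in universe:
                groups.setdefault(lid, set()).add(rid)
        return frozenset(frozenset(g) for g in groups.values())


@dataclass
class Benchmark:
    config: SimConfig
    reads: list[SequenceRecord]
    reference: list[SequenceRecord]
    tree: TreeNode
    taxonomy: dict[str, str]
    samples: SampleAssignment
    truth: GroundTruth
    universe: LineageUniverse


def _random_seq(rng, length) -> np.ndarray:
    return rng.integers(0, 4, size=length).astype(np.int8)


def _mutate(arr: np.ndarray, rate: float, rng) -> np.ndarray:
    """Substitute each site with probability ``rate`` (to a random other
    base)."""
    if rate <= 0:
        return arr.copy()
    hits = rng.random(arr.shape[0]) < rate
    out = arr.copy()
    n = int(hits.sum())
    if n:
        out[hits] = (out[hits] + rng.integers(1, 4, size=n)) % 4
    return out


def _decode(arr: np.ndarray) -> str:
    return "".join(_BASES[arr])


def _random_topology(leaf_ids, rng, next_label):
    """Random bifurcating topology over the given leaves."""
    if len(leaf_ids) == 1:
        return TreeNode(name=leaf_ids[0])
    # random non-trivial split
    k = int(rng.integers(1, len(leaf_ids)))
    idx = rng.permutation(len(leaf_ids))
    left = [leaf_ids[i] for i in sorted(idx[:k])]
    right = [leaf_ids[i] for i in sorted(idx[k:])]
    node = TreeNode(name=f"clade{next_label[0]}")
    next_label[0] += 1
    node.append(_random_topology(left, rng, next_label))
    node.append(_random_topology(right, rng, next_label))
    return node


def generate_reference_set(config: SimConfig) -> LineageUniverse:
    """Evolve reference + novel lineage centroids along a random tree.

    Terminal branches carry an expected per-site substitution fraction of
    ``lineage_divergence / 2`` and internal branches half of that, so even
    sister lineages differ by about the planted divergence. All pairwise
    centroid identities are verified to sit below both ``1 - divergence/2``
    and 0.97; a violation raises.
    """
    rng = np.random.default_rng([config.seed, 0])
    n = config.n_reference_lineages + config.n_novel_lineages
    lineage_ids = [f"L{i:03d}" for i in range(n)]
    counter = [0]
    tree = _random_topology(lineage_ids, rng, counter)
    term = config.lineage_divergence / 2
    for node in tree.traverse(include_self=True):
        if node.is_root():
            node.length = 0.0
        elif node.is_tip():
            node.length = term
        else:
            node.length = term / 2

    ancestor = _random_seq(rng, config.read_length)
    centroid_arrays: dict[str, np.ndarray] = {}

    def _evolve(node, seq):
        for child in node.children:
            child_seq = _mutate(seq, child.length, rng)
            if child.is_tip():
                centroid_arrays[child.name] = child_seq
            else:
                _evolve(child, child_seq)

    if tree.is_tip():
        centroid_arrays[tree.name] = ancestor
    else:
        _evolve(tree, ancestor)

    centroids = {lid: _decode(centroid_arrays[lid]) for lid in lineage_ids}
    novel = set(rng.choice(lineage_ids, size=config.n_novel_lineages,
                           replace=False).tolist())
    kinds = {lid: ("novel" if lid in novel else "reference")
             for lid in lineage_ids}

    ceiling = min(1 - config.lineage_divergence / 2, 0.97)
    ids = lineage_ids
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            ident = pairwise_identity(centroids[ids[i]], centroids[ids[j]])
            if ident > ceiling:
                raise RuntimeError(
                    f"planted lineages {ids[i]}/{ids[j]} too similar "
                    f"(identity {ident:.3f} > {ceiling:.3f}); "
                    "increase lineage_divergence")

    taxonomy = _tree_taxonomy(tree)
    return LineageUniverse(centroids=centroids, kinds=kinds, tree=tree,
                           taxonomy=taxonomy)


_RANK_PREFIXES = "pcofg"


def _tree_taxonomy(tree) -> dict[str, str]:
    """Greengenes-style 7-rank lineages from root-to-tip clade paths."""
    taxonomy = {}
    for tip in tree.tips():
        path = [a.name for a in reversed(list(tip.ancestors()))
                if a.name is not None]
        labels = (path + [""] * 5)[:5]
        ranks = ["k__SimBacteria"]
        ranks += [f"{p}__{l}" for p, l in zip(_RANK_PREFIXES, labels)]
        ranks.append(f"s__{tip.name}")
        taxonomy[tip.name] = ";".join(ranks)
    return taxonomy


def _make_contaminants(config, reference_records, rng):
    """Uniform-random sources verified < 60% identity to every reference."""
    sources = {}
    for i in range(config.n_contaminants):
        cid = f"C{i:02d}"
        for _attempt in range(100):
            seq = _decode(_random_seq(rng, config.read_length))
            worst = max(pairwise_identity(seq, rec.seq)
                        for rec in reference_records)
            if worst < 0.60:
                sources[cid] = seq
                break
        else:
            raise RuntimeError(
                "could not draw a contaminant below 60% identity to the "
                "reference collection")
    return sources


def simulate_reads(config: SimConfig, universe: LineageUniverse):
    """Draw per-sample reads from the planted lineages.

    Samples are split into ``n_sample_groups`` contiguous groups; each
    group has its own lognormal lineage-abundance profile and each sample
    perturbs it, giving real alpha- and beta-diversity structure. Reads
    mutate from their lineage centroid at ``substitution_rate`` per base;
    the configured fraction of each sample's reads are exact copies of
    contaminant source sequences (count exact, sources uniform).

    Returns ``(reads, samples, truth)``.
    """
    rng = np.random.default_rng([config.seed, 1])
    lineage_ids = universe.lineage_ids
    n_lineages = len(lineage_ids)
    centroid_arrays = {
        lid: np.array([("ACGT").index(c) for c in universe.centroids[lid]],
                      dtype=np.int8)
        for lid in lineage_ids}

    contaminants = {}
    if config.contaminant_fraction > 0 and config.n_contaminants > 0:
        contaminants = _make_contaminants(config, universe.reference, rng)

    group_base = {g: rng.normal(config.abundance_mu, config.abundance_sigma,
                                size=n_lineages)
                  for g in range(config.n_sample_groups)}
    n_cont = int(round(config.contaminant_fraction * config.reads_per_sample))
    n_lineage_reads = config.reads_per_sample - n_cont
    cont_ids = list(contaminants)

    reads: list[SequenceRecord] = []
    read_lineage: dict[str, str] = {}
    sample_map: dict[str, str] = {}
    for k in range(config.n_samples):
        sid = f"S{k}"
        g = k * config.n_sample_groups // config.n_samples
        logw = group_base[g] + rng.normal(0.0, config.within_group_sigma,
                                          size=n_lineages)
        w = np.exp(logw)
        p = w / w.sum()
        counts = rng.multinomial(n_lineage_reads, p)
        sample_reads: list[tuple[str, str]] = []
        for lid, c in zip(lineage_ids, counts):
            base = centroid_arrays[lid]
            for _ in range(int(c)):
                arr = _mutate(base, config.substitution_rate, rng)
                sample_reads.append((lid, _decode(arr)))
        for _ in range(n_cont):
            cid = cont_ids[int(rng.integers(len(cont_ids)))]
            sample_reads.append((cid, contaminants[cid]))
        order = rng.permutation(len(sample_reads))
        for serial, idx in enumerate(order):
            lid, seq = sample_reads[idx]
            rid = f"{sid}_{serial}"
            reads.append(SequenceRecord(rid, seq))
            read_lineage[rid] = lid
            sample_map[rid] = sid

    tree = universe.tree.copy()
    for node in tree.traverse(include_self=True):
        if node.length is None:
            node.length = 0.0
    if contaminants:
        # one basal contaminant clade: a long shared stem, short terminal
        # branches, mirroring contamination from a single foreign genome.
        # A fresh binary root keeps the tree strictly rooted.
        clade = TreeNode(name="contaminant_clade", length=0.5)
        for cid in contaminants:
            clade.append(TreeNode(name=cid, length=0.1))
        root = TreeNode(length=0.0)
        tree.length = 0.0
        root.append(tree)
        root.append(clade)
        tree = root

    lineage_kind = dict(universe.kinds)
    for cid in contaminants:
        lineage_kind[cid] = "contaminant"

    truth = GroundTruth(read_lineage=read_lineage,
                        lineage_kind=lineage_kind,
                        tree=tree,
                        taxonomy=dict(universe.taxonomy))
    return reads, SampleAssignment(sample_map), truth


def extend_tree_with_new_otus(tree: TreeNode, result, truth: GroundTruth,
                              branch_length: float | None = None) -> TreeNode:
    """Graft each new-tier OTU as a sibling of its true lineage's tip.

    The diversity metrics require every table OTU to be a tree tip;
    reference-tier OTUs already are, and this places every newly minted
    centroid next to the lineage its centroid read was simulated from,
    with a small fixed branch length. Returns a new tree; the input is not
    modified.
    """
    bl = 0.01 if branch_length is None else branch_length
    out = tree.copy()
    tip_nodes = {t.name: t for t in out.tips()}
    grafted: dict[str, TreeNode] = {}
    for rec in result.new_centroids:
        otu_id = rec.id
        centroid_read = result.otu_map.centroids[otu_id]
        lineage = truth.read_lineage.get(centroid_read)
        if lineage is None:
            raise ValueError(
                f"centroid read {centroid_read!r} of {otu_id!r} has no "
                "planted lineage")
        anchor = grafted.get(lineage)
        if anchor is None:
            tip = tip_nodes[lineage]
            tip.append(TreeNode(name=lineage, length=bl))
            tip.append(TreeNode(name=otu_id, length=bl))
            tip.name = None
            grafted[lineage] = tip
        else:
            anchor.append(TreeNode(name=otu_id, length=bl))
    return out


def make_benchmark(config: SimConfig | None = None,
                   output_dir=None) -> Benchmark:
    """Generate the full benchmark bundle, optionally writing it to disk.

    On disk: ``reads.fna``, ``reference.fna``, ``tree_true.nwk``,
    ``taxonomy.tsv`` and ``truth.tsv`` (read id, lineage, lineage kind).
    """
    config = config or SimConfig()
    universe = generate_reference_set(config)
    reads, samples, truth = simulate_reads(config, universe)
    bench = Benchmark(config=config, reads=reads,
                      reference=universe.reference, tree=truth.tree,
                      taxonomy=truth.taxonomy, samples=samples, truth=truth,
                      universe=universe)
    if output_dir is not None:
        out = Path(output_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_fasta(reads, out / "reads.fna")
        write_fasta(bench.reference, out / "reference.fna")
        write_newick(truth.tree, out / "tree_true.nwk")
        write_taxonomy(truth.taxonomy, out / "taxonomy.tsv")
        with open(out / "truth.tsv", "w") as fh:
            for rid, lid in truth.read_lineage.items():
                fh.write(f"{rid}\t{lid}\t{truth.lineage_kind[lid]}\n")
    return bench
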