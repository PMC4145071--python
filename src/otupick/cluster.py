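"""Greedy centroid-based clustering primitives (uclust-style engine).

Two modes are provided: closed-reference assignment against a fixed centroid
collection, and de novo clustering in which the input reads themselves found
centroids greedily, in input order.

Candidate centroids for a query are ranked by the number of distinct k-mers
("words") shared with each centroid, descending, ties broken by centroid
insertion order. The heuristic knobs mirror uclust's: ``max_accepts`` /
``max_rejects`` bound how many candidates are aligned before giving up, and
``stepwords`` caps how much of the query is scanned for words. With
``max_accepts`` and ``max_rejects`` at least the number of targets the engine
is *exhaustive*: every target is aligned and the output provably equals an
all-pairs best-hit search.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .align import encode, identity_statistics

__all__ = [
    "TIER_REFERENCE",
    "TIER_NEW_REFERENCE",
    "TIER_CLEANUP",
    "ClusteringParams",
    "OtuMap",
    "KmerIndex",
    "rank_candidates",
    "assign_closed_reference",
    "cluster_de_novo",
]

TIER_REFERENCE = "reference"
TIER_NEW_REFERENCE = "new_reference"
TIER_CLEANUP = "cleanup"


@dataclass(frozen=True)
class ClusteringParams:
    """Identity threshold plus the uclust-style heuristic knobs.

    Presets follow the published method definitions: ``slow`` =
    max_accepts 20 / max_rejects 500 / stepwords 20 / wordlength 12,
    ``fast`` = 1 / 8 / 8 / 8. ``fast`` is the default, matching the
    recommendation that fast mode does not measurably change downstream
    ecological statistics.
    """

    s: float = 0.97
    max_accepts: int = 1
    max_rejects: int = 8
    stepwords: int = 8
    wordlength: int = 8

    def __post_init__(self):
        if not 0 < self.s <= 1:
            raise ValueError("identity threshold s must be in (0, 1]")
        for name in ("max_accepts", "max_rejects", "stepwords", "wordlength"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")

    @classmethod
    def preset_slow(cls, s: float = 0.97) -> "ClusteringParams":
        return cls(s=s, max_accepts=20, max_rejects=500, stepwords=20, wordlength=12)

    @classmethod
    def preset_fast(cls, s: float = 0.97) -> "ClusteringParams":
        return cls(s=s, max_accepts=1, max_rejects=8, stepwords=8, wordlength=8)

    @classmethod
    def preset(cls, name: str, s: float = 0.97) -> "ClusteringParams":
        if name == "slow":
            return cls.preset_slow(s)
        if name == "fast":
            return cls.preset_fast(s)
        raise ValueError(f"unknown preset {name!r} (expected 'fast' or 'slow')")

    @classmethod
    def exhaustive(cls, s: float = 0.97, wordlength: int = 8) -> "ClusteringParams":
        """Settings under which the engine equals an all-pairs search."""
        big = 10**9
        return cls(s=s, max_accepts=big, max_rejects=big, stepwords=big,
                   wordlength=wordlength)

    def is_exhaustive(self, n_targets: int) -> bool:
        return self.max_accepts >= n_targets and self.max_rejects >= n_targets


class OtuMap:
    """Ordered partition of read ids into OTUs with provenance metadata.

    Equality (and the on-disk OTU map format) covers the membership
    structure only — OTU order, member order and ids. Centroid ids and
    provenance tiers are carried as side metadata.
    """

    def __init__(self):
        self._otus: dict[str, list[str]] = {}
        self.centroids: dict[str, str] = {}
        self.tiers: dict[str, str] = {}

    def add_otu(self, otu_id: str, members, centroid_id: str | None = None,
                tier: str | None = None) -> None:
        if otu_id in self._otus:
            raise ValueError(f"duplicate OTU id {otu_id!r}")
        self._otus[otu_id] = list(members)
        if centroid_id is not None:
            self.centroids[otu_id] = centroid_id
        if tier is not None:
            self.tiers[otu_id] = tier

    def append_member(self, otu_id: str, read_id: str) -> None:
        self._otus[otu_id].append(read_id)

    def items(self):
        return self._otus.items()

    def members(self, otu_id: str) -> list[str]:
        return self._otus[otu_id]

    @property
    def otu_ids(self) -> list[str]:
        return list(self._otus)

    def read_ids(self) -> list[str]:
        return [rid for members in self._otus.values() for rid in members]

    def __len__(self):
        return len(self._otus)

    def __contains__(self, otu_id):
        return otu_id in self._otus

    def __eq__(self, other):
        if not isinstance(other, OtuMap):
            return NotImplemented
        return list(self._otus.items()) == list(other._otus.items())

    def __repr__(self):
        return f"<OtuMap: {len(self)} OTUs, {len(self.read_ids())} reads>"

    def merged_with(self, *others: "OtuMap") -> "OtuMap":
        """Concatenate maps; OTU ids must be disjoint."""
        out = OtuMap()
        for m in (self, *others):
            for otu_id, members in m.items():
                out.add_otu(otu_id, members, m.centroids.get(otu_id),
                            m.tiers.get(otu_id))
        return out

    def partition(self) -> frozenset[frozenset[str]]:
        """Label-free view of the clustering, for partition comparisons."""
        return frozenset(frozenset(m) for m in self._otus.values() if m)


class KmerIndex:
    """Inverted index of the distinct k-mers of each target sequence."""

    def __init__(self, wordlength: int):
        if wordlength < 1:
            raise ValueError("wordlength must be >= 1")
        self.wordlength = wordlength
        self._postings: dict[str, list[int]] = {}
        self.target_ids: list[str] = []
        self._target_seqs: list[str] = []
        self.unique_word_counts: list[int] = []

    def add(self, target_id: str, seq: str) -> None:
        ordinal = len(self.target_ids)
        self.target_ids.append(target_id)
        self._target_seqs.append(seq)
        k = self.wordlength
        words = {seq[i : i + k] for i in range(len(seq) - k + 1)}
        self.unique_word_counts.append(len(words))
        for w in words:
            self._postings.setdefault(w, []).append(ordinal)

    def __len__(self):
        return len(self.target_ids)

    def shared_word_counts(self, query_seq: str,
                           stepwords: int | None = None) -> dict[int, int]:
        """Distinct shared words per target ordinal.

        When ``stepwords`` is given, scanning stops once
        ``stepwords * wordlength`` query positions have been examined
        (the heuristic early-termination cap).
        """
        k = self.wordlength
        limit = len(query_seq) - k + 1
        if stepwords is not None:
            limit = min(limit, stepwords * k)
        counts: dict[int, int] = {}
        seen: set[str] = set()
        for i in range(limit):
            w = query_seq[i : i + k]
            if w in seen:
                continue
            seen.add(w)
            for ordinal in self._postings.get(w, ()):
                counts[ordinal] = counts.get(ordinal, 0) + 1
        return counts


def rank_candidates(query_seq: str, index: KmerIndex,
                    stepwords: int | None = None) -> list[str]:
    """Target ids sharing >= 1 word with the query, best-shared first.

    Sorted by shared distinct-word count descending; ties broken by target
    insertion order. A query shorter than the word length yields no
    candidates.
    """
    ordinals = _rank_ordinals(query_seq, index, stepwords)
    return [index.target_ids[o] for o in ordinals]


def _rank_ordinals(query_seq, index, stepwords=None, include_zero=False):
    counts = index.shared_word_counts(query_seq, stepwords)
    ranked = sorted(counts, key=lambda o: (-counts[o], o))
    if include_zero:
        ranked += [o for o in range(len(index)) if o not in counts]
    return ranked


class _IdentityCache:
    """Memoised identity between query sequences and indexed targets."""

    def __init__(self):
        self._cache: dict[tuple[str, int], float] = {}

    def identity(self, query_seq: str, query_arr, target_key: int,
                 target_arr) -> float:
        key = (query_seq, target_key)
        hit = self._cache.get(key)
        if hit is None:
            m, c = identity_statistics(query_arr, target_arr)
            hit = m / c if c else 0.0
            self._cache[key] = hit
        return hit


def _evaluate(query_seq, query_arr, ordinals, target_arrs, params, cache,
              key_offset=0):
    """Accept/reject scan over ranked candidates.

    Returns (best_ordinal, best_identity) or (None, None). Stops after
    ``max_accepts`` accepts or ``max_rejects`` rejects; among accepts the
    highest identity wins, ties going to the earliest-ranked candidate.
    """
    best_o = None
    best_id = -1.0
    accepts = 0
    rejects = 0
    for o in ordinals:
        ident = cache.identity(query_seq, query_arr, key_offset + o,
                               target_arrs[o])
        if ident >= params.s:
            accepts += 1
            if ident > best_id:
                best_id = ident
                best_o = o
            if accepts >= params.max_accepts:
                break
        else:
            rejects += 1
            if rejects >= params.max_rejects:
                break
    if best_o is None:
        return None, None
    return best_o, best_id


def assign_closed_reference(reads, reference, params: ClusteringParams,
                            workers: int = 1):
    """Assign reads to fixed reference centroids at identity >= s.

    Returns ``(assignments, failures)`` where ``assignments`` maps read id to
    ``(reference_id, identity)`` and ``failures`` lists unassigned read ids
    in input order. The result depends only on each read's sequence, so it
    is invariant to how reads are partitioned across workers; ``workers``
    chunks the input and merging reproduces the serial result exactly.
    """
    reference = list(reference)
    if not reference:
        raise ValueError("closed-reference assignment requires a non-empty "
                         "reference collection")
    reads = list(reads)
    index = KmerIndex(params.wordlength)
    target_arrs = []
    for rec in reference:
        index.add(rec.id, rec.seq)
        target_arrs.append(encode(rec.seq))

    exhaustive = params.is_exhaustive(len(reference))
    stepcap = None if exhaustive else params.stepwords
    cache = _IdentityCache()

    # one decision per distinct sequence; identical reads share it
    by_seq: dict[str, tuple[str, float] | None] = {}
    unique = list(dict.fromkeys(r.seq for r in reads))

    if workers < 1:
        raise ValueError("workers must be >= 1")
    chunk = -(-len(unique) // workers) if unique else 1
    for start in range(0, len(unique), chunk):
        for seq in unique[start : start + chunk]:
            arr = encode(seq)
            ordinals = _rank_ordinals(seq, index, stepcap,
                                      include_zero=exhaustive)
            o, ident = _evaluate(seq, arr, ordinals, target_arrs, params,
                                 cache)
            by_seq[seq] = None if o is None else (index.target_ids[o], ident)

    assignments: dict[str, tuple[str, float]] = {}
    failures: list[str] = []
    for read in reads:
        hit = by_seq[read.seq]
        if hit is None:
            failures.append(read.id)
        else:
            assignments[read.id] = hit
    return assignments, failures


def cluster_de_novo(reads, params: ClusteringParams,
                    id_template: str = "denovo{}",
                    tier: str = TIER_NEW_REFERENCE) -> OtuMap:
    """Greedy de novo clustering of reads, in input order.

    Each read joins the best accepted existing centroid at identity >= s,
    otherwise it founds a new OTU with itself as centroid. OTU ids are
    ``id_template.format(i)`` with ``i`` counting from 0 in founding order.
    This stage is inherently serial: later reads must see OTUs founded by
    earlier ones.
    """
    reads = list(reads)
    otu_map = OtuMap()
    index = KmerIndex(params.wordlength)
    target_arrs: list = []
    centroid_reads: list = []
    cache = _IdentityCache()

    for read in reads:
        n_targets = len(index)
        exhaustive = params.is_exhaustive(n_targets) if n_targets else True
        stepcap = None if exhaustive else params.stepwords
        arr = encode(read.seq)
        ordinals = _rank_ordinals(read.seq, index, stepcap,
                                  include_zero=exhaustive)
        o, _ = _evaluate(read.seq, arr, ordinals, target_arrs, params, cache)
        if o is None:
            otu_id = id_template.format(len(otu_map))
            otu_map.add_otu(otu_id, [read.id], centroid_id=read.id, tier=tier)
            index.add(otu_id, read.seq)
            target_arrs.append(arr)
            centroid_reads.append(read)
        else:
            otu_map.append_member(index.target_ids[o], read.id)
    return otu_map
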