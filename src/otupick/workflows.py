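"""OTU picking workflows.

Four protocols over demultiplexed, quality-filtered amplicon reads:

* **de novo** — greedy clustering of the reads against themselves;
* **closed-reference** — reads are assigned to pre-existing reference
  centroids at identity >= s; non-matching reads are discarded;
* **classic open-reference** — a closed-reference pass, then one serial de
  novo pass over *all* reads that failed to match the reference;
* **subsampled open-reference** — the performance-oriented variant: after
  the closed-reference pass, only a small random fraction n of the failures
  is clustered de novo; the resulting centroids become "new reference"
  OTUs, the remaining failures are matched against them closed-reference
  (a parallelisable step), and whatever still fails is mopped up by a final
  de novo pass ("clean-up" OTUs).

Every workflow returns an :class:`OtuResult` with the tiered OTU map, the
full and min-count-filtered OTU tables, the newly minted centroids, and the
ids of any reads discarded before table construction. With a fixed seed the
whole pipeline is deterministic, and identical across worker counts because
only the embarrassingly parallel closed-reference stages are ever split.

An optional pre-filter (off by default) discards reads with no reference
match at a permissive identity (legacy value 0.60) before clustering, to
remove non-marker contaminants such as host genomic sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .cluster import (TIER_CLEANUP, TIER_NEW_REFERENCE, TIER_REFERENCE,
                      ClusteringParams, OtuMap, assign_closed_reference,
                      cluster_de_novo)
from .io import SampleAssignment, SequenceRecord
from .tables import OtuTable, build_table, filter_min_count

__all__ = [
    "NEW_REFERENCE_PREFIX",
    "CLEANUP_PREFIX",
    "WorkflowParams",
    "OtuResult",
    "prefilter_reads",
    "subsample_failures",
    "pick_de_novo",
    "pick_closed_reference",
    "pick_classic_open_reference",
    "pick_subsampled_open_reference",
    "iterative_update_reference",
    "filter_min_count",
]

#: naming conventions for OTUs minted outside the reference collection
NEW_REFERENCE_PREFIX = "New.ReferenceOTU"
CLEANUP_PREFIX = "New.CleanUpReferenceOTU"


@dataclass(frozen=True)
class WorkflowParams:
    """Knobs shared by the OTU picking workflows.

    subsample_fraction
        Fraction n of closed-reference failures clustered de novo to mint
        new reference centroids (default 0.001, i.e. 0.1%).
    min_otu_size
        Threshold c for the filtered table; OTUs observed fewer than c
        times in total are dropped (default 2: singletons excluded).
    prefilter_identity
        Permissive identity for the contaminant pre-filter, or ``None``
        (default) to skip it; the legacy value is 0.60.
    """

    clustering: ClusteringParams = field(default_factory=ClusteringParams)
    subsample_fraction: float = 0.001
    min_otu_size: int = 2
    prefilter_identity: float | None = None
    seed: int = 0
    workers: int = 1

    def __post_init__(self):
        if not 0 <= self.subsample_fraction <= 1:
            raise ValueError("subsample_fraction must be in [0, 1]")
        if self.min_otu_size < 0:
            raise ValueError("min_otu_size must be >= 0")
        if self.workers < 1:
            raise ValueError("workers must be >= 1")
        if self.prefilter_identity is not None:
            if not 0 <= self.prefilter_identity <= 1:
                raise ValueError("prefilter_identity must be in [0, 1]")
            if self.prefilter_identity > self.clustering.s:
                raise ValueError(
                    "prefilter identity must not exceed the clustering "
                    "threshold s")


@dataclass
class OtuResult:
    """Output bundle of one OTU picking run."""

    otu_map: OtuMap
    table_full: OtuTable
    table_filtered: OtuTable
    new_centroids: list[SequenceRecord]
    prefilter_discards: list[str]

    def tier_otu_ids(self, tier: str) -> list[str]:
        return [o for o, t in self.otu_map.tiers.items() if t == tier]

    @property
    def n_new_tier_otus(self) -> int:
        return len(self.tier_otu_ids(TIER_NEW_REFERENCE)) + \
            len(self.tier_otu_ids(TIER_CLEANUP))


def prefilter_reads(reads, reference, identity: float = 0.60,
                    params: WorkflowParams | None = None):
    """Split reads into (kept, discarded) by a permissive reference search.

    A read is kept iff it matches some reference centroid at >= ``identity``.
    Runs through the closed-reference engine, so it inherits partition
    invariance across workers.
    """
    params = params or WorkflowParams()
    screen = replace(params.clustering, s=identity) if identity > 0 else None
    if screen is None:
        return list(reads), []
    assignments, failures = assign_closed_reference(
        reads, reference, screen, workers=params.workers)
    failed = set(failures)
    kept = [r for r in reads if r.id not in failed]
    discarded = [r.id for r in reads if r.id in failed]
    return kept, discarded


def subsample_failures(failures, fraction: float, seed):
    """Uniform random subsample (without replacement) of the failure reads.

    The subsample size is ``round_half_up(len(failures) * fraction)``,
    floored at 1 whenever there are failures and ``fraction > 0`` so the
    de novo seeding stage is never vacuously empty. Both returned lists
    preserve the input order; together they partition the input.
    """
    if not 0 <= fraction <= 1:
        raise ValueError("fraction must be in [0, 1]")
    failures = list(failures)
    n = len(failures)
    if n == 0 or fraction == 0:
        return [], failures
    k = int(np.floor(n * fraction + 0.5))
    k = max(k, 1)
    k = min(k, n)
    rng = np.random.default_rng(seed)
    chosen = set(rng.choice(n, size=k, replace=False).tolist())
    sub = [failures[i] for i in range(n) if i in chosen]
    rest = [failures[i] for i in range(n) if i not in chosen]
    return sub, rest


def _finalize(otu_map, reads, samples, params, discards, new_centroids,
              taxonomy=None) -> OtuResult:
    if samples is None:
        samples = SampleAssignment.from_read_ids([r.id for r in reads])
    table_full = build_table(otu_map, samples, taxonomy=taxonomy)
    table_filtered = filter_min_count(table_full, params.min_otu_size)
    return OtuResult(otu_map, table_full, table_filtered,
                     new_centroids, discards)


def _apply_prefilter(reads, reference, params):
    if params.prefilter_identity is None:
        return list(reads), []
    return prefilter_reads(reads, reference, params.prefilter_identity,
                           params)


def pick_de_novo(reads, params: WorkflowParams | None = None,
                 samples: SampleAssignment | None = None,
                 taxonomy=None) -> OtuResult:
    """De novo OTU picking: greedy clustering of the reads themselves."""
    params = params or WorkflowParams()
    reads = list(reads)
    otu_map = cluster_de_novo(reads, params.clustering,
                              id_template="denovo{}",
                              tier=TIER_NEW_REFERENCE)
    by_id = {r.id: r for r in reads}
    centroids = [SequenceRecord(o, by_id[otu_map.centroids[o]].seq)
                 for o in otu_map.otu_ids]
    return _finalize(otu_map, reads, samples, params, [], centroids,
                     taxonomy)


def pick_closed_reference(reads, reference,
                          params: WorkflowParams | None = None,
                          samples: SampleAssignment | None = None,
                          taxonomy=None) -> OtuResult:
    """Closed-reference OTU picking; non-matching reads are discarded."""
    params = params or WorkflowParams()
    reads = list(reads)
    kept, discards = _apply_prefilter(reads, reference, params)
    assignments, failures = assign_closed_reference(
        kept, reference, params.clustering, workers=params.workers)
    otu_map = _map_from_assignments(assignments, reference)
    discards = discards + failures
    return _finalize(otu_map, kept, samples, params, discards, [], taxonomy)


def _map_from_assignments(assignments, reference, otu_map=None):
    """Reference-tier OTU map in reference order (occupied OTUs only)."""
    members: dict[str, list[str]] = {}
    for rid, (otu_id, _ident) in assignments.items():
        members.setdefault(otu_id, []).append(rid)
    out = otu_map or OtuMap()
    for rec in reference:
        if rec.id in members:
            if rec.id in out:
                for rid in members[rec.id]:
                    out.append_member(rec.id, rid)
            else:
                out.add_otu(rec.id, members[rec.id], centroid_id=rec.id,
                            tier=TIER_REFERENCE)
    return out


def pick_classic_open_reference(reads, reference,
                                params: WorkflowParams | None = None,
                                samples: SampleAssignment | None = None,
                                taxonomy=None) -> OtuResult:
    """Classic open-reference picking.

    A closed-reference pass at s, then one serial de novo pass over all
    failures. The de novo OTUs carry the new-reference tier and naming.
    """
    params = params or WorkflowParams()
    reads = list(reads)
    kept, discards = _apply_prefilter(reads, reference, params)
    assignments, failures = assign_closed_reference(
        kept, reference, params.clustering, workers=params.workers)
    ref_map = _map_from_assignments(assignments, reference)
    by_id = {r.id: r for r in kept}
    failure_reads = [by_id[rid] for rid in failures]
    novo_map = cluster_de_novo(failure_reads, params.clustering,
                               id_template=NEW_REFERENCE_PREFIX + "{}",
                               tier=TIER_NEW_REFERENCE)
    otu_map = ref_map.merged_with(novo_map)
    centroids = [SequenceRecord(o, by_id[novo_map.centroids[o]].seq)
                 for o in novo_map.otu_ids]
    return _finalize(otu_map, kept, samples, params, discards, centroids,
                     taxonomy)


def pick_subsampled_open_reference(reads, reference,
                                   params: WorkflowParams | None = None,
                                   samples: SampleAssignment | None = None,
                                   taxonomy=None) -> OtuResult:
    """Subsampled open-reference OTU picking.

    Stages:

    1. (optional) permissive pre-filter against the reference;
    2. closed-reference pass against the reference at identity s
       (**reference OTUs**);
    3. de novo clustering of a random fraction n of the failures; the
       centroids define **new reference OTUs** (``New.ReferenceOTU<i>``);
    4. closed-reference pass of the remaining failures against those new
       centroids — the parallelisable replacement for most of the serial
       de novo work;
    5. de novo clustering of whatever still fails (**clean-up OTUs**,
       ``New.CleanUpReferenceOTU<i>``).

    The tiers are merged into one OTU map / table; the filtered table drops
    OTUs with total count < ``min_otu_size``.
    """
    params = params or WorkflowParams()
    reads = list(reads)
    if not list(reference):
        raise ValueError("subsampled open-reference picking requires a "
                         "non-empty reference collection")
    kept, discards = _apply_prefilter(reads, reference, params)
    by_id = {r.id: r for r in kept}

    # stage 1: closed reference against the full reference
    assignments, failures = assign_closed_reference(
        kept, reference, params.clustering, workers=params.workers)
    ref_map = _map_from_assignments(assignments, reference)

    # stage 2: de novo over a random subsample of the failures
    sub_ids, rest_ids = subsample_failures(
        failures, params.subsample_fraction, params.seed)
    sub_reads = [by_id[rid] for rid in sub_ids]
    new_map = cluster_de_novo(sub_reads, params.clustering,
                              id_template=NEW_REFERENCE_PREFIX + "{}",
                              tier=TIER_NEW_REFERENCE)
    new_centroids = [SequenceRecord(o, by_id[new_map.centroids[o]].seq)
                     for o in new_map.otu_ids]

    # stage 3: closed reference of the remainder against the new centroids
    rest_reads = [by_id[rid] for rid in rest_ids]
    cleanup_input = rest_reads
    if new_centroids and rest_reads:
        new_assign, new_failures = assign_closed_reference(
            rest_reads, new_centroids, params.clustering,
            workers=params.workers)
        new_map = _map_from_assignments(new_assign, new_centroids,
                                        otu_map=new_map)
        cleanup_input = [by_id[rid] for rid in new_failures]

    # stage 4: final de novo clean-up
    cleanup_map = cluster_de_novo(cleanup_input, params.clustering,
                                  id_template=CLEANUP_PREFIX + "{}",
                                  tier=TIER_CLEANUP)
    cleanup_centroids = [SequenceRecord(o, by_id[cleanup_map.centroids[o]].seq)
                         for o in cleanup_map.otu_ids]

    otu_map = ref_map.merged_with(new_map, cleanup_map)
    return _finalize(otu_map, kept, samples, params, discards,
                     new_centroids + cleanup_centroids, taxonomy)


def iterative_update_reference(reference, result: OtuResult):
    """Append a run's new-tier centroids to the reference collection.

    The appended records keep their ``New.*`` OTU ids, so a later run
    assigns matching reads to the *same* OTU ids through its
    closed-reference tier — the basis of iterative picking on accumulating
    data.
    """
    existing = {rec.id for rec in reference}
    clash = [rec.id for rec in result.new_centroids if rec.id in existing]
    if clash:
        raise ValueError(f"new centroid ids already in reference: {clash}")
    return list(reference) + list(result.new_centroids)
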