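"""Readers and writers for the on-disk artifacts of OTU picking.

Formats:

* FASTA for reads, reference centroid collections and new centroids
  (parsed with scikit-bio; order preserved, ids must be unique, sequences
  uppercase-normalised DNA over ``ACGTN``);
* QIIME-style OTU maps: one OTU per line, tab separated, first field the
  OTU id, remaining fields member read ids;
* OTU tables, either the classic TSV dialect whose header line starts with
  ``#OTU ID`` (optional trailing ``taxonomy`` column) or a minimal sparse
  JSON dialect;
* rooted newick trees (scikit-bio ``TreeNode``; missing branch lengths are
  treated as 0);
* taxonomy maps: ``otu_id<TAB>semicolon-delimited lineage``.

Sample membership is recovered from read ids of the QIIME demultiplexing
convention ``<sampleid>_<serial>`` (split at the *last* underscore), unless
an explicit mapping is supplied.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO
from skbio import TreeNode

__all__ = [
    "SequenceRecord",
    "SampleAssignment",
    "read_fasta",
    "write_fasta",
    "read_otu_map",
    "write_otu_map",
    "read_otu_table",
    "write_otu_table",
    "read_newick",
    "write_newick",
    "read_taxonomy",
    "write_taxonomy",
]

_VALID = set("ACGTN")


@dataclass(frozen=True)
class SequenceRecord:
    """A single read or centroid: an id token plus an uppercase DNA string."""

    id: str
    seq: str

    def __post_init__(self):
        if not self.id or any(ch.isspace() for ch in self.id):
            raise ValueError(f"invalid sequence id {self.id!r}")
        if not self.seq:
            raise ValueError(f"empty sequence for id {self.id!r}")
        seq = self.seq.upper()
        if seq != self.seq:
            object.__setattr__(self, "seq", seq)
        bad = set(seq) - _VALID
        if bad:
            raise ValueError(
                f"sequence {self.id!r} contains non-DNA characters {sorted(bad)}"
            )

    def __len__(self):
        return len(self.seq)


class SampleAssignment:
    """Total mapping of read ids to sample ids."""

    def __init__(self, mapping: dict[str, str]):
        self._map = dict(mapping)

    @classmethod
    def from_read_ids(cls, read_ids) -> "SampleAssignment":
        """Infer samples from ``<sampleid>_<serial>`` ids (last underscore)."""
        mapping = {}
        for rid in read_ids:
            if "_" not in rid:
                raise ValueError(
                    f"read id {rid!r} has no '_' separator; supply an explicit "
                    "sample mapping"
                )
            mapping[rid] = rid.rsplit("_", 1)[0]
        return cls(mapping)

    @classmethod
    def from_file(cls, path) -> "SampleAssignment":
        mapping = {}
        with open(path) as fh:
            for ln, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line:
                    continue
                parts = line.split("\t")
                if len(parts) != 2:
                    raise ValueError(f"{path}:{ln}: expected 2 fields")
                mapping[parts[0]] = parts[1]
        return cls(mapping)

    def sample_of(self, read_id: str) -> str:
        try:
            return self._map[read_id]
        except KeyError:
            raise KeyError(f"read {read_id!r} has no sample assignment") from None

    def __contains__(self, read_id):
        return read_id in self._map

    def __len__(self):
        return len(self._map)

    @property
    def sample_ids(self) -> list[str]:
        """Distinct sample ids in first-appearance order."""
        seen = dict.fromkeys(self._map.values())
        return list(seen)


def read_fasta(path) -> list[SequenceRecord]:
    """Read a FASTA file into records, preserving file order.

    Duplicate ids and empty sequences are hard errors (clustering is order-
    and identity-dependent, so silently repairing input would be unsafe).
    """
    records = []
    seen = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append(SequenceRecord(rec.id, str(rec.seq)))
    return records


def write_fasta(records, path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n{rec.seq}\n")


def write_otu_map(otu_map, path) -> None:
    """Write a QIIME-style OTU map: ``otu_id<TAB>read1<TAB>read2...``."""
    with open(path, "w") as fh:
        for otu_id, members in otu_map.items():
            fh.write("\t".join([otu_id, *members]) + "\n")


def read_otu_map(path):
    from .cluster import OtuMap

    otu_map = OtuMap()
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(
                    f"{path}:{ln}: malformed OTU map line (fewer than 2 fields)"
                )
            otu_map.add_otu(fields[0], fields[1:])
    return otu_map


def write_otu_table(table, path, dialect: str = "classic_tsv") -> None:
    if dialect == "classic_tsv":
        _write_table_tsv(table, path)
    elif dialect == "json":
        _write_table_json(table, path)
    else:
        raise ValueError(f"unknown OTU table dialect {dialect!r}")


def _write_table_tsv(table, path):
    with_tax = table.taxonomy is not None
    with open(path, "w") as fh:
        header = ["#OTU ID", *table.sample_ids]
        if with_tax:
            header.append("taxonomy")
        fh.write("\t".join(header) + "\n")
        for otu_id in table.otu_ids:
            row = [otu_id] + [str(int(v)) for v in table.data.loc[otu_id]]
            if with_tax:
                row.append(table.taxonomy.get(otu_id, "Unassigned"))
            fh.write("\t".join(row) + "\n")


def _write_table_json(table, path):
    rows, cols, vals = [], [], []
    mat = table.data.to_numpy()
    for i in range(mat.shape[0]):
        for j in range(mat.shape[1]):
            if mat[i, j]:
                rows.append(i)
                cols.append(j)
                vals.append(int(mat[i, j]))
    payload = {
        "otu_ids": list(table.otu_ids),
        "sample_ids": list(table.sample_ids),
        "shape": [len(table.otu_ids), len(table.sample_ids)],
        "data": [rows, cols, vals],
    }
    if table.taxonomy is not None:
        payload["taxonomy"] = dict(table.taxonomy)
    with open(path, "w") as fh:
        json.dump(payload, fh)


def read_otu_table(path, dialect: str | None = None):
    from .tables import OtuTable

    path = Path(path)
    if dialect is None:
        with open(path) as fh:
            first = fh.read(1)
        dialect = "json" if first == "{" else "classic_tsv"
    if dialect == "json":
        with open(path) as fh:
            payload = json.load(fh)
        import numpy as np

        mat = np.zeros(payload["shape"], dtype=np.int64)
        for i, j, v in zip(*payload["data"]):
            _check_count(v, path)
            mat[i, j] = v
        return OtuTable(
            mat,
            payload["otu_ids"],
            payload["sample_ids"],
            taxonomy=payload.get("taxonomy"),
        )
    if dialect != "classic_tsv":
        raise ValueError(f"unknown OTU table dialect {dialect!r}")

    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if not header or header[0] != "#OTU ID":
            raise ValueError(f"{path}: classic OTU table must start with '#OTU ID'")
        has_tax = header[-1].lower() == "taxonomy"
        sample_ids = header[1:-1] if has_tax else header[1:]
        otu_ids, counts = [], []
        taxonomy = {} if has_tax else None
        for ln, line in enumerate(fh, 2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            expect = 1 + len(sample_ids) + (1 if has_tax else 0)
            if len(fields) != expect:
                raise ValueError(f"{path}:{ln}: expected {expect} fields")
            otu_ids.append(fields[0])
            vals = fields[1 : 1 + len(sample_ids)]
            counts.append([_check_count(v, path, ln) for v in vals])
            if has_tax:
                taxonomy[fields[0]] = fields[-1]
    import numpy as np

    mat = np.array(counts, dtype=np.int64).reshape(len(otu_ids), len(sample_ids))
    return OtuTable(mat, otu_ids, sample_ids, taxonomy=taxonomy)


def _check_count(value, path, ln=None):
    where = f"{path}:{ln}" if ln else str(path)
    try:
        f = float(value)
    except ValueError:
        raise ValueError(f"{where}: non-numeric count {value!r}") from None
    if f != int(f):
        raise ValueError(f"{where}: non-integer count {value!r}")
    if f < 0:
        raise ValueError(f"{where}: negative count {value!r}")
    return int(f)


def read_newick(path) -> TreeNode:
    """Read a rooted newick tree; missing branch lengths become 0."""
    tree = TreeNode.read(str(path), format="newick")
    tips = [t.name for t in tree.tips()]
    if len(tips) != len(set(tips)):
        raise ValueError(f"{path}: duplicate tip labels")
    for node in tree.traverse(include_self=True):
        if node.length is None:
            node.length = 0.0
    return tree


def write_newick(tree: TreeNode, path) -> None:
    tree.write(str(path), format="newick")


def read_taxonomy(path) -> dict[str, str]:
    taxonomy = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ValueError(f"{path}:{ln}: expected 'otu_id<TAB>lineage'")
            taxonomy[fields[0]] = fields[1]
    return taxonomy


def write_taxonomy(taxonomy: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        for otu_id, lineage in taxonomy.items():
            fh.write(f"{otu_id}\t{lineage}\n")
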