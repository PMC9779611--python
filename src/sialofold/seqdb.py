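"""Sequence database IO: FASTA, annotation tables, family tabulation.

The database is a flat set of secreted-protein records.  Each record may
carry a family/subgroup annotation and one or more cluster identifiers of
the form ``"<identity>-<index>"`` where the identity threshold is one of
25, 30, ..., 95 percent and the index is a 1-based rank.
"""

from __future__ import annotations

import os
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

__all__ = [
    "VALID_RESIDUES",
    "CLUSTER_THRESHOLDS",
    "SequenceRecord",
    "ClusterID",
    "FamilyTable",
    "SeqDBError",
    "read_fasta",
    "write_fasta",
    "read_annotation_table",
    "family_counts",
    "parse_cluster_id",
    "format_cluster_id",
]

#: Accepted amino-acid alphabet (20 standard residues plus the mask X).
VALID_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWYX")

#: Identity thresholds used by the cluster-ID scheme.
CLUSTER_THRESHOLDS = frozenset(range(25, 100, 5))

UNANNOTATED = "unannotated"


class SeqDBError(ValueError):
    """Raised for malformed sequence-database inputs."""


@dataclass(frozen=True, order=True)
class ClusterID:
    """A cluster identifier: identity threshold (%) and 1-based index."""

    identity_threshold: int
    cluster_index: int

    def __post_init__(self) -> None:
        if self.identity_threshold not in CLUSTER_THRESHOLDS:
            raise SeqDBError(
                f"identity threshold {self.identity_threshold} not in "
                f"{sorted(CLUSTER_THRESHOLDS)}"
            )
        if self.cluster_index < 1:
            raise SeqDBError(f"cluster index must be >= 1, got {self.cluster_index}")


@dataclass
class SequenceRecord:
    """One secreted-protein entry of the database."""

    record_id: str
    sequence: str
    description: str = ""
    family: str = ""
    subgroup: str = ""
    cluster_ids: list[ClusterID] = field(default_factory=list)
    disintegrin_flag: bool = False
    species: str = ""

    def __post_init__(self) -> None:
        if not self.record_id:
            raise SeqDBError("record_id must be non-empty")
        if not self.sequence:
            raise SeqDBError(f"record {self.record_id!r}: empty sequence")
        bad = set(self.sequence) - VALID_RESIDUES
        if bad:
            raise SeqDBError(
                f"record {self.record_id!r}: illegal residue character(s) "
                f"{''.join(sorted(bad))!r}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class FamilyTable:
    """Per-family record counts; unannotated records are counted too."""

    counts: dict[str, int]
    total: int

    def __getitem__(self, family: str) -> int:
        return self.counts.get(family, 0)


def parse_cluster_id(text: str) -> ClusterID:
    """Parse ``"<threshold>-<index>"`` into a :class:`ClusterID`.

    An optional non-numeric prefix (e.g. a genus tag such as ``"Amb-"``)
    before the threshold is tolerated and ignored.
    """
    parts = str(text).strip().split("-")
    if len(parts) >= 3 and parts[0] and not parts[0].isdigit():
        parts = parts[1:]  # genus-prefixed form like "Amb-25-357"
    if len(parts) != 2 or not parts[0].isdigit() or not parts[1].isdigit():
        raise SeqDBError(f"malformed cluster id {text!r}; expected '<int>-<int>'")
    return ClusterID(int(parts[0]), int(parts[1]))


def format_cluster_id(cid: ClusterID) -> str:
    return f"{cid.identity_threshold}-{cid.cluster_index}"


def read_fasta(path: str | os.PathLike) -> list[SequenceRecord]:
    """Read a FASTA file into validated records.

    The header token before the first whitespace becomes the record id;
    the rest of the header line is the description.  Sequences are
    uppercased; illegal residues raise :class:`SeqDBError`.
    """
    path = Path(path)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    header: str | None = None
    chunks: list[str] = []

    def flush() -> None:
        if header is None:
            return
        fields = header.split(None, 1)
        rid = fields[0]
        if rid in seen:
            raise SeqDBError(f"duplicate record id {rid!r} in {path}")
        seen.add(rid)
        records.append(
            SequenceRecord(
                record_id=rid,
                description=fields[1].strip() if len(fields) > 1 else "",
                sequence="".join(chunks).upper(),
            )
        )

    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                flush()
                header = line[1:].strip()
                chunks = []
            elif line.strip():
                if header is None:
                    raise SeqDBError(f"{path}: sequence data before first header")
                chunks.append(line.strip())
    flush()
    if not records:
        raise SeqDBError(f"{path}: no FASTA entries found")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | os.PathLike, width: int = 60) -> None:
    """Write records as FASTA, preserving order, ids and sequences."""
    with open(path, "w") as fh:
        for rec in records:
            head = rec.record_id if not rec.description else f"{rec.record_id} {rec.description}"
            fh.write(f">{head}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


_TRUEISH = {"1", "true", "yes", "y", "t"}


def _flaggish(value) -> bool:
    """Non-empty / true-like cell rule for the disintegrin column."""
    if value is None:
        return False
    if isinstance(value, bool):
        return value
    if isinstance(value, float) and value != value:  # NaN
        return False
    text = str(value).strip()
    if not text:
        return False
    if text.lower() in {"0", "false", "no", "n", "f", "nan", "none"}:
        return False
    return True


def read_annotation_table(
    path: str | os.PathLike,
    column_map: Mapping[str, str],
) -> list[SequenceRecord]:
    """Read an annotation spreadsheet (XLSX or TSV) into records.

    ``column_map`` maps logical names to actual column headers.  Required
    keys: ``id``.  Optional keys: ``family``, ``subgroup``, ``disintegrin``,
    ``sequence``, ``species``, ``cluster``.  When no ``sequence`` column is
    mapped, a placeholder single-residue sequence is stored so records
    remain valid for tabulation-only workflows.
    """
    import pandas as pd

    path = Path(path)
    if path.suffix.lower() in {".xlsx", ".xlsm"}:
        df = pd.read_excel(path, dtype=object)
    else:
        df = pd.read_csv(path, sep="\t", dtype=object)

    headers = list(df.columns)
    for logical, header in column_map.items():
        if header not in headers:
            raise SeqDBError(
                f"mapped column {header!r} (for {logical!r}) not found; "
                f"available headers: {headers}"
            )
    if "id" not in column_map:
        raise SeqDBError("column_map must map the 'id' column")

    def cell(row, key: str) -> str:
        if key not in column_map:
            return ""
        v = row[column_map[key]]
        if v is None or (isinstance(v, float) and v != v):
            return ""
        return str(v).strip()

    records: list[SequenceRecord] = []
    for _, row in df.iterrows():
        rid = cell(row, "id")
        if not rid:
            continue
        seq = cell(row, "sequence").upper() or "X"
        clusters: list[ClusterID] = []
        raw_cluster = cell(row, "cluster")
        if raw_cluster:
            for token in raw_cluster.replace(";", ",").split(","):
                token = token.strip()
                if token:
                    clusters.append(parse_cluster_id(token))
        records.append(
            SequenceRecord(
                record_id=rid,
                sequence=seq,
                family=cell(row, "family"),
                subgroup=cell(row, "subgroup"),
                species=cell(row, "species"),
                cluster_ids=clusters,
                disintegrin_flag=_flaggish(
                    row[column_map["disintegrin"]] if "disintegrin" in column_map else None
                ),
            )
        )
    return records


def family_counts(records: Sequence[SequenceRecord]) -> FamilyTable:
    """Tabulate records per family label (trimmed, case-sensitive).

    Records with an empty family label are counted under ``"unannotated"``.
    The counts always sum to the number of records.
    """
    counter: Counter[str] = Counter()
    for rec in records:
        label = rec.family.strip() or UNANNOTATED
        counter[label] += 1
    return FamilyTable(counts=dict(counter), total=len(records))
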