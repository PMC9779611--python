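"""Structural-search hit tables, Z-score banding and family-reassignment
rules.

Z-score bands follow the Dali manual convention; bands are implemented as
half-open intervals because the prose intervals share endpoints::

    homologous            z in [20, inf)
    probably_homologous   z in [8, 20)
    gray                  z in [2, 8)
    not_significant       z in (-inf, 2)
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from .prosite import MotifHit
from .seqdb import SequenceRecord

__all__ = [
    "DaliHit",
    "ZBAND_ORDER",
    "zband",
    "parse_hit_table",
    "best_hit",
    "CategoryConfig",
    "categorize",
    "FamilyAssignment",
    "classify",
    "classify_batch",
    "rename_motif",
    "MOTIF_RENAMES",
]


@dataclass(frozen=True)
class DaliHit:
    query_id: str
    target_pdb: str  # "4q1l-A" style: 4-char PDB id + chain
    z: float
    rmsd: float
    lali: int
    pct_id: float
    description: str = ""

    def __post_init__(self) -> None:
        if not math.isfinite(self.z):
            raise ValueError(f"non-finite Z score for {self.query_id!r}")
        if self.lali < 0:
            raise ValueError(f"negative aligned length for {self.query_id!r}")


ZBAND_ORDER = ("not_significant", "gray", "probably_homologous", "homologous")
_ZBAND_RANK = {name: i for i, name in enumerate(ZBAND_ORDER)}


def zband(z: float) -> str:
    """Map a finite Z score to its significance band."""
    if not math.isfinite(z):
        raise ValueError(f"Z score must be finite, got {z}")
    if z >= 20:
        return "homologous"
    if z >= 8:
        return "probably_homologous"
    if z >= 2:
        return "gray"
    return "not_significant"


def band_at_least(band: str, floor: str) -> bool:
    return _ZBAND_RANK[band] >= _ZBAND_RANK[floor]


def parse_hit_table(source: str | os.PathLike) -> list[DaliHit]:
    """Parse a structural-search hit table.

    Two dialects are accepted: a strict TSV with a header row
    (query_id, target, z, rmsd, lali, pct_id, description) and a lenient
    whitespace-separated form with the same column order and no header.
    ``source`` may be a path or the table text itself.
    """
    if isinstance(source, (str, Path)) and "\n" not in str(source) and Path(source).exists():
        text = Path(source).read_text()
    else:
        text = str(source)

    lines = [ln for ln in text.splitlines() if ln.strip() and not ln.lstrip().startswith("#")]
    if not lines:
        return []

    hits: list[DaliHit] = []
    first = lines[0].lower()
    strict = "query" in first and ("\t" in lines[0] or "z" in first.split())
    body = lines[1:] if strict else lines
    for lineno, line in enumerate(body, start=2 if strict else 1):
        fields = line.split("\t") if "\t" in line else line.split(None, 6)
        if len(fields) < 6:
            raise ValueError(f"hit table line {lineno}: expected ≥6 fields, got {len(fields)}")
        try:
            hits.append(
                DaliHit(
                    query_id=fields[0].strip(),
                    target_pdb=fields[1].strip(),
                    z=float(fields[2]),
                    rmsd=float(fields[3]),
                    lali=int(float(fields[4])),
                    pct_id=float(fields[5]),
                    description=fields[6].strip() if len(fields) > 6 else "",
                )
            )
        except ValueError as exc:
            raise ValueError(f"hit table line {lineno}: {exc}") from None
    return hits


def best_hit(hits: Sequence[DaliHit]) -> DaliHit:
    """Highest-Z hit; ties broken by lower RMSD, then target id."""
    if not hits:
        raise ValueError("best_hit of an empty hit list")
    return min(hits, key=lambda h: (-h.z, h.rmsd, h.target_pdb))


# ---------------------------------------------------------------------------
# Target categorization
# ---------------------------------------------------------------------------

#: Bacterial pore-forming toxin PDB entries matched by the cytotoxin group.
BACTERIAL_PORE_PDB = frozenset(
    {"2d42-A", "4rhz-A", "3zjx-A", "2ztb-B", "7ml9-A", "6lh8-A", "1w3a-A"}
)

_DEFAULT_KEYWORDS: dict[str, tuple[str, ...]] = {
    "metalloprotease": (
        "metalloprotease",
        "metalloproteinase",
        "adamalysin",
        "reprolysin",
        "leucurolysin",
        "adam",
        "adamts",
    ),
    "lipocalin": ("lipocalin", "histamine binding", "histamine-binding", "jacalin"),
    "ml_domain": ("niemann-pick", "niemann pick", "npc2", "ml domain", "der p 2", "der f 2"),
    "bacterial_pore_toxin": (
        "epsilon-toxin",
        "crystal protein",
        "aerolysin",
        "hemolytic lectin",
        "insecticidal",
        "pore-forming",
    ),
    "der_f7_jhbp": ("der f 7", "juvenile hormone binding", "jhbp"),
    "sulfotransferase": ("sulfotransferase",),
    "evasin": ("evasin",),
    "kunitz": ("kunitz", "bpti", "trypsin inhibitor"),
}

_DEFAULT_PDB_IDS: dict[str, frozenset[str]] = {
    "metalloprotease": frozenset({"4q1l-A"}),
    "bacterial_pore_toxin": BACTERIAL_PORE_PDB,
}


@dataclass
class CategoryConfig:
    """Keyword + PDB-id map driving deterministic target categorization.

    The map is data, not code: users may load their own from a key-value
    config file (see :func:`sialofold.cli.load_config`).
    """

    keywords: dict[str, tuple[str, ...]] = field(default_factory=lambda: dict(_DEFAULT_KEYWORDS))
    pdb_ids: dict[str, frozenset[str]] = field(default_factory=lambda: dict(_DEFAULT_PDB_IDS))

    def categorize(self, hit: DaliHit) -> str:
        for category, ids in self.pdb_ids.items():
            if hit.target_pdb in ids:
                return category
        desc = hit.description.lower()
        for category, words in self.keywords.items():
            if any(w in desc for w in words):
                return category
        return "other"


def categorize(hit: DaliHit, config: CategoryConfig | None = None) -> str:
    return (config or CategoryConfig()).categorize(hit)


# ---------------------------------------------------------------------------
# Reassignment rules
# ---------------------------------------------------------------------------


@dataclass
class FamilyAssignment:
    query_id: str
    old_family: str
    new_group: str
    new_subgroup: str
    rule_id: str
    evidence: dict

    def row(self) -> dict:
        return {
            "query_id": self.query_id,
            "old_family": self.old_family,
            "new_group": self.new_group,
            "new_subgroup": self.new_subgroup,
            "rule_id": self.rule_id,
            "best_target": self.evidence.get("best_target", ""),
            "z": self.evidence.get("z", ""),
            "band": self.evidence.get("band", ""),
        }


UNASSIGNED_GROUP = "no significant structural match"


def classify(
    record: SequenceRecord,
    hits: Sequence[DaliHit],
    motif_hits: Sequence[MotifHit] = (),
    config: CategoryConfig | None = None,
) -> FamilyAssignment:
    """Apply the reassignment rules to one query; first match fires.

    Rule order: R1 metalloproteoid (metalloprotease fold, zinc motif
    absent), R2 metalloprotease (motif present), R3 cytotoxin, R4
    Der f 7/JHBP, R5 Niemann-Pick, R6 lipocalin, R6b sulfotransferase,
    R7 unassigned fall-through.
    """
    cfg = config or CategoryConfig()
    zinc_present = any(h.pattern_id == "ZINC_BINDING" for h in motif_hits)
    subgroup = record.family.strip() or "unspecified"

    best: DaliHit | None = best_hit(hits) if hits else None
    evidence: dict = {"zinc_motif": zinc_present}
    if best is not None:
        band = zband(best.z)
        category = cfg.categorize(best)
        evidence.update(
            best_target=best.target_pdb,
            z=best.z,
            band=band,
            category=category,
            description=best.description,
        )

        if category == "metalloprotease" and band_at_least(band, "probably_homologous"):
            group = "Metalloprotease" if zinc_present else "Metalloproteoid"
            rule = "R2" if zinc_present else "R1"
            return FamilyAssignment(record.record_id, record.family, group, subgroup, rule, evidence)
        if best.target_pdb in cfg.pdb_ids.get("bacterial_pore_toxin", frozenset()) and best.z >= 10:
            return FamilyAssignment(
                record.record_id, record.family, "Cytotoxin", subgroup, "R3", evidence
            )
        if category == "der_f7_jhbp" and best.z > 10:
            return FamilyAssignment(
                record.record_id, record.family, "Der f 7 allergen/JHBP", subgroup, "R4", evidence
            )
        if category == "ml_domain" and best.z > 12:
            return FamilyAssignment(
                record.record_id, record.family, "Niemann-Pick", subgroup, "R5", evidence
            )
        if category == "lipocalin" and band_at_least(band, "probably_homologous"):
            return FamilyAssignment(
                record.record_id, record.family, "Lipocalin", subgroup, "R6", evidence
            )
        if category == "sulfotransferase" and band_at_least(band, "gray"):
            return FamilyAssignment(
                record.record_id, record.family, "Sulfotransferase", subgroup, "R6b", evidence
            )
    return FamilyAssignment(
        record.record_id, record.family, UNASSIGNED_GROUP, subgroup, "R7", evidence
    )


def classify_batch(
    records: Sequence[SequenceRecord],
    hits_by_query: Mapping[str, Sequence[DaliHit]],
    motifs_by_query: Mapping[str, Sequence[MotifHit]] | None = None,
    config: CategoryConfig | None = None,
) -> list[FamilyAssignment]:
    motifs_by_query = motifs_by_query or {}
    return [
        classify(
            rec,
            hits_by_query.get(rec.record_id, ()),
            motifs_by_query.get(rec.record_id, ()),
            config,
        )
        for rec in records
    ]


# ---------------------------------------------------------------------------
# Motif-model rename ledger
# ---------------------------------------------------------------------------

#: Static PSSM-model rename table established by the structural review.
MOTIF_RENAMES: dict[str, str] = {
    "40-800": "Kunitz",
    "40-584": "acid tail",
    "35-53": "Lipocalin",
    "Rapp-25-325": "cystatin",
    "25-159": "Cytochrome_B2",
    # metalloprotease models found to identify zinc-motif-free sequences
    "30-49": "Metalloproteoid",
    "30-561": "Metalloproteoid",
    "30-93": "Metalloproteoid",
    "35-121": "Metalloproteoid",
    "35-167": "Metalloproteoid",
    "35-414": "Metalloproteoid",
    "35-415": "Metalloproteoid",
    "35-768": "Metalloproteoid",
    "35-77": "Metalloproteoid",
    "50-341": "Metalloproteoid",
}


def rename_motif(motif_model_id: str) -> tuple[str, bool]:
    """Map a PSSM model id to its revised family label.

    Returns ``(label, known)``; unknown ids map to themselves with
    ``known=False`` so callers can emit a notice.
    """
    key = motif_model_id.strip()
    if key in MOTIF_RENAMES:
        return MOTIF_RENAMES[key], True
    return key, False
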