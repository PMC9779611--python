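"""Disintegrin candidate screen.

A candidate is an integrin-binding triad (RGD/KGD/KTS/RTS/RED) that sits
on a cysteine-stabilised hairpin protruding from the protein body:

- a cysteine within ``window`` residues on each side of the triad must
  form a disulfide bridge (checked against the detected topology), and
- the triad Cα centroid must protrude from the chain: its distance from
  the whole-chain Cα centroid, expressed as a z-score over the
  per-residue centroid distances, must reach ``protrusion_threshold``.

The protrusion measure is rigid-motion invariant by construction.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .disulfide import DisulfideTopology, detect_bonds
from .prosite import MotifHit, MotifLibrary, disintegrin_library, scan_sequence
from .seqdb import SequenceRecord
from .structmodel import StructureModel

__all__ = ["DisintegrinCandidate", "find_candidates", "batch_screen", "protrusion_zscore"]


@dataclass
class DisintegrinCandidate:
    record_id: str
    triad: str
    triad_start: int  # 1-based
    flank_before: int | None
    flank_after: int | None
    bridge_bonded: bool
    protrusion_z: float
    hairpin: bool
    rank_score: float
    model_missing: bool = False

    def row(self) -> dict:
        return {
            "record_id": self.record_id,
            "triad": self.triad,
            "triad_start": self.triad_start,
            "flank_before": self.flank_before if self.flank_before is not None else "",
            "flank_after": self.flank_after if self.flank_after is not None else "",
            "bridge_bonded": self.bridge_bonded,
            "protrusion_z": round(self.protrusion_z, 3) if math.isfinite(self.protrusion_z) else "",
            "hairpin": self.hairpin,
            "rank_score": round(self.rank_score, 3),
        }


def protrusion_zscore(chain_ca: np.ndarray, triad_indices: Sequence[int]) -> float:
    """Z-score of the triad centroid distance among per-residue distances.

    Distances are measured from the whole-chain Cα centroid; the score is
    ``(d_triad − mean(d_i)) / sd(d_i)`` with the population sd.
    """
    coords = np.asarray(chain_ca, dtype=float)
    centroid = coords.mean(axis=0)
    dists = np.linalg.norm(coords - centroid, axis=1)
    sd = float(dists.std())
    if sd == 0.0:
        return 0.0
    triad_centroid = coords[list(triad_indices)].mean(axis=0)
    d_triad = float(np.linalg.norm(triad_centroid - centroid))
    return (d_triad - float(dists.mean())) / sd


def _triad_from_hit(hit: MotifHit) -> tuple[str, int]:
    """Extract the 3-letter triad and its 1-based start from a motif hit.

    Flanked patterns match more than the triad; the triad named by the
    pattern id (``DISINTEGRIN_RGD`` → ``RGD``) is located inside the
    matched substring.
    """
    if hit.pattern_id.startswith("DISINTEGRIN_") and len(hit.pattern_id) == 15:
        triad = hit.pattern_id[-3:]
        offset = hit.matched.find(triad)
        if offset >= 0:
            return triad, hit.start + offset
    return hit.matched[:3], hit.start


def find_candidates(
    record: SequenceRecord,
    model: StructureModel | None,
    topology: DisulfideTopology | None,
    motif_hits: Sequence[MotifHit],
    window: int = 10,
    protrusion_threshold: float = 1.5,
) -> list[DisintegrinCandidate]:
    """Evaluate each triad motif hit against the hairpin criterion.

    Without a model the candidate is reported sequence-only (no bridge,
    no hairpin).  A model whose first-chain residue count disagrees with
    the sequence length is an error.
    """
    seq = record.sequence
    cys_positions = [i + 1 for i, aa in enumerate(seq) if aa == "C"]
    ordinal_of = {pos: k + 1 for k, pos in enumerate(cys_positions)}

    chain = None
    chain_ca = None
    if model is not None:
        chain = model.chains[0]
        if len(chain.residues) != len(seq):
            raise ValueError(
                f"model/sequence length mismatch for {record.record_id!r}: "
                f"{len(chain.residues)} residues vs {len(seq)} aa"
            )
        chain_ca = chain.ca_coords()
        if chain_ca.shape[0] != len(seq):
            raise ValueError(f"model for {record.record_id!r} has residues without Cα")

    bond_keys = topology.bond_keys if topology is not None else set()
    if model is not None and topology is None:
        warnings.warn(f"no disulfide data for {record.record_id!r}; bridges unresolved")

    candidates: list[DisintegrinCandidate] = []
    for hit in motif_hits:
        triad, triad_start = _triad_from_hit(hit)
        triad_end = triad_start + len(triad) - 1

        before = [p for p in cys_positions if triad_start - window <= p < triad_start]
        after = [p for p in cys_positions if triad_end < p <= triad_end + window]
        flank_before = max(before) if before else None
        flank_after = min(after) if after else None

        bridge = False
        if flank_before is not None and flank_after is not None and chain is not None:
            key = tuple(
                sorted(
                    (
                        (chain.chain_id, ordinal_of[flank_before]),
                        (chain.chain_id, ordinal_of[flank_after]),
                    )
                )
            )
            bridge = key in bond_keys

        if chain_ca is not None:
            z = protrusion_zscore(chain_ca, range(triad_start - 1, triad_end))
        else:
            z = float("nan")

        hairpin = bool(bridge and math.isfinite(z) and z >= protrusion_threshold)
        candidates.append(
            DisintegrinCandidate(
                record_id=record.record_id,
                triad=triad,
                triad_start=triad_start,
                flank_before=flank_before,
                flank_after=flank_after,
                bridge_bonded=bridge,
                protrusion_z=z,
                hairpin=hairpin,
                rank_score=z if hairpin else 0.0,
                model_missing=model is None,
            )
        )
    return candidates


def batch_screen(
    records: Sequence[SequenceRecord],
    models: Mapping[str, StructureModel] | None = None,
    library: MotifLibrary | None = None,
    window: int = 10,
    protrusion_threshold: float = 1.5,
    cutoff_angstrom: float = 3.0,
):
    """Screen a record set; returns (candidates sorted by rank, summary).

    Records without a model are screened sequence-only and flagged.  The
    summary counts hairpin-confirmed candidates vs motif-only ones.
    """
    library = library or disintegrin_library()
    models = models or {}

    all_candidates: list[DisintegrinCandidate] = []
    for rec in records:
        hits: list[MotifHit] = []
        for pat in library:
            hits.extend(scan_sequence(pat, rec))
        if not hits:
            continue
        model = models.get(rec.record_id)
        topology = detect_bonds(model, cutoff_angstrom) if model is not None else None
        all_candidates.extend(
            find_candidates(rec, model, topology, hits, window, protrusion_threshold)
        )

    all_candidates.sort(key=lambda c: (-c.rank_score, c.record_id, c.triad_start))
    n_hairpin = sum(1 for c in all_candidates if c.hairpin)
    summary = {
        "candidates": len(all_candidates),
        "hairpin_confirmed": n_hairpin,
        "motif_only": len(all_candidates) - n_hairpin,
        "records_flagged": len({c.record_id for c in all_candidates}),
    }
    return all_candidates, summary
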