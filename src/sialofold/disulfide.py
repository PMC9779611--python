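"""Disulfide-bond detection from model coordinates and connectivity
notation rendering/parsing.

Bonds are called from SG–SG distances below a cutoff (default 3.0 Å),
intra- and inter-chain alike.  Cysteine ordinals are 1-based per chain in
sequence order.  Three notations are supported::

    dash        C1-C6, C2-C4, C3-C5          (en-dash accepted on input)
    pipe        |C:1 C:3 |C:2 C:5 |C:4 C:6
    interchain  A:7|B:7  /  A:1|B:8, A:8|B:1

Methionine SD atoms are never considered; only cysteine SG.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .structmodel import StructureModel

__all__ = [
    "NotationError",
    "CysteineSite",
    "DisulfideBond",
    "DisulfideTopology",
    "DimerReport",
    "detect_bonds",
    "parse_notation",
    "render_dash",
    "render_pipe",
    "render_interchain",
    "consensus_topology",
    "dimer_bridge_scan",
]


class NotationError(ValueError):
    """Raised for malformed connectivity notation."""


@dataclass(frozen=True, order=True)
class CysteineSite:
    chain_id: str
    residue_number: int
    ordinal: int
    has_sg: bool = True

    @property
    def key(self) -> tuple[str, int]:
        return (self.chain_id, self.ordinal)


@dataclass(frozen=True)
class DisulfideBond:
    """An unordered bonded cysteine pair; sites stored in sorted order."""

    site_a: CysteineSite
    site_b: CysteineSite
    distance: float

    @property
    def key(self) -> tuple[tuple[str, int], tuple[str, int]]:
        return tuple(sorted((self.site_a.key, self.site_b.key)))  # type: ignore[return-value]

    @property
    def interchain(self) -> bool:
        return self.site_a.chain_id != self.site_b.chain_id


@dataclass
class DisulfideTopology:
    model_id: str
    sites: list[CysteineSite]
    bonds: list[DisulfideBond]
    free: list[CysteineSite]

    @property
    def bond_keys(self) -> set[tuple[tuple[str, int], tuple[str, int]]]:
        return {b.key for b in self.bonds}

    @property
    def intra_bonds(self) -> list[DisulfideBond]:
        return [b for b in self.bonds if not b.interchain]

    @property
    def inter_bonds(self) -> list[DisulfideBond]:
        return [b for b in self.bonds if b.interchain]

    @property
    def notation_dash(self) -> str:
        return render_dash(self)

    @property
    def notation_pipe(self) -> str:
        return render_pipe(self)

    @property
    def notation_interchain(self) -> str:
        return render_interchain(self)

    def check_conservation(self) -> bool:
        """2·bonds + free(SG-bearing) equals the SG-bearing site count."""
        n_sg = sum(1 for s in self.sites if s.has_sg)
        n_free_sg = sum(1 for s in self.free if s.has_sg)
        return 2 * len(self.bonds) + n_free_sg == n_sg


def _collect_sites(model: StructureModel, plddt_floor: float | None):
    """Cysteine sites with SG coordinates; ordinals per chain."""
    sites: list[CysteineSite] = []
    sg_coords: dict[tuple[str, int], np.ndarray] = {}
    for chain in model.chains:
        ordinal = 0
        for res in chain.residues:
            if res.name != "CYS":
                continue
            ordinal += 1
            if plddt_floor is not None:
                p = res.plddt
                if p is not None and p < plddt_floor:
                    continue
            sg = res.atom("SG")
            site = CysteineSite(chain.chain_id, res.number, ordinal, has_sg=sg is not None)
            sites.append(site)
            if sg is not None:
                sg_coords[site.key] = sg.coords
            else:
                warnings.warn(
                    f"cysteine {chain.chain_id}:{res.number} lacks an SG atom; counted free",
                    stacklevel=3,
                )
    return sites, sg_coords


def _match_greedy(pairs):
    """Greedy ascending-distance matching; each site used once."""
    used: set = set()
    chosen = []
    for dist, a, b in sorted(pairs, key=lambda t: (t[0], t[1].key, t[2].key)):
        if a.key in used or b.key in used:
            continue
        used.add(a.key)
        used.add(b.key)
        chosen.append((a, b, dist))
    return chosen


def _match_maxweight(pairs):
    """Maximum-cardinality, then minimum-total-distance matching.

    Candidate graphs at a 3 Å cutoff are tiny, so exhaustive search over
    edge subsets is affordable.
    """
    best: tuple[int, float, list] = (0, 0.0, [])
    edges = sorted(pairs, key=lambda t: (t[0], t[1].key, t[2].key))

    def rec(i: int, used: set, chosen: list, total: float) -> None:
        nonlocal best
        remaining = len(edges) - i
        if len(chosen) + remaining < best[0]:
            return
        if i == len(edges):
            cand = (len(chosen), -total, list(chosen))
            if (cand[0], cand[1]) > (best[0], -best[1]):
                best = (cand[0], total, cand[2])
            return
        dist, a, b = edges[i]
        if a.key not in used and b.key not in used:
            rec(i + 1, used | {a.key, b.key}, chosen + [(a, b, dist)], total + dist)
        rec(i + 1, used, chosen, total)

    rec(0, set(), [], 0.0)
    return best[2]


def detect_bonds(
    model: StructureModel,
    cutoff_angstrom: float = 3.0,
    plddt_floor: float | None = None,
    matching: str = "greedy",
) -> DisulfideTopology:
    """Detect disulfide bonds from all SG–SG distances below the cutoff.

    Conflicting candidates (one SG within cutoff of two partners) are
    resolved by greedy ascending-distance matching with each SG used at
    most once; ``matching="maxweight"`` switches to exact
    maximum-cardinality matching.  A model without cysteines yields an
    empty topology.
    """
    if cutoff_angstrom <= 0:
        raise ValueError(f"cutoff must be > 0, got {cutoff_angstrom}")
    sites, sg = _collect_sites(model, plddt_floor)
    candidates = []
    for a, b in itertools.combinations([s for s in sites if s.has_sg], 2):
        d = float(np.linalg.norm(sg[a.key] - sg[b.key]))
        if d < cutoff_angstrom:
            candidates.append((d, a, b))

    if matching == "greedy":
        chosen = _match_greedy(candidates)
    elif matching == "maxweight":
        chosen = _match_maxweight(candidates)
    else:
        raise ValueError(f"unknown matching mode {matching!r}")

    bonds = [
        DisulfideBond(*sorted((a, b), key=lambda s: s.key), distance=d) for a, b, d in chosen
    ]
    bonds.sort(key=lambda b: b.key)
    bonded_keys = {k for b in bonds for k in (b.site_a.key, b.site_b.key)}
    free = [s for s in sites if s.key not in bonded_keys]
    return DisulfideTopology(model_id=model.model_id, sites=sites, bonds=bonds, free=free)


# ---------------------------------------------------------------------------
# Notations
# ---------------------------------------------------------------------------


def _ordinal_pairs(topology: DisulfideTopology) -> list[tuple[int, int]]:
    pairs = [
        tuple(sorted((b.site_a.ordinal, b.site_b.ordinal)))
        for b in topology.intra_bonds
    ]
    return sorted(pairs)


def render_dash(topology: DisulfideTopology) -> str:
    """Intra-chain bonds as ``"C1-C6, C2-C4, C3-C5"`` (ASCII hyphen)."""
    return ", ".join(f"C{a}-C{b}" for a, b in _ordinal_pairs(topology))


def render_pipe(topology: DisulfideTopology) -> str:
    """Intra-chain bonds as ``"|C:1 C:3 |C:2 C:5 |C:4 C:6"``."""
    return " ".join(f"|C:{a} C:{b}" for a, b in _ordinal_pairs(topology))


def render_interchain(topology: DisulfideTopology) -> str:
    """Inter-chain bonds as ``"A:1|B:8, A:8|B:1"``."""
    pairs = sorted(b.key for b in topology.inter_bonds)
    return ", ".join(f"{a[0]}:{a[1]}|{b[0]}:{b[1]}" for a, b in pairs)


def _parse_site_token(token: str):
    token = token.strip()
    if ":" in token:
        chain, _, num = token.partition(":")
        chain = chain.strip()
        num = num.strip()
        if not chain or not num.isdigit():
            raise NotationError(f"malformed site token {token!r}")
        return (chain, int(num))
    if token.upper().startswith("C") and token[1:].isdigit():
        return int(token[1:])
    raise NotationError(f"malformed site token {token!r}")


def parse_notation(text: str):
    """Parse any supported connectivity notation into a bond set.

    Returns a set of unordered ordinal pairs ``(a, b)`` for plain
    notations, or a set of chain-qualified pairs
    ``((chain, ordinal), (chain, ordinal))`` when chains differ.
    Reuse of an ordinal across pairs is an error.
    """
    text = text.replace("–", "-").replace("—", "-").strip()
    if not text:
        raise NotationError("empty notation")

    raw_pairs: list[tuple] = []
    if text.startswith("|"):
        # pipe notation: groups of two whitespace-separated site tokens
        for group in text.split("|"):
            group = group.strip().rstrip(",")
            if not group:
                continue
            tokens = group.split()
            if len(tokens) != 2:
                raise NotationError(f"pipe group {group!r} must have exactly 2 sites")
            raw_pairs.append((_parse_site_token(tokens[0]), _parse_site_token(tokens[1])))
    else:
        for item in text.split(","):
            item = item.strip()
            if not item:
                continue
            if "|" in item:
                a, _, b = item.partition("|")
                raw_pairs.append((_parse_site_token(a), _parse_site_token(b)))
            else:
                # dash pair like "C1-C6"; split on the dash between tokens
                parts = item.split("-")
                if len(parts) != 2:
                    raise NotationError(f"malformed dash pair {item!r}")
                raw_pairs.append((_parse_site_token(parts[0]), _parse_site_token(parts[1])))

    pairs: set = set()
    seen: set = set()
    for a, b in raw_pairs:
        # normalise pipe tokens "C:1" to plain ordinals
        if isinstance(a, tuple) and a[0].upper() == "C" and isinstance(b, tuple) and b[0].upper() == "C":
            a, b = a[1], b[1]
        if type(a) is not type(b):
            raise NotationError(f"mixed chain-qualified and plain sites in {text!r}")
        if a == b:
            raise NotationError(f"self-bond {a!r}")
        for site in (a, b):
            if site in seen:
                raise NotationError(f"ordinal {site!r} used in more than one pair")
            seen.add(site)
        pairs.add(tuple(sorted((a, b))))
    if not pairs:
        raise NotationError(f"no pairs parsed from {text!r}")
    return pairs


# ---------------------------------------------------------------------------
# Consensus over a model family
# ---------------------------------------------------------------------------


def consensus_topology(
    models: Sequence,
    threshold: float = 0.8,
    cutoff_angstrom: float = 3.0,
):
    """Consensus bond set over ≥2 models plus per-bond support fractions.

    ``models`` may be :class:`~sialofold.structmodel.StructureModel`
    objects (bonds detected here) or ready
    :class:`DisulfideTopology` objects.  Models must agree on the per-chain
    cysteine ordinal counts.
    """
    if len(models) < 2:
        raise ValueError("consensus needs at least 2 models")
    topologies: list[DisulfideTopology] = [
        m if isinstance(m, DisulfideTopology) else detect_bonds(m, cutoff_angstrom)
        for m in models
    ]

    def ordinal_counts(t: DisulfideTopology) -> dict[str, int]:
        counts: dict[str, int] = {}
        for s in t.sites:
            counts[s.chain_id] = max(counts.get(s.chain_id, 0), s.ordinal)
        return counts

    ref_counts = ordinal_counts(topologies[0])
    for t in topologies[1:]:
        if ordinal_counts(t) != ref_counts:
            raise ValueError(
                f"cysteine ordinal counts differ: {ref_counts} vs {ordinal_counts(t)} "
                f"(model {t.model_id!r})"
            )

    support: dict = {}
    for t in topologies:
        for key in t.bond_keys:
            support[key] = support.get(key, 0) + 1
    n = len(topologies)
    fractions = {key: count / n for key, count in support.items()}
    consensus = {key for key, frac in fractions.items() if frac >= threshold}
    return consensus, fractions


# ---------------------------------------------------------------------------
# Dimer bridges
# ---------------------------------------------------------------------------


@dataclass
class DimerReport:
    inter_bonds: list[DisulfideBond]
    free: list[CysteineSite]
    symmetric: bool
    notation: str = ""


def dimer_bridge_scan(model: StructureModel, cutoff_angstrom: float = 3.0) -> DimerReport:
    """Report inter-chain disulfides and flag symmetric-dimer topologies.

    The topology is symmetric when every inter-chain bond (X:i, Y:j) has
    its reciprocal (X:j, Y:i) present as well (the i == j bridge is its
    own reciprocal).
    """
    topology = detect_bonds(model, cutoff_angstrom)
    inter = topology.inter_bonds
    keys = {b.key for b in inter}
    symmetric = bool(inter)
    for (ca, oa), (cb, ob) in keys:
        reciprocal = tuple(sorted(((ca, ob), (cb, oa))))
        if reciprocal not in keys:
            symmetric = False
            break
    return DimerReport(
        inter_bonds=inter,
        free=topology.free,
        symmetric=symmetric,
        notation=render_interchain(topology),
    )


def topology_rows(topology: DisulfideTopology) -> list[dict]:
    """Bond rows for TSV output."""
    return [
        {
            "model_id": topology.model_id,
            "chain_a": b.site_a.chain_id,
            "res_a": b.site_a.residue_number,
            "ordinal_a": b.site_a.ordinal,
            "chain_b": b.site_b.chain_id,
            "res_b": b.site_b.residue_number,
            "ordinal_b": b.site_b.ordinal,
            "distance": round(b.distance, 3),
        }
        for b in topology.bonds
    ]
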