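"""Deterministic synthetic inputs for the whole tool surface.

Everything here is generated from a seed at call time: toy PDB models
with engineered SG–SG distances, ideal helices/strands, self-avoiding
coil walks, protruding triad hairpins, jittered model families, hit
tables and annotation tables.  No generator touches the network or any
external file, and the same seed always yields byte-identical output.

Geometry is chemically plausible, not physical: residues are Cα-only
(plus SG for cysteines), consecutive Cα spacing is kept near 3.8 Å and
atom overlaps are rejected.
"""

from __future__ import annotations

import math
from typing import Iterable, Mapping, Sequence

import numpy as np

from .structmodel import Atom, Chain, Residue, StructureModel, write_pdb_text

__all__ = [
    "ideal_helix",
    "ideal_strand",
    "coil_walk",
    "make_cys_structure",
    "make_dimer_structure",
    "make_hairpin",
    "make_helix_decoy",
    "make_family",
    "make_annotation_table",
    "make_hit_table",
    "make_cytotoxin_scenario",
]

CA_STEP = 3.8  # canonical consecutive Cα spacing, Å
DEFAULT_PLDDT = 90.0


def _model_from_coords(
    coords: np.ndarray,
    model_id: str,
    chain_id: str = "A",
    resnames: Sequence[str] | None = None,
    sg_coords: Mapping[int, np.ndarray] | None = None,
    start_number: int = 1,
) -> StructureModel:
    """Cα-only model from an (n, 3) array; CYS residues may carry SG."""
    sg_coords = sg_coords or {}
    chain = Chain(chain_id)
    for i, xyz in enumerate(coords):
        name = resnames[i] if resnames is not None else "ALA"
        res = Residue(name=name, number=start_number + i)
        res.atoms.append(Atom("CA", "C", *(float(v) for v in xyz), b_factor=DEFAULT_PLDDT))
        if i in sg_coords:
            res.atoms.append(Atom("SG", "S", *(float(v) for v in sg_coords[i]), b_factor=DEFAULT_PLDDT))
        chain.residues.append(res)
    return StructureModel(model_id=model_id, chains=[chain])


# ---------------------------------------------------------------------------
# Ideal secondary-structure fixtures
# ---------------------------------------------------------------------------


def ideal_helix(n: int, model_id: str = "helix", chain_id: str = "A") -> StructureModel:
    """Ideal α-helix: radius 2.3 Å, rise 1.5 Å/residue, 100° twist."""
    t = np.arange(n)
    angle = np.deg2rad(100.0) * t
    coords = np.column_stack([2.3 * np.cos(angle), 2.3 * np.sin(angle), 1.5 * t])
    return _model_from_coords(coords, model_id, chain_id)


def ideal_strand(n: int, model_id: str = "strand", chain_id: str = "A") -> StructureModel:
    """Ideal extended strand: 3.8 Å Cα spacing in a flat zigzag."""
    a, b = 3.35, 0.897  # step projection and half zigzag amplitude
    t = np.arange(n)
    coords = np.column_stack([a * t, b * np.where(t % 2 == 0, 1.0, -1.0), np.zeros(n)])
    return _model_from_coords(coords, model_id, chain_id)


def coil_walk(
    n: int,
    seed: int,
    model_id: str = "coil",
    confine_radius: float | None = None,
    min_separation: float = 3.0,
) -> StructureModel:
    """Self-avoiding random walk with 3.8 Å steps (seeded, deterministic)."""
    rng = np.random.default_rng(seed)
    points = [np.zeros(3)]
    attempts = 0
    stuck = 0
    while len(points) < n:
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        candidate = points[-1] + CA_STEP * direction
        attempts += 1
        if attempts > 2000 * n:
            raise RuntimeError("coil walk failed to place residues; loosen constraints")
        ok = not (confine_radius is not None and np.linalg.norm(candidate) > confine_radius)
        if ok and len(points) > 1:
            ok = all(np.linalg.norm(candidate - p) >= min_separation for p in points[:-1])
        if ok:
            points.append(candidate)
            stuck = 0
        else:
            stuck += 1
            if stuck > 50 and len(points) > 1:  # dead end: backtrack one step
                points.pop()
                stuck = 0
    return _model_from_coords(np.array(points), model_id)


# ---------------------------------------------------------------------------
# Engineered disulfide fixtures
# ---------------------------------------------------------------------------


def _chain_path(anchors: list[np.ndarray], sign: float = 1.0) -> tuple[np.ndarray, list[int]]:
    """Polyline through anchor Cα positions with ~3.8 Å spacer steps.

    Returns all Cα coordinates and the index of each anchor within them.
    Spacers are arched out of the anchor plane, each segment at its own
    height, so segments crossing the same region never collide.
    """
    lateral = 3.0  # climb/descent columns sit beside the anchors
    coords: list[np.ndarray] = [np.asarray(anchors[0], float)]
    anchor_idx = [0]
    for seg, target in enumerate(anchors[1:]):
        target = np.asarray(target, float)
        prev = coords[-1]
        level = sign * (6.0 + 4.0 * (seg % 10))
        # route: sidestep, climb to the segment's private z-level, traverse,
        # descend beside the target, sidestep in.  Each segment traverses at
        # a unique height, so segments never cross; columns are unique per
        # (anchor, direction) so they never coincide either.
        up_col = np.array([prev[0], prev[1] + lateral, prev[2]])
        down_col = np.array([target[0], target[1] - lateral, target[2]])
        waypoints = [
            up_col,
            up_col + np.array([0.0, 0.0, level]),
            down_col + np.array([0.0, 0.0, level]),
            down_col,
            target,
        ]
        for wp in waypoints:
            start = coords[-1]
            dist = float(np.linalg.norm(wp - start))
            m = max(1, math.ceil(dist / CA_STEP))
            for k in range(1, m + 1):
                coords.append(start + (k / m) * (wp - start))
        anchor_idx.append(len(coords) - 1)
    return np.array(coords), anchor_idx


def _repair_overlaps(model: StructureModel, min_dist: float = 2.0, max_rounds: int = 200) -> None:
    """Deterministically nudge spacer (non-CYS) Cα atoms out of clashes.

    Anchor cysteines and SG atoms are immovable so engineered SG–SG
    distances are preserved exactly.
    """
    entries = []  # (movable, residue, atom)
    for chain in model.chains:
        for res in chain.residues:
            for atom in res.atoms:
                entries.append((res.name != "CYS", res, atom))
    nudges: dict[int, int] = {}
    for _ in range(max_rounds):
        coords = np.array([[a.x, a.y, a.z] for _, _, a in entries])
        diffs = coords[:, None, :] - coords[None, :, :]
        dists = np.sqrt((diffs**2).sum(-1))
        iu = np.triu_indices(len(entries), k=1)
        clash = [(dists[i, j], i, j) for i, j in zip(*iu) if dists[i, j] < min_dist]
        if not clash:
            return
        moved: set[int] = set()
        for d, i, j in sorted(clash):
            if i in moved or j in moved:
                continue
            target = next((k for k in (j, i) if entries[k][0]), None)
            if target is None:
                raise ValueError("impossible placement: immovable atoms overlap")
            # lateral (y) shift into otherwise-unused lanes; alternate the
            # direction on repeated nudges so the loop cannot ping-pong
            count = nudges.get(target, 0)
            nudges[target] = count + 1
            direction = 1.0 if count % 2 == 0 else -1.0
            entries[target][2].y += direction * (min_dist - d + 0.6 + 0.4 * count)
            moved.add(target)
    raise ValueError("impossible placement: could not resolve atom overlaps")


def _check_overlaps(model: StructureModel, min_dist: float = 1.0) -> None:
    coords = np.array(
        [a.coords for c in model.chains for r in c.residues for a in r.atoms]
    )
    if len(coords) < 2:
        return
    diffs = coords[:, None, :] - coords[None, :, :]
    dists = np.sqrt((diffs**2).sum(-1))
    np.fill_diagonal(dists, np.inf)
    if dists.min() < min_dist:
        raise ValueError(f"impossible placement: atoms overlap ({dists.min():.2f} Å apart)")


def make_cys_structure(
    pairs: Sequence[tuple[int, int, float]],
    n_cys: int,
    seed: int = 0,
    model_id: str = "cysfix",
) -> str:
    """PDB text of a single chain whose cysteine SG–SG distances are engineered.

    ``pairs`` lists ``(ordinal_a, ordinal_b, sg_distance)`` requests; the
    remaining ordinals are placed with every non-paired SG ≥ 8 Å from any
    other SG.  Distances should be given at millial (0.001 Å) precision so
    the fixed-column PDB round-trips them exactly.
    """
    used: set[int] = set()
    for a, b, d in pairs:
        if not (1 <= a <= n_cys and 1 <= b <= n_cys) or a == b:
            raise ValueError(f"invalid ordinal pair ({a}, {b}) for n_cys={n_cys}")
        if d <= 0:
            raise ValueError(f"non-positive SG distance {d}")
        if a in used or b in used:
            raise ValueError(f"ordinal reused in pair ({a}, {b})")
        used.update((a, b))

    # spatial layout: each pair occupies a slot on the x axis, free
    # cysteines a parallel row far in +y
    sg_pos: dict[int, np.ndarray] = {}
    ca_pos: dict[int, np.ndarray] = {}
    for k, (a, b, d) in enumerate(sorted(pairs)):
        cx = 22.0 * k
        sg_pos[a] = np.array([cx - d / 2.0, 0.0, 0.0])
        sg_pos[b] = np.array([cx + d / 2.0, 0.0, 0.0])
        ca_pos[a] = sg_pos[a] + np.array([-1.7, 1.7, 0.0])
        ca_pos[b] = sg_pos[b] + np.array([1.7, 1.7, 0.0])
    for j, ordinal in enumerate(o for o in range(1, n_cys + 1) if o not in used):
        sg_pos[ordinal] = np.array([22.0 * j, 30.0, 0.0])
        ca_pos[ordinal] = sg_pos[ordinal] + np.array([0.0, 2.4, 0.0])

    anchors = [ca_pos[o] for o in range(1, n_cys + 1)]
    coords, anchor_idx = _chain_path(anchors)
    resnames = ["ALA"] * len(coords)
    sg_by_index: dict[int, np.ndarray] = {}
    for ordinal, idx in zip(range(1, n_cys + 1), anchor_idx):
        resnames[idx] = "CYS"
        sg_by_index[idx] = sg_pos[ordinal]

    model = _model_from_coords(coords, model_id, resnames=resnames, sg_coords=sg_by_index)
    _repair_overlaps(model)
    _check_overlaps(model)
    return write_pdb_text(model)


def make_dimer_structure(
    inter_pairs: Sequence[tuple[int, int, float]],
    n_cys: int,
    intra_pairs_a: Sequence[tuple[int, int, float]] = (),
    intra_pairs_b: Sequence[tuple[int, int, float]] = (),
    seed: int = 0,
    model_id: str = "dimerfix",
) -> str:
    """Two-chain PDB text with engineered inter-chain SG bridges.

    ``inter_pairs`` lists ``(ordinal_in_A, ordinal_in_B, sg_distance)``;
    both chains carry ``n_cys`` cysteines.  Optional intra-chain pairs are
    engineered per chain as well.
    """
    keys = [("A", o) for o in range(1, n_cys + 1)] + [("B", o) for o in range(1, n_cys + 1)]
    paired: set[tuple[str, int]] = set()
    requests: list[tuple[tuple[str, int], tuple[str, int], float]] = []
    for a, b, d in inter_pairs:
        requests.append((("A", a), ("B", b), d))
    for a, b, d in intra_pairs_a:
        requests.append((("A", a), ("A", b), d))
    for a, b, d in intra_pairs_b:
        requests.append((("B", a), ("B", b), d))
    for sa, sb, d in requests:
        if sa in paired or sb in paired or sa == sb or d <= 0:
            raise ValueError(f"invalid or reused pair {sa}–{sb}")
        paired.update((sa, sb))

    sg_pos: dict[tuple[str, int], np.ndarray] = {}
    ca_pos: dict[tuple[str, int], np.ndarray] = {}
    for k, (sa, sb, d) in enumerate(requests):
        cx = 22.0 * k
        sg_pos[sa] = np.array([cx - d / 2.0, 0.0, 0.0])
        sg_pos[sb] = np.array([cx + d / 2.0, 0.0, 0.0])
        ca_pos[sa] = sg_pos[sa] + np.array([-1.7, 1.7, 0.0])
        ca_pos[sb] = sg_pos[sb] + np.array([1.7, -1.7, 0.0])
    for j, key in enumerate(k for k in keys if k not in paired):
        y = 30.0 if key[0] == "A" else -30.0
        sg_pos[key] = np.array([22.0 * j, y, 0.0])
        ca_pos[key] = sg_pos[key] + np.array([0.0, 2.4 if key[0] == "A" else -2.4, 0.0])

    chains: list[Chain] = []
    for chain_id, sign in (("A", 1.0), ("B", -1.0)):
        anchors = [ca_pos[(chain_id, o)] for o in range(1, n_cys + 1)]
        coords, anchor_idx = _chain_path(anchors, sign=sign)
        resnames = ["ALA"] * len(coords)
        sg_by_index = {}
        for ordinal, idx in zip(range(1, n_cys + 1), anchor_idx):
            resnames[idx] = "CYS"
            sg_by_index[idx] = sg_pos[(chain_id, ordinal)]
        part = _model_from_coords(coords, model_id, chain_id, resnames, sg_by_index)
        chains.append(part.chains[0])

    model = StructureModel(model_id=model_id, chains=chains)
    _repair_overlaps(model)
    _check_overlaps(model)
    return write_pdb_text(model)


# ---------------------------------------------------------------------------
# Hairpin / decoy fixtures for the disintegrin screen
# ---------------------------------------------------------------------------


def make_hairpin(
    triad: str = "RGD",
    arm_len: int = 8,
    flank_offset: int = 4,
    seed: int = 0,
    n_body: int = 30,
    bonded: bool = True,
    model_id: str = "hairpin",
) -> tuple[str, str]:
    """PDB text + sequence of a protruding triad hairpin on a compact body.

    Two antiparallel arms carry the triad at the apex; cysteines sit
    ``flank_offset`` residues before and after the triad centre and (when
    ``bonded``) their SG atoms are placed 2.05 Å apart.
    """
    if arm_len < 5:
        raise ValueError("arm_len must be >= 5")
    if not (2 <= flank_offset <= arm_len):
        raise ValueError("flank_offset must be within the arms")
    if len(triad) != 3:
        raise ValueError("triad must be 3 residues")

    body = coil_walk(n_body, seed=seed, confine_radius=7.0).chains[0].ca_coords()
    body = body - body.mean(axis=0)

    x0 = float(body[:, 0].max()) + 4.0
    up = np.column_stack(
        [x0 + 3.4 * np.arange(1, arm_len + 1), np.full(arm_len, 2.5), np.zeros(arm_len)]
    )
    apex_x = x0 + 3.4 * (arm_len + 1)
    apex = np.array(
        [[apex_x, 1.5, 0.0], [apex_x + 2.0, 0.0, 0.0], [apex_x, -1.5, 0.0]]
    )
    down = np.column_stack(
        [x0 + 3.4 * np.arange(arm_len, 0, -1), np.full(arm_len, -2.5), np.zeros(arm_len)]
    )
    coords = np.vstack([body, up, apex, down])

    n_total = coords.shape[0]
    triad_start = n_body + arm_len + 1  # 1-based
    centre = triad_start + 1
    cys_before = centre - flank_offset  # 1-based sequence positions
    cys_after = centre + flank_offset

    three = {
        "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE", "G": "GLY",
        "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU", "M": "MET", "N": "ASN",
        "P": "PRO", "Q": "GLN", "R": "ARG", "S": "SER", "T": "THR", "V": "VAL",
        "W": "TRP", "Y": "TYR",
    }
    seq = ["A"] * n_body + ["G"] * arm_len + list(triad) + ["G"] * arm_len
    seq[cys_before - 1] = "C"
    seq[cys_after - 1] = "C"
    resnames = [three[aa] for aa in seq]

    sg_by_index: dict[int, np.ndarray] = {}
    ca_b, ca_a = coords[cys_before - 1], coords[cys_after - 1]
    gap = ca_a - ca_b
    gap_len = float(np.linalg.norm(gap))
    unit = gap / gap_len
    mid = (ca_a + ca_b) / 2.0
    sg_half = 1.025 if bonded else 6.0
    sg_by_index[cys_before - 1] = mid - sg_half * unit
    sg_by_index[cys_after - 1] = mid + sg_half * unit

    model = _model_from_coords(coords, model_id, resnames=resnames, sg_coords=sg_by_index)
    return write_pdb_text(model), "".join(seq)


def make_helix_decoy(
    triad: str = "RGD",
    n: int = 41,
    flank_offset: int = 4,
    seed: int = 0,
    model_id: str = "decoy",
) -> tuple[str, str]:
    """Triad buried mid-helix with unbonded flanking cysteines (negative case)."""
    model = ideal_helix(n, model_id)
    coords = model.chains[0].ca_coords()
    coords = coords - coords.mean(axis=0)

    centre = n // 2 + 1
    triad_start = centre - 1
    seq = ["A"] * n
    seq[triad_start - 1 : triad_start + 2] = list(triad)
    seq[centre - flank_offset - 1] = "C"
    seq[centre + flank_offset - 1] = "C"
    three = {"A": "ALA", "C": "CYS", "R": "ARG", "G": "GLY", "D": "ASP", "K": "LYS",
             "T": "THR", "S": "SER", "E": "GLU"}
    resnames = [three.get(aa, "ALA") for aa in seq]
    sg_by_index = {
        centre - flank_offset - 1: coords[centre - flank_offset - 1] + np.array([8.0, 0, 0]),
        centre + flank_offset - 1: coords[centre + flank_offset - 1] + np.array([-8.0, 0, 0]),
    }
    out = _model_from_coords(coords, model_id, resnames=resnames, sg_coords=sg_by_index)
    return write_pdb_text(out), "".join(seq)


# ---------------------------------------------------------------------------
# Model families
# ---------------------------------------------------------------------------


def make_family(
    n_models: int,
    base_topology: str | Iterable[tuple[int, int]],
    sigma: float,
    seed: int,
    n_cys: int | None = None,
    bond_distance: float = 2.05,
) -> list[str]:
    """n jittered copies (i.i.d. Gaussian coordinate noise) of one base model.

    ``base_topology`` is a connectivity notation string (e.g.
    ``"C1-C4, C2-C5, C3-C6"``) or an iterable of ordinal pairs.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    from .disulfide import parse_notation
    from .structmodel import parse_pdb_text

    pairs = parse_notation(base_topology) if isinstance(base_topology, str) else set(
        tuple(sorted(p)) for p in base_topology
    )
    max_ord = max(max(p) for p in pairs)
    n_cys = n_cys or max_ord
    base_text = make_cys_structure(
        [(a, b, bond_distance) for a, b in sorted(pairs)], n_cys=n_cys, seed=seed
    )
    base = parse_pdb_text(base_text)

    rng = np.random.default_rng(seed)
    out: list[str] = []
    for i in range(n_models):
        model = parse_pdb_text(base_text, model_id=f"fam{i:03d}")
        for chain in model.chains:
            for res in chain.residues:
                for atom in res.atoms:
                    dx, dy, dz = rng.normal(0.0, sigma, size=3) if sigma > 0 else (0.0, 0.0, 0.0)
                    atom.x += float(dx)
                    atom.y += float(dy)
                    atom.z += float(dz)
        out.append(write_pdb_text(model))
    return out


# ---------------------------------------------------------------------------
# Tabular fixtures
# ---------------------------------------------------------------------------


def make_annotation_table(
    family_counts: Mapping[str, int],
    seed: int = 0,
    disintegrin_every: int = 0,
) -> str:
    """TSV annotation table with exactly the requested per-family counts.

    With ``disintegrin_every=k`` every k-th row gets a non-empty
    disintegrin cell.
    """
    lines = ["accession\tfamily\tdisintegrin\tsequence"]
    rng = np.random.default_rng(seed)
    counter = 0
    for family in sorted(family_counts):
        for i in range(family_counts[family]):
            counter += 1
            rid = f"SYN{counter:05d}.1"
            seq = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=30))
            flag = "RGD" if disintegrin_every and counter % disintegrin_every == 0 else ""
            lines.append(f"{rid}\t{family}\t{flag}\t{seq}")
    return "\n".join(lines) + "\n"


def make_hit_table(rows: Sequence[tuple], header: bool = True) -> str:
    """Serialise (query, target, z, rmsd, lali, pct_id, description) rows as TSV."""
    lines = ["query_id\ttarget\tz\trmsd\tlali\tpct_id\tdescription"] if header else []
    for row in rows:
        lines.append("\t".join(str(v) for v in row))
    return "\n".join(lines) + "\n"


def make_cytotoxin_scenario(
    seed: int = 0,
    n_der_f7: int = 94,
    n_pore: int = 32,
    n_sulfo: int = 2,
    n_none: int = 9,
):
    """Synthetic re-examination of a mislabelled family.

    Returns ``(records, hit_table_text)``: every record starts with the
    same old family label; the hit table sends ``n_der_f7`` queries to a
    Der f 7 target, ``n_pore`` to bacterial pore-forming entries,
    ``n_sulfo`` to sulfotransferases, and leaves ``n_none`` without a
    significant match.
    """
    from .daliclassify import BACTERIAL_PORE_PDB
    from .seqdb import SequenceRecord

    rng = np.random.default_rng(seed)
    pore_ids = sorted(BACTERIAL_PORE_PDB)
    records: list[SequenceRecord] = []
    rows: list[tuple] = []
    idx = 0

    def add(n: int, make_row) -> None:
        nonlocal idx
        for _ in range(n):
            idx += 1
            rid = f"CTX{idx:05d}.1"
            records.append(
                SequenceRecord(record_id=rid, sequence="MKVLAAGITTS", family="Cytotoxin")
            )
            row = make_row(rid)
            if row is not None:
                rows.append(row)

    add(
        n_der_f7,
        lambda rid: (rid, "3h4z-A", round(rng.uniform(10.5, 18.0), 1), 2.0, 110, 12.0,
                     "DER F 7 allergen"),
    )
    add(
        n_pore,
        lambda rid: (rid, pore_ids[int(rng.integers(len(pore_ids)))],
                     round(rng.uniform(10.0, 16.0), 1), 2.5, 150, 9.0, "EPSILON-TOXIN"),
    )
    add(
        n_sulfo,
        lambda rid: (rid, "1q44-A", round(rng.uniform(8.0, 14.0), 1), 2.2, 130, 15.0,
                     "protein tyrosine sulfotransferase"),
    )
    add(
        n_none,
        lambda rid: (rid, "9xxx-A", round(rng.uniform(0.2, 1.9), 1), 5.0, 30, 4.0,
                     "unrelated protein"),
    )
    return records, make_hit_table(rows)
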