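"""Structure models: PDB reading/writing, Kabsch superposition, coarse
secondary-structure assignment and family RMSD fingerprints.

Models are AlphaFold-style single- or multi-chain PDB files; per-residue
confidence (pLDDT) is read from the B-factor column of the Cα atom.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "PDBError",
    "Atom",
    "Residue",
    "Chain",
    "StructureModel",
    "SSEConfig",
    "SSEAnnotation",
    "SuperpositionResult",
    "RmsdFingerprint",
    "read_pdb",
    "parse_pdb_text",
    "write_pdb_text",
    "write_pdb",
    "kabsch_superpose",
    "assign_sse",
    "fingerprint",
]


class PDBError(ValueError):
    """Raised for malformed PDB input or degenerate geometry."""


@dataclass
class Atom:
    name: str
    element: str
    x: float
    y: float
    z: float
    b_factor: float = 0.0

    @property
    def coords(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z], dtype=float)


@dataclass
class Residue:
    name: str
    number: int
    atoms: list[Atom] = field(default_factory=list)

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    @property
    def ca(self) -> Atom | None:
        return self.atom("CA")

    @property
    def plddt(self) -> float | None:
        ca = self.ca
        return ca.b_factor if ca is not None else None


@dataclass
class Chain:
    chain_id: str
    residues: list[Residue] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.residues)

    def ca_coords(self) -> np.ndarray:
        """(n, 3) Cα coordinates; residues without Cα are skipped."""
        rows = [r.ca.coords for r in self.residues if r.ca is not None]
        return np.array(rows, dtype=float).reshape(-1, 3)


@dataclass
class StructureModel:
    model_id: str
    chains: list[Chain] = field(default_factory=list)

    def chain(self, chain_id: str) -> Chain:
        for c in self.chains:
            if c.chain_id == chain_id:
                return c
        raise KeyError(f"no chain {chain_id!r} in model {self.model_id!r}")

    @property
    def chain_ids(self) -> list[str]:
        return [c.chain_id for c in self.chains]

    def all_residues(self) -> list[tuple[str, Residue]]:
        return [(c.chain_id, r) for c in self.chains for r in c.residues]

    def ca_coords(self) -> np.ndarray:
        rows = [r.ca.coords for _, r in self.all_residues() if r.ca is not None]
        return np.array(rows, dtype=float).reshape(-1, 3)

    def plddt(self) -> list[float | None]:
        return [r.plddt for _, r in self.all_residues()]


def _infer_element(atom_name: str) -> str:
    stripped = atom_name.strip()
    if not stripped:
        return ""
    if stripped[0].isdigit():
        stripped = stripped.lstrip("0123456789")
    return stripped[0].upper() if stripped else ""


def parse_pdb_text(text: str, model_id: str = "model") -> StructureModel:
    """Parse PDB-format text (fixed columns, PDB v3.3 ATOM records).

    Only the first MODEL of a multi-model file is read.  The element is
    inferred from the atom name when the element column is blank.
    """
    chains: dict[str, Chain] = {}
    in_model = 0
    seen_atoms = False
    for lineno, line in enumerate(text.splitlines(), start=1):
        rec = line[:6].strip()
        if rec == "MODEL":
            in_model += 1
            if in_model > 1:
                break
            continue
        if rec == "ENDMDL":
            break
        if rec != "ATOM":
            continue
        seen_atoms = True
        try:
            x = float(line[30:38])
            y = float(line[38:46])
            z = float(line[46:54])
        except ValueError:
            raise PDBError(f"non-numeric coordinates on line {lineno}") from None
        if not (math.isfinite(x) and math.isfinite(y) and math.isfinite(z)):
            raise PDBError(f"non-finite coordinates on line {lineno}")
        try:
            b = float(line[60:66]) if line[60:66].strip() else 0.0
        except ValueError:
            b = 0.0
        name = line[12:16].strip()
        resname = line[17:20].strip()
        chain_id = line[21].strip() or "A"
        try:
            resnum = int(line[22:26])
        except ValueError:
            raise PDBError(f"non-numeric residue number on line {lineno}") from None
        element = line[76:78].strip() if len(line) >= 78 else ""
        element = element or _infer_element(name)

        chain = chains.setdefault(chain_id, Chain(chain_id))
        if chain.residues and chain.residues[-1].number == resnum:
            residue = chain.residues[-1]
        else:
            if chain.residues and resnum <= chain.residues[-1].number:
                raise PDBError(
                    f"residue numbers not strictly increasing in chain "
                    f"{chain_id!r} (line {lineno}: {resnum} after "
                    f"{chain.residues[-1].number})"
                )
            residue = Residue(name=resname, number=resnum)
            chain.residues.append(residue)
        residue.atoms.append(Atom(name=name, element=element, x=x, y=y, z=z, b_factor=b))

    if not seen_atoms:
        raise PDBError("no ATOM records found")
    return StructureModel(model_id=model_id, chains=list(chains.values()))


def read_pdb(path: str | os.PathLike) -> StructureModel:
    from pathlib import Path

    path = Path(path)
    with open(path) as fh:
        return parse_pdb_text(fh.read(), model_id=path.stem)


def write_pdb_text(model: StructureModel) -> str:
    """Serialise a model as PDB ATOM/TER records (fixed columns)."""
    lines: list[str] = []
    serial = 1
    for chain in model.chains:
        for res in chain.residues:
            for atom in res.atoms:
                name = atom.name if len(atom.name) == 4 else f" {atom.name:<3s}"
                lines.append(
                    f"ATOM  {serial:5d} {name:<4s} {res.name:<3s} {chain.chain_id}"
                    f"{res.number:4d}    {atom.x:8.3f}{atom.y:8.3f}{atom.z:8.3f}"
                    f"{1.00:6.2f}{atom.b_factor:6.2f}          {atom.element:>2s}"
                )
                serial += 1
        lines.append(f"TER   {serial:5d}")
        serial += 1
    lines.append("END")
    return "\n".join(lines) + "\n"


def write_pdb(model: StructureModel, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write(write_pdb_text(model))


# ---------------------------------------------------------------------------
# Kabsch superposition
# ---------------------------------------------------------------------------


@dataclass
class SuperpositionResult:
    """Optimal rigid transform mapping the mobile set onto the reference.

    ``rotation @ x + translation`` applied to mobile coordinates yields
    the superposed coordinates; ``rmsd`` is minimal over rigid motions.
    """

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float
    n_atoms: int

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return (self.rotation @ np.asarray(coords, float).T).T + self.translation


def kabsch_superpose(coords_ref: np.ndarray, coords_mobile: np.ndarray) -> SuperpositionResult:
    """Least-squares rigid-body superposition (proper rotation enforced).

    Raises :class:`PDBError` for fewer than 3 points, length mismatch, or
    collinear/degenerate point sets.
    """
    ref = np.asarray(coords_ref, dtype=float)
    mob = np.asarray(coords_mobile, dtype=float)
    if ref.shape != mob.shape or ref.ndim != 2 or ref.shape[1] != 3:
        raise PDBError(f"coordinate shapes differ or are not (n, 3): {ref.shape} vs {mob.shape}")
    n = ref.shape[0]
    if n < 3:
        raise PDBError(f"need at least 3 paired atoms, got {n}")

    ref_centroid = ref.mean(axis=0)
    mob_centroid = mob.mean(axis=0)
    ref_c = ref - ref_centroid
    mob_c = mob - mob_centroid

    for label, pts in (("reference", ref_c), ("mobile", mob_c)):
        sv = np.linalg.svd(pts, compute_uv=False)
        if sv[1] < 1e-8 * max(1.0, sv[0]):
            raise PDBError(f"{label} points are collinear or degenerate")

    h = mob_c.T @ ref_c
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    diag = np.diag([1.0, 1.0, d])
    rotation = vt.T @ diag @ u.T
    translation = ref_centroid - rotation @ mob_centroid

    moved = (rotation @ mob.T).T + translation
    rmsd = float(np.sqrt(np.mean(np.sum((moved - ref) ** 2, axis=1))))
    return SuperpositionResult(rotation=rotation, translation=translation, rmsd=rmsd, n_atoms=n)


# ---------------------------------------------------------------------------
# Secondary-structure assignment (Cα geometry, P-SEA-style thresholds)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SSEConfig:
    """Cα-distance windows for coarse secondary-structure assignment.

    A residue index i is helix-consistent when both the i→i+3 and i→i+4
    Cα distances fall in their windows; strand-consistent when the i→i+2
    distance falls in its window.  Runs of at least ``*_min_run``
    consecutive consistent indices are promoted to H/E labels covering the
    residues their windows span.
    """

    helix_d13: tuple[float, float] = (5.0, 6.2)
    helix_d14: tuple[float, float] = (5.9, 7.2)
    strand_d13: tuple[float, float] = (6.2, 7.2)
    helix_min_run: int = 2
    strand_min_run: int = 3


@dataclass
class SSEAnnotation:
    """Per-residue H/E/C labels, one string per chain."""

    labels: dict[str, str]

    def flat(self) -> str:
        return "".join(self.labels.values())

    def __getitem__(self, chain_id: str) -> str:
        return self.labels[chain_id]


def _in(window: tuple[float, float], value: float) -> bool:
    return window[0] <= value <= window[1]


def _assign_chain_sse(chain: Chain, cfg: SSEConfig) -> str:
    n = len(chain.residues)
    labels = ["C"] * n
    coords: list[np.ndarray | None] = [
        (r.ca.coords if r.ca is not None else None) for r in chain.residues
    ]

    def dist(i: int, j: int) -> float | None:
        a, b = coords[i], coords[j]
        if a is None or b is None:
            return None
        return float(np.linalg.norm(a - b))

    helix_flag = [False] * n
    strand_flag = [False] * n
    for i in range(n):
        if i + 4 < n:
            d13 = dist(i, i + 3)
            d14 = dist(i, i + 4)
            if d13 is not None and d14 is not None:
                helix_flag[i] = _in(cfg.helix_d13, d13) and _in(cfg.helix_d14, d14)
        if i + 2 < n:
            d2 = dist(i, i + 2)
            if d2 is not None:
                strand_flag[i] = _in(cfg.strand_d13, d2)

    def runs(flags: Sequence[bool]) -> list[tuple[int, int]]:
        out = []
        start = None
        for i, f in enumerate(flags):
            if f and start is None:
                start = i
            elif not f and start is not None:
                out.append((start, i - 1))
                start = None
        if start is not None:
            out.append((start, len(flags) - 1))
        return out

    for lo, hi in runs(helix_flag):
        if hi - lo + 1 >= cfg.helix_min_run:
            for i in range(lo, min(hi + 4, n - 1) + 1):
                labels[i] = "H"
    for lo, hi in runs(strand_flag):
        if hi - lo + 1 >= cfg.strand_min_run:
            for i in range(lo, min(hi + 2, n - 1) + 1):
                if labels[i] == "C":
                    labels[i] = "E"
    for i in range(n):
        if coords[i] is None:
            labels[i] = "C"
    return "".join(labels)


def assign_sse(model: StructureModel, config: SSEConfig | None = None) -> SSEAnnotation:
    """Assign H/E/C labels per residue from Cα geometry alone.

    Residues lacking a Cα are forced to coil.
    """
    cfg = config or SSEConfig()
    return SSEAnnotation(labels={c.chain_id: _assign_chain_sse(c, cfg) for c in model.chains})


# ---------------------------------------------------------------------------
# Family RMSD fingerprints
# ---------------------------------------------------------------------------


@dataclass
class RmsdFingerprint:
    """All-pairs superposition RMSD statistics over a model family (Å)."""

    n_models: int
    n_pairs: int
    min: float
    max: float
    mean: float
    sd: float

    def summary(self) -> str:
        return f"{self.min:.2f}-{self.max:.2f} ± {self.sd:.2f} Å"


def fingerprint(
    models: Sequence[StructureModel],
    residue_filter: str = "sse",
    pairing: Sequence[int] | None = None,
    sse_config: SSEConfig | None = None,
) -> RmsdFingerprint:
    """All-pairs Kabsch RMSD statistics for a family of models.

    Models are paired by flat residue index and must have equal residue
    counts.  With ``residue_filter="sse"`` only residues labelled H or E
    in *every* model are superposed; ``"all"`` uses every Cα.  An explicit
    ``pairing`` (flat residue indices) overrides both.
    """
    if len(models) < 2:
        raise PDBError("fingerprint needs at least 2 models")
    counts = {len(m.ca_coords()) for m in models}
    if len(counts) != 1:
        raise PDBError(f"models have unequal residue counts: {sorted(counts)}")
    n_res = counts.pop()

    if pairing is not None:
        idx = np.asarray(list(pairing), dtype=int)
    elif residue_filter == "all":
        idx = np.arange(n_res)
    elif residue_filter == "sse":
        shared = np.ones(n_res, dtype=bool)
        for m in models:
            labels = assign_sse(m, sse_config).flat()
            shared &= np.array([ch in "HE" for ch in labels])
        idx = np.nonzero(shared)[0]
        if idx.size == 0:
            raise PDBError("no residues assigned H/E in all models")
    else:
        raise PDBError(f"unknown residue_filter {residue_filter!r}")

    coords = [m.ca_coords()[idx] for m in models]
    rmsds: list[float] = []
    for i in range(len(models)):
        for j in range(i + 1, len(models)):
            rmsds.append(kabsch_superpose(coords[i], coords[j]).rmsd)
    arr = np.array(rmsds)
    return RmsdFingerprint(
        n_models=len(models),
        n_pairs=len(rmsds),
        min=float(arr.min()),
        max=float(arr.max()),
        mean=float(arr.mean()),
        sd=float(arr.std(ddof=1)) if len(rmsds) > 1 else 0.0,
    )
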