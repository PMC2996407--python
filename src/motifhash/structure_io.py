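"""PDB parsing into matchable target structures.

A *target* is one matchable unit — a single chain or a merged chain group —
reduced to its standard amino-acid residues.  Each residue carries its Cα
position, a side-chain centroid, a surface-depth estimate and its one-letter
label; per-target label counts feed the missed-match bookkeeping of the
significance model.

Surface depth is approximated without a molecular-surface mesh: an atom is
"exposed" when it has fewer than a threshold number of heavy-atom neighbors
from *other* residues within ``r_atom + 2 * probe_radius``; a residue's depth
is the distance from its atom closest to the exposed set (zero when the
residue itself has an exposed atom).  Precomputed depths (e.g. from a
surface-mesh program) may be supplied instead via a tab-separated sidecar
file, one line per residue: ``chain seq_number insertion_code depth``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import gemmi
import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "Residue",
    "TargetStructure",
    "ParseError",
    "parse_structure",
    "compute_depth",
    "sidechain_centroid",
    "residue_frequencies",
    "read_depth_sidecar",
    "write_minimal_pdb",
]

STANDARD_AA = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    # selenomethionine is kept, mapped to methionine
    "MSE": "M",
}
THREE_LETTER = {v: k for k, v in STANDARD_AA.items() if k != "MSE"}
ALPHABET = frozenset(THREE_LETTER)

BACKBONE_ATOMS = {"N", "CA", "C", "O", "OXT"}

#: default probe radius (Å) for the exposure test
DEFAULT_PROBE_RADIUS = 1.4
#: generic heavy-atom radius (Å) used in the exposure neighbor search
ATOM_RADIUS = 1.8
#: an atom is exposed when fewer than this many other-residue heavy atoms lie
#: within ATOM_RADIUS + 2*probe_radius; 6 is the coordination number of a
#: chain-like packing at ~3.8 Å spacing, and isolated residues are always
#: fully exposed because same-residue atoms are not counted
DEFAULT_EXPOSURE_THRESHOLD = 6


class ParseError(ValueError):
    """Raised for malformed or empty PDB input."""


@dataclass
class Residue:
    chain_id: str
    seq_number: int
    insertion_code: str  # "" when absent
    label: str  # one-letter amino-acid code
    ca: np.ndarray  # (3,) Å
    sidechain_centroid: np.ndarray  # (3,) Å
    depth: float = 0.0
    atom_coords: list = field(default_factory=list)  # [(element, (3,) array)]
    centroid_is_fallback: bool = False  # Cα used for a truncated side chain

    @property
    def res_id(self) -> tuple[str, int, str]:
        """External identity: author chain / number / insertion code."""
        return (self.chain_id, self.seq_number, self.insertion_code)

    def id_string(self) -> str:
        return f"{self.chain_id}{self.seq_number}{self.insertion_code}"


@dataclass
class TargetStructure:
    target_id: str
    residues: list  # list[Residue]
    label_counts: dict = field(default_factory=dict)

    def __post_init__(self):
        if not self.label_counts:
            self.label_counts = residue_frequencies(self)
        ids = [r.res_id for r in self.residues]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ParseError(f"duplicate residue identifiers in {self.target_id}: {dupes}")

    @property
    def ca_coords(self) -> np.ndarray:
        return np.array([r.ca for r in self.residues], dtype=float).reshape(-1, 3)

    @property
    def depths(self) -> np.ndarray:
        return np.array([r.depth for r in self.residues], dtype=float)

    def residue_by_id(self, res_id: tuple[str, int, str]) -> Residue:
        for r in self.residues:
            if r.res_id == res_id:
                return r
        raise KeyError(f"residue {res_id} not in {self.target_id}")


def residue_frequencies(target: TargetStructure) -> dict:
    """Exact multiset counts of the one-letter labels of a target."""
    counts: dict = {}
    for r in target.residues:
        counts[r.label] = counts.get(r.label, 0) + 1
    return counts


def sidechain_centroid(residue: Residue) -> np.ndarray:
    """Mean of the non-backbone heavy-atom coordinates of a residue.

    Glycine has no side chain and returns its Cα; a truncated non-glycine
    side chain also falls back to Cα and sets ``centroid_is_fallback``.
    """
    side = [
        xyz
        for name, xyz in residue.atom_coords
        if name.strip() not in BACKBONE_ATOMS and not name.strip().startswith("H")
    ]
    if residue.label == "G" or not side:
        if residue.label != "G" and not side:
            residue.centroid_is_fallback = True
        return np.array(residue.ca, dtype=float)
    return np.mean(np.asarray(side, dtype=float), axis=0)


def _pick_altloc(atoms):
    """Highest-occupancy alternate location; ties by altloc identifier order."""
    best = {}
    for atom in atoms:
        key = atom.name
        prev = best.get(key)
        if prev is None:
            best[key] = atom
            continue
        if (atom.occ, _alt_order(atom.altloc)) > (prev.occ, _alt_order(prev.altloc)):
            best[key] = atom
    return list(best.values())


def _alt_order(altloc: str) -> int:
    # '' sorts first among equals, then reverse alphabet so that under max()
    # comparison 'A' beats 'B' at equal occupancy
    return -ord(altloc) if altloc else 0


def parse_structure(pdb_text: str, chain_selection="all-separate", structure_id=None):
    """Parse PDB text into one target per chain, or one merged target.

    Parameters
    ----------
    pdb_text:
        Contents of a PDB file (ATOM/HETATM/TER records; first MODEL only).
    chain_selection:
        ``"all-separate"`` (default) — one TargetStructure per chain;
        ``"merged"`` — all chains as a single target;
        or an explicit list of chain ids (each its own target).
    structure_id:
        Base id for targets; defaults to the header id or ``"struct"``.

    Returns
    -------
    list of TargetStructure.  Hetero residues, waters and residues without a
    Cα are excluded; MSE is kept as methionine; alternate locations resolved
    by highest occupancy.
    """
    if not pdb_text or "ATOM" not in pdb_text:
        raise ParseError("no ATOM records found in PDB input")
    try:
        st = gemmi.read_pdb_string(pdb_text)
    except (RuntimeError, ValueError) as exc:
        raise ParseError(f"PDB parse failure: {exc}") from exc
    if len(st) == 0:
        raise ParseError("PDB input contains no model")
    base = structure_id or (st.name.strip().lower() or "struct")
    model = st[0]  # first MODEL only

    per_chain: dict[str, list[Residue]] = {}
    for chain in model:
        residues = []
        for res in chain:
            label = STANDARD_AA.get(res.name.upper())
            if label is None:
                continue  # hetero / modified residue outside the alphabet
            atoms = _pick_altloc(list(res))
            ca = next((a for a in atoms if a.name == "CA"), None)
            if ca is None:
                continue  # residues lacking a Cα record are dropped
            coords = [
                (a.name, np.array([a.pos.x, a.pos.y, a.pos.z]))
                for a in atoms
                if a.element.name != "H"
            ]
            r = Residue(
                chain_id=chain.name,
                seq_number=res.seqid.num,
                insertion_code=(res.seqid.icode or "").strip(),
                label=label,
                ca=np.array([ca.pos.x, ca.pos.y, ca.pos.z]),
                sidechain_centroid=np.zeros(3),
                atom_coords=coords,
            )
            r.sidechain_centroid = sidechain_centroid(r)
            residues.append(r)
        if residues:
            per_chain.setdefault(chain.name, []).extend(residues)

    if not per_chain:
        raise ParseError("no standard amino-acid residues with Cα found")

    available = sorted(per_chain)
    if chain_selection == "merged":
        merged = [r for c in available for r in per_chain[c]]
        return [TargetStructure(target_id=base, residues=merged)]
    if chain_selection == "all-separate":
        wanted = available
    else:
        wanted = list(chain_selection)
        missing = [c for c in wanted if c not in per_chain]
        if missing:
            raise ParseError(
                f"chain(s) {missing} not found; available chains: {available}"
            )
    return [
        TargetStructure(target_id=f"{base}_{c}", residues=per_chain[c]) for c in wanted
    ]


def compute_depth(
    target: TargetStructure,
    probe_radius: float = DEFAULT_PROBE_RADIUS,
    exposure_threshold: int = DEFAULT_EXPOSURE_THRESHOLD,
) -> TargetStructure:
    """Assign each residue its approximate distance to the molecular surface.

    Exposure is decided per heavy atom by neighbor counting (module
    docstring); residue depth is the minimum over its atoms of the distance
    to the nearest exposed atom, i.e. measured from the atom closest to the
    surface.  Mutates and returns ``target``.
    """
    coords, owner = [], []
    for i, res in enumerate(target.residues):
        for _, xyz in res.atom_coords:
            coords.append(xyz)
            owner.append(i)
    if len(coords) < 4:
        warnings.warn(
            f"{target.target_id}: fewer than 4 atoms; all depths set to 0",
            stacklevel=2,
        )
        for r in target.residues:
            r.depth = 0.0
        return target

    xyz = np.asarray(coords, dtype=float)
    owner = np.asarray(owner)
    tree = cKDTree(xyz)
    radius = ATOM_RADIUS + 2.0 * probe_radius
    neigh = tree.query_ball_point(xyz, r=radius)
    exposed = np.array(
        [
            sum(1 for j in nb if owner[j] != owner[i]) < exposure_threshold
            for i, nb in enumerate(neigh)
        ]
    )
    if not exposed.any():
        # pathological all-buried case: treat everything as surface
        exposed[:] = True
    exp_tree = cKDTree(xyz[exposed])
    dist_to_exposed = np.where(exposed, 0.0, exp_tree.query(xyz)[0])
    for i, res in enumerate(target.residues):
        res.depth = float(dist_to_exposed[owner == i].min())
    return target


def read_depth_sidecar(target: TargetStructure, text: str) -> TargetStructure:
    """Apply precomputed per-residue depths from a tab/space-separated sidecar.

    Each non-comment line: ``chain seq_number insertion_code depth`` with
    ``-`` for an empty insertion code.  Residues not listed keep their depth.
    """
    table = {}
    for ln, line in enumerate(text.splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 4:
            raise ParseError(f"depth sidecar line {ln}: expected 4 fields, got {len(parts)}")
        chain, num, icode, depth = parts
        table[(chain, int(num), "" if icode == "-" else icode)] = float(depth)
    for r in target.residues:
        if r.res_id in table:
            d = table[r.res_id]
            if d < 0:
                raise ParseError(f"negative depth for residue {r.res_id}")
            r.depth = d
    return target


def write_minimal_pdb(target: TargetStructure) -> str:
    """Serialize a target back to minimal ATOM records (all stored atoms).

    Coordinates are written at PDB precision (1e-3 Å); used for round-trip
    checks and for handing structures to external tools.
    """
    lines = []
    serial = 1
    for res in target.residues:
        resname = THREE_LETTER[res.label]
        for name, xyz in res.atom_coords:
            pad_name = f" {name:<3s}" if len(name) < 4 else name
            icode = res.insertion_code or " "
            element = name.strip()[0]
            lines.append(
                f"ATOM  {serial:5d} {pad_name:<4s} {resname} {res.chain_id[:1]}"
                f"{res.seq_number:4d}{icode}   "
                f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}"
                f"{1.00:6.2f}{0.00:6.2f}          {element:>2s}"
            )
            serial += 1
    lines.append("END")
    return "\n".join(lines) + "\n"
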