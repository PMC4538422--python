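"""Structure-derived ground-truth labels: solvent accessibility and contact number.

Given a protein chain with 3D coordinates, this module computes

* per-residue absolute accessible surface area (ASA, in square angstroms) with a
  deterministic Shrake-Rupley rolling-probe algorithm,
* relative solvent accessibility (RSA) by normalising against the maximum
  accessibility of the residue type in a Gly-X-Gly extended tripeptide,
* the 3-state burial label (B buried / I intermediate / E exposed) with
  thresholds at 10% and 40% RSA,
* the residue contact number: the count of other residues' C-beta atoms within
  7.5 A of this residue's C-beta, excluding near sequence neighbours, capped at
  14 (15 classes in total),

plus the dataset filters used when assembling a training corpus (minimum chain
length, minimum buried-residue ratio).  A parser for precomputed DSSP output is
provided as an alternative ASA source.
"""

from __future__ import annotations

import io
import math
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Atom",
    "Residue",
    "Chain",
    "ResidueLabels",
    "StructureError",
    "ChainNotFoundError",
    "MissingBackboneError",
    "MAX_ASA_GXG",
    "VDW_RADII",
    "THREE_TO_ONE",
    "parse_structure",
    "compute_asa",
    "parse_dssp",
    "align_dssp_asa",
    "relative_accessibility",
    "discretize_rsa",
    "virtual_cbeta",
    "contact_number",
    "label_chain",
    "labels_to_tsv",
    "dataset_filter",
]

# Maximum accessible surface area (A^2) of residue X in an extended Gly-X-Gly
# tripeptide; used to turn absolute ASA into relative solvent accessibility.
MAX_ASA_GXG: dict[str, float] = {
    "PHE": 210.0, "ILE": 175.0, "LEU": 170.0, "VAL": 155.0, "PRO": 145.0,
    "ALA": 115.0, "GLY": 75.0, "MET": 185.0, "CYS": 135.0, "TRP": 255.0,
    "TYR": 230.0, "THR": 140.0, "SER": 115.0, "GLN": 180.0, "ASN": 160.0,
    "GLU": 190.0, "ASP": 150.0, "HIS": 195.0, "LYS": 200.0, "ARG": 225.0,
}

# Heavy-atom van der Waals radii (A), Chothia-style values used for protein
# surface calculations.  Unknown elements fall back to ``default_radius``.
VDW_RADII: dict[str, float] = {"C": 1.76, "N": 1.65, "O": 1.40, "S": 1.85}

THREE_TO_ONE: dict[str, str] = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}

BURIAL_STATES = ("B", "I", "E")


class StructureError(ValueError):
    """Base class for structural-input errors."""


class ChainNotFoundError(StructureError):
    pass


class MissingBackboneError(StructureError):
    """Raised when residues lack backbone N/CA/C atoms.

    The offending residues are listed in :attr:`residues` as
    ``(seq_index, residue_name, missing_atom_names)`` tuples.
    """

    def __init__(self, residues: list[tuple[int, str, tuple[str, ...]]]):
        self.residues = residues
        super().__init__(
            "residues missing backbone atoms: "
            + ", ".join(f"{name}{idx} (missing {'/'.join(miss)})" for idx, name, miss in residues)
        )


@dataclass(frozen=True)
class Atom:
    name: str
    element: str
    coord: np.ndarray  # shape (3,), angstroms

    def __post_init__(self):
        object.__setattr__(self, "coord", np.asarray(self.coord, dtype=float))


@dataclass
class Residue:
    name: str          # 3-letter code, one of the 20 standard amino acids
    seq_index: int     # 1-based position in the chain
    atoms: list[Atom] = field(default_factory=list)

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    @property
    def one_letter(self) -> str:
        return THREE_TO_ONE.get(self.name, "X")


@dataclass
class Chain:
    """An ordered protein chain with all-atom coordinates."""

    id: str
    residues: list[Residue]

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def sequence(self) -> str:
        return "".join(r.one_letter for r in self.residues)

    def coords(self, atom_name: str) -> np.ndarray:
        """(L, 3) coordinates of the named atom; NaN rows where absent."""
        out = np.full((len(self.residues), 3), np.nan)
        for i, r in enumerate(self.residues):
            a = r.atom(atom_name)
            if a is not None:
                out[i] = a.coord
        return out


@dataclass
class ResidueLabels:
    """Per-residue ground-truth labels for one chain.

    ``cn_label`` is the capped contact number (0..14, i.e. 15 classes);
    ``burial3`` holds 'B'/'I'/'E' strings.
    """

    chain_id: str
    residue_names: list[str]
    asa: np.ndarray
    rsa: np.ndarray
    burial3: np.ndarray
    cn_raw: np.ndarray
    cn_label: np.ndarray

    def __len__(self) -> int:
        return len(self.residue_names)


# ---------------------------------------------------------------------------
# PDB parsing (Bio.PDB backed)
# ---------------------------------------------------------------------------

def parse_structure(pdb_text: str, chain_id: str, *, require_backbone: bool = True) -> Chain:
    """Parse one chain out of PDB-format text.

    Altloc conflicts keep the highest-occupancy conformer (ties: first seen);
    HETATM records are ignored except selenomethionine (MSE), which is mapped
    to MET.  Hydrogens are dropped.  Raises :class:`ChainNotFoundError` if the
    chain is absent and :class:`MissingBackboneError` (listing the flagged
    residues) if backbone N/CA/C atoms are missing.
    """
    from Bio.PDB import PDBParser

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        structure = PDBParser(QUIET=True).get_structure("s", io.StringIO(pdb_text))
    model = next(structure.get_models())
    if chain_id not in [c.id for c in model]:
        raise ChainNotFoundError(f"chain not found: {chain_id!r}")
    bio_chain = model[chain_id]

    residues: list[Residue] = []
    for res in bio_chain:
        hetflag = res.id[0]
        if hetflag not in (" ", "H_MSE"):
            continue  # waters / ligands
        name = "MET" if res.get_resname() == "MSE" else res.get_resname()
        if name not in THREE_TO_ONE:
            continue
        atoms = []
        for atom in res:
            # Bio.PDB DisorderedAtom already selects the max-occupancy altloc.
            el = (atom.element or atom.get_name()[0]).upper()
            if el == "H":
                continue
            aname = "SD" if res.get_resname() == "MSE" and atom.get_name() == "SE" else atom.get_name()
            atoms.append(Atom(aname, "S" if aname == "SD" and el == "SE" else el,
                              np.array(atom.get_coord(), dtype=float)))
        residues.append(Residue(name, res.id[1], atoms))

    if not residues:
        raise ChainNotFoundError(f"chain {chain_id!r} has no standard amino-acid residues")

    if require_backbone:
        flagged = []
        for r in residues:
            missing = tuple(n for n in ("N", "CA", "C") if r.atom(n) is None)
            if missing:
                flagged.append((r.seq_index, r.name, missing))
        if flagged:
            raise MissingBackboneError(flagged)
    return Chain(chain_id, residues)


# ---------------------------------------------------------------------------
# Accessible surface area (Shrake-Rupley, deterministic golden-spiral lattice)
# ---------------------------------------------------------------------------

def golden_spiral_points(n: int) -> np.ndarray:
    """``n`` near-uniform deterministic points on the unit sphere."""
    i = np.arange(n, dtype=float)
    z = 1.0 - (2.0 * i + 1.0) / n
    theta = i * math.pi * (3.0 - math.sqrt(5.0))  # golden angle
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


def compute_asa(
    chain: Chain,
    probe_radius: float = 1.4,
    n_points: int = 960,
    *,
    default_radius: float = 1.80,
) -> np.ndarray:
    """Per-residue accessible surface area in A^2.

    Rolling-probe point sampling: each heavy atom is covered with ``n_points``
    test points on a sphere of radius ``r_atom + probe_radius``; a point is
    accessible when it lies outside every other atom's probe-expanded sphere.
    The atom's accessible area is ``(exposed / n_points) * 4 pi (r+probe)^2``
    and residue ASA sums its heavy atoms.  Deterministic for fixed ``n_points``.
    """
    if probe_radius <= 0:
        raise ValueError("probe_radius must be positive")
    if n_points < 60:
        raise ValueError("n_points must be >= 60")

    coords, radii, owner = [], [], []
    for ri, res in enumerate(chain.residues):
        for a in res.atoms:
            if a.element == "H":
                continue
            r = VDW_RADII.get(a.element)
            if r is None:
                warnings.warn(f"unknown element {a.element!r}; using default radius {default_radius}")
                r = default_radius
            coords.append(a.coord)
            radii.append(r)
            owner.append(ri)
    xyz = np.asarray(coords)
    rad = np.asarray(radii) + probe_radius
    sphere = golden_spiral_points(n_points)

    from scipy.spatial import cKDTree

    tree = cKDTree(xyz)
    asa = np.zeros(len(chain.residues))
    max_r = rad.max()
    for i in range(len(xyz)):
        pts = xyz[i] + rad[i] * sphere
        # candidate occluders: any atom whose expanded sphere can reach a test point
        nbrs = [j for j in tree.query_ball_point(xyz[i], rad[i] + max_r) if j != i]
        exposed = np.ones(n_points, dtype=bool)
        if nbrs:
            d2 = ((pts[:, None, :] - xyz[nbrs][None, :, :]) ** 2).sum(-1)
            exposed = ~(d2 < (rad[nbrs] ** 2)[None, :] - 1e-12).any(axis=1)
        asa[owner[i]] += exposed.sum() / n_points * 4.0 * math.pi * rad[i] ** 2
    return asa


# ---------------------------------------------------------------------------
# DSSP output parsing (alternative ASA source)
# ---------------------------------------------------------------------------

def parse_dssp(dssp_text: str) -> list[dict]:
    """Extract per-residue accessibility from standard DSSP output.

    Returns records ``{"resnum", "chain", "aa", "acc"}`` in file order;
    chain-break rows (``!`` in the amino-acid column) are skipped.
    """
    lines = dssp_text.splitlines()
    start = None
    for i, ln in enumerate(lines):
        if ln.lstrip().startswith("#  RESIDUE"):
            start = i + 1
            break
    if start is None:
        raise StructureError("malformed DSSP text: '#  RESIDUE' header line not found")
    records = []
    for ln in lines[start:]:
        if len(ln) < 38 or ln[13] == "!":
            continue
        try:
            records.append({
                "resnum": int(ln[5:10]),
                "chain": ln[11].strip(),
                "aa": ln[13],
                "acc": float(ln[34:38]),
            })
        except ValueError as exc:
            raise StructureError(f"malformed DSSP residue line: {ln!r}") from exc
    return records


def align_dssp_asa(chain: Chain, records: list[dict]) -> np.ndarray:
    """ASA vector aligned to ``chain`` residue numbering from DSSP records."""
    by_num = {r["resnum"]: r for r in records if not r["chain"] or r["chain"] == chain.id}
    asa = np.empty(len(chain))
    mismatches = []
    for i, res in enumerate(chain.residues):
        rec = by_num.get(res.seq_index)
        if rec is None or (rec["aa"] != res.one_letter and rec["aa"] != "X"):
            mismatches.append(res.seq_index)
        else:
            asa[i] = rec["acc"]
    if mismatches:
        raise StructureError(f"DSSP/chain residue numbering mismatch at positions {mismatches}")
    return asa


# ---------------------------------------------------------------------------
# RSA, 3-state discretization
# ---------------------------------------------------------------------------

def relative_accessibility(
    asa: np.ndarray,
    residue_names: list[str],
    table: dict[str, float] | None = None,
    *,
    clip: bool = False,
) -> np.ndarray:
    """RSA = ASA / max-ASA(residue type).

    ``table`` defaults to the Gly-X-Gly constants.  Values above 1 are kept
    unless ``clip`` is set (observed ASA can exceed the tripeptide maximum).
    """
    table = MAX_ASA_GXG if table is None else table
    missing = [(i, n) for i, n in enumerate(residue_names) if n not in table]
    if missing:
        raise ValueError(f"residues without a max-ASA entry: {missing}")
    denom = np.array([table[n] for n in residue_names], dtype=float)
    rsa = np.asarray(asa, dtype=float) / denom
    return np.minimum(rsa, 1.0) if clip else rsa


def discretize_rsa(rsa: np.ndarray, low_threshold: float = 0.10, high_threshold: float = 0.40) -> np.ndarray:
    """3-state burial labels on half-open bins [0,low) -> B, [low,high) -> I, [high,inf) -> E."""
    rsa = np.asarray(rsa, dtype=float)
    if not 0 <= low_threshold < high_threshold:
        raise ValueError("thresholds must satisfy 0 <= low < high")
    if (rsa < 0).any():
        raise ValueError("negative RSA values")
    out = np.where(rsa < low_threshold, "B", np.where(rsa < high_threshold, "I", "E"))
    return out.astype("<U1")


# ---------------------------------------------------------------------------
# Contact number
# ---------------------------------------------------------------------------

# Ideal-geometry C-beta placement from backbone N/CA/C (tetrahedral carbon,
# 1.53 A bond, standard linear-combination recipe).
_CB_COEF = (-0.58273431, 0.56802827, -0.54067466)


def virtual_cbeta(n: np.ndarray, ca: np.ndarray, c: np.ndarray) -> np.ndarray:
    b = ca - n
    c_v = c - ca
    a = np.cross(b, c_v)
    return _CB_COEF[0] * a + _CB_COEF[1] * b + _CB_COEF[2] * c_v + ca


def _cbeta_coords(chain: Chain) -> np.ndarray:
    """C-beta coordinates; glycine (or missing CB) gets a virtual C-beta,
    falling back to CA when the backbone is incomplete."""
    out = np.empty((len(chain), 3))
    for i, res in enumerate(chain.residues):
        cb = res.atom("CB")
        if cb is not None:
            out[i] = cb.coord
            continue
        n, ca, c = res.atom("N"), res.atom("CA"), res.atom("C")
        if n is not None and ca is not None and c is not None:
            out[i] = virtual_cbeta(n.coord, ca.coord, c.coord)
        elif ca is not None:
            out[i] = ca.coord
        else:
            raise MissingBackboneError([(res.seq_index, res.name, ("CA",))])
    return out


def contact_number(
    chain: Chain,
    radius: float = 7.5,
    seq_exclusion: int = 5,
    cap: int = 14,
) -> tuple[np.ndarray, np.ndarray]:
    """Raw and capped contact numbers.

    ``cn_raw[i]`` counts residues j with ``|i - j| > seq_exclusion`` whose
    C-beta lies within ``radius`` of residue i's C-beta; ``cn_label`` caps the
    count at ``cap`` (so labels live in 0..cap, giving cap+1 classes).
    """
    L = len(chain)
    if L < 2:
        warnings.warn("chain shorter than 2 residues: contact numbers all zero")
        return np.zeros(L, dtype=int), np.zeros(L, dtype=int)
    cb = _cbeta_coords(chain)
    diff = cb[:, None, :] - cb[None, :, :]
    within = (diff ** 2).sum(-1) < radius ** 2
    idx = np.arange(L)
    near_seq = np.abs(idx[:, None] - idx[None, :]) <= seq_exclusion
    cn_raw = (within & ~near_seq).sum(axis=1)
    return cn_raw.astype(int), np.minimum(cn_raw, cap).astype(int)


# ---------------------------------------------------------------------------
# Labeling pipeline and dataset filters
# ---------------------------------------------------------------------------

def label_chain(
    chain: Chain,
    *,
    asa: np.ndarray | None = None,
    probe_radius: float = 1.4,
    n_points: int = 960,
    low_threshold: float = 0.10,
    high_threshold: float = 0.40,
    radius: float = 7.5,
    seq_exclusion: int = 5,
    cap: int = 14,
) -> ResidueLabels:
    """Full label computation for one chain (ASA may be supplied, e.g. from DSSP)."""
    names = [r.name for r in chain.residues]
    if asa is None:
        asa = compute_asa(chain, probe_radius, n_points)
    rsa = relative_accessibility(asa, names)
    burial = discretize_rsa(rsa, low_threshold, high_threshold)
    cn_raw, cn_label = contact_number(chain, radius, seq_exclusion, cap)
    return ResidueLabels(chain.id, names, np.asarray(asa, float), rsa, burial, cn_raw, cn_label)


def labels_to_tsv(labels: ResidueLabels, chain: Chain) -> str:
    """Per-residue label table (1-based positions)."""
    lines = ["chain\tpos\taa\tasa\trsa\tburial3\tcn_raw\tcn_label"]
    for i in range(len(labels)):
        lines.append(
            f"{labels.chain_id}\t{i + 1}\t{chain.residues[i].one_letter}\t"
            f"{labels.asa[i]:.3f}\t{labels.rsa[i]:.4f}\t{labels.burial3[i]}\t"
            f"{labels.cn_raw[i]}\t{labels.cn_label[i]}"
        )
    return "\n".join(lines) + "\n"


def dataset_filter(
    labeled_chains: list[ResidueLabels],
    min_length: int = 50,
    min_buried_ratio: float = 0.10,
) -> tuple[list[ResidueLabels], list[dict]]:
    """Apply corpus filters: length >= ``min_length`` and buried fraction >=
    ``min_buried_ratio``.  Returns the retained subset plus a per-chain report
    saying which rule (if any) removed each chain."""
    kept, report = [], []
    for lab in labeled_chains:
        L = len(lab)
        buried_ratio = float((lab.burial3 == "B").mean()) if L else 0.0
        if L < min_length:
            verdict = "rejected:length"
        elif buried_ratio < min_buried_ratio:
            verdict = "rejected:buried_ratio"
        else:
            verdict = "retained"
            kept.append(lab)
        report.append({
            "chain": lab.chain_id,
            "length": L,
            "buried_ratio": buried_ratio,
            "verdict": verdict,
        })
    return kept, report
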