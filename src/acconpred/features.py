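"""Per-residue input features and sliding-window assembly.

Three feature blocks feed the sequence model:

* evolution (40 values): 20 match-emission probabilities from a profile HMM
  plus 20 log-odds of those emissions against a fixed background amino-acid
  frequency vector.  Read from HHsuite ``.hhm`` files or a plain 40-column
  TSV dialect;
* structure (11 values): predicted 8-class and 3-class secondary-structure
  probabilities, concatenated ``[ss8 | ss3]``;
* amino acid (58 values): position-independent tables — 7 physicochemical
  properties, 11 secondary-structure segment endpoint propensities and 40
  correlated contact potential values per residue type.

The final model input for residue i is the concatenation of the per-residue
vectors in a window i-k .. i+k (k = 5 by default, zero padding beyond the
termini), giving (2k+1) * d dimensions.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np

__all__ = [
    "BLOCK_DIMS",
    "BACKGROUND_FREQS",
    "HHM_AA_ORDER",
    "FeatureMatrix",
    "AminoAcidTables",
    "load_aa_tables",
    "load_profile",
    "parse_hhm",
    "ss_probability_features",
    "amino_acid_features",
    "assemble_features",
]

BLOCK_DIMS = {"evolution": 40, "structure": 11, "amino_acid": 58}

AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"
HHM_AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"

# Background amino-acid frequencies (Robinson & Robinson counts, normalised),
# used for the 20 log-odds companions of the emission probabilities.
BACKGROUND_FREQS = {
    "A": 0.0780, "C": 0.0152, "D": 0.0535, "E": 0.0668, "F": 0.0397,
    "G": 0.0695, "H": 0.0229, "I": 0.0590, "K": 0.0592, "L": 0.0964,
    "M": 0.0238, "N": 0.0449, "P": 0.0492, "Q": 0.0426, "R": 0.0512,
    "S": 0.0712, "T": 0.0569, "V": 0.0673, "W": 0.0118, "Y": 0.0322,
}

_MIN_PROB = 2.0 ** -20  # floor for zero emissions ('*' in HHM scores)


@dataclass
class FeatureMatrix:
    """Per-residue features plus the windowed model input.

    ``windowed`` row i concatenates ``per_residue`` rows i-k .. i+k with a
    zero padding vector beyond the termini.
    """

    per_residue: np.ndarray     # (L, d)
    windowed: np.ndarray        # (L, (2k+1)*d)
    k: int
    block_dims: dict[str, int]

    @property
    def L(self) -> int:
        return self.per_residue.shape[0]

    @property
    def d(self) -> int:
        return self.per_residue.shape[1]


@dataclass
class AminoAcidTables:
    """Position-independent residue-type tables (rows follow ``AA_ORDER``)."""

    physicochemical: np.ndarray           # (20, 7)
    ss_endpoint_propensity: np.ndarray    # (20, 11)
    correlated_contact_potential: np.ndarray  # (20, 40)

    def __post_init__(self):
        for attr, cols in (("physicochemical", 7),
                           ("ss_endpoint_propensity", 11),
                           ("correlated_contact_potential", 40)):
            arr = np.asarray(getattr(self, attr), dtype=float)
            if arr.shape != (20, cols):
                raise ValueError(f"{attr} must have shape (20, {cols}), got {arr.shape}")
            setattr(self, attr, arr)

    def row(self, aa: str) -> np.ndarray:
        i = AA_ORDER.index(aa)
        return np.concatenate([
            self.physicochemical[i],
            self.ss_endpoint_propensity[i],
            self.correlated_contact_potential[i],
        ])


def load_aa_tables(path: str | Path | None = None) -> AminoAcidTables:
    """Load the packaged tables, or a user-supplied JSON with the same keys.

    The packaged file carries synthetic stand-in values for the two propensity
    tables (see its ``comment`` field); shapes are enforced either way.
    """
    if path is None:
        text = resources.files("acconpred").joinpath("data/aa_tables_synthetic.json").read_text()
    else:
        text = Path(path).read_text()
    data = json.loads(text)
    if data.get("amino_acids") != list(AA_ORDER):
        raise ValueError("amino-acid table rows must follow the order " + AA_ORDER)
    return AminoAcidTables(
        np.array(data["physicochemical"]),
        np.array(data["ss_endpoint_propensity"]),
        np.array(data["correlated_contact_potential"]),
    )


# ---------------------------------------------------------------------------
# Evolution block
# ---------------------------------------------------------------------------

def parse_hhm(text: str) -> np.ndarray:
    """Match-emission probabilities (L, 20) from an HHsuite ``.hhm`` file.

    HHM stores scores s = -1000 * log2(p); ``*`` denotes probability 0.
    Columns are reordered from the file's header line into ``AA_ORDER``.
    """
    lines = text.splitlines()
    try:
        hmm_at = next(i for i, ln in enumerate(lines)
                      if ln.startswith("HMM") and len(ln.split()) == 21)
    except StopIteration:
        raise ValueError("not an HHM file: no 'HMM' column-header line") from None
    file_order = lines[hmm_at].split()[1:]
    perm = [file_order.index(a) for a in AA_ORDER]

    probs = []
    i = hmm_at + 3  # skip the two transition-header lines
    lineno = i
    while i < len(lines):
        ln = lines[i].strip()
        if ln.startswith("//") or not ln:
            break
        tok = ln.split()
        if len(tok) < 22:
            raise ValueError(f"malformed HHM match-state line {i + 1}: {ln!r}")
        scores = tok[2:22]
        row = np.array([_MIN_PROB if s == "*" else 2.0 ** (-int(s) / 1000.0) for s in scores])
        probs.append(row[perm])
        i += 2  # every match state spans an emission line and a transition line
        lineno = i
    if not probs:
        raise ValueError(f"HHM file has no match states (stopped at line {lineno + 1})")
    return np.vstack(probs)


def _evolution_block(probs: np.ndarray) -> np.ndarray:
    bg = np.array([BACKGROUND_FREQS[a] for a in AA_ORDER])
    odds = np.log2(np.maximum(probs, _MIN_PROB) / bg)
    return np.concatenate([probs, odds], axis=1)


def load_profile(source: str | Path, sequence: str | None = None) -> np.ndarray:
    """Per-residue evolution block (L, 40) from a profile file.

    ``source`` may be a path or raw text in either the HHsuite HHM layout or
    the plain TSV dialect (exactly 40 numeric columns per residue: the 20
    emission probabilities followed by their 20 companion values, used as-is).
    Raises on residue-count mismatch against ``sequence`` when given.
    """
    s = str(source)
    if "\n" not in s and len(s) < 4096 and Path(s).is_file():
        text = Path(s).read_text()
    else:
        text = s
    if "HMM" in text and "NULL" in text or text.lstrip().startswith("HHsearch"):
        block = _evolution_block(parse_hhm(text))
    else:
        rows = []
        for lineno, ln in enumerate(text.splitlines(), start=1):
            ln = ln.strip()
            if not ln or ln.startswith("#"):
                continue
            tok = ln.split()
            if len(tok) != 40:
                raise ValueError(f"profile TSV line {lineno}: expected 40 columns, got {len(tok)}")
            try:
                rows.append([float(t) for t in tok])
            except ValueError:
                raise ValueError(f"profile TSV line {lineno}: non-numeric value") from None
        if not rows:
            raise ValueError("empty profile file")
        block = np.array(rows)
        if ((block[:, :20] < 0) | (block[:, :20] > 1)).any():
            raise ValueError("first 20 profile columns must be probabilities in [0, 1]")
    if sequence is not None and block.shape[0] != len(sequence):
        raise ValueError(f"profile has {block.shape[0]} residues but sequence has {len(sequence)}")
    return block


# ---------------------------------------------------------------------------
# Structure block
# ---------------------------------------------------------------------------

def ss_probability_features(
    ss3_probs: np.ndarray,
    ss8_probs: np.ndarray | None = None,
    *,
    tol: float = 1e-3,
) -> np.ndarray:
    """Structure block (L, 11): ``[ss8 | ss3]`` per residue.

    Each probability row must sum to 1 within ``tol``.  When no 8-class
    prediction is available, ``ss8_probs=None`` fills that sub-block with the
    uniform distribution.
    """
    ss3 = np.asarray(ss3_probs, dtype=float)
    if ss3.ndim != 2 or ss3.shape[1] != 3:
        raise ValueError(f"ss3 must be (L, 3), got {ss3.shape}")
    if ss8_probs is None:
        ss8 = np.full((ss3.shape[0], 8), 1.0 / 8.0)
    else:
        ss8 = np.asarray(ss8_probs, dtype=float)
        if ss8.ndim != 2 or ss8.shape[1] != 8:
            raise ValueError(f"ss8 must be (L, 8), got {ss8.shape}")
        if ss8.shape[0] != ss3.shape[0]:
            raise ValueError("ss3 and ss8 length mismatch")
    for name, arr in (("ss3", ss3), ("ss8", ss8)):
        bad = np.abs(arr.sum(axis=1) - 1.0) > tol
        if bad.any():
            raise ValueError(f"{name} rows do not sum to 1 at positions {np.flatnonzero(bad).tolist()}")
    return np.concatenate([ss8, ss3], axis=1)


# ---------------------------------------------------------------------------
# Amino-acid block
# ---------------------------------------------------------------------------

def amino_acid_features(sequence: str, tables: AminoAcidTables | None = None) -> np.ndarray:
    """Amino-acid block (L, 58): table rows looked up per residue type.

    ``X`` gets the column-mean row (with a warning); other non-standard
    letters raise.
    """
    import warnings

    tables = load_aa_tables() if tables is None else tables
    full = np.concatenate([tables.physicochemical,
                           tables.ss_endpoint_propensity,
                           tables.correlated_contact_potential], axis=1)
    mean_row = full.mean(axis=0)
    rows = []
    for i, aa in enumerate(sequence.upper()):
        if aa in AA_ORDER:
            rows.append(full[AA_ORDER.index(aa)])
        elif aa == "X":
            warnings.warn(f"unknown residue 'X' at position {i + 1}: using table means")
            rows.append(mean_row)
        else:
            raise ValueError(f"invalid residue letter {aa!r} at position {i + 1}")
    return np.array(rows)


# ---------------------------------------------------------------------------
# Window assembly
# ---------------------------------------------------------------------------

def assemble_features(
    blocks: dict[str, np.ndarray],
    k: int = 5,
    padding: np.ndarray | None = None,
) -> FeatureMatrix:
    """Concatenate the active blocks and build the (2k+1)-window input.

    ``blocks`` maps block names (any subset of evolution / structure /
    amino_acid, or custom names) to (L, dim) arrays; all must share L.
    ``padding`` (default zeros) fills window slots beyond the termini.
    """
    if not blocks:
        raise ValueError("no feature blocks given")
    order = [n for n in ("evolution", "structure", "amino_acid") if n in blocks]
    order += [n for n in blocks if n not in order]
    arrays = [np.asarray(blocks[n], dtype=float) for n in order]
    lengths = {a.shape[0] for a in arrays}
    if len(lengths) != 1:
        raise ValueError(f"inconsistent block lengths: { {n: blocks[n].shape[0] for n in order} }")
    per_residue = np.concatenate(arrays, axis=1)
    if not np.isfinite(per_residue).all():
        raise ValueError("non-finite feature values")
    windowed = window_stack(per_residue, k, padding)
    return FeatureMatrix(per_residue, windowed, k,
                         {n: blocks[n].shape[1] for n in order})


def window_stack(per_residue: np.ndarray, k: int, padding: np.ndarray | None = None) -> np.ndarray:
    """(L, (2k+1)*d) sliding-window view of an (L, d) matrix."""
    L, d = per_residue.shape
    pad = np.zeros(d) if padding is None else np.asarray(padding, dtype=float)
    if pad.shape != (d,):
        raise ValueError(f"padding must have shape ({d},)")
    padded = np.vstack([np.tile(pad, (k, 1)), per_residue, np.tile(pad, (k, 1))])
    return np.concatenate([padded[off:off + L] for off in range(2 * k + 1)], axis=1)
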