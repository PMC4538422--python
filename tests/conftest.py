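"""Shared fixtures and independent oracles for the test suite.

The oracles here deliberately avoid the library's own inference code: chain
quantities are computed by exhaustive enumeration over all label sequences
with plain Python loops, surface areas by a dense brute-force point test, and
contact numbers by an O(L^2) double loop.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
import pytest

from acconpred.cnf_core import CNFModel, TaskHead
from acconpred.structure_labels import Atom, Chain, Residue


# ---------------------------------------------------------------------------
# Exhaustive-enumeration oracle for linear-chain models
# ---------------------------------------------------------------------------

def enumerate_chain(S, T):
    """Brute-force logZ, unary and pairwise posteriors, and the MAP sequence.

    Scores every one of M^L label sequences explicitly; first-encountered
    maximum wins ties, and ``itertools.product`` iterates in lexicographic
    order, matching a lowest-index tie-break.
    """
    S = np.asarray(S, dtype=float)
    T = np.asarray(T, dtype=float)
    L, M = S.shape
    seq_scores = {}
    for y in itertools.product(range(M), repeat=L):
        s = 0.0
        for i in range(L):
            s += S[i][y[i]]
        for i in range(L - 1):
            s += T[y[i]][y[i + 1]]
        seq_scores[y] = s
    vals = list(seq_scores.values())
    mx = max(vals)
    logZ = mx + math.log(sum(math.exp(v - mx) for v in vals))
    unary = np.zeros((L, M))
    pairwise = np.zeros((L - 1, M, M)) if L > 1 else np.zeros((0, M, M))
    for y, s in seq_scores.items():
        p = math.exp(s - logZ)
        for i in range(L):
            unary[i, y[i]] += p
        for i in range(L - 1):
            pairwise[i, y[i], y[i + 1]] += p
    y_map = max(seq_scores, key=seq_scores.get)
    return logZ, unary, pairwise, np.array(y_map, dtype=int), seq_scores


def brute_force_asa(coords, radii, probe, n_points=10000):
    """Independent dense-point accessible-surface oracle (per-atom double loop)."""
    from acconpred.structure_labels import golden_spiral_points

    sphere = golden_spiral_points(n_points)
    out = np.zeros(len(coords))
    for i, (c, r) in enumerate(zip(coords, radii)):
        R = r + probe
        exposed = 0
        for p in c + R * sphere:
            ok = True
            for j, (c2, r2) in enumerate(zip(coords, radii)):
                if j == i:
                    continue
                if np.dot(p - c2, p - c2) < (r2 + probe) ** 2 - 1e-12:
                    ok = False
                    break
            if ok:
                exposed += 1
        out[i] = exposed / n_points * 4.0 * math.pi * R ** 2
    return out


def brute_force_contact_numbers(cb_coords, radius, seq_exclusion):
    L = len(cb_coords)
    out = np.zeros(L, dtype=int)
    for i in range(L):
        for j in range(L):
            if abs(i - j) <= seq_exclusion:
                continue
            if np.linalg.norm(cb_coords[i] - cb_coords[j]) < radius:
                out[i] += 1
    return out


# ---------------------------------------------------------------------------
# Model and structure factories
# ---------------------------------------------------------------------------

def random_model(rng, M=3, H=4, D=6, tasks=("t",), scale=1.0) -> CNFModel:
    heads = {
        t: TaskHead(scale * rng.normal(size=(M, H)), scale * rng.normal(size=M),
                    scale * rng.normal(size=(M, M)))
        for t in tasks
    }
    return CNFModel(scale * rng.normal(size=(H, D)), scale * rng.normal(size=H), heads)


def simple_residue(name, seq_index, center, with_cb=True):
    c = np.asarray(center, dtype=float)
    atoms = [
        Atom("N", "N", c + [-1.2, 0.5, 0.0]),
        Atom("CA", "C", c),
        Atom("C", "C", c + [1.2, 0.5, 0.0]),
    ]
    if with_cb:
        atoms.append(Atom("CB", "C", c + [0.0, -1.0, 1.1]))
    return Residue(name, seq_index, atoms)


@pytest.fixture
def tri_pdb_text():
    """Minimal 3-residue single-chain PDB text (ALA-GLY-SER)."""
    rows = [
        ("N", "N", "ALA", 1, (0.0, 0.0, 0.0)),
        ("CA", "C", "ALA", 1, (1.5, 0.0, 0.0)),
        ("C", "C", "ALA", 1, (2.2, 1.3, 0.0)),
        ("N", "N", "GLY", 2, (3.5, 1.3, 0.0)),
        ("CA", "C", "GLY", 2, (4.4, 2.4, 0.0)),
        ("C", "C", "GLY", 2, (5.8, 2.0, 0.3)),
        ("N", "N", "SER", 3, (6.8, 2.9, 0.3)),
        ("CA", "C", "SER", 3, (8.2, 2.6, 0.5)),
        ("C", "C", "SER", 3, (9.0, 3.8, 1.0)),
    ]
    lines = []
    for i, (an, el, rn, num, (x, y, z)) in enumerate(rows, start=1):
        lines.append(
            f"ATOM  {i:5d} {an:^4s} {rn:<3s} A{num:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          {el:>2s}"
        )
    lines.append("END")
    return "\n".join(lines) + "\n"


@pytest.fixture
def altloc_pdb_text():
    """One residue whose CA has altlocs A (occ 0.4) and B (occ 0.6)."""
    lines = [
        "ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N",
        "ATOM      2  CA AALA A   1       1.500   0.000   0.000  0.40  0.00           C",
        "ATOM      3  CA BALA A   1       1.700   0.100   0.000  0.60  0.00           C",
        "ATOM      4  C   ALA A   1       2.200   1.300   0.000  1.00  0.00           C",
        "END",
    ]
    return "\n".join(lines) + "\n"


@pytest.fixture
def dssp_text():
    """Three residues with ACC 10/20/30 plus a chain-break row."""
    def row(linenum, resnum, aa, acc):
        s = f"{linenum:5d}{resnum:5d} A {aa}"
        return s + " " * (34 - len(s)) + f"{acc:4d}"

    header = (
        "==== Secondary Structure Definition by the program DSSP ====\n"
        "  #  RESIDUE AA STRUCTURE BP1 BP2  ACC     N-H-->O    O-->H-N\n"
    )
    break_row = "    3      ! "
    body = "\n".join([row(1, 1, "A", 10), row(2, 2, "G", 20), break_row, row(4, 3, "S", 30)])
    return header + body + "\n"
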