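"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from mc4rkit import synth
from mc4rkit.sequences import (assign_bw_numbers, default_topology,
                               hmc4r_sequence, load_anchors, load_matrix)


@pytest.fixture(scope="session")
def hmc4r():
    return hmc4r_sequence()


@pytest.fixture(scope="session")
def topology():
    return default_topology()


@pytest.fixture(scope="session")
def bw(hmc4r, topology):
    return assign_bw_numbers(hmc4r, load_anchors(), topology)


@pytest.fixture(scope="session")
def bundle():
    """hMC4R toy bundle with loops and the planted ECL3 disulfide."""
    model, topo, manifest = synth.hmc4r_bundle(seed=0)
    return model, topo, manifest


@pytest.fixture(scope="session")
def helix_bundle():
    """Loop-free hMC4R bundle (receptor for exact-contact fixtures)."""
    model, topo, manifest = synth.hmc4r_bundle(seed=0, include_loops=False)
    return model, topo, manifest


@pytest.fixture(scope="session")
def surrogates():
    return synth.make_ortholog_surrogates(seed=0)


# ---------------------------------------------------------------------------
# independent oracles

def enumerate_global_alignments(a: str, b: str):
    """Every global alignment of two strings as move sequences
    ('M' aligned pair, 'A' gap in B consuming A, 'B' gap in A consuming B)."""
    def rec(i, j):
        if i == len(a) and j == len(b):
            yield ()
            return
        if i < len(a) and j < len(b):
            for rest in rec(i + 1, j + 1):
                yield ("M",) + rest
        if i < len(a):
            for rest in rec(i + 1, j):
                yield ("A",) + rest
        if j < len(b):
            for rest in rec(i, j + 1):
                yield ("B",) + rest
    yield from rec(0, 0)


def score_alignment_moves(a: str, b: str, moves, matrix_name="BLOSUM62",
                          gap_open=-10.0, gap_extend=-1.0) -> float:
    """Affine-gap score of a move sequence (gap of length L costs
    open + (L-1)*extend, matching the aligner's convention)."""
    mat = load_matrix(matrix_name)
    score = 0.0
    i = j = 0
    prev = None
    for move in moves:
        if move == "M":
            score += mat[a[i], b[j]]
            i += 1
            j += 1
        else:
            score += gap_extend if move == prev else gap_open
            if move == "A":
                i += 1
            else:
                j += 1
        prev = move
    return score


def best_alignment_score_bruteforce(a: str, b: str, **kw) -> float:
    return max(score_alignment_moves(a, b, m, **kw)
               for m in enumerate_global_alignments(a, b))


def horn_rotation(P: np.ndarray, Q: np.ndarray) -> np.ndarray:
    """Optimal rotation by Horn's quaternion method (independent of the
    SVD-based implementation under test)."""
    Pc = P - P.mean(axis=0)
    Qc = Q - Q.mean(axis=0)
    S = Pc.T @ Qc
    Sxx, Sxy, Sxz = S[0]
    Syx, Syy, Syz = S[1]
    Szx, Szy, Szz = S[2]
    N = np.array([
        [Sxx + Syy + Szz, Syz - Szy, Szx - Sxz, Sxy - Syx],
        [Syz - Szy, Sxx - Syy - Szz, Sxy + Syx, Szx + Sxz],
        [Szx - Sxz, Sxy + Syx, -Sxx + Syy - Szz, Syz + Szy],
        [Sxy - Syx, Szx + Sxz, Syz + Szy, -Sxx - Syy + Szz],
    ])
    w, v = np.linalg.eigh(N)
    q = v[:, np.argmax(w)]
    q0, q1, q2, q3 = q
    return np.array([
        [q0 * q0 + q1 * q1 - q2 * q2 - q3 * q3,
         2 * (q1 * q2 - q0 * q3), 2 * (q1 * q3 + q0 * q2)],
        [2 * (q1 * q2 + q0 * q3),
         q0 * q0 - q1 * q1 + q2 * q2 - q3 * q3, 2 * (q2 * q3 - q0 * q1)],
        [2 * (q1 * q3 - q0 * q2), 2 * (q2 * q3 + q0 * q1),
         q0 * q0 - q1 * q1 - q2 * q2 + q3 * q3],
    ])


def brute_force_contacts(model, ligand_chain: str, receptor_chain: str,
                         cutoff: float):
    """O(n²) all-pairs residue contact scan, independent of the KD-tree
    implementation under test."""
    lig = model.chain(ligand_chain)
    rec = model.chain(receptor_chain)
    found = {}
    for lr in lig.residues:
        la = np.array([a.pos for a in lr.heavy_atoms()])
        for rr in rec.residues:
            ra = np.array([a.pos for a in rr.heavy_atoms()])
            d = np.sqrt(((la[:, None, :] - ra[None, :, :]) ** 2).sum(-1))
            dmin = float(d.min())
            if dmin <= cutoff:
                found[(lr.number, rr.number)] = dmin
    return found
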