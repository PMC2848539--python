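"""Independent reference implementations used only to check the package.

Each oracle deliberately takes a different computational route from the code
under test: naive Python loops instead of vectorised/pruned search, explicit
column scans instead of coordinate arithmetic, scipy's rotation solver
instead of the package's SVD Kabsch, and explicit normal equations instead
of numpy's polynomial fitter.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.spatial.transform import Rotation

from ifacecov.alignments import GAP, STANDARD_AA
from ifacecov.interface import VdwTable


def interface_all_pairs(complex_structure, vdw: VdwTable | None = None):
    """Quadruple-loop interface assignment: atoms of every residue of one
    chain against every atom of the other chain."""
    vdw = vdw or VdwTable()
    chain_a, chain_b = complex_structure.chains
    in_a, in_b = set(), set()
    atoms_b = [(a, vdw.radius(a.element)) for a in chain_b.atoms()]
    for res_a in chain_a.residues:
        for at_a in res_a.atoms:
            r_a = vdw.radius(at_a.element)
            for at_b, r_b in atoms_b:
                if math.dist(at_a.position, at_b.position) < r_a + r_b + vdw.water_diameter:
                    in_a.add(res_a.res_id)
                    in_b.add((at_b.residue_number, at_b.insertion_code))
    return {
        chain_a.chain_id: tuple(sorted(in_a)),
        chain_b.chain_id: tuple(sorted(in_b)),
    }


def column_scan_metrics(aln, interface_positions, matrix):
    """Walk the alignment column by column, tracking the target position
    explicitly, and recount every statistic."""
    pos = aln.target_start - 1
    l_ali = n_ali = n_iden = n_pos = 0
    n_int_ali = int_iden = int_pos = 0
    members = set(interface_positions) if interface_positions else set()
    for t, m in zip(aln.target_aln, aln.template_aln):
        l_ali += 1
        if t != GAP:
            pos += 1
            n_ali += 1
        identical = t != GAP and m != GAP and t == m and t in STANDARD_AA
        positive = (t in STANDARD_AA and m in STANDARD_AA
                    and matrix[t][m] > 0)
        if identical:
            n_iden += 1
        if positive:
            n_pos += 1
        if t != GAP and pos in members:
            n_int_ali += 1
            if identical:
                int_iden += 1
            if positive:
                int_pos += 1
    out = {
        "q": 100.0 * n_ali / aln.target_full_length,
        "a_iden": 100.0 * n_iden / l_ali,
        "a_sim": 100.0 * n_pos / l_ali,
    }
    if members:
        out["q_int"] = 100.0 * n_int_ali / len(members)
        out["missing"] = len(members) - n_int_ali
        if n_int_ali:
            out["i_iden"] = 100.0 * int_iden / n_int_ali
            out["i_sim"] = 100.0 * int_pos / n_int_ali
    return out


def kabsch_rmsd_scipy(moving: np.ndarray, fixed: np.ndarray) -> float:
    """Optimal superposition RMSD via scipy's align_vectors."""
    mc = moving - moving.mean(axis=0)
    fc = fixed - fixed.mean(axis=0)
    _, rssd = Rotation.align_vectors(fc, mc)
    return float(rssd / np.sqrt(len(moving)))


def weighted_polyfit_normal_equations(x, y, w, degree):
    """Weighted least squares by explicitly solving X'WX b = X'Wy.

    Returns coefficients in ascending powers.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    W = np.diag(np.asarray(w, float))
    X = np.vander(x, degree + 1, increasing=True)
    return np.linalg.solve(X.T @ W @ X, X.T @ W @ y)
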