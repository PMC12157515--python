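"""Independent reference computations used to cross-check the geometry
module.  These deliberately avoid the package's own superposition and
trimming code paths: rotations come from scipy (Horn-style quaternion
alignment) or brute-force numeric optimization, and trimming is
re-derived by plain slicing."""

import numpy as np
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation


def oracle_superpose_rmsd(mobile, target):
    """Minimized RMSD via scipy's quaternion-based alignment."""
    P = np.asarray(mobile, float)
    Q = np.asarray(target, float)
    Pc = P - P.mean(axis=0)
    Qc = Q - Q.mean(axis=0)
    _, rssd = Rotation.align_vectors(Qc, Pc)
    return rssd / np.sqrt(len(P))


def oracle_superpose_bruteforce(mobile, target, n_starts=8, seed=0):
    """Minimized RMSD by numeric optimization over rotation vectors."""
    P = np.asarray(mobile, float)
    Q = np.asarray(target, float)
    Pc = P - P.mean(axis=0)
    Qc = Q - Q.mean(axis=0)

    def cost(rotvec):
        R = Rotation.from_rotvec(rotvec).as_matrix()
        d = Pc @ R.T - Qc
        return (d ** 2).sum()

    rng = np.random.default_rng(seed)
    best = np.inf
    for _ in range(n_starts):
        res = minimize(cost, rng.uniform(-np.pi, np.pi, 3), method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-14,
                                "maxiter": 5000})
        best = min(best, res.fun)
    return np.sqrt(best / len(P))


def oracle_transform(mobile, target):
    """(R, t) of the optimal superposition, via scipy."""
    P = np.asarray(mobile, float)
    Q = np.asarray(target, float)
    rot, _ = Rotation.align_vectors(Q - Q.mean(axis=0), P - P.mean(axis=0))
    R = rot.as_matrix()
    t = Q.mean(axis=0) - R @ P.mean(axis=0)
    return R, t


def _trim_slice(rng_long, rng_short):
    """Independent statement of the central-window trimming rule."""
    la = rng_long[1] - rng_long[0] + 1
    lb = rng_short[1] - rng_short[0] + 1
    d = la - lb
    residues = list(range(rng_long[0], rng_long[1] + 1))
    kept = residues[d // 2: d // 2 + lb]
    return (kept[0], kept[-1])


def oracle_pairwise_helix_rmsd(a, ann_a, b, ann_b):
    """Sheet-aligned helix RMSD computed with scipy alignment and
    slicing-based trimming, atom by atom."""
    atoms = ("N", "CA", "C", "O")
    sheet_a = sorted(ann_a.sheet_residues)
    sheet_b = sorted(ann_b.sheet_residues)
    A_sheet = np.array([a.residue(i).coords[x] for i in sheet_a for x in atoms])
    B_sheet = np.array([b.residue(i).coords[x] for i in sheet_b for x in atoms])
    R, t = oracle_transform(B_sheet, A_sheet)
    sq_sum, n_atoms = 0.0, 0
    for ha, hb in zip(ann_a.helices, ann_b.helices):
        la = ha[1] - ha[0] + 1
        lb = hb[1] - hb[0] + 1
        if la > lb:
            ha = _trim_slice(ha, hb)
        elif lb > la:
            hb = _trim_slice(hb, ha)
        for ia, ib in zip(range(ha[0], ha[1] + 1), range(hb[0], hb[1] + 1)):
            for x in atoms:
                pa = a.residue(ia).coords[x]
                pb = R @ b.residue(ib).coords[x] + t
                sq_sum += ((pa - pb) ** 2).sum()
                n_atoms += 1
    return np.sqrt(sq_sum / n_atoms)


def oracle_lhl_rmsd(prediction, design, annotation):
    """LHL RMSD via scipy alignment on the non-reshaped residues."""
    atoms = ("N", "CA", "C", "O")
    lhl = set(annotation.lhl_residues)
    frame = [i for i in design.indices if i not in lhl]
    moving = [i for i in design.indices if i in lhl]
    P = np.array([prediction.residue(i).coords[x] for i in frame for x in atoms])
    Q = np.array([design.residue(i).coords[x] for i in frame for x in atoms])
    R, t = oracle_transform(P, Q)
    sq = 0.0
    n = 0
    for i in moving:
        for x in atoms:
            d = (R @ prediction.residue(i).coords[x] + t
                 - design.residue(i).coords[x])
            sq += (d ** 2).sum()
            n += 1
    return np.sqrt(sq / n)
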