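"""Independent straight-line reference implementations used as test oracles.

Everything here is deliberately naive — explicit loops, no spatial index,
no caching, no reuse of the package's statistics — so that agreement with
the package is evidence, not tautology. These functions were written (and
their frozen expected values computed) before the corresponding package
code was finalised, directly from the standard definitions.
"""

from __future__ import annotations

import math

import numpy as np


# ---------------------------------------------------------------------------
# population genetics (operate on plain lists of equal-length strings)


def oracle_segregating_sites(rows: list[str]) -> int:
    L = len(rows[0])
    return sum(1 for c in range(L) if len({r[c] for r in rows}) > 1)


def oracle_pi(rows: list[str]) -> float:
    n = len(rows)
    L = len(rows[0])
    total = 0
    pairs = 0
    for i in range(n):
        for j in range(i + 1, n):
            pairs += 1
            total += sum(1 for c in range(L) if rows[i][c] != rows[j][c])
    return total / pairs


def oracle_tajimas_d(rows: list[str]) -> float | None:
    """Straight-line evaluation of the Tajima (1989) coefficient chain."""
    n = len(rows)
    S = oracle_segregating_sites(rows)
    if S == 0 or n < 3:
        return None
    pi = oracle_pi(rows)
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n * n + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    variance = e1 * S + e2 * S * (S - 1)
    if variance <= 0:  # identically zero at n = 3: D undefined
        return None
    return (pi - S / a1) / math.sqrt(variance)


def oracle_entropy_bits(rows: list[str]) -> list[float]:
    out = []
    for c in range(len(rows[0])):
        col = [r[c] for r in rows]
        ent = 0.0
        for state in set(col):
            p = col.count(state) / len(col)
            ent -= p * math.log2(p)
        out.append(ent)
    return out


# ---------------------------------------------------------------------------
# spatial neighborhoods (O(n^2), straight from atom coordinates)


def _residue_points(residue, metric: str, include_hydrogens: bool) -> np.ndarray:
    if metric == "c-alpha":
        ca = [a for a in residue.atoms if a.name == "CA"]
        return np.asarray([ca[0].coord]) if ca else np.empty((0, 3))
    pts = [a.coord for a in residue.atoms if include_hydrogens or not a.is_hydrogen]
    if not pts:
        pts = [a.coord for a in residue.atoms]
    return np.asarray(pts)


def oracle_residue_distance(a, b, metric: str, include_hydrogens: bool = False) -> float:
    pa = _residue_points(a, metric, include_hydrogens)
    pb = _residue_points(b, metric, include_hydrogens)
    if metric == "centroid":
        return float(np.linalg.norm(pa.mean(axis=0) - pb.mean(axis=0)))
    best = math.inf
    for x in pa:
        for y in pb:
            best = min(best, float(np.linalg.norm(x - y)))
    return best


def oracle_neighbors(structure, center_id, radius: float, metric: str,
                     include_hetero: bool = False, include_hydrogens: bool = False,
                     chain_scope: str = "all-chains") -> list:
    """Brute-force scan over every residue pair; closed ball (<= radius)."""
    residues = [
        r for r in structure.residues()
        if include_hetero or not r.is_hetero
    ]
    if metric == "c-alpha":
        residues = [r for r in residues if any(a.name == "CA" for a in r.atoms)]
    center = next(r for r in residues if r.id == center_id)
    out = []
    for r in residues:
        if chain_scope == "same-chain" and r.id.chain != center_id.chain:
            continue
        if oracle_residue_distance(center, r, metric, include_hydrogens) <= radius:
            out.append(r.id)
    return sorted(out)


def oracle_neighbors_vectorized(structure, radius: float, metric: str) -> dict:
    """All-centers brute force using one dense atom distance matrix.

    Still index-free (plain cdist + masks); used where per-pair Python loops
    would be too slow. Returns {center_id: sorted neighbor ids}.
    """
    from scipy.spatial.distance import cdist

    residues = [r for r in structure.residues() if not r.is_hetero]
    if metric == "c-alpha":
        residues = [r for r in residues if any(a.name == "CA" for a in r.atoms)]
        pts = np.asarray([next(a for a in r.atoms if a.name == "CA").coord for r in residues])
        dmat = cdist(pts, pts)
    elif metric == "centroid":
        pts = np.asarray([_residue_points(r, "centroid", False).mean(axis=0) for r in residues])
        dmat = cdist(pts, pts)
    else:
        coords = []
        owner = []
        for i, r in enumerate(residues):
            p = _residue_points(r, "min-atom", False)
            coords.append(p)
            owner.extend([i] * len(p))
        coords = np.concatenate(coords)
        owner = np.asarray(owner)
        atom_d = cdist(coords, coords)
        nres = len(residues)
        dmat = np.full((nres, nres), np.inf)
        np.minimum.at(dmat, (owner[:, None], owner[None, :]), atom_d)
    out = {}
    for i, r in enumerate(residues):
        out[r.id] = sorted(residues[j].id for j in np.flatnonzero(dmat[i] <= radius))
    return out


# ---------------------------------------------------------------------------
# end-to-end reference pipeline (no index, no caching)


def oracle_window_scores(structure, aln_rows: list[str], rmap, radius: float,
                         metric: str = "min-atom", stat: str = "tajimas-d") -> dict:
    """Straight-line pipeline: brute-force neighbors, manual column gather,
    complete deletion, oracle statistic. ``rmap`` supplies residue→columns."""
    residues = [r for r in structure.residues() if not r.is_hetero]
    scores = {}
    for center in residues:
        window = oracle_neighbors(structure, center.id, radius, metric)
        cols: list[int] = []
        for rid in sorted(window):
            c = rmap.columns_for(rid)
            if c is not None:
                cols.extend(c)
        if not cols:
            scores[center.id] = None
            continue
        sub = ["".join(row[c - 1] for c in cols) for row in aln_rows]
        keep = [
            k for k in range(len(cols))
            if not ({sub_r[k] for sub_r in sub} & {"-", "N"})
        ]
        sub = ["".join(r[k] for k in keep) for r in sub]
        if not sub[0]:
            scores[center.id] = None
            continue
        if stat == "tajimas-d":
            scores[center.id] = oracle_tajimas_d(sub)
        elif stat == "pi":
            scores[center.id] = oracle_pi(sub)
        elif stat == "seg-sites":
            scores[center.id] = float(oracle_segregating_sites(sub))
        else:
            raise ValueError(stat)
    return scores
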