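"""Brute-force flux-polytope vertex enumeration.

An independent reference method for checking LP-based FBA/FVA results on
tiny networks: the feasible set {v : S v = 0, A v <= b, lb <= v <= ub}
is projected onto the null space of S, every vertex of the resulting
low-dimensional polytope is enumerated by solving all d-subsets of
active inequality constraints with plain linear algebra, and flux ranges
are read off as min/max over vertices.  Because an LP optimum is always
attained at a vertex of a bounded polytope, these ranges equal FVA
ranges exactly (up to numerical tolerance).

Complexity is combinatorial; intended for networks of at most a dozen
reactions.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
from scipy.linalg import null_space

from .core import TaxonModel, build_lp_arrays


def enumerate_vertices(
    S: np.ndarray,
    lb: np.ndarray,
    ub: np.ndarray,
    A: np.ndarray | None = None,
    b: np.ndarray | None = None,
    tol: float = 1e-7,
) -> np.ndarray:
    """All vertices of {v : S v = 0, A v <= b, lb <= v <= ub}.

    Returns an array of shape (n_vertices, n_reactions); empty when the
    polytope is empty.  The polytope must be bounded (finite lb/ub
    guarantee this).
    """
    n = S.shape[1]
    N = null_space(S) if S.size else np.eye(n)
    if N.size == 0:
        # unique solution v = 0; a vertex iff feasible
        v = np.zeros(n)
        ok = np.all(v >= lb - tol) and np.all(v <= ub + tol)
        if ok and A is not None:
            ok = np.all(A @ v <= b + tol)
        return v[None, :] if ok else np.empty((0, n))
    d = N.shape[1]

    # inequalities G z <= h in null-space coordinates (v = N z)
    G_rows = [N, -N]
    h_rows = [ub, -lb]
    if A is not None and len(A):
        G_rows.append(A @ N)
        h_rows.append(np.asarray(b, dtype=float))
    G = np.vstack(G_rows)
    h = np.concatenate(h_rows)

    vertices: list[np.ndarray] = []
    for subset in combinations(range(len(G)), d):
        Gs = G[list(subset)]
        hs = h[list(subset)]
        try:
            z = np.linalg.solve(Gs, hs)
        except np.linalg.LinAlgError:
            continue
        if not np.all(np.isfinite(z)):
            continue
        # guard against ill-conditioned subsets
        if np.max(np.abs(Gs @ z - hs)) > tol * max(1.0, np.max(np.abs(hs))):
            continue
        scale = max(1.0, float(np.max(np.abs(h))))
        if np.all(G @ z <= h + tol * scale):
            vertices.append(N @ z)
    if not vertices:
        return np.empty((0, n))
    V = np.vstack(vertices)
    # deduplicate
    order = np.lexsort(V.T)
    V = V[order]
    keep = np.ones(len(V), dtype=bool)
    for i in range(1, len(V)):
        if np.max(np.abs(V[i] - V[i - 1])) < 1e-6:
            keep[i] = False
    return V[keep]


def vertex_fva(
    model: TaxonModel, reactions: list[str] | None = None
) -> dict[str, tuple[float, float]]:
    """FVA ranges by exhaustive vertex enumeration (reference method)."""
    arrays = build_lp_arrays(model)
    V = enumerate_vertices(arrays.S, arrays.lb, arrays.ub, arrays.A_ub, arrays.b_ub)
    if V.shape[0] == 0:
        raise ValueError("flux polytope is empty (model infeasible)")
    if reactions is None:
        reactions = [r.id for r in model.exchanges()]
    out = {}
    for rid in reactions:
        j = arrays.index[rid]
        out[rid] = (float(V[:, j].min()), float(V[:, j].max()))
    return out


def vertex_fba_max(model: TaxonModel, objective: str) -> float:
    """Maximal flux of ``objective`` by vertex enumeration."""
    return vertex_fva(model, [objective])[objective][1]
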