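"""Modified Shepard scattered-data interpolation (Franke-Nielson / Renka).

The interpolant blends local weighted-least-squares quadratic "nodal
functions" with compactly supported inverse-distance weights:

    F(p) = sum_k W_k(p) Q_k(p) / sum_k W_k(p)

    W_k(p) = [ (R_k - d_k)_+ / (R_k d_k) ]^2

where Q_k is a quadratic fitted around node k to its ``nq`` nearest other
nodes (constant term pinned to the node's own value, so F interpolates the
data exactly), d_k is the distance from p to node k, and R_k is the radius of
the ball about node k holding its ``nw`` nearest other nodes.  The weights
vanish at R_k, so F has compact local support and is continuous; with enough
neighbours (nq >= 13) any global bivariate quadratic is reproduced exactly.

Degenerate inputs degrade gracefully: fewer than 5 neighbours drop the fit to
linear, fewer than 2 to a constant; coincident nodes with equal values are
merged, with conflicting values rejected.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree

__all__ = ["ModifiedShepard", "fit_nodal_functions", "shepard_interpolate"]

_DUP_TOL = 1e-9          # planar km; below this two nodes are "the same place"


def _merge_duplicates(nodes, values):
    """Collapse coincident nodes; conflicting values are an error."""
    order = np.lexsort((nodes[:, 1], nodes[:, 0]))
    keep, val_of = [], {}
    for i in order:
        matched = False
        for j in keep:
            if (abs(nodes[i, 0] - nodes[j, 0]) <= _DUP_TOL
                    and abs(nodes[i, 1] - nodes[j, 1]) <= _DUP_TOL):
                if abs(values[i] - val_of[j]) > 1e-9 * max(1.0, abs(val_of[j])):
                    raise ValueError(
                        f"duplicate node locations with conflicting values: "
                        f"index {j} ({val_of[j]!r}) vs index {i} ({values[i]!r}) "
                        f"at {tuple(nodes[i])}")
                matched = True
                break
        if not matched:
            keep.append(i)
            val_of[i] = values[i]
    keep = sorted(keep)
    return nodes[keep], values[keep]


class ModifiedShepard:
    """Fitted Modified Shepard interpolant over planar nodes.

    Parameters
    ----------
    nodes : (n, 2) array
        Planar node coordinates (km).
    values : (n,) array
        Data values at the nodes.
    nq : int
        Neighbours used for each local quadratic fit (>= 5 for quadratic;
        smaller sets fall back to linear / constant fits).
    nw : int
        Neighbours defining each node's weight radius R_k.
    """

    def __init__(self, nodes, values, nq=13, nw=19):
        nodes = np.atleast_2d(np.asarray(nodes, dtype=float))
        values = np.asarray(values, dtype=float).ravel()
        if nodes.shape[0] != values.shape[0]:
            raise ValueError("nodes and values length mismatch")
        if nodes.shape[0] == 0:
            raise ValueError("empty nodal set")
        if nw < 1:
            raise ValueError("nw must be >= 1")
        nodes, values = _merge_duplicates(nodes, values)
        self.nodes, self.values = nodes, values
        self.nq, self.nw = int(nq), int(nw)
        n = len(values)
        # coefficients of Q_k in local coords: [dx, dy, dx^2, dx*dy, dy^2]
        self.coef = np.zeros((n, 5))
        if n == 1:
            self.radius = np.array([np.inf])
            return
        tree = cKDTree(nodes)
        kq = min(self.nq, n - 1)
        kw = min(self.nw, n - 1)
        kmax = max(kq, kw)
        dists, idx = tree.query(nodes, k=kmax + 1)  # includes the node itself
        dists, idx = dists[:, 1:], idx[:, 1:]
        self.radius = dists[:, kw - 1].copy()
        # tiny inflation keeps at least one strictly positive weight per node
        self.radius *= 1.0 + 1e-12

        for k in range(n):
            d = dists[k, :kq]
            nb = idx[k, :kq]
            rq = d[kq - 1] * (1.0 + 1e-12)
            w = ((rq - d) / (rq * d)) ** 2
            pos = w > 0
            d, nb, w = d[pos], nb[pos], w[pos]
            if len(nb) == 0:
                continue
            dx = nodes[nb, 0] - nodes[k, 0]
            dy = nodes[nb, 1] - nodes[k, 1]
            rhs = values[nb] - values[k]
            if len(nb) >= 5:
                basis = np.column_stack([dx, dy, dx * dx, dx * dy, dy * dy])
                cols = slice(0, 5)
            elif len(nb) >= 2:
                basis = np.column_stack([dx, dy])
                cols = slice(0, 2)
            else:  # single neighbour: constant nodal function
                continue
            sw = np.sqrt(w)
            sol, *_ = np.linalg.lstsq(basis * sw[:, None], rhs * sw,
                                      rcond=None)
            self.coef[k, cols] = sol

    def _eval_nodal(self, k_arr, px, py):
        """Evaluate Q_k at points; k_arr, px, py aligned 1-D arrays."""
        dx = px - self.nodes[k_arr, 0]
        dy = py - self.nodes[k_arr, 1]
        c = self.coef[k_arr]
        return (self.values[k_arr] + c[:, 0] * dx + c[:, 1] * dy
                + c[:, 2] * dx * dx + c[:, 3] * dx * dy + c[:, 4] * dy * dy)

    def __call__(self, points):
        """Interpolate at query points, shape (m, 2) -> (m,).

        Exact at nodes.  Queries outside every node's weight radius fall back
        to the nearest node's value (documented extrapolation rule).
        """
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        n, m = len(self.values), len(pts)
        if n == 1:
            return np.full(m, self.values[0])
        # full distance matrix: node counts here are O(10^2..10^3)
        diff = pts[:, None, :] - self.nodes[None, :, :]
        d = np.hypot(diff[..., 0], diff[..., 1])
        out = np.empty(m)
        hit = d <= _DUP_TOL
        exact = hit.any(axis=1)
        if exact.any():
            out[exact] = self.values[hit[exact].argmax(axis=1)]
        rest = ~exact
        if rest.any():
            dr = d[rest]
            w = np.zeros_like(dr)
            inside = dr < self.radius[None, :]
            w[inside] = (((self.radius[None, :] - dr)[inside]
                          / (self.radius[None, :] * dr)[inside]) ** 2)
            wsum = w.sum(axis=1)
            vals = np.empty(rest.sum())
            covered = wsum > 0
            if covered.any():
                qi, ki = np.nonzero(w[covered] > 0)
                rows = np.nonzero(covered)[0]
                q = self._eval_nodal(ki, pts[rest][rows[qi], 0],
                                     pts[rest][rows[qi], 1])
                num = np.zeros(covered.sum())
                np.add.at(num, qi, w[covered][qi, ki] * q)
                vals[covered] = num / wsum[covered]
            if (~covered).any():
                nearest = dr[~covered].argmin(axis=1)
                vals[~covered] = self.values[nearest]
            out[rest] = vals
        return out


def fit_nodal_functions(nodes, values, nq=13, nw=19) -> ModifiedShepard:
    """Fit the local quadratic nodal functions; returns the interpolant."""
    return ModifiedShepard(nodes, values, nq=nq, nw=nw)


def shepard_interpolate(interp: ModifiedShepard, points):
    """Evaluate a fitted Modified Shepard interpolant at query points."""
    return interp(points)
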