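"""Exact Shapley values for gradient-boosted trees, in float64.

Implements the polynomial-time TreeSHAP algorithm (path-extension /
unwinding over each decision path, feature absence weighted by node
cover) directly on the dumped tree ensemble. Working entirely in float64
keeps the local-accuracy identity

    base value + sum_f phi_f(x) = margin prediction f(x)

exact to machine precision, which the attribution layer asserts at 1e-6.
xgboost's built-in ``pred_contribs`` (the same algorithm, float32
output buffers) serves as an independent cross-check in the test suite.
"""

from __future__ import annotations

import json

import numpy as np
from numba import njit

__all__ = ["TreeEnsemble", "shap_values", "margin_predictions"]


class TreeEnsemble:
    """Flattened array view of an xgboost booster (regression, one group)."""

    def __init__(self, booster):
        feature_names = booster.feature_names
        dump = booster.get_dump(dump_format="json", with_stats=True)
        lefts, rights, miss, feats, thresholds, values, covers = (
            [] for _ in range(7)
        )
        offsets = [0]
        maxdepth = 0
        for s in dump:
            root = json.loads(s)
            nodes: dict[int, dict] = {}
            stack = [(root, 0)]
            while stack:
                nd, depth = stack.pop()
                maxdepth = max(maxdepth, depth)
                nodes[nd["nodeid"]] = nd
                for ch in nd.get("children", []):
                    stack.append((ch, depth + 1))
            n = max(nodes) + 1
            base = offsets[-1]
            left = np.full(n, -1, np.int64)
            right = np.full(n, -1, np.int64)
            missing = np.full(n, -1, np.int64)
            feat = np.full(n, -1, np.int64)
            thresh = np.zeros(n)
            val = np.zeros(n)
            cover = np.zeros(n)
            for i, nd in nodes.items():
                cover[i] = nd["cover"]
                if "leaf" in nd:
                    val[i] = nd["leaf"]
                else:
                    left[i] = nd["yes"]
                    right[i] = nd["no"]
                    missing[i] = nd.get("missing", nd["yes"])
                    f = nd["split"]
                    if feature_names and f in feature_names:
                        feat[i] = feature_names.index(f)
                    else:
                        feat[i] = int(str(f).lstrip("f"))
                    thresh[i] = nd["split_condition"]
            lefts.append(left + base)
            rights.append(right + base)
            miss.append(missing + base)
            # leaf marker must survive the offset shift
            for arr in (lefts, rights, miss):
                arr[-1][arr[-1] < base] = -1
            feats.append(feat)
            thresholds.append(thresh)
            values.append(val)
            covers.append(cover)
            offsets.append(base + n)

        self.left = np.concatenate(lefts) if lefts else np.empty(0, np.int64)
        self.right = np.concatenate(rights) if rights else np.empty(0, np.int64)
        self.missing = np.concatenate(miss) if miss else np.empty(0, np.int64)
        self.feature = np.concatenate(feats) if feats else np.empty(0, np.int64)
        self.threshold = np.concatenate(thresholds) if thresholds else np.empty(0)
        self.value = np.concatenate(values) if values else np.empty(0)
        self.cover = np.concatenate(covers) if covers else np.empty(0)
        self.tree_roots = np.array(offsets[:-1], np.int64)
        self.max_depth = maxdepth
        cfg = json.loads(booster.save_config())
        self.base_score = float(
            cfg["learner"]["learner_model_param"]["base_score"]
        )
        self.n_features = booster.num_features()

    def expected_values(self) -> np.ndarray:
        """Cover-weighted expected margin of each tree."""
        left, right, value, cover = self.left, self.right, self.value, self.cover
        out = np.zeros(len(self.tree_roots))
        for t, root in enumerate(self.tree_roots):
            ev: dict[int, float] = {}
            order = []
            stack = [int(root)]
            while stack:
                nd = stack.pop()
                order.append(nd)
                if left[nd] >= 0:
                    stack.append(int(left[nd]))
                    stack.append(int(right[nd]))
            for nd in reversed(order):
                if left[nd] < 0:
                    ev[nd] = value[nd]
                else:
                    ev[nd] = (
                        cover[left[nd]] * ev[left[nd]]
                        + cover[right[nd]] * ev[right[nd]]
                    ) / cover[nd]
            out[t] = ev[int(root)]
        return out


@njit(cache=True)
def _extend(d, z, o, w, l, pz, po, pi):
    d[l] = pi
    z[l] = pz
    o[l] = po
    w[l] = 1.0 if l == 0 else 0.0
    for i in range(l - 1, -1, -1):
        w[i + 1] += po * w[i] * (i + 1) / (l + 1)
        w[i] = pz * w[i] * (l - i) / (l + 1)


@njit(cache=True)
def _unwind(d, z, o, w, l, idx):
    of = o[idx]
    zf = z[idx]
    nxt = w[l]
    for i in range(l - 1, -1, -1):
        if of != 0.0:
            tmp = w[i]
            w[i] = nxt * (l + 1) / ((i + 1) * of)
            nxt = tmp - w[i] * zf * (l - i) / (l + 1)
        else:
            w[i] = w[i] * (l + 1) / (zf * (l - i))
    for i in range(idx, l):
        d[i] = d[i + 1]
        z[i] = z[i + 1]
        o[i] = o[i + 1]


@njit(cache=True)
def _unwound_sum(z, o, w, l, idx):
    of = o[idx]
    zf = z[idx]
    nxt = w[l]
    total = 0.0
    if of != 0.0:
        for i in range(l - 1, -1, -1):
            tmp = nxt * (l + 1) / ((i + 1) * of)
            total += tmp
            nxt = w[i] - tmp * zf * (l - i) / (l + 1)
    else:
        for i in range(l - 1, -1, -1):
            total += w[i] / (zf * (l - i) / (l + 1))
    return total


@njit(cache=True)
def _tree_shap_one(left, right, missing, feat, thresh, val, cover, x, phi,
                   root, db, zb, ob, wb,
                   fr_node, fr_len, fr_rl, fr_pz, fr_po, fr_pi):
    """One sample, one tree: depth-first walk with an explicit frame stack.

    Path arrays are stored per recursion level (row ``rl``); a frame
    copies its parent's row before extending, and sibling subtrees reuse
    rows only after the first subtree has fully completed, so parent rows
    stay intact throughout.
    """
    top = 0
    fr_node[0] = root
    fr_len[0] = 0
    fr_rl[0] = 0
    fr_pz[0] = 1.0
    fr_po[0] = 1.0
    fr_pi[0] = -1
    top = 1
    while top > 0:
        top -= 1
        node = fr_node[top]
        depth = fr_len[top]
        rl = fr_rl[top]
        pz = fr_pz[top]
        po = fr_po[top]
        pi = fr_pi[top]
        for i in range(depth):
            db[rl, i] = db[rl - 1, i]
            zb[rl, i] = zb[rl - 1, i]
            ob[rl, i] = ob[rl - 1, i]
            wb[rl, i] = wb[rl - 1, i]
        d = db[rl]
        z = zb[rl]
        o = ob[rl]
        w = wb[rl]
        _extend(d, z, o, w, depth, pz, po, pi)
        l = depth
        if left[node] < 0:
            for i in range(1, l + 1):
                s = _unwound_sum(z, o, w, l, i)
                phi[d[i]] += s * (o[i] - z[i]) * val[node]
        else:
            f = feat[node]
            xv = x[f]
            if np.isnan(xv):
                hot = missing[node]
            elif xv < thresh[node]:
                hot = left[node]
            else:
                hot = right[node]
            cold = right[node] if hot == left[node] else left[node]
            iz = 1.0
            io = 1.0
            k = -1
            for i in range(1, l + 1):
                if d[i] == f:
                    k = i
                    break
            if k >= 0:
                iz = z[k]
                io = o[k]
                _unwind(d, z, o, w, l, k)
                l -= 1
            # push cold first so the hot subtree (using rows > rl) fully
            # completes before the cold frame re-reads row rl
            fr_node[top] = cold
            fr_len[top] = l + 1
            fr_rl[top] = rl + 1
            fr_pz[top] = cover[cold] / cover[node] * iz
            fr_po[top] = 0.0
            fr_pi[top] = f
            top += 1
            fr_node[top] = hot
            fr_len[top] = l + 1
            fr_rl[top] = rl + 1
            fr_pz[top] = cover[hot] / cover[node] * iz
            fr_po[top] = io
            fr_pi[top] = f
            top += 1


@njit(cache=True)
def _shap_all(left, right, missing, feat, thresh, val, cover, roots,
              X, n_features, maxlen):
    n = X.shape[0]
    phi = np.zeros((n, n_features + 1))
    db = np.zeros((maxlen, maxlen), np.int64)
    zb = np.zeros((maxlen, maxlen))
    ob = np.zeros((maxlen, maxlen))
    wb = np.zeros((maxlen, maxlen))
    nstack = 2 * maxlen + 4
    fr_node = np.zeros(nstack, np.int64)
    fr_len = np.zeros(nstack, np.int64)
    fr_rl = np.zeros(nstack, np.int64)
    fr_pz = np.zeros(nstack)
    fr_po = np.zeros(nstack)
    fr_pi = np.zeros(nstack, np.int64)
    for s in range(n):
        for t in range(len(roots)):
            _tree_shap_one(left, right, missing, feat, thresh, val, cover,
                           X[s], phi[s], roots[t], db, zb, ob, wb,
                           fr_node, fr_len, fr_rl, fr_pz, fr_po, fr_pi)
    return phi


@njit(cache=True)
def _margins(left, right, missing, feat, thresh, val, roots, X):
    n = X.shape[0]
    out = np.zeros(n)
    for s in range(n):
        acc = 0.0
        for t in range(len(roots)):
            nd = roots[t]
            while left[nd] >= 0:
                xv = X[s, feat[nd]]
                if np.isnan(xv):
                    nd = missing[nd]
                elif xv < thresh[nd]:
                    nd = left[nd]
                else:
                    nd = right[nd]
            acc += val[nd]
        out[s] = acc
    return out


def shap_values(ens: TreeEnsemble, X: np.ndarray) -> tuple[np.ndarray, float]:
    """Per-sample, per-feature Shapley values and the scalar base value.

    Returns ``(phi, base)`` with ``phi`` of shape ``(n, n_features)``;
    ``base + phi.sum(axis=1)`` equals the margin prediction exactly.
    """
    X = np.ascontiguousarray(X, dtype=np.float64)
    base = ens.base_score + float(ens.expected_values().sum())
    if len(ens.tree_roots) == 0:
        return np.zeros((X.shape[0], ens.n_features)), base
    maxlen = ens.max_depth + 3
    phi = _shap_all(
        ens.left, ens.right, ens.missing, ens.feature, ens.threshold,
        ens.value, ens.cover, ens.tree_roots, X, ens.n_features, maxlen
    )
    # column n_features accumulates nothing in this formulation; the base
    # value is the sum of tree expectations plus the global bias.
    return phi[:, : ens.n_features], base


def margin_predictions(ens: TreeEnsemble, X: np.ndarray) -> np.ndarray:
    """Float64 margin predictions (base_score + summed leaf values)."""
    X = np.ascontiguousarray(X, dtype=np.float64)
    if len(ens.tree_roots) == 0:
        return np.full(X.shape[0], ens.base_score)
    return ens.base_score + _margins(
        ens.left, ens.right, ens.missing, ens.feature, ens.threshold,
        ens.value, ens.tree_roots, X
    )
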