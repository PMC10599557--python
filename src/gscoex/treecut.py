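"""Dynamic tree cut for average-linkage dendrograms of 1 - TOM dissimilarity.

A shape-adaptive re-implementation of the hybrid dynamic-cut idea (without the
PAM-like reassignment stage). Thresholds derive from the dendrogram's own height
range [h_ref, h_cut] (h_ref = 5th percentile of merge heights, h_cut defaults to
99% of the truncated range), so the cut adapts to the overall density of the
network. For a deep-split level ``d`` in 0..4 with permissiveness ``s_d`` in
(0.64, 0.73, 0.82, 0.91, 0.95), define ``max_join = h_ref + s_d * span`` and
``min_gap = 0.75 * (1 - s_d) * span`` with ``span = h_cut - h_ref``.

Two height statistics describe a branch:

* its *join height* — the height of its own top merge;
* its *completion height* — the 90th percentile of all merge heights inside the
  branch. Tight branches (co-expression modules) accrete their genes over a
  narrow low height band, so completion sits close to (and robustly below) the
  join even when stray genes attach one by one near the top.

Walking down from the root:

* a merge whose two sides each carry at least ``stray_min`` leaves is a
  *junction*. A junction is **split** into separate candidates when both sides
  hold ``min_module_size`` leaves, complete below ``max_join``, and are
  separated from the junction by at least ``min_gap`` — the signature of two
  real branches glued together above their cores;
* otherwise a branch is **accepted** as a module at the first node whose join
  height clears both ``max_join`` and a ``min_gap`` drop below the enclosing
  junction; descending to that node sheds the stray genes that accreted above
  it, which stay unassigned (label 0, downstream "grey").

Higher deep-split levels accept looser branches and demand smaller gaps,
producing more and smaller modules. The procedure is deterministic; within a
merge, ties resolve by scipy's leaf ordering (lower gene index first).
"""

from __future__ import annotations

import numpy as np

_PERMISSIVENESS = {0: 0.64, 1: 0.73, 2: 0.82, 3: 0.91, 4: 0.95}
_N_BINS = 512
_COMPLETION_Q = 0.9


def cut_tree_dynamic(
    Z: np.ndarray,
    min_module_size: int = 30,
    deep_split: int = 2,
    cut_height: float | None = None,
    stray_min: int | None = None,
) -> np.ndarray:
    """Assign each leaf a module number (1..k, 0 = unassigned) from linkage ``Z``."""
    if deep_split not in _PERMISSIVENESS:
        raise ValueError("deep_split must be an integer in 0..4")
    if min_module_size < 3:
        raise ValueError("min_module_size must be >= 3")
    n = Z.shape[0] + 1
    labels = np.zeros(n, dtype=int)
    if n < min_module_size:
        return labels
    if stray_min is None:
        stray_min = max(3, min_module_size // 3)
    heights = Z[:, 2]
    h_ref = float(np.percentile(heights, 5))
    h_top = float(heights.max())
    if cut_height is None:
        cut_height = h_ref + 0.99 * (h_top - h_ref)
    span = max(cut_height - h_ref, np.finfo(float).tiny)
    s = _PERMISSIVENESS[deep_split]
    max_join = h_ref + s * span
    # strictly positive floor keeps flat (tie-height) trees from shattering
    min_gap = max(0.75 * (1.0 - s) * span, 1e-10)

    # leaves are 0..n-1, internal node i is n+i with height Z[i, 2]
    left = Z[:, 0].astype(int)
    right = Z[:, 1].astype(int)
    count = np.ones(2 * n - 1, dtype=int)
    dist = np.zeros(2 * n - 1)
    # binned histogram of subtree merge heights -> robust completion quantile
    scale = _N_BINS / max(h_top, np.finfo(float).tiny)
    bins = np.minimum((heights * scale).astype(int), _N_BINS - 1)
    hist = np.zeros((2 * n - 1, _N_BINS), dtype=np.int32)
    completion = np.zeros(2 * n - 1)
    for i in range(n - 1):
        v = n + i
        l, r = left[i], right[i]
        count[v] = count[l] + count[r]
        dist[v] = heights[i]
        hist[v] = hist[l] + hist[r]
        hist[v, bins[i]] += 1
        cum = np.cumsum(hist[v])
        q = int(np.searchsorted(cum, _COMPLETION_Q * cum[-1]))
        completion[v] = (q + 1) / scale

    def tight(v: int) -> bool:
        return count[v] >= min_module_size and completion[v] <= max_join

    def leaves(v: int) -> list[int]:
        out, stack = [], [v]
        while stack:
            u = stack.pop()
            if u < n:
                out.append(u)
            else:
                stack.append(left[u - n])
                stack.append(right[u - n])
        return out

    def acceptable(u: int, attach: float) -> bool:
        return dist[u] <= max_join and attach - dist[u] >= min_gap

    next_label = 1
    stack = [(2 * n - 2, np.inf)]  # (branch top, height of the enclosing junction)
    while stack:
        v, attach = stack.pop()
        # walk the stray chain down to the first junction, remembering the
        # highest acceptable node on the way (module core plus low strays)
        cand = None
        junction = None
        u = v
        while u >= n and count[u] >= min_module_size:
            if cand is None and acceptable(u, attach):
                cand = u
            l, r = left[u - n], right[u - n]
            if min(count[l], count[r]) >= stray_min:
                junction = u
                break
            u = l if count[l] >= count[r] else r
        if junction is not None:
            l, r = left[junction - n], right[junction - n]
            if (
                tight(l)
                and tight(r)
                and dist[junction] - completion[l] >= min_gap
                and dist[junction] - completion[r] >= min_gap
            ):
                # two real branches glued together: substructure wins
                stack.append((l, dist[junction]))
                stack.append((r, dist[junction]))
                continue
            if cand is None:
                stack.append((l, dist[junction]))
                stack.append((r, dist[junction]))
                continue
        if cand is not None:
            labels[leaves(cand)] = next_label
            next_label += 1
    return labels
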