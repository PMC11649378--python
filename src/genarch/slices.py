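"""Time-sliced trait trajectories along a dated tree.

Reconstructed node states are interpolated linearly along every branch
(state changes at a constant rate within a branch), so the trait value can
be read off at any age, not only at nodes.  With ages in Myr before present
(parent age ``t0`` larger than child age ``t1``), a branch's line is
``v(t) = m·t + b`` with ``m = (v_t0 − v_t1)/(t0 − t1)`` and
``b = v_t0 − m·t0``.  Sampling all branches of a clade on a fixed age grid
(default spacing 5 Myr) yields per-clade trajectories summarized by their
median and mean.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

from .tree import DatedTree, TreeNode, assign_branches

__all__ = ["branch_line", "slice_values", "clade_trajectory"]


def branch_line(t0: float, t1: float, v0: float, v1: float) -> tuple[float, float]:
    """Slope and intercept of the linear state change along one branch."""
    if not t0 > t1:
        raise ValueError("parent age t0 must exceed child age t1 (zero-length branch)")
    m = (v0 - v1) / (t0 - t1)
    b = v0 - m * t0
    return m, b


def _node_states(tree: DatedTree, states: Mapping) -> dict[TreeNode, float]:
    """Accept states keyed by node, clade key, or tip name."""
    sample_key = next(iter(states))
    if isinstance(sample_key, TreeNode):
        return dict(states)
    return {node: float(states[tree.clade_key(node)]) for node in tree.nodes()}


def slice_values(
    tree: DatedTree, states: Mapping, t: float
) -> dict[TreeNode, float]:
    """Interpolated value of every branch alive at age ``t``.

    A branch (child node ``c``) is alive when ``age(c) ≤ t ≤ age(parent)``;
    zero-length branches are excluded.  Outside ``[0, root age]`` the result
    is empty.
    """
    node_states = _node_states(tree, states)
    ages = tree.ages()
    out: dict[TreeNode, float] = {}
    for child in tree.branches():
        t0, t1 = ages[child.parent], ages[child]
        if t0 <= t1:
            continue
        if t1 <= t <= t0:
            m, b = branch_line(t0, t1, node_states[child.parent], node_states[child])
            out[child] = m * t + b
    return out


def clade_trajectory(
    tree: DatedTree,
    states: Mapping,
    clade_map: Mapping[str, str],
    dt: float = 5.0,
    include_stem: bool = False,
) -> pd.DataFrame:
    """Per-clade trait trajectory on an age grid anchored at the present.

    Returns rows ``(clade, time, median, mean, n_branches)``; ages at which
    a clade has no living branch are omitted.  Both median and mean are
    reported because either may be the preferred per-slice summary.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    labels = assign_branches(tree, clade_map)
    root_age = tree.root_age()
    grid = np.arange(0.0, root_age + 0.5 * dt, dt)
    grid = grid[grid <= root_age + 1e-12]
    rows = []
    for t in grid:
        values = slice_values(tree, states, float(t))
        per_clade: dict[str, list[float]] = {}
        for branch, val in values.items():
            label = labels[branch]
            if label == "stem" and not include_stem:
                continue
            per_clade.setdefault(label, []).append(val)
        for label, vals in sorted(per_clade.items()):
            arr = np.asarray(vals)
            rows.append(
                {
                    "clade": label,
                    "time": float(t),
                    "median": float(np.median(arr)),
                    "mean": float(np.mean(arr)),
                    "n_branches": int(arr.size),
                }
            )
    return pd.DataFrame(rows)
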