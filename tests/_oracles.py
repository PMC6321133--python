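"""Independent brute-force oracles shared by unit and acceptance tests.

These are deliberately naive re-derivations from first principles; they never
call the library code paths they are used to check.
"""

import itertools

import numpy as np


# ---------------------------------------------------------------------------
# Trees as nested tuples: a leaf is ("name", length); an internal node is
# (children_tuple, length).  Root length is ignored.


def enumerate_rooted_binary_trees(leaves):
    """All rooted binary topologies over the given leaf names."""
    if len(leaves) == 1:
        yield leaves[0]
        return
    first, rest = leaves[0], leaves[1:]
    for k in range(0, len(rest)):
        for left_rest in itertools.combinations(rest, k):
            left = (first,) + left_rest
            right = tuple(x for x in rest if x not in left_rest)
            if not right:
                continue
            for lt in enumerate_rooted_binary_trees(left):
                for rt in enumerate_rooted_binary_trees(right):
                    yield (lt, rt)


def assign_lengths(topology, rng):
    """Attach pseudo-random positive branch lengths to every node, turning a
    bare topology (str leaf or 2-tuple of topologies) into the (node, length)
    form used by the branch-walk functions."""
    length = round(float(rng.uniform(0.1, 2.0)), 3)
    if isinstance(topology, str):
        return (topology, length)
    return (tuple(assign_lengths(c, rng) for c in topology), length)


def to_newick(tree, root=True):
    node, length = tree
    if isinstance(node, str):
        body = f"{node}:{length}"
    else:
        body = "(" + ",".join(to_newick(c, root=False) for c in node) + ")"
        if not root:
            body += f":{length}"
    return body + (";" if root else "")


def _leafset(tree):
    node, _ = tree
    if isinstance(node, str):
        return frozenset([node])
    out = frozenset()
    for child in node:
        out |= _leafset(child)
    return out


def branch_walk_unifrac(tree, abund_a, abund_b, weighted=False,
                        normalized=False):
    """UniFrac by exhaustively walking every branch of a nested-tuple tree.

    ``abund_a``/``abund_b`` map leaf name -> abundance.  Unweighted returns
    unique/total covered branch length over presence sets; weighted returns
    sum_b l_b |A_b/A_T - B_b/B_T| (optionally normalised by
    sum_b l_b (A_b/A_T + B_b/B_T)).
    """
    branches = list(_collect_branches(tree))
    a_total = sum(abund_a.values())
    b_total = sum(abund_b.values())
    if weighted:
        num = 0.0
        den = 0.0
        for leaves, length in branches:
            pa = sum(abund_a.get(x, 0) for x in leaves) / a_total
            pb = sum(abund_b.get(x, 0) for x in leaves) / b_total
            num += length * abs(pa - pb)
            den += length * (pa + pb)
        return num / den if normalized else num
    unique = 0.0
    covered = 0.0
    for leaves, length in branches:
        in_a = any(abund_a.get(x, 0) > 0 for x in leaves)
        in_b = any(abund_b.get(x, 0) > 0 for x in leaves)
        if in_a or in_b:
            covered += length
            if in_a != in_b:
                unique += length
    return unique / covered if covered > 0 else 0.0


def _collect_branches(tree, root=True):
    node, length = tree
    if not root:
        yield _leafset(tree), length
    if not isinstance(node, str):
        for child in node:
            yield from _collect_branches(child, root=False)


# ---------------------------------------------------------------------------
# Procrustes by grid search


def procrustes_m2_grid(a, b, n_theta=20000):
    """Minimise ||A' - s * B' R(theta)||^2 over rotation angle, reflection and
    scale for 2-D configurations, with both configurations standardised
    (centred, unit Frobenius norm) as in the conventional M^2 statistic.
    The optimal scale for a fixed rotation is closed-form; only the angle is
    gridded."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a = a - a.mean(axis=0)
    b = b - b.mean(axis=0)
    a = a / np.linalg.norm(a)
    b = b / np.linalg.norm(b)
    best = np.inf
    for refl in (1.0, -1.0):
        for theta in np.linspace(0, 2 * np.pi, n_theta, endpoint=False):
            c, s = np.cos(theta), np.sin(theta)
            R = np.array([[c, -s], [s, c]]) @ np.diag([1.0, refl])
            br = b @ R
            scale = float((a * br).sum())  # ||br||_F = 1
            resid = float(((a - scale * br) ** 2).sum())
            best = min(best, resid)
    return best
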