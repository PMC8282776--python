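"""Independent brute-force oracles used by the test suite and the
acceptance script. Each oracle recomputes a quantity by a mechanism
different from the implementation it checks (exhaustive enumeration,
naive scanning, regex backreferences), at sizes where that is feasible.
"""

from __future__ import annotations

import re
from itertools import combinations, product

import numpy as np

_ENC = {"A": 0, "C": 1, "G": 2, "T": 3}


def brute_force_inverted_repeat(sequence: str, min_len: int,
                                circular: bool = True):
    """Exhaustive maximal-inverted-repeat search via antidiagonal scans.

    For every pairing constant c, positions t with
    seq[t] == complement(seq[(c - t) mod L]) form runs; each maximal run
    is one arm of a maximal inverted match and its partner arm is the
    run's image under t -> c - t. Returns the best qualifying disjoint
    pair ordered like the detector (longest, then smallest starts), or
    None.
    """
    L = len(sequence)
    x = np.array([_ENC.get(ch, 255) for ch in sequence], dtype=np.int16)
    comp = np.where(x == 255, np.int16(-9), 3 - x)  # N never matches
    ts = np.arange(L)
    best = None
    for c in range(L):
        idx = (c - ts) % L
        m = x == comp[idx]
        runs = _circular_runs(m) if circular else _linear_runs(m)
        for t0, length in runs:
            if length >= L:  # whole-circle palindrome; cannot split cleanly
                continue
            t1 = t0 + length - 1
            p0, p1 = (c - t1) % L, (c - t0) % L  # partner arm endpoints
            if p0 == t0 % L:
                # run maps onto itself: an even-length palindromic region;
                # split into two adjacent arms
                h = length // 2
                if h < min_len:
                    continue
                a, b = (t0 % L, h), ((t0 + length - h) % L, h)
            else:
                if length < min_len:
                    continue
                a, b = (t0 % L, length), (p0, length)
            ia = (a[0], a[0] + a[1])
            ib = (b[0], b[0] + b[1])
            if _circ_overlap(ia, ib, L):
                continue
            pair = tuple(sorted([ia, ib]))
            key = (-(ia[1] - ia[0]), pair[0][0], pair[1][0])
            if best is None or key < best[0]:
                best = (key, pair)
    return best[1] if best else None


def _circular_runs(m: np.ndarray) -> list[tuple[int, int]]:
    """Maximal True runs on a circular boolean array as (start, length)."""
    L = len(m)
    if m.all():
        return [(0, L)]
    start = int(np.flatnonzero(~m)[0]) + 1  # rotate so a False precedes index 0
    mm = np.concatenate([m[start:], m[:start]])
    runs = []
    for t0, length in _linear_runs(mm):
        runs.append(((t0 + start) % L, length))
    return runs


def _linear_runs(m: np.ndarray) -> list[tuple[int, int]]:
    runs = []
    t = 0
    L = len(m)
    while t < L:
        if m[t]:
            t0 = t
            while t < L and m[t]:
                t += 1
            runs.append((t0, t - t0))
        else:
            t += 1
    return runs


def _circ_overlap(a: tuple[int, int], b: tuple[int, int], L: int) -> bool:
    occ = np.zeros(L, dtype=bool)
    occ[np.arange(a[0], a[1]) % L] = True
    return bool(occ[np.arange(b[0], b[1]) % L].any())


# ---------------------------------------------------------------------------


def brute_force_pi(rows: list[str], start: int = 0,
                   end: int | None = None) -> tuple[float, int]:
    """Nei's pi by direct pairwise counting with pairwise deletion.

    Returns (pi, n_pairs_used); pi is nan when no pair has valid sites.
    """
    end = len(rows[0]) if end is None else end
    n = len(rows)
    total, used = 0.0, 0
    for i, j in combinations(range(n), 2):
        diff = valid = 0
        for a, b in zip(rows[i][start:end], rows[j][start:end]):
            if a in "ACGT" and b in "ACGT":
                valid += 1
                if a != b:
                    diff += 1
        if valid:
            total += diff / valid
            used += 1
    if used == 0:
        return float("nan"), 0
    return total / used, used


# ---------------------------------------------------------------------------


def regex_tandem_repeats(protein: str, min_unit: int, max_unit: int,
                         min_total_len: int) -> list[tuple[int, str, int]]:
    """Tandem repeats via regex backreferences: (start, unit, copies).

    For each unit length, a match of (.{u})\\1+ anchored at every position
    gives a repeat run; runs not left-extendable, with a primitive unit,
    >= 2 full copies and span >= min_total_len are kept, then collapsed
    to the maximal hit per locus exactly as the scanner defines it.
    """
    n = len(protein)
    raw = []
    for u in range(min_unit, max_unit + 1):
        pat = re.compile(r"(.{%d})\1+" % u)
        for i in range(n - 2 * u + 1):
            m = pat.match(protein, i)
            if not m:
                continue
            if i >= 1 and i - 1 + u < n and protein[i - 1] == protein[i - 1 + u]:
                continue  # not left-maximal
            unit = m.group(1)
            if any(u % p == 0 and unit == unit[:p] * (u // p)
                   for p in range(1, u)):
                continue  # non-primitive unit
            span = m.end() - m.start()
            # regex matches whole copies only; extend by the partial tail
            tail = 0
            while m.end() + tail < n and protein[m.end() + tail] == protein[m.end() + tail - u]:
                tail += 1
            copies = (span + tail) // u
            if copies >= 2 and copies * u >= min_total_len:
                raw.append((i, unit, copies))
    raw.sort(key=lambda h: (-h[2] * len(h[1]), len(h[1]), h[0]))
    kept = []
    for h in raw:
        s, e = h[0], h[0] + h[2] * len(h[1])
        if all(e <= k[0] or k[0] + k[2] * len(k[1]) <= s for k in kept):
            kept.append(h)
    return sorted(kept)


# ---------------------------------------------------------------------------


def brute_force_parsimony(tree, states: dict) -> int:
    """Minimum change count by exhausting labelings of internal nodes
    (and missing-state leaves) over the observed state set."""
    observed = sorted({s for s in states.values() if s is not None}, key=str)
    free, fixed = [], {}
    for node in tree.preorder_node_iter():
        if node.is_leaf() and states.get(node.taxon.label) is not None:
            fixed[node] = states[node.taxon.label]
        else:
            free.append(node)
    edges = [(n.parent_node, n) for n in tree.preorder_node_iter()
             if n.parent_node is not None]
    best = None
    for combo in product(observed, repeat=len(free)):
        lab = dict(fixed)
        lab.update(zip(free, combo))
        cost = sum(1 for p, c in edges if lab[p] != lab[c])
        if best is None or cost < best:
            best = cost
    return best


def random_tree(n_leaves: int, rng: np.random.Generator,
                p_collapse: float = 0.0):
    """Random rooted tree over leaves t0..t{n-1}; internal edges are
    collapsed into polytomies with probability p_collapse."""
    import dendropy

    nodes = [f"t{i}" for i in range(n_leaves)]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        nodes.append(f"({a},{b})")
    tree = dendropy.Tree.get(data=nodes[0] + ";", schema="newick",
                             preserve_underscores=True)
    tree.is_rooted = True
    if p_collapse > 0:
        for edge in list(tree.preorder_edge_iter()):
            head = edge.head_node
            if (head.parent_node is not None and not head.is_leaf()
                    and rng.random() < p_collapse):
                head.edge.collapse()
    return tree


def naive_fragment_scan(fragment: str, target: str) -> list[tuple[int, str]]:
    """Every exact occurrence of the fragment (either strand) by direct
    position-by-position comparison; N never matches."""
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    rc = "".join(comp.get(b, "?") for b in reversed(fragment))
    k = len(fragment)
    out = []
    for query, strand in ((fragment, "+"), (rc, "-")):
        if "?" in query or "N" in query:
            continue
        for i in range(len(target) - k + 1):
            win = target[i:i + k]
            if "N" in win:
                continue
            if win == query:
                out.append((i, strand))
    return out
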