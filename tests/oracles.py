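"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the package's algorithms: S-values come from
exhaustive path enumeration, AUC from all-pairs counting, reachability
from a hand-rolled BFS.
"""

from collections import deque


def ancestors_bfs(dag, term):
    """Reachable set (including term) following child->parent edges."""
    seen = {term}
    queue = deque([term])
    while queue:
        node = queue.popleft()
        for _, parent in dag.graph.out_edges(node):
            if parent not in seen:
                seen.add(parent)
                queue.append(parent)
    return seen


def s_values_by_path_enumeration(dag, term, w_is_a=0.8, w_part_of=0.6):
    """S_A(t) = max over all A->t paths of the product of edge weights."""
    weights = {"is_a": w_is_a, "part_of": w_part_of}

    def edge_w(data):
        w = weights[data["relation"]]
        if "alt_relation" in data:
            w = max(w, weights[data["alt_relation"]])
        return w

    best = {term: 1.0}
    stack = [(term, 1.0)]
    while stack:
        node, product = stack.pop()
        for _, parent, data in dag.graph.out_edges(node, data=True):
            p = product * edge_w(data)
            if p > best.get(parent, 0.0):
                best[parent] = p
            stack.append((parent, p))  # re-expand: a smaller prefix may still win downstream
    return best


def wang_similarity_oracle(dag, a, b, w_is_a=0.8, w_part_of=0.6):
    if a == b:
        return 1.0
    sa = s_values_by_path_enumeration(dag, a, w_is_a, w_part_of)
    sb = s_values_by_path_enumeration(dag, b, w_is_a, w_part_of)
    shared = sa.keys() & sb.keys()
    if not shared:
        return 0.0
    return sum(sa[t] + sb[t] for t in shared) / (sum(sa.values()) + sum(sb.values()))


def auc_pair_counting(scores, positives):
    """P(random positive outscores random negative), ties counted one half."""
    pos = [s for g, s in scores.items() if g in positives]
    neg = [s for g, s in scores.items() if g not in positives]
    total = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                total += 1.0
            elif p == n:
                total += 0.5
    return total / (len(pos) * len(neg))
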