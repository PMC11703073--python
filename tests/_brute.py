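"""Independent brute-force PCSF oracle for small instances.

Enumerates every valid sub-forest of the augmented graph directly: for each
node subset, every assignment of a parent (an in-neighbour in the subset, or
the dummy for root candidates) is checked for acyclicity and the depth bound,
and the objective is evaluated from its definition. Completely independent of
the solver's layered dynamic program.
"""

import itertools

from exhaustnet.interactome import DUMMY


def brute_force_optimum(ag, prizes, cfg):
    """Minimum objective over all valid sub-forests, by exhaustive enumeration."""
    g = ag.base
    nodes = sorted(g.nodes)
    s = {v: cfg.beta * prizes.get(v) - cfg.mu * g.degree(v) for v in nodes}
    total = sum(s.values())
    preds = {v: sorted(g.graph.predecessors(v)) for v in nodes}
    best = total  # empty forest

    for r in range(1, len(nodes) + 1):
        for subset in itertools.combinations(nodes, r):
            in_subset = set(subset)
            cand = []
            feasible = True
            for v in subset:
                opts = [u for u in preds[v] if u in in_subset]
                if v in ag.root_candidates:
                    opts = opts + [DUMMY]
                if not opts:
                    feasible = False
                    break
                cand.append(opts)
            if not feasible:
                continue
            for assignment in itertools.product(*cand):
                parent = dict(zip(subset, assignment))
                depth = {}
                valid = True
                for v in subset:
                    path = []
                    x = v
                    while x != DUMMY and x not in depth and x not in path:
                        path.append(x)
                        x = parent[x]
                    if x == DUMMY:
                        d = -1
                    elif x in depth:
                        d = depth[x]
                    else:  # cycle
                        valid = False
                        break
                    for node in reversed(path):
                        d += 1
                        depth[node] = d
                    if d > cfg.depth:
                        valid = False
                        break
                if not valid:
                    continue
                cost = 0.0
                kappa = 0
                for v in subset:
                    p = parent[v]
                    if p == DUMMY:
                        cost += ag.omega
                        kappa += 1
                    else:
                        cost += g.cost(p, v)
                obj = total - sum(s[v] for v in subset) + cost
                if obj < best:
                    best = obj
    return best
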