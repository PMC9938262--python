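"""Clone-tree reconstruction from per-region clone prevalences.

Two constraints define feasibility of a parent assignment, evaluated with
a tolerance ``eps`` that absorbs sampling noise in CCF estimates:

* cross rule — a child's prevalence may not exceed its parent's in any
  region (child <= parent + eps);
* pigeonhole — the summed prevalences of a parent's children may not
  exceed the parent's in any region (sum(children) <= parent + eps).

The truncal (root) cluster must have maximal prevalence in every region.
When several parents are feasible for a cluster, the builder attaches it
to the feasible parent with the smallest total prevalence (deepest
nesting), a deterministic tie-break that maximizes tree resolution.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np

from mrith.variants import CloneCluster


class TreeConstructionError(ValueError):
    pass


@dataclass
class CloneTree:
    clusters: list[CloneCluster]
    parents: dict[int, int]         # cluster_id -> parent cluster_id (-1 root)
    evolution_pattern: str          # "linear" | "branched"

    @property
    def root(self) -> int:
        return next(c for c, p in self.parents.items() if p == -1)

    def to_dict(self) -> dict:
        return {
            "nodes": [
                {"cluster": c.cluster_id,
                 "n_mutations": len(c.members),
                 "prevalence": [round(float(x), 6) for x in c.prevalence]}
                for c in self.clusters],
            "parents": {str(k): v for k, v in self.parents.items()},
            "evolution_pattern": self.evolution_pattern,
        }


def check_tree(prevalence: np.ndarray, parents: dict[int, int],
               eps: float = 0.05) -> bool:
    """Direct check of the cross rule and pigeonhole constraint."""
    ids = sorted(parents)
    for c in ids:
        p = parents[c]
        if p == -1:
            continue
        if np.any(prevalence[c] > prevalence[p] + eps):
            return False
    for p in ids:
        kids = [c for c in ids if parents[c] == p]
        if kids and np.any(prevalence[kids].sum(axis=0)
                           > prevalence[p] + eps):
            return False
    return True


def tree_pattern(parents: dict[int, int]) -> str:
    counts: dict[int, int] = {}
    for c, p in parents.items():
        if p != -1:
            counts[p] = counts.get(p, 0) + 1
    return "linear" if all(v <= 1 for v in counts.values()) else "branched"


def build_clone_tree(clusters: list[CloneCluster], *,
                     eps: float = 0.05) -> CloneTree:
    """Greedy feasible-parent assignment with deepest-nesting tie-break.

    Clusters are placed in order of decreasing total prevalence; each is
    attached to the already-placed feasible parent (cross rule for the
    child, pigeonhole for the parent's child set) with the smallest total
    prevalence. Raises TreeConstructionError when no truncal cluster
    exists or a cluster has no feasible parent.
    """
    if not clusters:
        raise TreeConstructionError("no clusters supplied")
    ids = [c.cluster_id for c in clusters]
    prev = {c.cluster_id: np.asarray(c.prevalence, float) for c in clusters}
    order = sorted(ids, key=lambda c: (-float(prev[c].sum()), c))
    root = order[0]
    for c in ids:
        if np.any(prev[c] > prev[root] + eps):
            raise TreeConstructionError(
                "no truncal cluster: no cluster has maximal prevalence in "
                "every region")
    parents = {root: -1}
    children: dict[int, list[int]] = {root: []}
    for c in order[1:]:
        feasible = []
        for cand in parents:
            if np.any(prev[c] > prev[cand] + eps):
                continue  # cross rule violated
            sib = prev[c].copy()
            for k in children[cand]:
                sib = sib + prev[k]
            if np.any(sib > prev[cand] + eps):
                continue  # pigeonhole violated
            feasible.append(cand)
        if not feasible:
            raise TreeConstructionError(
                f"cluster {c}: no feasible parent (cross rule or pigeonhole "
                f"constraint violated against every placed cluster)")
        parent = min(feasible, key=lambda x: (float(prev[x].sum()), x))
        parents[c] = parent
        children[parent].append(c)
        children[c] = []
    arr_ids = sorted(ids)
    prev_arr = np.stack([prev[i] for i in arr_ids])
    idx = {cid: i for i, cid in enumerate(arr_ids)}
    assert check_tree(prev_arr, {idx[c]: (-1 if p == -1 else idx[p])
                                 for c, p in parents.items()}, eps)
    by_id = {c.cluster_id: c for c in clusters}
    return CloneTree(clusters=[by_id[i] for i in arr_ids], parents=parents,
                     evolution_pattern=tree_pattern(parents))


def enumerate_feasible_trees(clusters: list[CloneCluster], *,
                             eps: float = 0.05) -> list[dict[int, int]]:
    """All feasible rooted trees over the clusters (for <=~6 clusters).

    Exhaustive: the root is the cluster with maximal prevalence; every
    assignment of a parent to each remaining cluster is tested against
    both rules and acyclicity.
    """
    ids = [c.cluster_id for c in clusters]
    prev = {c.cluster_id: np.asarray(c.prevalence, float) for c in clusters}
    root = max(ids, key=lambda c: float(prev[c].sum()))
    others = [c for c in ids if c != root]
    out = []
    for combo in product(ids, repeat=len(others)):
        parents = {root: -1}
        parents.update({c: p for c, p in zip(others, combo)})
        if any(parents[c] == c for c in others):
            continue
        # acyclicity via root-reachability
        ok = True
        for c in others:
            seen, cur = set(), c
            while parents[cur] != -1:
                cur = parents[cur]
                if cur in seen or cur == c:
                    ok = False
                    break
                seen.add(cur)
            if not ok:
                break
        if not ok:
            continue
        arr_ids = sorted(ids)
        idx = {cid: i for i, cid in enumerate(arr_ids)}
        prev_arr = np.stack([prev[i] for i in arr_ids])
        if check_tree(prev_arr, {idx[c]: (-1 if p == -1 else idx[p])
                                 for c, p in parents.items()}, eps):
            out.append(parents)
    return out
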