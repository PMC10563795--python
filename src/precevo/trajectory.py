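"""Clonal-trajectory inference from multi-region VAFs and arm-level copy states.

Two independent routes produce a linear / branched / unclassifiable label per
patient:

* SNV route — variants are clustered by their cancer-cell-fraction (CCF)
  profile across regions, a clone tree is built by CCF containment, and the
  placement of the dominant high-grade clone relative to the low-grade
  lineage is classified.
* CNA route — per-region integer arm-state profiles (events >= 5 Mb) are
  placed at the leaves of every possible binary topology (exhaustive, small
  region counts only) and internal states are solved by unit-cost small
  parsimony; classification comes from the consensus over co-optimal
  topologies.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

from .cna import ArmTable, CnaEvent

__all__ = [
    "Clone",
    "CloneTree",
    "VariantCluster",
    "ArmStateProfile",
    "CnaTreeResult",
    "GRADE_ORDER",
    "cluster_variants",
    "build_snv_tree",
    "classify_topology",
    "arm_state_profiles",
    "build_cna_tree",
    "compare_trajectories",
    "detect_minor_expansion",
]

LINEAR, BRANCHED, UNCLASSIFIABLE = "linear", "branched", "unclassifiable"

#: histology grade ranks (AC and ND are non-neoplastic background)
GRADE_ORDER = {"ND": 0, "AC": 0, "LG": 1, "HG": 2, "PDAC": 3}

ROOT_ID = "root"
NEUTRAL_STATE = 2
MAX_STATE = 4


@dataclass
class Clone:
    id: str
    parent: str | None
    muts: frozenset = frozenset()
    events: frozenset = frozenset()


class CloneTree:
    """Rooted clone tree with per-region exact-clone fractions.

    ``fractions[region][clone]`` is the fraction of (all) cells whose exact
    clone identity is that clone; the CCF of a clone in a region is the sum
    over its subtree.  The root is a mutation-free normal ancestor and is
    never dominant.
    """

    def __init__(
        self,
        clones: Iterable[Clone],
        fractions: Mapping[str, Mapping[str, float]],
        topology: str | None = None,
        unresolved: bool = False,
    ):
        self.clones: dict[str, Clone] = {c.id: c for c in clones}
        if ROOT_ID not in self.clones:
            self.clones[ROOT_ID] = Clone(ROOT_ID, None)
        self.fractions = {
            r: {c: float(f) for c, f in fr.items()} for r, fr in fractions.items()
        }
        self.topology = topology
        self.unresolved = unresolved
        self._validate()

    def _validate(self) -> None:
        roots = [c for c in self.clones.values() if c.parent is None]
        if len(roots) != 1 or roots[0].id != ROOT_ID:
            raise ValueError("tree must have the single normal root")
        for c in self.clones.values():
            if c.parent is not None:
                p = self.clones[c.parent]
                if not (c.muts >= p.muts):
                    raise ValueError(f"clone {c.id} mutations do not nest in parent")
        for region, fr in self.fractions.items():
            vals = [f for f in fr.values()]
            if any(f < -1e-9 or f > 1 + 1e-9 for f in vals):
                raise ValueError(f"fractions out of [0,1] in region {region}")
            if sum(vals) > 1 + 1e-6:
                raise ValueError(f"fractions exceed 1 in region {region}")

    # -- structure ---------------------------------------------------------
    @property
    def regions(self) -> list[str]:
        return sorted(self.fractions)

    def children(self, clone_id: str) -> list[str]:
        return sorted(c.id for c in self.clones.values() if c.parent == clone_id)

    def ancestors(self, clone_id: str) -> list[str]:
        """Path root -> clone, inclusive, excluding the normal root."""
        path = []
        cur = clone_id
        while cur is not None and cur != ROOT_ID:
            path.append(cur)
            cur = self.clones[cur].parent
        return path[::-1]

    def is_ancestor(self, a: str, b: str) -> bool:
        """True when ``a`` is an ancestor of (or equal to) ``b``."""
        return a in self.ancestors(b) or a == ROOT_ID

    def mrca(self, a: str, b: str) -> str:
        pa, pb = self.ancestors(a), self.ancestors(b)
        common = ROOT_ID
        for x, y in zip(pa, pb):
            if x == y:
                common = x
            else:
                break
        return common

    # -- quantities --------------------------------------------------------
    def fraction(self, region: str, clone_id: str) -> float:
        return self.fractions.get(region, {}).get(clone_id, 0.0)

    def ccf(self, region: str, clone_id: str) -> float:
        total = self.fraction(region, clone_id)
        for child in self.children(clone_id):
            total += self.ccf(region, child)
        return total

    def dominant(self, region: str) -> str | None:
        """Clone with the largest exact fraction (ties: larger mutation set, lower id)."""
        candidates = [
            (self.fraction(region, cid), len(self.clones[cid].muts), cid)
            for cid in self.clones
            if cid != ROOT_ID and self.fraction(region, cid) > 0
        ]
        if not candidates:
            return None
        candidates.sort(key=lambda t: (-t[0], -t[1], t[2]))
        return candidates[0][2]

    def to_dict(self) -> dict:
        return {
            "clones": {
                c.id: {
                    "parent": c.parent,
                    "muts": sorted(map(list, c.muts)) if c.muts else [],
                    "events": sorted(c.events),
                }
                for c in self.clones.values()
            },
            "fractions": self.fractions,
            "topology": self.topology,
            "unresolved": self.unresolved,
        }


# ---------------------------------------------------------------------------
# SNV route
# ---------------------------------------------------------------------------

@dataclass
class VariantCluster:
    id: str
    variants: list
    ccf: dict  # region -> mean CCF

    def total_ccf(self) -> float:
        return sum(self.ccf.values())


def ccf_from_vaf(vaf: float, purity: float) -> float:
    """CCF under the diploid approximation: min(1, 2·VAF / purity)."""
    if purity <= 0:
        return 0.0
    return min(1.0, 2.0 * vaf / purity)


def cluster_variants(
    vaf_matrix: pd.DataFrame,
    purity: Mapping[str, float],
    presence_threshold: float = 0.01,
    merge_distance: float = 0.3,
    min_variants: int = 1,
) -> list[VariantCluster]:
    """Group variants by similarity of their CCF profiles across regions.

    ``vaf_matrix`` is regions x variants (NaN/0 for absent).  Profiles whose
    maximum coordinate-wise difference is below ``merge_distance`` end up in
    one cluster (complete linkage).  Clusters supported by fewer than
    ``min_variants`` variants are discarded as unattributable noise.
    Clusters are ordered by decreasing total CCF and labelled C1, C2, ...
    """
    if vaf_matrix.shape[0] < 2:
        raise ValueError("cannot cluster: need at least 2 regions")
    regions = sorted(vaf_matrix.index)
    vafs = vaf_matrix.loc[regions].fillna(0.0)
    ccf = vafs.copy()
    for r in regions:
        p = purity.get(r, 0.0)
        ccf.loc[r] = [ccf_from_vaf(v, p) for v in vafs.loc[r]]

    profiles = ccf.T.to_numpy()  # variants x regions
    n = profiles.shape[0]
    if n == 0:
        return []
    if n == 1:
        labels = np.array([1])
    else:
        z = linkage(profiles, method="complete", metric="chebyshev")
        labels = fcluster(z, t=merge_distance, criterion="distance")

    clusters = []
    for lab in sorted(set(labels)):
        idx = np.where(labels == lab)[0]
        mean = profiles[idx].mean(axis=0)
        clusters.append(
            VariantCluster(
                id="",
                variants=[ccf.columns[i] for i in idx],
                ccf={r: float(mean[j]) for j, r in enumerate(regions)},
            )
        )
    clusters = [c for c in clusters if len(c.variants) >= min_variants]
    clusters.sort(key=lambda c: (-c.total_ccf(), sorted(map(str, c.variants))))
    for i, c in enumerate(clusters):
        c.id = f"C{i + 1}"
    return clusters


def build_snv_tree(
    clusters: Sequence[VariantCluster],
    presence_threshold: float = 0.01,
    tol: float = 0.15,
) -> CloneTree:
    """Clone tree by CCF containment (parent CCF >= child CCF everywhere).

    A truncal cluster must be present in every neoplastic region; otherwise
    the tree is flagged unresolved and classifies as unclassifiable.  The
    pigeonhole sum rule (children cannot jointly exceed their parent) is
    checked per region within ``tol``.
    """
    if not clusters:
        return CloneTree([], {}, topology=UNCLASSIFIABLE, unresolved=True)
    regions = sorted(clusters[0].ccf)
    neoplastic = [
        r
        for r in regions
        if any(c.ccf.get(r, 0.0) >= presence_threshold for c in clusters)
    ]
    ordered = sorted(clusters, key=lambda c: (-c.total_ccf(), c.id))
    trunk = ordered[0]
    unresolved = False
    if not all(trunk.ccf.get(r, 0.0) >= presence_threshold for r in neoplastic):
        unresolved = True

    parent_of: dict[str, str] = {trunk.id: ROOT_ID}
    placed: list[VariantCluster] = [trunk]
    by_id = {c.id: c for c in ordered}
    for c in ordered[1:]:
        candidates = [
            p
            for p in placed
            if all(p.ccf.get(r, 0.0) >= c.ccf.get(r, 0.0) - tol for r in regions)
        ]
        if not candidates:
            unresolved = True
            parent_of[c.id] = trunk.id
        else:
            candidates.sort(key=lambda p: (p.total_ccf(), p.id))
            parent_of[c.id] = candidates[0].id
        placed.append(c)

    # pigeonhole sum rule per parent per region
    for pid in set(parent_of.values()):
        kids = [cid for cid, par in parent_of.items() if par == pid]
        if pid == ROOT_ID:
            continue
        for r in regions:
            if sum(by_id[k].ccf.get(r, 0.0) for k in kids) > by_id[pid].ccf.get(r, 0.0) + tol:
                unresolved = True

    clones = []
    muts_of: dict[str, frozenset] = {ROOT_ID: frozenset()}
    for c in ordered:
        pid = parent_of[c.id]
        muts_of[c.id] = muts_of[pid] | frozenset(c.variants)
        clones.append(Clone(c.id, pid, muts=muts_of[c.id]))

    fractions: dict[str, dict[str, float]] = {}
    for r in regions:
        fr = {}
        for c in ordered:
            kids = [k for k, par in parent_of.items() if par == c.id]
            f = c.ccf.get(r, 0.0) - sum(by_id[k].ccf.get(r, 0.0) for k in kids)
            fr[c.id] = max(0.0, f)
        total = sum(fr.values())
        if total > 1:
            fr = {k: v / total for k, v in fr.items()}
        fractions[r] = fr
    return CloneTree(clones, fractions, unresolved=unresolved)


def _pick_region(grades: Mapping[str, str], grade: str, tree: CloneTree) -> str | None:
    matching = sorted(r for r, g in grades.items() if g == grade and r in tree.fractions)
    return matching[0] if matching else None


def classify_topology(
    tree: CloneTree,
    grades: Mapping[str, str],
    presence_threshold: float = 0.01,
) -> str:
    """Linear / branched / unclassifiable placement of the dominant HG clone.

    Linear: the dominant HG clone descends stepwise from the LG lineage —
    every clone on its root path is present in the LG (or is the HG dominant
    itself) and the LG dominant lies on that path.  Branched: the HG dominant
    sits on a branch carrying no LG-present clone below the divergence point.
    """
    if tree.unresolved:
        return UNCLASSIFIABLE
    lg = _pick_region(grades, "LG", tree)
    hg = _pick_region(grades, "HG", tree)
    if lg is None or hg is None:
        return UNCLASSIFIABLE
    lg_dom, hg_dom = tree.dominant(lg), tree.dominant(hg)
    if lg_dom is None or hg_dom is None:
        return UNCLASSIFIABLE

    path = tree.ancestors(hg_dom)

    def lg_present(cid: str) -> bool:
        return tree.ccf(lg, cid) >= presence_threshold

    if lg_dom in path and all(c == hg_dom or lg_present(c) for c in path):
        return LINEAR

    if lg_dom not in path and not tree.is_ancestor(hg_dom, lg_dom):
        m = tree.mrca(lg_dom, hg_dom)
        below = path[path.index(m) + 1 :] if m in path else path
        if not any(lg_present(c) for c in below):
            return BRANCHED
    return UNCLASSIFIABLE


# ---------------------------------------------------------------------------
# CNA route
# ---------------------------------------------------------------------------

@dataclass
class ArmStateProfile:
    """Integer copy state (0–4; 2 = neutral) per chromosome arm for one region."""

    region: str
    states: dict

    def __post_init__(self):
        for arm, s in self.states.items():
            if not 0 <= int(s) <= MAX_STATE:
                raise ValueError(f"state {s} out of range for arm {arm}")


def arm_state_profiles(
    events_by_region: Mapping[str, Sequence[CnaEvent]],
    arms: ArmTable,
    min_event_mb: float = 5.0,
    cover_fraction: float = 0.5,
) -> list[ArmStateProfile]:
    """Collapse >= ``min_event_mb`` events into per-arm integer copy states.

    An arm is state 3 (single gain) when gain events cover at least
    ``cover_fraction`` of it, state 1 when losses do; otherwise neutral.
    cn-LOH is copy-neutral and maps to state 2.
    """
    from .cna import _arm_covered_fraction  # internal helper reuse

    profiles = []
    for region in sorted(events_by_region):
        big = [e for e in events_by_region[region] if e.length_mb >= min_event_mb]
        states = {}
        for arm_id in arms.arm_ids:
            gain_frac = _arm_covered_fraction(
                [e for e in big if e.direction == "gain"], arms, arm_id
            )
            loss_frac = _arm_covered_fraction(
                [e for e in big if e.direction == "loss"], arms, arm_id
            )
            if gain_frac >= cover_fraction and gain_frac >= loss_frac:
                states[arm_id] = 3
            elif loss_frac >= cover_fraction:
                states[arm_id] = 1
            else:
                states[arm_id] = NEUTRAL_STATE
        profiles.append(ArmStateProfile(region, states))
    return profiles


@dataclass
class CnaTreeResult:
    cost: int
    classification: str
    n_optimal: int
    topologies: list = field(default_factory=list)  # list of (parent-map, states)


def _enumerate_unrooted(leaves: Sequence[str]):
    """Yield every unrooted binary topology over ``leaves`` as an edge list."""
    leaves = list(leaves)
    if len(leaves) == 1:
        yield [], leaves[0]
        return
    if len(leaves) == 2:
        yield [(leaves[0], leaves[1])], leaves[0]
        return

    def add_leaf(edges, next_internal, remaining):
        if not remaining:
            yield edges
            return
        leaf = remaining[0]
        for i, (u, v) in enumerate(edges):
            node = f"_i{next_internal}"
            new_edges = edges[:i] + edges[i + 1 :] + [
                (u, node),
                (node, v),
                (node, leaf),
            ]
            yield from add_leaf(new_edges, next_internal + 1, remaining[1:])

    base = [(leaves[0], leaves[1])]
    for edges in add_leaf(base, 0, leaves[2:]):
        yield edges, leaves[0]


def _root_edges(edges: list[tuple[str, str]], root: str) -> dict[str, str]:
    """Orient an edge list away from ``root``; returns child -> parent."""
    adj: dict[str, list[str]] = {}
    for u, v in edges:
        adj.setdefault(u, []).append(v)
        adj.setdefault(v, []).append(u)
    parent = {root: None}
    stack = [root]
    while stack:
        u = stack.pop()
        for v in adj.get(u, []):
            if v not in parent:
                parent[v] = u
                stack.append(v)
    return parent


def _sankoff(
    parent: dict[str, str],
    leaf_states: Mapping[str, int],
    root: str,
) -> tuple[int, dict[str, int]]:
    """Unit-cost small parsimony for one character on a rooted tree.

    The root is a leaf with a fixed state.  Returns (min cost, one optimal
    assignment; ties resolved toward the parent state, then the lower state).
    """
    children: dict[str, list[str]] = {}
    for node, par in parent.items():
        if par is not None:
            children.setdefault(par, []).append(node)
    for kids in children.values():
        kids.sort()

    INF = 10**9
    cost: dict[str, list[int]] = {}

    def down(node: str) -> None:
        kids = children.get(node, [])
        if not kids:
            s = leaf_states[node]
            cost[node] = [0 if k == s else INF for k in range(MAX_STATE + 1)]
            return
        for k in kids:
            down(k)
        c = []
        for s in range(MAX_STATE + 1):
            tot = 0
            for k in kids:
                tot += min(
                    cost[k][t] + (0 if t == s else 1) for t in range(MAX_STATE + 1)
                )
            c.append(tot)
        cost[node] = c

    down(root)
    root_state = leaf_states[root]
    total = cost[root][root_state]

    assignment = {root: root_state}
    order = [root]
    while order:
        node = order.pop()
        s = assignment[node]
        for k in children.get(node, []):
            best = min(
                cost[k][t] + (0 if t == s else 1) for t in range(MAX_STATE + 1)
            )
            # prefer inheriting the parent state, then the lowest state
            choices = [
                t
                for t in range(MAX_STATE + 1)
                if cost[k][t] + (0 if t == s else 1) == best
            ]
            assignment[k] = s if s in choices else min(choices)
            order.append(k)
    return total, assignment


def _path_to_root(parent: dict[str, str], node: str) -> list[str]:
    path = [node]
    while parent[path[-1]] is not None:
        path.append(parent[path[-1]])
    return path


def _classify_parsimony_tree(
    parent: dict[str, str],
    states: dict[str, dict[str, int]],
    lg: str,
    hg: str,
) -> str:
    """Linear/branched from private arm changes below the LG–HG divergence."""
    path_lg = set(_path_to_root(parent, lg))
    mrca = next(n for n in _path_to_root(parent, hg) if n in path_lg)

    def changes(leaf: str) -> int:
        n = 0
        node = leaf
        while node != mrca:
            par = parent[node]
            for arm in states[node]:
                if states[node][arm] != states[par][arm]:
                    n += 1
            node = par
        return n

    private_lg, private_hg = changes(lg), changes(hg)
    if private_hg == 0:
        return UNCLASSIFIABLE
    return LINEAR if private_lg == 0 else BRANCHED


CNA_ROOT = "_diploid"


def build_cna_tree(
    profiles: Sequence[ArmStateProfile],
    grades: Mapping[str, str] | None = None,
    max_regions: int = 6,
) -> CnaTreeResult:
    """Exhaustive unit-cost small-parsimony tree over arm-state profiles.

    Leaves are the region profiles plus an all-neutral diploid root; every
    binary topology is scored and co-optimal ones vote on the linear/branched
    call (disagreement, or no discriminating events, yields unclassifiable).
    """
    if len(profiles) > max_regions:
        raise ValueError("exceeds exhaustive bound: more than 6 regions")
    if len(profiles) < 2:
        return CnaTreeResult(0, UNCLASSIFIABLE, 0)
    arms = sorted(set().union(*(p.states.keys() for p in profiles)))
    leaf_states_by_arm = {
        arm: {p.region: int(p.states.get(arm, NEUTRAL_STATE)) for p in profiles}
        for arm in arms
    }
    for arm in arms:
        leaf_states_by_arm[arm][CNA_ROOT] = NEUTRAL_STATE

    grades = grades or {}
    present = {p.region for p in profiles}
    lg = next((r for r in sorted(grades) if grades[r] == "LG" and r in present), None)
    hg = next((r for r in sorted(grades) if grades[r] == "HG" and r in present), None)

    leaves = [CNA_ROOT] + sorted(p.region for p in profiles)
    best_cost = None
    optima: list[tuple[dict, dict]] = []
    for edges, _ in _enumerate_unrooted(leaves):
        parent = _root_edges(edges, CNA_ROOT)
        total = 0
        states: dict[str, dict[str, int]] = {}
        for arm in arms:
            c, assign = _sankoff(parent, leaf_states_by_arm[arm], CNA_ROOT)
            total += c
            for node, s in assign.items():
                states.setdefault(node, {})[arm] = s
        if best_cost is None or total < best_cost:
            best_cost = total
            optima = [(parent, states)]
        elif total == best_cost:
            optima.append((parent, states))

    if lg is None or hg is None:
        return CnaTreeResult(best_cost or 0, UNCLASSIFIABLE, len(optima), optima)

    labels = {
        _classify_parsimony_tree(parent, states, lg, hg) for parent, states in optima
    }
    classification = labels.pop() if len(labels) == 1 else UNCLASSIFIABLE
    return CnaTreeResult(best_cost or 0, classification, len(optima), optima)


# ---------------------------------------------------------------------------
# Cohort-level comparisons
# ---------------------------------------------------------------------------

def compare_trajectories(
    snv_labels: Mapping[str, str],
    cna_labels: Mapping[str, str],
    include_unclassifiable: bool = False,
) -> tuple[pd.DataFrame, float]:
    """Per-patient SNV vs CNA concordance and the cohort agreement fraction.

    Pairs where either route is unclassifiable are excluded from the fraction
    unless ``include_unclassifiable`` is set.
    """
    patients = sorted(set(snv_labels) | set(cna_labels))
    rows = []
    for p in patients:
        s = snv_labels.get(p, UNCLASSIFIABLE)
        c = cna_labels.get(p, UNCLASSIFIABLE)
        informative = include_unclassifiable or (
            s != UNCLASSIFIABLE and c != UNCLASSIFIABLE
        )
        rows.append(
            {"patient": p, "snv": s, "cna": c, "agree": s == c, "informative": informative}
        )
    df = pd.DataFrame(rows, columns=["patient", "snv", "cna", "agree", "informative"])
    informative = df[df["informative"]]
    agreement = float(informative["agree"].mean()) if len(informative) else float("nan")
    return df, agreement


def detect_minor_expansion(
    tree: CloneTree,
    grades: Mapping[str, str],
    low: float = 0.05,
    high: float = 0.5,
    presence_threshold: float = 0.01,
) -> list[dict]:
    """Clones present as a minor population that dominate a higher-grade region.

    Reports clones whose CCF is in [presence_threshold, ``low``] in one region
    and >= ``high`` in a region of strictly higher grade.
    """
    if len(tree.regions) < 2:
        return []
    out = []
    for cid in sorted(tree.clones):
        if cid == ROOT_ID:
            continue
        for r1, r2 in itertools.permutations(tree.regions, 2):
            g1 = GRADE_ORDER.get(grades.get(r1, ""), -1)
            g2 = GRADE_ORDER.get(grades.get(r2, ""), -1)
            if g1 < 0 or g2 <= g1:
                continue
            c1, c2 = tree.ccf(r1, cid), tree.ccf(r2, cid)
            if presence_threshold <= c1 <= low and c2 >= high:
                out.append(
                    {"clone": cid, "from": r1, "to": r2, "ccf_from": c1, "ccf_to": c2}
                )
    return out
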