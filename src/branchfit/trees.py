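"""Tumor mutation trees, expansion rules, and cohort I/O.

A mutation tree is a rooted tree whose nodes are subclones.  Each node
carries the set of mutations it newly acquired (``new_mutations``); its
genotype is the union of new mutations along the root-to-node path.  The
root represents the wild-type population and carries no mutations.
Mutations are integers ``1..n`` with an optional label table kept at the
cohort level.  Genotypes are immutable frozensets so they can key
dictionaries (union trees, fitness lookups).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator

__all__ = [
    "SubcloneNode",
    "MutationTree",
    "Cohort",
    "ExpansionRule",
    "ISA",
    "RELAXED",
    "RuleViolation",
    "compute_genotypes",
    "validate_rule",
    "prune_unobserved",
    "augment_tree",
    "union_tree",
    "read_cohort",
    "write_cohort",
    "cohort_from_dict",
    "cohort_to_dict",
    "to_newick",
]


class TreeError(ValueError):
    """Structural problem in a mutation tree (cycle, bad parent, ISA clash)."""


@dataclass(frozen=True)
class SubcloneNode:
    """One subclone: the cells sharing a genotype, attached to a tree node."""

    id: str
    new_mutations: frozenset = frozenset()
    count: int = 0
    genotype: frozenset | None = None
    is_augmented: bool = False

    def __post_init__(self):
        object.__setattr__(self, "new_mutations", frozenset(self.new_mutations))
        if self.genotype is not None:
            object.__setattr__(self, "genotype", frozenset(self.genotype))
        if self.count < 0 or self.count != int(self.count):
            raise TreeError(f"node {self.id!r}: count must be a non-negative integer")
        if self.is_augmented and self.count != 0:
            raise TreeError(f"augmented node {self.id!r} must have zero count")


@dataclass
class MutationTree:
    """Rooted tumor mutation tree with per-patient metadata.

    Parameters
    ----------
    nodes
        Mapping node id -> :class:`SubcloneNode`.
    parents
        Mapping node id -> parent id (root maps to ``None``).
    patient_id
        Sample identifier.
    sampling_time
        Time of diagnosis/biopsy in years, or ``None`` if unknown (it is
        then integrated out of the likelihood).
    c_seq
        Number of sequenced cells; must equal the sum of node counts.
    c_tumor
        Estimated total tumor cell count at sampling (may be ``None``).
    weight
        Likelihood multiplier for multi-tree-per-patient input.
    """

    nodes: dict = field(default_factory=dict)
    parents: dict = field(default_factory=dict)
    patient_id: str = ""
    sampling_time: float | None = None
    c_seq: int | None = None
    c_tumor: float | None = None
    weight: float = 1.0

    # -- construction helpers -------------------------------------------------

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple],
        counts: dict | None = None,
        **meta,
    ) -> "MutationTree":
        """Build a tree from ``(parent_id|None, node_id, new_mutations)`` triples.

        The triple with parent ``None`` defines the root.  ``counts`` maps
        node id -> observed sequenced-cell count.
        """
        counts = counts or {}
        tree = cls(**meta)
        for parent, nid, muts in edges:
            tree.nodes[nid] = SubcloneNode(
                id=nid, new_mutations=frozenset(muts), count=counts.get(nid, 0)
            )
            tree.parents[nid] = parent
        tree._check_structure()
        compute_genotypes(tree, inplace=True)
        if tree.c_seq is None:
            tree.c_seq = sum(n.count for n in tree.nodes.values())
        return tree

    # -- structure ------------------------------------------------------------

    @property
    def root_id(self) -> str:
        roots = [nid for nid, p in self.parents.items() if p is None]
        if len(roots) != 1:
            raise TreeError(f"tree must have exactly one root, found {len(roots)}")
        return roots[0]

    def children(self, nid: str) -> list:
        return [c for c, p in self.parents.items() if p == nid]

    def path_to_root(self, nid: str) -> list:
        """Node ids from ``nid`` up to (and including) the root."""
        path = [nid]
        seen = {nid}
        while self.parents[path[-1]] is not None:
            p = self.parents[path[-1]]
            if p in seen:
                raise TreeError(f"cycle detected at node {p!r}")
            path.append(p)
            seen.add(p)
        return path

    def topological_order(self) -> list:
        """Node ids root-first; raises on cycles or disconnected nodes."""
        order = []
        stack = [self.root_id]
        while stack:
            nid = stack.pop()
            order.append(nid)
            stack.extend(sorted(self.children(nid), reverse=True))
        if len(order) != len(self.nodes):
            raise TreeError("tree is not connected (unreachable nodes present)")
        return order

    def mutant_nodes(self) -> list:
        root = self.root_id
        return [nid for nid in self.topological_order() if nid != root]

    def _check_structure(self) -> None:
        root = self.root_id
        if self.nodes[root].new_mutations:
            raise TreeError("root mutation set must be empty")
        for nid, p in self.parents.items():
            if p is not None and p not in self.nodes:
                raise TreeError(f"node {nid!r} references unknown parent {p!r}")
        self.topological_order()

    def copy(self) -> "MutationTree":
        return MutationTree(
            nodes=dict(self.nodes),
            parents=dict(self.parents),
            patient_id=self.patient_id,
            sampling_time=self.sampling_time,
            c_seq=self.c_seq,
            c_tumor=self.c_tumor,
            weight=self.weight,
        )

    def genotype_of(self, nid: str) -> frozenset:
        g = self.nodes[nid].genotype
        if g is None:
            raise TreeError("genotypes not computed; call compute_genotypes first")
        return g

    def all_mutations(self) -> frozenset:
        return frozenset().union(*(n.new_mutations for n in self.nodes.values()))

    def observed_total(self) -> int:
        return sum(n.count for n in self.nodes.values())


# -- expansion rules ---------------------------------------------------------


@dataclass(frozen=True)
class ExpansionRule:
    """Predicate deciding which new subclones may emerge next.

    Under the infinite sites assumption (ISA) a mutation may appear at most
    once in the whole tree; relaxed rules admit parallel/repeated mutations.
    """

    name: str

    def admits(self, tree: MutationTree, parent_id: str, new_mutations: frozenset) -> bool:
        new_mutations = frozenset(new_mutations)
        if not new_mutations:
            return False
        if self.name == "relaxed":
            # only forbid immediate back-mutation bookkeeping clashes
            return new_mutations.isdisjoint(tree.genotype_of(parent_id))
        used = tree.all_mutations()
        return new_mutations.isdisjoint(used)


ISA = ExpansionRule("ISA")
RELAXED = ExpansionRule("relaxed")


@dataclass(frozen=True)
class RuleViolation:
    node_id: str
    mutation: int
    reason: str


# -- operations ---------------------------------------------------------------


def compute_genotypes(tree: MutationTree, rule: ExpansionRule | None = None,
                      inplace: bool = False) -> MutationTree:
    """Fill each node's genotype with the union of new mutations on its root path.

    Idempotent and independent of node insertion order.  With ``rule=ISA`` a
    repeated mutation along a lineage raises :class:`TreeError`.
    """
    if not inplace:
        tree = tree.copy()
    for nid in tree.topological_order():
        parent = tree.parents[nid]
        node = tree.nodes[nid]
        if parent is None:
            g = frozenset()
        else:
            pg = tree.nodes[parent].genotype
            if (rule is None or rule.name == "ISA") and not node.new_mutations.isdisjoint(pg):
                dup = sorted(node.new_mutations & pg)
                raise TreeError(
                    f"node {nid!r} repeats mutation(s) {dup} already on its lineage (ISA)"
                )
            g = pg | node.new_mutations
        tree.nodes[nid] = replace(node, genotype=g)
    return tree


def validate_rule(tree: MutationTree, rule: ExpansionRule) -> list:
    """Return the list of rule violations (empty iff the tree is consistent)."""
    violations = []
    if rule.name == "relaxed":
        for nid in tree.mutant_nodes():
            node = tree.nodes[nid]
            pg = tree.genotype_of(tree.parents[nid])
            for m in sorted(node.new_mutations & pg):
                violations.append(RuleViolation(nid, m, "mutation already on lineage"))
        return violations
    # ISA: every mutation appears in exactly one node's new_mutations
    owner: dict = {}
    for nid in tree.mutant_nodes():
        for m in sorted(tree.nodes[nid].new_mutations):
            if m in owner:
                violations.append(
                    RuleViolation(nid, m, f"mutation also introduced at node {owner[m]!r}")
                )
            else:
                owner[m] = nid
    return violations


def prune_unobserved(tree: MutationTree) -> MutationTree:
    """Iteratively remove zero-count leaves (unobserved subclones).

    Internal zero-count nodes are retained: they are needed to explain the
    genotypes of their observed descendants.  Idempotent.
    """
    tree = tree.copy()
    root = tree.root_id
    changed = True
    while changed:
        changed = False
        for nid in list(tree.nodes):
            if nid == root:
                continue
            if tree.nodes[nid].count == 0 and not tree.children(nid):
                del tree.nodes[nid]
                del tree.parents[nid]
                changed = True
    return tree


def _canonical_sorted(genotype: frozenset) -> tuple:
    return tuple(sorted(genotype))


def augment_tree(tree: MutationTree, rule: ExpansionRule = ISA,
                 max_mutations: int = 2, n: int | None = None) -> MutationTree:
    """Attach zero-count subclones for every admissible unobserved genotype.

    Candidate genotypes are ``g_v ∪ S`` for an existing node ``v`` and a
    non-empty set ``S`` of mutations unused anywhere in the tree (ISA), with
    total size at most ``max_mutations``.  Each distinct genotype is added
    once, under the parent with the lexicographically smallest genotype among
    those already in the (augmented) tree.  Original topology and counts are
    unchanged; added nodes are flagged ``is_augmented``.
    """
    if n is None:
        n = max(tree.all_mutations(), default=0)
    tree = tree.copy()
    if rule.name != "ISA":
        rule = ISA  # augmentation only enumerates ISA-admissible children
    used = tree.all_mutations()
    free = [m for m in range(1, n + 1) if m not in used]
    present = {tree.genotype_of(nid): nid for nid in tree.topological_order()}
    # enumerate candidate genotypes by size so parents exist before children
    from itertools import combinations

    candidates = []
    for base_id in tree.topological_order():
        g = tree.genotype_of(base_id)
        if len(g) >= max_mutations:
            continue
        for k in range(1, max_mutations - len(g) + 1):
            for extra in combinations(free, k):
                candidates.append(g | frozenset(extra))
    for geno in sorted(set(candidates), key=lambda g: (len(g), _canonical_sorted(g))):
        if geno in present:
            continue
        # parent: smallest existing genotype that is a subset of size |g|-1
        parents = [p for p in present if p < geno and len(p) == len(geno) - 1]
        if not parents:
            continue
        parent_geno = min(parents, key=_canonical_sorted)
        new_mut = geno - parent_geno
        nid = "aug_" + "_".join(str(m) for m in _canonical_sorted(geno))
        tree.nodes[nid] = SubcloneNode(
            id=nid, new_mutations=new_mut, count=0, genotype=geno, is_augmented=True
        )
        tree.parents[nid] = present[parent_geno]
        present[geno] = nid
    return tree


def union_tree(cohort: "Cohort") -> MutationTree:
    """Minimal tree containing every genotype observed anywhere in the cohort.

    Nodes are identified by genotype; the parent of a genotype must be
    consistent across trees, otherwise :class:`TreeError` is raised.  The
    node count of the result is the "union tree size" driving inference cost.
    """
    parent_of: dict = {}
    for tree in cohort.trees:
        for nid in tree.mutant_nodes():
            g = tree.genotype_of(nid)
            pg = tree.genotype_of(tree.parents[nid])
            if g in parent_of and parent_of[g] != pg:
                raise TreeError(
                    f"incompatible lineages for genotype {sorted(g)}: "
                    f"parents {sorted(parent_of[g])} vs {sorted(pg)}"
                )
            parent_of[g] = pg
    ids = {frozenset(): "root"}
    for g in sorted(parent_of, key=lambda g: (len(g), _canonical_sorted(g))):
        ids[g] = "u_" + "_".join(map(str, _canonical_sorted(g))) if g else "root"
    out = MutationTree(patient_id="union")
    out.nodes["root"] = SubcloneNode(id="root", genotype=frozenset())
    out.parents["root"] = None
    for g, nid in ids.items():
        if not g:
            continue
        pg = parent_of[g]
        if pg not in ids:
            raise TreeError(f"genotype {sorted(g)} has no ancestor node for {sorted(pg)}")
        out.nodes[nid] = SubcloneNode(id=nid, new_mutations=g - pg, genotype=g)
        out.parents[nid] = ids[pg]
    out.c_seq = 0
    return out


# -- cohort -------------------------------------------------------------------


@dataclass
class Cohort:
    """A set of tumor mutation trees over a common mutation universe ``1..n``."""

    trees: list = field(default_factory=list)
    n: int = 0
    mutations: list = field(default_factory=list)

    def __post_init__(self):
        if not self.mutations:
            self.mutations = [f"M{i}" for i in range(1, self.n + 1)]
        for t in self.trees:
            bad = [m for m in t.all_mutations() if not 1 <= m <= self.n]
            if bad:
                raise TreeError(f"tree {t.patient_id!r} uses out-of-range mutations {bad}")

    def __len__(self) -> int:
        return len(self.trees)

    def __iter__(self) -> Iterator[MutationTree]:
        return iter(self.trees)


# -- JSON I/O -----------------------------------------------------------------


def _tree_to_dict(tree: MutationTree) -> dict:
    nodes = []
    for nid in tree.topological_order():
        node = tree.nodes[nid]
        nodes.append(
            {
                "id": nid,
                "parent": tree.parents[nid],
                "new_mutations": sorted(node.new_mutations),
                "count": int(node.count),
            }
        )
    d = {
        "patient_id": tree.patient_id,
        "sampling_time": tree.sampling_time,
        "C_seq": tree.c_seq,
        "C_tumor": tree.c_tumor,
        "nodes": nodes,
    }
    if tree.weight != 1.0:
        d["weight"] = tree.weight
    return d


def _tree_from_dict(d: dict, where: str) -> MutationTree:
    for key in ("patient_id", "C_seq", "nodes"):
        if key not in d:
            raise TreeError(f"{where}: missing required key {key!r}")
    edges, counts = [], {}
    for nd in d["nodes"]:
        for key in ("id", "parent", "new_mutations", "count"):
            if key not in nd:
                raise TreeError(f"{where}, node {nd.get('id', '?')!r}: missing key {key!r}")
        if nd["count"] < 0 or nd["count"] != int(nd["count"]):
            raise TreeError(f"{where}, node {nd['id']!r}: negative or non-integer count")
        edges.append((nd["parent"], nd["id"], frozenset(nd["new_mutations"])))
        counts[nd["id"]] = int(nd["count"])
    tree = MutationTree.from_edges(
        edges,
        counts,
        patient_id=d["patient_id"],
        sampling_time=d.get("sampling_time"),
        c_seq=int(d["C_seq"]),
        c_tumor=d.get("C_tumor"),
        weight=float(d.get("weight", 1.0)),
    )
    total = tree.observed_total()
    if total != tree.c_seq:
        raise TreeError(
            f"{where}: C_seq={tree.c_seq} but node counts sum to {total}"
        )
    return tree


def cohort_to_dict(cohort: Cohort) -> dict:
    return {
        "n": cohort.n,
        "mutations": list(cohort.mutations),
        "trees": [_tree_to_dict(t) for t in cohort.trees],
    }


def cohort_from_dict(d: dict) -> Cohort:
    for key in ("n", "trees"):
        if key not in d:
            raise TreeError(f"cohort: missing required key {key!r}")
    trees = [
        _tree_from_dict(td, f"tree #{i} ({td.get('patient_id', '?')})")
        for i, td in enumerate(d["trees"])
    ]
    return Cohort(trees=trees, n=int(d["n"]), mutations=list(d.get("mutations", [])))


def write_cohort(cohort: Cohort, path) -> None:
    with open(path, "w") as fh:
        json.dump(cohort_to_dict(cohort), fh, indent=1)


def read_cohort(path) -> Cohort:
    with open(path) as fh:
        return cohort_from_dict(json.load(fh))


# -- Newick export ------------------------------------------------------------


def to_newick(tree: MutationTree) -> str:
    """Newick string with genotype and count carried in node comments.

    Export-only convenience; the JSON schema is the canonical format.
    """

    def fmt(nid: str) -> str:
        kids = sorted(tree.children(nid))
        inner = "(" + ",".join(fmt(k) for k in kids) + ")" if kids else ""
        g = ",".join(map(str, sorted(tree.genotype_of(nid))))
        return f"{inner}{nid}[&genotype={{{g}}},count={tree.nodes[nid].count}]"

    return fmt(tree.root_id) + ";"
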