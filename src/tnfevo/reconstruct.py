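"""WGD-constrained Dollo and Wagner parsimony on the species tree.

Presence/absence of each orthology group evolves under Dollo parsimony: a
group arises exactly once (at the branch its origin constraint dictates, or
at the most recent common ancestor of the species carrying it when
unconstrained) and can only be lost afterwards; losses are minimised. Copy
numbers within the presence region evolve under Wagner parsimony: integer
states, cost |Delta| per branch, anchored at one copy where the group
originates. Ties in the Wagner assignment are broken toward the smallest
ancestral count, so duplications are called as late as possible.

Copy gains on a branch annotated with the teleost-specific WGD are labelled
``wgd_retention`` when the group predates that branch; gains elsewhere are
``tandem_duplication``. A species present in the tree but absent from the
count matrix is missing data: it never induces a loss.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import (
    ConstraintSet,
    CountMatrix,
    Event,
    EventHistory,
    InfeasibleConstraintError,
    OriginConstraint,
    SpeciesTree,
    ValidationError,
)

__all__ = [
    "OriginPlacement",
    "place_origin",
    "dollo_losses",
    "wagner_counts",
    "infer_history",
    "ancestral_repertoire",
    "progenitor_count",
    "post_wgd_gene_count",
    "conservation_summary",
    "ConservationSummary",
]

#: Wagner headroom above the largest observed count, covering WGD doublings.
WAGNER_HEADROOM = 4
WAGNER_STATE_CAP = 32


@dataclass(frozen=True)
class OriginPlacement:
    """Where a group arises: the branch (child-node name) and the event label."""

    group: str
    branch: str
    event: str  # "origin" always; ``via`` records the constraint kind
    via: str = "unconstrained"


def _presence_leaves(group: str, matrix: CountMatrix, tree: SpeciesTree) -> tuple[set, set]:
    """(present leaves, missing-data leaves) for one group."""
    leaves = set(tree.leaves)
    scored = leaves & set(matrix.species)
    present = {s for s in scored if matrix.count(s, group) > 0}
    missing = leaves - scored
    return present, missing


def place_origin(
    group: str,
    matrix: CountMatrix,
    tree: SpeciesTree,
    constraint: OriginConstraint | None = None,
) -> OriginPlacement:
    """Resolve the branch on which ``group`` originates.

    Unconstrained groups originate on the branch above the MRCA of the species
    that carry them (standard Dollo). WGD-constrained groups originate on the
    branch carrying that WGD event; tandem-constrained groups on their stated
    branch. An origin that is not ancestral to every carrier species raises
    :class:`InfeasibleConstraintError`.
    """
    present, _ = _presence_leaves(group, matrix, tree)
    origin = constraint.origin if constraint is not None else "unconstrained"

    if origin == "unconstrained":
        if not present:
            raise ValidationError(
                f"group {group!r} has no presences and no constraint forcing existence"
            )
        node = tree.mrca(present)
        return OriginPlacement(group=group, branch=node, event="origin", via="unconstrained")

    if origin in ("pre_WGD", "WGD1", "WGD2"):
        wgd = "WGD1" if origin == "pre_WGD" else origin
        branch = tree.wgd_branch(wgd)
        if branch is None:
            if origin == "pre_WGD":
                branch = tree.root  # no WGD in the tree: pre-WGD = root stem
            else:
                raise InfeasibleConstraintError(
                    f"group {group!r} requires event {wgd} absent from the tree"
                )
    else:  # tandem
        branch = constraint.branch  # type: ignore[union-attr]
        if branch is None or branch not in tree.nodes:
            raise InfeasibleConstraintError(
                f"tandem origin of {group!r} names unknown branch {branch!r}"
            )
    for leaf in present:
        if not tree.is_ancestor(branch, leaf):
            raise InfeasibleConstraintError(
                f"origin of {group!r} on branch {branch!r} is not ancestral to carrier {leaf!r}"
            )
    return OriginPlacement(group=group, branch=branch, event="origin", via=origin)


def dollo_losses(
    tree: SpeciesTree,
    origin_node: str,
    present: set[str],
    missing: set[str] = frozenset(),
) -> list[str]:
    """Branches (child-node names) carrying Dollo losses below ``origin_node``.

    A loss is placed at the root of every maximal subtree below the origin
    whose scored leaves all lack the group; subtrees consisting solely of
    missing-data leaves induce no loss.
    """
    state: dict[str, str] = {}
    for node in tree.postorder():
        if tree.is_leaf(node):
            state[node] = "present" if node in present else ("missing" if node in missing else "absent")
        else:
            kids = [state[c] for c in tree.children(node)]
            if any(s == "present" for s in kids):
                state[node] = "present"
            elif all(s == "missing" for s in kids):
                state[node] = "missing"
            else:
                state[node] = "absent"
    losses = []
    for node in tree.preorder():
        if not tree.is_ancestor(origin_node, node):
            continue
        if state[node] != "absent":
            continue
        par = tree.parent(node)
        if node == origin_node or (par is not None and state[par] == "present"):
            losses.append(node)
    return losses


def wagner_counts(
    tree: SpeciesTree,
    region: set[str],
    leaf_counts: dict[str, int],
    origin_node: str,
    origin_count: int = 1,
) -> dict[str, int]:
    """Minimal-|Delta| integer copy numbers on the presence region.

    ``region`` is the set of nodes where the group is present (it must be
    connected and contain ``origin_node``); leaf counts are fixed; the state
    entering ``origin_node`` from the origin event is ``origin_count``. Exact
    Sankoff dynamic programme over states ``1..S``; ties break toward the
    smallest ancestral count.
    """
    if origin_node not in region:
        raise ValueError("origin node must belong to the presence region")
    smax = max(
        [origin_count]
        + [leaf_counts[n] for n in region if n in leaf_counts]
    )
    smax = min(smax + WAGNER_HEADROOM, WAGNER_STATE_CAP)
    states = np.arange(1, smax + 1)
    INF = 10**9
    cost: dict[str, np.ndarray] = {}
    for node in tree.postorder():
        if node not in region:
            continue
        if tree.is_leaf(node):
            c = np.full(len(states), INF)
            k = leaf_counts[node]
            c[states == k] = 0
            cost[node] = c
        else:
            c = np.zeros(len(states))
            for child in tree.children(node):
                if child not in region:
                    continue
                child_cost = cost[child][None, :] + np.abs(states[:, None] - states[None, :])
                c = c + child_cost.min(axis=1)
            cost[node] = c
    root_cost = cost[origin_node] + np.abs(states - origin_count)
    assignment: dict[str, int] = {}
    best = int(states[int(np.argmin(root_cost))])  # argmin takes smallest on ties
    assignment[origin_node] = best
    for node in tree.preorder():
        if node not in region or node == origin_node:
            continue
        par = tree.parent(node)
        if par not in assignment:
            continue
        trans = cost[node] + np.abs(states - assignment[par])
        assignment[node] = int(states[int(np.argmin(trans))])
    return assignment


def infer_history(
    matrix: CountMatrix,
    tree: SpeciesTree,
    constraints: ConstraintSet | None = None,
) -> EventHistory:
    """Reconstruct the full event history of every group in the matrix."""
    constraints = constraints or ConstraintSet()
    events: list[Event] = []
    repertoires: dict[str, dict[str, int]] = {n: {} for n in tree.nodes}

    ts_branch = tree.wgd_branch("TS_WGD")

    for group in matrix.groups:
        present, missing = _presence_leaves(group, matrix, tree)
        if not present and group not in constraints:
            continue
        constraint = constraints.get(group)
        placement = place_origin(group, matrix, tree, constraint)
        origin_node = placement.branch
        events.append(Event(branch=origin_node, kind="origin", group=group))

        losses = dollo_losses(tree, origin_node, present, missing)
        for branch in losses:
            events.append(Event(branch=branch, kind="loss", group=group))

        # presence region: nodes below the origin not under a loss branch
        lost = set()
        for lb in losses:
            lost.update(tree._subtree(lb))
        region = {
            n
            for n in tree._subtree(origin_node)
            if n not in lost and (not tree.is_leaf(n) or n in present or n in missing)
        }
        leaf_counts = {s: matrix.count(s, group) for s in present}
        # missing-data leaves inside the region carry no count constraint:
        # drop them (and any internal node whose region descendants are all
        # missing) from the Wagner programme.
        informative = set()
        for n in tree.postorder():
            if n not in region:
                continue
            if tree.is_leaf(n):
                if n in present:
                    informative.add(n)
            elif any(c in informative for c in tree.children(n)):
                informative.add(n)
        informative.add(origin_node)
        assignment = wagner_counts(tree, informative, leaf_counts, origin_node)

        node_count: dict[str, int] = {}
        for node in tree.preorder():
            if node not in region:
                continue
            par = tree.parent(node)
            if node in informative:
                count = assignment[node]
            else:
                # missing-data region nodes inherit the nearest reconstructed
                # ancestor's count (imputation, not evidence)
                count = node_count.get(par, 1) if par is not None else 1
            node_count[node] = count
            repertoires[node][group] = count
            if node not in informative:
                continue
            prev = 1 if node == origin_node else assignment[par]
            delta = count - prev
            if delta > 0:
                if ts_branch == node and origin_node != node:
                    kind = "wgd_retention"
                else:
                    kind = "tandem_duplication"
                events.append(Event(branch=node, kind=kind, group=group, n=delta))
            elif delta < 0:
                events.append(Event(branch=node, kind="copy_loss", group=group, n=-delta))

    history = EventHistory(events, repertoires)
    # leaf repertoires must reproduce the matrix exactly
    for species in matrix.species:
        if species not in tree.nodes:
            continue
        rep = history.repertoires.get(species, {})
        for group in matrix.groups:
            if rep.get(group, 0) != matrix.count(species, group):
                raise AssertionError(
                    f"leaf repertoire mismatch for {species}/{group}"
                )
    return history


def ancestral_repertoire(history: EventHistory, node: str) -> dict[str, int]:
    """Group -> copy-count map at ``node`` (groups with count >= 1 only)."""
    return history.repertoire(node)


def progenitor_count(
    history: EventHistory, constraints: ConstraintSet, tree: SpeciesTree
) -> int:
    """Number of distinct pre-WGD gene lineages implied by the history.

    WGD-originated groups contribute their progenitor id; tandem-originated
    groups inherit the progenitor of their (transitively resolved) parent;
    unconstrained groups whose Dollo origin is the root stem count as their
    own lineage; anything originating later contributes nothing.
    """
    lineages: set[str] = set()
    for group in history.groups:
        c = constraints.root_constraint(group)
        if c.origin in ("pre_WGD", "WGD1", "WGD2"):
            if not c.progenitor:
                raise ValidationError(f"WGD-originated group {c.group!r} lacks progenitor")
            lineages.add(c.progenitor)
        elif c.origin == "unconstrained":
            origin = history.origin_of(group)
            # root-originating groups are their own pre-WGD lineage
            if origin.branch == tree.root:
                lineages.add(f"lineage:{group}")
    return len(lineages)


def post_wgd_gene_count(
    history: EventHistory,
    constraints: ConstraintSet,
    tree: SpeciesTree,
) -> int:
    """Genes existing immediately after the second ancestral WGD.

    Counts groups whose origin is at or before WGD2: WGD- and pre-WGD-
    constrained groups always; tandem groups only when their duplication
    branch lies strictly above the WGD2 branch (a tandem on the WGD-bearing
    stem itself postdates the WGDs of that stem); unconstrained groups when
    their Dollo origin is ancestral to (or at) the node just below WGD2.
    """
    wgd2 = tree.wgd_branch("WGD2")
    anchor = wgd2 if wgd2 is not None else tree.root
    n = 0
    for group in history.groups:
        c = constraints.get(group)
        if c.origin in ("pre_WGD", "WGD1", "WGD2"):
            n += 1
        elif c.origin == "tandem":
            if c.branch is not None and tree.is_ancestor(c.branch, anchor, strict=True):
                n += 1
        else:
            origin = history.origin_of(group)
            if tree.is_ancestor(origin.branch, anchor):
                n += 1
    return n


# ---------------------------------------------------------------------------
# Conservation summary
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ConservationSummary:
    """Partition of orthology groups by phylogenetic breadth of retention."""

    universal: tuple[str, ...]  # present in every species
    shared_not_universal: tuple[str, ...]  # >=1 agnathan and >=1 gnathostome
    gnathostome_only: tuple[str, ...]
    agnathan_only: tuple[str, ...]
    per_species_groups: dict[str, int]  # number of groups present
    per_species_genes: dict[str, int]  # total genes including Other
    absent_in_reference: tuple[str, ...]
    reference_species: str

    @property
    def n_groups(self) -> int:
        return (
            len(self.universal)
            + len(self.shared_not_universal)
            + len(self.gnathostome_only)
            + len(self.agnathan_only)
        )


def conservation_summary(
    matrix: CountMatrix,
    tree: SpeciesTree,
    agnathan_root: str = "agnathan_ancestor",
    reference_species: str = "Homo_sapiens",
) -> ConservationSummary:
    """Classify groups by retention across the agnathan/gnathostome divide."""
    if agnathan_root in tree.nodes:
        agnathans = set(tree.leaf_set(agnathan_root)) & set(matrix.species)
    else:
        agnathans = set()
    gnathostomes = set(matrix.species) - agnathans

    universal, shared, gn_only, ag_only = [], [], [], []
    for group in matrix.groups:
        carriers = set(matrix.present_species(group))
        if not carriers:
            continue
        in_ag = bool(carriers & agnathans)
        in_gn = bool(carriers & gnathostomes)
        if carriers == set(matrix.species):
            universal.append(group)
        elif in_ag and in_gn:
            shared.append(group)
        elif in_gn:
            gn_only.append(group)
        else:
            ag_only.append(group)

    per_groups = {s: len(matrix.groups_present(s)) for s in matrix.species}
    per_genes = {s: int(matrix.totals[s]) for s in matrix.species}
    absent_ref = tuple(
        g
        for g in matrix.groups
        if matrix.present_species(g) and (
            reference_species not in matrix.species
            or matrix.count(reference_species, g) == 0
        )
    )
    return ConservationSummary(
        universal=tuple(universal),
        shared_not_universal=tuple(shared),
        gnathostome_only=tuple(gn_only),
        agnathan_only=tuple(ag_only),
        per_species_groups=per_groups,
        per_species_genes=per_genes,
        absent_in_reference=absent_ref,
        reference_species=reference_species,
    )
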