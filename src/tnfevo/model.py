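"""Core data types for gene-family evolution analysis.

The central objects are a rooted, name-annotated species tree whose branches
may carry whole-genome-duplication (WGD) events, a species x orthology-group
count matrix, a table of per-group origin constraints (which WGD, or which
tandem duplication, created each group), gene trees with bootstrap supports,
BED-like gene-order tracks, and the per-branch event histories produced by
parsimony reconstruction.

Branches are identified throughout by the name of their child node; the root
node's own name addresses the stem lineage above the root, which is where the
two ancestral vertebrate WGDs live in the packaged data.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "ValidationError",
    "InfeasibleConstraintError",
    "WGD_EVENT_NAMES",
    "UNASSIGNED",
    "SpeciesTree",
    "CountMatrix",
    "OriginConstraint",
    "ConstraintSet",
    "GeneTree",
    "GeneTrack",
    "Event",
    "EventHistory",
    "SequenceAssignment",
]

WGD_EVENT_NAMES = ("WGD1", "WGD2", "TS_WGD")

#: Sentinel group label for sequences not placed in any orthology group.
UNASSIGNED = "UNASSIGNED"


class ValidationError(ValueError):
    """Malformed or inconsistent input data."""


class InfeasibleConstraintError(ValueError):
    """An origin constraint that no Dollo history can satisfy."""


# ---------------------------------------------------------------------------
# Species tree
# ---------------------------------------------------------------------------


class SpeciesTree:
    """Rooted species tree with named internal nodes and branch WGD events.

    Parameters
    ----------
    parent
        Mapping node name -> parent name (root maps to ``None``).
    lengths
        Mapping node name -> length of the branch above it (may be missing).
    branch_events
        Mapping branch (child-node name) -> ordered tuple of WGD event names.
        Keying the root's name places events on the stem above the root.
    """

    def __init__(
        self,
        parent: Mapping[str, str | None],
        lengths: Mapping[str, float] | None = None,
        branch_events: Mapping[str, Sequence[str]] | None = None,
    ) -> None:
        self._parent = dict(parent)
        self._lengths = dict(lengths or {})
        self._events = {k: tuple(v) for k, v in (branch_events or {}).items() if v}
        self._children: dict[str, list[str]] = {n: [] for n in self._parent}
        roots = [n for n, p in self._parent.items() if p is None]
        if len(roots) != 1:
            raise ValidationError(f"tree must have exactly one root, found {roots!r}")
        self.root = roots[0]
        for node, par in self._parent.items():
            if par is None:
                continue
            if par not in self._parent:
                raise ValidationError(f"parent {par!r} of {node!r} is not a node")
            self._children[par].append(node)
        self._validate()

    def _validate(self) -> None:
        # connectivity / acyclicity
        seen = set()
        stack = [self.root]
        while stack:
            n = stack.pop()
            if n in seen:
                raise ValidationError(f"cycle through node {n!r}")
            seen.add(n)
            stack.extend(self._children[n])
        if seen != set(self._parent):
            raise ValidationError("tree is not connected")
        for length in self._lengths.values():
            if length < 0:
                raise ValidationError("branch lengths must be non-negative")
        for branch, events in self._events.items():
            if branch not in self._parent:
                raise ValidationError(f"event on nonexistent branch {branch!r}")
            for ev in events:
                if ev not in WGD_EVENT_NAMES:
                    raise ValidationError(f"unknown event {ev!r} on branch {branch!r}")
            if "TS_WGD" in events and ({"WGD1", "WGD2"} & set(events)):
                raise ValidationError(
                    f"TS_WGD cannot share branch {branch!r} with WGD1/WGD2"
                )
            if "WGD1" in events and "WGD2" in events:
                if events.index("WGD1") > events.index("WGD2"):
                    raise ValidationError(f"WGD1 must precede WGD2 on branch {branch!r}")

    # -- structure ---------------------------------------------------------

    @property
    def nodes(self) -> list[str]:
        return list(self._parent)

    def parent(self, node: str) -> str | None:
        return self._parent[node]

    def children(self, node: str) -> tuple[str, ...]:
        return tuple(self._children[node])

    def is_leaf(self, node: str) -> bool:
        return not self._children[node]

    @property
    def leaves(self) -> list[str]:
        return [n for n in self.postorder() if self.is_leaf(n)]

    @property
    def internal_nodes(self) -> list[str]:
        return [n for n in self.postorder() if not self.is_leaf(n)]

    def branch_length(self, node: str) -> float:
        return self._lengths.get(node, 0.0)

    @property
    def branch_events(self) -> dict[str, tuple[str, ...]]:
        return dict(self._events)

    def events_on(self, branch: str) -> tuple[str, ...]:
        return self._events.get(branch, ())

    def postorder(self) -> Iterator[str]:
        def walk(n: str) -> Iterator[str]:
            for c in self._children[n]:
                yield from walk(c)
            yield n

        return walk(self.root)

    def preorder(self) -> Iterator[str]:
        stack = [self.root]
        while stack:
            n = stack.pop()
            yield n
            stack.extend(reversed(self._children[n]))

    def leaf_set(self, node: str) -> frozenset[str]:
        """Leaves descending from (and including, if a leaf) ``node``."""
        return frozenset(n for n in self._subtree(node) if self.is_leaf(n))

    def _subtree(self, node: str) -> Iterator[str]:
        stack = [node]
        while stack:
            n = stack.pop()
            yield n
            stack.extend(self._children[n])

    def path_to_root(self, node: str) -> list[str]:
        path = [node]
        while (p := self._parent[path[-1]]) is not None:
            path.append(p)
        return path

    def is_ancestor(self, ancestor: str, node: str, strict: bool = False) -> bool:
        path = self.path_to_root(node)
        if strict:
            path = path[1:]
        return ancestor in path

    def mrca(self, nodes: Iterable[str]) -> str:
        nodes = list(nodes)
        if not nodes:
            raise ValueError("mrca of empty node set")
        common = set(self.path_to_root(nodes[0]))
        for n in nodes[1:]:
            common &= set(self.path_to_root(n))
        # deepest common ancestor = first hit walking up from any member
        for n in self.path_to_root(nodes[0]):
            if n in common:
                return n
        raise AssertionError("unreachable")

    def wgd_branch(self, event: str) -> str | None:
        """Branch carrying ``event`` (child-node name), or None."""
        hits = [b for b, evs in self._events.items() if event in evs]
        if not hits:
            return None
        if len(hits) > 1:
            raise ValidationError(f"event {event!r} occurs on multiple branches")
        return hits[0]

    def with_events(self, branch_events: Mapping[str, Sequence[str]]) -> "SpeciesTree":
        return SpeciesTree(self._parent, self._lengths, branch_events)

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, SpeciesTree)
            and self._parent == other._parent
            and self._lengths == other._lengths
            and self._events == other._events
        )

    def __repr__(self) -> str:  # pragma: no cover
        return f"SpeciesTree({len(self.leaves)} leaves, root={self.root!r})"


# ---------------------------------------------------------------------------
# Count matrix
# ---------------------------------------------------------------------------


class CountMatrix:
    """Species x orthology-group gene counts plus per-species "Other" tallies.

    ``counts`` is an integer DataFrame (index: species, columns: groups);
    ``other`` holds per-species numbers of detected-but-unplaced sequences.
    The "Other" column never takes part in group-level inference.
    """

    def __init__(self, counts: pd.DataFrame, other: pd.Series | None = None) -> None:
        counts = counts.fillna(0)
        bad = counts.apply(lambda col: (col % 1 != 0) | (col < 0)).any().any()
        if bad:
            raise ValidationError("counts must be non-negative integers")
        self.counts = counts.astype(int)
        if other is None:
            other = pd.Series(0, index=counts.index)
        self.other = other.reindex(counts.index).fillna(0).astype(int)
        if (self.other < 0).any():
            raise ValidationError("Other counts must be non-negative")
        if self.counts.index.has_duplicates:
            raise ValidationError("duplicate species rows")
        if self.counts.columns.has_duplicates:
            raise ValidationError("duplicate group columns")

    @property
    def species(self) -> list[str]:
        return list(self.counts.index)

    @property
    def groups(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def totals(self) -> pd.Series:
        """Per-species totals including the Other column."""
        return self.counts.sum(axis=1) + self.other

    def count(self, species: str, group: str) -> int:
        return int(self.counts.at[species, group])

    def present_species(self, group: str) -> list[str]:
        col = self.counts[group]
        return list(col.index[col > 0])

    def groups_present(self, species: str) -> list[str]:
        row = self.counts.loc[species]
        return list(row.index[row > 0])

    def subset(self, species: Sequence[str]) -> "CountMatrix":
        return CountMatrix(self.counts.loc[list(species)], self.other.loc[list(species)])

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, CountMatrix)
            and self.counts.equals(other.counts)
            and self.other.equals(other.other)
        )


# ---------------------------------------------------------------------------
# Origin constraints
# ---------------------------------------------------------------------------

ORIGIN_KINDS = ("pre_WGD", "WGD1", "WGD2", "tandem", "unconstrained")
CLUSTERS = ("TNF", "EDA", "FASL", "CD40L", "4-1BBL", "unassigned")


@dataclass(frozen=True)
class OriginConstraint:
    """Stated origin of one orthology group.

    ``origin`` is one of pre_WGD / WGD1 / WGD2 / tandem / unconstrained. For
    tandem origins ``parent_group`` names the duplicated group and ``branch``
    the branch (child-node name) carrying the duplication. ``progenitor``
    labels the pre-WGD lineage; ``sublineage`` optionally distinguishes the
    post-WGD1 copies of a progenitor for the ohnolog-quartet bookkeeping.
    ``paralogon`` is the ancestral chromosome ("9", "16" or "unknown").
    """

    group: str
    cluster: str = "unassigned"
    origin: str = "unconstrained"
    parent_group: str | None = None
    branch: str | None = None
    progenitor: str | None = None
    sublineage: str = ""
    paralogon: str = "unknown"

    def __post_init__(self) -> None:
        if self.origin not in ORIGIN_KINDS:
            raise ValidationError(f"unknown origin kind {self.origin!r}")
        if self.cluster not in CLUSTERS:
            raise ValidationError(f"unknown cluster {self.cluster!r}")
        if self.paralogon not in ("9", "16", "unknown"):
            raise ValidationError(f"paralogon must be 9, 16 or unknown")
        if self.origin == "tandem" and not self.parent_group:
            raise ValidationError(f"tandem origin of {self.group!r} needs parent_group")
        if self.origin in ("WGD1", "WGD2") and not self.progenitor:
            raise ValidationError(
                f"WGD-originated group {self.group!r} lacks a progenitor id"
            )


class ConstraintSet:
    """Collection of :class:`OriginConstraint`, one per group.

    Groups without an entry default to ``unconstrained``.
    """

    def __init__(self, constraints: Iterable[OriginConstraint] = ()) -> None:
        self._by_group: dict[str, OriginConstraint] = {}
        for c in constraints:
            if c.group in self._by_group:
                raise ValidationError(f"duplicate constraint for group {c.group!r}")
            self._by_group[c.group] = c
        self._validate()

    def _validate(self) -> None:
        for c in self._by_group.values():
            if c.origin == "tandem" and c.parent_group not in self._by_group:
                raise ValidationError(
                    f"tandem parent {c.parent_group!r} of {c.group!r} is not a known group"
                )
        quartets: dict[tuple[str, str], int] = {}
        for c in self._by_group.values():
            if c.origin in ("WGD1", "WGD2"):
                key = (c.progenitor or "", c.sublineage)
                quartets[key] = quartets.get(key, 0) + 1
        for key, n in quartets.items():
            if n > 4:
                raise ValidationError(
                    f"more than 4 ohnologs ({n}) in WGD quartet {key!r}"
                )
        # tandem chains must terminate (no cycles)
        for c in self._by_group.values():
            self.root_constraint(c.group)

    def get(self, group: str) -> OriginConstraint:
        return self._by_group.get(group, OriginConstraint(group=group))

    def __contains__(self, group: str) -> bool:
        return group in self._by_group

    def __iter__(self) -> Iterator[OriginConstraint]:
        return iter(self._by_group.values())

    def __len__(self) -> int:
        return len(self._by_group)

    def root_constraint(self, group: str) -> OriginConstraint:
        """Follow tandem parents up to the non-tandem founding constraint."""
        seen = set()
        c = self.get(group)
        while c.origin == "tandem":
            if c.group in seen:
                raise ValidationError(f"tandem cycle through {c.group!r}")
            seen.add(c.group)
            c = self.get(c.parent_group)  # type: ignore[arg-type]
        return c


# ---------------------------------------------------------------------------
# Gene tree
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneLeaf:
    species: str
    accession: str

    @property
    def label(self) -> str:
        return f"{self.species}|{self.accession}"


class GeneTree:
    """Rooted gene tree with integer bootstrap supports on internal branches.

    Leaves are labelled ``species|accession``. Supports are percentages in
    [0, 100]; a missing support is treated as 0 by downstream consumers.
    """

    def __init__(self, tree: dendropy.Tree) -> None:
        self._tree = tree
        labels = [t.label for t in tree.taxon_namespace if t.label]
        if len(labels) != len(set(labels)):
            raise ValidationError("duplicate gene-tree leaf labels")
        for node in tree.preorder_node_iter():
            s = _node_support(node)
            if s is not None and not (0 <= s <= 100):
                raise ValidationError(f"support {s} outside [0, 100]")

    @classmethod
    def from_newick(cls, text: str) -> "GeneTree":
        try:
            tree = dendropy.Tree.get(
                data=text,
                schema="newick",
                suppress_internal_node_taxa=True,
                rooting="force-rooted",
                preserve_underscores=True,
            )
        except Exception as exc:  # dendropy raises assorted error types
            raise ValidationError(f"malformed newick: {exc}") from exc
        return cls(tree)

    def to_newick(self) -> str:
        return self._tree.as_string(schema="newick", suppress_rooting=True).strip() + "\n"

    @property
    def leaves(self) -> list[GeneLeaf]:
        out = []
        for taxon in self._tree.taxon_namespace:
            out.append(_parse_leaf_label(taxon.label))
        return out

    def leaf_labels(self) -> list[str]:
        return [t.label for t in self._tree.taxon_namespace]

    def clades_with_support(self) -> list[tuple[frozenset[str], int | None]]:
        """All internal non-root clades as (leaf-label set, support)."""
        out = []
        for node in self._tree.preorder_node_iter():
            if node is self._tree.seed_node or node.is_leaf():
                continue
            leaves = frozenset(
                lf.taxon.label for lf in node.leaf_iter() if lf.taxon is not None
            )
            out.append((leaves, _node_support(node)))
        return out


def _node_support(node: dendropy.Node) -> int | None:
    if node.is_leaf() or node.parent_node is None:
        return None
    label = node.label
    if label in (None, ""):
        return None
    try:
        return int(round(float(label)))
    except ValueError:
        return None


def _parse_leaf_label(label: str) -> GeneLeaf:
    if "|" in label:
        species, accession = label.split("|", 1)
    else:
        species, accession = "", label
    return GeneLeaf(species=species, accession=accession)


# ---------------------------------------------------------------------------
# Gene-order tracks
# ---------------------------------------------------------------------------

TRACK_COLUMNS = ["species", "scaffold", "start", "end", "strand", "gene_id", "family"]


class GeneTrack:
    """Ordered gene positions for one species (BED-like, 0-based half-open).

    Records are sorted by (scaffold, start, end); a dense per-scaffold rank is
    assigned so neighbourhood logic can work in gene-order space. ``family``
    carries the cross-species orthology label of each gene (empty if unknown).
    Strand is recorded but plays no role in neighbourhood comparisons.
    """

    def __init__(self, species: str, records: pd.DataFrame) -> None:
        df = records.copy()
        missing = [c for c in ("scaffold", "start", "end", "gene_id") if c not in df]
        if missing:
            raise ValidationError(f"track missing columns {missing}")
        if "strand" not in df:
            df["strand"] = "+"
        if "family" not in df:
            df["family"] = ""
        df["family"] = df["family"].fillna("")
        if (df["start"] >= df["end"]).any():
            bad = df.loc[df["start"] >= df["end"], "gene_id"].iloc[0]
            raise ValidationError(f"gene {bad!r} has start >= end")
        if df["gene_id"].duplicated().any():
            raise ValidationError("duplicate gene ids in track")
        df = df.sort_values(["scaffold", "start", "end"], kind="mergesort")
        df = df.reset_index(drop=True)
        df["rank"] = df.groupby("scaffold").cumcount()
        self.species = species
        self.df = df
        self._index = {g: i for i, g in enumerate(df["gene_id"])}

    def __len__(self) -> int:
        return len(self.df)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._index

    def record(self, gene_id: str) -> pd.Series:
        try:
            return self.df.iloc[self._index[gene_id]]
        except KeyError:
            raise KeyError(f"gene {gene_id!r} not on track for {self.species!r}")

    def scaffold(self, name: str) -> pd.DataFrame:
        return self.df[self.df["scaffold"] == name]

    def scaffold_of(self, gene_id: str) -> str:
        return str(self.record(gene_id)["scaffold"])

    def families_on_scaffold(self, name: str) -> set[str]:
        fams = set(self.scaffold(name)["family"])
        fams.discard("")
        return fams

    def adjacent(self, gene_id: str, skip_families: set[str] | None = None) -> list[pd.Series]:
        """The immediately adjacent gene on each side of ``gene_id``.

        ``skip_families`` lists family labels that do not count as markers
        (e.g. tandem copies of the focal gene's own family): they are stepped
        over and the next gene outward is taken instead.
        """
        skip = skip_families or set()
        rec = self.record(gene_id)
        sc = self.scaffold(str(rec["scaffold"])).sort_values("rank")
        rank = int(rec["rank"])
        out = []
        for direction in (-1, 1):
            r = rank + direction
            ranks = set(sc["rank"])
            while r in ranks:
                row = sc[sc["rank"] == r].iloc[0]
                if str(row["family"]) not in skip:
                    out.append(row)
                    break
                r += direction
        return out


# ---------------------------------------------------------------------------
# Event history
# ---------------------------------------------------------------------------

EVENT_KINDS = (
    "origin",
    "loss",
    "wgd_retention",
    "tandem_duplication",
    "copy_gain",
    "copy_loss",
)


@dataclass(frozen=True, order=True)
class Event:
    """One reconstructed (or simulated) event on a branch.

    ``branch`` is the child-node name; ``n`` counts copies gained or lost
    (1 for presence-level origin/loss).
    """

    branch: str
    kind: str
    group: str
    n: int = 1

    def __post_init__(self) -> None:
        if self.kind not in EVENT_KINDS:
            raise ValidationError(f"unknown event kind {self.kind!r}")
        if self.n < 1:
            raise ValidationError("event multiplicity must be >= 1")


class EventHistory:
    """Per-branch events plus per-node gene repertoires.

    Invariants: each group has exactly one origin (Dollo single-gain axiom),
    and no event touches a group on a branch above its origin.
    """

    def __init__(
        self,
        events: Iterable[Event],
        repertoires: Mapping[str, Mapping[str, int]],
    ) -> None:
        self.events = sorted(events)
        self.repertoires = {
            node: {g: int(n) for g, n in rep.items() if n > 0}
            for node, rep in repertoires.items()
        }
        origins: dict[str, int] = {}
        for ev in self.events:
            if ev.kind == "origin":
                origins[ev.group] = origins.get(ev.group, 0) + 1
        for group, n in origins.items():
            if n != 1:
                raise ValidationError(f"group {group!r} has {n} origin events")

    @property
    def groups(self) -> list[str]:
        return sorted({ev.group for ev in self.events if ev.kind == "origin"})

    def events_on(self, branch: str, kind: str | None = None) -> list[Event]:
        return [
            ev
            for ev in self.events
            if ev.branch == branch and (kind is None or ev.kind == kind)
        ]

    def events_of_kind(self, kind: str) -> list[Event]:
        return [ev for ev in self.events if ev.kind == kind]

    def origin_of(self, group: str) -> Event:
        for ev in self.events:
            if ev.kind == "origin" and ev.group == group:
                return ev
        raise KeyError(f"group {group!r} has no origin event")

    def repertoire(self, node: str) -> dict[str, int]:
        try:
            return dict(self.repertoires[node])
        except KeyError:
            raise KeyError(f"unknown node {node!r}")


# ---------------------------------------------------------------------------
# Sequence assignments
# ---------------------------------------------------------------------------

ASSIGNMENT_FLAGS = (
    "clade_support",
    "synteny_same_position",
    "synteny_same_chromosome",
    "conflict",
)


@dataclass(frozen=True)
class SequenceAssignment:
    """Placement of one sequence into at most one orthology group."""

    accession: str
    species: str
    group: str = UNASSIGNED
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        for fl in self.flags:
            if fl not in ASSIGNMENT_FLAGS:
                raise ValidationError(f"unknown evidence flag {fl!r}")

    @property
    def assigned(self) -> bool:
        return self.group != UNASSIGNED
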