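"""Readers and writers for trees, matrices, constraints, tracks and results.

All tabular formats are UTF-8 TSV with ``#`` comment lines. Species trees are
newick with named internal nodes; WGD events ride in a separate two-column
table keyed by the child node of the branch that carries them (newick comment
dialects are too toolchain-dependent to carry events portably).
"""

from __future__ import annotations

import io as _io
from typing import Iterable, Mapping

import dendropy
import pandas as pd

from .model import (
    ConstraintSet,
    CountMatrix,
    Event,
    EventHistory,
    GeneTrack,
    GeneTree,
    OriginConstraint,
    SequenceAssignment,
    SpeciesTree,
    TRACK_COLUMNS,
    ValidationError,
)

__all__ = [
    "read_species_tree",
    "write_species_tree",
    "read_count_matrix",
    "write_count_matrix",
    "read_constraints",
    "write_constraints",
    "read_gene_track",
    "read_gene_tracks",
    "write_gene_tracks",
    "read_gene_tree",
    "read_assignments",
    "write_assignments",
    "write_history",
]

OTHER_COLUMN = "Other"
TOTAL_COLUMN = "No."


def _read_tsv(text: str, **kwargs) -> pd.DataFrame:
    return pd.read_csv(
        _io.StringIO(text), sep="\t", comment="#", dtype=str, keep_default_na=False, **kwargs
    )


# ---------------------------------------------------------------------------
# Species tree
# ---------------------------------------------------------------------------


def read_species_tree(newick_text: str, events_table: str | None = None) -> SpeciesTree:
    """Parse a rooted species tree and an optional branch-event table.

    The event table has columns ``branch`` (child-node name) and ``events``
    (comma-separated, ordered oldest first).
    """
    try:
        tree = dendropy.Tree.get(
            data=newick_text,
            schema="newick",
            suppress_internal_node_taxa=True,
            rooting="force-rooted",
            preserve_underscores=True,
        )
    except Exception as exc:
        raise ValidationError(f"malformed newick: {exc}") from exc

    parent: dict[str, str | None] = {}
    lengths: dict[str, float] = {}

    def name_of(node: dendropy.Node) -> str:
        if node.taxon is not None and node.taxon.label:
            return node.taxon.label
        if node.label:
            return node.label
        raise ValidationError("species-tree internal nodes must be named")

    for node in tree.preorder_node_iter():
        name = name_of(node)
        if name in parent:
            raise ValidationError(f"duplicate node name {name!r}")
        parent[name] = name_of(node.parent_node) if node.parent_node else None
        if node.edge.length is not None:
            lengths[name] = float(node.edge.length)

    branch_events: dict[str, tuple[str, ...]] = {}
    if events_table:
        df = _read_tsv(events_table)
        if not {"branch", "events"} <= set(df.columns):
            raise ValidationError("event table needs 'branch' and 'events' columns")
        for _, row in df.iterrows():
            evs = tuple(e.strip() for e in str(row["events"]).split(",") if e.strip())
            branch_events[str(row["branch"])] = evs
    return SpeciesTree(parent, lengths, branch_events)


def write_species_tree(tree: SpeciesTree) -> tuple[str, str]:
    """Serialize to (newick text, event-table TSV)."""

    def render(node: str) -> str:
        children = tree.children(node)
        label = node
        length = f":{tree.branch_length(node):g}" if tree.parent(node) else ""
        if not children:
            return f"{label}{length}"
        inner = ",".join(render(c) for c in children)
        return f"({inner}){label}{length}"

    newick = render(tree.root) + ";\n"
    lines = ["branch\tevents"]
    for branch, events in sorted(tree.branch_events.items()):
        lines.append(f"{branch}\t{','.join(events)}")
    return newick, "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Count matrix
# ---------------------------------------------------------------------------


def read_count_matrix(tsv_text: str) -> CountMatrix:
    """Parse a species x group count table.

    The first column holds species ids; blank cells are zeros. A column named
    ``Other`` collects unplaced sequences; an optional ``No.`` column states
    per-species totals and is checked against the recomputed row sums.
    """
    df = _read_tsv(tsv_text)
    if df.shape[1] < 2:
        raise ValidationError("count matrix needs a species column and >=1 group")
    df = df.set_index(df.columns[0])

    def to_int(val: str, context: str) -> int:
        val = val.strip()
        if val == "":
            return 0
        try:
            f = float(val)
        except ValueError:
            raise ValidationError(f"non-integer cell {val!r} in {context}")
        if f < 0 or f != int(f):
            raise ValidationError(f"cell {val!r} in {context} is not a non-negative integer")
        return int(f)

    parsed = df.apply(lambda col: [to_int(v, col.name) for v in col])
    totals = parsed.pop(TOTAL_COLUMN) if TOTAL_COLUMN in parsed else None
    other = parsed.pop(OTHER_COLUMN) if OTHER_COLUMN in parsed else None
    matrix = CountMatrix(parsed, other)
    if totals is not None:
        mismatch = matrix.totals != totals
        if mismatch.any():
            row = mismatch.index[mismatch][0]
            raise ValidationError(
                f"row total mismatch for {row!r}: counted "
                f"{int(matrix.totals[row])}, stated {int(totals[row])}"
            )
    return matrix


def write_count_matrix(matrix: CountMatrix, include_total: bool = True) -> str:
    df = matrix.counts.copy()
    df[OTHER_COLUMN] = matrix.other
    if include_total:
        df[TOTAL_COLUMN] = matrix.totals
    df = df.replace(0, "")
    if include_total:
        df[TOTAL_COLUMN] = matrix.totals  # totals always printed, even 0
    buf = _io.StringIO()
    df.to_csv(buf, sep="\t", index_label="species")
    return buf.getvalue()


# ---------------------------------------------------------------------------
# Origin constraints
# ---------------------------------------------------------------------------

_CONSTRAINT_COLUMNS = [
    "group",
    "cluster",
    "origin",
    "parent_group",
    "branch",
    "progenitor",
    "sublineage",
    "paralogon",
]


def read_constraints(tsv_text: str) -> ConstraintSet:
    df = _read_tsv(tsv_text)
    if df.empty and "group" not in df.columns:
        return ConstraintSet()
    if "group" not in df.columns:
        raise ValidationError("constraint table needs a 'group' column")
    out = []
    for _, row in df.iterrows():
        get = lambda col, default="": str(row[col]).strip() if col in df.columns else default
        out.append(
            OriginConstraint(
                group=get("group"),
                cluster=get("cluster") or "unassigned",
                origin=get("origin") or "unconstrained",
                parent_group=get("parent_group") or None,
                branch=get("branch") or None,
                progenitor=get("progenitor") or None,
                sublineage=get("sublineage"),
                paralogon=get("paralogon") or "unknown",
            )
        )
    return ConstraintSet(out)


def write_constraints(constraints: ConstraintSet) -> str:
    rows = []
    for c in constraints:
        rows.append(
            {
                "group": c.group,
                "cluster": c.cluster,
                "origin": c.origin,
                "parent_group": c.parent_group or "",
                "branch": c.branch or "",
                "progenitor": c.progenitor or "",
                "sublineage": c.sublineage,
                "paralogon": c.paralogon,
            }
        )
    df = pd.DataFrame(rows, columns=_CONSTRAINT_COLUMNS)
    buf = _io.StringIO()
    df.to_csv(buf, sep="\t", index=False)
    return buf.getvalue()


# ---------------------------------------------------------------------------
# Gene tracks
# ---------------------------------------------------------------------------


def read_gene_tracks(tsv_text: str) -> dict[str, GeneTrack]:
    """Parse a multi-species BED-like table into per-species tracks."""
    df = _read_tsv(tsv_text)
    missing = [c for c in TRACK_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"track table missing columns {missing}")
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    return {
        species: GeneTrack(species, sub.drop(columns=["species"]))
        for species, sub in df.groupby("species", sort=True)
    }


def read_gene_track(tsv_text: str) -> GeneTrack:
    """Parse a single-species track; errors if several species are present."""
    tracks = read_gene_tracks(tsv_text)
    if len(tracks) != 1:
        raise ValidationError(f"expected one species, found {sorted(tracks)}")
    return next(iter(tracks.values()))


def write_gene_tracks(tracks: Iterable[GeneTrack]) -> str:
    frames = []
    for track in sorted(tracks, key=lambda t: t.species):
        df = track.df[["scaffold", "start", "end", "strand", "gene_id", "family"]].copy()
        df.insert(0, "species", track.species)
        frames.append(df)
    out = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(columns=TRACK_COLUMNS)
    buf = _io.StringIO()
    out.to_csv(buf, sep="\t", index=False)
    return buf.getvalue()


# ---------------------------------------------------------------------------
# Gene trees and assignments
# ---------------------------------------------------------------------------


def read_gene_tree(newick_text: str) -> GeneTree:
    return GeneTree.from_newick(newick_text)


def read_assignments(tsv_text: str) -> list[SequenceAssignment]:
    df = _read_tsv(tsv_text)
    out = []
    for _, row in df.iterrows():
        flags = tuple(f for f in str(row.get("evidence_flags", "")).split(",") if f)
        out.append(
            SequenceAssignment(
                accession=str(row["accession"]),
                species=str(row["species"]),
                group=str(row["group"]),
                flags=flags,
            )
        )
    return out


def write_assignments(assignments: Iterable[SequenceAssignment]) -> str:
    rows = [
        {
            "accession": a.accession,
            "species": a.species,
            "group": a.group,
            "evidence_flags": ",".join(a.flags),
        }
        for a in assignments
    ]
    df = pd.DataFrame(rows, columns=["accession", "species", "group", "evidence_flags"])
    buf = _io.StringIO()
    df.to_csv(buf, sep="\t", index=False)
    return buf.getvalue()


# ---------------------------------------------------------------------------
# Event histories
# ---------------------------------------------------------------------------


def write_history(history: EventHistory) -> tuple[str, str]:
    """Serialize to (events TSV, repertoires TSV)."""
    ev_rows = [
        {"branch": e.branch, "group": e.group, "event": e.kind, "n": e.n}
        for e in history.events
    ]
    ev = pd.DataFrame(ev_rows, columns=["branch", "group", "event", "n"])
    rep_rows = [
        {"node": node, "group": g, "count": n}
        for node in sorted(history.repertoires)
        for g, n in sorted(history.repertoires[node].items())
    ]
    rep = pd.DataFrame(rep_rows, columns=["node", "group", "count"])
    b1, b2 = _io.StringIO(), _io.StringIO()
    ev.to_csv(b1, sep="\t", index=False)
    rep.to_csv(b2, sep="\t", index=False)
    return b1.getvalue(), b2.getvalue()


def read_history(events_tsv: str, repertoires_tsv: str) -> EventHistory:
    ev = _read_tsv(events_tsv)
    events = [
        Event(branch=r["branch"], kind=r["event"], group=r["group"], n=int(r["n"]))
        for _, r in ev.iterrows()
    ]
    rep = _read_tsv(repertoires_tsv)
    repertoires: dict[str, dict[str, int]] = {}
    for _, r in rep.iterrows():
        repertoires.setdefault(r["node"], {})[r["group"]] = int(r["count"])
    return EventHistory(events, repertoires)
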