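"""Orthology-group classification from gene trees plus synteny corroboration.

Leaves of a bootstrap-annotated gene tree are placed into orthology groups by
four rules applied in order:

1. a supported clade (subtending-branch bootstrap >= ``min_support``) that
   contains reference-species genes which no supported internal branch can
   separate species-consistently defines one group, named after those
   reference genes (two inseparable reference genes yield a merged,
   slash-joined name such as ``TNFSF1/2``);
2. a supported clade without reference genes but spanning >=2 species defines
   a novel group with a deterministic auto-name;
3. a leaf outside any qualifying clade is rescued into a group when it has
   same-position or same-chromosome synteny evidence with a member of exactly
   one group;
4. anything else stays UNASSIGNED.

"Species-consistently separable" operationalises the idea that two reference
genes belong to distinct groups only when a supported branch splits the clade
with at most one reference gene per side while keeping each non-reference
species' genes together; when every species' genes are equally related to
both reference genes no such branch exists and the genes merge.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from .model import (
    GeneTree,
    CountMatrix,
    SequenceAssignment,
    UNASSIGNED,
    ValidationError,
)
from .synteny import SyntenyEvidence, evidence_rank

import pandas as pd

__all__ = [
    "ClassificationConfig",
    "supported_clades",
    "classify",
    "assignments_to_matrix",
    "merged_group_name",
]


@dataclass(frozen=True)
class ClassificationConfig:
    """Knobs of the classification stage.

    ``min_support`` is the bootstrap percentage below which a branch is
    uninformative (95 marks significant support); ``reference_species`` seeds
    group names from its annotated genes; ``allow_synteny_rescue`` enables
    rule 3.
    """

    min_support: int = 95
    reference_species: str = "Homo_sapiens"
    allow_synteny_rescue: bool = True

    def __post_init__(self) -> None:
        if not (0 <= self.min_support <= 100):
            raise ValidationError("min_support must lie in [0, 100]")


def supported_clades(tree: GeneTree, min_support: int) -> list[frozenset[str]]:
    """All clades whose subtending branch has support >= ``min_support``.

    Singleton leaves are always included (a leaf needs no support). Missing
    supports count as 0. The root has no subtending branch and is excluded.
    """
    out = {frozenset([lab]) for lab in tree.leaf_labels()}
    for leaves, support in tree.clades_with_support():
        if (support or 0) >= min_support:
            out.add(leaves)
    return sorted(out, key=lambda s: (-len(s), sorted(s)))


def merged_group_name(names: Sequence[str]) -> str:
    """Slash-join group names, compressing a shared prefix (TNFSF1/2)."""
    names = sorted(set(names))
    if len(names) == 1:
        return names[0]
    prefix = names[0]
    for name in names[1:]:
        while not name.startswith(prefix):
            prefix = prefix[:-1]
    # only compress on a meaningful shared stem
    if len(prefix) >= 3 and all(len(n) > len(prefix) for n in names):
        return names[0] + "/" + "/".join(n[len(prefix):] for n in names[1:])
    return "/".join(names)


def _species_of(label: str) -> str:
    return label.split("|", 1)[0] if "|" in label else ""


def _accession_of(label: str) -> str:
    return label.split("|", 1)[1] if "|" in label else label


def _separable(
    clade: frozenset[str],
    clades: list[frozenset[str]],
    refs: Mapping[str, str],
) -> bool:
    """True if a supported branch splits ``clade``'s reference genes
    species-consistently (<=1 reference per side, each non-reference species
    wholly on one side)."""
    refs_in = {l for l in clade if l in refs}
    if len(refs_in) < 2:
        return False
    nonref_species: dict[str, set[str]] = {}
    for label in clade:
        if label in refs_in:
            continue
        nonref_species.setdefault(_species_of(label), set()).add(label)
    for part in clades:
        # only internal branches can separate: a bare leaf is no partition
        if len(part) < 2 or not (part < clade):
            continue
        inside = refs_in & part
        outside = refs_in - part
        if not inside or not outside:
            continue
        if len(inside) > 1 or len(outside) > 1:
            continue
        consistent = all(
            leaves <= part or leaves.isdisjoint(part)
            for leaves in nonref_species.values()
        )
        if consistent:
            return True
    return False


def classify(
    tree: GeneTree,
    config: ClassificationConfig | None = None,
    synteny: Sequence[SyntenyEvidence] = (),
    reference_labels: Mapping[str, str] | None = None,
) -> list[SequenceAssignment]:
    """Assign every gene-tree leaf to at most one orthology group.

    ``reference_labels`` maps reference-species accessions (or full
    ``species|accession`` labels) to known group names; it may be empty for
    fully de-novo grouping.
    """
    config = config or ClassificationConfig()
    reference_labels = dict(reference_labels or {})
    labels = tree.leaf_labels()

    # resolve reference map onto full leaf labels
    refs: dict[str, str] = {}
    for label in labels:
        acc = _accession_of(label)
        if label in reference_labels:
            refs[label] = reference_labels[label]
        elif acc in reference_labels:
            refs[label] = reference_labels[acc]

    clades = supported_clades(tree, config.min_support)

    # rule 1: maximal inseparable supported clades holding reference genes
    ref_clades: list[tuple[frozenset[str], str]] = []
    candidates = [
        c
        for c in clades
        if any(l in refs for l in c) and not _separable(c, clades, refs)
    ]
    for clade in candidates:  # sorted large -> small
        if any(clade <= chosen for chosen, _ in ref_clades):
            continue
        names = sorted({refs[l] for l in clade if l in refs})
        ref_clades.append((clade, merged_group_name(names)))

    assigned: dict[str, SequenceAssignment] = {}

    def assign(label: str, group: str, flags: tuple[str, ...]) -> None:
        assigned[label] = SequenceAssignment(
            accession=_accession_of(label),
            species=_species_of(label),
            group=group,
            flags=flags,
        )

    for clade, name in ref_clades:
        for label in clade:
            assign(label, name, ("clade_support",))

    # rule 2: novel groups -- supported multi-species clades with no reference
    taken = set().union(*(c for c, _ in ref_clades)) if ref_clades else set()
    novel: list[frozenset[str]] = []
    for clade in clades:
        if len(clade) < 2 or clade & taken:
            continue
        if any(l in refs for l in clade):
            continue
        if len({_species_of(l) for l in clade}) < 2:
            continue
        if any(clade <= chosen for chosen in novel):
            continue
        novel.append(clade)
    for clade in novel:
        name = "GRP-" + min(_accession_of(l) for l in clade)
        for label in clade:
            assign(label, name, ("clade_support",))

    # rule 3: synteny rescue of the leftovers
    if config.allow_synteny_rescue and synteny:
        member_group = {
            (a.species, a.accession): a.group for a in assigned.values() if a.assigned
        }
        for label in labels:
            if label in assigned:
                continue
            key = (_species_of(label), _accession_of(label))
            votes: dict[str, int] = {}
            for ev in synteny:
                if evidence_rank(ev.evidence_class) <= 0:
                    continue
                a_key = (ev.species_a, ev.gene_a)
                b_key = (ev.species_b, ev.gene_b)
                if a_key == key:
                    other = b_key
                elif b_key == key:
                    other = a_key
                else:
                    continue
                group = member_group.get(other)
                if group is None:
                    continue
                rank = evidence_rank(ev.evidence_class)
                votes[group] = max(votes.get(group, -1), rank)
            if not votes:
                continue
            best = max(votes.values())
            winners = sorted(g for g, r in votes.items() if r == best)
            if len(winners) > 1:
                assign(label, UNASSIGNED, ("conflict",))
            else:
                flag = (
                    "synteny_same_position" if best == 2 else "synteny_same_chromosome"
                )
                assign(label, winners[0], (flag,))

    out = []
    for label in labels:
        if label in assigned:
            out.append(assigned[label])
        else:
            out.append(
                SequenceAssignment(
                    accession=_accession_of(label),
                    species=_species_of(label),
                    group=UNASSIGNED,
                )
            )
    return out


def assignments_to_matrix(assignments: Sequence[SequenceAssignment]) -> CountMatrix:
    """Tally assignments into a species x group count matrix.

    UNASSIGNED sequences land in the per-species "Other" tally.
    """
    species = sorted({a.species for a in assignments})
    groups = sorted({a.group for a in assignments if a.assigned})
    counts = pd.DataFrame(0, index=species, columns=groups, dtype=int)
    other = pd.Series(0, index=species, dtype=int)
    for a in assignments:
        if a.assigned:
            counts.at[a.species, a.group] += 1
        else:
            other[a.species] += 1
    return CountMatrix(counts, other)
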