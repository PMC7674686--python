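"""Microsynteny evidence between gene neighbourhoods, and its chance model.

Two genes in different species are scored *same_position* when at least one
gene immediately adjacent to the first (rank distance 1 in gene order) has an
ortholog immediately adjacent to the second — shared flanking genes are very
unlikely by chance, and the probability of such a collision is modelled as
``neighbor_slots / genome_gene_count`` (four slots in a 20,000-gene genome
give 1/5,000). When no flanker is shared but a neighbour's ortholog lies on
the second gene's scaffold, the pair is scored *same_chromosome*, consistent
with intrachromosomal rearrangement. Pairs with an empty or unavailable
neighbourhood are *undetermined*, never *none*.

Adjacency is defined on gene order (ranks), not base pairs; the base-pair
window only bounds how far a neighbourhood extends on sparse scaffolds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .model import GeneTrack

__all__ = [
    "SyntenyEvidence",
    "Neighborhood",
    "EVIDENCE_CLASSES",
    "evidence_rank",
    "neighborhood",
    "shared_neighbor_evidence",
    "chance_probability",
    "corroborate",
    "GroupSyntenyVerdict",
    "DEFAULT_WINDOW_BP",
    "DEFAULT_MAX_WINDOW_BP",
    "DEFAULT_NEIGHBOR_SLOTS",
]

#: evidence classes in decreasing strength; ``undetermined`` is incomparable
EVIDENCE_CLASSES = ("same_position", "same_chromosome", "none", "undetermined")

DEFAULT_WINDOW_BP = 200_000
DEFAULT_MAX_WINDOW_BP = 1_000_000
#: two immediately flanking genes per side of the focal gene
DEFAULT_NEIGHBOR_SLOTS = 4


def evidence_rank(evidence_class: str) -> int:
    """Total order on determinate classes: same_position > same_chromosome > none."""
    order = {"same_position": 2, "same_chromosome": 1, "none": 0, "undetermined": -1}
    return order[evidence_class]


@dataclass(frozen=True)
class SyntenyEvidence:
    """Neighbourhood comparison between one gene pair across two species."""

    species_a: str
    gene_a: str
    species_b: str
    gene_b: str
    evidence_class: str
    shared_neighbors: tuple[str, ...] = ()
    collision_probability: float = 1.0

    def __post_init__(self) -> None:
        if self.evidence_class not in EVIDENCE_CLASSES:
            raise ValueError(f"unknown evidence class {self.evidence_class!r}")
        if not (0.0 <= self.collision_probability <= 1.0):
            raise ValueError("collision probability outside [0, 1]")
        if self.evidence_class == "same_position" and not self.shared_neighbors:
            raise ValueError("same_position requires >=1 shared adjacent neighbor")


@dataclass(frozen=True)
class Neighborhood:
    """Neighbours of a focal gene, split by side, nearest first."""

    gene_id: str
    left: tuple[str, ...]
    right: tuple[str, ...]
    one_sided: bool

    @property
    def all(self) -> tuple[str, ...]:
        return self.left + self.right

    @property
    def empty(self) -> bool:
        return not (self.left or self.right)


def neighborhood(
    track: GeneTrack,
    gene: str,
    k_genes: int = 2,
    window_bp: int = DEFAULT_WINDOW_BP,
    max_window_bp: int = DEFAULT_MAX_WINDOW_BP,
) -> Neighborhood:
    """Up to ``k_genes`` neighbours per side of ``gene`` within a bp window.

    The window starts at ``window_bp`` per side and, on a side with no
    neighbour inside it, expands toward ``max_window_bp`` until the nearest
    gene enters or the scaffold ends. The neighbourhood is flagged one-sided
    when a side stays empty.
    """
    rec = track.record(gene)  # KeyError if absent
    sc = track.scaffold(str(rec["scaffold"]))
    rank = int(rec["rank"])
    start, end = int(rec["start"]), int(rec["end"])

    def side(rows: pd.DataFrame, gap_of) -> tuple[str, ...]:
        picked = []
        for _, row in rows.iterrows():
            gap = gap_of(row)
            if gap <= window_bp or (not picked and gap <= max_window_bp):
                picked.append(str(row["gene_id"]))
            if len(picked) >= k_genes:
                break
        return tuple(picked)

    left_rows = sc[sc["rank"] < rank].sort_values("rank", ascending=False)
    right_rows = sc[sc["rank"] > rank].sort_values("rank")
    left = side(left_rows, lambda r: max(0, start - int(r["end"])))
    right = side(right_rows, lambda r: max(0, int(r["start"]) - end))
    return Neighborhood(gene_id=gene, left=left, right=right, one_sided=not (left and right))


def chance_probability(genome_gene_count: int, neighbor_slots: int) -> float:
    """Probability that an unrelated gene lands in a flanking slot by chance.

    With ``neighbor_slots`` candidate positions in a genome of
    ``genome_gene_count`` genes the collision probability is simply
    ``slots / genes``, capped at 1 (e.g. 4/20,000 = 1/5,000).
    """
    if genome_gene_count <= 0:
        raise ValueError("genome_gene_count must be positive")
    if neighbor_slots < 0:
        raise ValueError("neighbor_slots must be non-negative")
    return min(neighbor_slots / genome_gene_count, 1.0)


def shared_neighbor_evidence(
    track_a: GeneTrack,
    track_b: GeneTrack,
    gene_a: str,
    gene_b: str,
    orthology_map: Mapping[str, str] | None = None,
    k_genes: int = 2,
    window_bp: int = DEFAULT_WINDOW_BP,
    max_window_bp: int = DEFAULT_MAX_WINDOW_BP,
    neighbor_slots: int = DEFAULT_NEIGHBOR_SLOTS,
) -> SyntenyEvidence:
    """Compare the neighbourhoods of ``gene_a`` and ``gene_b``.

    ``orthology_map`` maps gene ids to cross-species family labels; when
    omitted, the ``family`` column of the tracks is used. Classification:
    *same_position* if an immediately adjacent neighbour of ``gene_a`` shares
    a family with an immediately adjacent neighbour of ``gene_b``;
    *same_chromosome* if any neighbour's family occurs anywhere on
    ``gene_b``'s scaffold; *none* otherwise; *undetermined* when either
    neighbourhood is empty.
    """

    def family(track: GeneTrack, gene_id: str) -> str:
        if orthology_map is not None:
            return orthology_map.get(gene_id, "")
        return str(track.record(gene_id)["family"])

    nb_a = neighborhood(track_a, gene_a, k_genes, window_bp, max_window_bp)
    nb_b = neighborhood(track_b, gene_b, k_genes, window_bp, max_window_bp)
    if nb_a.empty or nb_b.empty:
        return SyntenyEvidence(
            species_a=track_a.species,
            gene_a=gene_a,
            species_b=track_b.species,
            gene_b=gene_b,
            evidence_class="undetermined",
        )

    genome_b = max(len(track_b), 1)

    # tandem copies of the focal family are not independent markers
    focal_fams = {family(track_a, gene_a), family(track_b, gene_b)} - {""}
    adj_a = {
        family(track_a, str(r["gene_id"])): str(r["gene_id"])
        for r in track_a.adjacent(gene_a, skip_families=focal_fams)
    }
    adj_b = {
        family(track_b, str(r["gene_id"])): str(r["gene_id"])
        for r in track_b.adjacent(gene_b, skip_families=focal_fams)
    }
    adj_a.pop("", None)
    adj_b.pop("", None)
    shared = sorted(set(adj_a) & set(adj_b))
    if shared:
        return SyntenyEvidence(
            species_a=track_a.species,
            gene_a=gene_a,
            species_b=track_b.species,
            gene_b=gene_b,
            evidence_class="same_position",
            shared_neighbors=tuple(shared),
            collision_probability=chance_probability(genome_b, neighbor_slots),
        )

    scaffold_b = track_b.scaffold_of(gene_b)
    fams_on_scaffold = track_b.families_on_scaffold(scaffold_b)
    neighbor_fams = {family(track_a, g) for g in nb_a.all} - {""}
    hit = sorted(neighbor_fams & fams_on_scaffold)
    if hit:
        # collision chance of landing anywhere on that scaffold
        p = min(len(track_b.scaffold(scaffold_b)) / genome_b, 1.0)
        return SyntenyEvidence(
            species_a=track_a.species,
            gene_a=gene_a,
            species_b=track_b.species,
            gene_b=gene_b,
            evidence_class="same_chromosome",
            shared_neighbors=tuple(hit),
            collision_probability=p,
        )
    return SyntenyEvidence(
        species_a=track_a.species,
        gene_a=gene_a,
        species_b=track_b.species,
        gene_b=gene_b,
        evidence_class="none",
    )


@dataclass(frozen=True)
class GroupSyntenyVerdict:
    """Best synteny evidence for one (group, species) across comparators."""

    group: str
    species: str
    best_class: str
    combined_probability: float
    corroborated: bool
    n_comparisons: int


def corroborate(
    group: str,
    evidence: Sequence[SyntenyEvidence],
    alpha: float = 1e-3,
) -> list[GroupSyntenyVerdict]:
    """Combine per-pair evidence into per-species verdicts for a group.

    For each species appearing on the A side of the evidence list, the verdict
    takes the best evidence class across comparator species and multiplies the
    collision probabilities of the determinate comparisons (treated as
    independent); the verdict is corroborated when the combined probability
    falls below ``alpha`` and the best class is positive.
    """
    by_species: dict[str, list[SyntenyEvidence]] = {}
    for ev in evidence:
        by_species.setdefault(ev.species_a, []).append(ev)
    verdicts = []
    for species in sorted(by_species):
        evs = by_species[species]
        determinate = [e for e in evs if e.evidence_class != "undetermined"]
        if not determinate:
            verdicts.append(
                GroupSyntenyVerdict(
                    group=group,
                    species=species,
                    best_class="undetermined",
                    combined_probability=1.0,
                    corroborated=False,
                    n_comparisons=len(evs),
                )
            )
            continue
        best = max(determinate, key=lambda e: evidence_rank(e.evidence_class))
        positive = [e for e in determinate if evidence_rank(e.evidence_class) > 0]
        combined = math.prod(e.collision_probability for e in positive) if positive else 1.0
        verdicts.append(
            GroupSyntenyVerdict(
                group=group,
                species=species,
                best_class=best.evidence_class,
                combined_probability=combined,
                corroborated=bool(positive) and combined < alpha,
                n_comparisons=len(evs),
            )
        )
    return verdicts
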