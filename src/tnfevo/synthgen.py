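"""Birth--death simulation of gene-family evolution on a species tree.

The generator mirrors the assumed generative structure of the analysis:
``n_progenitors`` single-origin gene lineages exist at the top of the root
stem; at every ancestral WGD each extant gene copy is retained as a duplicate
with probability ``wgd_retention_prob``, and each retained duplicate founds a
new orthology group (ohnolog); at a teleost-style WGD (``TS_WGD``) retained
duplicates stay inside their group as extra copies. Along branches, copies
are lost by Poisson thinning (per-copy survival ``exp(-loss_rate * t)``) and
tandem duplicates arise at ``tandem_rate`` per copy per unit branch length,
staying in their parent's group and, on gene-order tracks, adjacent to it.
WGD events fire at the start of their branch, before the branch-length
processes.

Every simulated group records its true origin event and progenitor lineage,
so reconstructions can be scored against the truth; emitted matrices, tracks
and gene trees are mutually consistent by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .model import (
    ConstraintSet,
    CountMatrix,
    Event,
    EventHistory,
    GeneTrack,
    GeneTree,
    OriginConstraint,
    SpeciesTree,
    ValidationError,
)

__all__ = [
    "SimulationConfig",
    "SimulatedHistory",
    "simulate_history",
    "simulate_tracks",
    "simulate_gene_tree",
    "recovery_report",
    "RecoveryMetrics",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the generative model.

    Rates are per gene copy per unit branch length; ``support_noise`` is the
    standard deviation (percent) of the downward perturbation applied to
    bootstrap supports; ``genome_gene_count`` sizes the background genome of
    the gene-order tracks (default 20,000, an ordinary vertebrate gene count).
    """

    seed: int = 0
    wgd_retention_prob: float = 0.9
    loss_rate: float = 0.1
    tandem_rate: float = 0.05
    rearrangement_rate: float = 0.1
    support_noise: float = 5.0
    n_progenitors: int = 3
    genome_gene_count: int = 20_000

    def __post_init__(self) -> None:
        if not (0.0 <= self.wgd_retention_prob <= 1.0):
            raise ValidationError("wgd_retention_prob must lie in [0, 1]")
        for name in ("loss_rate", "tandem_rate", "rearrangement_rate", "support_noise"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be non-negative")
        if self.n_progenitors < 1 or self.genome_gene_count < 1:
            raise ValidationError("n_progenitors and genome_gene_count must be >= 1")


class SimulatedHistory(EventHistory):
    """Event history emitted by the simulator, with the truth attached."""

    def __init__(
        self,
        events,
        repertoires,
        tree: SpeciesTree,
        constraints: ConstraintSet,
        group_order: Sequence[str],
    ) -> None:
        super().__init__(events, repertoires)
        self.tree = tree
        self.true_constraints = constraints
        self.group_order = list(group_order)


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed % (2**31), stream])


def simulate_history(
    config: SimulationConfig, tree: SpeciesTree
) -> tuple[SimulatedHistory, CountMatrix]:
    """Simulate one family history; returns (truth history, leaf matrix)."""
    rng = _rng(config, 0)
    events: list[Event] = []
    repertoires: dict[str, dict[str, int]] = {}
    constraints: list[OriginConstraint] = []
    group_order: list[str] = []

    def new_group(name: str, origin: str, progenitor: str, parent: str | None, branch: str) -> None:
        group_order.append(name)
        constraints.append(
            OriginConstraint(
                group=name,
                origin=origin,
                parent_group=parent,
                branch=branch if origin == "tandem" else None,
                progenitor=progenitor,
                sublineage=parent or "",
            )
        )
        events.append(Event(branch=branch, kind="origin", group=name))

    progenitor_of: dict[str, str] = {}
    stem_state: dict[str, int] = {}
    for i in range(1, config.n_progenitors + 1):
        name = f"FAM{i}"
        stem_state[name] = 1
        progenitor_of[name] = f"P{i}"
        new_group(name, "pre_WGD", f"P{i}", None, tree.root)

    def process_branch(branch: str, state: dict[str, int]) -> dict[str, int]:
        state = dict(state)
        # WGD events first (they sit at the top of the branch)
        for ev_name in tree.events_on(branch):
            if ev_name in ("WGD1", "WGD2"):
                tag = "w1" if ev_name == "WGD1" else "w2"
                for group in sorted(state):
                    retained = int(rng.binomial(state[group], config.wgd_retention_prob))
                    for j in range(retained):
                        suffix = tag if retained == 1 else f"{tag}{chr(ord('a') + j)}"
                        child = f"{group}.{suffix}"
                        state[child] = 1
                        progenitor_of[child] = progenitor_of[group]
                        new_group(child, ev_name, progenitor_of[group], group, branch)
            else:  # TS_WGD: retained duplicates stay within their group
                for group in sorted(state):
                    gained = int(rng.binomial(state[group], config.wgd_retention_prob))
                    if gained:
                        state[group] += gained
                        events.append(
                            Event(branch=branch, kind="wgd_retention", group=group, n=gained)
                        )
        # branch-length processes: Poisson losses, then tandem duplications
        t = tree.branch_length(branch)
        if t > 0:
            survival = math.exp(-config.loss_rate * t)
            for group in sorted(state):
                kept = int(rng.binomial(state[group], survival))
                lost = state[group] - kept
                if lost:
                    state[group] = kept
                    kind = "loss" if kept == 0 else "copy_loss"
                    events.append(Event(branch=branch, kind=kind, group=group, n=lost))
            for group in sorted(state):
                if state[group] == 0:
                    continue
                gained = int(rng.poisson(config.tandem_rate * t * state[group]))
                if gained:
                    state[group] += gained
                    events.append(
                        Event(branch=branch, kind="tandem_duplication", group=group, n=gained)
                    )
        return state

    node_state: dict[str, dict[str, int]] = {}

    def walk(node: str, incoming: dict[str, int]) -> None:
        state = process_branch(node, incoming)
        node_state[node] = state
        repertoires[node] = {g: n for g, n in state.items() if n > 0}
        for child in tree.children(node):
            walk(child, state)

    walk(tree.root, stem_state)

    species = [n for n in tree.preorder() if tree.is_leaf(n)]
    counts = pd.DataFrame(
        {
            g: [node_state[s].get(g, 0) for s in species]
            for g in group_order
        },
        index=species,
        dtype=int,
    )
    matrix = CountMatrix(counts)
    history = SimulatedHistory(
        events, repertoires, tree, ConstraintSet(constraints), group_order
    )
    return history, matrix


# ---------------------------------------------------------------------------
# Gene-order tracks
# ---------------------------------------------------------------------------

_GENE_PITCH = 1_500
_GENE_LEN = 1_000


def copy_id(group: str, species: str, index: int) -> str:
    """Stable identifier of one gene copy, shared by tracks and gene trees."""
    return f"{group}-{species}-{index}"


def simulate_tracks(
    history: SimulatedHistory, config: SimulationConfig
) -> dict[str, GeneTrack]:
    """Gene-order tracks consistent with the history's leaf repertoires.

    Background genes keep a conserved ancestral order across species (their
    family label is shared, providing the orthology map); each group occupies
    one ancestral slot, with extra copies placed in tandem next to it. Each
    species' order is then perturbed by ``Poisson(rearrangement_rate * path
    length * track size)`` random gene moves.
    """
    rng = _rng(config, 1)
    tree = history.tree
    n_bg = config.genome_gene_count
    n_scaffolds = 4 if n_bg >= 40 else 1
    background = [f"BG{i:05d}" for i in range(n_bg)]
    # ancestral slot of each group: (position in background order)
    slots = {
        g: int(rng.integers(0, n_bg)) for g in history.group_order
    }

    per_scaffold = -(-n_bg // n_scaffolds)
    tracks: dict[str, GeneTrack] = {}
    species_list = [n for n in tree.preorder() if tree.is_leaf(n)]
    for sp_index, species in enumerate(species_list):
        sp_rng = np.random.default_rng([config.seed % (2**31), 1, sp_index])
        rep = history.repertoires.get(species, {})
        # scaffolds are cut in ancestral coordinates, so without
        # rearrangement every neighbour relation is conserved across species
        scaffolds: list[list[tuple[str, str]]] = [[] for _ in range(n_scaffolds)]
        for pos, bg in enumerate(background):
            sc = scaffolds[pos // per_scaffold]
            for group in sorted(g for g, s in slots.items() if s == pos and rep.get(g, 0) > 0):
                for k in range(rep[group]):
                    sc.append((copy_id(group, species, k), group))
            sc.append((f"{species}:{bg}", bg))
        # rearrangement: random relocations across the whole genome
        path_len = sum(
            tree.branch_length(n) for n in tree.path_to_root(species)
        )
        total = sum(len(sc) for sc in scaffolds)
        lam = config.rearrangement_rate * path_len * total
        n_moves = int(sp_rng.poisson(lam)) if lam > 0 else 0
        for _ in range(n_moves):
            i = int(sp_rng.integers(0, total))
            for sc in scaffolds:
                if i < len(sc):
                    gene = sc.pop(i)
                    break
                i -= len(sc)
            j = int(sp_rng.integers(0, total))
            for sc in scaffolds:
                if j <= len(sc):
                    sc.insert(j, gene)
                    break
                j -= len(sc)
        rows = []
        for sc_idx, sc in enumerate(scaffolds):
            for offset, (gid, fam) in enumerate(sc):
                rows.append(
                    {
                        "scaffold": f"sc{sc_idx:02d}",
                        "start": offset * _GENE_PITCH,
                        "end": offset * _GENE_PITCH + _GENE_LEN,
                        "strand": "+",
                        "gene_id": gid,
                        "family": fam,
                    }
                )
        tracks[species] = GeneTrack(species, pd.DataFrame(rows))
    return tracks


# ---------------------------------------------------------------------------
# Gene trees
# ---------------------------------------------------------------------------


def simulate_gene_tree(history: SimulatedHistory, config: SimulationConfig) -> GeneTree:
    """Gene tree concordant with the history: one supported clade per group.

    Each orthology group forms a clade of its surviving copies attached to
    the root; branch supports are 100 minus half-normal noise of scale
    ``support_noise``, clamped to [0, 100]. A fixed seed yields byte-identical
    newick.
    """
    rng = _rng(config, 2)
    tree = history.tree
    species_list = [n for n in tree.preorder() if tree.is_leaf(n)]
    parts = []
    for group in history.group_order:
        leaves = []
        for species in species_list:
            k = history.repertoires.get(species, {}).get(group, 0)
            leaves.extend(
                f"{species}|{copy_id(group, species, i)}" for i in range(k)
            )
        if not leaves:
            continue
        if len(leaves) == 1:
            parts.append(leaves[0])
        else:
            if config.support_noise > 0:
                support = int(round(
                    min(100.0, max(0.0, 100.0 - abs(rng.normal(0.0, config.support_noise))))
                ))
            else:
                support = 100
            parts.append("(" + ",".join(leaves) + ")" + str(support))
    if not parts:
        raise ValidationError("history has no surviving gene copies")
    newick = "(" + ",".join(parts) + ");\n" if len(parts) > 1 else parts[0] + ";\n"
    return GeneTree.from_newick(newick)


# ---------------------------------------------------------------------------
# Recovery metrics
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RecoveryMetrics:
    """How well an inferred history matches the simulated truth."""

    repertoire_precision: float
    repertoire_recall: float
    event_precision: float
    event_recall: float
    origin_accuracy: float


def _prf(truth: set, inferred: set) -> tuple[float, float]:
    tp = len(truth & inferred)
    precision = tp / len(inferred) if inferred else 1.0
    recall = tp / len(truth) if truth else 1.0
    return precision, recall


def recovery_report(truth: EventHistory, inferred: EventHistory) -> RecoveryMetrics:
    """Score an inferred history against the simulated truth.

    Repertoires are compared as presence sets per node, events as
    (branch, kind, group, n) tuples, and origins by branch per group.
    """
    if set(truth.repertoires) != set(inferred.repertoires):
        raise ValidationError("histories are defined on different trees")
    truth_rep = {
        (node, g) for node, rep in truth.repertoires.items() for g in rep
    }
    inf_rep = {
        (node, g) for node, rep in inferred.repertoires.items() for g in rep
    }
    rp, rr = _prf(truth_rep, inf_rep)
    truth_ev = {(e.branch, e.kind, e.group, e.n) for e in truth.events}
    inf_ev = {(e.branch, e.kind, e.group, e.n) for e in inferred.events}
    ep, er = _prf(truth_ev, inf_ev)
    groups = truth.groups
    hits = 0
    for g in groups:
        try:
            if inferred.origin_of(g).branch == truth.origin_of(g).branch:
                hits += 1
        except KeyError:
            pass
    origin_acc = hits / len(groups) if groups else 1.0
    return RecoveryMetrics(
        repertoire_precision=rp,
        repertoire_recall=rr,
        event_precision=ep,
        event_recall=er,
        origin_accuracy=origin_acc,
    )
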