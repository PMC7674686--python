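"""Packaged reference data: the ten-species TNF-superfamily study inputs.

The package ships (i) the rooted species tree of the three agnathans
(*Petromyzon marinus*, *Lethenteron camtschaticum*, *Eptatretus burgeri*),
two chondrichthyans (*Rhincodon typus*, *Callorhinchus milii*), three
actinopterygians (*Danio rerio*, *Takifugu rubripes*, *Lepisosteus oculatus*),
*Latimeria chalumnae* and *Homo sapiens*, with the two ancestral vertebrate
WGDs on the stem and the teleost-specific WGD on the *Danio*+*Takifugu* stem;
(ii) the published census of genes per orthology group in those ten species;
and (iii) the origin-constraint table encoding which WGD or tandem duplication
created each of the 24 orthology groups.
"""

from __future__ import annotations

from importlib import resources

from . import io as _io
from .model import ConstraintSet, CountMatrix, SequenceAssignment, SpeciesTree, UNASSIGNED

__all__ = [
    "species_tree",
    "count_matrix",
    "constraints",
    "census_assignments",
    "AGNATHAN_ROOT",
    "GNATHOSTOME_ROOT",
    "REFERENCE_SPECIES",
]

AGNATHAN_ROOT = "agnathan_ancestor"
GNATHOSTOME_ROOT = "gnathostome_ancestor"
REFERENCE_SPECIES = "Homo_sapiens"


def _data(name: str) -> str:
    return resources.files("tnfevo.data").joinpath(name).read_text(encoding="utf-8")


def species_tree() -> SpeciesTree:
    """The ten-species tree with WGD1/WGD2 on the vertebrate stem and TS_WGD."""
    return _io.read_species_tree(_data("species_tree.nwk"), _data("wgd_events.tsv"))


def count_matrix() -> CountMatrix:
    """Census of gene counts per species and orthology group (24 groups)."""
    return _io.read_count_matrix(_data("tnfsf_counts.tsv"))


def constraints() -> ConstraintSet:
    """Origin model: WGD2 ohnolog quartets plus dated tandem duplications."""
    return _io.read_constraints(_data("origin_constraints.tsv"))


def census_assignments() -> list[SequenceAssignment]:
    """Synthetic per-sequence expansion of the census matrix.

    The census counts genes, not named sequences; this helper materialises one
    assignment record per counted gene with synthetic accession ids (the real
    accessions are not packaged), which is sufficient to exercise matrix
    construction from assignments. "Other" tallies expand to UNASSIGNED rows.
    """
    matrix = count_matrix()
    out = []
    for species in matrix.species:
        k = 0
        for group in matrix.groups:
            for _ in range(matrix.count(species, group)):
                k += 1
                out.append(
                    SequenceAssignment(
                        accession=f"{species}-SYN{k:03d}",
                        species=species,
                        group=group,
                        flags=("clade_support",),
                    )
                )
        for _ in range(int(matrix.other[species])):
            k += 1
            out.append(
                SequenceAssignment(
                    accession=f"{species}-SYN{k:03d}", species=species, group=UNASSIGNED
                )
            )
    return out
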