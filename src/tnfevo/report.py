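"""Pipeline orchestration and publication-style tabular reports.

``run_pipeline`` reads a flat key=value config, runs the requested stages
(fixture reconstruction, or simulate-then-infer with recovery metrics) and
writes a self-describing run directory: stage TSVs, a machine-readable
``summary.json`` whose every number is recomputed from stage outputs, and a
log of versions, seeds and parameters. Reruns with the same config and seed
produce byte-identical summaries.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import platform
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from . import __version__, fixtures
from . import io as _io
from .model import ConstraintSet, CountMatrix, SpeciesTree, ValidationError
from .reconstruct import (
    conservation_summary,
    infer_history,
    post_wgd_gene_count,
    progenitor_count,
)
from .synthgen import (
    SimulationConfig,
    recovery_report,
    simulate_gene_tree,
    simulate_history,
    simulate_tracks,
)

__all__ = ["run_pipeline", "render_table1", "read_config", "reconstruction_summary"]

log = logging.getLogger("tnfevo")


def render_table1(matrix: CountMatrix, fmt: str = "tsv") -> str:
    """Render the species x group census with Other and total columns."""
    df = matrix.counts.copy()
    df["Other"] = matrix.other
    df["No."] = matrix.totals
    if fmt == "tsv":
        shown = df.replace(0, "")
        shown["No."] = df["No."]
        out = shown.to_csv(sep="\t", index_label="species")
        return out
    if fmt == "markdown":
        header = "| species | " + " | ".join(df.columns) + " |"
        sep = "|" + "---|" * (len(df.columns) + 1)
        rows = [
            "| " + " | ".join([str(idx)] + [str(v) if v else "" for v in row]) + " |"
            for idx, row in df.iterrows()
        ]
        return "\n".join([header, sep, *rows]) + "\n"
    raise ValueError(f"unknown format {fmt!r}")


def reconstruction_summary(
    matrix: CountMatrix,
    tree: SpeciesTree,
    constraints: ConstraintSet,
    agnathan_root: str = "agnathan_ancestor",
    reference_species: str = "Homo_sapiens",
) -> dict:
    """Reconstruct and condense the headline quantities into plain JSON."""
    history = infer_history(matrix, tree, constraints)
    losses_per_branch: dict[str, list[str]] = {}
    for ev in history.events_of_kind("loss"):
        losses_per_branch.setdefault(ev.branch, []).append(ev.group)
    repertoire_sizes = {
        node: len(history.repertoires.get(node, {}))
        for node in tree.internal_nodes
    }
    cons = conservation_summary(
        matrix, tree, agnathan_root=agnathan_root, reference_species=reference_species
    )
    return {
        "n_species": len(matrix.species),
        "n_groups": len(matrix.groups),
        "progenitor_count": progenitor_count(history, constraints, tree),
        "post_wgd_gene_count": post_wgd_gene_count(history, constraints, tree),
        "ancestral_repertoire_sizes": dict(sorted(repertoire_sizes.items())),
        "losses_per_branch": {
            b: sorted(gs) for b, gs in sorted(losses_per_branch.items())
        },
        "conservation": {
            "universal": sorted(cons.universal),
            "shared_not_universal": sorted(cons.shared_not_universal),
            "gnathostome_only": sorted(cons.gnathostome_only),
            "agnathan_only": sorted(cons.agnathan_only),
            "absent_in_reference": sorted(cons.absent_in_reference),
            "reference_species": cons.reference_species,
        },
        "per_species_genes": cons.per_species_genes,
        "per_species_groups": cons.per_species_groups,
    }


def read_config(path: Path) -> dict[str, str]:
    """Flat key=value config; '#' starts a comment."""
    out: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValidationError(f"bad config line {line!r}")
        key, value = line.split("=", 1)
        out[key.strip()] = value.strip()
    return out


_SIM_KEYS = {
    "wgd_retention_prob": float,
    "loss_rate": float,
    "tandem_rate": float,
    "rearrangement_rate": float,
    "support_noise": float,
    "n_progenitors": int,
    "genome_gene_count": int,
}


def run_pipeline(config_path: str | Path) -> Path:
    """Execute the configured stages; returns the run directory."""
    config_path = Path(config_path)
    cfg = read_config(config_path)
    outdir = Path(cfg.get("outdir", "tnfevo_run"))
    mode = cfg.get("mode", "fixture")
    seed = int(cfg.get("seed", "0"))

    # resolve inputs up front so missing files fail before any stage runs
    if mode == "fixture":
        tree = (
            _io.read_species_tree(
                Path(cfg["tree"]).read_text(),
                Path(cfg["events"]).read_text() if "events" in cfg else None,
            )
            if "tree" in cfg
            else fixtures.species_tree()
        )
        matrix = (
            _io.read_count_matrix(Path(cfg["matrix"]).read_text())
            if "matrix" in cfg
            else fixtures.count_matrix()
        )
        constraints = (
            _io.read_constraints(Path(cfg["constraints"]).read_text())
            if "constraints" in cfg
            else fixtures.constraints()
        )
    elif mode == "simulate":
        tree = (
            _io.read_species_tree(
                Path(cfg["tree"]).read_text(),
                Path(cfg["events"]).read_text() if "events" in cfg else None,
            )
            if "tree" in cfg
            else fixtures.species_tree()
        )
        sim_kwargs = {
            k: cast(cfg[k]) for k, cast in _SIM_KEYS.items() if k in cfg
        }
        sim_config = SimulationConfig(seed=seed, **sim_kwargs)
    else:
        raise ValidationError(f"unknown mode {mode!r}")

    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        log.info(
            "tnfevo %s | python %s | numpy %s pandas %s dendropy %s",
            __version__,
            platform.python_version(),
            np.__version__,
            pd.__version__,
            dendropy.__version__,
        )
        log.info("config %s: %s", config_path, cfg)
        (outdir / "config.txt").write_text(config_path.read_text())

        if mode == "simulate":
            history, matrix = simulate_history(sim_config, tree)
            tracks = simulate_tracks(history, sim_config)
            gene_tree = simulate_gene_tree(history, sim_config)
            (outdir / "gene_tree.nwk").write_text(gene_tree.to_newick())
            (outdir / "tracks.tsv").write_text(
                _io.write_gene_tracks(tracks.values())
            )
            ev_tsv, rep_tsv = _io.write_history(history)
            (outdir / "truth_events.tsv").write_text(ev_tsv)
            (outdir / "truth_repertoires.tsv").write_text(rep_tsv)
            constraints = history.true_constraints
            log.info(
                "simulated %d groups, %d events", len(history.groups), len(history.events)
            )
            inferred = infer_history(matrix, tree, constraints)
            metrics = recovery_report(history, inferred)
            summary = reconstruction_summary(matrix, tree, constraints)
            summary["recovery"] = dataclasses.asdict(metrics)
            history_out = inferred
        else:
            summary = reconstruction_summary(
                matrix,
                tree,
                constraints,
                agnathan_root=cfg.get("agnathan_root", "agnathan_ancestor"),
                reference_species=cfg.get("reference_species", "Homo_sapiens"),
            )
            history_out = infer_history(matrix, tree, constraints)

        (outdir / "matrix.tsv").write_text(_io.write_count_matrix(matrix))
        (outdir / "table.tsv").write_text(render_table1(matrix))
        ev_tsv, rep_tsv = _io.write_history(history_out)
        (outdir / "events.tsv").write_text(ev_tsv)
        (outdir / "repertoires.tsv").write_text(rep_tsv)
        (outdir / "summary.json").write_text(
            json.dumps(summary, indent=2, sort_keys=True) + "\n"
        )
        log.info(
            "reconstructed %d events across %d branches",
            len(history_out.events),
            len({e.branch for e in history_out.events}),
        )
    finally:
        log.removeHandler(handler)
        handler.close()
    return outdir
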