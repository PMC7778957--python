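"""YAML project configuration: data paths, dialects and column maps.

A project config names the annotation table set, the interaction sources
(with their dialect and, for DOMINE-style tables, the confidence classes to
keep) and optionally a structure directory with a chain-assignment table.
Relative paths are resolved against the config file's directory, so a
fixture directory written by the generator is self-contained.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import yaml

from . import annotation, interaction_sources, joint_graph, structure_interface
from .errors import LoadError


@dataclass
class Project:
    """All loaded inputs of one analysis session."""

    store: annotation.AnnotationStore
    ppi: dict
    ddi: dict
    graph: joint_graph.JointGraph
    posnet: structure_interface.PositionSpecificPPI | None
    expression_path: Path | None


def load_config(path) -> tuple[dict, Path]:
    path = Path(path)
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict) or "annotation" not in cfg:
        raise LoadError(f"config {path} lacks an 'annotation' section")
    return cfg, path.parent


def load_project(config_path, with_structures: bool = True) -> Project:
    """Load every input a config names and build the joint graph."""
    cfg, base = load_config(config_path)

    ann = cfg["annotation"]
    columns = ann.get("columns")
    sequences = None
    if ann.get("fasta"):
        sequences = annotation.read_protein_fasta(base / ann["fasta"])
    store = annotation.load_annotation(
        genes=base / ann["genes"],
        transcripts=base / ann["transcripts"],
        exons=base / ann["exons"],
        domains=base / ann["domains"],
        idmap=base / ann["idmap"],
        sequences=sequences,
        columns=columns,
    )

    sources = cfg.get("sources", {})
    ppi_cfg = sources.get("ppi", {})
    ppi = interaction_sources.read_ppi(
        base / ppi_cfg["path"],
        columns=tuple(ppi_cfg.get("columns", ("gene_a", "gene_b"))),
        idmap=store.idmap,
    )
    ddi_sets = []
    for entry in sources.get("ddi", []):
        dialect = entry.get("dialect", "threedid")
        if dialect == "threedid":
            ddi_sets.append(interaction_sources.read_ddi_3did(base / entry["path"]))
        elif dialect == "domine":
            keep = frozenset(entry.get("keep", interaction_sources.DEFAULT_KEEP))
            ddi_sets.append(interaction_sources.read_ddi_domine(base / entry["path"], keep=keep))
        else:
            raise LoadError(f"unknown DDI dialect {dialect!r}")
    ddi = interaction_sources.merge_ddi(*ddi_sets) if ddi_sets else {}

    graph = joint_graph.build_joint_graph(ppi, ddi, store)

    posnet = None
    struct_cfg = cfg.get("structures")
    if with_structures and struct_cfg:
        struct_dir = base / struct_cfg["dir"]
        structures = {p.stem: p for p in sorted(struct_dir.glob("*.pdb"))}
        if structures:
            posnet = structure_interface.build_position_network(
                structures, base / struct_cfg["chain_assignments"], store
            )

    expression_path = (base / cfg["expression"]) if cfg.get("expression") else None
    return Project(store, ppi, ddi, graph, posnet, expression_path)
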