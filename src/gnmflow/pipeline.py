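"""End-to-end run configuration and pipeline composition.

A :class:`RunConfig` fully determines one perturbation analysis: the
structure source, the contact cutoff, the perturbed residue, the time grid,
the excitation metric and threshold, and the clustering options.  Running
the pipeline is deterministic — the same configuration always produces
byte-identical output files.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import yaml

from gnmflow import gnm, pathway, propagation, structures
from gnmflow.errors import GnmflowError, InputError

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "read_annotations"]


@dataclass
class RunConfig:
    """Everything needed to reproduce one perturbation run.

    Residues are addressed the way structural biologists name them —
    chain + author residue number (+ insertion code) — or, for synthetic
    structures, by 0-based serial index.  Exactly one of ``pdb_path`` /
    ``synthetic`` selects the structure source.
    """

    pdb_path: Optional[str] = None
    synthetic: Optional[Dict] = None      # {"recipe", "n", "spacing"}
    chain_filter: Optional[List[str]] = None
    cutoff: float = 7.0                   # contact cutoff, Angstrom
    perturb_chain: Optional[str] = None
    perturb_residue_number: Optional[int] = None
    perturb_insertion_code: str = ""
    perturb_serial: Optional[int] = None  # alternative to chain+number
    displacement: float = 1.0
    initial_velocity: float = 0.0
    t_end: float = 20.0                   # units sqrt(m/gamma)
    dt: float = 0.001
    metric_kind: str = "squared"          # "squared" or "amplitude"
    threshold: float = 0.01
    gap_tolerance: int = 2
    annotation_file: Optional[str] = None
    top_fraction: float = 0.1
    output_dir: str = "gnmflow_out"
    seed: int = 0                         # reserved; current methods are deterministic

    def to_dict(self) -> Dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: Dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise InputError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    # -- resolution helpers -------------------------------------------------

    def load_structure(self) -> structures.StructureModel:
        if (self.pdb_path is None) == (self.synthetic is None):
            raise InputError(
                "config must set exactly one of pdb_path / synthetic"
            )
        if self.pdb_path is not None:
            chains = set(self.chain_filter) if self.chain_filter else None
            return structures.read_pdb_calpha(self.pdb_path,
                                              chain_filter=chains)
        spec = dict(self.synthetic)
        return structures.make_synthetic(
            spec["recipe"], int(spec["n"]), float(spec["spacing"])
        )

    def resolve_perturbed_serial(self,
                                 structure: structures.StructureModel) -> int:
        if self.perturb_serial is not None:
            if not 0 <= self.perturb_serial < len(structure):
                raise InputError(
                    f"perturb_serial {self.perturb_serial} out of range for "
                    f"{len(structure)}-residue structure"
                )
            return self.perturb_serial
        if self.perturb_chain is None or self.perturb_residue_number is None:
            raise InputError(
                "config must set perturb_serial or perturb_chain + "
                "perturb_residue_number"
            )
        return structure.serial_of(self.perturb_chain,
                                   self.perturb_residue_number,
                                   self.perturb_insertion_code)


def read_annotations(path, structure: structures.StructureModel) -> List[Optional[str]]:
    """Read a two-column annotation file (residue identifier, label).

    Identifiers are ``CHAIN:NUMBER`` or ``CHAIN:NUMBER:ICODE`` (e.g.
    ``A:127``); blank lines and ``#`` comments are ignored.  Returns one
    label per residue (``None`` where unannotated).
    """
    labels: List[Optional[str]] = [None] * len(structure)
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 2:
                raise InputError(
                    f"{path}:{lineno}: expected 'identifier label', got {raw!r}"
                )
            ident, label = parts
            bits = ident.split(":")
            if len(bits) not in (2, 3):
                raise InputError(
                    f"{path}:{lineno}: identifier must be CHAIN:NUMBER[:ICODE]"
                )
            chain, number = bits[0], int(bits[1])
            icode = bits[2] if len(bits) == 3 else ""
            serial = structure.serial_of(chain, number, icode)
            labels[serial] = label
    return labels


def run_pipeline(config: RunConfig) -> Dict:
    """Run the full analysis and write the output bundle.

    Writes ``excitation.tsv``, ``pathway.json``, ``pathway_edges.tsv``,
    ``anisotropy.tsv`` and ``run.log`` into ``config.output_dir``; returns
    the in-memory results keyed by the same names.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines: List[str] = []

    def log(msg: str) -> None:
        logger.info(msg)
        log_lines.append(msg)

    def stage(name: str):
        log(f"stage: {name}")

    try:
        stage("load structure")
        structure = config.load_structure()
        log(f"structure '{structure.source}' with {len(structure)} residues")

        stage("resolve perturbed residue")
        source = config.resolve_perturbed_serial(structure)
        log(f"perturbed residue serial {source} "
            f"({structure.nodes[source].label})")

        stage("build contact network")
        kirchhoff = gnm.build_kirchhoff(structure, cutoff=config.cutoff)
        log(f"cutoff {config.cutoff} A, "
            f"{int(kirchhoff.degrees.sum() // 2)} contacts, "
            f"{kirchhoff.n_components} component(s)")

        stage("eigendecomposition")
        modes = gnm.decompose(kirchhoff)

        stage("propagate perturbation")
        spec = propagation.PerturbationSpec(
            residue_serial=source,
            displacement=config.displacement,
            initial_velocity=config.initial_velocity,
        )
        grid = propagation.default_time_grid(config.t_end, config.dt)
        traj = propagation.respond(modes, spec, grid)

        stage("detect excitations")
        table = propagation.detect_excited(traj, config.threshold,
                                           config.metric_kind)
        log(f"{table.n_excited} residues excited "
            f"({config.metric_kind} metric, threshold {config.threshold})")

        stage("cluster and order pathway")
        annotations = None
        if config.annotation_file:
            annotations = read_annotations(config.annotation_file, structure)
        clusters = pathway.cluster_excited(
            table, gap_tolerance=config.gap_tolerance,
            annotations=annotations, structure=structure,
        )
        report = pathway.order_pathway(
            clusters, source, structure=structure,
            parameters={
                "threshold": config.threshold,
                "metric_kind": config.metric_kind,
                "cutoff": config.cutoff,
                "t_end": config.t_end,
                "dt": config.dt,
                "gap_tolerance": config.gap_tolerance,
            },
        )
        log(f"{len(clusters)} cluster(s); order by excitation time: "
            + " -> ".join(structure.nodes[c.central_residue].label
                          for c in report.clusters))

        stage("anisotropy profile")
        profile = pathway.anisotropy_profile(kirchhoff, structure, table,
                                             modes, source)
        log("Spearman rank correlations: "
            + json.dumps(profile.rank_correlations, sort_keys=True))

        stage("write outputs")
        table.to_tsv(out / "excitation.tsv", structure)
        report.to_json(out / "pathway.json")
        report.edge_table().to_csv(out / "pathway_edges.tsv", sep="\t",
                                   index=False, float_format="%.6g")
        profile.to_tsv(out / "anisotropy.tsv")
    except GnmflowError as exc:
        failed = log_lines[-1] if log_lines else "startup"
        raise type(exc)(f"[{failed}] {exc}") from exc

    import gnmflow

    header = [
        f"gnmflow {gnmflow.__version__}",
        "resolved config: " + json.dumps(config.to_dict(), sort_keys=True),
    ]
    (out / "run.log").write_text("\n".join(header + log_lines) + "\n")

    return {
        "structure": structure,
        "kirchhoff": kirchhoff,
        "modes": modes,
        "trajectory": traj,
        "excitation": table,
        "pathway": report,
        "anisotropy": profile,
    }
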