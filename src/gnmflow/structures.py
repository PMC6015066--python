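"""Coarse-grained structure input.

A protein is reduced to one node per residue, placed at the C-alpha atom.
This module reads that representation from PDB files and also generates
deterministic synthetic geometries (chains, rings, cubic lattices) used as
analytically tractable fixtures.
"""

from __future__ import annotations

import io
import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence, Set, Union

import numpy as np
import gemmi

from gnmflow.errors import EmptyStructureError, FormatError, InputError

logger = logging.getLogger(__name__)

__all__ = [
    "ResidueNode",
    "StructureModel",
    "read_pdb_calpha",
    "make_synthetic",
    "write_pdb_calpha",
]


@dataclass(frozen=True)
class ResidueNode:
    """One coarse-grained node: a residue represented by its C-alpha.

    Parameters
    ----------
    chain_id : str
        PDB chain identifier.
    residue_number : int
        Author residue number (PDB numbering, e.g. 127 for Asn127).
    insertion_code : str
        PDB insertion code, ``""`` when absent.
    residue_name : str
        Three-letter residue name.
    position : numpy.ndarray
        Cartesian coordinates in Angstrom, shape ``(3,)``.
    serial_index : int
        0-based contiguous index in file order; the row/column index of this
        residue in every matrix the package builds.
    """

    chain_id: str
    residue_number: int
    insertion_code: str
    residue_name: str
    position: np.ndarray
    serial_index: int

    def __post_init__(self):
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise InputError(
                f"node {self.chain_id}{self.residue_number}: position must be "
                f"a finite 3-vector, got {self.position!r}"
            )
        object.__setattr__(self, "position", pos)

    @property
    def identifier(self) -> tuple:
        return (self.chain_id, self.residue_number, self.insertion_code)

    @property
    def label(self) -> str:
        """Human-readable residue label, e.g. ``A/ASN127``."""
        icode = self.insertion_code or ""
        return f"{self.chain_id}/{self.residue_name}{self.residue_number}{icode}"


@dataclass
class StructureModel:
    """Ordered list of residue nodes plus a provenance label."""

    nodes: list
    source: str = "unknown"

    def __post_init__(self):
        if len(self.nodes) < 2:
            raise EmptyStructureError(
                f"structure '{self.source}' has {len(self.nodes)} node(s); "
                "at least 2 are required"
            )
        seen = set()
        for expect, node in enumerate(self.nodes):
            if node.serial_index != expect:
                raise FormatError(
                    f"serial_index gap at position {expect} "
                    f"(got {node.serial_index})"
                )
            if node.identifier in seen:
                raise FormatError(
                    f"duplicate residue identifier {node.identifier}"
                )
            seen.add(node.identifier)

    def __len__(self) -> int:
        return len(self.nodes)

    @property
    def n_residues(self) -> int:
        return len(self.nodes)

    @property
    def coords(self) -> np.ndarray:
        """``(N, 3)`` array of node coordinates in Angstrom."""
        return np.stack([node.position for node in self.nodes])

    def serial_of(self, chain_id: str, residue_number: int,
                  insertion_code: str = "") -> int:
        """Map a PDB residue identifier to its 0-based serial index."""
        for node in self.nodes:
            if node.identifier == (chain_id, residue_number, insertion_code):
                return node.serial_index
        raise InputError(
            f"residue {chain_id}/{residue_number}{insertion_code or ''} "
            f"not found in structure '{self.source}'"
        )

    def labels(self) -> list:
        return [node.label for node in self.nodes]


def _select_calpha(residue: "gemmi.Residue") -> Optional["gemmi.Atom"]:
    """Pick the C-alpha of a residue, resolving alternate locations.

    Keeps the altloc with the highest occupancy; ties are broken by altloc
    identifier order.  Calcium ions are also named ``CA`` in PDB files, so
    the element must be carbon.
    """
    candidates = [
        atom for atom in residue
        if atom.name == "CA" and atom.element.name == "C"
    ]
    if not candidates:
        return None
    return min(candidates, key=lambda a: (-a.occ, a.altloc or ""))


def read_pdb_calpha(
    pdb_source: Union[str, Path, io.IOBase],
    chain_filter: Optional[Set[str]] = None,
    model_index: int = 0,
) -> StructureModel:
    """Read a PDB file into the one-node-per-residue representation.

    Parameters
    ----------
    pdb_source : path or text stream
        PDB-format input.
    chain_filter : set of str, optional
        If given, keep only these chains.  HETATM residues are excluded
        unless they carry a C-alpha carbon *and* their chain is explicitly
        listed here.
    model_index : int
        Which model of a multi-model (NMR) file to use; default the first.

    Returns
    -------
    StructureModel

    Raises
    ------
    FormatError
        Unparseable input or duplicate residue identifiers.
    EmptyStructureError
        Fewer than two C-alpha nodes survive the filters.
    InputError
        ``model_index`` out of range.
    """
    if hasattr(pdb_source, "read"):
        text = pdb_source.read()
        if isinstance(text, bytes):
            text = text.decode()
        source_label = "<stream>"
        try:
            st = gemmi.read_pdb_string(text)
        except (RuntimeError, ValueError) as exc:
            raise FormatError(f"cannot parse PDB stream: {exc}") from exc
    else:
        path = Path(pdb_source)
        source_label = str(path)
        if not path.exists():
            raise InputError(f"no such file: {path}")
        try:
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Detect)
        except (RuntimeError, ValueError) as exc:
            raise FormatError(f"cannot parse {path}: {exc}") from exc

    if len(st) == 0:
        raise EmptyStructureError(f"{source_label}: no models")
    if not 0 <= model_index < len(st):
        raise InputError(
            f"model_index {model_index} out of range (file has {len(st)} models)"
        )
    model = st[model_index]

    nodes = []
    seen = set()
    for chain in model:
        if chain_filter is not None and chain.name not in chain_filter:
            continue
        for residue in chain:
            is_het = residue.het_flag == "H"
            if is_het and chain_filter is None:
                continue
            atom = _select_calpha(residue)
            if atom is None:
                if not is_het:
                    logger.warning(
                        "%s: residue %s %s%s lacks a C-alpha; skipped",
                        source_label, residue.name, chain.name, residue.seqid.num,
                    )
                continue
            icode = residue.seqid.icode.strip()
            ident = (chain.name, residue.seqid.num, icode)
            if ident in seen:
                raise FormatError(
                    f"{source_label}: duplicate residue identifier {ident}"
                )
            seen.add(ident)
            nodes.append(
                ResidueNode(
                    chain_id=chain.name,
                    residue_number=residue.seqid.num,
                    insertion_code=icode,
                    residue_name=residue.name,
                    position=np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
                    serial_index=len(nodes),
                )
            )

    if len(nodes) == 0:
        raise EmptyStructureError(
            f"{source_label}: no C-alpha atoms after filtering "
            f"(chain_filter={sorted(chain_filter) if chain_filter else None})"
        )
    return StructureModel(nodes=nodes, source=source_label)


def make_synthetic(recipe: str, n: int, spacing: float) -> StructureModel:
    """Generate a deterministic synthetic structure.

    Recipes
    -------
    ``chain``
        ``n`` collinear points along x at the given spacing.
    ``ring``
        ``n`` points equally spaced on a circle of circumference
        ``n * spacing`` (so adjacent chord lengths approach ``spacing``
        for large ``n``).
    ``lattice``
        ``n`` points filling a cubic grid of side ``ceil(n ** (1/3))``
        in x-fastest order.
    """
    if n < 2:
        raise InputError(f"n must be >= 2, got {n}")
    if not spacing > 0:
        raise InputError(f"spacing must be positive, got {spacing}")

    if recipe == "chain":
        positions = [(i * spacing, 0.0, 0.0) for i in range(n)]
    elif recipe == "ring":
        radius = n * spacing / (2.0 * math.pi)
        positions = [
            (radius * math.cos(2.0 * math.pi * i / n),
             radius * math.sin(2.0 * math.pi * i / n),
             0.0)
            for i in range(n)
        ]
    elif recipe == "lattice":
        side = math.ceil(n ** (1.0 / 3.0))
        while side ** 3 < n:  # guard against floating-point cube roots
            side += 1
        positions = []
        for i in range(n):
            x, rem = i % side, i // side
            y, z = rem % side, rem // side
            positions.append((x * spacing, y * spacing, z * spacing))
    else:
        raise InputError(
            f"unknown recipe {recipe!r}; expected chain, ring or lattice"
        )

    nodes = [
        ResidueNode(
            chain_id="A",
            residue_number=i + 1,
            insertion_code="",
            residue_name="GLY",
            position=np.array(pos),
            serial_index=i,
        )
        for i, pos in enumerate(positions)
    ]
    return StructureModel(nodes=nodes, source=f"synthetic:{recipe}:{n}:{spacing}")


def write_pdb_calpha(structure: StructureModel,
                     path: Optional[Union[str, Path]] = None) -> str:
    """Serialize the node list as a minimal C-alpha-only PDB text.

    Round-trips through :func:`read_pdb_calpha`: re-reading the output
    reproduces the same nodes (coordinates at PDB's 3-decimal precision).
    """
    lines = []
    for node in structure.nodes:
        x, y, z = node.position
        lines.append(
            "ATOM  {serial:>5} {name:<4}{alt}{res:<3} {chain}{num:>4}{icode}   "
            "{x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{b:6.2f}          {el:>2}".format(
                serial=node.serial_index + 1,
                name=" CA ",
                alt=" ",
                res=node.residue_name,
                chain=node.chain_id,
                num=node.residue_number,
                icode=node.insertion_code or " ",
                x=x, y=y, z=z, occ=1.0, b=0.0, el="C",
            )
        )
    lines.append("END")
    text = "\n".join(lines) + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text
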