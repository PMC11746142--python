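"""Cα-level structural containers and PDB/mmCIF I/O.

The plasticity analyses work entirely on Cα traces: a monomer is an ordered
set of numbered Cα coordinates with named segment ranges (the α-helices and
loops of the PspA fold), and an assembly is a set of such chains generated
by a helical symmetry operator. File I/O goes through gemmi so deposited
models and synthetic fixtures are read identically.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

__all__ = ["ToyMonomer", "AssemblyModel", "load_model", "write_pdb"]

# 62 one-character PDB chain identifiers, step-major assignment order
_CHAIN_ALPHABET = (
    "ABCDEFGHIJKLMNOPQRSTUVWXYZabcdefghijklmnopqrstuvwxyz0123456789"
)


@dataclass
class ToyMonomer:
    """Ordered Cα trace with residue numbers and named segment ranges.

    ``segment_map`` maps segment names (e.g. ``"alpha1"``) to inclusive
    residue-number ranges; ranges must be disjoint and residue numbers
    strictly increasing.
    """

    residue_numbers: np.ndarray  # (N,) int, strictly increasing
    coordinates: np.ndarray  # (N, 3) float, Å
    segment_map: dict[str, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        nums = np.asarray(self.residue_numbers, dtype=int)
        xyz = np.asarray(self.coordinates, dtype=float)
        if nums.ndim != 1 or xyz.shape != (nums.size, 3):
            raise ValueError("need matching residue numbers and (N, 3) coordinates")
        if np.any(np.diff(nums) <= 0):
            raise ValueError("residue numbers must be strictly increasing")
        if not np.all(np.isfinite(xyz)):
            raise ValueError("coordinates must be finite")
        spans = sorted(self.segment_map.values())
        for (a0, a1), (b0, b1) in zip(spans, spans[1:]):
            if a1 >= b0:
                raise ValueError("segment ranges must be disjoint")
        self.residue_numbers = nums
        self.coordinates = xyz

    def __len__(self) -> int:
        return self.residue_numbers.size

    def index_of(self, residue: int) -> int:
        idx = np.searchsorted(self.residue_numbers, residue)
        if idx >= len(self) or self.residue_numbers[idx] != residue:
            raise KeyError(f"residue {residue} not in monomer")
        return int(idx)

    def coords_for(self, start: int, stop: int) -> np.ndarray:
        """Cα coordinates for residues in the inclusive range [start, stop]."""
        sel = (self.residue_numbers >= start) & (self.residue_numbers <= stop)
        if not sel.any():
            raise KeyError(f"no residues in range {start}-{stop}")
        return self.coordinates[sel]

    def copy(self) -> "ToyMonomer":
        return ToyMonomer(
            self.residue_numbers.copy(), self.coordinates.copy(), dict(self.segment_map)
        )


@dataclass
class AssemblyModel:
    """Named chains of numbered Cα coordinates, e.g. one helical assembly.

    ``chain_order`` preserves lattice order (step-major, cyclic-copy-minor
    for generated assemblies) so that integer chain offsets are meaningful.
    """

    chains: dict[str, dict[int, np.ndarray]]
    chain_order: list[str]
    source: str = ""
    rod_diameter: float | None = None

    def __post_init__(self) -> None:
        if set(self.chain_order) != set(self.chains):
            raise ValueError("chain_order must list exactly the chain names")

    @property
    def n_chains(self) -> int:
        return len(self.chain_order)

    def ca(self, chain: str, residue: int) -> np.ndarray:
        try:
            return self.chains[chain][residue]
        except KeyError:
            raise KeyError(f"no Cα for residue {residue} in chain {chain}") from None

    def chain_coords(self, chain: str) -> np.ndarray:
        resmap = self.chains[chain]
        return np.array([resmap[r] for r in sorted(resmap)])

    def as_monomer(self, chain: str, segment_map: Mapping[str, tuple[int, int]] | None = None) -> ToyMonomer:
        resmap = self.chains[chain]
        nums = np.array(sorted(resmap), dtype=int)
        xyz = np.array([resmap[r] for r in nums])
        return ToyMonomer(nums, xyz, dict(segment_map or {}))


def chain_name(index: int) -> str:
    """Stable one-character chain id for lattice index ``index`` (< 62)."""
    if index >= len(_CHAIN_ALPHABET):
        raise ValueError("more chains than available PDB chain identifiers")
    return _CHAIN_ALPHABET[index]


def load_model(path: str | Path, rod_diameter: float | None = None) -> AssemblyModel:
    """Load all chains with Cα atoms from a PDB or mmCIF file."""
    import gemmi

    structure = gemmi.read_structure(str(path))
    if len(structure) == 0:
        raise ValueError(f"no models found in {path}")
    model = structure[0]
    chains: dict[str, dict[int, np.ndarray]] = {}
    order: list[str] = []
    for chain in model:
        resmap: dict[int, np.ndarray] = {}
        for residue in chain:
            atom = residue.find_atom("CA", "*")
            if atom is not None:
                resmap[residue.seqid.num] = np.array(
                    [atom.pos.x, atom.pos.y, atom.pos.z]
                )
        if resmap:
            chains[chain.name] = resmap
            order.append(chain.name)
    if not chains:
        raise ValueError(f"no Cα atoms found in {path}")
    return AssemblyModel(chains, order, source=str(path), rod_diameter=rod_diameter)


def write_pdb(model: AssemblyModel, path: str | Path) -> None:
    """Write an assembly as a Cα-only PDB file (residues typed as ALA)."""
    import gemmi

    structure = gemmi.Structure()
    structure.name = "pspatools-assembly"
    gmodel = gemmi.Model("1")
    serial = 1
    for name in model.chain_order:
        gchain = gemmi.Chain(name)
        for resnum in sorted(model.chains[name]):
            residue = gemmi.Residue()
            residue.name = "ALA"
            residue.seqid = gemmi.SeqId(resnum, " ")
            atom = gemmi.Atom()
            atom.name = "CA"
            atom.element = gemmi.Element("C")
            x, y, z = model.chains[name][resnum]
            atom.pos = gemmi.Position(float(x), float(y), float(z))
            atom.serial = serial
            serial += 1
            residue.add_atom(atom)
            gchain.add_residue(residue)
        gmodel.add_chain(gchain)
    structure.add_model(gmodel)
    structure.setup_entities()
    structure.write_pdb(str(path))
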