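"""PDB reading/writing for labeled structure frames (via biotite).

Coordinates are stored in Angstrom in PDB and converted to nm in memory.
Segment tags are reconstructed on read from a chain -> segment map for the
siRNA strands and from residue names for copolymer beads (LYS -> PLL,
PEG -> PEG, LAC/PLA -> PLA).  Donor/acceptor flags and hydrogen-donor links
are rebuilt from elements (N donors+acceptors, O/P acceptors; an H belongs
to the nearest heavy atom within 0.15 nm).
"""

from __future__ import annotations

import numpy as np
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile
from scipy.spatial import cKDTree

from .structure import SIRNA, StructureFrame

__all__ = ["write_pdb", "read_pdb"]

_RESNAME_SEGMENT = {"LYS": "PLL", "PEG": "PEG", "LAC": "PLA", "PLA": "PLA"}


def write_pdb(frame: StructureFrame, path) -> None:
    """Write a frame as a single-model PDB (nm -> Angstrom)."""
    n = frame.n_atoms
    atoms = struc.AtomArray(n)
    atoms.coord = frame.coords * 10.0
    atoms.chain_id = frame.chain.astype("U4")
    atoms.res_id = frame.resid
    atoms.res_name = frame.resname.astype("U5")
    atoms.element = frame.element.astype("U2")
    atoms.atom_name = np.array(
        [f"{e}{i % 100}" for i, e in enumerate(frame.element)], dtype="U6"
    )
    atoms.hetero = np.zeros(n, bool)
    pdb = PDBFile()
    pdb.set_structure(atoms)
    pdb.write(str(path))


def read_pdb(path, sirna_chains: tuple[str, ...] = ("A", "B")) -> list[StructureFrame]:
    """Read a (possibly multi-MODEL) PDB into labeled frames.

    ``sirna_chains`` names the duplex strands; every other chain is a
    copolymer whose bead segments come from residue names.
    """
    pdb = PDBFile.read(str(path))
    stack = pdb.get_structure()  # AtomArrayStack, coords in Angstrom
    frames = []
    for model in stack:
        segment = np.empty(model.array_length(), dtype="U8")
        for i in range(model.array_length()):
            if model.chain_id[i] in sirna_chains:
                segment[i] = SIRNA
            else:
                try:
                    segment[i] = _RESNAME_SEGMENT[model.res_name[i]]
                except KeyError:
                    raise ValueError(
                        f"cannot map residue {model.res_name[i]!r} in chain "
                        f"{model.chain_id[i]!r} to a copolymer segment"
                    ) from None
        element = model.element.astype("U2")
        coords = model.coord / 10.0
        heavy = element != "H"
        h_parent = np.full(len(element), -1, int)
        if (~heavy).any() and heavy.any():
            tree = cKDTree(coords[heavy])
            d, j = tree.query(coords[~heavy])
            heavy_idx = np.flatnonzero(heavy)
            h_idx = np.flatnonzero(~heavy)
            ok = d <= 0.15
            h_parent[h_idx[ok]] = heavy_idx[j[ok]]
        frames.append(StructureFrame(
            coords=coords, element=element,
            resname=model.res_name.astype("U5"), resid=model.res_id,
            chain=model.chain_id.astype("U4"), segment=segment,
            is_donor=(element == "N"),
            is_acceptor=np.isin(element, ("N", "O", "P")),
            h_parent=h_parent,
        ))
    return frames
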