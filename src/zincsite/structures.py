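"""Lightweight protein-structure container and PDB/mmCIF I/O (via gemmi).

Only what the geometric descriptors need is retained: per-residue C-alpha and
C-beta coordinates with chain/number/insertion-code addressing, plus the
structure's non-hydrogen polymer atom cloud (element symbols + coordinates)
for the hydrophobic-contrast descriptor, and the reported resolution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import gemmi
import numpy as np

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}


@dataclass(frozen=True)
class Residue:
    """A standard amino-acid residue with C-alpha/C-beta coordinates (A)."""

    chain: str
    number: int
    icode: str
    res_type: str  # one-letter code
    ca: Optional[np.ndarray]
    cb: Optional[np.ndarray]

    @property
    def label(self) -> str:
        """Chain:number(+insertion code) address, e.g. ``"A:42"``."""
        return f"{self.chain}:{self.number}{self.icode.strip()}"


@dataclass
class ProteinStructure:
    """Parsed polymer content of one structure (or fixture)."""

    id: str
    residues: list[Residue]
    atom_elements: tuple[str, ...]
    atom_coords: np.ndarray
    resolution: Optional[float] = None

    def residue_by_label(self, chain: str, number: int, icode: str = "") -> Residue:
        for res in self.residues:
            if (res.chain, res.number, res.icode.strip()) == (chain, number, icode.strip()):
                return res
        raise KeyError(f"no residue {chain}:{number}{icode} in structure {self.id}")


def idealized_cb(n: np.ndarray, ca: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Virtual C-beta from backbone N/CA/C using ideal tetrahedral geometry."""
    b = ca - n
    c_vec = c - ca
    a = np.cross(b, c_vec)
    return -0.58273431 * a + 0.56802827 * b - 0.54067466 * c_vec + ca


_WATER_NAMES = {"HOH", "WAT", "DOD"}


def load_structure(
    path: Union[str, Path],
    assembly: Optional[str] = None,
    include_hetero: bool = False,
) -> ProteinStructure:
    """Read a PDB or mmCIF file into a :class:`ProteinStructure`.

    Uses the first model.  Waters and hydrogens are always excluded; other
    hetero compounds are excluded from the atom cloud unless
    ``include_hetero`` is set (they are never enumerable residues).  Glycine
    (or any residue missing its C-beta) gets an idealized C-beta built from
    the backbone when N/CA/C are present, with a warning.

    Parameters
    ----------
    assembly:
        Name of a biological assembly defined in the file (e.g. ``"1"``).
        When given, the file's transformation operators are applied before
        extraction; otherwise coordinates are used as deposited.
    include_hetero:
        Include non-water hetero atoms in the atom cloud used by the
        hydrophobic-contrast descriptor.
    """
    path = Path(path)
    st = gemmi.read_structure(str(path))
    st.setup_entities()
    if assembly is not None:
        how = gemmi.HowToNameCopiedChain.AddNumber
        st.transform_to_assembly(assembly, how)
    st.remove_hydrogens()
    model = st[0]

    residues: list[Residue] = []
    elements: list[str] = []
    coords: list[list[float]] = []
    for chain in model:
        for res in chain:
            if res.name in _WATER_NAMES:
                continue
            one = THREE_TO_ONE.get(res.name)
            if one is None:
                if include_hetero:
                    for atom in res:
                        elements.append(atom.element.name.upper())
                        coords.append(atom.pos.tolist())
                continue  # modified / nonstandard residues are not enumerated
            atoms = {atom.name: atom for atom in res}
            ca = atoms.get("CA")
            cb = atoms.get("CB")
            ca_pos = np.array(ca.pos.tolist()) if ca else None
            cb_pos = np.array(cb.pos.tolist()) if cb else None
            if cb_pos is None and ca_pos is not None:
                n, c = atoms.get("N"), atoms.get("C")
                if n is not None and c is not None:
                    warnings.warn(
                        f"residue {chain.name}:{res.seqid.num} ({res.name}) has no "
                        "C-beta; using an idealized C-beta from backbone geometry"
                    )
                    cb_pos = idealized_cb(
                        np.array(n.pos.tolist()), ca_pos, np.array(c.pos.tolist())
                    )
            residues.append(
                Residue(
                    chain=chain.name,
                    number=res.seqid.num,
                    icode=(res.seqid.icode or "").strip(),
                    res_type=one,
                    ca=ca_pos,
                    cb=cb_pos,
                )
            )
            for atom in res:
                elements.append(atom.element.name.upper())
                coords.append(atom.pos.tolist())

    resolution = st.resolution if st.resolution and st.resolution > 0 else None
    return ProteinStructure(
        id=st.name or path.stem,
        residues=residues,
        atom_elements=tuple(elements),
        atom_coords=np.array(coords, dtype=float).reshape(-1, 3),
        resolution=resolution,
    )


def write_pdb(structure: ProteinStructure, path: Union[str, Path]) -> None:
    """Serialize a :class:`ProteinStructure` to a minimal PDB file.

    Each residue is written with its C-alpha and (when present) C-beta atom;
    the loose atom cloud entries beyond those are emitted as single-atom UNK
    residues on chain X so the file round-trips through standard parsers.
    """
    st = gemmi.Structure()
    st.name = structure.id
    if structure.resolution is not None:
        st.resolution = structure.resolution
    model = gemmi.Model("1")
    chains: dict[str, gemmi.Chain] = {}

    n_res_atoms = 0
    for res in structure.residues:
        chain = chains.get(res.chain)
        if chain is None:
            chain = gemmi.Chain(res.chain)
            chains[res.chain] = chain
        gres = gemmi.Residue()
        gres.name = ONE_TO_THREE[res.res_type]
        gres.seqid = gemmi.SeqId(res.number, res.icode or " ")
        for name, pos in (("CA", res.ca), ("CB", res.cb)):
            if pos is None:
                continue
            atom = gemmi.Atom()
            atom.name = name
            atom.element = gemmi.Element("C")
            atom.pos = gemmi.Position(*map(float, pos))
            gres.add_atom(atom)
            n_res_atoms += 1
        chain.add_residue(gres)
    for chain in chains.values():
        model.add_chain(chain)

    extra_elements = structure.atom_elements[n_res_atoms:]
    extra_coords = structure.atom_coords[n_res_atoms:]
    if len(extra_elements):
        xchain = gemmi.Chain("X")
        for i, (element, pos) in enumerate(zip(extra_elements, extra_coords), start=1):
            gres = gemmi.Residue()
            gres.name = "UNK"
            gres.seqid = gemmi.SeqId(i, " ")
            gres.het_flag = "H"
            atom = gemmi.Atom()
            atom.name = element
            atom.element = gemmi.Element(element)
            atom.pos = gemmi.Position(*map(float, pos))
            gres.add_atom(atom)
            xchain.add_residue(gres)
        model.add_chain(xchain)

    st.add_model(model)
    st.setup_entities()
    doc_path = Path(path)
    st.write_pdb(str(doc_path))
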