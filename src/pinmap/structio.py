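"""Atomic structure containers and file I/O.

The object model is a thin chain -> residue -> atom hierarchy carrying the
per-residue confidence (pLDDT) that structure predictors store in the
B-factor column.  Reading and writing of PDB/mmCIF goes through gemmi;
predicted-aligned-error (PAE) matrices are read from the JSON layout used
by the AlphaFold database.

Conventions
-----------
* Coordinates are in Angstrom throughout.
* Residue numbering is author numbering; it is never renumbered.
* On read, only the highest-occupancy alternate location of each atom is
  kept (ties broken by altloc character), since predicted models carry no
  altlocs and experimental references may.
* Hydrogens are retained on read but excluded from geometry by default.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np

__all__ = [
    "Atom",
    "Residue",
    "Chain",
    "StructureModel",
    "PAEMatrix",
    "SelectionSpec",
    "AtomKey",
    "ParseError",
    "read_structure",
    "write_structure",
    "read_pae_json",
    "select",
    "equivalent_atom_map",
]

#: Elements treated as hydrogen for heavy-atom filtering.
_HYDROGEN = {"H", "D"}

# Element symbols accepted without a radius override (bio-organic subset
# plus common ions seen in deposited models).
_KNOWN_ELEMENTS = {
    "H", "D", "C", "N", "O", "S", "P", "SE",
    "F", "CL", "BR", "I", "NA", "MG", "K", "CA", "ZN", "FE", "MN", "CU",
}


class ParseError(ValueError):
    """Raised when a coordinate or PAE file cannot be parsed."""


@dataclass
class Atom:
    """A single atom with its author metadata.

    ``bfactor`` carries the per-residue pLDDT when the model comes from a
    structure predictor.
    """

    name: str
    element: str
    coords: np.ndarray
    bfactor: float = 0.0
    altloc: str = ""
    occupancy: float = 1.0

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.name!r}: coordinates must be a finite 3-vector")
        self.element = self.element.upper().strip()
        if self.element not in _KNOWN_ELEMENTS:
            raise ValueError(f"atom {self.name!r}: unrecognized element {self.element!r}")
        if self.bfactor < 0:
            raise ValueError(f"atom {self.name!r}: negative B-factor")

    @property
    def is_hydrogen(self) -> bool:
        return self.element in _HYDROGEN

    def copy(self) -> "Atom":
        return replace(self, coords=self.coords.copy())


@dataclass
class Residue:
    res_name: str
    res_seq: int
    icode: str = ""
    atoms: list[Atom] = field(default_factory=list)

    @property
    def plddt(self) -> float | None:
        """Per-residue confidence: the CA B-factor (predictor convention),
        falling back to the mean atom B-factor for CA-less residues."""
        for atom in self.atoms:
            if atom.name == "CA" and not atom.is_hydrogen:
                return float(atom.bfactor)
        if not self.atoms:
            return None
        return float(np.mean([a.bfactor for a in self.atoms]))

    @property
    def id(self) -> tuple[int, str]:
        return (self.res_seq, self.icode)

    def get_atom(self, name: str) -> Atom | None:
        for atom in self.atoms:
            if atom.name == name:
                return atom
        return None

    def copy(self) -> "Residue":
        return Residue(self.res_name, self.res_seq, self.icode,
                       [a.copy() for a in self.atoms])


@dataclass
class Chain:
    chain_id: str
    residues: list[Residue] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [r.id for r in self.residues]
        if len(ids) != len(set(ids)):
            raise ValueError(f"chain {self.chain_id!r}: duplicate residue ids")

    def get_residue(self, res_seq: int, icode: str = "") -> Residue | None:
        for res in self.residues:
            if res.res_seq == res_seq and res.icode == icode:
                return res
        return None

    def copy(self) -> "Chain":
        return Chain(self.chain_id, [r.copy() for r in self.residues])


@dataclass
class StructureModel:
    model_id: str
    chains: list[Chain] = field(default_factory=list)
    source: str = "synthetic"

    def __post_init__(self) -> None:
        ids = [c.chain_id for c in self.chains]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate chain ids")

    def get_chain(self, chain_id: str) -> Chain | None:
        for chain in self.chains:
            if chain.chain_id == chain_id:
                return chain
        return None

    def iter_residues(self) -> Iterator[tuple[Chain, Residue]]:
        for chain in self.chains:
            for res in chain.residues:
                yield chain, res

    def iter_atoms(self) -> Iterator[tuple[Chain, Residue, Atom]]:
        for chain, res in self.iter_residues():
            for atom in res.atoms:
                yield chain, res, atom

    @property
    def n_residues(self) -> int:
        return sum(len(c.residues) for c in self.chains)

    @property
    def n_atoms(self) -> int:
        return sum(len(r.atoms) for _, r in self.iter_residues())

    def residue_index(self) -> list[tuple[str, int]]:
        """(chain_id, res_seq) for every residue in model order; this is the
        index convention used by :class:`PAEMatrix`."""
        return [(c.chain_id, r.res_seq) for c, r in self.iter_residues()]

    def coords(self, heavy_only: bool = True) -> np.ndarray:
        pts = [a.coords for _, _, a in self.iter_atoms()
               if not (heavy_only and a.is_hydrogen)]
        return np.array(pts, dtype=float).reshape(-1, 3)

    def copy(self) -> "StructureModel":
        return StructureModel(self.model_id, [c.copy() for c in self.chains],
                              self.source)


@dataclass
class PAEMatrix:
    """Square predicted-aligned-error matrix (Angstrom), indexed by the
    residue order of the model it belongs to."""

    values: np.ndarray
    residue_index: list[tuple[str, int]]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ParseError(f"PAE matrix must be square, got shape {self.values.shape}")
        if np.any(self.values < 0):
            raise ParseError("PAE matrix contains negative entries")
        if len(self.residue_index) != self.values.shape[0]:
            raise ParseError(
                f"residue index length {len(self.residue_index)} does not match "
                f"matrix dimension {self.values.shape[0]}")

    @property
    def n(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class SelectionSpec:
    """Declarative atom selection.

    ``chain_id`` accepts a single id or a sequence of ids (a molecule made
    of several chains, e.g. both chains of a homodimer).  ``res_range`` is
    an inclusive [start, end] in author numbering.
    """

    chain_id: str | tuple[str, ...] | None = None
    res_range: tuple[int, int] | None = None
    atom_names: frozenset[str] | None = None
    heavy_only: bool = False

    def __post_init__(self) -> None:
        if isinstance(self.chain_id, (list, tuple, set)):
            object.__setattr__(self, "chain_id", tuple(sorted(self.chain_id)))
        if self.atom_names is not None:
            object.__setattr__(self, "atom_names", frozenset(self.atom_names))
        if self.res_range is not None:
            start, end = self.res_range
            if start > end:
                raise ValueError(f"res_range start {start} > end {end}")
            object.__setattr__(self, "res_range", (int(start), int(end)))

    @property
    def chain_ids(self) -> tuple[str, ...] | None:
        if self.chain_id is None:
            return None
        if isinstance(self.chain_id, str):
            return (self.chain_id,)
        return self.chain_id

    def matches_chain(self, chain_id: str) -> bool:
        return self.chain_ids is None or chain_id in self.chain_ids

    def matches_residue(self, res: Residue) -> bool:
        if self.res_range is not None:
            lo, hi = self.res_range
            if not lo <= res.res_seq <= hi:
                return False
        return True

    def matches_atom(self, atom: Atom) -> bool:
        if self.heavy_only and atom.is_hydrogen:
            return False
        if self.atom_names is not None and atom.name not in self.atom_names:
            return False
        return True


#: Hashable reference to an atom inside a model.
AtomKey = tuple[str, int, str, str]  # (chain_id, res_seq, icode, atom_name)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def _gemmi_to_model(st, source: str) -> StructureModel:
    import gemmi

    if len(st) == 0:
        raise ParseError(f"{source}: file contains no models")
    gm = st[0]
    chains: list[Chain] = []
    for gchain in gm:
        residues: list[Residue] = []
        for gres in gchain:
            # keep the dominant altloc per atom name
            best: dict[str, object] = {}
            for gatom in gres:
                key = gatom.name
                prev = best.get(key)
                if prev is None:
                    best[key] = gatom
                else:
                    if (gatom.occ, _altloc_rank(gatom.altloc)) > \
                            (prev.occ, _altloc_rank(prev.altloc)):
                        best[key] = gatom
            atoms = []
            for gatom in gres:  # preserve file order
                if best.get(gatom.name) is not gatom:
                    continue
                atoms.append(Atom(
                    name=gatom.name,
                    element=gatom.element.name,
                    coords=np.array([gatom.pos.x, gatom.pos.y, gatom.pos.z]),
                    bfactor=max(float(gatom.b_iso), 0.0),
                    altloc=(gatom.altloc or "").strip("\x00"),
                    occupancy=float(gatom.occ),
                ))
            residues.append(Residue(
                res_name=gres.name,
                res_seq=int(gres.seqid.num),
                icode=(gres.seqid.icode or "").strip(),
                atoms=atoms,
            ))
        if residues:
            chains.append(Chain(gchain.name, residues))
    if not chains:
        raise ParseError(f"{source}: no atoms found")
    model_id = st.name or Path(source).stem
    return StructureModel(model_id=model_id, chains=chains, source=source)


def _altloc_rank(altloc: str) -> int:
    # empty altloc preferred on ties, then alphabetical order ('A' beats 'B')
    a = (altloc or "").strip("\x00").strip()
    if not a:
        return 1000
    return 255 - ord(a)


def read_structure(path: str | Path, dialect: str = "auto") -> StructureModel:
    """Read a PDB or mmCIF file into a :class:`StructureModel`.

    Per-residue pLDDT is available afterwards through ``Residue.plddt``
    (the CA B-factor, as predictors write it).
    """
    import gemmi

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect not in ("pdb", "mmcif", "auto"):
        raise ValueError(f"unknown dialect {dialect!r}; expected pdb, mmcif or auto")
    if dialect == "auto":
        dialect = "mmcif" if path.suffix.lower() in (".cif", ".mmcif") else "pdb"
    try:
        if dialect == "pdb":
            st = gemmi.read_pdb(str(path))
        else:
            doc = gemmi.cif.read(str(path))
            st = gemmi.make_structure_from_block(doc.sole_block())
    except (RuntimeError, ValueError) as exc:
        raise ParseError(f"{path}: {exc}") from exc
    st.setup_entities()
    return _gemmi_to_model(st, str(path))


# PDB fixed columns: coordinates are %8.3f, serial %5d, resSeq %4d
_PDB_COORD_MAX = 9999.999
_PDB_COORD_MIN = -999.999
_PDB_RESSEQ_MAX = 9999


def write_structure(model: StructureModel, path: str | Path,
                    dialect: str = "pdb") -> None:
    """Write a model as fixed-column PDB (the only supported output dialect)."""
    import gemmi

    if dialect != "pdb":
        raise ValueError(f"unsupported output dialect {dialect!r}")
    if not model.chains or any(not c.residues for c in model.chains):
        raise ValueError("cannot write a model with an empty chain")
    for chain, res, atom in model.iter_atoms():
        if res.res_seq > _PDB_RESSEQ_MAX or res.res_seq < -999:
            raise ValueError(
                f"residue number {res.res_seq} does not fit PDB columns")
        if np.any(atom.coords > _PDB_COORD_MAX) or np.any(atom.coords < _PDB_COORD_MIN):
            raise ValueError(
                f"coordinate overflow of PDB columns for atom {atom.name!r} "
                f"in {chain.chain_id}/{res.res_seq}")

    st = gemmi.Structure()
    st.name = model.model_id
    gm = gemmi.Model("1")
    for chain in model.chains:
        gchain = gemmi.Chain(chain.chain_id)
        for res in chain.residues:
            gres = gemmi.Residue()
            gres.name = res.res_name
            gres.seqid = gemmi.SeqId(res.res_seq, res.icode or " ")
            for atom in res.atoms:
                gatom = gemmi.Atom()
                gatom.name = atom.name
                gatom.element = gemmi.Element(atom.element.capitalize())
                gatom.pos = gemmi.Position(*atom.coords)
                gatom.b_iso = atom.bfactor
                gatom.occ = atom.occupancy
                if atom.altloc:
                    gatom.altloc = atom.altloc
                gres.add_atom(gatom)
            gchain.add_residue(gres)
        gm.add_chain(gchain)
    st.add_model(gm)
    st.setup_entities()
    doc_path = str(Path(path))
    st.write_pdb(doc_path)


def read_pae_json(path: str | Path, model: StructureModel | None = None) -> PAEMatrix:
    """Read an AlphaFold-style PAE JSON file.

    The file must hold a square matrix under ``predicted_aligned_error``
    (either at top level or inside a one-element list, the two layouts the
    AlphaFold database has used).  If ``model`` is given, its residue order
    labels the matrix axes; the residue count must then match the matrix
    dimension.
    """
    path = Path(path)
    with open(path) as fh:
        data = json.load(fh)
    if isinstance(data, list):
        if not data:
            raise ParseError(f"{path}: empty JSON list")
        data = data[0]
    if not isinstance(data, dict) or "predicted_aligned_error" not in data:
        raise ParseError(f"{path}: missing 'predicted_aligned_error' key")
    raw = data["predicted_aligned_error"]
    try:
        values = np.asarray(raw, dtype=float)
    except (TypeError, ValueError) as exc:
        raise ParseError(f"{path}: non-numeric PAE entries") from exc
    if values.ndim != 2 or values.shape[0] != values.shape[1]:
        raise ParseError(f"{path}: PAE matrix is not square (shape {values.shape})")
    if model is not None:
        index = model.residue_index()
        if len(index) != values.shape[0]:
            raise ParseError(
                f"{path}: PAE dimension {values.shape[0]} does not match model "
                f"residue count {len(index)}")
    else:
        index = [("", i + 1) for i in range(values.shape[0])]
    return PAEMatrix(values=values, residue_index=index)


def write_pae_json(pae: PAEMatrix, path: str | Path) -> None:
    """Write a PAE matrix in the AlphaFold database JSON layout."""
    payload = [{
        "predicted_aligned_error": [[round(float(v), 2) for v in row]
                                    for row in pae.values],
        "max_predicted_aligned_error": round(float(pae.values.max()), 2)
        if pae.n else 0.0,
    }]
    with open(path, "w") as fh:
        json.dump(payload, fh)


# ---------------------------------------------------------------------------
# Selection and atom pairing
# ---------------------------------------------------------------------------

def select(model: StructureModel, spec: SelectionSpec) -> StructureModel:
    """Project a model onto the sub-model matching ``spec``.

    Selection is a projection: applying the same spec twice gives the same
    result.  Empty selections are allowed and yield a model with no chains.
    """
    chains: list[Chain] = []
    for chain in model.chains:
        if not spec.matches_chain(chain.chain_id):
            continue
        residues: list[Residue] = []
        for res in chain.residues:
            if not spec.matches_residue(res):
                continue
            atoms = [a.copy() for a in res.atoms if spec.matches_atom(a)]
            if atoms:
                residues.append(Residue(res.res_name, res.res_seq, res.icode, atoms))
        if residues:
            chains.append(Chain(chain.chain_id, residues))
    return StructureModel(model.model_id, chains, model.source)


def equivalent_atom_map(
    a: StructureModel,
    b: StructureModel,
    heavy_only: bool = True,
) -> list[tuple[AtomKey, Atom, Atom]]:
    """Pair atoms of two models matched on (chain, residue, icode, atom name).

    Unmatched atoms are dropped; the pairing is symmetric in its arguments.
    Raises ``ValueError`` when no atom can be paired.
    """
    def atom_table(model: StructureModel) -> dict[AtomKey, Atom]:
        table: dict[AtomKey, Atom] = {}
        for chain, res, atom in model.iter_atoms():
            if heavy_only and atom.is_hydrogen:
                continue
            table[(chain.chain_id, res.res_seq, res.icode, atom.name)] = atom
        return table

    table_a = atom_table(a)
    table_b = atom_table(b)
    pairs = [(key, table_a[key], table_b[key])
             for key in table_a if key in table_b]
    if not pairs:
        raise ValueError("no equivalent atoms between the two models")
    pairs.sort(key=lambda p: p[0])
    return pairs
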