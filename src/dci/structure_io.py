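"""Structure I/O: PDB text to a coarse-grained C-alpha model and back.

The elastic network models in this package operate on one coordinate per
residue (the C-alpha atom).  :func:`parse_structure` reduces a PDB file to
that representation; :func:`write_labeled_structure` writes community
assignments back onto the original file as B-factors so any molecular viewer
can colour them; :func:`write_trajectory` emits mode-displaced conformers as
a multi-model PDB.

Parsing is delegated to :mod:`gemmi`.  Policy decisions live here:

* HETATM records (ligands, ions, waters) are excluded by default — bound
  cofactors are not part of the protein elastic network — with an explicit
  include-list for modified residues such as MSE that should be treated as
  part of the chain.
* For alternate locations the highest-occupancy conformer wins; occupancy
  ties prefer altloc ``A``, then file order.
* Multi-model files contribute only their first MODEL: the network model
  takes a single equilibrium structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Collection, Mapping, Sequence

import gemmi
import numpy as np

from .errors import EmptySelectionError, ParseError

__all__ = [
    "ResidueKey",
    "CalphaModel",
    "parse_structure",
    "write_labeled_structure",
    "write_trajectory",
    "assignments_table",
    "parse_assignments",
]


@dataclass(frozen=True, order=True)
class ResidueKey:
    """Identity of a residue within a structure: chain, number, insertion code."""

    chain_id: str
    residue_number: int
    insertion_code: str = ""

    def __str__(self) -> str:
        return f"{self.chain_id}/{self.residue_number}{self.insertion_code}"


@dataclass
class CalphaModel:
    """Ordered C-alpha point model of a structure.

    ``residues[i]`` identifies the residue whose C-alpha sits at
    ``coordinates[i]`` (angstroms).  Order follows the source file.
    """

    residues: list[ResidueKey]
    coordinates: np.ndarray  # (N, 3) float64, angstroms
    source_id: str = ""
    _index: dict[ResidueKey, int] = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] != 3:
            raise ValueError("coordinates must be an (N, 3) array")
        if len(self.residues) != len(self.coordinates):
            raise ValueError("one coordinate triple per residue required")
        if len(set(self.residues)) != len(self.residues):
            raise ValueError("residue keys must be unique")
        self._index = {key: i for i, key in enumerate(self.residues)}

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def n_residues(self) -> int:
        return len(self.residues)

    def index_of(self, key: ResidueKey) -> int:
        return self._index[key]

    def __contains__(self, key: ResidueKey) -> bool:
        return key in self._index


def _icode(res: gemmi.Residue) -> str:
    icode = res.seqid.icode
    return "" if icode in (" ", "\x00") else icode


def _in_ranges(num: int, ranges: Sequence[tuple[int, int]]) -> bool:
    return any(lo <= num <= hi for lo, hi in ranges)


def _pick_calpha(res: gemmi.Residue) -> gemmi.Atom | None:
    """Select the C-alpha of a residue, resolving altlocs by occupancy."""
    candidates = [
        (idx, atom)
        for idx, atom in enumerate(res)
        if atom.name == "CA" and atom.element.name == "C"
    ]
    if not candidates:
        return None
    # highest occupancy; ties prefer altloc 'A', then file order
    def rank(item):
        idx, atom = item
        return (-atom.occ, 0 if atom.altloc == "A" else 1, idx)

    return min(candidates, key=rank)[1]


def _validate_coordinate_fields(pdb_text: str) -> None:
    """Reject ATOM/HETATM lines whose fixed-column coordinates are not numbers.

    The underlying reader silently zero-fills unparseable fields; corrupt
    input should fail loudly instead, naming the line.
    """
    for lineno, line in enumerate(pdb_text.splitlines(), start=1):
        if not line.startswith(("ATOM  ", "HETATM")):
            continue
        for lo, hi in ((30, 38), (38, 46), (46, 54)):
            text = line[lo:hi].strip()
            try:
                float(text)
            except ValueError:
                raise ParseError(
                    f"line {lineno}: malformed coordinate field {text!r}"
                ) from None


def parse_structure(
    pdb_text: str,
    *,
    chains: Collection[str] | None = None,
    residue_ranges: Mapping[str, Sequence[tuple[int, int]]] | None = None,
    hetatm_include: Collection[str] = (),
    source_id: str = "structure",
) -> CalphaModel:
    """Read PDB text into a :class:`CalphaModel`.

    Parameters
    ----------
    pdb_text:
        Contents of a PDB file.
    chains:
        Chain identifiers to keep; ``None`` keeps all chains.
    residue_ranges:
        Optional per-chain list of inclusive ``(start, end)`` residue-number
        ranges; chains absent from the mapping keep all residues.
    hetatm_include:
        Residue names from HETATM records to retain (e.g. ``{"MSE"}``).
        Everything else recorded as HETATM — ligands, ions, waters — is
        dropped.
    source_id:
        Label stored on the model (used in reports).

    Raises
    ------
    ParseError
        If the text cannot be parsed as PDB.
    EmptySelectionError
        If no residue with a C-alpha atom survives the filters.
    """
    _validate_coordinate_fields(pdb_text)
    try:
        structure = gemmi.read_pdb_string(pdb_text)
    except (RuntimeError, ValueError) as exc:
        raise ParseError(f"could not parse PDB text: {exc}") from exc
    if len(structure) == 0:
        raise EmptySelectionError("no models in input")

    include = {name.upper() for name in hetatm_include}
    wanted_chains = set(chains) if chains is not None else None

    residues: list[ResidueKey] = []
    coords: list[tuple[float, float, float]] = []
    model = structure[0]  # first MODEL only
    for chain in model:
        if wanted_chains is not None and chain.name not in wanted_chains:
            continue
        ranges = residue_ranges.get(chain.name) if residue_ranges else None
        for res in chain:
            if res.is_water():
                continue
            if res.het_flag == "H" and res.name.upper() not in include:
                continue
            if ranges is not None and not _in_ranges(res.seqid.num, ranges):
                continue
            atom = _pick_calpha(res)
            if atom is None:
                continue
            key = ResidueKey(chain.name, res.seqid.num, _icode(res))
            residues.append(key)
            coords.append((atom.pos.x, atom.pos.y, atom.pos.z))

    if not residues:
        raise EmptySelectionError(
            "empty selection: no C-alpha atoms remain after filtering"
        )
    return CalphaModel(residues, np.array(coords, dtype=float), source_id=source_id)


def write_labeled_structure(
    model: CalphaModel,
    labels: Sequence[int],
    original_pdb_text: str,
) -> str:
    """Return PDB text with community indices written into the B-factor column.

    Every atom of residue ``i`` in ``model`` gets B-factor equal to its
    (1-based) community index; atoms of residues outside the model get 0.00.
    """
    labels = list(labels)
    if len(labels) != len(model):
        raise ValueError(
            f"labels length {len(labels)} does not match model size {len(model)}"
        )
    label_of = {key: float(lab) for key, lab in zip(model.residues, labels)}

    try:
        structure = gemmi.read_pdb_string(original_pdb_text)
    except (RuntimeError, ValueError) as exc:
        raise ParseError(f"could not parse PDB text: {exc}") from exc
    for mdl in structure:
        for chain in mdl:
            for res in chain:
                key = ResidueKey(chain.name, res.seqid.num, _icode(res))
                b = label_of.get(key, 0.0)
                for atom in res:
                    atom.b_iso = b
    return structure.make_pdb_string()


def write_trajectory(
    frames: Sequence[np.ndarray],
    model: CalphaModel,
) -> str:
    """Write coordinate frames as a multi-model, C-alpha-only PDB.

    One MODEL/ENDMDL block per frame, in order.  Residue identities come from
    ``model``; each residue is emitted as a single CA atom (residue name ALA,
    a placeholder — the coarse-grained model carries no sequence).
    """
    if len(frames) == 0:
        raise ValueError("empty frame list")
    n = len(model)
    arrays = []
    for k, frame in enumerate(frames):
        arr = np.asarray(frame, dtype=float)
        if arr.shape != (n, 3):
            raise ValueError(f"frame {k} has shape {arr.shape}, expected {(n, 3)}")
        arrays.append(arr)

    structure = gemmi.Structure()
    structure.name = model.source_id or "trajectory"
    for k, arr in enumerate(arrays):
        mdl = gemmi.Model(k + 1)
        chain = None
        for i, key in enumerate(model.residues):
            if chain is None or chain.name != key.chain_id:
                chain = gemmi.Chain(key.chain_id)
                mdl.add_chain(chain)
                chain = mdl[-1]
            res = gemmi.Residue()
            res.name = "ALA"
            res.seqid = gemmi.SeqId(key.residue_number, key.insertion_code or " ")
            atom = gemmi.Atom()
            atom.name = "CA"
            atom.element = gemmi.Element("C")
            atom.occ = 1.0
            atom.b_iso = 0.0
            atom.pos = gemmi.Position(*arr[i])
            res.add_atom(atom)
            chain.add_residue(res)
        structure.add_model(mdl)
    structure.setup_entities()
    return structure.make_pdb_string()


def assignments_table(model: CalphaModel, labels: Sequence[int]) -> str:
    """Tab-separated community assignment table (chain, resnum, icode, community)."""
    if len(labels) != len(model):
        raise ValueError("labels length does not match model size")
    lines = ["chain\tresnum\ticode\tcommunity"]
    for key, lab in zip(model.residues, labels):
        lines.append(
            f"{key.chain_id}\t{key.residue_number}\t{key.insertion_code}\t{int(lab)}"
        )
    return "\n".join(lines) + "\n"


def parse_assignments(text: str) -> tuple[list[ResidueKey], list[int]]:
    """Inverse of :func:`assignments_table`."""
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines or lines[0].split("\t")[:4] != ["chain", "resnum", "icode", "community"]:
        raise ParseError("assignment table must start with its header line")
    keys: list[ResidueKey] = []
    labels: list[int] = []
    for lineno, line in enumerate(lines[1:], start=2):
        parts = line.split("\t")
        if len(parts) < 4:
            raise ParseError(f"assignment table line {lineno}: expected 4 columns")
        try:
            keys.append(ResidueKey(parts[0], int(parts[1]), parts[2].strip()))
            labels.append(int(parts[3]))
        except ValueError as exc:
            raise ParseError(f"assignment table line {lineno}: {exc}") from exc
    return keys, labels
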