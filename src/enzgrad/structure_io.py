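"""Reading protein structures and catalytic-site annotations.

Structures are read from PDB-format text (biological assembly or a single
chain).  The unit of analysis is the residue, represented by the geometric
center of its side-chain atoms; glycine, and any residue whose side-chain
atoms are missing from the coordinate record, falls back to the C-alpha
position.  Biological-assembly files that encode symmetry copies as multiple
MODEL records are flattened into one model whose duplicated chains receive
suffixed identifiers ("A", "A-2", ...), so that packing and distance metrics
see every subunit copy.
"""

from __future__ import annotations

import io
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from Bio.PDB import PDBParser
from Bio.PDB.Atom import DisorderedAtom
from Bio.PDB.PDBExceptions import PDBConstructionWarning

from .exceptions import (
    AnnotationError,
    CenterError,
    ChainNotFoundError,
    StructureParseError,
)

logger = logging.getLogger(__name__)

#: Backbone atom names excluded from the side-chain geometric center.
BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O", "OXT"})

#: The 20 standard three-letter amino-acid codes.
STANDARD_AA = (
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
)
_STANDARD_SET = frozenset(STANDARD_AA)

#: Nonstandard residues mapped onto a standard parent (selenomethionine).
NONSTANDARD_MAP = {"MSE": "MET"}


@dataclass(frozen=True)
class Atom:
    name: str
    element: str
    coord: np.ndarray  # (3,) in Angstrom

    def __post_init__(self) -> None:
        object.__setattr__(self, "coord", np.asarray(self.coord, dtype=float))


@dataclass
class Residue:
    """One amino-acid residue with its atoms and derived center."""

    chain_id: str
    residue_number: int
    insertion: str  # "" when absent
    residue_type: str  # 3-letter code, post nonstandard mapping
    atoms: list[Atom]

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.residue_number, self.insertion)

    @property
    def center(self) -> np.ndarray:
        return residue_center(self)


@dataclass
class StructureModel:
    """An ordered collection of residues from one PDB entry."""

    pdb_id: str
    residues: list[Residue]
    provenance: str  # "assembly" | "single_chain"
    chains: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not self.chains:
            self.chains = {r.chain_id for r in self.residues}
        keys = [r.key for r in self.residues]
        if len(set(keys)) != len(keys):
            raise StructureParseError(
                f"{self.pdb_id}: duplicate residue keys after parsing"
            )

    def __len__(self) -> int:
        return len(self.residues)

    def centers(self) -> np.ndarray:
        """(n, 3) array of side-chain geometric centers, in file order."""
        return np.array([r.center for r in self.residues])

    def index_of(self, chain_id: str, residue_number: int, insertion: str = "") -> int:
        for i, r in enumerate(self.residues):
            if r.key == (chain_id, residue_number, insertion):
                return i
        raise KeyError((chain_id, residue_number, insertion))


@dataclass(frozen=True)
class CatalyticAnnotation:
    """Catalytic residues as a set of (chain_id, residue_number) pairs."""

    sites: frozenset[tuple[str, int]]

    def __len__(self) -> int:
        return len(self.sites)

    def indices_in(self, structure: StructureModel) -> list[int]:
        """Row indices of annotated residues, in structure order."""
        return [
            i
            for i, r in enumerate(structure.residues)
            if (r.chain_id, r.residue_number) in self.sites
        ]


def residue_center(residue: Residue) -> np.ndarray:
    """Geometric (unweighted mean) center of the side-chain atoms, in Angstrom.

    Glycine has no side chain and uses its C-alpha; the same fallback applies
    to any residue whose side-chain atoms are all absent from the coordinate
    record (a disordered side chain), which is logged rather than dropped.
    Hydrogens and backbone atoms (N, CA, C, O, OXT) are never part of the
    center.
    """
    if not residue.atoms:
        raise CenterError(f"residue {residue.key} has no atoms")
    side = [
        a.coord
        for a in residue.atoms
        if a.name not in BACKBONE_ATOMS and a.element not in ("H", "D")
    ]
    if side:
        return np.mean(side, axis=0)
    for a in residue.atoms:
        if a.name == "CA":
            if residue.residue_type != "GLY":
                logger.info(
                    "residue %s (%s): no side-chain atoms, using C-alpha",
                    residue.key,
                    residue.residue_type,
                )
            return np.asarray(a.coord, dtype=float)
    raise CenterError(
        f"residue {residue.key} has neither side-chain atoms nor a C-alpha"
    )


def _pick_altloc(atom):
    """Resolve a possibly disordered atom to its highest-occupancy conformer.

    Ties keep the conformer listed first in the file.
    """
    if isinstance(atom, DisorderedAtom):
        children = atom.disordered_get_list()
        best = max(children, key=lambda a: (a.get_occupancy() or 0.0))
        # max() keeps the first of tied occupancies because it is stable
        # over the insertion-ordered child list.
        return best
    return atom


def parse_structure(
    pdb_text: str,
    mode: str = "assembly",
    chain: str | None = None,
    pdb_id: str = "",
) -> StructureModel:
    """Parse PDB-format text into a :class:`StructureModel`.

    Parameters
    ----------
    pdb_text:
        Contents of a PDB file.  Multi-MODEL biological assemblies are
        concatenated into one model; chains repeated across MODELs receive
        suffixed ids ("A", "A-2", ...).
    mode:
        ``"assembly"`` keeps every chain of every MODEL; ``"single_chain"``
        keeps only `chain` from the first MODEL.
    chain:
        Chain id, required when ``mode="single_chain"``.

    Only standard amino acids are kept (selenomethionine is mapped to MET);
    waters, ligands and other HETATM records are excluded, and alternate
    locations are resolved to the highest-occupancy conformer.
    """
    if mode not in ("assembly", "single_chain"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "single_chain" and not chain:
        raise ValueError("single_chain mode requires a chain id")
    if "ATOM" not in pdb_text and "HETATM" not in pdb_text:
        raise StructureParseError("no ATOM records in input")

    parser = PDBParser(QUIET=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", PDBConstructionWarning)
        bio_structure = parser.get_structure(pdb_id or "structure", io.StringIO(pdb_text))

    models = list(bio_structure)
    if not models:
        raise StructureParseError("no models parsed from input")

    residues: list[Residue] = []
    seen_chain_ids: set[str] = set()
    for m_index, model in enumerate(models):
        for bio_chain in model:
            base_id = bio_chain.id
            chain_id = base_id if m_index == 0 else f"{base_id}-{m_index + 1}"
            if mode == "single_chain":
                if m_index > 0:
                    continue
                if base_id != chain:
                    continue
            for bio_res in bio_chain:
                hetflag, resseq, icode = bio_res.get_id()
                resname = bio_res.get_resname().strip()
                is_het = hetflag.strip() != ""
                if resname in NONSTANDARD_MAP:
                    resname = NONSTANDARD_MAP[resname]
                elif is_het:
                    continue  # waters, ligands
                elif resname not in _STANDARD_SET:
                    logger.warning(
                        "excluding nonstandard residue %s %s%s", resname, base_id, resseq
                    )
                    continue
                atoms = [
                    Atom(
                        name=a.get_name(),
                        element=(a.element or "").upper(),
                        coord=a.get_coord(),
                    )
                    for a in (_pick_altloc(raw) for raw in bio_res)
                ]
                if not atoms:
                    continue
                residues.append(
                    Residue(
                        chain_id=chain_id,
                        residue_number=int(resseq),
                        insertion=icode.strip(),
                        residue_type=resname,
                        atoms=atoms,
                    )
                )
                seen_chain_ids.add(chain_id)

    if mode == "single_chain" and not residues:
        raise ChainNotFoundError(f"chain {chain!r} not found in structure")
    if not residues:
        raise StructureParseError("no standard amino-acid residues in input")

    provenance = "assembly" if mode == "assembly" else "single_chain"
    return StructureModel(
        pdb_id=pdb_id, residues=residues, provenance=provenance, chains=seen_chain_ids
    )


def _base_chain(chain_id: str) -> str:
    """Chain id with any MODEL-copy suffix ("A-2" -> "A") removed."""
    base, dash, suffix = chain_id.rpartition("-")
    if dash and suffix.isdigit():
        return base
    return chain_id


def load_catalytic_annotation(
    table_text: str, structure: StructureModel
) -> CatalyticAnnotation:
    """Load catalytic residues from CSV text with header ``pdb_id,chain,residue_number``.

    The ``pdb_id`` column is optional.  In assembly mode an annotation on one
    chain is propagated to every symmetry copy of that chain (ids sharing the
    same base, e.g. "A" and "A-2").  Every row must resolve to at least one
    residue of `structure`; unresolvable rows raise :class:`AnnotationError`
    listing the offenders.
    """
    lines = [ln.strip() for ln in table_text.strip().splitlines() if ln.strip()]
    if not lines:
        raise AnnotationError("empty annotation table")
    header = [h.strip().lower() for h in lines[0].split(",")]
    try:
        chain_col = header.index("chain")
        num_col = header.index("residue_number")
    except ValueError as exc:
        raise AnnotationError(
            f"annotation header must contain 'chain' and 'residue_number', got {header}"
        ) from exc

    rows: list[tuple[str, int]] = []
    for ln in lines[1:]:
        parts = [p.strip() for p in ln.split(",")]
        try:
            rows.append((parts[chain_col], int(parts[num_col])))
        except (IndexError, ValueError) as exc:
            raise AnnotationError(f"malformed annotation row: {ln!r}") from exc
    if not rows:
        raise AnnotationError("annotation table has a header but no rows")

    present = {(r.chain_id, r.residue_number) for r in structure.residues}
    sites: set[tuple[str, int]] = set()
    bad: list[tuple[str, int]] = []
    for chain_id, number in rows:
        copies = [
            c for c in structure.chains if _base_chain(c) == _base_chain(chain_id)
        ]
        resolved = [(c, number) for c in copies if (c, number) in present]
        if not resolved:
            bad.append((chain_id, number))
        sites.update(resolved)
    if bad:
        raise AnnotationError(f"annotation rows not found in structure: {bad}")
    return CatalyticAnnotation(sites=frozenset(sites))
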