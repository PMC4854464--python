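"""Per-residue structural metrics and the assembled site table.

For every residue of a structure this module computes:

* **WCN** (weighted contact number), the packing density
  ``WCN_i = sum_{j != i} 1 / r_ij**2`` over side-chain geometric centers
  (units 1/A^2) — high in the protein core;
* **ASA/RSA**, the solvent-accessible surface area from a Shrake–Rupley
  quadrature (probe 1.4 A) normalized by the residue type's maximum
  accessibility in an extended Gly-X-Gly tripeptide;
* **d**, the Euclidean distance to the nearest catalytic residue
  (catalytic residues have d = 0 by definition);
* an **interface** flag: a residue whose RSA computed on the isolated chain
  exceeds its RSA in the full assembly by at least 0.10 sits in a
  subunit-subunit interface.

All metrics default to the full biological assembly; single-chain and
interface-excluded variants are explicit options.  Metrics are always
computed on the full selected coordinate set before any rows are dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import TYPE_CHECKING, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist, pdist, squareform

from .exceptions import MetricError
from .shell_analysis import assign_shell
from .structure_io import CatalyticAnnotation, StructureModel

if TYPE_CHECKING:
    from .rates import RateVector

logger = logging.getLogger(__name__)

#: Maximum solvent accessibility (A^2) of residue X in an extended Gly-X-Gly
#: tripeptide; theoretical values of Tien et al. (2013).  User-overridable.
MAX_ASA_GLY_X_GLY: Mapping[str, float] = {
    "ALA": 129.0, "ARG": 274.0, "ASN": 195.0, "ASP": 193.0, "CYS": 167.0,
    "GLN": 225.0, "GLU": 223.0, "GLY": 104.0, "HIS": 224.0, "ILE": 197.0,
    "LEU": 201.0, "LYS": 236.0, "MET": 224.0, "PHE": 240.0, "PRO": 159.0,
    "SER": 155.0, "THR": 172.0, "TRP": 285.0, "TYR": 263.0, "VAL": 174.0,
}

#: Van der Waals radii (A) by element for the Shrake-Rupley quadrature.
VDW_RADII: Mapping[str, float] = {
    "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80,
    "SE": 1.90, "H": 1.20, "D": 1.20,
}
DEFAULT_VDW_RADIUS = 1.70

#: Default probe radius (water) and quadrature size.
PROBE_RADIUS = 1.4
N_SPHERE_POINTS = 960

#: Serialized site-table columns, names and order fixed.
SITE_TABLE_COLUMNS = [
    "protein_id", "chain", "residue_number", "residue_type",
    "K", "wcn", "asa", "rsa", "d", "shell", "is_catalytic", "is_interface",
]


def weighted_contact_number(centers: Sequence[np.ndarray] | np.ndarray) -> np.ndarray:
    """Packing density per site: sum over all other sites of 1/r^2 (1/A^2).

    A single-center input returns ``[0.0]`` with a warning; coincident
    centers are an error because the contact weight diverges.
    """
    pts = np.asarray(centers, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValueError("centers must be an (n, 3) array")
    if not np.all(np.isfinite(pts)):
        raise MetricError("non-finite center coordinates")
    n = len(pts)
    if n == 1:
        logger.warning("WCN of a single-residue structure is 0 by convention")
        return np.zeros(1)
    d2 = squareform(pdist(pts, metric="sqeuclidean"))
    off = ~np.eye(n, dtype=bool)
    if np.any(d2[off] == 0.0):
        i, j = np.argwhere((d2 == 0.0) & off)[0]
        raise MetricError(f"coincident centers at indices {i} and {j}")
    with np.errstate(divide="ignore"):
        inv = np.where(off, 1.0 / np.where(d2 == 0.0, np.inf, d2), 0.0)
    return inv.sum(axis=1)


def distance_to_catalytic(
    centers: Sequence[np.ndarray] | np.ndarray, catalytic_indices: Iterable[int]
) -> np.ndarray:
    """Distance (A) from each site to the nearest catalytic residue.

    Catalytic sites get exactly 0.
    """
    pts = np.asarray(centers, dtype=float)
    idx = sorted(set(int(i) for i in catalytic_indices))
    if not idx:
        raise MetricError("empty catalytic index set")
    if any(i < 0 or i >= len(pts) for i in idx):
        raise MetricError("catalytic index out of range")
    d = cdist(pts, pts[idx]).min(axis=1)
    d[idx] = 0.0
    return d


def sphere_points(n: int) -> np.ndarray:
    """Quasi-uniform unit-sphere points from a golden-angle Fibonacci lattice."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + np.sqrt(5.0)) * i
    return np.column_stack(
        [np.cos(theta) * np.sin(phi), np.sin(theta) * np.sin(phi), np.cos(phi)]
    )


def shrake_rupley_asa(
    spheres: Sequence[tuple[np.ndarray, float]],
    probe_radius: float = PROBE_RADIUS,
    n_points: int = N_SPHERE_POINTS,
) -> np.ndarray:
    """Accessible surface area (A^2) per sphere, Shrake-Rupley quadrature.

    Each sphere is expanded by the probe radius and covered with `n_points`
    quasi-uniform test points; a point counts as accessible iff it lies
    outside every other expanded sphere.  The area is the accessible
    fraction of the expanded-sphere surface.
    """
    if n_points < 92:
        raise ValueError("n_points must be >= 92 for a usable quadrature")
    centers = np.asarray([c for c, _ in spheres], dtype=float)
    radii = np.asarray([r for _, r in spheres], dtype=float)
    if np.any(radii <= 0):
        raise MetricError("non-positive sphere radius")
    expanded = radii + probe_radius
    n = len(centers)
    unit = sphere_points(n_points)
    areas = np.empty(n)
    tree = cKDTree(centers)
    r_max = expanded.max()
    for i in range(n):
        neighbors = [
            j
            for j in tree.query_ball_point(centers[i], expanded[i] + r_max)
            if j != i
            and np.linalg.norm(centers[j] - centers[i]) < expanded[i] + expanded[j]
        ]
        pts = centers[i] + expanded[i] * unit
        if neighbors:
            dist = cdist(pts, centers[neighbors])
            accessible = np.all(dist >= expanded[neighbors], axis=1)
            frac = accessible.mean()
        else:
            frac = 1.0
        areas[i] = 4.0 * np.pi * expanded[i] ** 2 * frac
    return areas


def residue_asa(
    structure: StructureModel,
    probe_radius: float = PROBE_RADIUS,
    n_points: int = N_SPHERE_POINTS,
    atom_radius: float | None = None,
    chain_subset: set[str] | None = None,
) -> np.ndarray:
    """Per-residue ASA (A^2): sum of atomic Shrake-Rupley areas.

    Heavy atoms only; `atom_radius` overrides the per-element van der Waals
    radius (used for single-pseudo-atom synthetic structures).  When
    `chain_subset` is given, only those chains contribute atoms (residues of
    other chains get NaN) — this is how isolated-chain ASA is computed for
    interface detection.
    """
    spheres: list[tuple[np.ndarray, float]] = []
    owner: list[int] = []
    for ri, res in enumerate(structure.residues):
        if chain_subset is not None and res.chain_id not in chain_subset:
            continue
        for atom in res.atoms:
            if atom.element in ("H", "D"):
                continue
            radius = (
                atom_radius
                if atom_radius is not None
                else VDW_RADII.get(atom.element, DEFAULT_VDW_RADIUS)
            )
            spheres.append((atom.coord, radius))
            owner.append(ri)
    if not spheres:
        raise MetricError("no heavy atoms to compute ASA from")
    areas = shrake_rupley_asa(spheres, probe_radius=probe_radius, n_points=n_points)
    out = np.full(len(structure.residues), np.nan)
    out_sum = np.zeros(len(structure.residues))
    np.add.at(out_sum, owner, areas)
    touched = np.zeros(len(structure.residues), dtype=bool)
    touched[owner] = True
    out[touched] = out_sum[touched]
    return out


def relative_solvent_accessibility(
    asa_per_residue: Sequence[float],
    residue_types: Sequence[str],
    max_asa: Mapping[str, float] | None = None,
    cross_chain_linked: Iterable[int] = (),
) -> np.ndarray:
    """RSA = ASA / max-ASA(residue type); cross-chain-linked residues get 0.

    Values above 1 are retained (the normalization is not a hard bound); the
    count of such sites is logged.
    """
    table = MAX_ASA_GLY_X_GLY if max_asa is None else max_asa
    asa = np.asarray(asa_per_residue, dtype=float)
    if len(asa) != len(residue_types):
        raise ValueError("asa and residue_types length mismatch")
    try:
        denom = np.array([table[t] for t in residue_types], dtype=float)
    except KeyError as exc:
        raise MetricError(f"no maximum ASA for residue type {exc.args[0]!r}") from exc
    rsa = asa / denom
    linked = sorted(set(int(i) for i in cross_chain_linked))
    if linked:
        rsa[linked] = 0.0
    n_over = int(np.sum(rsa > 1.0))
    if n_over:
        logger.info("%d residues have RSA > 1 (kept unclipped)", n_over)
    return rsa


def detect_interface(
    rsa_single_chain: Sequence[float],
    rsa_assembly: Sequence[float],
    threshold: float = 0.10,
    relative: bool = False,
) -> np.ndarray:
    """Flag residues whose RSA drops by >= `threshold` on assembly formation.

    The default reads the 10% criterion as an absolute RSA difference of
    0.10; ``relative=True`` instead requires the drop to be at least 10% of
    the isolated-chain RSA.
    """
    single = np.asarray(rsa_single_chain, dtype=float)
    assembly = np.asarray(rsa_assembly, dtype=float)
    if single.shape != assembly.shape:
        raise ValueError("RSA vectors must be aligned and of equal length")
    delta = single - assembly
    if relative:
        with np.errstate(divide="ignore", invalid="ignore"):
            frac = np.where(single > 0, delta / single, 0.0)
        return frac >= threshold
    return delta >= threshold


def find_cross_chain_links(
    structure: StructureModel, cutoff: float = 2.1
) -> set[int]:
    """Residue indices with a covalent-range heavy-atom contact across chains.

    Captures disulfide bridges and inter-chain peptide linkages, whose
    burial is chemical rather than solvent-driven; such residues are
    assigned RSA 0.
    """
    coords, chains, owner = [], [], []
    for ri, res in enumerate(structure.residues):
        for atom in res.atoms:
            if atom.element in ("H", "D"):
                continue
            coords.append(atom.coord)
            chains.append(res.chain_id)
            owner.append(ri)
    if not coords:
        return set()
    coords = np.asarray(coords)
    tree = cKDTree(coords)
    linked: set[int] = set()
    for a, b in tree.query_pairs(cutoff):
        if chains[a] != chains[b]:
            linked.add(owner[a])
            linked.add(owner[b])
    return linked


def read_dssp_acc(dssp_text: str) -> dict[tuple[str, int, str], float]:
    """Read the ACC column of a classic DSSP output file.

    Returns a mapping ``(chain, residue_number, insertion) -> ASA`` usable as
    `asa_override` in :func:`build_site_table`, for bit-comparable
    reproduction of analyses that used DSSP areas.
    """
    acc: dict[tuple[str, int, str], float] = {}
    in_body = False
    for line in dssp_text.splitlines():
        if line.startswith("  #  RESIDUE"):
            in_body = True
            continue
        if not in_body or len(line) < 38:
            continue
        if line[13] == "!":  # chain break
            continue
        try:
            resnum = int(line[5:10])
        except ValueError:
            continue
        icode = line[10].strip()
        chain = line[11].strip()
        acc[(chain, resnum, icode)] = float(line[34:38])
    if not acc:
        raise MetricError("no residue records found in DSSP text")
    return acc


@dataclass
class SiteTable:
    """Per-residue analysis table for one protein.

    ``df`` has the fixed :data:`SITE_TABLE_COLUMNS` (plus ``d_interface``
    when interfaces exist).  ``provenance`` records the coordinate set and
    interface handling used, e.g. ``("assembly", "interfaces_kept")``.
    """

    protein_id: str
    df: pd.DataFrame
    provenance: tuple[str, str]

    @property
    def n_sites(self) -> int:
        return len(self.df)

    def to_tsv(self, path) -> None:
        cols = SITE_TABLE_COLUMNS + (
            ["d_interface"] if "d_interface" in self.df.columns else []
        )
        self.df.to_csv(path, sep="\t", index=False, columns=cols, float_format="%.6g")

    @classmethod
    def from_tsv(cls, path, provenance: tuple[str, str] = ("assembly", "interfaces_kept")):
        df = pd.read_csv(path, sep="\t")
        missing = [c for c in SITE_TABLE_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"site table missing columns: {missing}")
        pid = str(df["protein_id"].iloc[0]) if len(df) else ""
        return cls(protein_id=pid, df=df, provenance=provenance)


def build_site_table(
    structure: StructureModel,
    annotation: CatalyticAnnotation | None,
    rates: "RateVector | Sequence[float] | None",
    *,
    exclude_interfaces: bool = False,
    interface_threshold: float = 0.10,
    interface_relative: bool = False,
    probe_radius: float = PROBE_RADIUS,
    n_points: int = N_SPHERE_POINTS,
    atom_radius: float | None = None,
    max_asa: Mapping[str, float] | None = None,
    asa_override: Mapping[tuple[str, int, str], float] | None = None,
) -> SiteTable:
    """Assemble the per-residue :class:`SiteTable` for one protein.

    All metrics (WCN, ASA/RSA, d, interface flags) are computed on the full
    selected coordinate set; only afterwards, with ``exclude_interfaces``,
    are interface rows dropped.  `rates` may be a :class:`RateVector` or a
    plain normalized-rate sequence aligned to residue order; ``None`` leaves
    the K column NaN (metrics-only table).  `asa_override` substitutes
    precomputed per-residue areas (e.g. from :func:`read_dssp_acc`).
    """
    from .rates import RateVector  # local import to avoid a cycle

    n = len(structure.residues)
    centers = structure.centers()
    wcn = weighted_contact_number(centers)

    if asa_override is not None:
        try:
            asa = np.array([asa_override[r.key] for r in structure.residues])
        except KeyError as exc:
            raise MetricError(f"asa_override missing residue {exc.args[0]!r}") from exc
    else:
        asa = residue_asa(
            structure,
            probe_radius=probe_radius,
            n_points=n_points,
            atom_radius=atom_radius,
        )

    multichain = len(structure.chains) > 1
    linked = find_cross_chain_links(structure) if multichain else set()
    types = [r.residue_type for r in structure.residues]
    rsa = relative_solvent_accessibility(asa, types, max_asa=max_asa, cross_chain_linked=linked)

    if multichain and asa_override is None:
        rsa_single = np.empty(n)
        for chain_id in sorted(structure.chains):
            idx = [i for i, r in enumerate(structure.residues) if r.chain_id == chain_id]
            asa_c = residue_asa(
                structure,
                probe_radius=probe_radius,
                n_points=n_points,
                atom_radius=atom_radius,
                chain_subset={chain_id},
            )
            rsa_c = relative_solvent_accessibility(asa_c[idx], [types[i] for i in idx], max_asa=max_asa)
            rsa_single[idx] = rsa_c
        is_interface = detect_interface(
            rsa_single, rsa, threshold=interface_threshold, relative=interface_relative
        )
    else:
        is_interface = np.zeros(n, dtype=bool)

    is_catalytic = np.zeros(n, dtype=bool)
    if annotation is not None and len(annotation):
        cat_idx = annotation.indices_in(structure)
        if not cat_idx:
            raise MetricError("annotation resolves to no residue of this structure")
        is_catalytic[cat_idx] = True
        d = distance_to_catalytic(centers, cat_idx)
        shell = np.array([assign_shell(x) for x in d])
    else:
        d = np.full(n, np.nan)
        shell = np.full(n, -1)

    if rates is None:
        k = np.full(n, np.nan)
    else:
        k = np.asarray(rates.K if isinstance(rates, RateVector) else rates, dtype=float)
        if len(k) != n:
            raise MetricError(
                f"rate/residue count mismatch: {len(k)} rates vs {n} residues"
            )

    df = pd.DataFrame(
        {
            "protein_id": structure.pdb_id or "protein",
            "chain": [r.chain_id for r in structure.residues],
            "residue_number": [r.residue_number for r in structure.residues],
            "residue_type": types,
            "K": k,
            "wcn": wcn,
            "asa": asa,
            "rsa": rsa,
            "d": d,
            "shell": shell,
            "is_catalytic": is_catalytic,
            "is_interface": is_interface,
        }
    )
    if is_interface.any():
        iface_centers = centers[is_interface]
        df["d_interface"] = cdist(centers, iface_centers).min(axis=1)

    if exclude_interfaces:
        df = df.loc[~df["is_interface"]].reset_index(drop=True)

    provenance = (
        structure.provenance,
        "interfaces_excluded" if exclude_interfaces else "interfaces_kept",
    )
    return SiteTable(protein_id=structure.pdb_id or "protein", df=df, provenance=provenance)
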