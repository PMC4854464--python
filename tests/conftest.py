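"""Shared fixtures: hand-built PDB texts and small synthetic proteins."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from enzgrad.synthetic_data import SyntheticConfig, synthesize

settings.register_profile(
    "enzgrad",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("enzgrad")


def pdb_line(
    serial: int,
    name: str,
    resname: str,
    chain: str,
    resseq: int,
    x: float,
    y: float,
    z: float,
    element: str = "C",
    altloc: str = " ",
    occupancy: float = 1.0,
    icode: str = " ",
    record: str = "ATOM",
) -> str:
    """Format one fixed-column PDB coordinate record."""
    padded = name if len(name) == 4 else f" {name:<3s}"
    return (
        f"{record:<6s}{serial:5d} {padded}{altloc}{resname:>3s} {chain}"
        f"{resseq:4d}{icode}   {x:8.3f}{y:8.3f}{z:8.3f}{occupancy:6.2f}"
        f"{0.0:6.2f}          {element:>2s}"
    )


def make_pdb(lines: list[str]) -> str:
    return "\n".join(lines + ["END"]) + "\n"


@pytest.fixture
def two_ala_pdb() -> str:
    """Chain A with two alanines; side chains are single CB atoms."""
    return make_pdb(
        [
            pdb_line(1, "N", "ALA", "A", 1, 0.0, 0.0, 0.0, "N"),
            pdb_line(2, "CA", "ALA", "A", 1, 1.5, 0.0, 0.0),
            pdb_line(3, "C", "ALA", "A", 1, 2.0, 1.0, 0.0),
            pdb_line(4, "O", "ALA", "A", 1, 2.0, 2.0, 0.0, "O"),
            pdb_line(5, "CB", "ALA", "A", 1, 1.5, -1.5, 0.0),
            pdb_line(6, "N", "ALA", "A", 2, 3.0, 1.0, 0.0, "N"),
            pdb_line(7, "CA", "ALA", "A", 2, 4.5, 1.0, 0.0),
            pdb_line(8, "C", "ALA", "A", 2, 5.0, 2.0, 0.0),
            pdb_line(9, "O", "ALA", "A", 2, 5.0, 3.0, 0.0, "O"),
            pdb_line(10, "CB", "ALA", "A", 2, 4.5, -0.5, 0.0),
        ]
    )


@pytest.fixture
def dimer_assembly_pdb() -> str:
    """Two MODELs, each chain A with two residues: a symmetry-copy assembly."""
    body = []
    for m, dz in ((1, 0.0), (2, 20.0)):
        body.append(f"MODEL     {m:4d}")
        body += [
            pdb_line(1, "CA", "GLY", "A", 1, 0.0, 0.0, dz),
            pdb_line(2, "CA", "SER", "A", 2, 5.0, 0.0, dz),
            pdb_line(3, "OG", "SER", "A", 2, 5.0, 1.0, dz, "O"),
        ]
        body.append("ENDMDL")
    return make_pdb(body)


@pytest.fixture(scope="session")
def small_protein():
    """A deterministic 60-site synthetic protein shared across tests."""
    return synthesize(SyntheticConfig(n_sites=60, n_catalytic=2, seed=17))


@pytest.fixture(scope="session")
def default_protein():
    """A generator-default synthetic protein (300 sites, buried site)."""
    return synthesize(SyntheticConfig(seed=11))


def random_cloud(n: int, seed: int, scale: float = 20.0) -> np.ndarray:
    return np.random.default_rng(seed).uniform(-scale, scale, size=(n, 3))
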