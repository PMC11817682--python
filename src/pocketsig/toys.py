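"""Programmatically built toy peptide structures with prescribed geometry.

A toy structure is a small chain assembled from ideal internal
coordinates (standard bond lengths and angles) in which every requested
backbone or side-chain torsion is set exactly, so the featurization code
can be verified against closed-form values without any external file.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .featurize import StructureEnsemble

__all__ = ["ToyStructure", "make_toy_structures", "place_atom", "SUPPORTED_RESIDUES"]

# ideal geometry (Angstrom, degrees)
B_N_CA, B_CA_C, B_C_N, B_C_O = 1.458, 1.525, 1.329, 1.231
B_CA_CB, B_SIDE = 1.530, 1.520
A_N_CA_C, A_CA_C_N, A_C_N_CA = 111.0, 116.2, 121.7
A_CA_C_O = 120.5
A_N_CA_CB, A_SIDE = 110.5, 112.0
OMEGA = 180.0

# side-chain construction recipes: atom -> (frame atoms a, b, c, bond, angle,
# dihedral source).  The dihedral source is either a named torsion ("chi1",
# "chi2"), a fixed value in degrees, or ("offset", torsion, degrees).
_SIDECHAINS: dict[str, list[tuple[str, tuple[str, str, str], float, float, object]]] = {
    "GLY": [],
    "ALA": [("CB", ("C", "N", "CA"), B_CA_CB, A_N_CA_CB, -122.0)],
    "SER": [
        ("CB", ("C", "N", "CA"), B_CA_CB, A_N_CA_CB, -122.0),
        ("OG", ("N", "CA", "CB"), 1.417, A_SIDE, "chi1"),
    ],
    "CYS": [
        ("CB", ("C", "N", "CA"), B_CA_CB, A_N_CA_CB, -122.0),
        ("SG", ("N", "CA", "CB"), 1.808, A_SIDE, "chi1"),
    ],
    "THR": [
        ("CB", ("C", "N", "CA"), B_CA_CB, A_N_CA_CB, -122.0),
        ("OG1", ("N", "CA", "CB"), 1.417, A_SIDE, "chi1"),
        ("CG2", ("N", "CA", "CB"), B_SIDE, A_SIDE, ("offset", "chi1", 120.0)),
    ],
    "VAL": [
        ("CB", ("C", "N", "CA"), B_CA_CB, A_N_CA_CB, -122.0),
        ("CG1", ("N", "CA", "CB"), B_SIDE, A_SIDE, "chi1"),
        ("CG2", ("N", "CA", "CB"), B_SIDE, A_SIDE, ("offset", "chi1", 120.0)),
    ],
    "ILE": [
        ("CB", ("C", "N", "CA"), B_CA_CB, A_N_CA_CB, -122.0),
        ("CG1", ("N", "CA", "CB"), B_SIDE, A_SIDE, "chi1"),
        ("CG2", ("N", "CA", "CB"), B_SIDE, A_SIDE, ("offset", "chi1", 120.0)),
        ("CD1", ("CA", "CB", "CG1"), B_SIDE, A_SIDE, "chi2"),
    ],
    "LEU": [
        ("CB", ("C", "N", "CA"), B_CA_CB, A_N_CA_CB, -122.0),
        ("CG", ("N", "CA", "CB"), B_SIDE, A_SIDE, "chi1"),
        ("CD1", ("CA", "CB", "CG"), B_SIDE, A_SIDE, "chi2"),
        ("CD2", ("CA", "CB", "CG"), B_SIDE, A_SIDE, ("offset", "chi2", 120.0)),
    ],
    "MET": [
        ("CB", ("C", "N", "CA"), B_CA_CB, A_N_CA_CB, -122.0),
        ("CG", ("N", "CA", "CB"), B_SIDE, A_SIDE, "chi1"),
        ("SD", ("CA", "CB", "CG"), 1.803, A_SIDE, "chi2"),
        ("CE", ("CB", "CG", "SD"), 1.791, 100.9, 180.0),
    ],
    "ASP": [
        ("CB", ("C", "N", "CA"), B_CA_CB, A_N_CA_CB, -122.0),
        ("CG", ("N", "CA", "CB"), B_SIDE, A_SIDE, "chi1"),
        ("OD1", ("CA", "CB", "CG"), 1.250, 118.0, "chi2"),
        ("OD2", ("CA", "CB", "CG"), 1.250, 118.0, ("offset", "chi2", 180.0)),
    ],
    "ASN": [
        ("CB", ("C", "N", "CA"), B_CA_CB, A_N_CA_CB, -122.0),
        ("CG", ("N", "CA", "CB"), B_SIDE, A_SIDE, "chi1"),
        ("OD1", ("CA", "CB", "CG"), 1.231, 120.8, "chi2"),
        ("ND2", ("CA", "CB", "CG"), 1.328, 116.4, ("offset", "chi2", 180.0)),
    ],
    "GLU": [
        ("CB", ("C", "N", "CA"), B_CA_CB, A_N_CA_CB, -122.0),
        ("CG", ("N", "CA", "CB"), B_SIDE, A_SIDE, "chi1"),
        ("CD", ("CA", "CB", "CG"), B_SIDE, A_SIDE, "chi2"),
        ("OE1", ("CB", "CG", "CD"), 1.250, 118.0, 0.0),
        ("OE2", ("CB", "CG", "CD"), 1.250, 118.0, 180.0),
    ],
    "GLN": [
        ("CB", ("C", "N", "CA"), B_CA_CB, A_N_CA_CB, -122.0),
        ("CG", ("N", "CA", "CB"), B_SIDE, A_SIDE, "chi1"),
        ("CD", ("CA", "CB", "CG"), B_SIDE, A_SIDE, "chi2"),
        ("OE1", ("CB", "CG", "CD"), 1.231, 120.8, 0.0),
        ("NE2", ("CB", "CG", "CD"), 1.328, 116.4, 180.0),
    ],
    "LYS": [
        ("CB", ("C", "N", "CA"), B_CA_CB, A_N_CA_CB, -122.0),
        ("CG", ("N", "CA", "CB"), B_SIDE, A_SIDE, "chi1"),
        ("CD", ("CA", "CB", "CG"), B_SIDE, A_SIDE, "chi2"),
        ("CE", ("CB", "CG", "CD"), B_SIDE, A_SIDE, 180.0),
        ("NZ", ("CG", "CD", "CE"), 1.489, A_SIDE, 180.0),
    ],
}
SUPPORTED_RESIDUES = tuple(sorted(_SIDECHAINS))


def place_atom(
    a: np.ndarray, b: np.ndarray, c: np.ndarray,
    bond: float, angle_deg: float, dihedral_rad: float,
) -> np.ndarray:
    """Place a new atom bonded to ``c`` given internal coordinates.

    Natural-extension reference frame: bond length to c, angle b-c-new,
    dihedral a-b-c-new (exact by construction).
    """
    angle = np.deg2rad(angle_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d2 = np.array(
        [
            -bond * np.cos(angle),
            bond * np.sin(angle) * np.cos(dihedral_rad),
            bond * np.sin(angle) * np.sin(dihedral_rad),
        ]
    )
    return c + d2[0] * bc + d2[1] * m + d2[2] * n


@dataclass
class ToyStructure:
    """Named atoms with one or more coordinate frames."""

    resids: np.ndarray
    resnames: np.ndarray
    atom_names: np.ndarray
    coords: np.ndarray  # (n_frames, n_atoms, 3)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim == 2:
            self.coords = self.coords[None]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    def to_universe(self):
        import MDAnalysis as mda

        resids_unique, resindex = np.unique(self.resids, return_inverse=True)
        u = mda.Universe.empty(
            n_atoms=self.n_atoms,
            n_residues=resids_unique.size,
            atom_resindex=resindex,
            trajectory=True,
        )
        u.add_TopologyAttr("names", self.atom_names.tolist())
        u.add_TopologyAttr("resids", resids_unique.tolist())
        res_names = [
            str(self.resnames[np.flatnonzero(self.resids == r)[0]]) for r in resids_unique
        ]
        u.add_TopologyAttr("resnames", res_names)
        u.add_TopologyAttr("elements", [n[0] for n in self.atom_names])
        u.load_new(self.coords, order="fac")
        return u

    def to_ensemble(self, ligand_id: str = "toy") -> StructureEnsemble:
        return StructureEnsemble(
            ligand_id=ligand_id,
            resids=self.resids.astype(int),
            resnames=self.resnames.astype(str),
            atom_names=self.atom_names.astype(str),
            coords=self.coords.copy(),
        )

    def write_pdb(self, path: str | Path) -> None:
        import warnings

        import MDAnalysis as mda

        u = self.to_universe()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            with mda.Writer(str(path), multiframe=self.n_frames > 1) as w:
                for _ in u.trajectory:
                    w.write(u.atoms)

    def transformed(self, rotation: np.ndarray | None = None, translation=0.0) -> "ToyStructure":
        coords = self.coords.copy()
        if rotation is not None:
            coords = coords @ np.asarray(rotation, float).T
        coords = coords + translation
        return ToyStructure(self.resids, self.resnames, self.atom_names, coords)


def _build_frame(
    residues: Sequence[tuple[int, str]],
    torsions: Mapping[tuple[int, str], float],
) -> tuple[list[int], list[str], list[str], np.ndarray]:
    """One chain frame with the requested torsions set exactly (radians)."""
    for (resid, angle), _ in torsions.items():
        if angle in ("chi1", "chi2"):
            resname = dict(residues).get(resid)
            if resname is None:
                raise ValueError(f"torsion requested for absent residue {resid}")
            names = [rec[0] for rec in _SIDECHAINS[resname]]
            needed = {"chi1": 2, "chi2": 4}[angle]
            if len(names) < needed:
                raise ValueError(
                    f"residue type {resname} (residue {resid}) does not define {angle}"
                )

    def tor(resid: int, angle: str, default_deg: float) -> float:
        return float(torsions.get((resid, angle), np.deg2rad(default_deg)))

    resids: list[int] = []
    resnames: list[str] = []
    names: list[str] = []
    coords: list[np.ndarray] = []
    backbone: dict[tuple[int, str], np.ndarray] = {}

    def add(resid: int, resname: str, name: str, pos: np.ndarray) -> None:
        resids.append(resid)
        resnames.append(resname)
        names.append(name)
        coords.append(pos)
        if name in ("N", "CA", "C", "O"):
            backbone[(resid, name)] = pos

    for i, (resid, resname) in enumerate(residues):
        if resname not in _SIDECHAINS:
            raise ValueError(
                f"unsupported toy residue type {resname!r}; supported: {SUPPORTED_RESIDUES}"
            )
        if i == 0:
            n = np.zeros(3)
            ca = np.array([B_N_CA, 0.0, 0.0])
            ang = np.deg2rad(A_N_CA_C)
            c = ca + B_CA_C * np.array([-np.cos(ang), np.sin(ang), 0.0])
        else:
            prev = residues[i - 1][0]
            n = place_atom(
                backbone[(prev, "N")], backbone[(prev, "CA")], backbone[(prev, "C")],
                B_C_N, A_CA_C_N, tor(prev, "psi", -45.0),
            )
            ca = place_atom(
                backbone[(prev, "CA")], backbone[(prev, "C")], n,
                B_N_CA, A_C_N_CA, np.deg2rad(OMEGA),
            )
            c = place_atom(
                backbone[(prev, "C")], n, ca,
                B_CA_C, A_N_CA_C, tor(resid, "phi", -60.0),
            )
        add(resid, resname, "N", n)
        add(resid, resname, "CA", ca)
        add(resid, resname, "C", c)
        # carbonyl O: anti to the next N, i.e. dihedral N-CA-C-O = psi + pi
        o = place_atom(n, ca, c, B_C_O, A_CA_C_O, tor(resid, "psi", -45.0) + np.pi)
        add(resid, resname, "O", o)

        placed = {"N": n, "CA": ca, "C": c, "O": o}
        for name, (fa, fb, fc), bond, angle, dsrc in _SIDECHAINS[resname]:
            if isinstance(dsrc, str):
                dihedral = tor(resid, dsrc, -60.0)
            elif isinstance(dsrc, tuple):
                _, base, off = dsrc
                dihedral = tor(resid, base, -60.0) + np.deg2rad(off)
            else:
                dihedral = np.deg2rad(float(dsrc))
            pos = place_atom(placed[fa], placed[fb], placed[fc], bond, angle, dihedral)
            placed[name] = pos
            add(resid, resname, name, pos)

    return resids, resnames, names, np.array(coords)


def make_toy_structures(
    residues: Sequence[tuple[int, str]],
    frame_torsions: Sequence[Mapping[tuple[int, str], float]] | Mapping[tuple[int, str], float] | None = None,
    ligand_id: str = "toy",
) -> ToyStructure:
    """Build a toy chain ensemble with requested torsions (radians).

    ``frame_torsions`` is one mapping ``(resid, angle) -> value`` per frame
    (or a single mapping for a one-frame structure).  Unrequested angles
    take ideal helix-like defaults.  Requesting an angle a residue type
    does not define raises a ValueError.
    """
    if frame_torsions is None:
        frame_torsions = [{}]
    elif isinstance(frame_torsions, Mapping):
        frame_torsions = [frame_torsions]
    frames = []
    meta = None
    for tors in frame_torsions:
        resids, resnames, names, coords = _build_frame(residues, tors)
        if meta is None:
            meta = (resids, resnames, names)
        frames.append(coords)
    resids, resnames, names = meta
    return ToyStructure(
        resids=np.array(resids),
        resnames=np.array(resnames),
        atom_names=np.array(names),
        coords=np.stack(frames),
    )
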