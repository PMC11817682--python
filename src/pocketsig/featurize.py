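"""Per-frame feature vectors from receptor structural ensembles.

Each sampled configuration of the receptor's intracellular region is
characterized by three feature vectors:

* ``theta`` — the backbone and side-chain torsion angles (psi, phi, chi1,
  chi2) of the intracellular residues, in radians wrapped to [-pi, pi);
* ``ca``    — pairwise distances between C-alpha atoms of anchor residues
  at the middle/intracellular end of each helix and loop midpoints (A);
* ``hb``    — distances between intracellular hydrogen-bond donor and
  acceptor heavy atoms observed close together in a reference frame (A).

Residues are identified both by their sequence position and by their
Ballesteros-Weinstein (BW) label, the standard cross-receptor numbering
for seven-transmembrane receptors.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .distance import wrap_angles

__all__ = [
    "ResidueRef",
    "AtomRef",
    "FeatureSpec",
    "ConfigurationFeatures",
    "FeatureLayout",
    "FeatureTable",
    "StructureEnsemble",
    "read_bw_map",
    "build_default_spec",
    "derive_hbond_pairs",
    "featurize_frame",
    "featurize_ensemble",
    "DEFAULT_TORSION_RANGES",
    "DEFAULT_CA_ANCHORS",
]

ANGLE_NAMES = ("psi", "phi", "chi1", "chi2")

# Intracellular residue ranges of the mu opioid receptor used for torsion
# features: G84(1.46)-D116(2.50), S156(3.39)-W194(4.50), P246(5.50)-F291(6.44),
# Y328(7.43)-F349(H8).
DEFAULT_TORSION_RANGES: tuple[tuple[int, int], ...] = (
    (84, 116),
    (156, 194),
    (246, 291),
    (328, 349),
)

# Anchor residues (middle and intracellular end of each helix plus loop
# midpoints) whose pairwise C-alpha distances form the second feature vector.
DEFAULT_CA_ANCHORS: tuple[int, ...] = (
    84, 91, 99, 102, 105, 116, 156, 164, 170, 178, 183,
    194, 253, 260, 267, 271, 283, 291, 328, 338, 343, 349,
)

# chi1 is N-CA-CB-<G>; residues without a gamma heavy atom have no chi1.
CHI1_GAMMA_ATOM: dict[str, str] = {
    "ARG": "CG", "ASN": "CG", "ASP": "CG", "GLN": "CG", "GLU": "CG",
    "HIS": "CG", "LEU": "CG", "LYS": "CG", "MET": "CG", "PHE": "CG",
    "PRO": "CG", "TRP": "CG", "TYR": "CG",
    "ILE": "CG1", "VAL": "CG1", "SER": "OG", "THR": "OG1", "CYS": "SG",
}

# chi2 is CA-CB-<G>-<D>; for ambiguous terminal branches (Asp, Asn, Phe,
# Tyr, Trp, His, Leu) the lower-numbered branch atom is used.
CHI2_DELTA_ATOM: dict[str, tuple[str, str]] = {
    "ARG": ("CG", "CD"), "GLN": ("CG", "CD"), "GLU": ("CG", "CD"),
    "LYS": ("CG", "CD"), "PRO": ("CG", "CD"),
    "ILE": ("CG1", "CD1"), "LEU": ("CG", "CD1"), "MET": ("CG", "SD"),
    "ASN": ("CG", "OD1"), "ASP": ("CG", "OD1"),
    "PHE": ("CG", "CD1"), "TYR": ("CG", "CD1"), "TRP": ("CG", "CD1"),
    "HIS": ("CG", "ND1"),
}

# Polar heavy atoms acting as hydrogen-bond donors/acceptors.  Backbone N
# is a donor (except proline) and backbone O an acceptor for every residue.
SIDECHAIN_DONORS: dict[str, tuple[str, ...]] = {
    "SER": ("OG",), "THR": ("OG1",), "TYR": ("OH",),
    "ASN": ("ND2",), "GLN": ("NE2",), "LYS": ("NZ",),
    "ARG": ("NE", "NH1", "NH2"), "HIS": ("ND1", "NE2"), "TRP": ("NE1",),
}
SIDECHAIN_ACCEPTORS: dict[str, tuple[str, ...]] = {
    "SER": ("OG",), "THR": ("OG1",), "TYR": ("OH",),
    "ASN": ("OD1",), "GLN": ("OE1",),
    "ASP": ("OD1", "OD2"), "GLU": ("OE1", "OE2"), "HIS": ("ND1", "NE2"),
}


@dataclass(frozen=True, order=True)
class ResidueRef:
    """A residue identified by sequence position, BW label and 3-letter code."""

    seq_position: int
    bw_label: str
    residue_name: str = ""

    def __post_init__(self) -> None:
        if self.seq_position < 1:
            raise ValueError(f"seq_position must be >= 1, got {self.seq_position}")
        if not self.bw_label:
            raise ValueError(f"empty BW label for residue {self.seq_position}")

    def __str__(self) -> str:
        name = self.residue_name or "UNK"
        return f"{name}{self.seq_position}^{self.bw_label}"


@dataclass(frozen=True, order=True)
class AtomRef:
    """A named atom within a residue."""

    residue: ResidueRef
    atom_name: str

    def __str__(self) -> str:
        return f"{self.residue}.{self.atom_name}"


@dataclass(frozen=True)
class FeatureSpec:
    """Declarative definition of the three feature vectors."""

    torsion_selection: tuple[tuple[ResidueRef, str], ...]
    ca_pair_selection: tuple[tuple[ResidueRef, ResidueRef], ...]
    hbond_pair_selection: tuple[tuple[AtomRef, AtomRef], ...] = ()
    hbond_cutoff: float = 8.0

    def __post_init__(self) -> None:
        if self.hbond_cutoff <= 0:
            raise ValueError(f"hbond_cutoff must be positive, got {self.hbond_cutoff}")
        if len(self.torsion_selection) < 1:
            raise ValueError("torsion_selection must contain at least one entry")
        if len(self.ca_pair_selection) < 1:
            raise ValueError("ca_pair_selection must contain at least one entry")
        for name, sel in (
            ("torsion_selection", self.torsion_selection),
            ("ca_pair_selection", self.ca_pair_selection),
            ("hbond_pair_selection", self.hbond_pair_selection),
        ):
            if len(set(sel)) != len(sel):
                raise ValueError(f"duplicate entries in {name}")
        for ref, angle in self.torsion_selection:
            if angle not in ANGLE_NAMES:
                raise ValueError(f"unknown angle {angle!r} for {ref}")
        for a, b in self.ca_pair_selection:
            if abs(a.seq_position - b.seq_position) < 2:
                raise ValueError(
                    f"C-alpha pair {a}-{b} lacks the required sequence separation >= 2"
                )

    @property
    def n_theta(self) -> int:
        return len(self.torsion_selection)

    @property
    def n_ca(self) -> int:
        return len(self.ca_pair_selection)

    @property
    def n_hb(self) -> int:
        return len(self.hbond_pair_selection)

    @property
    def layout(self) -> "FeatureLayout":
        return FeatureLayout(self.n_theta, self.n_ca, self.n_hb)

    def column_names(self) -> list[str]:
        cols = [f"theta:{ref.bw_label}:{angle}" for ref, angle in self.torsion_selection]
        cols += [f"ca:{a.bw_label}|{b.bw_label}" for a, b in self.ca_pair_selection]
        cols += [
            f"hb:{d.residue.bw_label}.{d.atom_name}|{a.residue.bw_label}.{a.atom_name}"
            for d, a in self.hbond_pair_selection
        ]
        return cols


@dataclass(frozen=True)
class FeatureLayout:
    """Sizes of the three feature blocks within a flat feature vector."""

    n_theta: int
    n_ca: int
    n_hb: int

    @property
    def n_features(self) -> int:
        return self.n_theta + self.n_ca + self.n_hb

    @property
    def theta_slice(self) -> slice:
        return slice(0, self.n_theta)

    @property
    def ca_slice(self) -> slice:
        return slice(self.n_theta, self.n_theta + self.n_ca)

    @property
    def hb_slice(self) -> slice:
        return slice(self.n_theta + self.n_ca, self.n_features)


@dataclass
class ConfigurationFeatures:
    """One frame's torsion (rad), C-alpha (A) and H-bond (A) feature vectors."""

    theta: np.ndarray
    ca: np.ndarray
    hb: np.ndarray

    def __post_init__(self) -> None:
        self.theta = np.asarray(self.theta, dtype=float).ravel()
        self.ca = np.asarray(self.ca, dtype=float).ravel()
        self.hb = np.asarray(self.hb, dtype=float).ravel()
        for name, v in (("theta", self.theta), ("ca", self.ca), ("hb", self.hb)):
            if not np.all(np.isfinite(v)):
                raise ValueError(f"non-finite values in {name} features")
        if np.any(self.theta < -np.pi) or np.any(self.theta >= np.pi):
            raise ValueError("torsion features must lie in [-pi, pi)")

    @property
    def layout(self) -> FeatureLayout:
        return FeatureLayout(self.theta.size, self.ca.size, self.hb.size)

    def concatenated(self) -> np.ndarray:
        return np.concatenate([self.theta, self.ca, self.hb])


class FeatureTable:
    """Stack of per-frame feature vectors with ligand bookkeeping.

    Stored as an ``(n_frames, n_features)`` float array whose columns are
    ordered theta-block, ca-block, hb-block per the :class:`FeatureLayout`.
    """

    def __init__(
        self,
        values: np.ndarray,
        layout: FeatureLayout,
        ligand_ids: Sequence[str],
        columns: Sequence[str] | None = None,
    ) -> None:
        values = np.atleast_2d(np.asarray(values, dtype=float))
        if values.shape[1] != layout.n_features:
            raise ValueError(
                f"feature matrix has {values.shape[1]} columns, layout expects "
                f"{layout.n_features}"
            )
        if len(ligand_ids) != values.shape[0]:
            raise ValueError("ligand_ids length does not match frame count")
        if columns is None:
            columns = (
                [f"theta:t{i}" for i in range(layout.n_theta)]
                + [f"ca:c{i}" for i in range(layout.n_ca)]
                + [f"hb:h{i}" for i in range(layout.n_hb)]
            )
        if len(columns) != layout.n_features:
            raise ValueError("column count does not match layout")
        self.values = values
        self.layout = layout
        self.ligand_ids = np.asarray(ligand_ids, dtype=object)
        self.columns = list(columns)

    # -- block views ------------------------------------------------------
    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def theta(self) -> np.ndarray:
        return self.values[:, self.layout.theta_slice]

    @property
    def ca(self) -> np.ndarray:
        return self.values[:, self.layout.ca_slice]

    @property
    def hb(self) -> np.ndarray:
        return self.values[:, self.layout.hb_slice]

    def frame(self, i: int) -> ConfigurationFeatures:
        return ConfigurationFeatures(self.theta[i], self.ca[i], self.hb[i])

    def frames(self) -> list[ConfigurationFeatures]:
        return [self.frame(i) for i in range(self.n_frames)]

    @property
    def ligands(self) -> list[str]:
        seen: dict[str, None] = {}
        for lid in self.ligand_ids:
            seen.setdefault(str(lid))
        return list(seen)

    def mask(self, mask: np.ndarray) -> "FeatureTable":
        return FeatureTable(self.values[mask], self.layout, self.ligand_ids[mask], self.columns)

    def for_ligands(self, ligands: Iterable[str]) -> "FeatureTable":
        keep = set(ligands)
        return self.mask(np.array([lid in keep for lid in self.ligand_ids]))

    @staticmethod
    def concat(tables: Sequence["FeatureTable"]) -> "FeatureTable":
        if not tables:
            raise ValueError("no tables to concatenate")
        layout = tables[0].layout
        if any(t.layout != layout for t in tables):
            raise ValueError("feature tables disagree on layout")
        return FeatureTable(
            np.vstack([t.values for t in tables]),
            layout,
            np.concatenate([t.ligand_ids for t in tables]),
            tables[0].columns,
        )

    # -- CSV round-trip ----------------------------------------------------
    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.columns)
        df.insert(0, "frame_index", np.arange(self.n_frames))
        df.insert(0, "ligand_id", self.ligand_ids)
        return df

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False, float_format="%.17g")

    @classmethod
    def from_csv(cls, path: str | Path) -> "FeatureTable":
        df = pd.read_csv(path)
        feature_cols = [c for c in df.columns if c not in ("ligand_id", "frame_index")]
        n_theta = sum(c.startswith("theta:") for c in feature_cols)
        n_ca = sum(c.startswith("ca:") for c in feature_cols)
        n_hb = sum(c.startswith("hb:") for c in feature_cols)
        if n_theta + n_ca + n_hb != len(feature_cols):
            raise ValueError("feature table has unrecognized columns")
        ordered = (
            [c for c in feature_cols if c.startswith("theta:")]
            + [c for c in feature_cols if c.startswith("ca:")]
            + [c for c in feature_cols if c.startswith("hb:")]
        )
        return cls(
            df[ordered].to_numpy(dtype=float),
            FeatureLayout(n_theta, n_ca, n_hb),
            df["ligand_id"].astype(str).to_numpy(),
            ordered,
        )


@dataclass
class StructureEnsemble:
    """A multi-frame coordinate set (Angstrom) sharing one topology.

    Multi-model PDB files are read through MDAnalysis; coordinates are
    held as float64 so downstream geometry is at full precision.
    """

    ligand_id: str
    resids: np.ndarray      # (n_atoms,)
    resnames: np.ndarray    # (n_atoms,)
    atom_names: np.ndarray  # (n_atoms,)
    coords: np.ndarray      # (n_frames, n_atoms, 3)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim == 2:
            self.coords = self.coords[None]
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("ensemble coordinates contain non-finite values")

    @classmethod
    def from_pdb(cls, path: str | Path, ligand_id: str | None = None) -> "StructureEnsemble":
        import MDAnalysis as mda

        path = Path(path)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            u = mda.Universe(str(path))
            frames = np.stack(
                [u.atoms.positions.astype(float) for _ in u.trajectory]
            )
        return cls(
            ligand_id=ligand_id or path.stem,
            resids=u.atoms.resids.astype(int),
            resnames=u.atoms.resnames.astype(str),
            atom_names=u.atoms.names.astype(str),
            coords=frames,
        )

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    def atom_index(self) -> dict[tuple[int, str], int]:
        return {
            (int(r), str(n)): i
            for i, (r, n) in enumerate(zip(self.resids, self.atom_names))
        }

    def residue_names(self) -> dict[int, str]:
        out: dict[int, str] = {}
        for r, name in zip(self.resids, self.resnames):
            out.setdefault(int(r), str(name))
        return out

    def coordinates(self, frame: int = 0) -> np.ndarray:
        return self.coords[frame]


def read_bw_map(path: str | Path) -> dict[int, str]:
    """Read a two-column (seq_position, bw_label) CSV into a mapping."""
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValueError("BW map CSV needs two columns: seq_position, bw_label")
    pos_col, bw_col = df.columns[:2]
    return {int(p): str(b) for p, b in zip(df[pos_col], df[bw_col])}


def _residue_ref(resid: int, bw_map: Mapping[int, str], resnames: Mapping[int, str]) -> ResidueRef:
    bw = bw_map.get(resid, str(resid))
    name = resnames.get(resid, "")
    if resid not in resnames:
        raise KeyError(f"structure lacks residue {ResidueRef(resid, bw, name or 'UNK')}")
    return ResidueRef(resid, bw, name)


def build_default_spec(
    structure: StructureEnsemble,
    bw_map: Mapping[int, str],
    torsion_ranges: Sequence[tuple[int, int]] = DEFAULT_TORSION_RANGES,
    ca_anchors: Sequence[int] = DEFAULT_CA_ANCHORS,
    hbond_cutoff: float = 8.0,
) -> FeatureSpec:
    """Feature spec over the receptor's intracellular region.

    Torsions cover psi/phi/chi1/chi2 for every residue in the intracellular
    ranges, omitting angles undefined for the residue type (no chi1 for
    Gly/Ala, no chi2 for Ser/Thr/Cys/Val/Ala/Gly) and backbone angles
    undefined at chain termini.  C-alpha pairs are all unordered anchor
    pairs with sequence separation >= 2.  The H-bond pair list starts empty;
    fill it with :func:`derive_hbond_pairs` against a reference frame.
    """
    resnames = structure.residue_names()
    torsions: list[tuple[ResidueRef, str]] = []
    for lo, hi in torsion_ranges:
        for resid in range(lo, hi + 1):
            ref = _residue_ref(resid, bw_map, resnames)
            if resid + 1 in resnames:
                torsions.append((ref, "psi"))
            if resid - 1 in resnames:
                torsions.append((ref, "phi"))
            if ref.residue_name in CHI1_GAMMA_ATOM:
                torsions.append((ref, "chi1"))
            if ref.residue_name in CHI2_DELTA_ATOM:
                torsions.append((ref, "chi2"))
    anchors = [_residue_ref(r, bw_map, resnames) for r in ca_anchors]
    ca_pairs = [
        (a, b)
        for a, b in itertools.combinations(anchors, 2)
        if abs(a.seq_position - b.seq_position) >= 2
    ]
    return FeatureSpec(
        torsion_selection=tuple(torsions),
        ca_pair_selection=tuple(ca_pairs),
        hbond_pair_selection=(),
        hbond_cutoff=hbond_cutoff,
    )


def _polar_atoms(ref: ResidueRef, kind: str) -> list[AtomRef]:
    atoms: list[str] = []
    if kind == "donor":
        if ref.residue_name != "PRO":
            atoms.append("N")
        atoms.extend(SIDECHAIN_DONORS.get(ref.residue_name, ()))
    else:
        atoms.append("O")
        atoms.extend(SIDECHAIN_ACCEPTORS.get(ref.residue_name, ()))
    return [AtomRef(ref, a) for a in atoms]


def derive_hbond_pairs(
    spec: FeatureSpec,
    reference: StructureEnsemble,
    cutoff: float | None = None,
) -> FeatureSpec:
    """Fill the H-bond pair selection from a single reference frame.

    Every (donor, acceptor) heavy-atom pair among the polar N/O atoms of the
    spec's intracellular residues whose distance in the reference frame is
    within ``cutoff`` (default: the spec's ``hbond_cutoff``, 8.0 A) is kept.
    Pairs within one residue are excluded.  The returned ordering is
    deterministic (donor residue, donor atom, acceptor residue, acceptor atom).
    """
    cutoff = spec.hbond_cutoff if cutoff is None else float(cutoff)
    if cutoff <= 0:
        raise ValueError(f"cutoff must be positive, got {cutoff}")
    resnames = reference.residue_names()
    index = reference.atom_index()
    coords = reference.coordinates(0)
    residues = sorted({ref for ref, _ in spec.torsion_selection})
    donors: list[tuple[AtomRef, int]] = []
    acceptors: list[tuple[AtomRef, int]] = []
    for ref in residues:
        if ref.seq_position not in resnames:
            raise KeyError(f"reference structure lacks residue {ref}")
        for aref in _polar_atoms(ref, "donor"):
            key = (ref.seq_position, aref.atom_name)
            if key in index:
                donors.append((aref, index[key]))
        for aref in _polar_atoms(ref, "acceptor"):
            key = (ref.seq_position, aref.atom_name)
            if key in index:
                acceptors.append((aref, index[key]))
    pairs: list[tuple[AtomRef, AtomRef]] = []
    for dref, di in donors:
        for aref, ai in acceptors:
            if dref.residue.seq_position == aref.residue.seq_position:
                continue
            if np.linalg.norm(coords[di] - coords[ai]) <= cutoff:
                pairs.append((dref, aref))
    pairs = sorted(
        set(pairs),
        key=lambda p: (
            p[0].residue.seq_position, p[0].atom_name,
            p[1].residue.seq_position, p[1].atom_name,
        ),
    )
    return replace(spec, hbond_pair_selection=tuple(pairs), hbond_cutoff=cutoff)


def dihedral_angle(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> float:
    """Signed dihedral (radians, in [-pi, pi)) defined by four points."""
    b0 = np.asarray(p1, float) - np.asarray(p0, float)
    b1 = np.asarray(p2, float) - np.asarray(p1, float)
    b2 = np.asarray(p3, float) - np.asarray(p2, float)
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    b1_norm = np.linalg.norm(b1)
    if np.linalg.norm(n1) < 1e-9 or np.linalg.norm(n2) < 1e-9 or b1_norm < 1e-9:
        raise ValueError("degenerate (collinear) geometry: dihedral undefined")
    x = float(np.dot(n1, n2))
    y = float(np.dot(np.cross(n1, n2), b1 / b1_norm))
    return float(wrap_angles(np.arctan2(y, x)))


_TORSION_BACKBONE = {
    # angle -> list of (residue offset, atom name)
    "phi": [(-1, "C"), (0, "N"), (0, "CA"), (0, "C")],
    "psi": [(0, "N"), (0, "CA"), (0, "C"), (1, "N")],
}


class SpecResolver:
    """Resolve a FeatureSpec against one topology into atom index tuples."""

    def __init__(self, structure: StructureEnsemble, spec: FeatureSpec) -> None:
        self.spec = spec
        index = structure.atom_index()

        def lookup(resid: int, atom: str, what: str) -> int:
            try:
                return index[(resid, atom)]
            except KeyError:
                raise KeyError(f"cannot resolve atom {atom} of residue {resid} for {what}")

        self.torsion_quads: list[tuple[int, int, int, int]] = []
        for ref, angle in spec.torsion_selection:
            label = f"{angle} of {ref}"
            if angle in _TORSION_BACKBONE:
                atoms = [
                    lookup(ref.seq_position + off, name, label)
                    for off, name in _TORSION_BACKBONE[angle]
                ]
            elif angle == "chi1":
                gamma = CHI1_GAMMA_ATOM.get(ref.residue_name)
                if gamma is None:
                    raise KeyError(f"residue type {ref.residue_name} has no chi1 ({ref})")
                atoms = [lookup(ref.seq_position, a, label) for a in ("N", "CA", "CB", gamma)]
            elif angle == "chi2":
                gd = CHI2_DELTA_ATOM.get(ref.residue_name)
                if gd is None:
                    raise KeyError(f"residue type {ref.residue_name} has no chi2 ({ref})")
                atoms = [
                    lookup(ref.seq_position, a, label) for a in ("CA", "CB", gd[0], gd[1])
                ]
            else:  # pragma: no cover - guarded by FeatureSpec validation
                raise ValueError(f"unknown angle {angle}")
            self.torsion_quads.append(tuple(atoms))

        self.ca_pairs = [
            (
                lookup(a.seq_position, "CA", f"C-alpha pair {a}-{b}"),
                lookup(b.seq_position, "CA", f"C-alpha pair {a}-{b}"),
            )
            for a, b in spec.ca_pair_selection
        ]
        self.hb_pairs = [
            (
                lookup(d.residue.seq_position, d.atom_name, f"H-bond pair {d}|{a}"),
                lookup(a.residue.seq_position, a.atom_name, f"H-bond pair {d}|{a}"),
            )
            for d, a in spec.hbond_pair_selection
        ]

    def features(self, coords: np.ndarray) -> ConfigurationFeatures:
        theta = np.array(
            [dihedral_angle(*(coords[i] for i in quad)) for quad in self.torsion_quads]
        )
        ca = np.array(
            [np.linalg.norm(coords[i] - coords[j]) for i, j in self.ca_pairs]
        )
        hb = np.array(
            [np.linalg.norm(coords[i] - coords[j]) for i, j in self.hb_pairs]
        )
        return ConfigurationFeatures(
            theta=theta if theta.size else np.empty(0),
            ca=ca if ca.size else np.empty(0),
            hb=hb if hb.size else np.empty(0),
        )


def featurize_frame(structure: StructureEnsemble, spec: FeatureSpec, frame: int = 0) -> ConfigurationFeatures:
    """Feature vectors of one frame of an ensemble."""
    resolver = SpecResolver(structure, spec)
    return resolver.features(structure.coordinates(frame))


def featurize_ensemble(ensemble: StructureEnsemble, spec: FeatureSpec) -> FeatureTable:
    """Feature table over every frame of an ensemble, frame order preserved."""
    resolver = SpecResolver(ensemble, spec)
    rows = []
    for k in range(ensemble.n_frames):
        try:
            feats = resolver.features(ensemble.coordinates(k))
        except (ValueError, KeyError) as exc:
            raise type(exc)(f"frame {k}: {exc}") from exc
        rows.append(feats.concatenated())
    return FeatureTable(
        np.vstack(rows),
        spec.layout,
        [ensemble.ligand_id] * len(rows),
        spec.column_names(),
    )
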