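"""Synthetic ensembles with the statistical structure the analysis assumes.

Each ligand's ensemble is an i.i.d. mixture over a small set of "true"
conformations: cluster centers in the torsion + distance feature space,
plus per-kind Gaussian noise (torsions perturbed on the circle, distances
reflected positive).  Efficacies are generated by the linear model the
pipeline fits — a weighted sum of planted per-pathway slopes over the
realized conformation fractions, plus observation noise — so every
downstream stage has exact ground truth to recover.

The generator emits feature tables directly (no coordinates) for speed;
the :mod:`pocketsig.toys` builder provides the coordinate path used to
exercise featurization.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .distance import DistanceWeights, combined_distance, wrap_angles
from .efficacy import PATHWAYS, EfficacyRecord, EfficacyTable
from .featurize import ConfigurationFeatures, FeatureLayout, FeatureTable
from .toys import ToyStructure, make_toy_structures  # noqa: F401  (re-export)

__all__ = [
    "SyntheticScenario",
    "sample_ensembles",
    "make_efficacies",
    "make_toy_structures",
    "preset",
    "PRESETS",
]

REFERENCE_WEIGHTS = DistanceWeights(0.25, 0.25, 0.5)


@dataclass
class SyntheticScenario:
    """Planted mixture-of-conformations scenario."""

    name: str
    centers_theta: np.ndarray     # (C, N_theta), radians in [-pi, pi)
    centers_ca: np.ndarray        # (C, N_ca), Angstrom
    centers_hb: np.ndarray        # (C, N_hb), Angstrom
    mixtures: pd.DataFrame        # ligand x conformation weights, rows sum to 1
    true_slopes: pd.DataFrame     # pathway x conformation, efficacy %
    noise_theta: float = 0.1
    noise_ca: float = 0.25
    noise_hb: float = 0.25
    efficacy_noise_sd: float = 0.0
    n_efficacy_records: int = 1
    frames_per_ligand: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        self.centers_theta = wrap_angles(np.atleast_2d(np.asarray(self.centers_theta, float)))
        self.centers_ca = np.atleast_2d(np.asarray(self.centers_ca, float))
        self.centers_hb = np.atleast_2d(np.asarray(self.centers_hb, float))
        c = self.centers_theta.shape[0]
        if self.centers_ca.shape[0] != c or self.centers_hb.shape[0] != c:
            raise ValueError("center blocks disagree on conformation count")
        if list(self.mixtures.columns) != list(range(1, c + 1)):
            self.mixtures = self.mixtures.set_axis(range(1, c + 1), axis=1)
        rowsums = self.mixtures.to_numpy().sum(axis=1)
        if not np.allclose(rowsums, 1.0, atol=1e-9):
            raise ValueError("mixture rows must sum to 1")
        if np.any(self.mixtures.to_numpy() < 0):
            raise ValueError("mixture weights must be nonnegative")
        if self.true_slopes.shape[1] != c:
            raise ValueError("true_slopes column count must equal n_conformations")
        for v in (self.noise_theta, self.noise_ca, self.noise_hb, self.efficacy_noise_sd):
            if v < 0:
                raise ValueError("noise levels must be nonnegative")
        if self.frames_per_ligand < 1:
            raise ValueError("frames_per_ligand must be >= 1")

    @property
    def n_conformations(self) -> int:
        return self.centers_theta.shape[0]

    @property
    def ligands(self) -> list[str]:
        return list(self.mixtures.index)

    @property
    def layout(self) -> FeatureLayout:
        return FeatureLayout(
            self.centers_theta.shape[1], self.centers_ca.shape[1], self.centers_hb.shape[1]
        )

    def center_features(self, conf: int) -> ConfigurationFeatures:
        i = conf - 1
        return ConfigurationFeatures(
            self.centers_theta[i], self.centers_ca[i], self.centers_hb[i]
        )

    def min_center_separation(self, weights: DistanceWeights = REFERENCE_WEIGHTS) -> float:
        c = self.n_conformations
        dmin = np.inf
        for i in range(1, c + 1):
            for j in range(i + 1, c + 1):
                dmin = min(
                    dmin,
                    combined_distance(self.center_features(i), self.center_features(j), weights),
                )
        return float(dmin)

    def noise_scale(self, weights: DistanceWeights = REFERENCE_WEIGHTS) -> float:
        """Typical within-conformation combined distance between two frames."""
        s2 = np.sqrt(2.0)
        return float(
            weights.w_theta * s2 * self.noise_theta
            + weights.w_ca * s2 * self.noise_ca
            + weights.w_hb * s2 * self.noise_hb
        )

    def validate_separable(self, factor: float = 4.0) -> None:
        sep = self.min_center_separation()
        noise = self.noise_scale()
        if noise > 0 and sep <= factor * noise:
            raise ValueError(
                f"centers are not separable: min separation {sep:.3f} <= "
                f"{factor} x noise scale {noise:.3f}"
            )

    def to_yaml(self, path: str | Path) -> None:
        payload = {
            "name": self.name,
            "centers_theta": self.centers_theta.tolist(),
            "centers_ca": self.centers_ca.tolist(),
            "centers_hb": self.centers_hb.tolist(),
            "mixtures": {
                str(lig): row.tolist()
                for lig, row in zip(self.mixtures.index, self.mixtures.to_numpy())
            },
            "true_slopes": {
                str(p): row.tolist()
                for p, row in zip(self.true_slopes.index, self.true_slopes.to_numpy())
            },
            "noise_theta": self.noise_theta,
            "noise_ca": self.noise_ca,
            "noise_hb": self.noise_hb,
            "efficacy_noise_sd": self.efficacy_noise_sd,
            "n_efficacy_records": self.n_efficacy_records,
            "frames_per_ligand": self.frames_per_ligand,
            "seed": self.seed,
        }
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SyntheticScenario":
        d = yaml.safe_load(Path(path).read_text())
        mixtures = pd.DataFrame.from_dict(d["mixtures"], orient="index")
        slopes = pd.DataFrame.from_dict(d["true_slopes"], orient="index")
        slopes.columns = range(1, slopes.shape[1] + 1)
        return cls(
            name=d["name"],
            centers_theta=np.array(d["centers_theta"]),
            centers_ca=np.array(d["centers_ca"]),
            centers_hb=np.array(d["centers_hb"]),
            mixtures=mixtures,
            true_slopes=slopes,
            noise_theta=d["noise_theta"],
            noise_ca=d["noise_ca"],
            noise_hb=d["noise_hb"],
            efficacy_noise_sd=d["efficacy_noise_sd"],
            n_efficacy_records=d["n_efficacy_records"],
            frames_per_ligand=d["frames_per_ligand"],
            seed=d["seed"],
        )


def sample_ensembles(
    scenario: SyntheticScenario, rng: np.random.Generator | None = None
) -> tuple[FeatureTable, np.ndarray]:
    """Draw per-ligand frame ensembles; returns (features, true labels).

    Per frame: a conformation is drawn from the ligand's mixture, torsions
    are the center plus wrapped-normal noise, distances the center plus
    normal noise reflected positive.  Reproducible from the scenario seed.
    """
    if rng is None:
        rng = np.random.default_rng(scenario.seed)
    lay = scenario.layout
    confs = np.arange(1, scenario.n_conformations + 1)
    blocks, lids, labels = [], [], []
    for lig in scenario.ligands:
        p = scenario.mixtures.loc[lig].to_numpy(dtype=float)
        draw = rng.choice(confs, size=scenario.frames_per_ligand, p=p / p.sum())
        theta = wrap_angles(
            scenario.centers_theta[draw - 1]
            + rng.normal(0.0, scenario.noise_theta, (draw.size, lay.n_theta))
        )
        ca = np.abs(
            scenario.centers_ca[draw - 1]
            + rng.normal(0.0, scenario.noise_ca, (draw.size, lay.n_ca))
        )
        hb = np.abs(
            scenario.centers_hb[draw - 1]
            + rng.normal(0.0, scenario.noise_hb, (draw.size, lay.n_hb))
        )
        blocks.append(np.hstack([theta, ca, hb]))
        lids.extend([lig] * draw.size)
        labels.append(draw)
    table = FeatureTable(np.vstack(blocks), lay, lids)
    return table, np.concatenate(labels)


def realized_fractions(
    scenario: SyntheticScenario, labels: np.ndarray, ligand_ids: Sequence[str]
) -> pd.DataFrame:
    labels = np.asarray(labels, dtype=int)
    ligand_ids = np.asarray(ligand_ids, dtype=object)
    rows = []
    for lig in scenario.ligands:
        mask = ligand_ids == lig
        counts = np.bincount(labels[mask], minlength=scenario.n_conformations + 1)[1:]
        rows.append(counts / counts.sum())
    return pd.DataFrame(
        rows, index=scenario.ligands, columns=range(1, scenario.n_conformations + 1)
    )


def make_efficacies(
    scenario: SyntheticScenario,
    fractions: pd.DataFrame,
    rng: np.random.Generator | None = None,
) -> EfficacyTable:
    """Efficacy records from the planted linear model over realized fractions.

    ``value = sum_c beta*_c f_{l,c} + N(0, efficacy_noise_sd)`` per record;
    ``n_efficacy_records`` > 1 emits replicate records so the median of
    assays is exercised downstream.
    """
    if rng is None:
        rng = np.random.default_rng(scenario.seed + 1)
    if scenario.true_slopes.shape[1] != fractions.shape[1]:
        raise ValueError("slope length must equal the conformation count")
    records = []
    for lig in fractions.index:
        f = fractions.loc[lig].to_numpy(dtype=float)
        for pathway in scenario.true_slopes.index:
            base = float(scenario.true_slopes.loc[pathway].to_numpy() @ f)
            for r in range(scenario.n_efficacy_records):
                noise = rng.normal(0.0, scenario.efficacy_noise_sd) if scenario.efficacy_noise_sd else 0.0
                records.append(
                    EfficacyRecord(str(lig), str(pathway), base + noise, assay=f"synthetic-{r}")
                )
    return EfficacyTable(records)


def _spread_centers(
    rng: np.random.Generator,
    c: int,
    layout: FeatureLayout,
    theta_spread: float = np.pi,
    ca_range: tuple[float, float] = (8.0, 20.0),
    hb_range: tuple[float, float] = (3.0, 10.0),
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    theta = rng.uniform(-theta_spread, theta_spread, (c, layout.n_theta))
    ca = rng.uniform(*ca_range, (c, layout.n_ca))
    hb = rng.uniform(*hb_range, (c, layout.n_hb))
    return wrap_angles(theta), ca, hb


def _separable_centers(
    rng: np.random.Generator, c: int, layout: FeatureLayout,
    noise: tuple[float, float, float], factor: float = 4.0, max_tries: int = 500,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Draw centers until the pairwise separation invariant holds."""
    s2 = np.sqrt(2.0)
    w = REFERENCE_WEIGHTS
    floor = factor * s2 * (w.w_theta * noise[0] + w.w_ca * noise[1] + w.w_hb * noise[2])
    for _ in range(max_tries):
        th, ca, hb = _spread_centers(rng, c, layout)
        feats = [ConfigurationFeatures(th[i], ca[i], hb[i]) for i in range(c)]
        sep = min(
            combined_distance(feats[i], feats[j], w)
            for i in range(c) for j in range(i + 1, c)
        )
        if sep > floor:
            return th, ca, hb
    raise RuntimeError("could not draw separable centers; widen ranges or lower noise")


def _preset_separable_small(seed: int) -> SyntheticScenario:
    rng = np.random.default_rng(seed)
    layout = FeatureLayout(8, 6, 6)
    th, ca, hb = _separable_centers(rng, 3, layout, (0.10, 0.20, 0.20))
    mixtures = pd.DataFrame(
        [
            [0.80, 0.10, 0.10],
            [0.10, 0.80, 0.10],
            [0.10, 0.10, 0.80],
            [0.50, 0.30, 0.20],
            [0.20, 0.50, 0.30],
            [0.30, 0.20, 0.50],
        ],
        index=[f"L{i}" for i in range(1, 7)],
        columns=range(1, 4),
    )
    slopes = pd.DataFrame(
        [[100.0, 50.0, 0.0], [90.0, 10.0, 40.0]], index=list(PATHWAYS), columns=range(1, 4)
    )
    scen = SyntheticScenario(
        name="separable_small",
        centers_theta=th, centers_ca=ca, centers_hb=hb,
        mixtures=mixtures, true_slopes=slopes,
        noise_theta=0.10, noise_ca=0.20, noise_hb=0.20,
        efficacy_noise_sd=0.0, n_efficacy_records=1,
        frames_per_ligand=200, seed=seed,
    )
    scen.validate_separable()
    return scen


def _preset_noisy_medium(seed: int) -> SyntheticScenario:
    rng = np.random.default_rng(seed)
    layout = FeatureLayout(12, 10, 10)
    th, ca, hb = _spread_centers(rng, 4, layout)
    base = np.array(
        [
            [0.70, 0.10, 0.10, 0.10],
            [0.10, 0.70, 0.10, 0.10],
            [0.10, 0.10, 0.70, 0.10],
            [0.10, 0.10, 0.10, 0.70],
            [0.40, 0.30, 0.20, 0.10],
            [0.10, 0.20, 0.30, 0.40],
            [0.25, 0.25, 0.25, 0.25],
            [0.55, 0.05, 0.05, 0.35],
        ]
    )
    mixtures = pd.DataFrame(base, index=[f"L{i}" for i in range(1, 9)], columns=range(1, 5))
    slopes = pd.DataFrame(
        [[100.0, 60.0, 20.0, -10.0], [95.0, 15.0, 55.0, 5.0]],
        index=list(PATHWAYS), columns=range(1, 5),
    )
    return SyntheticScenario(
        name="noisy_medium",
        centers_theta=th, centers_ca=ca, centers_hb=hb,
        mixtures=mixtures, true_slopes=slopes,
        noise_theta=0.30, noise_ca=0.50, noise_hb=0.50,
        efficacy_noise_sd=5.0, n_efficacy_records=3,
        frames_per_ligand=150, seed=seed,
    )


# ligand codes follow the study system: reference agonist DAMGO plus ten
# other mu-opioid-receptor ligands and the apo receptor is not modeled.
PAPER_SHAPED_LIGANDS = (
    "DAM", "FEN", "LFT", "MPH", "TRV", "SR", "PZM", "FH", "C5", "C6", "MP",
)


def _preset_paper_shaped(seed: int) -> SyntheticScenario:
    rng = np.random.default_rng(seed)
    c = 14
    layout = FeatureLayout(40, 30, 30)
    th, ca, hb = _spread_centers(rng, c, layout)
    # occupancy pattern of the study system: some ligands dominated by a
    # single conformation, others spread over two or more; most conformations
    # are shared between ligands while a few are (nearly) ligand-specific
    mix = np.full((11, c), 0.2 / c)
    shared_pool = rng.permutation(c)[:8]
    for i in range(11):
        mix[i, rng.choice(shared_pool)] += 0.55
        mix[i, rng.choice(shared_pool)] += 0.15
        mix[i, rng.integers(0, c)] += 0.10
    mix /= mix.sum(axis=1, keepdims=True)
    mixtures = pd.DataFrame(mix, index=list(PAPER_SHAPED_LIGANDS), columns=range(1, c + 1))
    slopes_g = np.linspace(110.0, -20.0, c)
    slopes_b = rng.permutation(np.linspace(100.0, -15.0, c))
    slopes = pd.DataFrame(
        np.vstack([slopes_g, slopes_b]), index=list(PATHWAYS), columns=range(1, c + 1)
    )
    return SyntheticScenario(
        name="paper_shaped",
        centers_theta=th, centers_ca=ca, centers_hb=hb,
        mixtures=mixtures, true_slopes=slopes,
        noise_theta=0.15, noise_ca=0.30, noise_hb=0.30,
        efficacy_noise_sd=5.0, n_efficacy_records=3,
        # three pooled replicate runs of 50 frames per ligand
        frames_per_ligand=150, seed=seed,
    )


def grid_identifiability_dataset(seed: int = 11):
    """Dataset on which exactly one hyperparameter pattern is correct.

    The true 4-conformation structure lives only in the C-alpha feature
    block (3 A between adjacent centers); the torsion and H-bond blocks
    carry decoy partitions drawn independently per frame (2.1 rad and
    2.0 A scale).  Under complete linkage the weight pattern
    (0.25, 0.5, 0.25) separates the true conformations (worst
    within-conformation combined distance 0.25*2.1 + 0.25*2.0 = 1.03
    against a between-conformation floor of 0.5*3.0 = 1.5) while the
    hb-heavy and torsion-heavy patterns cannot (1.53 and 1.55 against
    0.75).  Targets are noise-free linear functions of the realized
    fractions, so the grid-search loss is ~0 exactly at hyperparameters
    that recover the planted conformations; the deterministic grid order
    then returns the planted point.

    Returns ``(features, targets, true_labels, planted, grid)``.
    """
    from .efficacy import GridSpec, Hyperparameters

    rng = np.random.default_rng(seed)
    n_t = n_c = n_h = 6
    theta_groups = np.array([-2.1, 0.0, 2.1])       # decoy partition, radians
    hb_groups = np.array([5.0, 7.0])                # decoy partition, Angstrom
    ca_centers = np.array([8.0, 11.0, 14.0, 17.0])  # true conformations
    mixtures = np.array(
        [
            [0.70, 0.10, 0.10, 0.10],
            [0.10, 0.70, 0.10, 0.10],
            [0.10, 0.10, 0.70, 0.10],
            [0.10, 0.10, 0.10, 0.70],
            [0.40, 0.30, 0.20, 0.10],
            [0.25, 0.25, 0.25, 0.25],
        ]
    )
    slopes = pd.DataFrame(
        [[100.0, 60.0, 20.0, -20.0], [90.0, 10.0, 50.0, -10.0]],
        index=list(PATHWAYS), columns=range(1, 5),
    )
    ligands = [f"L{i}" for i in range(1, 7)]
    n_frames = 40
    blocks, lids, labels = [], [], []
    target_rows = []
    for li, lig in enumerate(ligands):
        true = rng.choice(np.arange(1, 5), size=n_frames, p=mixtures[li])
        d_theta = rng.integers(0, theta_groups.size, n_frames)
        d_hb = rng.integers(0, hb_groups.size, n_frames)
        theta = wrap_angles(
            theta_groups[d_theta][:, None] + rng.normal(0.0, 0.05, (n_frames, n_t))
        )
        ca = ca_centers[true - 1][:, None] + rng.normal(0.0, 0.1, (n_frames, n_c))
        hb = hb_groups[d_hb][:, None] + rng.normal(0.0, 0.1, (n_frames, n_h))
        blocks.append(np.hstack([theta, ca, hb]))
        lids.extend([lig] * n_frames)
        labels.append(true)
        f = np.bincount(true, minlength=5)[1:] / n_frames
        target_rows.append(slopes.to_numpy() @ f)
    features = FeatureTable(np.vstack(blocks), FeatureLayout(n_t, n_c, n_h), lids)
    targets = pd.DataFrame(target_rows, index=ligands, columns=list(PATHWAYS))
    planted = Hyperparameters(
        weights=DistanceWeights(0.25, 0.5, 0.25), h=5, delta=1.0, c=4
    )
    grid = GridSpec(
        w_values=(0.25,),
        h_values=(2, 3, 4, 5, 6, 7),
        delta_values=(1.0, 2.0, 3.0),
        c_values=(2, 3, 4, 5, 6),
    )
    return features, targets, np.concatenate(labels), planted, grid


PRESETS = {
    "separable_small": _preset_separable_small,
    "noisy_medium": _preset_noisy_medium,
    "paper_shaped": _preset_paper_shaped,
}


def preset(name: str, seed: int = 7) -> SyntheticScenario:
    """Fixed, documented scenarios keyed by name."""
    try:
        factory = PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; available presets: {sorted(PRESETS)}"
        ) from None
    return factory(seed)
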