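"""Linear efficacy model over conformation populations.

Signaling efficacy of ligand ``l`` along a pathway is modeled as a
weighted sum over conformations::

    E_l = sum_n beta_n * f_{l,n}

where ``f_{l,n}`` is the equilibrium fraction of ligand ``l``'s ensemble
in conformation ``n`` and the slopes ``beta`` are the ordinary
least-squares solution (no intercept; fractions sum to one, so an
intercept would be confounded with a constant shift of all slopes).

Training uses nested leave-one-out (LOO): the outer loop holds out one
ligand for validation; the inner loop, run on each outer training set,
holds out one further ligand at a time to score a hyperparameter
combination (distance weights, cluster count h, bandwidth delta,
conformation count c).  The grid-search loss is the sum over both
pathways of the inner-LOO mean squared error.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .cluster import (
    ConformationClusterer,
    ConformationModel,
    conformation_fractions,
    fit_conformation_model,
    hierarchical_cluster,
    similarity_from_rmsd,
    spectral_conformations,
)
from .distance import (
    DistanceWeights,
    combine_components,
    component_matrices,
    cross_component_matrices,
)
from .featurize import FeatureTable

logger = logging.getLogger(__name__)

PATHWAYS = ("Gprotein", "barr2")

__all__ = [
    "PATHWAYS",
    "EfficacyRecord",
    "EfficacyTable",
    "median_efficacy",
    "EfficacyRegressor",
    "fit_slopes",
    "predict_efficacy",
    "Hyperparameters",
    "GridSpec",
    "inner_loo_loss",
    "grid_search",
    "outer_loo_cross_validation",
    "CrossValidationResult",
    "evaluate",
]


@dataclass(frozen=True)
class EfficacyRecord:
    """One literature efficacy measurement, % relative to the reference agonist."""

    ligand_id: str
    pathway: str
    value: float
    assay: str = ""

    def __post_init__(self) -> None:
        if self.pathway not in PATHWAYS:
            raise ValueError(f"unknown pathway {self.pathway!r}; expected one of {PATHWAYS}")
        if not np.isfinite(self.value):
            raise ValueError(f"non-finite efficacy for {self.ligand_id}/{self.pathway}")


class EfficacyTable:
    """Curated per-ligand, per-pathway efficacy records."""

    def __init__(self, records: Sequence[EfficacyRecord]) -> None:
        if not records:
            raise ValueError("efficacy table is empty")
        self.records = list(records)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(r.ligand_id, r.pathway, r.value, r.assay) for r in self.records],
            columns=["ligand_id", "pathway", "value", "assay"],
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "EfficacyTable":
        df = pd.read_csv(path)
        return cls(
            [
                EfficacyRecord(str(r.ligand_id), str(r.pathway), float(r.value),
                               "" if pd.isna(getattr(r, "assay", "")) else str(getattr(r, "assay", "")))
                for r in df.itertuples(index=False)
            ]
        )

    def median_view(self) -> pd.DataFrame:
        return median_efficacy(self)

    @property
    def ligands(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.records:
            seen.setdefault(r.ligand_id)
        return list(seen)


def median_efficacy(table: EfficacyTable) -> pd.DataFrame:
    """Per (ligand, pathway) sample median of reported efficacies.

    The median across assays is the regression target; for even record
    counts it is the mean of the two central values.
    """
    df = table.to_dataframe()
    out = df.pivot_table(index="ligand_id", columns="pathway", values="value", aggfunc="median")
    missing = out.isna()
    if missing.any().any():
        lig, path = next(
            (i, c) for i, c in itertools.product(out.index, out.columns) if missing.loc[i, c]
        )
        raise KeyError(f"no efficacy records for ligand {lig!r}, pathway {path!r}")
    # preserve first-appearance ligand order and canonical pathway order
    cols = [p for p in PATHWAYS if p in out.columns] + [
        p for p in out.columns if p not in PATHWAYS
    ]
    return out.loc[table.ligands, cols]


class EfficacyRegressor:
    """No-intercept least-squares map from fraction rows to efficacies.

    scikit-learn style estimator: ``fit(F, E)`` with ``F`` of shape
    (n_ligands, c) and ``E`` of shape (n_ligands,) or (n_ligands,
    n_pathways).  When the design is rank-deficient (fewer ligands than
    conformations is routine at this problem size) the minimum-norm
    solution is returned and a warning logged.  Fitted slopes live in
    ``coef_`` with shape (n_pathways, c).
    """

    def __init__(self) -> None:
        pass

    def get_params(self, deep: bool = True) -> dict:
        return {}

    def set_params(self, **params) -> "EfficacyRegressor":
        if params:
            raise ValueError(f"unknown parameters {sorted(params)}")
        return self

    def fit(self, F: np.ndarray, E: np.ndarray) -> "EfficacyRegressor":
        F = np.asarray(F, dtype=float)
        E = np.asarray(E, dtype=float)
        if F.ndim != 2:
            raise ValueError("fraction matrix must be 2-D")
        if F.shape[0] < 2:
            raise ValueError(f"need at least 2 training ligands, got {F.shape[0]}")
        single = E.ndim == 1
        E2 = E[:, None] if single else E
        if E2.shape[0] != F.shape[0]:
            raise ValueError("fraction and efficacy row counts differ")
        coef, _, rank, _ = np.linalg.lstsq(F, E2, rcond=None)
        if rank < F.shape[1]:
            logger.warning(
                "rank-deficient design (rank %d < %d conformations); "
                "returning the minimum-norm slope solution",
                rank,
                F.shape[1],
            )
        self.coef_ = coef.T  # (n_targets, c)
        self.rank_ = int(rank)
        self.n_features_in_ = F.shape[1]
        self._single_target = single
        return self

    def predict(self, F: np.ndarray) -> np.ndarray:
        if not hasattr(self, "coef_"):
            raise AttributeError("EfficacyRegressor is not fitted yet")
        F = np.atleast_2d(np.asarray(F, dtype=float))
        if F.shape[1] != self.n_features_in_:
            raise ValueError(
                f"fraction rows have {F.shape[1]} conformations, model expects "
                f"{self.n_features_in_}"
            )
        out = F @ self.coef_.T
        return out[:, 0] if self._single_target else out

    def score(self, F: np.ndarray, E: np.ndarray) -> float:
        E = np.asarray(E, dtype=float)
        pred = self.predict(F)
        ss_res = np.sum((E - pred) ** 2)
        ss_tot = np.sum((E - E.mean(axis=0)) ** 2)
        return float(1.0 - ss_res / ss_tot)


def fit_slopes(fractions: pd.DataFrame, efficacies: pd.DataFrame) -> pd.DataFrame:
    """OLS slopes per pathway; rows = pathways, columns = conformation ids."""
    common = [lig for lig in fractions.index if lig in efficacies.index]
    if len(common) < 2:
        raise ValueError("need at least 2 training ligands shared by fractions and targets")
    reg = EfficacyRegressor().fit(
        fractions.loc[common].to_numpy(), efficacies.loc[common].to_numpy()
    )
    return pd.DataFrame(reg.coef_, index=list(efficacies.columns), columns=fractions.columns)


def predict_efficacy(f_row: np.ndarray, slopes: np.ndarray) -> np.ndarray | float:
    """Dot product of a fraction row with per-pathway slope vectors."""
    f_row = np.asarray(f_row, dtype=float)
    slopes = np.asarray(slopes, dtype=float)
    beta = np.atleast_2d(slopes)
    if beta.shape[1] != f_row.size:
        raise ValueError(
            f"fraction row has {f_row.size} conformations, slopes have {beta.shape[1]}"
        )
    out = beta @ f_row
    return float(out[0]) if slopes.ndim == 1 else out


@dataclass(frozen=True)
class Hyperparameters:
    """One point of the distance/clustering hyperparameter space."""

    weights: DistanceWeights
    h: int
    delta: float
    c: int

    def __post_init__(self) -> None:
        if self.h < 2:
            raise ValueError(f"h must be >= 2, got {self.h}")
        if not (2 <= self.c <= self.h - 1):
            raise ValueError(f"c must satisfy 2 <= c <= h-1 (h={self.h}); got {self.c}")
        if self.delta <= 0:
            raise ValueError(f"delta must be positive, got {self.delta}")

    def as_dict(self) -> dict:
        return {
            "w_theta": self.weights.w_theta,
            "w_ca": self.weights.w_ca,
            "w_hb": self.weights.w_hb,
            "h": self.h,
            "delta": self.delta,
            "c": self.c,
        }


@dataclass(frozen=True)
class GridSpec:
    """Hyperparameter grid in the deterministic search order.

    Weight triples are generated from each ``w`` as the three patterns
    ``(w, w, 1-2w)``, ``(w, 1-2w, w)``, ``(1-2w, w, w)``; patterns with a
    negative entry are skipped with a logged notice (the printed grid
    value w = 1 is excluded this way).  ``c_values=None`` means the full
    range 2..h-1 for each h.
    """

    w_values: tuple[float, ...] = (0.1, 0.2, 0.25, 0.33)
    h_values: tuple[int, ...] = tuple(range(2, 41))
    delta_values: tuple[float, ...] = (1.0, 2.0, 3.0)
    c_values: tuple[int, ...] | None = None

    def weight_triples(self) -> list[DistanceWeights]:
        triples: list[DistanceWeights] = []
        seen: set[tuple[float, float, float]] = set()
        for w in self.w_values:
            for raw in ((w, w, 1 - 2 * w), (w, 1 - 2 * w, w), (1 - 2 * w, w, w)):
                if min(raw) < 0:
                    logger.info("skipping weight triple %s (negative entry)", raw)
                    continue
                # renormalize away float dust so the convex constraint holds exactly
                total = sum(raw)
                key = tuple(round(x / total, 12) for x in raw)
                if key in seen:
                    continue
                seen.add(key)
                triples.append(DistanceWeights(*(x / total for x in raw)))
        return triples

    def points(self) -> list[Hyperparameters]:
        pts = []
        for wt in self.weight_triples():
            for h in sorted(self.h_values):
                cs = range(2, h) if self.c_values is None else [
                    c for c in sorted(self.c_values) if 2 <= c <= h - 1
                ]
                for delta in sorted(self.delta_values):
                    for c in cs:
                        pts.append(Hyperparameters(weights=wt, h=h, delta=delta, c=c))
        if not pts:
            raise ValueError("hyperparameter grid is empty after validity filtering")
        return pts

    @staticmethod
    def single(hp: Hyperparameters) -> "GridSpec":
        return _SinglePointGrid(hp)


class _SinglePointGrid(GridSpec):
    """Degenerate grid holding one explicit hyperparameter point."""

    def __init__(self, hp: Hyperparameters) -> None:
        object.__setattr__(self, "w_values", ())
        object.__setattr__(self, "h_values", (hp.h,))
        object.__setattr__(self, "delta_values", (hp.delta,))
        object.__setattr__(self, "c_values", (hp.c,))
        object.__setattr__(self, "_hp", hp)

    def weight_triples(self) -> list[DistanceWeights]:
        return [self._hp.weights]

    def points(self) -> list[Hyperparameters]:
        return [self._hp]


def _assign_by_medoid(dist_rows: np.ndarray, cluster_to_conf: np.ndarray) -> np.ndarray:
    """Nearest-medoid conformation labels; ties -> lowest conformation id."""
    labels = np.empty(dist_rows.shape[0], dtype=int)
    for i, row in enumerate(dist_rows):
        candidates = np.flatnonzero(np.isclose(row, row.min(), rtol=0.0, atol=1e-12))
        labels[i] = int(cluster_to_conf[candidates].min())
    return labels


def _fraction_row(labels: np.ndarray, c: int) -> np.ndarray:
    counts = np.bincount(labels, minlength=c + 1)[1 : c + 1]
    return counts / counts.sum()


def _evaluate_points(
    features: FeatureTable,
    targets: pd.DataFrame,
    points: Sequence[Hyperparameters],
    components: tuple[np.ndarray, np.ndarray, np.ndarray] | None = None,
) -> list[dict[str, float]]:
    """Inner-LOO loss of each hyperparameter point, sharing heavy work.

    Per-component distance matrices are computed once; the hierarchical
    stage is cached per (weights, subtraining fold, h); the spectral stage
    per (delta, c).  Returns, per point, the per-pathway mean squared
    subtest error.
    """
    ligands = [lig for lig in targets.index]
    if len(ligands) < 3:
        raise ValueError("inner LOO needs at least 3 training ligands")
    lig_idx = {
        lig: np.flatnonzero(features.ligand_ids == lig) for lig in ligands
    }
    for lig, idx in lig_idx.items():
        if idx.size == 0:
            raise ValueError(f"ligand {lig!r} has no frames in the feature table")
    if components is None:
        components = component_matrices(features.theta, features.ca, features.hb)
    d_th, d_ca, d_hb = components
    pathways = list(targets.columns)

    # group points by weight triple, preserving order
    losses: dict[int, dict[str, float]] = {
        k: {p: 0.0 for p in pathways} for k in range(len(points))
    }
    by_weights: dict[tuple[float, float, float], list[int]] = {}
    for k, pt in enumerate(points):
        key = (pt.weights.w_theta, pt.weights.w_ca, pt.weights.w_hb)
        by_weights.setdefault(key, []).append(k)

    ca_all = features.ca
    for wkey, kidx in by_weights.items():
        D = combine_components(d_th, d_ca, d_hb, DistanceWeights(*wkey))
        for held in ligands:
            train_ligs = [lig for lig in ligands if lig != held]
            sub_idx = np.concatenate([lig_idx[lig] for lig in train_ligs])
            held_idx = lig_idx[held]
            D_sub = D[np.ix_(sub_idx, sub_idx)]
            sub_lids = features.ligand_ids[sub_idx]
            # stage-1 cache per h
            by_h: dict[int, list[int]] = {}
            for k in kidx:
                by_h.setdefault(points[k].h, []).append(k)
            for h, kh in sorted(by_h.items()):
                try:
                    hier = hierarchical_cluster(D_sub, h)
                except ValueError as exc:
                    raise ValueError(f"subtraining without {held!r}: {exc}") from exc
                ca_med = ca_all[sub_idx[hier.medoid_frames]]
                diff = ca_med[:, None, :] - ca_med[None, :, :]
                D_rmsd = np.sqrt(np.mean(diff**2, axis=-1))
                np.fill_diagonal(D_rmsd, 0.0)
                d_held_to_med = D[np.ix_(held_idx, sub_idx[hier.medoid_frames])]
                by_dc: dict[tuple[float, int], list[int]] = {}
                for k in kh:
                    by_dc.setdefault((points[k].delta, points[k].c), []).append(k)
                spectral_cache: dict[tuple[float, int], np.ndarray] = {}
                for (delta, c), kdc in sorted(by_dc.items()):
                    S = similarity_from_rmsd(D_rmsd, delta)
                    ctc = spectral_cache.get((delta, c))
                    if ctc is None:
                        ctc = spectral_conformations(S, c)
                        spectral_cache[(delta, c)] = ctc
                    frame_labels = ctc[hier.labels - 1]
                    fr = conformation_fractions(frame_labels, sub_lids, c, train_ligs)
                    slopes = fit_slopes(fr, targets.loc[train_ligs])
                    held_labels = _assign_by_medoid(d_held_to_med, ctc)
                    f_held = _fraction_row(held_labels, c)
                    pred = slopes.to_numpy() @ f_held
                    for k in kdc:
                        for pi, p in enumerate(pathways):
                            err = float(targets.loc[held, p]) - float(pred[pi])
                            losses[k][p] += err**2
    n = len(ligands)
    return [{p: losses[k][p] / n for p in pathways} for k in range(len(points))]


def inner_loo_loss(
    features: FeatureTable,
    targets: pd.DataFrame,
    hp: Hyperparameters,
    components: tuple[np.ndarray, np.ndarray, np.ndarray] | None = None,
) -> tuple[dict[str, float], float]:
    """Leave-one-ligand-out loss of one hyperparameter point.

    For each training ligand the conformation model is refit on the
    remaining ligands' frames, the held ligand's frames are assigned by
    nearest medoid, slopes are refit and the ligand's efficacy predicted.
    Returns the per-pathway mean squared error and their sum.
    """
    per_pathway = _evaluate_points(features, targets, [hp], components)[0]
    return per_pathway, float(sum(per_pathway.values()))


def grid_search(
    features: FeatureTable,
    targets: pd.DataFrame,
    grid: GridSpec,
    return_trace: bool = False,
):
    """Argmin of the summed inner-LOO loss over the hyperparameter grid.

    Ties resolve to the first point in the deterministic grid order
    (weights, then h, then delta, then c ascending).  A single-point grid
    is returned without evaluation.
    """
    points = grid.points()
    if len(points) == 1:
        if return_trace:
            return points[0], pd.DataFrame(
                [points[0].as_dict() | {"loss": np.nan}]
            )
        return points[0]
    losses = _evaluate_points(features, targets, points)
    totals = np.array([sum(l.values()) for l in losses])
    # losses within numerical noise of the minimum are ties; the first point
    # in grid order wins (otherwise float dust would decide between them)
    tol = 1e-9 + 1e-9 * totals.min()
    best_k = int(np.flatnonzero(totals <= totals.min() + tol)[0])
    if return_trace:
        trace = pd.DataFrame(
            [
                pt.as_dict() | {f"loss_{p}": l[p] for p in l} | {"loss": t}
                for pt, l, t in zip(points, losses, totals)
            ]
        )
        return points[best_k], trace
    return points[best_k]


@dataclass
class CrossValidationResult:
    """Outputs of the outer leave-one-out cross-validation."""

    predictions: pd.DataFrame          # held-out prediction per ligand x pathway
    prediction_sd: pd.DataFrame        # SD of each ligand's prediction across models
    all_predictions: dict[str, pd.DataFrame]  # per CV model: every ligand's prediction
    fold_hyperparameters: dict[str, Hyperparameters]
    slope_mean: pd.DataFrame           # pathway x conformation, across-model mean
    slope_sd: pd.DataFrame
    slopes_per_model: dict[str, pd.DataFrame]
    metrics: pd.DataFrame              # pathway x {MAE, RMSE, R2}
    reference_model: ConformationModel
    reference_fractions: pd.DataFrame
    reference_slopes: pd.DataFrame
    targets: pd.DataFrame


def _conf_medoid_features(model: ConformationModel, features: FeatureTable):
    vals = features.values[model.conformation_medoids]
    lay = features.layout
    return vals[:, lay.theta_slice], vals[:, lay.ca_slice], vals[:, lay.hb_slice]


def _align_slopes_to_reference(
    fold_model: ConformationModel,
    fold_features: FeatureTable,
    fold_slopes: pd.DataFrame,
    ref_model: ConformationModel,
    ref_features: FeatureTable,
    weights: DistanceWeights,
) -> pd.DataFrame:
    """Express a fold's slopes in the reference conformation indexing.

    Each fold conformation is matched to the reference conformation whose
    medoid is nearest under the combined distance; collisions are averaged
    and unmatched reference conformations are NaN.
    """
    f_th, f_ca, f_hb = _conf_medoid_features(fold_model, fold_features)
    r_th, r_ca, r_hb = _conf_medoid_features(ref_model, ref_features)
    d_th, d_ca, d_hb = cross_component_matrices(f_th, f_ca, f_hb, r_th, r_ca, r_hb)
    D = combine_components(d_th, d_ca, d_hb, weights)
    mapping = np.argmin(D, axis=1)  # fold conf j -> ref conf mapping[j]
    pathways = list(fold_slopes.index)
    sums = np.zeros((len(pathways), ref_model.c))
    counts = np.zeros(ref_model.c)
    for j in range(fold_model.c):
        sums[:, mapping[j]] += fold_slopes.to_numpy()[:, j]
        counts[mapping[j]] += 1
    with np.errstate(invalid="ignore"):
        aligned = sums / counts
    return pd.DataFrame(aligned, index=pathways, columns=range(1, ref_model.c + 1))


def outer_loo_cross_validation(
    features: FeatureTable,
    efficacies: EfficacyTable | pd.DataFrame,
    grid: GridSpec,
    medoid_metric: str = "ca_features",
) -> CrossValidationResult:
    """Leave-one-ligand-out cross-validation of the full pipeline.

    For each ligand L: hyperparameters are selected by grid search on the
    remaining ligands, the conformation model and slopes are refit on all
    of them, and L is predicted through nearest-medoid assignment of its
    frames.  Also reports the SD of every ligand's prediction across the
    n cross-validation models and the across-model mean/SD of the slopes
    (folds aligned to a reference model fit on all ligands).
    """
    targets = (
        median_efficacy(efficacies) if isinstance(efficacies, EfficacyTable) else efficacies
    )
    ligands = [lig for lig in targets.index]
    if len(ligands) < 4:
        raise ValueError(f"outer LOO needs at least 4 ligands, got {len(ligands)}")
    missing = [lig for lig in ligands if lig not in set(features.ligand_ids)]
    if missing:
        raise ValueError(f"no frames for ligands {missing}")
    pathways = list(targets.columns)

    fold_hps: dict[str, Hyperparameters] = {}
    fold_models: dict[str, ConformationModel] = {}
    fold_features: dict[str, FeatureTable] = {}
    fold_slopes: dict[str, pd.DataFrame] = {}
    all_predictions: dict[str, pd.DataFrame] = {}

    for held in ligands:
        train_ligs = [lig for lig in ligands if lig != held]
        train_tab = features.for_ligands(train_ligs)
        hp = grid_search(train_tab, targets.loc[train_ligs], grid)
        model = fit_conformation_model(
            train_tab, h=hp.h, delta=hp.delta, c=hp.c, weights=hp.weights,
            medoid_metric=medoid_metric,
        )
        fractions = model.clusterer.fractions(train_tab.ligand_ids, train_ligs)
        slopes = fit_slopes(fractions, targets.loc[train_ligs])
        held_tab = features.for_ligands([held])
        held_labels = model.clusterer.predict(held_tab)
        f_held = _fraction_row(held_labels, hp.c)

        preds = pd.DataFrame(index=ligands, columns=pathways, dtype=float)
        preds.loc[train_ligs] = fractions.loc[train_ligs].to_numpy() @ slopes.to_numpy().T
        preds.loc[held] = slopes.to_numpy() @ f_held

        fold_hps[held] = hp
        fold_models[held] = model
        fold_features[held] = train_tab
        fold_slopes[held] = slopes
        all_predictions[held] = preds

    held_out = pd.DataFrame(
        [all_predictions[lig].loc[lig] for lig in ligands], index=ligands
    )[pathways]
    stacked = np.stack([all_predictions[m].to_numpy() for m in ligands])
    prediction_sd = pd.DataFrame(stacked.std(axis=0, ddof=1), index=ligands, columns=pathways)

    # reference conformational space: the modal fold hyperparameters, fit on all ligands
    hp_counts: dict[Hyperparameters, int] = {}
    for hp in fold_hps.values():
        hp_counts[hp] = hp_counts.get(hp, 0) + 1
    ref_hp = max(hp_counts, key=lambda hp: (hp_counts[hp], -list(fold_hps.values()).index(hp)))
    ref_model = fit_conformation_model(
        features.for_ligands(ligands), h=ref_hp.h, delta=ref_hp.delta, c=ref_hp.c,
        weights=ref_hp.weights, medoid_metric=medoid_metric,
    )
    ref_tab = features.for_ligands(ligands)
    ref_fractions = ref_model.clusterer.fractions(ref_tab.ligand_ids, ligands)
    ref_slopes = fit_slopes(ref_fractions, targets)

    aligned = []
    for held in ligands:
        if fold_models[held].c != ref_model.c:
            logger.warning(
                "fold without %s chose c=%d (reference c=%d); excluded from slope summary",
                held, fold_models[held].c, ref_model.c,
            )
            continue
        aligned.append(
            _align_slopes_to_reference(
                fold_models[held], fold_features[held], fold_slopes[held],
                ref_model, ref_tab, ref_hp.weights,
            )
        )
    stack = np.stack([a.to_numpy() for a in aligned])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        slope_mean = pd.DataFrame(
            np.nanmean(stack, axis=0), index=pathways, columns=range(1, ref_model.c + 1)
        )
        slope_sd = pd.DataFrame(
            np.nanstd(stack, axis=0, ddof=1) if stack.shape[0] > 1 else np.zeros_like(stack[0]),
            index=pathways, columns=range(1, ref_model.c + 1),
        )

    metrics = evaluate(held_out, targets)
    return CrossValidationResult(
        predictions=held_out,
        prediction_sd=prediction_sd,
        all_predictions=all_predictions,
        fold_hyperparameters=fold_hps,
        slope_mean=slope_mean,
        slope_sd=slope_sd,
        slopes_per_model=fold_slopes,
        metrics=metrics,
        reference_model=ref_model,
        reference_fractions=ref_fractions,
        reference_slopes=ref_slopes,
        targets=targets,
    )


def evaluate(predictions: pd.DataFrame, observed: pd.DataFrame) -> pd.DataFrame:
    """MAE, RMSE and R^2 per pathway of predictions against observed medians."""
    common = [lig for lig in observed.index if lig in predictions.index]
    if len(common) < 2:
        raise ValueError("evaluation needs at least 2 ligands")
    rows = {}
    for p in observed.columns:
        obs = observed.loc[common, p].to_numpy(dtype=float)
        pred = predictions.loc[common, p].to_numpy(dtype=float)
        err = pred - obs
        mae = float(np.mean(np.abs(err)))
        rmse = float(np.sqrt(np.mean(err**2)))
        ss_tot = float(np.sum((obs - obs.mean()) ** 2))
        if ss_tot == 0.0:
            warnings.warn(f"observed efficacies for {p} have zero variance; R2 undefined")
            r2 = float("nan")
        else:
            r2 = float(1.0 - np.sum(err**2) / ss_tot)
        rows[p] = {"MAE": mae, "RMSE": rmse, "R2": r2}
    return pd.DataFrame(rows).T
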