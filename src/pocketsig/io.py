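"""Serialization glue: trained-model JSON, run reports, fraction tables."""

from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .cluster import ConformationClusterer
from .efficacy import Hyperparameters
from .distance import DistanceWeights
from .featurize import FeatureLayout, FeatureTable

__all__ = ["TrainedModel", "save_model", "load_model", "write_report"]


@dataclass
class TrainedModel:
    """A fitted conformation model plus per-pathway slopes, ready to predict."""

    clusterer: ConformationClusterer
    slopes: pd.DataFrame  # pathway x conformation (1..c)

    def predict(self, features: FeatureTable) -> pd.Series:
        """Efficacy per pathway for one new ligand's ensemble."""
        labels = self.clusterer.predict(features)
        counts = np.bincount(labels, minlength=self.clusterer.c + 1)[1:]
        f = counts / counts.sum()
        return pd.Series(self.slopes.to_numpy() @ f, index=self.slopes.index)

    @property
    def hyperparameters(self) -> Hyperparameters:
        cl = self.clusterer
        return Hyperparameters(
            weights=DistanceWeights(*cl.weights), h=cl.h, delta=cl.delta, c=cl.c
        )


def save_model(model: TrainedModel, path: str | Path) -> None:
    cl = model.clusterer
    cl._check_fitted()
    payload = {
        "format": "pocketsig-model-v1",
        "hyperparameters": {
            "weights": list(cl.weights),
            "h": cl.h,
            "delta": cl.delta,
            "c": cl.c,
            "medoid_metric": cl.medoid_metric,
        },
        "layout": [cl.layout_.n_theta, cl.layout_.n_ca, cl.layout_.n_hb],
        "cluster_to_conf": cl.cluster_to_conf_.tolist(),
        "medoid_features": cl.medoid_features_.tolist(),
        "conformation_medoids": cl.conformation_medoids_.tolist(),
        "slopes": {
            "pathways": list(model.slopes.index),
            "values": model.slopes.to_numpy().tolist(),
        },
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def load_model(path: str | Path) -> TrainedModel:
    d = json.loads(Path(path).read_text())
    if d.get("format") != "pocketsig-model-v1":
        raise ValueError(f"{path} is not a pocketsig model file")
    hp = d["hyperparameters"]
    cl = ConformationClusterer(
        h=hp["h"], delta=hp["delta"], c=hp["c"],
        weights=tuple(hp["weights"]), medoid_metric=hp["medoid_metric"],
    )
    lay = FeatureLayout(*d["layout"])
    med = np.array(d["medoid_features"], dtype=float)
    cl.layout_ = lay
    cl.cluster_to_conf_ = np.array(d["cluster_to_conf"], dtype=int)
    cl.conformation_medoids_ = np.array(d["conformation_medoids"], dtype=int)
    cl.medoid_features_ = med
    cl.medoid_theta_ = med[:, lay.theta_slice]
    cl.medoid_ca_ = med[:, lay.ca_slice]
    cl.medoid_hb_ = med[:, lay.hb_slice]
    cl.labels_ = np.empty(0, dtype=int)  # frame labels are not serialized
    slopes = pd.DataFrame(
        d["slopes"]["values"],
        index=d["slopes"]["pathways"],
        columns=range(1, hp["c"] + 1),
    )
    return TrainedModel(clusterer=cl, slopes=slopes)


def write_report(path: str | Path, seed: int, config: dict, **sections) -> None:
    """JSON run report: config echo + hash, seed, versions, result sections."""
    import pocketsig

    config_json = json.dumps(config, sort_keys=True, default=str)
    payload = {
        "seed": seed,
        "config": config,
        "config_sha256": hashlib.sha256(config_json.encode()).hexdigest(),
        "versions": {
            "pocketsig": pocketsig.__version__,
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    payload.update(sections)
    Path(path).write_text(json.dumps(payload, indent=1, default=str))
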