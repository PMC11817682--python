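import numpy as np
import pytest

from pocketsig.distance import DistanceWeights
from pocketsig.synthetic import (
    make_efficacies,
    preset,
    realized_fractions,
    sample_ensembles,
)

REFERENCE_W = DistanceWeights(0.25, 0.25, 0.5)


@pytest.fixture(scope="session")
def separable_data():
    """separable_small scenario with sampled ensembles and exact targets."""
    scen = preset("separable_small", seed=7)
    table, labels = sample_ensembles(scen)
    fractions = realized_fractions(scen, labels, table.ligand_ids)
    efficacies = make_efficacies(scen, fractions)
    return {
        "scenario": scen,
        "table": table,
        "labels": labels,
        "fractions": fractions,
        "efficacies": efficacies,
    }


@pytest.fixture(scope="session")
def fitted_model(separable_data):
    from pocketsig.cluster import fit_conformation_model

    return fit_conformation_model(
        separable_data["table"], h=12, delta=2.0, c=3, weights=REFERENCE_W
    )


@pytest.fixture(scope="session")
def toy_chain():
    """Five-residue toy chain with prescribed torsions and its feature spec."""
    from pocketsig.featurize import build_default_spec, derive_hbond_pairs
    from pocketsig.toys import make_toy_structures

    residues = [(1, "MET"), (2, "SER"), (3, "GLN"), (4, "MET"), (5, "LEU")]
    torsions = {
        (2, "phi"): np.deg2rad(-75.0),
        (2, "psi"): np.deg2rad(130.0),
        (3, "chi1"): np.deg2rad(60.0),
        (4, "chi2"): np.deg2rad(-170.0),
    }
    toy = make_toy_structures(residues, torsions)
    ens = toy.to_ensemble("toy")
    bw = {i: f"1.{45 + i}" for i in range(1, 6)}
    spec = build_default_spec(ens, bw, torsion_ranges=[(1, 5)], ca_anchors=[1, 3, 5])
    spec = derive_hbond_pairs(spec, ens, cutoff=8.0)
    return {"residues": residues, "torsions": torsions, "toy": toy, "spec": spec, "bw": bw}


def brute_force_combined(fi, fj, w: DistanceWeights) -> float:
    """Independent per-element oracle for the combined configuration distance."""
    acc = 0.0
    for k in range(len(fi.theta)):
        d = abs(fi.theta[k] - fj.theta[k])
        acc += min(d, 2 * np.pi - d) ** 2
    out = w.w_theta * np.sqrt(acc / len(fi.theta))
    for name, wk in (("ca", w.w_ca), ("hb", w.w_hb)):
        a, b = getattr(fi, name), getattr(fj, name)
        acc = sum((a[k] - b[k]) ** 2 for k in range(len(a)))
        out += wk * np.sqrt(acc / len(a))
    return out
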