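"""Efficacy response functions and activation scores.

For a structural feature x (a torsion angle or an interatomic distance),
the efficacy response function (ERF) of a pathway is the slope-weighted
sum of the per-conformation probability densities of that feature::

    r(x) = sum_c  beta_bar_c * p_c(x)

where ``beta_bar_c`` is the across-cross-validation-model mean regression
slope of conformation c.  Because slopes may be negative an ERF can be
negative, and it is not normalized: it is a map of which feature values
favor (high ERF) or disfavor (low ERF) activation along a pathway.

Densities are histogram estimates.  Torsional samples are triplicated at
x +/- 2*pi before binning so the estimate is continuous across the
periodic boundary, then renormalized so the numerical integral over
[-pi, pi) is one.

Two gated combinations of the two pathways' ERFs rank features: the
general activation function a(x) is nonzero where both ERFs share a
sign, the selective activation function s(x) where they oppose (positive
s marks G-protein-favoring, negative beta-arrestin-favoring values).
Their integral scores use the rectangle rule on a 1000-point grid.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ERFCurve",
    "ActivationProfile",
    "make_grid",
    "conformation_density",
    "efficacy_response",
    "general_activation",
    "selective_activation",
    "activation_score",
    "build_activation_profile",
    "rank_features",
    "profiles_to_tidy",
]

N_GRID = 1000
DEFAULT_BINS = 60
PERIODIC_DOMAIN = (-np.pi, np.pi)


def make_grid(domain: tuple[float, float], n: int = N_GRID) -> np.ndarray:
    """Midpoints of ``n`` equal subintervals of the domain."""
    lo, hi = domain
    if not hi > lo:
        raise ValueError(f"empty domain {domain}")
    spacing = (hi - lo) / n
    return lo + spacing * (np.arange(n) + 0.5)


@dataclass
class ERFCurve:
    """One feature's efficacy response function sampled on the grid."""

    feature_id: str
    pathway: str
    grid: np.ndarray
    values: np.ndarray
    domain: tuple[float, float]
    periodic: bool

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.grid.shape != self.values.shape:
            raise ValueError("grid and values differ in shape")
        step = np.diff(self.grid)
        if self.grid.size > 1 and not np.allclose(step, step[0], rtol=1e-9, atol=1e-12):
            raise ValueError("grid is not evenly spaced")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite ERF values")


@dataclass
class ActivationProfile:
    """General and selective activation of one feature, with scores."""

    feature_id: str
    grid: np.ndarray
    a_values: np.ndarray
    s_values: np.ndarray
    general_score: float
    selective_score: float
    domain: tuple[float, float]
    periodic: bool

    def __post_init__(self) -> None:
        if np.any(self.a_values * self.s_values != 0.0):
            raise ValueError("general and selective activation overlap (gates not exclusive)")


def conformation_density(
    samples: np.ndarray,
    domain: tuple[float, float] | None = None,
    periodic: bool = False,
    bins: int = DEFAULT_BINS,
    grid: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Histogram density of one feature within one conformation.

    Periodic features use the domain [-pi, pi); each sample is triplicated
    at +/- 2*pi before binning and the result renormalized so the
    1000-point rectangle-rule integral over the period is exactly one.
    Returns ``(grid, density)``.
    """
    samples = np.asarray(samples, dtype=float).ravel()
    if samples.size == 0:
        raise ValueError("conformation has no samples for this feature")
    if periodic:
        domain = PERIODIC_DOMAIN
        if np.any(samples < -np.pi) or np.any(samples >= np.pi):
            raise ValueError("periodic samples must lie in [-pi, pi)")
        data = np.concatenate([samples, samples + 2 * np.pi, samples - 2 * np.pi])
        edges = np.linspace(-3 * np.pi, 3 * np.pi, 3 * bins + 1)
    else:
        if domain is None:
            domain = (float(samples.min()) - 0.5, float(samples.max()) + 0.5)
        data = samples
        edges = np.linspace(domain[0], domain[1], bins + 1)
    counts, edges = np.histogram(data, bins=edges, density=True)
    if grid is None:
        grid = make_grid(domain)
    idx = np.clip(np.searchsorted(edges, grid, side="right") - 1, 0, counts.size - 1)
    values = counts[idx]
    spacing = (domain[1] - domain[0]) / grid.size
    integral = spacing * values.sum()
    if integral <= 0:
        raise ValueError("density integrates to zero on the requested domain")
    return grid, values / integral


def efficacy_response(
    densities: Sequence[np.ndarray],
    mean_slopes: np.ndarray,
    grid: np.ndarray,
    feature_id: str = "",
    pathway: str = "",
    domain: tuple[float, float] | None = None,
    periodic: bool = False,
) -> ERFCurve:
    """Slope-weighted sum of per-conformation densities."""
    mean_slopes = np.asarray(mean_slopes, dtype=float)
    if len(densities) != mean_slopes.size:
        raise ValueError(
            f"{len(densities)} densities but {mean_slopes.size} slopes"
        )
    stack = np.stack([np.asarray(d, dtype=float) for d in densities])
    if stack.shape[1] != grid.size:
        raise ValueError("densities and grid differ in length")
    values = mean_slopes @ stack
    if domain is None:
        domain = (float(grid[0]), float(grid[-1]))
    return ERFCurve(
        feature_id=feature_id, pathway=pathway, grid=grid, values=values,
        domain=domain, periodic=periodic,
    )


def _gated_min(r_g: np.ndarray, r_b: np.ndarray, same_sign: bool) -> np.ndarray:
    sg, sb = np.sign(r_g), np.sign(r_b)
    gate = (sg == sb) if same_sign else (sg == -sb)
    gate &= (sg != 0) & (sb != 0)
    return np.where(gate, sg * np.minimum(np.abs(r_g), np.abs(r_b)), 0.0)


def _check_shared_grid(r_g: ERFCurve, r_b: ERFCurve) -> None:
    if r_g.grid.shape != r_b.grid.shape or not np.allclose(r_g.grid, r_b.grid):
        raise ValueError("ERF curves are not on a shared grid")


def general_activation(r_g: ERFCurve, r_b: ERFCurve) -> np.ndarray:
    """a(x): sign-gated minimum magnitude where both ERFs share a sign."""
    _check_shared_grid(r_g, r_b)
    return _gated_min(r_g.values, r_b.values, same_sign=True)


def selective_activation(r_g: ERFCurve, r_b: ERFCurve) -> np.ndarray:
    """s(x): sign-gated minimum magnitude where the ERFs oppose.

    Positive values mark G-protein-favoring feature values, negative ones
    beta-arrestin-favoring values.
    """
    _check_shared_grid(r_g, r_b)
    return _gated_min(r_g.values, r_b.values, same_sign=False)


def activation_score(values: np.ndarray, domain: tuple[float, float]) -> float:
    """Rectangle-rule integral: grid spacing times the sum over the grid."""
    values = np.asarray(values, dtype=float)
    lo, hi = domain
    if not hi > lo:
        raise ValueError(f"empty domain {domain}")
    spacing = (hi - lo) / values.size
    return float(spacing * values.sum())


def build_activation_profile(
    feature_id: str,
    samples_by_conformation: Sequence[np.ndarray],
    slopes_g: np.ndarray,
    slopes_b: np.ndarray,
    periodic: bool,
    domain: tuple[float, float] | None = None,
    bins: int = DEFAULT_BINS,
) -> tuple[ERFCurve, ERFCurve, ActivationProfile]:
    """ERFs for both pathways plus the activation profile of one feature."""
    if periodic:
        domain = PERIODIC_DOMAIN
    elif domain is None:
        allv = np.concatenate([np.asarray(s, float).ravel() for s in samples_by_conformation])
        domain = (float(allv.min()) - 0.5, float(allv.max()) + 0.5)
    grid = make_grid(domain)
    densities = [
        conformation_density(s, domain=domain, periodic=periodic, bins=bins, grid=grid)[1]
        for s in samples_by_conformation
    ]
    r_g = efficacy_response(densities, slopes_g, grid, feature_id, "Gprotein", domain, periodic)
    r_b = efficacy_response(densities, slopes_b, grid, feature_id, "barr2", domain, periodic)
    a = general_activation(r_g, r_b)
    s = selective_activation(r_g, r_b)
    profile = ActivationProfile(
        feature_id=feature_id,
        grid=grid,
        a_values=a,
        s_values=s,
        general_score=activation_score(a, domain),
        selective_score=activation_score(s, domain),
        domain=domain,
        periodic=periodic,
    )
    return r_g, r_b, profile


def rank_features(
    profiles: Sequence[ActivationProfile],
    by: str = "general",
    top_fraction: float | None = None,
) -> list[ActivationProfile]:
    """Stable descending sort by absolute activation score.

    ``top_fraction`` (e.g. 0.02 for the top 2%) truncates the ranking to
    ``ceil(fraction * n)`` features.
    """
    if not profiles:
        raise ValueError("no profiles to rank")
    if by == "general":
        key = lambda p: abs(p.general_score)
    elif by == "selective":
        key = lambda p: abs(p.selective_score)
    else:
        raise ValueError(f"unknown ranking key {by!r}; use 'general' or 'selective'")
    ranked = sorted(profiles, key=key, reverse=True)  # timsort: ties keep input order
    if top_fraction is not None:
        if not 0 < top_fraction <= 1:
            raise ValueError("top_fraction must be in (0, 1]")
        ranked = ranked[: int(np.ceil(top_fraction * len(profiles)))]
    return ranked


def profiles_to_tidy(
    curves: Mapping[str, tuple[ERFCurve, ERFCurve, ActivationProfile]],
) -> pd.DataFrame:
    """Long-format table (feature_id, x, r_G, r_b, a, s) for CSV export."""
    frames = []
    for fid, (r_g, r_b, prof) in curves.items():
        frames.append(
            pd.DataFrame(
                {
                    "feature_id": fid,
                    "x": prof.grid,
                    "r_G": r_g.values,
                    "r_b": r_b.values,
                    "a": prof.a_values,
                    "s": prof.s_values,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def scores_table(profiles: Sequence[ActivationProfile]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "feature_id": [p.feature_id for p in profiles],
            "general_score": [p.general_score for p in profiles],
            "selective_score": [p.selective_score for p in profiles],
        }
    )


def plot_profile(r_g: ERFCurve, r_b: ERFCurve, profile: ActivationProfile, path: str | Path) -> None:
    """Convenience per-feature curve figure (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3))
    ax.plot(profile.grid, r_g.values, label="r_G")
    ax.plot(profile.grid, r_b.values, label="r_barr2")
    ax.plot(profile.grid, profile.a_values, label="a(x)", ls="--")
    ax.plot(profile.grid, profile.s_values, label="s(x)", ls=":")
    ax.axhline(0, color="k", lw=0.5)
    ax.set_xlabel(profile.feature_id)
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
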