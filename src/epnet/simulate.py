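"""Synthetic multi-observer rating datasets with controlled reliability.

A shared latent-Gaussian machinery generates every item type so the
variance-ratio -> ICC link stays transparent.  For community i, observer j and
item q:

    latent truth   t_iq = mu_{r(i),q} + c_iq,          c_iq ~ N(0, s_c^2)
    observer view  z_ijq = t_iq + b_jq + e_ijq,        b_jq ~ N(0, s_o^2),
                                                       e_ijq ~ N(0, s_e^2)

where mu_{r,q} is a region-specific baseline (regional prevalence contrasts),
b_jq a per-observer column effect shared across communities and e_ijq residual
noise.  Ordinal items discretize z with equally spaced cutpoints, counts are
rounded exponentiated latents, and binary items draw the truth as
Bernoulli(logistic(t)) then flip each observer's copy with a small
miscoding probability.  On the continuous latent scale the expected ICC is
the variance ratio s_c^2 / (s_c^2 + s_o^2 + s_e^2); thresholding attenuates
it, so that ratio is an upper-bound target for discrete items.

The default scenario mirrors the study design: 86 communities over five
countries (37 Canada / 20 Brazil-Colombia / 29 India-China; 50 urban, 36
rural), 3 observers, and regional baselines that reproduce the qualitative
contrasts of the descriptive results (sidewalks and crosswalks far more
prevalent in Canada than in India/China, landscaping richer in Canada, more
disorder in rural communities' regions).  Items are conditionally independent
given region and community effect -- co-occurrence structure between real
features (e.g. sidewalks and crosswalks) is not emulated.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd
import yaml
from scipy.special import expit, logit
from sklearn.base import BaseEstimator

from .instrument import (
    CommunityMeta,
    ItemCatalog,
    RatingDataset,
    build_catalog,
    region_group,
)

__all__ = [
    "SimulationParams",
    "LatentCommunity",
    "RatingSimulator",
    "simulate_truth",
    "simulate_ratings",
    "simulate_dataset",
    "simulate_two_way_matrix",
    "expected_icc",
    "default_region_mix",
    "params_to_yaml",
    "params_from_yaml",
]

#: (country, urbanicity) -> community count in the emulated study design
STUDY_DESIGN: dict[tuple[str, str], int] = {
    ("Canada", "urban"): 24,
    ("Canada", "rural"): 13,
    ("Brazil", "urban"): 3,
    ("Brazil", "rural"): 3,
    ("Colombia", "urban"): 8,
    ("Colombia", "rural"): 6,
    ("China", "urban"): 10,
    ("China", "rural"): 4,
    ("India", "urban"): 5,
    ("India", "rural"): 10,
}


def default_region_mix() -> dict[tuple[str, str], int]:
    return dict(STUDY_DESIGN)


def _p(prob: float) -> float:
    """Latent (log-odds) baseline giving binary prevalence ``prob``."""
    return float(logit(prob))


#: Region-group baselines on the latent scale for a subset of items,
#: chosen to echo the published descriptive contrasts (e.g. sidewalks in
#: ~97% of Canadian communities vs ~1 in 3 in India).  Items not listed
#: default to baseline 0 (binary prevalence 1/2, ordinal centred).
DEFAULT_PREVALENCE_PROFILES: dict[str, dict[str, float]] = {
    "Canada": {
        "Q1": _p(0.97), "Q2": 1.0, "Q15": _p(0.89), "Q17a": _p(0.8),
        "Q17c": _p(0.6), "Q17d": _p(0.7), "Q5": _p(0.05),
        "Q21": 0.6, "Q22": 0.8, "Q24": -0.8, "Q23": -0.8, "Q30": -0.9,
        "Q25.bench": _p(0.6), "Q25.street_lamp": _p(0.9),
        "Q19.desert": _p(1e-6),
    },
    "Brazil/Colombia": {
        "Q1": _p(0.85), "Q2": 0.5, "Q15": _p(0.55), "Q17a": _p(0.5),
        "Q17c": _p(0.3), "Q17d": _p(0.35), "Q5": _p(0.01),
        "Q21": 0.0, "Q22": -0.5, "Q24": 0.1, "Q23": -0.1, "Q30": -0.2,
        "Q25.bench": _p(0.35), "Q25.street_lamp": _p(0.7),
        "Q19.desert": _p(1e-6),
    },
    "India/China": {
        "Q1": _p(0.45), "Q2": -0.5, "Q15": _p(0.3), "Q17a": _p(0.25),
        "Q17c": _p(0.2), "Q17d": _p(0.2), "Q5": _p(0.08),
        "Q21": -0.4, "Q22": -1.0, "Q24": 0.6, "Q23": 0.0, "Q30": 0.3,
        "Q25.bench": _p(0.2), "Q25.street_lamp": _p(0.5),
        "Q19.desert": _p(1e-6),
    },
}


@dataclass(frozen=True)
class SimulationParams:
    """Knobs of the rating-data generator.

    ``sigma_community``, ``sigma_observer`` and ``sigma_error`` are standard
    deviations on the shared latent scale; their squared ratio
    s_c^2/(s_c^2+s_o^2+s_e^2) is the expected (continuous-scale) ICC.  The
    defaults give an expected ICC of about 0.86, in the middle of the
    published per-item range.  ``misclassification_eps`` is the probability an
    observer miscodes a binary item (flip).  ``region_mix`` maps
    (country, urbanicity) to community counts; if its total differs from
    ``n_communities`` the mix is rescaled by largest remainder.
    """

    n_communities: int = 86
    n_observers: int = 3
    sigma_community: float = 1.5
    sigma_observer: float = 0.35
    sigma_error: float = 0.5
    misclassification_eps: float = 0.03
    ordinal_cut_spacing: float = 1.0
    region_mix: Mapping[tuple[str, str], int] = field(default_factory=default_region_mix)
    prevalence_profiles: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {r: dict(v) for r, v in DEFAULT_PREVALENCE_PROFILES.items()}
    )
    seed: int | None = None

    def __post_init__(self) -> None:
        if min(self.sigma_community, self.sigma_observer, self.sigma_error) < 0:
            raise ValueError("variance parameters must be non-negative")
        if not 0 <= self.misclassification_eps <= 1:
            raise ValueError("misclassification_eps must be a probability")
        if self.n_communities < 1 or self.n_observers < 1:
            raise ValueError("need at least 1 community and 1 observer")
        if self.ordinal_cut_spacing <= 0:
            raise ValueError("ordinal_cut_spacing must be positive")

    def baseline(self, region: str, item_id: str) -> float:
        return float(self.prevalence_profiles.get(region, {}).get(item_id, 0.0))


@dataclass(frozen=True)
class LatentCommunity:
    """Ground truth for one simulated community."""

    meta: CommunityMeta
    latent: dict[str, float]  # item_id -> continuous latent value
    truth: dict[str, int]  # item_id -> true categorical level


def expected_icc(p: SimulationParams) -> float:
    """Latent-scale target reliability s_c^2 / (s_c^2 + s_o^2 + s_e^2).

    This is the exact ICC of the continuous latent responses and an
    upper-bound approximation for thresholded ordinal/binary outputs.
    """
    total = p.sigma_community**2 + p.sigma_observer**2 + p.sigma_error**2
    if total == 0:
        raise ValueError("expected ICC undefined when all variances are zero")
    return p.sigma_community**2 / total


def _allocate_mix(p: SimulationParams) -> list[tuple[str, str]]:
    """(country, urbanicity) per community, rescaled by largest remainder."""
    mix = {k: int(v) for k, v in p.region_mix.items() if v > 0}
    total = sum(mix.values())
    if total == 0:
        raise ValueError("region_mix is empty")
    if total == p.n_communities:
        alloc = mix
    else:
        exact = {k: v * p.n_communities / total for k, v in mix.items()}
        alloc = {k: int(np.floor(v)) for k, v in exact.items()}
        short = p.n_communities - sum(alloc.values())
        remainders = sorted(exact, key=lambda k: exact[k] - alloc[k], reverse=True)
        for k in remainders[:short]:
            alloc[k] += 1
    cells = []
    for (country, urb), cnt in alloc.items():
        cells.extend([(country, urb)] * cnt)
    return cells


def _ordinal_cuts(n_levels: int, spacing: float) -> np.ndarray:
    # n_levels-1 equally spaced cutpoints centred on 0
    return spacing * (np.arange(1, n_levels) - n_levels / 2)


def _discretize(z: float, scale, spacing: float) -> int:
    if scale.kind == "count":
        value = int(round(np.exp(z)))
        if scale.max_level is not None:
            value = min(value, scale.max_level)
        return max(value, 0)
    levels = scale.levels
    cuts = _ordinal_cuts(len(levels), spacing)
    return int(levels[int(np.searchsorted(cuts, z, side="right"))])


def simulate_truth(
    p: SimulationParams, rng: np.random.Generator | None = None, catalog: ItemCatalog | None = None
) -> list[LatentCommunity]:
    """Draw latent values and true levels for every community x item.

    The latent value is the regional baseline plus a community effect
    ~ N(0, s_c^2).  True levels threshold the latent for ordinal/count items
    and are Bernoulli(logistic(latent)) for binary items.  Reproducible under
    a seeded generator.
    """
    rng = rng if rng is not None else np.random.default_rng(p.seed)
    catalog = catalog if catalog is not None else build_catalog()
    cells = _allocate_mix(p)
    out = []
    for i, (country, urb) in enumerate(cells):
        meta = CommunityMeta(f"C{i + 1:03d}", country, urb)
        region = meta.region_group
        latent: dict[str, float] = {}
        truth: dict[str, int] = {}
        for item in catalog:
            z = p.baseline(region, item.item_id) + rng.normal(0.0, p.sigma_community)
            latent[item.item_id] = z
            if item.scale.kind == "binary":
                truth[item.item_id] = int(rng.random() < expit(z))
            else:
                truth[item.item_id] = _discretize(z, item.scale, p.ordinal_cut_spacing)
        out.append(LatentCommunity(meta, latent, truth))
    return out


def simulate_ratings(
    truth: list[LatentCommunity],
    p: SimulationParams,
    rng: np.random.Generator | None = None,
    catalog: ItemCatalog | None = None,
) -> RatingDataset:
    """Layer observer effects and residual noise on latent truths.

    Each observer carries a column effect b_jq ~ N(0, s_o^2) per item, shared
    across communities (the two-way model's rater effect).  Ordinal and count
    responses re-threshold the noisy latent; binary responses flip the true
    level with probability ``misclassification_eps``.  The returned dataset
    passes validation by construction.
    """
    rng = rng if rng is not None else np.random.default_rng(p.seed)
    catalog = catalog if catalog is not None else build_catalog()
    observers = [f"obs{j + 1}" for j in range(p.n_observers)]
    item_ids = catalog.item_ids
    obs_effects = {
        (obs, q): rng.normal(0.0, p.sigma_observer) for obs in observers for q in item_ids
    }
    records = []
    for lc in truth:
        for obs in observers:
            for item in catalog:
                q = item.item_id
                if item.scale.kind == "binary":
                    resp = lc.truth[q]
                    if rng.random() < p.misclassification_eps:
                        resp = 1 - resp
                else:
                    z = lc.latent[q] + obs_effects[(obs, q)] + rng.normal(0.0, p.sigma_error)
                    resp = _discretize(z, item.scale, p.ordinal_cut_spacing)
                records.append(
                    (lc.meta.community_id, lc.meta.country, lc.meta.urbanicity, obs, q, resp)
                )
    long = pd.DataFrame(
        records,
        columns=["community_id", "country", "urbanicity", "observer_id", "item_id", "response"],
    )
    return RatingDataset(long, catalog)


def simulate_dataset(
    p: SimulationParams, seed: int | None = None, catalog: ItemCatalog | None = None
) -> RatingDataset:
    """Truth + ratings in one call; ``seed`` overrides ``p.seed``."""
    rng = np.random.default_rng(seed if seed is not None else p.seed)
    catalog = catalog if catalog is not None else build_catalog()
    truth = simulate_truth(p, rng, catalog)
    return simulate_ratings(truth, p, rng, catalog)


def simulate_two_way_matrix(
    n: int,
    k: int,
    sigma_community: float,
    sigma_observer: float,
    sigma_error: float,
    rng: np.random.Generator,
    mean: float = 0.0,
) -> np.ndarray:
    """Continuous n x k grid from the two-way random-effects model itself.

    y_ij = mean + c_i + b_j + e_ij.  This is the latent-scale idealization
    used for estimator recovery and CI-coverage experiments, where the
    population ICC is exactly the variance ratio.
    """
    c = rng.normal(0.0, sigma_community, size=(n, 1))
    b = rng.normal(0.0, sigma_observer, size=(1, k))
    e = rng.normal(0.0, sigma_error, size=(n, k))
    return mean + c + b + e


# -- scenario config --------------------------------------------------------


def params_to_yaml(p: SimulationParams) -> str:
    doc = {
        "n_communities": p.n_communities,
        "n_observers": p.n_observers,
        "sigma_community": p.sigma_community,
        "sigma_observer": p.sigma_observer,
        "sigma_error": p.sigma_error,
        "misclassification_eps": p.misclassification_eps,
        "ordinal_cut_spacing": p.ordinal_cut_spacing,
        "seed": p.seed,
        "region_mix": {f"{c}|{u}": int(n) for (c, u), n in p.region_mix.items()},
        "prevalence_profiles": {r: dict(v) for r, v in p.prevalence_profiles.items()},
    }
    return yaml.safe_dump(doc, sort_keys=False)


def params_from_yaml(text: str) -> SimulationParams:
    doc = yaml.safe_load(text) or {}
    if "region_mix" in doc:
        doc["region_mix"] = {
            tuple(key.split("|")): int(n) for key, n in doc["region_mix"].items()
        }
    return SimulationParams(**doc)


class RatingSimulator(BaseEstimator):
    """Estimator-style front end over the generator (sklearn conventions).

    ``sample(seed)`` draws a full rating dataset; parameters mirror
    :class:`SimulationParams` so they compose with ``get_params`` /
    ``set_params`` and grid utilities.
    """

    def __init__(
        self,
        n_communities: int = 86,
        n_observers: int = 3,
        sigma_community: float = 1.5,
        sigma_observer: float = 0.35,
        sigma_error: float = 0.5,
        misclassification_eps: float = 0.03,
        ordinal_cut_spacing: float = 1.0,
        seed: int | None = None,
    ):
        self.n_communities = n_communities
        self.n_observers = n_observers
        self.sigma_community = sigma_community
        self.sigma_observer = sigma_observer
        self.sigma_error = sigma_error
        self.misclassification_eps = misclassification_eps
        self.ordinal_cut_spacing = ordinal_cut_spacing
        self.seed = seed

    def _params(self) -> SimulationParams:
        return SimulationParams(
            n_communities=self.n_communities,
            n_observers=self.n_observers,
            sigma_community=self.sigma_community,
            sigma_observer=self.sigma_observer,
            sigma_error=self.sigma_error,
            misclassification_eps=self.misclassification_eps,
            ordinal_cut_spacing=self.ordinal_cut_spacing,
            seed=self.seed,
        )

    def sample(self, seed: int | None = None) -> RatingDataset:
        return simulate_dataset(self._params(), seed=seed)

    def expected_icc(self) -> float:
        return expected_icc(self._params())
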