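"""Domain summary scores for the photo-audit instrument.

Items are combined into six construct domains -- urban density,
aesthetics/beautification, community disorder, community appeal, pedestrian
safety, and bike lanes -- by allocating a small number of points to each
contributing feature and summing within the domain, giving roughly equal
weight to each feature.  Grouped features (street furniture, crosswalk safety
features) earn one point each up to a cap.  Score brackets:

==================  =========
urban density       0 -- 9
aesthetics          0 -- 12
disorder            0 -- 4
appeal              4 -- 16
pedestrian safety   0 -- 14
bike lanes          0 -- 3 or 0 -- 4 (two published variants, see below)
==================  =========

Bike lanes are kept separate from pedestrian safety because lane counts are
sparse in several regions.  The published bracket for bike lanes is
ambiguous: the component listing (present 0-1, quality 0-2) sums to 3 while
the stated range is 0-4 and the quality item is scaled 1-3.  Both readings are
implemented (``bike_lane_variant`` "0-3" or "0-4", the latter the default as
it matches the realized range of the published summary tables); neither is
asserted as an invariant.

Communities are classified high/mid/low per domain by the empirical tertiles
of the observer-averaged score distribution.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from sklearn.base import BaseEstimator, TransformerMixin

from .instrument import ItemCatalog, RatingDataset, build_catalog, validate_dataset

__all__ = [
    "PointMap",
    "Component",
    "DomainSpec",
    "DomainScorer",
    "default_domain_specs",
    "score_domain",
    "score_dataset",
    "classify_tertiles",
    "summarize_scores",
    "enumerate_domain_scores",
    "specs_to_yaml",
    "specs_from_yaml",
    "DOMAINS",
    "EXCLUDED_ITEMS",
]

DOMAINS = (
    "urban_density",
    "aesthetics_beautification",
    "community_disorder",
    "community_appeal",
    "pedestrian_safety",
    "bike_lanes",
)

#: Items collected by the instrument but deliberately left out of every
#: domain score: building counts/awnings and parking lots / street width
#: (poor construct fit across countries), vehicle counts (sparse, partly
#: unreliable), obstacles and building-design diversity (borderline
#: reliability / ambiguous domain), and the biking-suitability opinion
#: (unreliable, sparse lane counts).
EXCLUDED_ITEMS = frozenset(
    {"Q27", "Q28", "Q29", "Q8", "Q9", "Q11", "Q32", "Q35"}
    | {f"Q13.{part}" for part in ("bicycles", "cars", "buses", "rickshaws", "motorcycles", "trucks")}
)


@dataclass(frozen=True)
class PointMap:
    """Points earned by each admissible response code of one item."""

    item_id: str
    mapping: tuple[tuple[int, int], ...]  # (response code, points), immutable

    @classmethod
    def make(cls, item_id: str, mapping: Mapping[int, int]) -> "PointMap":
        return cls(item_id, tuple(sorted(mapping.items())))

    @property
    def as_dict(self) -> dict[int, int]:
        return dict(self.mapping)

    @property
    def max_points(self) -> int:
        return max(p for _, p in self.mapping)

    @property
    def min_points(self) -> int:
        return min(p for _, p in self.mapping)


@dataclass(frozen=True)
class Component:
    """A named feature (or capped feature group) contributing to one domain.

    ``cap`` bounds the group's total contribution.  ``guard`` names an item
    whose absence (code 0) zeroes the component: sidewalk completeness and
    quality only count when sidewalks are present at all, bike-lane quality
    only when a lane exists.
    """

    name: str
    maps: tuple[PointMap, ...]
    cap: int | None = None
    guard: str | None = None

    @property
    def max_points(self) -> int:
        total = sum(m.max_points for m in self.maps)
        return total if self.cap is None else min(self.cap, total)

    @property
    def min_points(self) -> int:
        if self.guard is not None:
            return 0
        return sum(m.min_points for m in self.maps)

    def score(self, responses: Mapping[str, object]) -> tuple[int, list[str]]:
        """Points earned plus the list of item ids with missing responses."""
        missing: list[str] = []
        if self.guard is not None:
            g = responses.get(self.guard)
            if g is None or (isinstance(g, float) and np.isnan(g)):
                missing.append(self.guard)
                return 0, missing
            if int(g) == 0:
                return 0, missing
        total = 0
        for pm in self.maps:
            r = responses.get(pm.item_id)
            if r is None or (isinstance(r, float) and np.isnan(r)):
                missing.append(pm.item_id)
                continue
            code = int(r)
            table = pm.as_dict
            if code not in table:
                raise ValueError(f"no point mapping for {pm.item_id}={code}")
            total += table[code]
        if self.cap is not None:
            total = min(total, self.cap)
        return total, missing


@dataclass(frozen=True)
class DomainSpec:
    """Point allocation for one construct domain."""

    name: str
    components: tuple[Component, ...]

    @property
    def max_score(self) -> int:
        return sum(c.max_points for c in self.components)

    @property
    def min_score(self) -> int:
        return sum(c.min_points for c in self.components)

    @property
    def item_ids(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for comp in self.components:
            if comp.guard is not None:
                seen.setdefault(comp.guard, None)
            for pm in comp.maps:
                seen.setdefault(pm.item_id, None)
        return tuple(seen)


_INDICATOR = {0: 0, 1: 1}
_SHIFT14 = {1: 0, 2: 1, 3: 2, 4: 3}  # 4-level "none .. many" -> 0-3 points
_ANY14 = {1: 0, 2: 1, 3: 1, 4: 1}  # any non-"none" level -> 1 point
_LIKERT = {1: 1, 2: 2, 3: 3, 4: 4}


def default_domain_specs(
    catalog: ItemCatalog | None = None, bike_lane_variant: str = "0-4"
) -> tuple[DomainSpec, ...]:
    """The default point allocations for the six domains.

    Mappings left implicit by the published allocation table are fixed as the
    minimal monotone maps achieving the printed brackets: 4-level ordinal
    amount items earn level-1 points (0-3); disorder indicators and public art
    earn 1 for any non-"none" level; the natural-features indicator is 1 if
    any natural-feature part is present.  "Street density" is bound to the
    pedestrian-density item, the only density item retained after exclusions.

    Raises ``KeyError`` naming the item if the catalog lacks a required item.
    """
    if bike_lane_variant not in ("0-3", "0-4"):
        raise ValueError("bike_lane_variant must be '0-3' or '0-4'")
    catalog = catalog if catalog is not None else build_catalog()
    for required in (
        "Q1", "Q2", "Q4", "Q5", "Q6", "Q7", "Q10", "Q12", "Q14", "Q15",
        "Q17a", "Q17b", "Q17c", "Q17d", "Q17e", "Q17f", "Q18",
        "Q19.open_field", "Q19.water", "Q19.mountains", "Q19.greenbelt", "Q19.desert",
        "Q21", "Q22", "Q23", "Q24", "Q26", "Q30", "Q31",
        "Q25.bench", "Q25.trashcan", "Q25.bus_shelter", "Q25.street_lamp",
        "Q33", "Q34", "Q36", "Q37",
    ):
        if required not in catalog:
            raise KeyError(f"catalog is missing required item {required}")

    def pm(item_id: str, mapping: Mapping[int, int]) -> PointMap:
        return PointMap.make(item_id, mapping)

    urban_density = DomainSpec(
        "urban_density",
        (
            Component("street_density", (pm("Q10", _SHIFT14),)),
            Component("vehicle_density", (pm("Q12", _SHIFT14),)),
            Component("parked_cars", (pm("Q14", _SHIFT14),)),
        ),
    )
    aesthetics = DomainSpec(
        "aesthetics_beautification",
        (
            Component(
                "natural_features",
                tuple(
                    pm(f"Q19.{part}", _INDICATOR)
                    for part in ("open_field", "water", "mountains", "greenbelt", "desert")
                ),
                cap=1,
            ),
            Component("street_trees", (pm("Q21", _SHIFT14),)),
            Component("landscaping", (pm("Q22", _SHIFT14),)),
            Component(
                "street_furniture",
                tuple(
                    pm(f"Q25.{part}", _INDICATOR)
                    for part in ("bench", "trashcan", "bus_shelter", "street_lamp")
                ),
                cap=4,
            ),
            Component("public_art", (pm("Q26", _ANY14),)),
        ),
    )
    disorder = DomainSpec(
        "community_disorder",
        (
            Component("litter", (pm("Q24", _ANY14),)),
            Component("graffiti", (pm("Q23", _ANY14),)),
            Component("derelict_buildings", (pm("Q30", _ANY14),)),
            Component("poorly_maintained", (pm("Q31", {1: 1, 2: 0, 3: 0}),)),
        ),
    )
    appeal = DomainSpec(
        "community_appeal",
        tuple(
            Component(name, (pm(q, _LIKERT),))
            for name, q in (
                ("safe_pedestrian_friendly", "Q33"),
                ("suitable_for_walking", "Q34"),
                ("attractive_buildings", "Q36"),
                ("aesthetically_appealing", "Q37"),
            )
        ),
    )
    pedestrian_safety = DomainSpec(
        "pedestrian_safety",
        (
            Component("sidewalks", (pm("Q1", _INDICATOR),)),
            Component("sidewalk_completeness", (pm("Q2", {0: 0, 1: 1, 2: 2}),), guard="Q1"),
            Component("sidewalk_quality", (pm("Q4", _SHIFT14),), guard="Q1"),
            Component("crosswalks", (pm("Q15", _INDICATOR),)),
            Component(
                "crosswalk_features",
                tuple(pm(q, _INDICATOR) for q in ("Q17a", "Q17b", "Q17e", "Q17f")),
                cap=4,
            ),
            Component(
                "traffic_signals_signs",
                (pm("Q17c", _INDICATOR), pm("Q17d", _INDICATOR)),
                cap=1,
            ),
            Component(
                "median_grass_strip",
                (pm("Q18", _ANY14), pm("Q7", {1: 0, 2: 1, 3: 1})),
            ),
        ),
    )
    quality_map = {1: 1, 2: 2, 3: 3} if bike_lane_variant == "0-4" else {1: 0, 2: 1, 3: 2}
    bike_lanes = DomainSpec(
        "bike_lanes",
        (
            Component("present", (pm("Q5", _INDICATOR),)),
            Component("quality", (pm("Q6", quality_map),), guard="Q5"),
        ),
    )
    return (urban_density, aesthetics, disorder, appeal, pedestrian_safety, bike_lanes)


def score_domain(
    responses: Mapping[str, object], spec: DomainSpec
) -> tuple[int, list[str]]:
    """Score one community x observer response mapping on one domain.

    Missing component responses contribute 0 points and are returned in the
    missing-components list rather than imputed, so a score with missing
    inputs may fall below the domain's nominal minimum.
    """
    total = 0
    missing: list[str] = []
    for comp in spec.components:
        pts, miss = comp.score(responses)
        total += pts
        missing.extend(miss)
    return total, missing


def score_dataset(
    ds: RatingDataset, specs: Sequence[DomainSpec] | None = None
) -> pd.DataFrame:
    """Score every (community, observer) record on every domain.

    Returns a long frame with columns ``community_id, country, urbanicity,
    observer_id, domain, score, n_missing, missing_components`` -- one row per
    card per domain, in dataset order.  Deterministic.
    """
    if specs is None:
        specs = default_domain_specs(ds.catalog)
    wide = ds.to_wide()
    records = []
    for responses in wide.to_dict("records"):  # dotted item ids stay intact
        for spec in specs:
            score, missing = score_domain(responses, spec)
            records.append(
                {
                    "community_id": responses["community_id"],
                    "country": responses["country"],
                    "urbanicity": responses["urbanicity"],
                    "observer_id": responses["observer_id"],
                    "domain": spec.name,
                    "score": score,
                    "n_missing": len(missing),
                    "missing_components": "|".join(missing),
                }
            )
    return pd.DataFrame.from_records(records)


def community_means(cards: pd.DataFrame) -> pd.DataFrame:
    """Observer-averaged score per community x domain."""
    return (
        cards.groupby(["community_id", "domain"], sort=False)["score"]
        .mean()
        .reset_index()
    )


def classify_tertiles(cards: pd.DataFrame, domain: str) -> pd.DataFrame:
    """Label communities low/mid/high by tertiles of observer-mean scores.

    Bands are closed on the left boundary going down: ``low`` is
    score <= 1/3-quantile, ``mid`` is (1/3-quantile, 2/3-quantile], ``high``
    above; exact boundary ties therefore fall in the lower band.  If the two
    quantiles coincide (e.g. all scores equal) every community is ``mid``.
    Requires at least 3 communities.
    """
    means = community_means(cards)
    means = means[means["domain"] == domain]
    if means.empty:
        raise ValueError(f"no scores for domain {domain!r}")
    if len(means) < 3:
        raise ValueError("tertile classification needs at least 3 communities")
    scores = means["score"].to_numpy(float)
    q_low, q_high = np.quantile(scores, [1 / 3, 2 / 3])
    if q_low == q_high:
        labels = np.full(len(scores), "mid", dtype=object)
    else:
        labels = np.where(scores <= q_low, "low", np.where(scores <= q_high, "mid", "high"))
    out = means[["community_id", "domain"]].copy()
    out["score"] = scores
    out["label"] = labels
    return out.reset_index(drop=True)


_GROUPERS = {
    "overall": None,
    "country_region": "region_group",
    "urbanicity": "urbanicity",
    "observer": "observer_id",
}


def summarize_scores(
    cards: pd.DataFrame, group_by: str = "overall"
) -> pd.DataFrame:
    """Mean/SD summary tables of domain scores.

    For ``overall``, ``country_region`` and ``urbanicity`` groupings the
    per-community observer-mean score is summarized over communities; for the
    ``observer`` grouping each observer's own scores are summarized over
    communities.  SD uses n-1 denominators; a single observation reports
    SD 0 with its n so tables stay total.
    """
    if group_by not in _GROUPERS:
        raise ValueError(f"unknown grouping {group_by!r}; choose from {sorted(_GROUPERS)}")
    if cards.empty:
        raise ValueError("no score cards to summarize")
    from .instrument import REGION_GROUPS

    cards = cards.copy()
    cards["region_group"] = cards["country"].map(REGION_GROUPS)
    if group_by == "observer":
        per_unit = cards
        keys = ["observer_id", "domain"]
    else:
        meta = cards[["community_id", "region_group", "urbanicity"]].drop_duplicates("community_id")
        per_unit = community_means(cards).merge(meta, on="community_id")
        keys = ["domain"] if group_by == "overall" else [_GROUPERS[group_by], "domain"]
    grouped = per_unit.groupby(keys, sort=False)["score"]
    out = grouped.agg(mean="mean", sd="std", n="count").reset_index()
    out["sd"] = out["sd"].fillna(0.0)
    if group_by == "overall":
        out.insert(0, "group", "overall")
    else:
        out = out.rename(columns={keys[0]: "group"})
    return out


def enumerate_domain_scores(
    spec: DomainSpec, catalog: ItemCatalog | None = None
) -> np.ndarray:
    """All attainable scores of a domain by brute force over its response space.

    Enumerates the Cartesian product of admissible levels of every item the
    spec touches (guards included) and scores each combination; used to verify
    score brackets and by the bracket acceptance checks.
    """
    catalog = catalog if catalog is not None else build_catalog()
    item_ids = spec.item_ids
    level_sets = [catalog[i].scale.levels for i in item_ids]
    if any(not levels for levels in level_sets):
        raise ValueError("cannot enumerate an unbounded (count) item")
    scores = []
    for combo in itertools.product(*level_sets):
        responses = dict(zip(item_ids, combo))
        score, missing = score_domain(responses, spec)
        assert not missing
        scores.append(score)
    return np.asarray(scores)


# ---------------------------------------------------------------------------
# Config serialization: flat, human-editable, so alternative weightings can be
# tried without touching code.
# ---------------------------------------------------------------------------


def specs_to_yaml(specs: Sequence[DomainSpec]) -> str:
    doc = []
    for spec in specs:
        comps = []
        for c in spec.components:
            comps.append(
                {
                    "name": c.name,
                    "cap": c.cap,
                    "guard": c.guard,
                    "points": {m.item_id: {int(k): int(v) for k, v in m.mapping} for m in c.maps},
                }
            )
        doc.append({"domain": spec.name, "components": comps})
    return yaml.safe_dump(doc, sort_keys=False)


def specs_from_yaml(text: str) -> tuple[DomainSpec, ...]:
    doc = yaml.safe_load(text)
    specs = []
    for entry in doc:
        comps = []
        for c in entry["components"]:
            maps = tuple(
                PointMap.make(item_id, {int(k): int(v) for k, v in table.items()})
                for item_id, table in c["points"].items()
            )
            comps.append(Component(c["name"], maps, cap=c.get("cap"), guard=c.get("guard")))
        specs.append(DomainSpec(entry["domain"], tuple(comps)))
    return tuple(specs)


class DomainScorer(TransformerMixin, BaseEstimator):
    """Transformer mapping rating datasets to per-card domain scores.

    Follows the scikit-learn estimator contract: parameters are set in
    ``__init__``, ``fit`` validates the input and freezes the domain specs as
    ``specs_``, ``transform`` produces one row per (community, observer) with
    one column per domain.

    Parameters
    ----------
    specs
        Domain specs to apply; ``None`` uses the default allocation.
    bike_lane_variant
        "0-4" (default) or "0-3"; ignored when ``specs`` is given.
    """

    def __init__(self, specs: Sequence[DomainSpec] | None = None, bike_lane_variant: str = "0-4"):
        self.specs = specs
        self.bike_lane_variant = bike_lane_variant

    def fit(self, X: RatingDataset, y=None) -> "DomainScorer":
        ds = self._as_dataset(X)
        violations = validate_dataset(ds)
        if violations:
            first = violations[0]
            raise ValueError(
                f"dataset fails validation ({len(violations)} violations; first: "
                f"{first.community_id}/{first.observer_id}/{first.item_id}: {first.reason})"
            )
        self.catalog_ = ds.catalog
        self.specs_ = (
            tuple(self.specs)
            if self.specs is not None
            else default_domain_specs(ds.catalog, self.bike_lane_variant)
        )
        return self

    def transform(self, X: RatingDataset) -> pd.DataFrame:
        if not hasattr(self, "specs_"):
            raise ValueError("DomainScorer is not fitted; call fit first")
        ds = self._as_dataset(X)
        cards = score_dataset(ds, self.specs_)
        wide = cards.pivot_table(
            index=["community_id", "country", "urbanicity", "observer_id"],
            columns="domain",
            values="score",
            aggfunc="first",
            sort=False,
        ).reset_index()
        wide.columns.name = None
        order = [s.name for s in self.specs_]
        return wide[["community_id", "country", "urbanicity", "observer_id"] + order]

    def score_cards(self, X: RatingDataset) -> pd.DataFrame:
        """Long-form cards with missing-component reports."""
        if not hasattr(self, "specs_"):
            raise ValueError("DomainScorer is not fitted; call fit first")
        return score_dataset(self._as_dataset(X), self.specs_)

    @staticmethod
    def _as_dataset(X) -> RatingDataset:
        return X if isinstance(X, RatingDataset) else RatingDataset.from_long(X)
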