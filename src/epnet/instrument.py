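"""Photo-audit instrument schema: items, response scales, rating datasets.

The instrument is a 37-question pro forma applied by central observers to a
standard photo set of a community's commercial centre.  Several questions have
named parts (sidewalk surfaces, vehicle types, crosswalk features, natural
features, street furniture), each of which is rated -- and its reliability
reported -- separately, so the catalog carries one item per part: 60 items in
total.  Questions 1-32 are objective presence/amount measures; questions 33-37
ask the observer for an overall opinion on a 4-point agreement scale.

Rating data are exchanged as long tables (one row per community x observer x
item) or wide tables (one row per community x observer, one column per item);
long form is canonical.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "ResponseScale",
    "ItemDefinition",
    "ItemCatalog",
    "CommunityMeta",
    "RatingDataset",
    "Violation",
    "DatasetStructureError",
    "build_catalog",
    "validate_dataset",
    "region_group",
    "REGION_GROUPS",
    "LONG_COLUMNS",
    "META_COLUMNS",
]

CATALOG_VERSION = "1.0"

#: country -> regional grouping used in all per-region reporting
REGION_GROUPS: dict[str, str] = {
    "Canada": "Canada",
    "Brazil": "Brazil/Colombia",
    "Colombia": "Brazil/Colombia",
    "India": "India/China",
    "China": "India/China",
}

META_COLUMNS = ("community_id", "country", "urbanicity")
LONG_COLUMNS = META_COLUMNS + ("observer_id", "item_id", "response")

URBANICITY_LEVELS = ("urban", "rural")


def region_group(country: str) -> str:
    """Regional grouping (Canada / Brazil-Colombia / India-China) of a country."""
    try:
        return REGION_GROUPS[country]
    except KeyError:
        raise ValueError(f"unknown country {country!r}") from None


class DatasetStructureError(ValueError):
    """A rating table is structurally malformed (missing columns, bad dtypes).

    Distinct from content violations, which are enumerated by
    :func:`validate_dataset` rather than raised.
    """


@dataclass(frozen=True)
class ResponseScale:
    """Admissible response codes for one item.

    Parameters
    ----------
    kind
        One of ``binary`` (0/1), ``ordinal`` (consecutive integers,
        ``min_level``..``max_level``), ``count`` (non-negative integers,
        optionally bounded above) or ``categorical`` (labelled integer codes).
    min_level, max_level
        Smallest and largest admissible code; ``max_level`` is ``None`` for an
        unbounded count.
    labels
        Human-readable level names, aligned with the codes (empty for counts).
    """

    kind: str
    min_level: int = 0
    max_level: int | None = None
    labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.kind not in ("binary", "ordinal", "count", "categorical"):
            raise ValueError(f"unknown scale kind {self.kind!r}")
        if self.kind == "binary" and (self.min_level, self.max_level) != (0, 1):
            raise ValueError("binary scale must have levels 0/1")
        if self.kind == "count":
            if self.min_level != 0:
                raise ValueError("count scale starts at 0")
        elif self.max_level is None or self.max_level <= self.min_level:
            raise ValueError("scale needs max_level > min_level")
        if self.kind in ("ordinal", "categorical", "binary") and self.labels:
            if len(self.labels) != len(self.levels):
                raise ValueError("labels must align with levels")

    @property
    def levels(self) -> tuple[int, ...]:
        """Ordered admissible codes (empty tuple for unbounded counts)."""
        if self.max_level is None:
            return ()
        return tuple(range(self.min_level, self.max_level + 1))

    @property
    def floor(self) -> int:
        """The 'absence' code: the lowest level of the scale."""
        return self.min_level

    def is_admissible(self, code: object) -> bool:
        if code is None or (isinstance(code, float) and np.isnan(code)):
            return False
        try:
            value = float(code)
        except (TypeError, ValueError):
            return False
        if value != int(value):
            return False
        value = int(value)
        if value < self.min_level:
            return False
        return self.max_level is None or value <= self.max_level


def binary(labels: tuple[str, str] = ("no", "yes")) -> ResponseScale:
    return ResponseScale("binary", 0, 1, labels)


def ordinal(lo: int, hi: int, labels: tuple[str, ...] = ()) -> ResponseScale:
    return ResponseScale("ordinal", lo, hi, labels)


def count(max_level: int | None = None) -> ResponseScale:
    return ResponseScale("count", 0, max_level)


@dataclass(frozen=True)
class ItemDefinition:
    """One scoreable item: a question or a named part of a multi-part question."""

    item_id: str
    stem: str  # question number shared by parts, e.g. "Q19" for "Q19.desert"
    text: str
    scale: ResponseScale
    objective: bool = True


@dataclass(frozen=True)
class CommunityMeta:
    community_id: str
    country: str
    urbanicity: str

    def __post_init__(self) -> None:
        region_group(self.country)  # raises on unknown country
        if self.urbanicity not in URBANICITY_LEVELS:
            raise ValueError(f"urbanicity must be one of {URBANICITY_LEVELS}")

    @property
    def region_group(self) -> str:
        return REGION_GROUPS[self.country]


# ---------------------------------------------------------------------------
# The canonical catalog.  One row per reliability-table row; multi-part
# questions expanded into dotted ids (Q3.concrete, Q17a, Q19.desert, ...).
# ---------------------------------------------------------------------------

_L14 = ("1", "2", "3", "4")

_ITEM_TABLE: tuple[tuple[str, str, ResponseScale, bool], ...] = (
    ("Q1", "Are sidewalks present", binary(), True),
    ("Q2", "Type of sidewalk present", ResponseScale("categorical", 0, 2, ("none", "partial", "complete")), True),
    ("Q3.concrete", "Sidewalk surface: concrete", binary(), True),
    ("Q3.paving_bricks", "Sidewalk surface: paving bricks", binary(), True),
    ("Q3.asphalt", "Sidewalk surface: asphalt", binary(), True),
    ("Q4", "Quality of sidewalk (1 poor to 4 well maintained)", ordinal(1, 4, _L14), True),
    ("Q5", "Bicycle lanes present", binary(), True),
    ("Q6", "Quality of bicycle lanes (1 low to 3 high quality)", ordinal(1, 3, ("1", "2", "3")), True),
    ("Q7", "Grass/dirt strip between sidewalk and road", ordinal(1, 3, ("no", "some", "all")), True),
    ("Q8", "Parking lots present", ordinal(1, 4, ("none", "1", "2", "3+")), True),
    ("Q9", "Width of street/road (lanes)", ordinal(1, 4, ("1", "2-3", "4-5", ">5")), True),
    ("Q10", "Level of pedestrian density (1 low to 4 high)", ordinal(1, 4, _L14), True),
    ("Q11", "Amount of obstacles seen (1 to 4)", ordinal(1, 4, _L14), True),
    ("Q12", "Level of motor vehicle density (1 to 4)", ordinal(1, 4, _L14), True),
    ("Q13.bicycles", "Number of bicycles seen", count(), True),
    ("Q13.cars", "Number of cars seen", count(), True),
    ("Q13.buses", "Number of buses seen", count(), True),
    ("Q13.rickshaws", "Number of rickshaws seen", count(), True),
    ("Q13.motorcycles", "Number of motorcycles/scooters seen", count(), True),
    ("Q13.trucks", "Number of trucks seen", count(), True),
    ("Q14", "Amount of parked cars seen (1 none to >4 cars)", ordinal(1, 4, ("none", "1-2", "3-4", ">4")), True),
    ("Q15", "Are there crosswalks present", binary(), True),
    ("Q16", "Number of crosswalks present", ordinal(1, 3, ("1-2", "3-4", ">4")), True),
    ("Q17a", "Crosswalk: white/coloured painted lines", binary(), True),
    ("Q17b", "Crosswalk: different road surface or paving", binary(), True),
    ("Q17c", "Crosswalk: traffic signals", binary(), True),
    ("Q17d", "Crosswalk: stop/yield signs", binary(), True),
    ("Q17e", "Crosswalk: pedestrian activated signal", binary(), True),
    ("Q17f", "Crosswalk: pedestrian crossing signs", binary(), True),
    ("Q18", "Median strip quality (1 no strip to 4 high quality strip)", ordinal(1, 4, _L14), True),
    ("Q19.open_field", "Natural feature: open field", binary(), True),
    ("Q19.water", "Natural feature: bodies of water", binary(), True),
    ("Q19.mountains", "Natural feature: mountains/hills", binary(), True),
    ("Q19.greenbelt", "Natural feature: greenbelt/forest", binary(), True),
    ("Q19.desert", "Natural feature: desert", binary(), True),
    ("Q20", "Percentage of natural features present in photos", count(100), True),
    ("Q21", "Number of trees planted (1 none to 4 many)", ordinal(1, 4, ("none", "1-2", "some", "many")), True),
    ("Q22", "Number of man-made landscapes present (1 none to 4 many)", ordinal(1, 4, ("none", "1-2", "some", "many")), True),
    ("Q23", "Graffiti present (1 none to 4 many)", ordinal(1, 4, ("none", "1-2", "some", "many")), True),
    ("Q24", "Litter/garbage present (1 none to 4 many)", ordinal(1, 4, ("none", "1-2", "some", "many")), True),
    ("Q25.bench", "Street furniture: benches", binary(), True),
    ("Q25.trashcan", "Street furniture: trash can", binary(), True),
    ("Q25.newspaper_box", "Street furniture: newspaper boxes", binary(), True),
    ("Q25.bike_rack", "Street furniture: bike rack", binary(), True),
    ("Q25.parking_meter", "Street furniture: parking meter", binary(), True),
    ("Q25.street_lamp", "Street furniture: street lamp", binary(), True),
    ("Q25.bus_shelter", "Street furniture: bus shelter", binary(), True),
    ("Q25.phone_booth", "Street furniture: phone booth", binary(), True),
    ("Q26", "Number of public art displayed (1 none to 4 many)", ordinal(1, 4, ("none", "1-2", "some", "many")), True),
    ("Q27", "Are buildings or houses present", binary(), True),
    ("Q28", "Number of buildings, houses and/or structures present", count(), True),
    ("Q29", "Amount of awnings present (1 none to 4 many)", ordinal(1, 4, ("none", "1-2", "some", "many")), True),
    ("Q30", "Number of derelict or vacant buildings present", ordinal(1, 4, ("none", "1", "2", "3+")), True),
    ("Q31", "Exterior of buildings maintained (1 poor to 3 well maintained)", ordinal(1, 3, ("poor", "fair", "well")), True),
    ("Q32", "Diversity of building design/architecture (1 minimal to 3 many)", ordinal(1, 3, ("minimal", "some", "many")), True),
    ("Q33", "Opinion: neighbourhood is very safe and pedestrian friendly", ordinal(1, 4, _L14), False),
    ("Q34", "Opinion: streets and sidewalks suitable for walking", ordinal(1, 4, _L14), False),
    ("Q35", "Opinion: streets and sidewalks suitable for biking", ordinal(1, 4, _L14), False),
    ("Q36", "Opinion: buildings, homes and structures are very attractive", ordinal(1, 4, _L14), False),
    ("Q37", "Opinion: neighbourhood as a whole is aesthetically appealing", ordinal(1, 4, _L14), False),
)


class ItemCatalog:
    """Ordered collection of :class:`ItemDefinition` with lookup by item id."""

    def __init__(self, items: Iterable[ItemDefinition], version: str = CATALOG_VERSION):
        items = tuple(items)
        ids = [it.item_id for it in items]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate item ids in catalog")
        self._items: dict[str, ItemDefinition] = {it.item_id: it for it in items}
        self.version = version

    def __getitem__(self, item_id: str) -> ItemDefinition:
        return self._items[item_id]

    def __contains__(self, item_id: str) -> bool:
        return item_id in self._items

    def __iter__(self) -> Iterator[ItemDefinition]:
        return iter(self._items.values())

    def __len__(self) -> int:
        return len(self._items)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ItemCatalog):
            return NotImplemented
        return self.version == other.version and tuple(self) == tuple(other)

    @property
    def item_ids(self) -> tuple[str, ...]:
        return tuple(self._items)

    @property
    def stems(self) -> tuple[str, ...]:
        """Distinct question stems, in catalog order."""
        seen: dict[str, None] = {}
        for it in self:
            seen.setdefault(it.stem, None)
        return tuple(seen)

    @property
    def opinion_item_ids(self) -> tuple[str, ...]:
        return tuple(it.item_id for it in self if not it.objective)

    # -- interchange -------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for it in self:
            rows.append(
                {
                    "item_id": it.item_id,
                    "stem": it.stem,
                    "text": it.text,
                    "kind": it.scale.kind,
                    "min_level": it.scale.min_level,
                    "max_level": it.scale.max_level,
                    "labels": "|".join(it.scale.labels),
                    "objective": it.objective,
                }
            )
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, version: str = CATALOG_VERSION) -> "ItemCatalog":
        items = []
        for row in frame.itertuples(index=False):
            max_level = None if pd.isna(row.max_level) else int(row.max_level)
            labels = tuple(str(row.labels).split("|")) if isinstance(row.labels, str) and row.labels else ()
            scale = ResponseScale(row.kind, int(row.min_level), max_level, labels)
            items.append(ItemDefinition(row.item_id, row.stem, row.text, scale, bool(row.objective)))
        return cls(items, version=version)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "ItemCatalog":
        return cls.from_frame(pd.read_csv(path))


def build_catalog() -> ItemCatalog:
    """The canonical 60-item instrument catalog.

    Multi-part questions are expanded into one item per part because
    reliability is assessed and reported per part.  Items Q33-Q37 are the five
    observer-opinion items; everything else is objective.
    """
    items = [
        ItemDefinition(item_id, item_id.split(".")[0].rstrip("abcdef"), text, scale, obj)
        for item_id, text, scale, obj in _ITEM_TABLE
    ]
    return ItemCatalog(items)


# ---------------------------------------------------------------------------
# Rating datasets
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Violation:
    """One content problem found in a rating dataset."""

    community_id: str
    observer_id: str
    item_id: str
    reason: str


class RatingDataset:
    """A community x observer x item response table plus its catalog.

    Internally stores the canonical long form; wide form is derived.  Missing
    responses are admissible at the dataset level (rows may simply be absent,
    or carry NaN) and are handled downstream per analysis.
    """

    def __init__(self, long: pd.DataFrame, catalog: ItemCatalog | None = None):
        self.catalog = catalog if catalog is not None else build_catalog()
        missing = [c for c in LONG_COLUMNS if c not in long.columns]
        if missing:
            raise DatasetStructureError(f"long table missing columns {missing}")
        long = long.loc[:, list(LONG_COLUMNS)].copy()
        for col in ("community_id", "country", "urbanicity", "observer_id", "item_id"):
            long[col] = long[col].astype(str)
        long["response"] = pd.to_numeric(long["response"], errors="coerce")
        self.long = long.reset_index(drop=True)

    # -- constructors ------------------------------------------------------

    @classmethod
    def from_long(cls, frame: pd.DataFrame, catalog: ItemCatalog | None = None) -> "RatingDataset":
        return cls(frame, catalog)

    @classmethod
    def from_wide(cls, frame: pd.DataFrame, catalog: ItemCatalog | None = None) -> "RatingDataset":
        key_cols = list(META_COLUMNS) + ["observer_id"]
        missing = [c for c in key_cols if c not in frame.columns]
        if missing:
            raise DatasetStructureError(f"wide table missing columns {missing}")
        long = frame.melt(id_vars=key_cols, var_name="item_id", value_name="response")
        long = long.dropna(subset=["response"])
        return cls(long, catalog)

    @classmethod
    def read_csv(cls, path, catalog: ItemCatalog | None = None, wide: bool | None = None) -> "RatingDataset":
        frame = pd.read_csv(path)
        if wide is None:  # autodetect: canonical long tables carry these two columns
            wide = not {"item_id", "response"}.issubset(frame.columns)
        return cls.from_wide(frame, catalog) if wide else cls.from_long(frame, catalog)

    # -- views -------------------------------------------------------------

    def to_long(self) -> pd.DataFrame:
        return self.long.copy()

    def to_wide(self) -> pd.DataFrame:
        key_cols = list(META_COLUMNS) + ["observer_id"]
        wide = self.long.pivot_table(
            index=key_cols, columns="item_id", values="response", aggfunc="first"
        ).reset_index()
        wide.columns.name = None
        ordered = [c for c in self.catalog.item_ids if c in wide.columns]
        return wide[key_cols + ordered]

    def to_csv(self, path, wide: bool = False) -> None:
        (self.to_wide() if wide else self.to_long()).to_csv(path, index=False)

    @property
    def communities(self) -> pd.DataFrame:
        """One row per community with country, region group and urbanicity."""
        meta = self.long[list(META_COLUMNS)].drop_duplicates("community_id")
        meta = meta.reset_index(drop=True)
        meta["region_group"] = meta["country"].map(REGION_GROUPS)
        return meta

    @property
    def n_communities(self) -> int:
        return self.long["community_id"].nunique()

    @property
    def n_observers(self) -> int:
        return self.long["observer_id"].nunique()

    def item_matrix(self, item_id: str) -> pd.DataFrame:
        """Communities x observers response grid for one item (NaN = missing)."""
        sub = self.long[self.long["item_id"] == item_id]
        return sub.pivot_table(
            index="community_id", columns="observer_id", values="response", aggfunc="first"
        )


def validate_dataset(ds: RatingDataset) -> list[Violation]:
    """Enumerate content violations of a dataset against its catalog.

    Returns an empty list iff every response is an admissible level of its
    item's scale, all item ids are known, and no (community, observer, item)
    triple is duplicated.  Structural problems (wrong columns) raise
    :class:`DatasetStructureError` at construction instead.
    """
    violations: list[Violation] = []
    long = ds.long
    dup = long.duplicated(subset=["community_id", "observer_id", "item_id"], keep="first")
    for row in long[dup].itertuples(index=False):
        violations.append(
            Violation(row.community_id, row.observer_id, row.item_id, "duplicate record")
        )
    for row in long.itertuples(index=False):
        if row.item_id not in ds.catalog:
            violations.append(
                Violation(row.community_id, row.observer_id, row.item_id, "unknown item id")
            )
            continue
        if pd.isna(row.response):
            continue  # missing is admissible at dataset level
        scale = ds.catalog[row.item_id].scale
        if not scale.is_admissible(row.response):
            hi = scale.max_level
            bound = f"[{scale.min_level}, {hi if hi is not None else 'inf'}]"
            violations.append(
                Violation(
                    row.community_id,
                    row.observer_id,
                    row.item_id,
                    f"response {row.response:g} outside admissible range {bound}",
                )
            )
    meta = long[["community_id", "country"]].drop_duplicates()
    for row in meta[~meta["country"].isin(REGION_GROUPS)].itertuples(index=False):
        violations.append(
            Violation(row.community_id, "", "", f"unknown country {row.country!r}")
        )
    return violations
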