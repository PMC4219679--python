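"""Inter-rater reliability via the two-way random-effects intraclass correlation.

Each item is rated for every community by the same small panel of observers,
so both communities (rows) and observers (columns) are modelled as random:

    y_ij = mu + c_i + o_j + e_ij,   c_i ~ N(0, s2_c), o_j ~ N(0, s2_o),
                                    e_ij ~ N(0, s2_e)

The single-rater absolute-agreement ICC -- ICC(A,1) in the McGraw & Wong
taxonomy, ICC(2,1) in Shrout & Fleiss's -- is the default form, since a
systematic observer offset is a real disagreement for an audit instrument:

    ICC(A,1) = (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)

with MSR/MSC/MSE the row/column/error mean squares of the two-way ANOVA.
The consistency form ICC(C,1) = (MSR - MSE) / (MSR + (k-1) MSE) ignores
column effects and is available by flag.  95% confidence intervals use the
exact F constructions (Satterthwaite-style approximate denominator degrees of
freedom for the agreement form).

Degenerate items follow two reporting conventions: an item on which every
observer agrees exactly for every community, with the feature present (or the
response off its floor) somewhere, is reported as ICC 1.00; an item never
observed anywhere (its response at the scale floor in every community for
every observer) is reported as not calculable.  Negative point estimates are
retained internally and clipped to 0 only in display tables.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import f as f_dist
from sklearn.base import BaseEstimator

from .instrument import ItemCatalog, RatingDataset, build_catalog

__all__ = [
    "VarianceComponents",
    "ICCResult",
    "BandCounts",
    "ICCReliability",
    "anova_decompose",
    "icc_two_way_random",
    "classify_bands",
    "reliability_report",
    "load_published_icc",
    "DEFAULT_THRESHOLDS",
    "ALTERNATE_THRESHOLDS",
]

#: band cuts of the published by-region summary (>=0.7 good, <0.4 poor)
DEFAULT_THRESHOLDS = (0.4, 0.7)
#: band cuts of the published overall results text (>=0.75 high, <=0.40 low)
ALTERNATE_THRESHOLDS = (0.4, 0.6, 0.75)


@dataclass(frozen=True)
class VarianceComponents:
    """Mean squares of the two-way (communities x observers) ANOVA."""

    ms_rows: float
    ms_cols: float
    ms_error: float
    n: int
    k: int
    grand_mean: float

    @property
    def df_rows(self) -> int:
        return self.n - 1

    @property
    def df_cols(self) -> int:
        return self.k - 1

    @property
    def df_error(self) -> int:
        return (self.n - 1) * (self.k - 1)

    @property
    def ss_total(self) -> float:
        return (
            self.ms_rows * self.df_rows
            + self.ms_cols * self.df_cols
            + self.ms_error * self.df_error
        )


@dataclass(frozen=True)
class ICCResult:
    """Per-item reliability estimate with its 95% CI and degeneracy status.

    ``degeneracy`` is one of ``none``, ``constant_perfect_agreement``
    (estimate fixed at 1.00, no CI), ``never_observed`` (no estimate) or
    ``insufficient_data``.
    """

    item_id: str
    estimate: float
    ci_low: float
    ci_high: float
    n: int
    k: int
    form: str = "absolute_agreement"
    degeneracy: str = "none"
    components: VarianceComponents | None = None

    @property
    def display_estimate(self) -> float:
        """Estimate clipped to [0, 1] for reporting tables."""
        if np.isnan(self.estimate):
            return float("nan")
        return float(min(max(self.estimate, 0.0), 1.0))


def anova_decompose(values: np.ndarray) -> VarianceComponents:
    """Two-way ANOVA mean squares of a complete n x k rating grid.

    ``ms_rows = k * sum_i (rowmean_i - grand)^2 / (n-1)`` and analogously for
    columns; the error mean square is the interaction/residual term
    ``sum_ij (y_ij - rowmean_i - colmean_j + grand)^2 / ((n-1)(k-1))``.
    The row, column and error sums of squares decompose the total exactly.
    """
    y = np.asarray(values, dtype=float)
    if y.ndim != 2:
        raise ValueError("rating matrix must be 2-dimensional")
    if np.isnan(y).any():
        raise ValueError("rating matrix contains missing entries; delete listwise first")
    n, k = y.shape
    if n < 2 or k < 2:
        raise ValueError("need at least 2 communities and 2 observers")
    grand = y.mean()
    row_means = y.mean(axis=1)
    col_means = y.mean(axis=0)
    ms_rows = k * np.square(row_means - grand).sum() / (n - 1)
    ms_cols = n * np.square(col_means - grand).sum() / (k - 1)
    resid = y - row_means[:, None] - col_means[None, :] + grand
    ms_error = np.square(resid).sum() / ((n - 1) * (k - 1))
    return VarianceComponents(float(ms_rows), float(ms_cols), float(ms_error), n, k, float(grand))


def _insufficient(item_id: str, n: int, k: int, form: str) -> ICCResult:
    nan = float("nan")
    return ICCResult(item_id, nan, nan, nan, n, k, form, "insufficient_data")


def icc_two_way_random(
    values: np.ndarray,
    form: str = "absolute_agreement",
    alpha: float = 0.05,
    item_id: str = "",
    floor: float | None = 0.0,
) -> ICCResult:
    """Single-rater two-way random-effects ICC of an n x k rating grid.

    Rows (communities) with any missing entry are dropped listwise.  ``floor``
    is the response code meaning "absent"; a grid constant at the floor yields
    the ``never_observed`` convention, any other perfectly agreed grid yields
    ``constant_perfect_agreement`` with estimate 1.00.  Insufficient data
    (fewer than 2 complete rows or 2 observers) yields an
    ``insufficient_data`` result rather than an exception.
    """
    if form not in ("absolute_agreement", "consistency"):
        raise ValueError("form must be 'absolute_agreement' or 'consistency'")
    y = np.asarray(values, dtype=float)
    if y.ndim != 2:
        raise ValueError("rating matrix must be 2-dimensional")
    y = y[~np.isnan(y).any(axis=1)]
    n, k = y.shape
    if n < 2 or k < 2:
        return _insufficient(item_id, n, k, form)

    rows_constant = bool((y == y[:, [0]]).all())
    if rows_constant:
        if floor is not None and bool((y == floor).all()):
            nan = float("nan")
            return ICCResult(item_id, nan, nan, nan, n, k, form, "never_observed")
        nan = float("nan")
        return ICCResult(item_id, 1.0, nan, nan, n, k, form, "constant_perfect_agreement")

    comp = anova_decompose(y)
    # float64 arithmetic so degenerate mean squares yield inf/nan, not raises
    msr, msc, mse = (np.float64(v) for v in (comp.ms_rows, comp.ms_cols, comp.ms_error))
    with np.errstate(divide="ignore", invalid="ignore"):
        if form == "consistency":
            est = (msr - mse) / (msr + (k - 1) * mse)
            f_obs = msr / mse
            fl = f_obs / f_dist.ppf(1 - alpha / 2, n - 1, (n - 1) * (k - 1))
            fu = f_obs * f_dist.ppf(1 - alpha / 2, (n - 1) * (k - 1), n - 1)
            lo = (fl - 1) / (fl + k - 1)
            hi = (fu - 1) / (fu + k - 1)
        else:
            denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
            est = (msr - mse) / denom
            # Satterthwaite-style df for the (a MSC + b MSE) denominator
            a = (k * est) / (n * (1 - est))
            b = 1 + (k * est * (n - 1)) / (n * (1 - est))
            v_num = (a * msc + b * mse) ** 2
            v_den = (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
            v = v_num / v_den
            f1 = f_dist.ppf(1 - alpha / 2, n - 1, v)
            f2 = f_dist.ppf(1 - alpha / 2, v, n - 1)
            lo = n * (msr - f1 * mse) / (f1 * (k * msc + (k * n - k - n) * mse) + n * msr)
            hi = n * (f2 * msr - mse) / (k * msc + (k * n - k - n) * mse + n * f2 * msr)
    est, lo, hi = (float(x) if np.isfinite(x) else float("nan") for x in (est, lo, hi))
    return ICCResult(item_id, est, lo, hi, n, k, form, "none", comp)


@dataclass(frozen=True)
class BandCounts:
    """Items per reliability band, bands inclusive of their lower cut.

    ``counts[i]`` is the number of valued estimates in band i, bands ordered
    ascending: below the first threshold, then between successive thresholds
    (closed left, open right), then at/above the last threshold.
    ``n_not_calculable`` counts never-observed / unvalued items, excluded from
    the bands but part of the reporting denominator.
    """

    thresholds: tuple[float, ...]
    counts: tuple[int, ...]
    n_valued: int
    n_not_calculable: int
    group: str = "overall"

    @property
    def denominator(self) -> int:
        return self.n_valued + self.n_not_calculable

    def band_labels(self) -> tuple[str, ...]:
        t = self.thresholds
        labels = [f"<{t[0]:g}"]
        labels += [f"{a:g}-{b:g}" for a, b in zip(t[:-1], t[1:])]
        labels.append(f">={t[-1]:g}")
        return tuple(labels)

    def to_frame(self) -> pd.DataFrame:
        denom = max(self.denominator, 1)
        rows = [
            {
                "group": self.group,
                "band": label,
                "count": count,
                "denominator": self.denominator,
                "percent": 100.0 * count / denom,
            }
            for label, count in zip(self.band_labels(), self.counts)
        ]
        return pd.DataFrame(rows)


def classify_bands(
    results: Iterable[ICCResult | float],
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
    group: str = "overall",
) -> BandCounts:
    """Count reliability estimates per band with inclusive lower bounds.

    Accepts :class:`ICCResult` objects or bare estimates; not-calculable
    entries (NaN / never observed / insufficient data) are excluded from the
    bands and tallied separately.  Degenerate perfect-agreement items count as
    1.00.  Thresholds must be strictly increasing.
    """
    thresholds = tuple(float(t) for t in thresholds)
    if not thresholds or any(b <= a for a, b in zip(thresholds, thresholds[1:])):
        raise ValueError("thresholds must be non-empty and strictly increasing")
    values = []
    n_excluded = 0
    for r in results:
        est = r.estimate if isinstance(r, ICCResult) else float(r)
        if est is None or np.isnan(est):
            n_excluded += 1
        else:
            values.append(est)
    edges = np.asarray(thresholds)
    counts = [0] * (len(edges) + 1)
    for v in values:
        counts[int(np.searchsorted(edges, v, side="right"))] += 1
    return BandCounts(thresholds, tuple(counts), len(values), n_excluded, group)


def reliability_report(
    ds: RatingDataset,
    form: str = "absolute_agreement",
    alpha: float = 0.05,
    by_region: bool = False,
) -> pd.DataFrame:
    """Per-item ICC table in catalog order, optionally per regional group.

    Each item's community x observer grid is extracted, communities with any
    missing observer response deleted listwise, and the ICC estimated.  Items
    absent from the dataset (or left with fewer than 2 complete communities)
    are reported as ``insufficient_data``.  With ``by_region`` the same report
    is computed within each regional grouping having at least 2 communities,
    stacked with a ``group`` column.
    """
    groups: list[tuple[str, RatingDataset]] = [("overall", ds)]
    if by_region:
        meta = ds.communities
        for region in meta["region_group"].dropna().unique():
            ids = set(meta.loc[meta["region_group"] == region, "community_id"])
            if len(ids) < 2:
                continue
            sub = RatingDataset(ds.long[ds.long["community_id"].isin(ids)], ds.catalog)
            groups.append((region, sub))

    frames = []
    for group, sub in groups:
        rows = []
        for item in sub.catalog:
            grid = sub.item_matrix(item.item_id)
            if grid.empty or grid.shape[1] < 2:
                res = _insufficient(item.item_id, grid.shape[0], grid.shape[1], form)
            else:
                res = icc_two_way_random(
                    grid.to_numpy(float),
                    form=form,
                    alpha=alpha,
                    item_id=item.item_id,
                    floor=item.scale.floor,
                )
            rows.append(
                {
                    "group": group,
                    "item_id": item.item_id,
                    "label": item.text,
                    "n": res.n,
                    "k": res.k,
                    "icc": res.estimate,
                    "ci_low": res.ci_low,
                    "ci_high": res.ci_high,
                    "degeneracy": res.degeneracy,
                }
            )
        frames.append(pd.DataFrame(rows))
    out = pd.concat(frames, ignore_index=True)
    return out if by_region else out.drop(columns="group")


def format_reliability_table(report: pd.DataFrame) -> pd.DataFrame:
    """Display version of a report: estimates clipped to [0, 1], 2 decimals."""
    out = report.copy()
    for col in ("icc", "ci_low", "ci_high"):
        out[col] = out[col].clip(0.0, 1.0).round(2)
    return out


def load_published_icc() -> pd.DataFrame:
    """The published per-item ICC point estimates and CIs, shipped as data.

    59 items carry numeric estimates; the never-observed desert item is NaN.
    Used for band-count checks; the underlying observer responses are not
    machine-readable from the publication.
    """
    ref = importlib.resources.files("epnet.data").joinpath("published_icc.csv")
    with importlib.resources.as_file(ref) as path:
        return pd.read_csv(path)


class ICCReliability(BaseEstimator):
    """Estimator computing per-item inter-rater reliability for a dataset.

    scikit-learn style: hyperparameters in ``__init__``, data in ``fit``.
    After fitting, ``results_`` holds the per-item report (catalog order) and
    ``band_counts`` summarizes it.

    Parameters
    ----------
    form
        "absolute_agreement" (default; penalizes systematic observer offsets)
        or "consistency".
    alpha
        CI level is 1 - alpha (default 95%).
    by_region
        Also compute per-regional-group reports.
    """

    def __init__(self, form: str = "absolute_agreement", alpha: float = 0.05, by_region: bool = False):
        self.form = form
        self.alpha = alpha
        self.by_region = by_region

    def fit(self, X: RatingDataset, y=None) -> "ICCReliability":
        ds = X if isinstance(X, RatingDataset) else RatingDataset.from_long(X)
        self.results_ = reliability_report(
            ds, form=self.form, alpha=self.alpha, by_region=self.by_region
        )
        self.n_communities_ = ds.n_communities
        self.n_observers_ = ds.n_observers
        return self

    def band_counts(self, thresholds: Sequence[float] = DEFAULT_THRESHOLDS) -> BandCounts:
        if not hasattr(self, "results_"):
            raise ValueError("ICCReliability is not fitted; call fit first")
        res = self.results_
        if "group" in res.columns:
            res = res[res["group"] == "overall"]
        return classify_bands(res["icc"].tolist(), thresholds)
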