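"""Standardization of heterogeneous per-study variables into a common schema.

Multi-study pooled analyses receive each study's data in its original
coding: sun exposure as ordered frequency classes in one study, hours per
day in another, days per year in a third; nevus counts as class intervals;
and so on.  This module implements the recoding rules that map all of them
onto one harmonized scale, plus the ordered subject-level exclusion rules
applied before analysis, with an audit trail that reconciles counts exactly.

The sun-exposure target scale is *hours of exposure per day*, from 0 (no
exposure) to a cap of 6 (maximum hours per day).  Ordered classes are
mapped onto equally spaced points of [0, 6]; other continuous codings
(days/year, hours/year) are rescaled proportionally so that each study's
mean lands on the reference mean ``nu`` computed from studies natively
coded in hours/day.  The underlying assumption is that the average
exposure pattern is comparable across studies, so the recode regroups
subjects with similar exposure rather than measuring absolute dose.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MAX_HOURS_PER_DAY = 6.0

__all__ = [
    "MAX_HOURS_PER_DAY",
    "ExposureRecodingState",
    "ExclusionLog",
    "DataDictionary",
    "VariableDef",
    "recode_ordered_classes",
    "rescale_continuous_exposure",
    "compute_reference_nu",
    "average_over_periods",
    "class_to_median",
    "apply_exclusions",
    "harmonize_study",
    "EXCLUSION_ORDER",
]


def recode_ordered_classes(labels, values):
    """Map ordered exposure classes onto equally spaced hours/day.

    With ``m`` ordered classes, class ``j`` (1-based) maps to
    ``6 * (j - 1) / (m - 1)``: the four-class case (never, seldom, often,
    always) gives 0, 2, 4, 6 hours/day, and the rule generalizes linearly
    to any number of classes.  Missing values stay missing.

    Parameters
    ----------
    labels
        The class labels in increasing exposure order (at least two).
    values
        Per-subject class labels; ``None``/NaN are treated as missing.
    """
    labels = list(labels)
    m = len(labels)
    if m < 2:
        raise ValueError("at least two ordered classes required")
    mapping = {lab: MAX_HOURS_PER_DAY * j / (m - 1) for j, lab in enumerate(labels)}
    out = np.full(len(values), np.nan)
    for i, v in enumerate(values):
        if v is None or (isinstance(v, float) and np.isnan(v)):
            continue
        if v not in mapping:
            raise ValueError(f"value {v!r} not in declared class labels {labels!r}")
        out[i] = mapping[v]
    return out


@dataclass
class ExposureRecodingState:
    """Audit record of a proportional exposure rescale.

    Keeps the original values, the study mean ``mu``, the reference mean
    ``nu`` and both the pre-cap and capped recoded values, so the
    transformation can be reviewed and inverted up to the cap.
    """

    x: np.ndarray
    n: int
    mu: float
    nu: float
    x_hat_raw: np.ndarray
    x_hat: np.ndarray

    @property
    def n_capped(self) -> int:
        return int(np.nansum(self.x_hat_raw > MAX_HOURS_PER_DAY))


def rescale_continuous_exposure(x, nu: float) -> ExposureRecodingState:
    """Rescale a continuous exposure to hours/day by mean-matching.

    Each observation is recoded as ``x_hat_i = nu * x_i / mu`` where ``mu``
    is the study mean over non-missing values, so the study mean maps onto
    the reference mean ``nu``; recoded values above 6 hours/day are set to
    6.  Raises if the study mean is zero (scale undefined: the variable is
    unusable for this study).
    """
    x = np.asarray(x, dtype=float)
    if nu <= 0:
        raise ValueError("reference mean nu must be positive")
    nonmiss = x[~np.isnan(x)]
    if nonmiss.size == 0:
        raise ValueError("no non-missing exposure values")
    mu = float(nonmiss.mean())
    if mu == 0:
        raise ValueError("study mean is zero: exposure scale undefined, flag variable unusable")
    raw = nu * x / mu
    capped = np.minimum(raw, MAX_HOURS_PER_DAY)
    return ExposureRecodingState(x, int(nonmiss.size), mu, nu, raw, capped)


def compute_reference_nu(hours_per_day_datasets) -> float:
    """Reference mean exposure ``nu`` from studies coded in hours/day.

    Subject-weighted: all non-missing values from the qualifying studies
    are pooled and averaged, so a study of 300 subjects contributes three
    times the weight of one with 100.
    """
    pooled = []
    for x in hours_per_day_datasets:
        x = np.asarray(x, dtype=float)
        pooled.append(x[~np.isnan(x)])
    if not pooled or sum(p.size for p in pooled) == 0:
        raise ValueError(
            "no dataset natively coded in hours/day: designate at least one "
            "reference study before rescaling continuous exposures"
        )
    nu = float(np.concatenate(pooled).mean())
    if not 0 < nu <= MAX_HOURS_PER_DAY:
        raise ValueError(f"reference mean {nu:.3g} outside (0, {MAX_HOURS_PER_DAY}]")
    return nu


def average_over_periods(values, years):
    """Duration-weighted average of exposures reported over time periods.

    ``values`` and ``years`` are subjects x periods arrays; the result per
    subject is ``sum(value * years) / sum(years)`` over periods where the
    value is non-missing.  Subjects with no usable period get NaN.
    """
    v = np.atleast_2d(np.asarray(values, dtype=float))
    y = np.atleast_2d(np.asarray(years, dtype=float))
    if v.shape != y.shape:
        raise ValueError("values and durations must have the same shape")
    if (y < 0).any():
        raise ValueError("negative period durations")
    ok = ~np.isnan(v) & (y > 0)
    wsum = np.where(ok, y, 0.0).sum(axis=1)
    num = np.where(ok, v * y, 0.0).sum(axis=1)
    out = np.full(v.shape[0], np.nan)
    np.divide(num, wsum, out=out, where=wsum > 0)
    return out


def class_to_median(intervals, open_maximum: float | None = None):
    """Recode class intervals to their medians (midpoints).

    A closed interval ``(a, b)`` maps to ``(a + b) / 2``; the open top
    category ``(a, None)`` maps to ``(a + open_maximum) / 2``, where the
    maximum is chosen from the observed pooled data.  Returns the list of
    numeric codes, one per interval.
    """
    prev_hi = -np.inf
    out = []
    for i, (a, b) in enumerate(intervals):
        if b is None:
            if open_maximum is None:
                raise ValueError("open top category requires an explicit maximum")
            if open_maximum < a:
                raise ValueError("open-category maximum below its lower bound")
            out.append((a + open_maximum) / 2)
            if i != len(intervals) - 1:
                raise ValueError("open category must be the last interval")
            continue
        if b < a:
            raise ValueError(f"interval ({a}, {b}) reversed")
        if a < prev_hi:
            raise ValueError("intervals overlap or are out of order")
        prev_hi = b
        out.append((a + b) / 2)
    return out


# --------------------------------------------------------------------------
# subject-level exclusions

#: Exclusion rules in their declared application order (first match wins).
EXCLUSION_ORDER = (
    "multiple_primary_melanoma",
    "missing_all_genotypes",
    "non_skin_melanoma",
    "atypical_mole_syndrome_noncase",
    "non_first_primary",
    "familial_melanoma",
    "other_invalid_status",
)


def _rule_mask(rule: str, df: pd.DataFrame, variant_cols) -> pd.Series:
    def col(name, default=0):
        return df[name] if name in df.columns else pd.Series(default, index=df.index)

    if rule == "multiple_primary_melanoma":
        return col("multiple_primary").fillna(0).astype(float) > 0
    if rule == "missing_all_genotypes":
        cols = [c for c in variant_cols if c in df.columns]
        if not cols:
            return pd.Series(True, index=df.index)
        return df[cols].isna().all(axis=1)
    if rule == "non_skin_melanoma":
        return col("case_type", "").astype(str) == "non_skin_melanoma"
    if rule == "atypical_mole_syndrome_noncase":
        ams = col("atypical_mole_syndrome").fillna(0).astype(float) > 0
        return ams & (col("status").fillna(-1).astype(float) == 0)
    if rule == "non_first_primary":
        fp = col("first_primary", 1).fillna(1).astype(float)
        return (fp == 0) & (col("status").fillna(0).astype(float) == 1)
    if rule == "familial_melanoma":
        # familial: >=2 first-degree OR >=3 any-degree affected relatives
        first = col("relatives_first_degree").fillna(0).astype(float)
        anyd = col("relatives_any_degree").fillna(0).astype(float)
        return (first >= 2) | (np.maximum(anyd, first) >= 3)
    if rule == "other_invalid_status":
        return ~col("status").astype(float).isin([0.0, 1.0])
    raise KeyError(f"unknown exclusion rule: {rule!r}")


@dataclass
class ExclusionLog:
    """Ordered audit of subject exclusions; counts always reconcile."""

    initial: int
    entries: list = field(default_factory=list)  # (rule, count, ids)
    final: int = 0

    def validate(self) -> None:
        removed = sum(c for _, c, _ in self.entries)
        if self.initial - removed != self.final:
            raise AssertionError(
                f"exclusion log does not reconcile: {self.initial} - {removed} "
                f"!= {self.final}"
            )

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(r, c) for r, c, _ in self.entries], columns=["rule", "removed"]
        )


def apply_exclusions(df: pd.DataFrame, rules=EXCLUSION_ORDER, variant_cols=()):
    """Apply subject-level exclusion rules in order, first match wins.

    Each subject is removed under the first rule it matches, so the
    per-rule counts are disjoint and sum to initial - final.  Returns the
    retained rows and an :class:`ExclusionLog`.
    """
    log = ExclusionLog(initial=len(df))
    remaining = df
    for rule in rules:
        mask = _rule_mask(rule, remaining, variant_cols)
        hit = remaining.index[mask.to_numpy(dtype=bool)]
        log.entries.append((rule, len(hit), list(hit)))
        remaining = remaining.drop(index=hit)
    log.final = len(remaining)
    log.validate()
    return remaining, log


# --------------------------------------------------------------------------
# data dictionary driven harmonization


@dataclass
class VariableDef:
    """How one study variable maps onto a harmonized target variable."""

    source: str
    rule: str  # identity | ordered_classes | rescale_continuous | class_median | periods_average
    params: dict = field(default_factory=dict)


@dataclass
class DataDictionary:
    """Per-study recode plan: target variable -> :class:`VariableDef`."""

    variables: dict

    def __post_init__(self):
        known = {
            "identity",
            "ordered_classes",
            "rescale_continuous",
            "class_median",
            "periods_average",
        }
        for target, vd in self.variables.items():
            if vd.rule not in known:
                raise ValueError(f"{target}: unknown recode rule {vd.rule!r}")


def harmonize_study(df: pd.DataFrame, dictionary: DataDictionary, nu: float | None = None):
    """Recode one study table onto the harmonized schema.

    Applies each variable's declared rule; ``rescale_continuous`` requires
    the reference mean ``nu`` (see :func:`compute_reference_nu`).  Columns
    not mentioned in the dictionary pass through unchanged.
    """
    out = df.copy()
    for target, vd in dictionary.variables.items():
        if vd.source not in df.columns:
            raise KeyError(f"source column {vd.source!r} for {target!r} missing")
        src = df[vd.source]
        if vd.rule == "identity":
            out[target] = src.astype(float) if vd.params.get("numeric", True) else src
        elif vd.rule == "ordered_classes":
            out[target] = recode_ordered_classes(vd.params["labels"], src.tolist())
        elif vd.rule == "rescale_continuous":
            if nu is None:
                raise ValueError(f"{target}: rescale_continuous requires reference nu")
            out[target] = rescale_continuous_exposure(src.to_numpy(float), nu).x_hat
        elif vd.rule == "class_median":
            medians = class_to_median(vd.params["intervals"], vd.params.get("open_maximum"))
            mapping = dict(zip(vd.params["labels"], medians))
            out[target] = src.map(mapping).astype(float)
        elif vd.rule == "periods_average":
            cols_v = vd.params["value_columns"]
            cols_y = vd.params["year_columns"]
            out[target] = average_over_periods(
                df[cols_v].to_numpy(float), df[cols_y].to_numpy(float)
            )
        if target != vd.source and vd.source in out.columns:
            out = out.drop(columns=[vd.source])
    return out
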