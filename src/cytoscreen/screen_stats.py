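"""Plate and screen statistics: Z′-factor QC, Z-score hit calling, FP/FN.

Assay quality is scored with the Z′-factor

    Z' = 1 - 3 (sigma_s + sigma_c) / |mu_s - mu_c|

where *s* is the positive-control and *c* the negative-control
population; Z' approaches 1 for a wide, tight separation and drops
below 0 when the controls overlap. Compound wells are scored as
Z-scores against the negative controls of their screening batch,

    Z = (x - mu_c) / sigma_c,

with hits called at an absolute Z-score of 2 or more (inclusive; the
two-sided normal tail at |Z| = 2 is p ≈ 0.045). False positives are
negative-control wells with |Z| strictly greater than the cutoff, false
negatives positive-control wells with |Z| strictly less than it —
the strict/inclusive asymmetry between the two definitions is kept
deliberately. Sample SDs use the n−1 denominator throughout; wells
flagged excluded (e.g. compound precipitate) never enter any statistic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DegenerateControlsError, InputError, InsufficientDataError
from .phenotypes import ENDPOINTS

ROLES = ("compound", "negative_control", "positive_control", "excluded")

HIT_COLUMNS = [
    "compound_id",
    "endpoint",
    "timepoint_h",
    "n_replicates",
    "aggregated_value",
    "z_score",
    "is_hit",
]


@dataclass
class ControlStats:
    """Location/spread of one control population for one endpoint."""

    endpoint: str
    mean: float
    sd: float
    cv_pct: float
    n: int


def control_stats(values: Sequence[float], endpoint: str = "n_cells") -> ControlStats:
    """Sample mean, SD (n−1) and CV% of a control population.

    CV is reported as NaN when the mean is zero.
    """
    arr = np.asarray(list(values), dtype=float)
    if arr.size < 2:
        raise InsufficientDataError(f"need >= 2 control values, got {arr.size}")
    if not np.all(np.isfinite(arr)):
        raise InputError("control values must be finite")
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1))
    cv = float("nan") if mean == 0 else 100.0 * sd / abs(mean)
    return ControlStats(endpoint=endpoint, mean=mean, sd=sd, cv_pct=cv, n=arr.size)


def zprime(pos: ControlStats, neg: ControlStats) -> float:
    """Z′-factor of a positive/negative control pair (symmetric in its args)."""
    sep = abs(pos.mean - neg.mean)
    if sep == 0:
        raise DegenerateControlsError("control means are equal; Z' undefined")
    return 1.0 - 3.0 * (pos.sd + neg.sd) / sep


def zscore(value: float, neg: ControlStats) -> float:
    """Standardise a well value by the negative-control mean and SD."""
    if neg.sd <= 0:
        raise DegenerateControlsError("negative-control SD must be > 0 for Z-scores")
    return (value - neg.mean) / neg.sd


def hit_cutoff_pvalue(z_cutoff: float = 2.0) -> float:
    """Two-sided standard-normal tail probability of the hit cutoff."""
    return float(2.0 * sps.norm.sf(z_cutoff))


def percent_of_control(values: Sequence[float], neg_mean: float) -> list[float]:
    """Express well values as percent of the negative-control mean."""
    if neg_mean == 0:
        raise InputError("negative-control mean is zero; percent-of-control undefined")
    return [100.0 * float(v) / neg_mean for v in values]


# ---------------------------------------------------------------------------
# layout handling


def _merge(summaries: pd.DataFrame, layout: pd.DataFrame) -> pd.DataFrame:
    for col in ("plate_id", "well_id"):
        if col not in summaries.columns or col not in layout.columns:
            raise InputError(f"summaries and layout both need a '{col}' column")
    merged = summaries.merge(layout, on=["plate_id", "well_id"], how="inner", validate="1:1")
    if "excluded" in merged.columns:
        merged = merged[~merged["excluded"].fillna(False).astype(bool)]
    merged = merged[merged["role"] != "excluded"]
    return merged


def _check_endpoint(endpoint: str) -> None:
    if endpoint not in ENDPOINTS:
        raise InputError(f"unknown endpoint {endpoint!r}; expected one of {ENDPOINTS}")


def _batches(merged: pd.DataFrame, batch_scope: str):
    if batch_scope == "plate":
        yield from ((str(k), g) for k, g in merged.groupby("plate_id"))
    elif batch_scope == "batch":
        if "batch_id" in merged.columns and merged["batch_id"].notna().any():
            yield from ((str(k), g) for k, g in merged.groupby("batch_id"))
        else:
            # default reading: the plate set processed together is one batch
            yield "batch", merged
    else:
        raise InputError("batch_scope must be 'batch' or 'plate'")


def _neg_stats(batch: pd.DataFrame, endpoint: str) -> ControlStats:
    neg = batch.loc[batch["role"] == "negative_control", endpoint]
    return control_stats(neg.to_numpy(), endpoint)


def call_hits(
    well_summaries: pd.DataFrame,
    layout: pd.DataFrame,
    endpoint: str,
    timepoint_h: int | None = None,
    z_cutoff: float = 2.0,
    replicate_agg: str = "mean",
    batch_scope: str = "batch",
) -> pd.DataFrame:
    """Call compound hits at |Z| >= ``z_cutoff`` against batch negative controls.

    Replicate compound wells are aggregated to one value per compound
    before scoring (``replicate_agg``: ``mean`` (default), ``median``, or
    ``per_well_any`` which scores every replicate and flags a hit when any
    replicate crosses the cutoff; the reported Z is then the most extreme
    replicate's). Compounds with no usable replicate wells appear with
    ``n_replicates = 0``, NaN Z and ``is_hit = False``.
    """
    _check_endpoint(endpoint)
    if replicate_agg not in ("mean", "median", "per_well_any"):
        raise InputError("replicate_agg must be 'mean', 'median' or 'per_well_any'")
    merged = _merge(well_summaries, layout)
    if timepoint_h is not None:
        merged = merged[merged["timepoint_h"] == timepoint_h]

    records = []
    for batch_id, batch in _batches(merged, batch_scope):
        neg = _neg_stats(batch, endpoint)
        if neg.sd <= 0:
            raise DegenerateControlsError(
                f"batch {batch_id}: negative controls have zero spread"
            )
        compounds = batch[batch["role"] == "compound"]
        all_ids = compounds["compound_id"].dropna().unique()
        for cid in sorted(all_ids):
            vals = compounds.loc[compounds["compound_id"] == cid, endpoint].dropna()
            n_rep = len(vals)
            if n_rep == 0:
                records.append((cid, endpoint, timepoint_h, 0, np.nan, np.nan, False, batch_id))
                continue
            if replicate_agg == "per_well_any":
                zs = np.array([zscore(v, neg) for v in vals])
                z = float(zs[np.argmax(np.abs(zs))])
                agg = float(vals.mean())
                hit = bool(np.any(np.abs(zs) >= z_cutoff))
            else:
                agg = float(vals.mean() if replicate_agg == "mean" else vals.median())
                z = zscore(agg, neg)
                hit = bool(abs(z) >= z_cutoff)
            records.append((cid, endpoint, timepoint_h, n_rep, agg, z, hit, batch_id))

    return pd.DataFrame(records, columns=HIT_COLUMNS + ["batch_id"])


def fp_fn_rates(
    well_summaries: pd.DataFrame,
    layout: pd.DataFrame,
    endpoint: str,
    neg: ControlStats | None = None,
    z_cutoff: float = 2.0,
) -> tuple[float, float]:
    """False-positive and false-negative rates on control wells.

    Per-well Z-scores (no replicate aggregation) against the
    negative-control statistics; FP = fraction of negative wells with
    |Z| strictly above the cutoff, FN = fraction of positive wells with
    |Z| strictly below it.
    """
    _check_endpoint(endpoint)
    merged = _merge(well_summaries, layout)
    negs = merged.loc[merged["role"] == "negative_control", endpoint].dropna()
    poss = merged.loc[merged["role"] == "positive_control", endpoint].dropna()
    if negs.empty or poss.empty:
        raise InsufficientDataError("both negative and positive control wells are required")
    if neg is None:
        neg = control_stats(negs.to_numpy(), endpoint)
    z_neg = np.abs((negs.to_numpy() - neg.mean) / neg.sd)
    z_pos = np.abs((poss.to_numpy() - neg.mean) / neg.sd)
    return float(np.mean(z_neg > z_cutoff)), float(np.mean(z_pos < z_cutoff))


def qc_report(
    well_summaries: pd.DataFrame,
    layout: pd.DataFrame,
    endpoints: Sequence[str] = ENDPOINTS,
    z_cutoff: float = 2.0,
    batch_scope: str = "batch",
) -> pd.DataFrame:
    """Per-batch, per-endpoint QC table: Z′, control stats, FP/FN rates."""
    merged = _merge(well_summaries, layout)
    rows = []
    for batch_id, batch in _batches(merged, batch_scope):
        for ep in endpoints:
            _check_endpoint(ep)
            neg_vals = batch.loc[batch["role"] == "negative_control", ep].dropna()
            pos_vals = batch.loc[batch["role"] == "positive_control", ep].dropna()
            neg = control_stats(neg_vals.to_numpy(), ep)
            pos = control_stats(pos_vals.to_numpy(), ep)
            fp, fn = fp_fn_rates(well_summaries, layout, ep, neg=neg, z_cutoff=z_cutoff)
            rows.append(
                {
                    "batch_id": batch_id,
                    "endpoint": ep,
                    "zprime": zprime(pos, neg),
                    "neg_mean": neg.mean,
                    "neg_sd": neg.sd,
                    "pos_mean": pos.mean,
                    "pos_sd": pos.sd,
                    "fp_rate": fp,
                    "fn_rate": fn,
                }
            )
    return pd.DataFrame(rows)


def dose_response_table(
    well_summaries: pd.DataFrame,
    layout: pd.DataFrame,
    compound_id: str,
    endpoint: str,
) -> pd.DataFrame:
    """Per-dose summary for one compound, plus a monotonic-trend flag.

    Rows are sorted by ascending dose within each timepoint; the trend
    flag is the sign of the Spearman correlation of dose vs per-dose mean
    (``increasing``/``decreasing``/``none``; NaN with fewer than 2 doses).
    Percent-of-control uses the same timepoint's negative-control mean.
    """
    _check_endpoint(endpoint)
    merged = _merge(well_summaries, layout)
    sub = merged[(merged["role"] == "compound") & (merged["compound_id"] == compound_id)]
    if sub.empty:
        raise InputError(f"unknown compound {compound_id!r}")

    rows = []
    for tp, tp_group in sub.groupby("timepoint_h", dropna=False):
        neg_sel = merged["role"] == "negative_control"
        if not pd.isna(tp):
            neg_sel &= merged["timepoint_h"] == tp
        neg_mean = merged.loc[neg_sel, endpoint].mean()
        per_dose = (
            tp_group.groupby("dose_uM")[endpoint]
            .agg(mean="mean", sd=lambda s: s.std(ddof=1), n="size")
            .reset_index()
            .sort_values("dose_uM")
        )
        if len(per_dose) >= 2 and per_dose["mean"].nunique() > 1:
            rho = sps.spearmanr(per_dose["dose_uM"], per_dose["mean"]).statistic
            trend = "increasing" if rho > 0 else ("decreasing" if rho < 0 else "none")
        elif len(per_dose) >= 2:
            trend = "none"
        else:
            trend = None
        for _, r in per_dose.iterrows():
            rows.append(
                {
                    "compound_id": compound_id,
                    "endpoint": endpoint,
                    "timepoint_h": tp,
                    "dose_uM": r["dose_uM"],
                    "mean": r["mean"],
                    "sd": r["sd"],
                    "n": int(r["n"]),
                    "pct_of_control": 100.0 * r["mean"] / neg_mean if neg_mean else np.nan,
                    "trend": trend,
                }
            )
    return pd.DataFrame(rows)


def cross_timepoint_hits(hits: pd.DataFrame) -> pd.DataFrame:
    """Convenience: per compound × endpoint, flag hits at every timepoint.

    Adds ``hit_all_timepoints`` to a per-timepoint hit table produced by
    :func:`call_hits` runs concatenated over timepoints.
    """
    both = (
        hits.groupby(["compound_id", "endpoint"])["is_hit"]
        .agg(lambda s: bool(s.all()) and len(s) > 1)
        .rename("hit_all_timepoints")
        .reset_index()
    )
    return hits.merge(both, on=["compound_id", "endpoint"], how="left")
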