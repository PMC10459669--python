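"""Bioactivity table curation: type/label filtering, value integration,
activity classification, and per-target scale filtering.

Records carry potencies in -logM (negative decadic log of a molar
concentration, so 1 uM = 6).  Curation keeps the five routinely assayed
activity types, keeps only structure-consistent cross-database matches,
integrates repeated measurements of one molecule by unit-width -logM
bucketing (the most populated bucket's mean wins), classifies active vs
inactive at the 1 uM threshold, and drops targets with too few endpoints to
support a per-target regression model.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .errors import EmptyInputError

logger = logging.getLogger(__name__)

ALLOWED_ACTIVITY_TYPES = frozenset({"IC50", "Ki", "Kd", "EC50", "Potency"})
ALLOWED_MATCH_LABELS = frozenset({"1 structure", "match"})
ACTIVE_THRESHOLD_LOGM = 6.0          # 1 uM
DEFAULT_MIN_ENDPOINTS = 300


def to_neg_log_molar(value_molar: float) -> float:
    """Convert a molar concentration to -logM (1e-6 M -> 6.0)."""
    if value_molar <= 0:
        raise ValueError("molar concentration must be positive")
    return float(-np.log10(value_molar))


def filter_records(table: pd.DataFrame) -> pd.DataFrame:
    """Keep the five allowed activity types and structure-consistent labels.

    Rows with non-finite values are dropped too; every drop is logged with
    its reason.
    """
    if table.empty:
        return table.copy()
    keep_type = table["activity_type"].isin(ALLOWED_ACTIVITY_TYPES)
    keep_match = table["match_label"].isin(ALLOWED_MATCH_LABELS)
    keep_value = np.isfinite(
        pd.to_numeric(table["value_logM"], errors="coerce")
    )
    for reason, mask in [
        ("activity type outside whitelist", ~keep_type),
        ("match label not structure-consistent", ~keep_match),
        ("non-finite value", ~keep_value),
    ]:
        n = int(mask.sum())
        if n:
            logger.info("dropping %d records: %s", n, reason)
    return table[keep_type & keep_match & keep_value].copy()


def bucket_integrate(values) -> float:
    """Integrate repeated -logM measurements of one endpoint.

    Values are binned into half-open unit buckets [k, k+1) on integer -logM
    edges; the mean of the most populated bucket is returned.  Frequency
    ties go to the more potent (higher -logM) bucket.
    """
    values = np.asarray(list(values), dtype=np.float64)
    if values.size == 0:
        raise EmptyInputError("bucket_integrate on empty value list")
    buckets = np.floor(values).astype(np.int64)
    keys, counts = np.unique(buckets, return_counts=True)
    best = keys[counts == counts.max()].max()  # tie -> higher -logM
    return float(values[buckets == best].mean())


def classify_active(value_logM: float, threshold: float = ACTIVE_THRESHOLD_LOGM) -> str:
    """Label a potency as active (>= 6 -logM, i.e. <= 1 uM) or inactive."""
    if not np.isfinite(value_logM):
        raise ValueError("value must be finite")
    return "active" if value_logM >= threshold else "inactive"


def filter_targets(
    table: pd.DataFrame, min_endpoints: int = DEFAULT_MIN_ENDPOINTS
) -> pd.DataFrame:
    """Drop all records of targets with fewer than `min_endpoints` endpoints."""
    if table.empty:
        return table.copy()
    counts = table.groupby("target_id")["target_id"].transform("size")
    dropped = table.loc[counts < min_endpoints, "target_id"].nunique()
    if dropped:
        logger.info("dropping %d targets below %d endpoints", dropped, min_endpoints)
    return table[counts >= min_endpoints].copy()


def curate(
    table: pd.DataFrame, min_endpoints: int = DEFAULT_MIN_ENDPOINTS
) -> pd.DataFrame:
    """Full curation: record filters, per-endpoint value integration, then
    the per-target scale filter.  One row per (molecule, target) remains."""
    kept = filter_records(table)
    if kept.empty:
        return kept
    integrated = (
        kept.groupby(["molecule_id", "target_id"], sort=False)
        .agg(
            smiles=("smiles", "first"),
            activity_type=("activity_type", "first"),
            value_logM=("value_logM", bucket_integrate),
            source=("source", "first"),
        )
        .reset_index()
    )
    integrated["activity_class"] = integrated["value_logM"].map(classify_active)
    return filter_targets(integrated, min_endpoints=min_endpoints)
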