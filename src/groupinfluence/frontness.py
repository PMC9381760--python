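"""Propensity of individuals to occupy the front half of the group.

An individual is in the front half at time t when its front-back position in
the full-group centroid frame is strictly positive (a position exactly on
the centroid line counts as back). Proportions are reported per contiguous
segment (default one hour) with enough valid samples, plus a per-individual
overall mean across all valid time points, the 'frontness' covariate used in
the status models and correlations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .frame import KinematicTable


@dataclass
class FrontnessRecord:
    individual_id: str
    session_id: str
    segment_start: float
    segment_length: float
    prop_front: float
    n_valid: int
    overall_mean: float


def frontness_proportions(
    table: KinematicTable,
    segment: float = 3600.0,
    min_valid: int = 600,
) -> pd.DataFrame:
    """Per-segment and overall front-half occupancy per individual.

    Segments are aligned to session start; a final partial segment is kept
    when it still holds at least ``min_valid`` valid samples. Returns a tidy
    frame (ind_id, session_id, segment_start, prop_front, n_valid,
    overall_mean); empty segments are omitted.
    """
    df = table.df
    rows = df[df["valid_position"].astype(bool)].copy()
    if rows.empty:
        return pd.DataFrame(
            columns=[
                "ind_id", "session_id", "segment_start", "prop_front",
                "n_valid", "overall_mean",
            ]
        )
    rows["front"] = (rows["fb_position"] > 0).astype(float)
    overall = rows.groupby("focal_id")["front"].mean()
    rows["segment_start"] = (rows["t"] // segment) * segment

    recs = []
    grouped = rows.groupby(["focal_id", "session_id", "segment_start"])
    for (ind, sid, seg), g in grouped:
        n = len(g)
        if n < min_valid:
            continue
        recs.append(
            {
                "ind_id": ind,
                "session_id": sid,
                "segment_start": float(seg),
                "prop_front": float(g["front"].mean()),
                "n_valid": n,
                "overall_mean": float(overall[ind]),
            }
        )
    return pd.DataFrame(recs)


def frontness_summary(records: pd.DataFrame) -> pd.DataFrame:
    """One row per individual: overall frontness and segment count."""
    if records.empty:
        return pd.DataFrame(columns=["ind_id", "frontness", "n_segments"])
    out = (
        records.groupby("ind_id")
        .agg(frontness=("overall_mean", "first"), n_segments=("prop_front", "size"))
        .reset_index()
    )
    return out
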