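"""Multitarget product score, reference thresholding, and rank cascades.

The multitarget score of a candidate is the plain product of its per-target
affinity scores (each in [0, 1]):

    MScore = DAS_target1 x DAS_target2 [x ...]

so it is high only when every single-target score is high — one weak target
annihilates the product. Screening ranks candidates by MScore and selects
those at or above a threshold, canonically the MScore of a pair of known
reference inhibitors (one per target). `retain_fraction` is the generic
"keep the best x%" filter used to cascade ranked lists.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class ScreenResult:
    """Per-compound screening outcome."""

    compound_id: str
    das_by_target: dict[str, float]
    mscore: float
    rank: int
    selected: bool


def mscore(das_values: Sequence[float]) -> float:
    """Product of >=2 per-target scores, each validated to lie in [0, 1]."""
    if len(das_values) < 2:
        raise ValueError(f"mscore needs >=2 per-target scores, got {len(das_values)}")
    for v in das_values:
        if not (0.0 <= v <= 1.0):
            raise ValueError(f"DAS value out of [0, 1]: {v}")
    return math.prod(das_values)


def screen(
    das_table: pd.DataFrame,
    reference_das: Mapping[str, float] | None = None,
    threshold: float | None = None,
) -> pd.DataFrame:
    """Rank candidates by multitarget score and flag the selected ones.

    Parameters
    ----------
    das_table
        One row per compound (index = compound id), one column per target,
        values in [0, 1]. Every candidate must be scored on every target.
    reference_das
        Per-target scores of the reference compounds; the selection
        threshold is their product. Keys must match the table columns.
    threshold
        Explicit threshold overriding the reference-derived one.

    Returns
    -------
    DataFrame with the per-target scores, ``mscore``, ``rank`` (1 = best)
    and ``selected`` (mscore >= threshold, inclusive so the references pass
    their own bar); sorted by descending mscore, ties broken by ascending
    compound id. The threshold used is stored in ``.attrs["threshold"]``.
    """
    if das_table.shape[1] < 2:
        raise ValueError("screening needs >=2 target columns")
    if das_table.isna().any().any():
        bad = das_table.index[das_table.isna().any(axis=1)].tolist()
        raise ValueError(f"missing target scores for compounds: {bad}")
    arr = das_table.to_numpy(dtype=float)
    if ((arr < 0) | (arr > 1)).any():
        raise ValueError("DAS values must lie in [0, 1]")

    if threshold is None:
        if reference_das is None:
            raise ValueError("provide reference_das or an explicit threshold")
        missing = set(das_table.columns) - set(reference_das)
        if missing:
            raise ValueError(f"reference_das lacks targets: {sorted(missing)}")
        threshold = mscore([reference_das[t] for t in das_table.columns])

    out = das_table.copy()
    out.columns = [f"das_{t}" for t in das_table.columns]
    out["mscore"] = arr.prod(axis=1)
    out = _sorted_by_mscore(out)
    out["rank"] = np.arange(1, len(out) + 1)
    out["selected"] = out["mscore"] >= threshold
    out.attrs["threshold"] = float(threshold)
    return out


def _sorted_by_mscore(df: pd.DataFrame) -> pd.DataFrame:
    order = sorted(range(len(df)), key=lambda i: (-df["mscore"].iloc[i], str(df.index[i])))
    return df.iloc[order]


def to_records(report: pd.DataFrame) -> list[ScreenResult]:
    """Convert a `screen` report into typed per-compound records."""
    das_cols = [c for c in report.columns if c.startswith("das_")]
    return [
        ScreenResult(
            compound_id=str(idx),
            das_by_target={c[len("das_"):]: float(row[c]) for c in das_cols},
            mscore=float(row["mscore"]),
            rank=int(row["rank"]),
            selected=bool(row["selected"]),
        )
        for idx, row in report.iterrows()
    ]


def retain_fraction(
    scored_items: Sequence[tuple[str, float]],
    fraction: float = 0.5,
    better: str = "higher",
) -> list[tuple[str, float]]:
    """Keep the best `fraction` of items (floor, minimum 1) by score.

    `better` states the score polarity: ``"higher"`` for similarity-like
    scores, ``"lower"`` for energies/docking scores. Ties break by id for
    reproducibility.
    """
    if not scored_items:
        raise ValueError("retain_fraction needs a non-empty list")
    if not 0.0 < fraction <= 1.0:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    if better not in {"higher", "lower"}:
        raise ValueError(f"better must be 'higher' or 'lower', got {better!r}")
    for item_id, score in scored_items:
        if not math.isfinite(score):
            raise ValueError(f"non-finite score for {item_id!r}: {score}")
    sign = -1.0 if better == "higher" else 1.0
    ranked = sorted(scored_items, key=lambda t: (sign * t[1], str(t[0])))
    k = max(1, math.floor(fraction * len(scored_items)))
    return ranked[:k]
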