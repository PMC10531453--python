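"""Cell-line-panel concordance between drug potency and target expression.

Given a compound's antiproliferative activity pattern (GI50 across a panel
of tumor cell lines, canonically the 60-line NCI panel) and a target
protein's expression pattern across the same lines, each vector is
normalized by mean-centering and dividing by its maximum absolute
deviation, so every entry lies in [-1, 1] and the most extreme line sits
at +/-1. The matching score is then

    delta_i = NEP_i * NGI50_i          (per cell line)
    Phi     = sum_i delta_i            (over the panel)

Phi reaches the panel size L only for identical two-level +/-1 patterns and
is near 0 for unrelated patterns; a high Phi says the compound is most
potent exactly in the lines where the target is most expressed, which is
COMPARE-style evidence that the target mediates the activity. With several
expression experiments per target, the per-target value is the maximum Phi
over experiments, and the cross-target mean of those maxima summarizes a
putative multi-target compound.

GI50 is a concentration (lower = more potent), so raw molar GI50 enters as
-log10 by default (`orientation="negated_log10"`): positive Phi then means
"more potent where more expressed". Already potency-oriented inputs use
`orientation="as_is"`.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

NCI60_SIZE = 60


def round_half_up(x: float) -> int:
    """Round to the nearest integer, halves away from zero upward (26.5 -> 27)."""
    return int(Decimal(repr(float(x))).quantize(Decimal("1"), rounding=ROUND_HALF_UP))


@dataclass
class CellLinePanel:
    """One raw pattern (expression or activity) over a panel of cell lines."""

    cell_line_ids: list[str]
    raw: np.ndarray = field(repr=False)
    kind: str = "expression"  # "expression" | "activity"
    orientation: str = "as_is"  # "as_is" | "negated_log10"

    def __post_init__(self) -> None:
        self.raw = np.asarray(self.raw, dtype=float)
        if len(self.cell_line_ids) != self.raw.shape[0]:
            raise ValueError(
                f"{len(self.cell_line_ids)} cell line ids but {self.raw.shape[0]} values"
            )
        if self.kind not in {"expression", "activity"}:
            raise ValueError(f"kind must be 'expression' or 'activity', got {self.kind!r}")
        if self.orientation not in {"as_is", "negated_log10"}:
            raise ValueError(f"unknown orientation {self.orientation!r}")

    def __len__(self) -> int:
        return len(self.cell_line_ids)

    def oriented_values(self) -> np.ndarray:
        """Raw values on the "larger = stronger" scale used for matching."""
        if self.orientation == "negated_log10":
            if np.nanmin(self.raw) <= 0:
                raise ValueError("negated_log10 orientation requires strictly positive raw values")
            return -np.log10(self.raw)
        return self.raw.copy()


@dataclass(frozen=True)
class NormalizedPattern:
    """Mean-centered, max-abs-scaled pattern in [-1, 1]."""

    cell_line_ids: tuple[str, ...]
    values: np.ndarray = field(repr=False)
    mu: float = 0.0
    max_abs_dev: float = 0.0


@dataclass(frozen=True)
class MatchingResult:
    """Per-line delta products and their sum Phi for one pattern pair."""

    per_cell_delta: np.ndarray = field(repr=False)
    phi: float = 0.0


def drop_missing_pairs(a: CellLinePanel, b: CellLinePanel) -> tuple[CellLinePanel, CellLinePanel]:
    """Drop cell lines missing in either panel (pairwise), preserving order."""
    if a.cell_line_ids != b.cell_line_ids:
        raise ValueError("panels must share the same cell-line ids in the same order")
    keep = np.isfinite(a.raw) & np.isfinite(b.raw)
    dropped = int((~keep).sum())
    if dropped:
        logger.info("dropped %d cell lines with missing values (pairwise)", dropped)
    ids = [cid for cid, k in zip(a.cell_line_ids, keep) if k]
    return (
        CellLinePanel(ids, a.raw[keep], a.kind, a.orientation),
        CellLinePanel(ids, b.raw[keep], b.kind, b.orientation),
    )


def normalize_pattern(panel: CellLinePanel) -> NormalizedPattern:
    """Mean-center and scale by the maximum absolute deviation.

    A constant pattern has no deviations to scale; it normalizes to all
    zeros (with a warning) and contributes nothing to any matching score.
    """
    if len(panel) < 2:
        raise ValueError(f"normalization needs >=2 cell lines, got {len(panel)}")
    v = panel.oriented_values()
    if not np.isfinite(v).all():
        raise ValueError("pattern contains missing values; apply drop_missing_pairs first")
    mu = float(v.mean())
    dev = v - mu
    m = float(np.abs(dev).max())
    if m == 0.0:
        logger.warning("constant %s pattern: normalized to all zeros", panel.kind)
        return NormalizedPattern(tuple(panel.cell_line_ids), np.zeros_like(dev), mu, 0.0)
    return NormalizedPattern(tuple(panel.cell_line_ids), dev / m, mu, m)


def matching_score(
    nep: NormalizedPattern, ngi: NormalizedPattern, clamp_negative: bool = False
) -> MatchingResult:
    """Elementwise-product concordance Phi between two normalized patterns.

    Raw Phi (in [-L, L]) is reported by default; `clamp_negative` floors it
    at 0, matching conventions that treat anti-correlation as "no match".
    """
    if nep.cell_line_ids != ngi.cell_line_ids:
        raise ValueError("mismatched or reordered cell-line ids between patterns")
    delta = nep.values * ngi.values
    phi = float(delta.sum())
    if clamp_negative and phi < 0.0:
        phi = 0.0
    return MatchingResult(per_cell_delta=delta, phi=phi)


@dataclass(frozen=True)
class MatchingSummary:
    """Per-target maxima over experiments and their cross-target mean."""

    per_target_max: dict[str, float]
    mean_matching: float

    @property
    def mean_matching_display(self) -> int:
        return round_half_up(self.mean_matching)


def aggregate_matching(phi_by_target: Mapping[str, Sequence[float]]) -> MatchingSummary:
    """Max over experiments per target, then the arithmetic mean across targets.

    The mean is reported unrounded; `mean_matching_display` applies
    round-half-up to reproduce integer report tables.
    """
    if not phi_by_target:
        raise ValueError("aggregate_matching needs at least one target")
    per_target: dict[str, float] = {}
    for target, phis in phi_by_target.items():
        phis = list(phis)
        if not phis:
            raise ValueError(f"no experiments for target {target!r}")
        per_target[target] = float(max(phis))
    mean = float(np.mean(list(per_target.values())))
    return MatchingSummary(per_target_max=per_target, mean_matching=mean)


def match_panels(
    activity: CellLinePanel,
    expression_by_target: Mapping[str, Mapping[str, CellLinePanel]],
    clamp_negative: bool = False,
) -> tuple[MatchingSummary, pd.DataFrame]:
    """Full matching analysis of one compound against several targets.

    Parameters
    ----------
    activity
        The compound's activity panel.
    expression_by_target
        target -> {experiment name -> expression panel}.

    Returns the aggregated summary and a tidy per-experiment table with
    columns target, experiment, phi.
    """
    rows = []
    phi_by_target: dict[str, list[float]] = {}
    for target, experiments in expression_by_target.items():
        phis = []
        for exp_name, exp_panel in experiments.items():
            a, e = drop_missing_pairs(activity, exp_panel)
            res = matching_score(normalize_pattern(e), normalize_pattern(a), clamp_negative)
            phis.append(res.phi)
            rows.append({"target": target, "experiment": exp_name, "phi": res.phi})
        phi_by_target[target] = phis
    summary = aggregate_matching(phi_by_target)
    return summary, pd.DataFrame(rows, columns=["target", "experiment", "phi"])


def load_panel_csv(
    path, kind: str = "activity", orientation: str = "as_is"
) -> dict[str, CellLinePanel]:
    """Read a panel CSV: first column cell_line_id, one column per pattern.

    Activity files carry one column per compound. Expression files carry
    one column per experiment, named ``TARGET:experiment`` so several
    experiments group under one target (see `group_expression_columns`).
    """
    df = pd.read_csv(path, dtype={0: str})
    first = df.columns[0]
    ids = df[first].astype(str).tolist()
    return {
        str(col): CellLinePanel(ids, df[col].to_numpy(dtype=float), kind, orientation)
        for col in df.columns[1:]
    }


def group_expression_columns(
    panels: Mapping[str, CellLinePanel],
) -> dict[str, dict[str, CellLinePanel]]:
    """Group ``TARGET:experiment``-named panels into target -> experiments."""
    grouped: dict[str, dict[str, CellLinePanel]] = {}
    for name, panel in panels.items():
        if ":" in name:
            target, exp = name.split(":", 1)
        else:
            target, exp = name, name
        grouped.setdefault(target, {})[exp] = panel
    return grouped


def match_report(
    activity_panels: Mapping[str, CellLinePanel],
    expression_by_target: Mapping[str, Mapping[str, CellLinePanel]],
    clamp_negative: bool = False,
) -> pd.DataFrame:
    """Matching report for many compounds: one row per compound.

    Columns: ``max_phi_<target>`` per target, ``mean_matching`` (full
    precision) and ``mean_matching_display`` (round-half-up integer);
    sorted by descending mean matching.
    """
    rows = []
    for compound_id, activity in activity_panels.items():
        summary, _ = match_panels(activity, expression_by_target, clamp_negative)
        row: dict[str, object] = {"compound_id": compound_id}
        for target, value in summary.per_target_max.items():
            row[f"max_phi_{target}"] = value
        row["mean_matching"] = summary.mean_matching
        row["mean_matching_display"] = summary.mean_matching_display
        rows.append(row)
    df = pd.DataFrame(rows).set_index("compound_id")
    return df.sort_values("mean_matching", ascending=False, kind="mergesort")
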