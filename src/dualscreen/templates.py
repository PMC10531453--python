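"""Descriptor-statistics target templates and the 0-1 affinity score (DAS).

A target template summarizes a set of known high-affinity inhibitors as one
(mean, standard deviation) couple per molecular descriptor. Scoring a
candidate reduces each shared descriptor to a z-score against the template
and maps it through a Gaussian kernel,

    s_j = exp(-z_j^2 / 2),    z_j = (x_j - mean_j) / sd_j,

then aggregates the Z best per-descriptor scores (arithmetic mean, the
``G = a`` setting). The resulting DAS lies in [0, 1]: 1 means the candidate
sits exactly on the template means for all aggregated descriptors; large
deviations drive the score toward 0. Defaults are N = 500 template
descriptors, Z = 50 aggregated scores.

Template construction ranks descriptors by conservation across the actives
(ascending coefficient of variation sd / (|mean| + eps)): the descriptors a
family of binders agrees on are the ones that characterize it. Standard
deviations are floored so that a descriptor constant across the actives
still scores candidates smoothly instead of producing infinite z.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from dualscreen.descriptors import DescriptorMatrix

logger = logging.getLogger(__name__)

_CV_EPS = 1e-9


@dataclass(frozen=True)
class ScorerConfig:
    """Template/scoring parameters (N, Z, G in the screening literature).

    n_descriptors : N, descriptors retained in the template (default 500)
    z_top : Z, best-matching descriptor scores aggregated per candidate
        (default 50)
    aggregation : G, aggregation function; only "a" (arithmetic mean)
    sigma_floor_rel : relative floor applied to template SDs
    """

    n_descriptors: int = 500
    z_top: int = 50
    aggregation: str = "a"
    sigma_floor_rel: float = 1e-3

    def __post_init__(self) -> None:
        if self.n_descriptors < 1:
            raise ValueError("n_descriptors (N) must be a positive integer")
        if not 1 <= self.z_top <= self.n_descriptors:
            raise ValueError(
                f"z_top (Z) must satisfy 1 <= Z <= N, got Z={self.z_top}, N={self.n_descriptors}"
            )
        if self.aggregation != "a":
            raise ValueError(f"unsupported aggregation {self.aggregation!r}; only 'a'")
        if self.sigma_floor_rel <= 0:
            raise ValueError("sigma_floor_rel must be positive")

    def to_dict(self) -> dict:
        return {
            "n_descriptors": self.n_descriptors,
            "z_top": self.z_top,
            "aggregation": self.aggregation,
            "sigma_floor_rel": self.sigma_floor_rel,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ScorerConfig":
        return cls(**d)


@dataclass(frozen=True)
class AffinityScore:
    """A candidate's DAS against one target template."""

    compound_id: str
    target_name: str
    das: float
    n_descriptors_used: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.das <= 1.0:
            raise ValueError(f"DAS out of [0, 1]: {self.das}")


@dataclass
class TargetTemplate:
    """Per-descriptor (mean, sd) couples plus the scoring configuration.

    `entries` has columns descriptor, mean, sd (sd already floored),
    ordered by conservation rank.
    """

    target_name: str
    entries: pd.DataFrame = field(repr=False)
    config: ScorerConfig = field(default_factory=ScorerConfig)
    provenance: str = ""

    def __post_init__(self) -> None:
        required = {"descriptor", "mean", "sd"}
        if not required <= set(self.entries.columns):
            raise ValueError(f"template entries need columns {sorted(required)}")
        if self.entries["descriptor"].duplicated().any():
            raise ValueError("duplicate descriptor names in template")
        if (self.entries["sd"] <= 0).any():
            raise ValueError("template SDs must be strictly positive (flooring failed?)")

    @property
    def descriptor_names(self) -> list[str]:
        return self.entries["descriptor"].tolist()

    def __len__(self) -> int:
        return len(self.entries)

    def to_csv(self, path: str | Path) -> None:
        """Write entries as CSV plus a JSON config sidecar (lossless floats)."""
        path = Path(path)
        self.entries.to_csv(path, index=False)  # shortest-repr floats, lossless
        sidecar = path.with_suffix(path.suffix + ".config.json")
        sidecar.write_text(
            json.dumps(
                {
                    "target_name": self.target_name,
                    "config": self.config.to_dict(),
                    "provenance": self.provenance,
                },
                indent=2,
            )
            + "\n"
        )

    @classmethod
    def from_csv(cls, path: str | Path) -> "TargetTemplate":
        path = Path(path)
        entries = pd.read_csv(path).astype({"mean": float, "sd": float})
        sidecar = path.with_suffix(path.suffix + ".config.json")
        meta = json.loads(sidecar.read_text()) if sidecar.is_file() else {}
        return cls(
            target_name=meta.get("target_name", path.stem),
            entries=entries,
            config=ScorerConfig.from_dict(meta["config"]) if "config" in meta else ScorerConfig(),
            provenance=meta.get("provenance", ""),
        )


def build_template(
    actives: DescriptorMatrix,
    config: ScorerConfig | None = None,
    target_name: str = "target",
    max_missing_frac: float = 0.5,
) -> TargetTemplate:
    """Build a (mean, sd) template from the descriptor matrix of actives.

    Per-descriptor moments use the non-missing values only (population SD).
    Descriptors are ranked by ascending coefficient of variation, ties
    broken lexicographically by name, and the top N retained. If fewer than
    N descriptors survive the missingness filter the template is built on
    all of them with a warning.
    """
    if config is None:
        config = ScorerConfig()
    if actives.n_compounds < 2:
        raise ValueError(
            f"template building needs >=2 actives (SD undefined for {actives.n_compounds})"
        )

    usable = actives.drop_sparse_descriptors(max_missing_frac)
    means = usable.values.mean(axis=0, skipna=True)
    sds = usable.values.std(axis=0, ddof=0, skipna=True)

    cv = sds / (means.abs() + _CV_EPS)
    order = pd.DataFrame({"cv": cv, "descriptor": cv.index.astype(str)}).sort_values(
        ["cv", "descriptor"], kind="mergesort"
    )
    n_keep = min(config.n_descriptors, len(order))
    if n_keep < config.n_descriptors:
        logger.warning(
            "only %d usable descriptors for template %r (N=%d requested)",
            n_keep, target_name, config.n_descriptors,
        )
    kept = order["descriptor"].iloc[:n_keep].tolist()

    floor = config.sigma_floor_rel * np.maximum(means[kept].abs().to_numpy(), 1.0)
    entries = pd.DataFrame(
        {
            "descriptor": kept,
            "mean": means[kept].to_numpy(),
            "sd": np.maximum(sds[kept].to_numpy(), floor),
        }
    )
    provenance = (
        f"built from {actives.n_compounds} actives, {usable.n_descriptors} usable "
        f"descriptors, N={config.n_descriptors}, Z={config.z_top}, G={config.aggregation}"
    )
    return TargetTemplate(target_name=target_name, entries=entries,
                          config=config, provenance=provenance)


def das_score(candidate: pd.Series, template: TargetTemplate,
              compound_id: str | None = None) -> AffinityScore:
    """Score one candidate (descriptor-indexed Series) against a template."""
    cid = compound_id if compound_id is not None else str(candidate.name)
    x = candidate.reindex(template.descriptor_names).to_numpy(dtype=float)
    valid = np.isfinite(x)
    n_valid = int(valid.sum())
    z_needed = template.config.z_top
    if n_valid < z_needed:
        raise ValueError(
            f"candidate {cid!r} shares only {n_valid} non-missing descriptors with "
            f"template {template.target_name!r}; Z={z_needed} required"
        )
    mean = template.entries["mean"].to_numpy()[valid]
    sd = template.entries["sd"].to_numpy()[valid]
    z = (x[valid] - mean) / sd
    s = np.exp(-0.5 * z * z)
    top = np.partition(s, n_valid - z_needed)[n_valid - z_needed:]
    das = float(np.clip(top.mean(), 0.0, 1.0))
    return AffinityScore(cid, template.target_name, das, z_needed)


def score_matrix(matrix: DescriptorMatrix, template: TargetTemplate) -> pd.Series:
    """Vectorized DAS for every compound in a matrix.

    Returns a float Series named after the target, indexed by compound id.
    Any compound with fewer than Z scorable descriptors is fatal.
    """
    cfg = template.config
    x = matrix.values.reindex(columns=template.descriptor_names).to_numpy(dtype=float)
    valid = np.isfinite(x)
    n_valid = valid.sum(axis=1)
    short = n_valid < cfg.z_top
    if short.any():
        bad = [matrix.compound_ids[i] for i in np.flatnonzero(short)]
        raise ValueError(
            f"{len(bad)} compounds share fewer than Z={cfg.z_top} descriptors with "
            f"template {template.target_name!r}: {bad[:5]}..."
        )
    mean = template.entries["mean"].to_numpy()
    sd = template.entries["sd"].to_numpy()
    z = (x - mean) / sd
    s = np.where(valid, np.exp(-0.5 * z * z), -1.0)  # sentinel below any real score
    s.sort(axis=1)
    das = np.clip(s[:, -cfg.z_top:].mean(axis=1), 0.0, 1.0)
    return pd.Series(das, index=matrix.values.index, name=template.target_name)
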