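"""Synthetic inputs with known ground truth for the screening pipeline.

Two generators cover the two halves of the pipeline:

* `gen_descriptor_population` draws active and decoy descriptor matrices.
  Actives come from per-descriptor normal distributions
  Normal(active_means, active_sds); decoys share those distributions
  except that a random fraction of descriptors has its mean displaced by a
  fixed number of active SDs. This emulates a congeneric family of binders
  versus a background library that drifts away from the family on part of
  descriptor space, and gives exact truth labels for enrichment tests.

* `gen_cell_panel` draws NCI60-like paired data: a latent per-target
  pattern z over the cell lines, expression experiments as z plus
  measurement noise, and a compound potency pattern correlated with a
  chosen target's latent at a tunable concordance rho
  (potency = rho * z + sqrt(1 - rho^2) * independent noise).

Both are pure functions of their spec (seed included). Defaults reflect the
benchmark conditions used throughout the test-suite: 200 + 200 molecules
over 1000 descriptors with a 3-SD shift on half the descriptors, and a
60-line panel with 16 and 8 expression experiments for the two targets.

A ~20-molecule fixture of valid drug-like SMILES is included for end-to-end
smoke tests through the real descriptor engine; statistical claims are
tested on the vector-level generators, not on chemistry.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from dualscreen.descriptors import DescriptorMatrix, MoleculeRecord
from dualscreen.matching import CellLinePanel

#: Drug-like molecules for smoke-testing the descriptor engine end to end.
FIXTURE_SMILES: tuple[tuple[str, str], ...] = (
    ("aspirin", "CC(=O)Oc1ccccc1C(=O)O"),
    ("caffeine", "Cn1cnc2c1c(=O)n(C)c(=O)n2C"),
    ("ibuprofen", "CC(C)Cc1ccc(cc1)C(C)C(=O)O"),
    ("paracetamol", "CC(=O)Nc1ccc(O)cc1"),
    ("naproxen", "COc1ccc2cc(ccc2c1)C(C)C(=O)O"),
    ("diclofenac", "OC(=O)Cc1ccccc1Nc1c(Cl)cccc1Cl"),
    ("nicotine", "CN1CCCC1c1cccnc1"),
    ("warfarin", "CC(=O)CC(c1ccccc1)c1c(O)c2ccccc2oc1=O"),
    ("quercetin", "Oc1cc(O)c2c(c1)oc(-c1ccc(O)c(O)c1)c(O)c2=O"),
    ("atenolol", "CC(C)NCC(O)COc1ccc(CC(N)=O)cc1"),
    ("propranolol", "CC(C)NCC(O)COc1cccc2ccccc12"),
    ("lidocaine", "CCN(CC)CC(=O)Nc1c(C)cccc1C"),
    ("metformin", "CN(C)C(=N)NC(N)=N"),
    ("sulfanilamide", "Nc1ccc(cc1)S(N)(=O)=O"),
    ("benzocaine", "CCOC(=O)c1ccc(N)cc1"),
    ("salbutamol", "CC(C)(C)NCC(O)c1ccc(O)c(CO)c1"),
    ("chlorpromazine", "CN(C)CCCN1c2ccccc2Sc2ccc(Cl)cc21"),
    ("fluoxetine", "CNCCC(Oc1ccc(cc1)C(F)(F)F)c1ccccc1"),
    ("imatinib", "Cc1ccc(NC(=O)c2ccc(CN3CCN(C)CC3)cc2)cc1Nc1nccc(-c2cccnc2)n1"),
    ("olaparib", "O=c1[nH]nc(Cc2ccc(F)c(C(=O)N3CCN(C(=O)C4CC4)CC3)c2)c2ccccc12"),
)


def fixture_molecules() -> list[MoleculeRecord]:
    """The built-in fixture as molecule records."""
    return [MoleculeRecord(id=name, structure=smi) for name, smi in FIXTURE_SMILES]


@dataclass(frozen=True)
class PopulationSpec:
    """Conditions for an actives-vs-decoys descriptor population."""

    n_actives: int = 200
    n_decoys: int = 200
    n_descriptors: int = 1000
    active_means: np.ndarray | None = None  # drawn U(-5, 5) if None
    active_sds: np.ndarray | None = None  # drawn U(0.5, 2) if None
    decoy_shift_sd_units: float = 3.0
    shifted_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_actives, self.n_decoys, self.n_descriptors) < 1:
            raise ValueError("population sizes must be positive")
        if self.decoy_shift_sd_units < 0:
            raise ValueError("decoy_shift_sd_units must be non-negative")
        if not 0.0 <= self.shifted_fraction <= 1.0:
            raise ValueError("shifted_fraction must lie in [0, 1]")


@dataclass(frozen=True)
class DescriptorPopulation:
    """Generated actives/decoys with exact truth."""

    actives: DescriptorMatrix
    decoys: DescriptorMatrix
    labels: pd.Series = field(repr=False)  # 1 = active, 0 = decoy, by compound id
    shifted_descriptors: np.ndarray = field(repr=False)  # bool per descriptor
    generating_means: np.ndarray = field(repr=False, default=None)
    generating_sds: np.ndarray = field(repr=False, default=None)

    def combined(self) -> DescriptorMatrix:
        return DescriptorMatrix(pd.concat([self.actives.values, self.decoys.values]))


def gen_descriptor_population(spec: PopulationSpec) -> DescriptorPopulation:
    """Draw actives around template means and decoys with shifted means."""
    rng = np.random.default_rng(spec.seed)
    p = spec.n_descriptors
    means = (
        np.asarray(spec.active_means, dtype=float)
        if spec.active_means is not None
        else rng.uniform(-5.0, 5.0, p)
    )
    sds = (
        np.asarray(spec.active_sds, dtype=float)
        if spec.active_sds is not None
        else rng.uniform(0.5, 2.0, p)
    )
    if means.shape != (p,) or sds.shape != (p,):
        raise ValueError("active_means/active_sds must have length n_descriptors")
    if (sds <= 0).any():
        raise ValueError("active_sds must be strictly positive")

    shifted = rng.random(p) < spec.shifted_fraction
    direction = rng.choice([-1.0, 1.0], p)
    decoy_means = means + np.where(shifted, spec.decoy_shift_sd_units * sds * direction, 0.0)

    names = [f"D{i + 1:04d}" for i in range(p)]
    act = rng.normal(means, sds, (spec.n_actives, p))
    dec = rng.normal(decoy_means, sds, (spec.n_decoys, p))
    act_ids = [f"ACT{i + 1:04d}" for i in range(spec.n_actives)]
    dec_ids = [f"DEC{i + 1:04d}" for i in range(spec.n_decoys)]

    actives = DescriptorMatrix(pd.DataFrame(act, index=act_ids, columns=names))
    decoys = DescriptorMatrix(pd.DataFrame(dec, index=dec_ids, columns=names))
    labels = pd.Series(
        [1] * spec.n_actives + [0] * spec.n_decoys, index=act_ids + dec_ids, name="is_active"
    )
    return DescriptorPopulation(actives, decoys, labels, shifted, means, sds)


@dataclass(frozen=True)
class PanelSpec:
    """Conditions for an NCI60-like paired activity/expression panel."""

    n_lines: int = 60
    rho: float = 0.5
    n_experiments_per_target: Mapping[str, int] = field(
        default_factory=lambda: {"CDK1": 16, "PARP1": 8}
    )
    noise_sd: float = 0.25
    latent: str = "gaussian"  # "gaussian" | "two_level"
    coupled_target: str | None = None  # default: first target name
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_lines < 2:
            raise ValueError("n_lines must be >= 2")
        if not -1.0 <= self.rho <= 1.0:
            raise ValueError(f"|rho| must be <= 1, got {self.rho}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.latent not in {"gaussian", "two_level"}:
            raise ValueError(f"unknown latent kind {self.latent!r}")
        if not self.n_experiments_per_target:
            raise ValueError("need at least one target")


@dataclass(frozen=True)
class CellPanelData:
    """Generated paired panel with its generating truth."""

    activity: CellLinePanel
    expression: dict[str, dict[str, CellLinePanel]]  # target -> experiment -> panel
    latent_by_target: dict[str, np.ndarray] = field(repr=False)
    rho: float = 0.0


def gen_cell_panel(spec: PanelSpec) -> CellPanelData:
    """Draw one compound's potency pattern plus per-target expression panels.

    The potency pattern is coupled to `coupled_target`'s latent pattern at
    concordance `rho`; other targets' latents are independent. All panels
    are emitted in "larger = stronger" orientation (`as_is`).
    """
    rng = np.random.default_rng(spec.seed)
    L = spec.n_lines
    ids = [f"CL{i + 1:02d}" for i in range(L)]

    def draw_latent() -> np.ndarray:
        if spec.latent == "two_level":
            z = np.where(np.arange(L) < L // 2, 1.0, -1.0)
            return z
        return rng.standard_normal(L)

    targets = list(spec.n_experiments_per_target)
    latents = {t: draw_latent() for t in targets}
    coupled = spec.coupled_target if spec.coupled_target is not None else targets[0]
    if coupled not in latents:
        raise ValueError(f"coupled_target {coupled!r} not among targets {targets}")

    expression: dict[str, dict[str, CellLinePanel]] = {}
    for t in targets:
        expression[t] = {}
        for e in range(spec.n_experiments_per_target[t]):
            values = latents[t] + rng.normal(0.0, spec.noise_sd, L)
            expression[t][f"exp{e + 1:02d}"] = CellLinePanel(ids, values, "expression", "as_is")

    eps = rng.standard_normal(L) if spec.latent == "gaussian" else draw_noise_two_level(rng, L)
    potency = spec.rho * latents[coupled] + np.sqrt(1.0 - spec.rho**2) * eps
    activity = CellLinePanel(ids, potency, "activity", "as_is")
    return CellPanelData(activity, expression, latents, spec.rho)


def draw_noise_two_level(rng: np.random.Generator, n_lines: int) -> np.ndarray:
    """Balanced random +/-1 noise pattern, for two-level latent panels."""
    z = np.where(np.arange(n_lines) < n_lines // 2, 1.0, -1.0)
    return rng.permutation(z)
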