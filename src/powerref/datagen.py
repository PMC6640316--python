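"""Simulated datasets drawn from a population design.

Participants are drawn as jointly normal vectors over the within-participant
cells (Cholesky factor of the design's correlation matrix, unit SDs), one
independent sample per between-group.  A root seed plus a replicate index
seeds each dataset through :class:`numpy.random.SeedSequence`, so replicate
``k`` of a simulation can be regenerated in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .scenarios import PopulationDesign

__all__ = ["Dataset", "sample_dataset", "to_long", "from_long", "sample_batch"]

_MIN_N = 3


@dataclass(frozen=True)
class Dataset:
    """One simulated balanced dataset.

    ``data`` has shape ``(n_groups, n, n_within)``: for every between-group,
    ``n`` participants with one response per within-participant cell.
    """

    design: PopulationDesign
    data: np.ndarray
    n: int
    seed: int | None = None
    replicate: int | None = None

    @property
    def groups(self) -> tuple[np.ndarray, ...]:
        return tuple(self.data[g] for g in range(self.data.shape[0]))

    @property
    def n_total(self) -> int:
        return self.data.shape[0] * self.n


def _rng_for(seed, replicate):
    if seed is None:
        return np.random.default_rng()
    key = (int(seed),) if replicate is None else (int(seed), int(replicate))
    return np.random.default_rng(np.random.SeedSequence(key))


def sample_dataset(design: PopulationDesign, n: int, seed: int | None = None,
                   replicate: int | None = None) -> Dataset:
    """Draw one balanced dataset of ``n`` participants per group.

    Deterministic for fixed ``(design, n, seed, replicate)``.  Sample
    moments converge to the design's cell means and correlation matrix as
    ``n`` grows.
    """
    if n < _MIN_N:
        raise ValueError(f"need at least {_MIN_N} participants per group")
    rng = _rng_for(seed, replicate)
    L = design.cholesky()
    z = rng.standard_normal((design.n_groups, int(n), design.n_within))
    data = z @ L.T + design.cell_means[:, None, :]
    return Dataset(design=design, data=data, n=int(n), seed=seed,
                   replicate=replicate)


def sample_batch(design: PopulationDesign, n: int, reps: int,
                 rng: np.random.Generator) -> np.ndarray:
    """Vectorized draw of ``reps`` datasets: shape (reps, n_groups, n, k).

    The Monte-Carlo engine's bulk path; one generator stream fills the whole
    batch (use :func:`sample_dataset` when individual replicates must be
    reproducible in isolation).
    """
    L = design.cholesky()
    z = rng.standard_normal((int(reps), design.n_groups, int(n),
                             design.n_within))
    return z @ L.T + design.cell_means[None, :, None, :]


def transform_base(design: PopulationDesign, z: np.ndarray) -> np.ndarray:
    """Map standard-normal draws (..., n_groups, n, k) onto the design."""
    L = design.cholesky()
    return z @ L.T + design.cell_means[None, :, None, :]


def to_long(dataset: Dataset) -> pd.DataFrame:
    """Long-format table with columns Participant, Condition, Response
    (plus Group when the design has more than one between-group).

    One row per (participant, within-cell); participants are numbered
    consecutively across groups.  Lossless against :func:`from_long`.
    """
    design = dataset.design
    rows = []
    pid = 0
    for g, glabel in enumerate(design.group_labels):
        for i in range(dataset.n):
            pid += 1
            for j, wlabel in enumerate(design.within_labels):
                rows.append((f"P{pid}", glabel, wlabel,
                             float(dataset.data[g, i, j])))
    df = pd.DataFrame(rows, columns=["Participant", "Group", "Condition",
                                     "Response"])
    if design.n_groups == 1:
        df = df.drop(columns="Group")
    return df


def from_long(df: pd.DataFrame, design: PopulationDesign) -> Dataset:
    """Rebuild the wide (group, participant, cell) array from long format."""
    wide = df.copy()
    if "Group" not in wide.columns:
        wide["Group"] = design.group_labels[0]
    g_index = {g: i for i, g in enumerate(design.group_labels)}
    w_index = {w: j for j, w in enumerate(design.within_labels)}
    per_group: dict[int, dict[str, np.ndarray]] = {}
    for (grp, pid), sub in wide.groupby(["Group", "Participant"], sort=False):
        vec = np.full(design.n_within, np.nan)
        for _, row in sub.iterrows():
            vec[w_index[row["Condition"]]] = row["Response"]
        per_group.setdefault(g_index[grp], {})[pid] = vec
    ns = {len(v) for v in per_group.values()}
    if len(ns) != 1:
        raise ValueError("unbalanced groups cannot round-trip to a Dataset")
    n = ns.pop()
    data = np.stack([
        np.stack(list(per_group[g].values())) for g in range(design.n_groups)
    ])
    return Dataset(design=design, data=data, n=n)
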