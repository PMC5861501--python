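"""Time-lagged regression problems from time-course expression data.

The regulatory model regresses a target gene's value at time ``t+1`` on the
values of its candidate regulators at time ``t``:

    e_i(t+1) = f_i(e_{-i}(t)) + noise

so every replicate of ``T_r`` time points contributes ``T_r - 1`` samples,
and no sample ever spans a replicate boundary.  The lag is one index step
regardless of wall-clock spacing between measurements.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .data_model import TimeCourseDataset


@dataclass
class LaggedProblem:
    """One per-target regression problem.

    ``features[s, k]`` is the expression of candidate regulator
    ``regulator_indices[k]`` at time ``t`` and ``targets[s]`` the target
    gene's expression at ``t+1``, for sample (replicate, t) pair ``s``.
    """

    features: np.ndarray
    targets: np.ndarray
    regulator_indices: list[int]
    target_index: int

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        self.targets = np.asarray(self.targets, dtype=float)
        self.regulator_indices = [int(k) for k in self.regulator_indices]
        self.target_index = int(self.target_index)
        if self.features.ndim != 2:
            raise ValueError("features must be a 2-D matrix")
        if self.features.shape[0] != self.targets.shape[0]:
            raise ValueError("features and targets disagree on sample count")
        if self.features.shape[1] != len(self.regulator_indices):
            raise ValueError("feature columns do not match regulator_indices")
        if self.target_index in self.regulator_indices:
            raise ValueError("target gene cannot be its own candidate regulator")

    @property
    def n_samples(self) -> int:
        return self.features.shape[0]

    @property
    def n_regulators(self) -> int:
        return self.features.shape[1]


def standardize_genes(dataset: TimeCourseDataset) -> TimeCourseDataset:
    """Scale every gene's pooled series to mean 0 and population SD 1.

    Pooling is across all replicates; the replicate structure of the
    returned dataset is unchanged.  A gene with zero variance is only
    centred (its series becomes all zeros) and a warning is emitted.
    The transform is idempotent.
    """
    pooled = dataset.pooled()
    mean = pooled.mean(axis=0)
    sd = pooled.std(axis=0)  # population SD
    degenerate = sd == 0
    if np.any(degenerate):
        names = [dataset.gene_names[g] for g in np.flatnonzero(degenerate)]
        warnings.warn(
            f"constant expression for gene(s) {names}; centred only, not scaled",
            UserWarning,
            stacklevel=2,
        )
    scale = np.where(degenerate, 1.0, sd)
    return TimeCourseDataset(
        gene_names=list(dataset.gene_names),
        replicates=[(block - mean) / scale for block in dataset.replicates],
        time_labels=dataset.time_labels,
    )


def build_lagged_problem(
    dataset: TimeCourseDataset,
    target_index: int,
    candidate_regulators: Sequence[int] | None = None,
) -> LaggedProblem:
    """Assemble the lag-1 regression problem for one target gene.

    By default every gene except the target is a candidate regulator; a
    restricted regulator list (e.g. known transcription factors) may be
    supplied instead, from which the target is always removed.
    """
    p = dataset.n_genes
    target_index = int(target_index)
    if not 0 <= target_index < p:
        raise IndexError(f"target_index {target_index} out of range for {p} genes")
    if candidate_regulators is None:
        regulators = [k for k in range(p) if k != target_index]
    else:
        regulators = sorted({int(k) for k in candidate_regulators} - {target_index})
        if not regulators:
            raise ValueError("no candidate regulators left after removing the target")
        for k in regulators:
            if not 0 <= k < p:
                raise IndexError(f"regulator index {k} out of range for {p} genes")

    feature_blocks = []
    target_blocks = []
    for block in dataset.replicates:
        feature_blocks.append(block[:-1, regulators])
        target_blocks.append(block[1:, target_index])
    return LaggedProblem(
        features=np.vstack(feature_blocks),
        targets=np.concatenate(target_blocks),
        regulator_indices=regulators,
        target_index=target_index,
    )
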