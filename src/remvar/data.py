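"""Two-level tabular data: subjects (level 1) nested in clusters (level 2)."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["MultilevelDataset"]


@dataclass
class MultilevelDataset:
    """Subject-level rows with an outcome, a cluster id and covariates.

    ``subject_cols`` / ``cluster_cols`` declare the partition of the
    covariates into subject-level (x_s) and cluster-level (x_c) columns.
    Cluster-level columns must be constant within each cluster.  Rows with
    missing values in any used column are rejected at construction, with the
    dropped count logged and kept in ``n_dropped``.
    """

    frame: pd.DataFrame
    outcome: str
    cluster: str
    subject_cols: list[str] = field(default_factory=list)
    cluster_cols: list[str] = field(default_factory=list)
    offset: str | None = None
    n_dropped: int = 0

    def __post_init__(self):
        used = [self.outcome, self.cluster, *self.subject_cols, *self.cluster_cols]
        if self.offset is not None:
            used.append(self.offset)
        missing = [c for c in used if c not in self.frame.columns]
        if missing:
            raise ValueError(f"columns not found in data: {missing}")

        frame = self.frame[used].copy()
        keep = frame.notna().all(axis=1)
        self.n_dropped = int((~keep).sum())
        if self.n_dropped:
            logger.info("dropped %d rows with missing values", self.n_dropped)
            frame = frame.loc[keep]
        if frame.empty:
            raise ValueError("no complete rows in dataset")

        for col in self.cluster_cols:
            nuniq = frame.groupby(self.cluster, observed=True)[col].nunique()
            bad = nuniq[nuniq > 1]
            if len(bad):
                raise ValueError(
                    f"cluster-level column {col!r} varies within clusters "
                    f"{list(bad.index[:5])}"
                )
        self.frame = frame.reset_index(drop=True)

    # -- convenience accessors -------------------------------------------
    @property
    def covariate_cols(self) -> list[str]:
        return [*self.subject_cols, *self.cluster_cols]

    @property
    def n_clusters(self) -> int:
        return int(self.frame[self.cluster].nunique())

    @property
    def n_subjects(self) -> int:
        return int(len(self.frame))

    @property
    def cluster_sizes(self) -> pd.Series:
        return self.frame[self.cluster].value_counts().sort_index()

    def validate_outcome(self, family: str) -> None:
        y = self.frame[self.outcome].to_numpy()
        if family == "binomial":
            if not np.isin(y, (0, 1)).all():
                raise ValueError("binomial family requires a 0/1 outcome")
        elif family == "poisson":
            if (y < 0).any() or not np.allclose(y, np.round(y)):
                raise ValueError("poisson family requires non-negative integer outcomes")
        elif family == "normal":
            pass
        else:
            raise ValueError(f"unknown family {family!r}")

    @classmethod
    def from_csv(
        cls,
        path: str | Path,
        outcome: str,
        cluster: str,
        subject_cols: Sequence[str] = (),
        cluster_cols: Sequence[str] = (),
        offset: str | None = None,
    ) -> "MultilevelDataset":
        frame = pd.read_csv(path)
        return cls(
            frame=frame,
            outcome=outcome,
            cluster=cluster,
            subject_cols=list(subject_cols),
            cluster_cols=list(cluster_cols),
            offset=offset,
        )

    def to_csv(self, path: str | Path) -> None:
        self.frame.to_csv(path, index=False)

    def subset_clusters(self, cluster_ids: Sequence) -> "MultilevelDataset":
        """Dataset restricted to the given clusters, duplicates relabeled.

        Duplicated clusters receive fresh unique ids so that a bootstrap
        resample keeps N distinct clusters.
        """
        groups = {cid: df for cid, df in self.frame.groupby(self.cluster, observed=True)}
        blocks = []
        for new_id, cid in enumerate(cluster_ids):
            block = groups[cid].copy()
            block[self.cluster] = new_id
            blocks.append(block)
        frame = pd.concat(blocks, ignore_index=True)
        return MultilevelDataset(
            frame=frame,
            outcome=self.outcome,
            cluster=self.cluster,
            subject_cols=list(self.subject_cols),
            cluster_cols=list(self.cluster_cols),
            offset=self.offset,
        )
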