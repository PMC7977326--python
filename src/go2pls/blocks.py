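"""Data containers for two-block omics integration.

An :class:`OmicsBlock` wraps one samples x features matrix together with its
identifiers and centering/scaling state.  A :class:`GroupStructure` partitions
one block's features into named groups (e.g. CpG sites grouped by target gene)
for group-wise penalisation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["OmicsBlock", "GroupStructure", "center_scale"]


@dataclass
class OmicsBlock:
    """One data matrix (N samples x p features) with identifiers.

    Parameters
    ----------
    data
        Numeric matrix of shape ``(n_samples, n_features)``.
    sample_ids, feature_ids
        Unique identifiers; generated as ``s0..`` / ``f0..`` when omitted.
    means, scales
        Per-feature centering constants; ``None`` until :func:`center_scale`
        has been applied.  ``scales`` stays ``None`` for centering-only.
    """

    data: np.ndarray
    sample_ids: list[str] = field(default=None)  # type: ignore[assignment]
    feature_ids: list[str] = field(default=None)  # type: ignore[assignment]
    means: np.ndarray | None = None
    scales: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be a 2-D samples x features matrix")
        n, p = self.data.shape
        if self.sample_ids is None:
            self.sample_ids = [f"s{i}" for i in range(n)]
        if self.feature_ids is None:
            self.feature_ids = [f"f{j}" for j in range(p)]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.feature_ids = [str(f) for f in self.feature_ids]
        if len(self.sample_ids) != n:
            raise ValueError(f"{len(self.sample_ids)} sample ids for {n} rows")
        if len(self.feature_ids) != p:
            raise ValueError(f"{len(self.feature_ids)} feature ids for {p} columns")
        for label, ids in (("sample", self.sample_ids), ("feature", self.feature_ids)):
            if len(set(ids)) != len(ids):
                dupes = sorted({i for i in ids if ids.count(i) > 1})
                raise ValueError(f"duplicate {label} ids: {dupes[:5]}")

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_features(self) -> int:
        return self.data.shape[1]

    @property
    def is_centered(self) -> bool:
        return self.means is not None

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "OmicsBlock":
        """Build a block from a samples x features DataFrame."""
        return cls(
            data=df.to_numpy(dtype=float),
            sample_ids=[str(i) for i in df.index],
            feature_ids=[str(c) for c in df.columns],
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.data, index=self.sample_ids, columns=self.feature_ids)

    def apply_centering(self, new: np.ndarray) -> np.ndarray:
        """Center (and scale) *new* data with the stored training constants."""
        if self.means is None:
            raise ValueError("block has no centering constants; call center_scale first")
        out = np.asarray(new, dtype=float) - self.means
        if self.scales is not None:
            out = out / self.scales
        return out


def center_scale(block: OmicsBlock, scale: bool = False) -> OmicsBlock:
    """Column-center a block, optionally scaling columns to unit variance.

    Covariance maximisation between two blocks requires column-centered data;
    centering constants are stored on the returned block so new samples can be
    projected consistently.

    Raises
    ------
    ValueError
        On missing values, or on zero-variance columns when ``scale=True``
        (the offending feature ids are listed).
    """
    X = block.data
    if X.shape[0] < 2:
        raise ValueError("need at least 2 samples to center")
    bad = ~np.isfinite(X)
    if bad.any():
        cols = sorted({block.feature_ids[j] for j in np.where(bad.any(axis=0))[0]})
        raise ValueError(f"missing/non-finite values in features: {cols[:10]}")
    means = X.mean(axis=0)
    centered = X - means
    scales = None
    if scale:
        sd = centered.std(axis=0, ddof=1)
        zero = np.where(sd == 0)[0]
        if zero.size:
            names = [block.feature_ids[j] for j in zero]
            raise ValueError(f"zero-variance columns cannot be scaled: {names[:10]}")
        scales = sd
        centered = centered / sd
    return OmicsBlock(
        data=centered,
        sample_ids=list(block.sample_ids),
        feature_ids=list(block.feature_ids),
        means=means,
        scales=scales,
    )


@dataclass
class GroupStructure:
    """Partition of a block's features into named groups.

    ``indices[j]`` holds the column indices of group ``names[j]``; sizes
    ``p_j = len(indices[j])``.  Sparse (individual-feature) selection is the
    special case in which every group is a singleton.
    """

    names: list[str]
    indices: list[np.ndarray]

    def __post_init__(self) -> None:
        self.names = [str(n) for n in self.names]
        self.indices = [np.asarray(ix, dtype=int) for ix in self.indices]
        if len(self.names) != len(self.indices):
            raise ValueError("names and indices length mismatch")
        for name, ix in zip(self.names, self.indices):
            if ix.size == 0:
                raise ValueError(f"group {name!r} is empty")
        all_ix = np.concatenate(self.indices) if self.indices else np.empty(0, int)
        if np.unique(all_ix).size != all_ix.size:
            raise ValueError("groups overlap: some feature belongs to two groups")

    @property
    def n_groups(self) -> int:
        return len(self.names)

    @property
    def sizes(self) -> np.ndarray:
        return np.array([ix.size for ix in self.indices])

    @property
    def n_features(self) -> int:
        return int(self.sizes.sum()) if self.names else 0

    def validate_for(self, p: int) -> None:
        """Check the groups exactly partition ``range(p)``."""
        all_ix = np.sort(np.concatenate(self.indices))
        if all_ix.size != p or not np.array_equal(all_ix, np.arange(p)):
            raise ValueError(
                f"groups cover {all_ix.size} of {p} features and must partition all of them"
            )

    @classmethod
    def singletons(cls, feature_ids: list[str] | int) -> "GroupStructure":
        """One group per feature (sparse selection; GO2PLS reduces to SO2PLS)."""
        if isinstance(feature_ids, int):
            feature_ids = [f"f{j}" for j in range(feature_ids)]
        return cls(
            names=list(feature_ids),
            indices=[np.array([j]) for j in range(len(feature_ids))],
        )

    @classmethod
    def from_labels(cls, labels: list[str]) -> "GroupStructure":
        """Build from a per-feature group label vector (order of first appearance)."""
        order: dict[str, list[int]] = {}
        for j, lab in enumerate(labels):
            order.setdefault(str(lab), []).append(j)
        return cls(names=list(order), indices=[np.array(v) for v in order.values()])

    @classmethod
    def from_mapping(
        cls, feature_ids: list[str], mapping: dict[str, str]
    ) -> "GroupStructure":
        """Build from a feature_id -> group_id mapping.

        Features absent from the mapping become singleton groups (named after
        the feature); the count is logged.  Mapped ids that do not occur in
        ``feature_ids`` are ignored with a warning.
        """
        unknown = sorted(set(mapping) - set(feature_ids))
        if unknown:
            logger.warning(
                "%d mapped feature ids absent from block (e.g. %s); ignored",
                len(unknown), unknown[:5],
            )
        labels = []
        n_singleton = 0
        for fid in feature_ids:
            if fid in mapping:
                labels.append(f"g:{mapping[fid]}")
            else:
                labels.append(f"singleton:{fid}")
                n_singleton += 1
        if n_singleton:
            logger.info("%d unmapped features assigned singleton groups", n_singleton)
        struct = cls.from_labels(labels)
        struct.names = [n.split(":", 1)[1] for n in struct.names]
        return struct
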