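"""Readers and writers for the delimited formats the tool exchanges.

Matrices travel as TSV/CSV (header row = feature ids, first column = sample
ids) or Matrix-Market triplets with sidecar id lists; group mappings as
two-column delimited text (feature_id, group_id); designs as YAML.
"""

from __future__ import annotations

import logging
import os

import numpy as np
import pandas as pd
import yaml

from .blocks import GroupStructure, OmicsBlock
from .simulation import ScenarioDesign

logger = logging.getLogger(__name__)

__all__ = [
    "read_matrix", "write_matrix", "read_groups", "write_groups",
    "read_design", "write_design", "align_samples",
]


def _sep_for(path) -> str:
    return "," if str(path).endswith(".csv") else "\t"


def read_matrix(path, orientation: str = "samples_by_features") -> OmicsBlock:
    """Read a delimited matrix into an :class:`OmicsBlock`.

    TSV by default, CSV by ``.csv`` extension; a ``.mtx`` file is read as
    Matrix-Market with ``<path>.rows``/``<path>.cols`` id sidecars.
    ``orientation="features_by_samples"`` transposes after reading.  Ragged
    rows, non-numeric cells and duplicate ids raise with the offending
    location named.
    """
    path = str(path)
    if orientation not in ("samples_by_features", "features_by_samples"):
        raise ValueError(f"unknown orientation {orientation!r}")
    if path.endswith(".mtx"):
        from scipy.io import mmread

        mat = mmread(path)
        if hasattr(mat, "todense"):
            mat = np.asarray(mat.todense(), dtype=float)
        else:
            mat = np.asarray(mat, dtype=float)
        with open(path + ".rows") as fh:
            rows = [ln.strip() for ln in fh if ln.strip()]
        with open(path + ".cols") as fh:
            cols = [ln.strip() for ln in fh if ln.strip()]
        df = pd.DataFrame(mat, index=rows, columns=cols)
    else:
        sep = _sep_for(path)
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split(sep)
        feats = header[1:]
        if len(set(feats)) != len(feats):
            dupes = sorted({f for f in feats if feats.count(f) > 1})
            raise ValueError(f"{path}: duplicate feature ids: {dupes[:5]}")
        # round_trip parsing keeps write->read bit-exact
        df = pd.read_csv(path, sep=sep, index_col=0, float_precision="round_trip")
        bad = df.isna()
        if bad.to_numpy().any():
            i = int(np.argmax(bad.to_numpy().any(axis=1)))
            j = int(np.argmax(bad.to_numpy()[i]))
            raise ValueError(
                f"{path}: missing/non-numeric cell at row {df.index[i]!r}, "
                f"column {df.columns[j]!r}"
            )
        try:
            df = df.astype(float)
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{path}: non-numeric cell ({exc})") from exc
    if orientation == "features_by_samples":
        df = df.T
    return OmicsBlock.from_frame(df)


def write_matrix(block: OmicsBlock, path) -> None:
    """Write a block as delimited text (inverse of :func:`read_matrix`)."""
    block.to_frame().to_csv(path, sep=_sep_for(path))


def read_groups(path, block: OmicsBlock) -> GroupStructure:
    """Read a two-column (feature_id, group_id) mapping for ``block``.

    Unmapped features become singleton groups; ids in the file but absent
    from the block produce a warning; a feature mapped to two different
    groups is an error.
    """
    try:
        df = pd.read_csv(path, sep=_sep_for(path), header=None, dtype=str,
                         comment="#", skip_blank_lines=True)
    except pd.errors.EmptyDataError:
        logger.info("%s is empty; every feature becomes a singleton group", path)
        return GroupStructure.singletons(block.feature_ids)
    if df.shape[1] != 2:
        raise ValueError(f"{path}: expected 2 columns, found {df.shape[1]}")
    df.columns = ["feature_id", "group_id"]
    # drop a header line if present
    if df.iloc[0, 0] in ("feature_id", "feature") and len(df) > 1:
        df = df.iloc[1:]
    conflicts = df.groupby("feature_id")["group_id"].nunique()
    doubly = conflicts[conflicts > 1]
    if len(doubly):
        raise ValueError(
            f"{path}: features mapped to multiple groups: {list(doubly.index)[:5]}"
        )
    mapping = dict(zip(df["feature_id"], df["group_id"]))
    return GroupStructure.from_mapping(block.feature_ids, mapping)


def write_groups(groups: GroupStructure, feature_ids: list[str], path) -> None:
    rows = []
    for name, ix in zip(groups.names, groups.indices):
        for j in ix:
            rows.append((feature_ids[j], name))
    pd.DataFrame(rows, columns=["feature_id", "group_id"]).to_csv(
        path, sep=_sep_for(path), index=False, header=False
    )


def read_design(path) -> ScenarioDesign:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return ScenarioDesign.from_dict(doc)


def write_design(design: ScenarioDesign, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(design.to_dict(), fh, sort_keys=True)


def align_samples(x: OmicsBlock, y: OmicsBlock) -> tuple[OmicsBlock, OmicsBlock]:
    """Align two blocks on their sample-id intersection, in X's order.

    Mismatching samples are dropped with a warning; an empty intersection is
    an error.
    """
    common = [s for s in x.sample_ids if s in set(y.sample_ids)]
    if not common:
        raise ValueError("X and Y share no sample ids")
    dropped = (len(x.sample_ids) - len(common)) + (len(y.sample_ids) - len(common))
    if dropped:
        logger.warning("dropping %d unmatched samples across the two blocks", dropped)
    xi = [x.sample_ids.index(s) for s in common]
    yi = [y.sample_ids.index(s) for s in common]
    return (
        OmicsBlock(x.data[xi], common, list(x.feature_ids)),
        OmicsBlock(y.data[yi], common, list(y.feature_ids)),
    )
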