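"""Vectorizing connectivity matrices into named edge features."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .group_stats import SubjectFeatureTable
from .kls_network import ConnectivityMatrix

__all__ = [
    "edge_name",
    "parse_edge_name",
    "matrices_to_features",
    "feature_table",
]


def edge_name(i: int, j: int) -> str:
    """Canonical name of the connection between region ids i and j."""
    a, b = sorted((int(i), int(j)))
    return f"{a}-{b}"


def parse_edge_name(name: str) -> tuple[int, int]:
    a, b = name.split("-")
    return int(a), int(b)


def matrices_to_features(matrices: list[ConnectivityMatrix]) -> pd.DataFrame:
    """Upper-triangle KLS values of each subject as one row per subject."""
    if not matrices:
        raise ValueError("no matrices supplied")
    ref_ids = matrices[0].region_ids
    pairs, _ = matrices[0].upper_triangle()
    cols = [edge_name(i, j) for i, j in pairs]
    rows = []
    for m in matrices:
        if m.region_ids != ref_ids:
            raise ValueError(f"region ordering of {m.subject_id} differs")
        _, vals = m.upper_triangle()
        rows.append(vals)
    return pd.DataFrame(np.vstack(rows), columns=cols)


def feature_table(
    matrices: list[ConnectivityMatrix],
    group: str,
    age,
    sex,
) -> SubjectFeatureTable:
    """Bundle one group's matrices and covariates into a feature table."""
    return SubjectFeatureTable(
        subject_ids=[m.subject_id for m in matrices],
        group=np.repeat(group, len(matrices)),
        age=age,
        sex=sex,
        features=matrices_to_features(matrices),
    )
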