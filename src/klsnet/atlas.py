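"""Default 90-region automated-anatomical-labelling parcellation metadata.

Region ids 1-90 follow the standard AAL ordering (odd = left, even = right,
cerebellum excluded). Each region belongs to one of six gross groups used
for aggregating connection weights: frontal, temporal, parietal, occipital,
central structures, and insula-and-cingulate.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["LOBES", "aal90_table", "aal90_lookup", "write_aal90_lookup"]

LOBES = (
    "frontal",
    "temporal",
    "parietal",
    "occipital",
    "central structures",
    "insula-and-cingulate",
)

# (base name, lobe group); expanded to .L/.R pairs in AAL order.
_AAL45: list[tuple[str, str]] = [
    ("Precentral", "frontal"),
    ("Frontal.Sup", "frontal"),
    ("Frontal.Sup.Orb", "frontal"),
    ("Frontal.Mid", "frontal"),
    ("Frontal.Mid.Orb", "frontal"),
    ("Frontal.Inf.Oper", "frontal"),
    ("Frontal.Inf.Tri", "frontal"),
    ("Frontal.Inf.Orb", "frontal"),
    ("Rolandic.Oper", "frontal"),
    ("Supp.Motor.Area", "frontal"),
    ("Olfactory", "frontal"),
    ("Frontal.Sup.Medial", "frontal"),
    ("Frontal.Med.Orb", "frontal"),
    ("Rectus", "frontal"),
    ("Insula", "insula-and-cingulate"),
    ("Cingulum.Ant", "insula-and-cingulate"),
    ("Cingulum.Mid", "insula-and-cingulate"),
    ("Cingulum.Post", "insula-and-cingulate"),
    ("Hippocampus", "temporal"),
    ("ParaHippocampal", "temporal"),
    ("Amygdala", "temporal"),
    ("Calcarine", "occipital"),
    ("Cuneus", "occipital"),
    ("Lingual", "occipital"),
    ("Occipital.Sup", "occipital"),
    ("Occipital.Mid", "occipital"),
    ("Occipital.Inf", "occipital"),
    ("Fusiform", "temporal"),
    ("Postcentral", "parietal"),
    ("Parietal.Sup", "parietal"),
    ("Parietal.Inf", "parietal"),
    ("SupraMarginal", "parietal"),
    ("Angular", "parietal"),
    ("Precuneus", "parietal"),
    ("Paracentral.Lobule", "frontal"),
    ("Caudate", "central structures"),
    ("Putamen", "central structures"),
    ("Pallidum", "central structures"),
    ("Thalamus", "central structures"),
    ("Heschl", "temporal"),
    ("Temporal.Sup", "temporal"),
    ("Temporal.Pole.Sup", "temporal"),
    ("Temporal.Mid", "temporal"),
    ("Temporal.Pole.Mid", "temporal"),
    ("Temporal.Inf", "temporal"),
]


def aal90_table() -> pd.DataFrame:
    """Return the 90-row lookup table with columns id, name, lobe."""
    rows = []
    for k, (base, lobe) in enumerate(_AAL45):
        rows.append((2 * k + 1, f"{base}.L", lobe))
        rows.append((2 * k + 2, f"{base}.R", lobe))
    return pd.DataFrame(rows, columns=["id", "name", "lobe"])


def aal90_lookup() -> tuple[list[int], list[str], dict[int, str]]:
    """Return (region_ids, region_names, lobe_map) for the 90-region atlas."""
    tbl = aal90_table()
    ids = [int(i) for i in tbl["id"]]
    names = [str(n) for n in tbl["name"]]
    lobes = dict(zip(ids, (str(g) for g in tbl["lobe"])))
    return ids, names, lobes


def write_aal90_lookup(path) -> None:
    aal90_table().to_csv(path, sep="\t", index=False)
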