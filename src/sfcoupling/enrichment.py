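"""Network/region mapping of vertex-level hits and chi-squared enrichment.

Significant SNP-vertex associations are mapped through the mesh labels to
atlas regions or networks and tested for enrichment with Pearson's
chi-squared statistic on a 2x2 contingency table (no continuity
correction), mirroring standard association-enrichment practice.  The Dice
coefficient quantifies robustness of association sets across subsamples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .datatypes import SurfaceMesh

__all__ = ["ContingencyTable2x2", "map_vertices", "aggregate_hits",
           "enrichment_chisq", "network_enrichment",
           "locus_network_enrichment", "dice_overlap"]

GROUPINGS = ("region", "functional_network", "anatomical_network", "cortex")


@dataclass
class ContingencyTable2x2:
    """Counts: (a) in-group significant, (b) out-of-group significant,
    (c) in-group non-significant, (d) out-of-group non-significant."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency counts must be non-negative")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d


def map_vertices(mesh: SurfaceMesh, grouping: str = "functional_network"
                 ) -> pd.DataFrame:
    """Label per unmasked vertex under the requested grouping.

    ``region`` uses the atlas region id; ``functional_network`` the
    network label; ``anatomical_network`` and ``cortex`` coarse-grain the
    regions (regions are grouped into roughly equal contiguous strips, a
    stand-in for named anatomical groupings on synthetic meshes).
    """
    if grouping not in GROUPINGS:
        raise ValueError(f"unknown grouping {grouping!r}; "
                         f"one of {GROUPINGS}")
    sub = mesh.table[~mesh.table["mask"]]
    if grouping == "region":
        label = sub["region"].astype(str)
    elif grouping == "functional_network":
        label = sub["network"].map(lambda v: f"net{v}")
    else:
        n_groups = 6 if grouping == "anatomical_network" else 22
        regions = sorted(mesh.table["region"].unique())
        of = {r: f"{grouping[:4]}{(i * n_groups) // len(regions) + 1}"
              for i, r in enumerate(regions)}
        label = sub["region"].map(of)
    return pd.DataFrame({"vertex_id": sub["vertex_id"].to_numpy(),
                         "label": label.to_numpy()})


def aggregate_hits(vertex_labels: pd.DataFrame,
                   hits: pd.DataFrame) -> pd.Series:
    """Per-label counts of significant SNP-vertex associations.

    ``hits`` needs a ``vertex_id`` column (one row per significant
    association).  Labels with no hits report 0.
    """
    lab_of = dict(zip(vertex_labels["vertex_id"], vertex_labels["label"]))
    unknown = set(hits["vertex_id"]) - set(lab_of)
    if unknown:
        raise KeyError(f"hit vertex {sorted(unknown)[0]} not on the mesh")
    counts = hits["vertex_id"].map(lab_of).value_counts()
    all_labels = pd.unique(vertex_labels["label"])
    return counts.reindex(all_labels, fill_value=0).astype(int)


def enrichment_chisq(table: ContingencyTable2x2) -> tuple[float, float]:
    """Pearson chi-squared statistic (no continuity correction) and its
    1-df p-value for a 2x2 table."""
    a, b, c, d = table.a, table.b, table.c, table.d
    n = table.total
    if n == 0:
        raise ValueError("empty contingency table")
    row1, row2 = a + b, c + d
    col1, col2 = a + c, b + d
    if 0 in (row1, row2, col1, col2):
        raise ValueError("degenerate table: zero row or column margin")
    stat = n * (a * d - b * c) ** 2 / (row1 * row2 * col1 * col2)
    return float(stat), float(chi2.sf(stat, df=1))


def network_enrichment(assoc: pd.DataFrame, grouping_labels: pd.DataFrame
                       ) -> pd.DataFrame:
    """Enrichment of significant associations per network/region label.

    ``assoc`` needs ``vertex_id`` and boolean ``significant`` columns, one
    row per tested SNP-vertex unit.  For every label a 2x2 table
    (in/out of group x significant/insignificant) is tested; degenerate
    tables are skipped.
    """
    lab_of = dict(zip(grouping_labels["vertex_id"],
                      grouping_labels["label"]))
    labels = assoc["vertex_id"].map(lab_of)
    if labels.isna().any():
        raise KeyError("association vertex not present in the grouping")
    sig = assoc["significant"].to_numpy(bool)
    rows = []
    for lab in pd.unique(grouping_labels["label"]):
        inside = (labels == lab).to_numpy()
        t = ContingencyTable2x2(
            a=int((inside & sig).sum()), b=int((~inside & sig).sum()),
            c=int((inside & ~sig).sum()), d=int((~inside & ~sig).sum()))
        try:
            stat, p = enrichment_chisq(t)
        except ValueError:
            continue
        rows.append((lab, stat, p, t.a, t.b, t.c, t.d))
    return pd.DataFrame(rows, columns=["label", "chi2", "p",
                                       "a", "b", "c", "d"])


def locus_network_enrichment(assignments: pd.DataFrame) -> pd.DataFrame:
    """Joint cytoband x network enrichment of significant associations.

    ``assignments`` has one row per association with columns ``cytoband``,
    ``network`` and boolean ``significant``.  For every (cytoband,
    network) pair seen among significant associations, a 2x2 table counts
    significant associations inside/outside the band crossed with
    inside/outside the network; degenerate pairs are skipped with a note.
    """
    required = {"cytoband", "network", "significant"}
    if not required <= set(assignments.columns):
        raise ValueError(f"assignments needs columns {sorted(required)}")
    if len(assignments) == 0:
        raise ValueError("no associations supplied")
    sig = assignments[assignments["significant"]]
    pairs = sig[["cytoband", "network"]].drop_duplicates()
    rows = []
    skipped = []
    sig_flag = assignments["significant"].to_numpy(bool)
    for band, net in pairs.itertuples(index=False):
        in_band = (assignments["cytoband"] == band).to_numpy()
        in_net = (assignments["network"] == net).to_numpy()
        t = ContingencyTable2x2(
            a=int((sig_flag & in_band & in_net).sum()),
            b=int((sig_flag & in_band & ~in_net).sum()),
            c=int((sig_flag & ~in_band & in_net).sum()),
            d=int((sig_flag & ~in_band & ~in_net).sum()))
        try:
            stat, p = enrichment_chisq(t)
        except ValueError as exc:
            skipped.append((band, net, str(exc)))
            continue
        rows.append((band, net, stat, p, t.a, t.b, t.c, t.d))
    out = pd.DataFrame(rows, columns=["cytoband", "network", "chi2", "p",
                                      "a", "b", "c", "d"])
    out.attrs["skipped"] = skipped
    return out


def dice_overlap(set_a, set_b) -> float:
    """Dice coefficient 2|A∩B| / (|A| + |B|); 0 when both sets are empty."""
    a, b = set(set_a), set(set_b)
    if not a and not b:
        return 0.0
    return 2.0 * len(a & b) / (len(a) + len(b))
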