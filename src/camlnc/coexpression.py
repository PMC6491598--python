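"""lncRNA-mRNA co-expression networks by Pearson correlation thresholding.

An edge joins a lncRNA and an mRNA whenever |r| strictly exceeds the
threshold (default 0.95) over the shared diel condition series; edge sign
records the direction of correlation.  Zero-variance profiles cannot be
correlated and are skipped (counted, not fatal).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .data_model import DataError, ExpressionMatrix, collapse_replicates


def pearson_r(a, b) -> float:
    """Pearson product-moment correlation of two equal-length vectors."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 3:
        raise DataError("pearson_r requires two equal-length vectors of size >= 3")
    if a.std() == 0 or b.std() == 0:
        raise DataError("pearson_r undefined for zero-variance input")
    return float(np.corrcoef(a, b)[0, 1])


@dataclass
class CoexpressionNetwork:
    """Bipartite lncRNA-mRNA edge list at a fixed |r| threshold."""

    edges: pd.DataFrame  # columns: lncrna, mrna, r, sign
    r_threshold: float
    n_skipped_lncrna: int = 0
    n_skipped_mrna: int = 0
    lncrna_ids: list[str] = field(default_factory=list)
    mrna_ids: list[str] = field(default_factory=list)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def n_positive(self) -> int:
        return int((self.edges["sign"] == "positive").sum())

    @property
    def n_negative(self) -> int:
        return int((self.edges["sign"] == "negative").sum())

    def nodes(self) -> set[str]:
        return set(self.edges["lncrna"]) | set(self.edges["mrna"])

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        for row in self.edges.itertuples():
            g.add_node(row.lncrna, kind="lncRNA")
            g.add_node(row.mrna, kind="mRNA")
            g.add_edge(row.lncrna, row.mrna, r=float(row.r), sign=row.sign)
        return g

    def write_tsv(self, path: str) -> None:
        self.edges.to_csv(path, sep="\t", index=False, float_format="%.6g")

    def write_graphml(self, path: str) -> None:
        nx.write_graphml(self.to_networkx(), path)


def _condition_values(m: ExpressionMatrix) -> pd.DataFrame:
    if m.samples["replicate"].notna().any():
        m = collapse_replicates(m)
    return m.values


def build_network(
    lnc_expr: ExpressionMatrix,
    mrna_expr: ExpressionMatrix,
    r_threshold: float = 0.95,
) -> CoexpressionNetwork:
    """All-pairs Pearson correlation between lncRNA and mRNA rows, keeping
    pairs with r > threshold or r < -threshold (strict).

    The two matrices must share an identical sample/condition column set
    (replicates are collapsed to condition means first).  Rows with zero
    variance are skipped and counted.
    """
    lv = _condition_values(lnc_expr)
    mv = _condition_values(mrna_expr)
    if list(lv.columns) != list(mv.columns):
        raise DataError("lncRNA and mRNA matrices must share identical sample columns")
    if lv.shape[1] < 3:
        raise DataError("need >= 3 conditions to correlate")

    def standardize(df: pd.DataFrame):
        x = df.to_numpy(dtype=float)
        mu = x.mean(axis=1, keepdims=True)
        sd = x.std(axis=1, keepdims=True)
        ok = sd[:, 0] > 0
        z = np.zeros_like(x)
        z[ok] = (x[ok] - mu[ok]) / sd[ok]
        return z, ok

    zl, ok_l = standardize(lv)
    zm, ok_m = standardize(mv)
    n = lv.shape[1]
    r = zl @ zm.T / n
    r = np.clip(r, -1.0, 1.0)
    mask = (np.abs(r) > r_threshold) & ok_l[:, None] & ok_m[None, :]
    li, mi = np.nonzero(mask)
    edges = pd.DataFrame(
        {
            "lncrna": lv.index.to_numpy()[li],
            "mrna": mv.index.to_numpy()[mi],
            "r": r[li, mi],
        }
    )
    edges["sign"] = np.where(edges["r"] > 0, "positive", "negative")
    edges = edges.sort_values(["lncrna", "mrna"]).reset_index(drop=True)
    return CoexpressionNetwork(
        edges=edges,
        r_threshold=r_threshold,
        n_skipped_lncrna=int((~ok_l).sum()),
        n_skipped_mrna=int((~ok_m).sum()),
        lncrna_ids=list(lv.index),
        mrna_ids=list(mv.index),
    )


def induced_subnetwork(net: CoexpressionNetwork, node_ids) -> CoexpressionNetwork:
    """Edges of ``net`` with both endpoints in ``node_ids`` (may be empty)."""
    node_ids = set(node_ids)
    if not node_ids:
        raise DataError("induced_subnetwork requires a nonempty node set")
    keep = net.edges["lncrna"].isin(node_ids) & net.edges["mrna"].isin(node_ids)
    return CoexpressionNetwork(
        edges=net.edges[keep].reset_index(drop=True),
        r_threshold=net.r_threshold,
        lncrna_ids=[i for i in net.lncrna_ids if i in node_ids],
        mrna_ids=[i for i in net.mrna_ids if i in node_ids],
    )


def degree_summary(net: CoexpressionNetwork) -> pd.DataFrame:
    """Per-node bipartite degree table with node class."""
    rows = []
    for cls, col in (("lncRNA", "lncrna"), ("mRNA", "mrna")):
        counts = net.edges[col].value_counts()
        for node, deg in counts.items():
            rows.append({"node": node, "class": cls, "degree": int(deg)})
    df = pd.DataFrame(rows, columns=["node", "class", "degree"])
    return df.sort_values(["class", "node"]).reset_index(drop=True)
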