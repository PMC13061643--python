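"""TF core-regulatory-network strength statistic and network comparison.

The network is a directed graph of TF -> TF regulatory edges (edge lists
are inputs; motif scanning and super-enhancer assignment are upstream of
this package).  A TF's regulatory strength is its out-degree minus its
in-degree, so strengths sum to zero over any network: each edge
contributes +1 to its source and -1 to its target.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Iterable, Mapping
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm


@dataclasses.dataclass
class TFNetwork:
    """Directed TF network with optional per-TF expression values.

    Self-loops are excluded by default; parallel edges are collapsed
    unless ``weighted`` is set, in which case multiplicity contributes to
    degree counts.
    """

    nodes: frozenset
    edges: tuple          # ((regulator, target, multiplicity), ...)
    expression: dict = dataclasses.field(default_factory=dict)

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple[str, str]],
        expression: Mapping[str, float] | None = None,
        allow_self: bool = False,
        weighted: bool = False,
    ) -> "TFNetwork":
        counts: dict[tuple[str, str], int] = {}
        nodes = set()
        for u, v in edges:
            nodes.update((u, v))
            if u == v and not allow_self:
                continue
            counts[(u, v)] = counts.get((u, v), 0) + 1
        tupled = tuple(sorted(
            (u, v, (m if weighted else 1)) for (u, v), m in counts.items()
        ))
        return cls(nodes=frozenset(nodes), edges=tupled,
                   expression=dict(expression or {}))

    @classmethod
    def from_tsv(cls, path: str | Path, **kwargs) -> "TFNetwork":
        df = pd.read_csv(path, sep="\t", comment="#", header=None,
                         names=["regulator", "target"])
        return cls.from_edges(zip(df["regulator"], df["target"]), **kwargs)


def tf_strength(net: TFNetwork) -> pd.Series:
    """Per-TF regulatory strength: out-degree minus in-degree."""
    strength = {n: 0 for n in sorted(net.nodes)}
    for u, v, m in net.edges:
        strength[u] += m
        strength[v] -= m
    return pd.Series(strength, name="strength")


def rank_tfs(strengths: pd.Series,
             expression: Mapping[str, float] | None = None) -> pd.DataFrame:
    """Ranked table by descending strength; ties break alphabetically."""
    df = pd.DataFrame({"tf": strengths.index, "strength": strengths.values})
    df = df.sort_values(["strength", "tf"], ascending=[False, True],
                        kind="mergesort").reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    if expression is not None:
        df["expression"] = df["tf"].map(expression)
    return df[["rank", "tf", "strength"] +
              (["expression"] if expression is not None else [])]


@dataclasses.dataclass
class NetworkComparison:
    shared_fraction: float
    table: pd.DataFrame           # tf, strength_a, strength_b, delta
    slope: float | None
    intercept: float | None
    slope_ci: tuple[float, float] | None
    intercept_ci: tuple[float, float] | None
    message: str = ""


def compare_networks(net_a: TFNetwork, net_b: TFNetwork) -> NetworkComparison:
    """Compare two TF networks over their shared TFs.

    Reports the shared-TF fraction over the node union, per-TF strength
    pairs with deltas (A minus B), and an ordinary least-squares
    regression of strength in B on strength in A with 95% confidence
    intervals.  Regression is refused with fewer than 3 shared TFs.
    """
    sa = tf_strength(net_a)
    sb = tf_strength(net_b)
    shared = sorted(net_a.nodes & net_b.nodes)
    union = net_a.nodes | net_b.nodes
    frac = len(shared) / len(union) if union else 0.0
    table = pd.DataFrame(
        {"tf": shared,
         "strength_a": [sa[t] for t in shared],
         "strength_b": [sb[t] for t in shared]}
    )
    table["delta"] = table["strength_a"] - table["strength_b"]

    if len(shared) < 3:
        return NetworkComparison(
            shared_fraction=frac, table=table, slope=None, intercept=None,
            slope_ci=None, intercept_ci=None,
            message="fewer than 3 shared TFs; regression refused",
        )
    x = sm.add_constant(table["strength_a"].to_numpy(dtype=float))
    fit = sm.OLS(table["strength_b"].to_numpy(dtype=float), x).fit()
    ci = fit.conf_int(alpha=0.05)
    return NetworkComparison(
        shared_fraction=frac, table=table,
        slope=float(fit.params[1]), intercept=float(fit.params[0]),
        slope_ci=(float(ci[1, 0]), float(ci[1, 1])),
        intercept_ci=(float(ci[0, 0]), float(ci[0, 1])),
    )
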