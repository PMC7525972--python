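"""Centrality ranking, key-microbe nomination, and focal-genus reports."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import rankdata

from glvnet.inference import ConsensusNetwork

CENTRALITY_NAMES = ("degree", "betweenness", "closeness")


@dataclass
class CentralityReport:
    """Per-taxon centrality scores, component ranks, and the final rank.

    ``frame`` columns: the three centrality scores; ``rank_degree``,
    ``rank_closeness``, ``rank_betweenness`` (1 = best, ties averaged);
    ``total_rank`` (their sum); ``final_rank`` (dense rank of total_rank,
    ascending); boolean ``key`` (final_rank == 1).
    """

    frame: pd.DataFrame

    @property
    def key_taxa(self) -> list[str]:
        return sorted(self.frame.index[self.frame["key"]])

    def write_csv(self, path) -> None:
        self.frame.to_csv(path, index_label="taxon")


@dataclass
class FocalInteractionTable:
    """Signed in/out neighbor lists of one focal taxon."""

    focal: str
    influenced_by_positive: list[str]
    influenced_by_negative: list[str]
    influences_positive: list[str]
    influences_negative: list[str]

    @property
    def counts(self) -> tuple[int, int, int, int]:
        """(in+, in-, out+, out-) list lengths."""
        return (
            len(self.influenced_by_positive),
            len(self.influenced_by_negative),
            len(self.influences_positive),
            len(self.influences_negative),
        )

    def to_frame(self) -> pd.DataFrame:
        cols = {
            "influenced_by_positive": self.influenced_by_positive,
            "influenced_by_negative": self.influenced_by_negative,
            "influences_positive": self.influences_positive,
            "influences_negative": self.influences_negative,
        }
        depth = max((len(v) for v in cols.values()), default=0)
        return pd.DataFrame(
            {k: v + [""] * (depth - len(v)) for k, v in cols.items()}
        )


def _as_digraph(network: ConsensusNetwork | nx.DiGraph) -> nx.DiGraph:
    if isinstance(network, nx.DiGraph):
        return network
    return network.to_networkx()


def centralities(
    network: ConsensusNetwork | nx.DiGraph, weighted: bool = False
) -> pd.DataFrame:
    """Degree (in+out), betweenness, and closeness per node.

    Paths are directed and unweighted by default (edge presence only);
    ``weighted=True`` uses distance ``1/|mean_strength|``.  Betweenness is
    unnormalized pair counts; closeness is outgoing-distance closeness with
    within-reachable-set normalization, so isolated nodes score 0.
    """
    g = _as_digraph(network)
    if g.number_of_nodes() == 0:
        raise ValueError("network has no nodes")
    weight = None
    if weighted:
        weight = "distance"
        for _, _, data in g.edges(data=True):
            data["distance"] = 1.0 / max(abs(data.get("mean_strength", 1.0)), 1e-12)
    degree = dict(g.degree())
    betweenness = nx.betweenness_centrality(g, normalized=False, weight=weight)
    closeness = nx.closeness_centrality(g.reverse(copy=False), distance=weight)
    frame = pd.DataFrame(
        {
            "degree": pd.Series(degree),
            "betweenness": pd.Series(betweenness),
            "closeness": pd.Series(closeness),
        }
    )
    return frame.loc[list(g.nodes)]


def rank_aggregate(cent: pd.DataFrame | ConsensusNetwork | nx.DiGraph) -> CentralityReport:
    """Aggregate the three centralities into a final rank.

    Each centrality is ranked descending (1 = highest score, ties
    averaged); ``total_rank`` sums the three; ``final_rank`` is the dense
    rank of ``total_rank`` ascending, so the taxon (or taxa, under ties)
    with the smallest total is the key microbe.
    """
    if not isinstance(cent, pd.DataFrame):
        cent = centralities(cent)
    if len(cent) == 0:
        raise ValueError("empty centrality table")
    frame = cent.copy()
    for name in CENTRALITY_NAMES:
        frame[f"rank_{name}"] = rankdata(-frame[name].to_numpy(), method="average")
    frame["total_rank"] = (
        frame["rank_degree"] + frame["rank_betweenness"] + frame["rank_closeness"]
    )
    frame["final_rank"] = (
        pd.Series(frame["total_rank"]).rank(method="dense").astype(int).to_numpy()
    )
    frame["key"] = frame["final_rank"] == 1
    return CentralityReport(frame)


def rank_regression(report: CentralityReport) -> tuple[float, float]:
    """OLS of final rank on the three component ranks.

    Returns ``(R^2, overall-F p-value)``.  Constant component-rank columns
    (fully tied centralities) carry no information and are dropped with a
    warning before fitting.
    """
    import statsmodels.api as sm

    frame = report.frame
    if len(frame) < 5:
        raise ValueError("rank regression needs at least 5 nodes")
    predictors = frame[[f"rank_{name}" for name in CENTRALITY_NAMES]]
    constant = [c for c in predictors.columns if predictors[c].nunique() == 1]
    if constant:
        warnings.warn(f"dropping constant predictor(s): {constant}")
        predictors = predictors.drop(columns=constant)
    if predictors.shape[1] == 0:
        warnings.warn("all predictors constant; regression undefined")
        return 0.0, 1.0
    response = frame["final_rank"].to_numpy().astype(float)
    if np.ptp(response) == 0:
        warnings.warn("final_rank is constant; regression undefined")
        return 0.0, 1.0
    design = sm.add_constant(predictors.to_numpy())
    model = sm.OLS(response, design).fit()
    p_value = float(model.f_pvalue)
    if np.isnan(p_value) and model.rsquared > 1 - 1e-12:
        p_value = 0.0  # exact fit: F statistic degenerates
    return float(model.rsquared), p_value


def fragmentation(network: ConsensusNetwork | nx.DiGraph) -> int:
    """Number of weakly connected components (1 = unfragmented)."""
    g = _as_digraph(network)
    if g.number_of_nodes() == 0:
        raise ValueError("network has no nodes")
    return nx.number_weakly_connected_components(g)


def focal_report(
    network: ConsensusNetwork | nx.DiGraph, focal_taxon: str
) -> FocalInteractionTable:
    """Alphabetical signed in/out neighbor lists of one focal taxon."""
    g = _as_digraph(network)
    if focal_taxon not in g:
        raise KeyError(
            f"{focal_taxon!r} is not a network node; available: {sorted(g.nodes)}"
        )
    in_pos = sorted(u for u, _, d in g.in_edges(focal_taxon, data=True) if d["sign"] > 0)
    in_neg = sorted(u for u, _, d in g.in_edges(focal_taxon, data=True) if d["sign"] < 0)
    out_pos = sorted(v for _, v, d in g.out_edges(focal_taxon, data=True) if d["sign"] > 0)
    out_neg = sorted(v for _, v, d in g.out_edges(focal_taxon, data=True) if d["sign"] < 0)
    return FocalInteractionTable(
        focal=focal_taxon,
        influenced_by_positive=in_pos,
        influenced_by_negative=in_neg,
        influences_positive=out_pos,
        influences_negative=out_neg,
    )
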