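"""Replicate-assembly ensemble gLV regression and sign-consensus network.

A composite time series is built by choosing, at every time point, the
sample of one replicate animal.  With R replicates and K time points there
are R^K such assemblies; a discrete gLV regression is fitted to each, and
an interaction j -> i is kept in the consensus network only if its fitted
coefficient carries the same sign in strictly more than ``cutoff`` of the
ensemble members.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd

from glvnet.abundance import AbundanceTable, to_relative

logger = logging.getLogger(__name__)

#: Default ceiling on R^K for exhaustive enumeration.
ENUMERATION_CEILING = 200_000


class EnsembleSizeError(ValueError):
    """R^K exceeds the enumeration ceiling; advise subsampling."""


@dataclass
class FitConfig:
    """Configuration of the per-assembly gLV regression.

    ``regression`` is one of ``pls`` (partial least squares, default: the
    only backend that is usable when taxa outnumber transitions), ``ridge``
    or ``ols``.  ``pseudocount`` replaces zeros before the log transform;
    ``None`` means half the smallest nonzero value of the series.
    """

    regression: str = "pls"
    n_components: int = 2
    ridge_lambda: float = 1.0
    pseudocount: float | None = None

    def __post_init__(self) -> None:
        if self.regression not in ("pls", "ridge", "ols"):
            raise ValueError(
                f"unknown regression backend {self.regression!r}; "
                "use 'pls', 'ridge' or 'ols'"
            )


@dataclass
class CoefficientEnsemble:
    """Stack of fitted gLV coefficients, one member per assembly.

    ``growth`` has shape ``(M, n_taxa)``; ``interactions`` has shape
    ``(M, n_taxa, n_taxa)`` with entry ``(m, i, j)`` the fitted effect of
    taxon j on taxon i in member m.
    """

    growth: np.ndarray
    interactions: np.ndarray
    taxa: list[str]
    assemblies: np.ndarray
    config: FitConfig = field(default_factory=FitConfig)

    def __post_init__(self) -> None:
        m, n = self.growth.shape
        if self.interactions.shape != (m, n, n):
            raise ValueError("growth/interaction shapes disagree")
        if len(self.taxa) != n:
            raise ValueError("taxon labels do not match coefficient dimension")

    @property
    def n_members(self) -> int:
        return self.growth.shape[0]

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)


@dataclass
class ConsensusNetwork:
    """Directed signed network of reliable interactions.

    ``edges`` columns: ``source``, ``target`` (source acts on target),
    ``sign`` (+1/-1), ``support`` (fraction of ensemble members with that
    sign), ``mean_strength`` (mean coefficient over supporting members).
    """

    taxa: list[str]
    edges: pd.DataFrame
    cutoff: float = 0.7
    n_members: int = 1

    EDGE_COLUMNS = ("source", "target", "sign", "support", "mean_strength")

    def __post_init__(self) -> None:
        if list(self.edges.columns) != list(self.EDGE_COLUMNS):
            self.edges = self.edges.loc[:, list(self.EDGE_COLUMNS)]
        self.edges = self.edges.sort_values(["source", "target"]).reset_index(drop=True)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.taxa)
        for row in self.edges.itertuples(index=False):
            g.add_edge(
                row.source,
                row.target,
                sign=int(row.sign),
                support=float(row.support),
                mean_strength=float(row.mean_strength),
            )
        return g

    def write_edgelist(self, path) -> None:
        out = self.edges.copy()
        out["sign"] = np.where(out["sign"] > 0, "+", "-")
        out.to_csv(path, index=False)

    @classmethod
    def read_edgelist(
        cls, path, taxa: Sequence[str] | None = None, cutoff: float = 0.7,
        n_members: int = 1,
    ) -> "ConsensusNetwork":
        frame = pd.read_csv(path)
        frame["sign"] = np.where(frame["sign"].astype(str) == "+", 1, -1)
        if taxa is None:
            taxa = sorted(set(frame["source"]) | set(frame["target"]))
        return cls(list(taxa), frame, cutoff=cutoff, n_members=n_members)

    def write_graphml(self, path) -> None:
        nx.write_graphml(self.to_networkx(), path)

    def write_gexf(self, path) -> None:
        nx.write_gexf(self.to_networkx(), path)


def enumerate_assemblies(
    n_replicates: int,
    n_timepoints: int,
    mode: str = "full",
    n_subsample: int | None = None,
    seed: int | np.random.Generator | None = None,
    ceiling: int = ENUMERATION_CEILING,
) -> np.ndarray:
    """Enumerate (or subsample) replicate-choice vectors.

    Returns an ``(M, n_timepoints)`` integer array with values in
    ``1..n_replicates``.  Full mode lists all ``R^K`` assemblies in
    lexicographic order; subsample mode draws ``n_subsample`` distinct
    assemblies with a seeded generator.
    """
    if n_replicates < 1 or n_timepoints < 1:
        raise ValueError("n_replicates and n_timepoints must be >= 1")
    total = n_replicates**n_timepoints
    if mode == "full":
        if total > ceiling:
            raise EnsembleSizeError(
                f"{n_replicates}^{n_timepoints} = {total} assemblies exceed the "
                f"ceiling of {ceiling}; use mode='subsample'"
            )
        powers = n_replicates ** np.arange(n_timepoints - 1, -1, -1, dtype=np.int64)
        idx = np.arange(total, dtype=np.int64)
        return ((idx[:, None] // powers) % n_replicates + 1).astype(np.int16)
    if mode == "subsample":
        if n_subsample is None or n_subsample < 1:
            raise ValueError("subsample mode requires n_subsample >= 1")
        if n_subsample > total:
            raise ValueError(
                f"cannot draw {n_subsample} distinct assemblies from {total}"
            )
        rng = np.random.default_rng(seed)
        chosen: dict[tuple, None] = {}
        while len(chosen) < n_subsample:
            batch = rng.integers(1, n_replicates + 1, size=(n_subsample, n_timepoints))
            for row in batch:
                chosen.setdefault(tuple(int(v) for v in row), None)
                if len(chosen) == n_subsample:
                    break
        return np.array(list(chosen.keys()), dtype=np.int16)
    raise ValueError(f"unknown mode {mode!r}; use 'full' or 'subsample'")


def _group_tensor(
    table: AbundanceTable, group: str
) -> tuple[np.ndarray, np.ndarray, list[int]]:
    """Relative abundances as (replicate, time, taxon) plus the day grid."""
    sub = table.subset(group)
    rel = to_relative(sub)
    meta = sub.metadata
    days = np.array(sorted(meta["day"].unique()))
    reps = sorted(meta["replicate"].unique())
    tensor = np.empty((len(reps), len(days), len(sub.taxa)))
    for r_idx, rep in enumerate(reps):
        for t_idx, day in enumerate(days):
            mask = (meta["replicate"] == rep) & (meta["day"] == day)
            if mask.sum() != 1:
                raise ValueError(
                    f"expected exactly one sample for (group={group!r}, "
                    f"replicate={rep}, day={day:g}); found {int(mask.sum())}"
                )
            tensor[r_idx, t_idx] = rel.loc[mask].to_numpy()[0]
    return tensor, days, reps


def assemble_series(
    table: AbundanceTable, group: str, assembly: Sequence[int]
) -> tuple[np.ndarray, np.ndarray]:
    """Build one composite taxon x time relative-abundance matrix.

    Column ``k`` is the relative-abundance profile of replicate
    ``assembly[k]`` at the group's k-th sampling day.  Returns
    ``(series, days)``.
    """
    tensor, days, reps = _group_tensor(table, group)
    assembly = np.asarray(assembly, dtype=int)
    if assembly.shape != (len(days),):
        raise ValueError(
            f"assembly length {assembly.size} != {len(days)} time points"
        )
    rep_pos = {rep: i for i, rep in enumerate(reps)}
    try:
        rows = np.array([rep_pos[int(r)] for r in assembly])
    except KeyError as exc:
        raise ValueError(
            f"assembly references unknown replicate {exc} in group {group!r}"
        ) from None
    series = tensor[rows, np.arange(len(days)), :].T
    return series, days


def _default_pseudocount(series: np.ndarray) -> float:
    positive = series[series > 0]
    if positive.size == 0:
        raise ValueError("series has no positive values")
    return float(positive.min() / 2.0)


def fit_glv_series(
    series: np.ndarray,
    time_grid: Sequence[float],
    config: FitConfig | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Fit the discrete gLV regression to one taxon x time series.

    Per taxon i the response is the per-day log change
    ``y_i(k) = (ln x_i(t_{k+1}) - ln x_i(t_k)) / dt_k`` and the predictors
    are all taxa's abundances at ``t_k`` plus an intercept.  Returns the
    growth vector ``b`` and interaction matrix ``a`` (row i = effects on
    taxon i).
    """
    config = config or FitConfig()
    x = np.asarray(series, dtype=float)
    grid = np.asarray(time_grid, dtype=float)
    if x.ndim != 2 or x.shape[1] != grid.size:
        raise ValueError(
            f"series shape {x.shape} does not match {grid.size} time points"
        )
    if grid.size < 2:
        raise ValueError("need at least two time points")
    dt = np.diff(grid)
    if np.any(dt == 0):
        raise ValueError("zero time step in time_grid")
    if np.any(dt < 0):
        raise ValueError("time_grid must be increasing")
    if np.any(x < 0):
        raise ValueError("abundances must be non-negative")

    pc = config.pseudocount if config.pseudocount is not None else _default_pseudocount(x)
    xp = np.where(x > 0, x, pc)
    y = np.diff(np.log(xp), axis=1) / dt  # (n_taxa, K-1)
    predictors = x[:, :-1].T  # (K-1, n_taxa)
    n_taxa = x.shape[0]

    if config.regression == "ols":
        design = np.column_stack([np.ones(predictors.shape[0]), predictors])
        sol, *_ = np.linalg.lstsq(design, y.T, rcond=None)
        return sol[0].copy(), sol[1:].T.copy()

    if config.regression == "ridge":
        from sklearn.linear_model import Ridge

        model = Ridge(alpha=config.ridge_lambda, fit_intercept=True)
        model.fit(predictors, y.T)
        return np.atleast_1d(model.intercept_).astype(float), np.atleast_2d(
            model.coef_
        ).astype(float)

    # pls: one single-response fit per taxon (constant responses short-circuit
    # to a zero coefficient row, which PLS cannot represent)
    from sklearn.cross_decomposition import PLSRegression

    n_comp = min(config.n_components, predictors.shape[0], predictors.shape[1])
    b = np.zeros(n_taxa)
    a = np.zeros((n_taxa, n_taxa))
    for i in range(n_taxa):
        yi = y[i]
        if np.allclose(yi, yi[0]):
            b[i] = yi[0]
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pls = PLSRegression(n_components=n_comp, scale=True)
            pls.fit(predictors, yi)
        a[i] = pls.coef_.ravel()
        b[i] = float(np.atleast_1d(pls.intercept_)[0])
    return b, a


def ensemble_from_replicates(
    replicates: np.ndarray,
    time_grid: Sequence[float],
    assemblies: np.ndarray,
    fit_config: FitConfig | None = None,
    taxa: Sequence[str] | None = None,
    replicate_ids: Sequence[int] | None = None,
) -> CoefficientEnsemble:
    """Fit one gLV regression per assembly of a replicate trajectory stack.

    ``replicates`` has shape ``(R, n_taxa, K)``; values may be absolute
    abundances (e.g. ground-truth trajectories for recovery testing) or
    relative abundances.  ``replicate_ids`` maps assembly values to stack
    rows (default ``1..R``).
    """
    fit_config = fit_config or FitConfig()
    replicates = np.asarray(replicates, dtype=float)
    if replicates.ndim != 3:
        raise ValueError("replicates must have shape (R, n_taxa, K)")
    assemblies = np.asarray(assemblies, dtype=int)
    if assemblies.ndim != 2 or assemblies.shape[0] == 0:
        raise ValueError("assemblies must be a nonempty (M, K) array")
    n_reps, n_taxa, n_times = replicates.shape
    if assemblies.shape[1] != n_times:
        raise ValueError(
            f"assembly length {assemblies.shape[1]} != {n_times} time points"
        )
    ids = list(replicate_ids) if replicate_ids is not None else list(range(1, n_reps + 1))
    rep_pos = {rep: i for i, rep in enumerate(ids)}
    labels = list(taxa) if taxa is not None else [f"taxon_{i}" for i in range(n_taxa)]
    col = np.arange(n_times)

    growth = np.empty((assemblies.shape[0], n_taxa))
    interactions = np.empty((assemblies.shape[0], n_taxa, n_taxa))
    for m, assembly in enumerate(assemblies):
        try:
            rows = np.array([rep_pos[int(r)] for r in assembly])
            series = replicates[rows, :, col].T
            b, a = fit_glv_series(series, time_grid, fit_config)
        except Exception as exc:
            raise RuntimeError(
                f"fit failed for assembly #{m} {tuple(int(v) for v in assembly)}: {exc}"
            ) from exc
        growth[m] = b
        interactions[m] = a
    return CoefficientEnsemble(
        growth=growth,
        interactions=interactions,
        taxa=labels,
        assemblies=assemblies,
        config=replace(fit_config),
    )


def infer_ensemble(
    table: AbundanceTable,
    group: str,
    assemblies: np.ndarray,
    fit_config: FitConfig | None = None,
) -> CoefficientEnsemble:
    """Fit the gLV regression to every assembly of one group's series."""
    fit_config = fit_config or FitConfig()
    tensor, days, reps = _group_tensor(table, group)
    ensemble = ensemble_from_replicates(
        tensor.transpose(0, 2, 1),
        days,
        assemblies,
        fit_config,
        taxa=table.taxa,
        replicate_ids=reps,
    )
    logger.info(
        "fitted ensemble: group=%s members=%d taxa=%d backend=%s",
        group, ensemble.n_members, ensemble.n_taxa, fit_config.regression,
    )
    return ensemble


def support_threshold_count(ensemble_size: int, cutoff: float) -> int:
    """Smallest integer count strictly exceeding ``cutoff * ensemble_size``."""
    if not 0 < cutoff < 1:
        raise ValueError("cutoff must be in (0, 1)")
    if ensemble_size < 1:
        raise ValueError("ensemble_size must be >= 1")
    return int(math.floor(cutoff * ensemble_size)) + 1


def consensus_network(
    ensemble: CoefficientEnsemble,
    cutoff: float = 0.7,
    include_self: bool = False,
) -> ConsensusNetwork:
    """Keep interactions whose sign recurs in > ``cutoff`` of members.

    Edge direction follows the coefficient convention: entry ``(i, j)``
    describes the effect of taxon j on taxon i, so a retained entry
    becomes the edge ``j -> i``.  When both signs pass the threshold
    (possible only for ``cutoff < 0.5``) the majority sign wins.
    """
    if ensemble.n_members == 0:
        raise ValueError("empty ensemble")
    a = ensemble.interactions
    m_total = ensemble.n_members
    needed = support_threshold_count(m_total, cutoff)
    pos_counts = (a > 0).sum(axis=0)
    neg_counts = (a < 0).sum(axis=0)

    records = []
    for i in range(ensemble.n_taxa):
        for j in range(ensemble.n_taxa):
            if i == j and not include_self:
                continue
            pos_ok = pos_counts[i, j] >= needed
            neg_ok = neg_counts[i, j] >= needed
            if not (pos_ok or neg_ok):
                continue
            if pos_ok and (not neg_ok or pos_counts[i, j] >= neg_counts[i, j]):
                sign, count = 1, int(pos_counts[i, j])
                strength = float(a[:, i, j][a[:, i, j] > 0].mean())
            else:
                sign, count = -1, int(neg_counts[i, j])
                strength = float(a[:, i, j][a[:, i, j] < 0].mean())
            records.append(
                {
                    "source": ensemble.taxa[j],
                    "target": ensemble.taxa[i],
                    "sign": sign,
                    "support": count / m_total,
                    "mean_strength": strength,
                }
            )
    edges = pd.DataFrame(records, columns=list(ConsensusNetwork.EDGE_COLUMNS))
    return ConsensusNetwork(
        taxa=list(ensemble.taxa), edges=edges, cutoff=cutoff, n_members=m_total
    )
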