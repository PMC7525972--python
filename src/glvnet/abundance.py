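"""Count-table ingestion, membership classes, and alpha diversity.

The on-disk format is a mothur-style "shared" TSV (label, Group = sample
name, numOtus, then one column per taxon) plus a metadata TSV mapping
each sample to (group, replicate, day).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

ABUNDANCE_CLASSES = ("high", "low", "rare")


class SharedFileParseError(ValueError):
    """Malformed shared/metadata file (message carries the line number)."""


class AbundanceTable:
    """Sample x taxon count matrix with per-sample (group, replicate, day).

    Parameters
    ----------
    counts
        Non-negative integer frame, index = sample IDs, columns = taxa.
    metadata
        Frame indexed by sample ID with columns ``group``, ``replicate``,
        ``day``; must cover every sample in ``counts``.
    """

    def __init__(self, counts: pd.DataFrame, metadata: pd.DataFrame):
        if counts.index.has_duplicates:
            dupes = counts.index[counts.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample IDs: {dupes}")
        if (counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        missing = [s for s in counts.index if s not in metadata.index]
        if missing:
            raise ValueError(f"metadata missing sample(s): {missing}")
        required = {"group", "replicate", "day"}
        absent = required - set(metadata.columns)
        if absent:
            raise ValueError(f"metadata lacks column(s): {sorted(absent)}")
        self.counts = counts.astype(np.int64)
        self.metadata = metadata.loc[counts.index, ["group", "replicate", "day"]].copy()
        self.metadata["replicate"] = self.metadata["replicate"].astype(int)
        self.metadata["day"] = self.metadata["day"].astype(float)
        empty = self.counts.columns[self.counts.sum(axis=0) == 0].tolist()
        if empty:
            logger.info("taxa with zero total counts: %s", empty)

    @property
    def samples(self) -> list[str]:
        return list(self.counts.index)

    @property
    def taxa(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def groups(self) -> list[str]:
        seen: dict[str, None] = {}
        for g in self.metadata["group"]:
            seen.setdefault(g, None)
        return list(seen)

    def subset(self, group: str) -> "AbundanceTable":
        mask = self.metadata["group"] == group
        if not mask.any():
            raise KeyError(f"no samples for group {group!r}; have {self.groups}")
        return AbundanceTable(self.counts.loc[mask], self.metadata.loc[mask])

    def equals(self, other: "AbundanceTable") -> bool:
        return self.counts.equals(other.counts) and self.metadata.equals(other.metadata)

    def write(self, shared_path, metadata_path) -> None:
        """Write the shared-style TSV and the metadata TSV."""
        with open(shared_path, "w") as fh:
            fh.write("label\tGroup\tnumOtus\t" + "\t".join(self.taxa) + "\n")
            n = len(self.taxa)
            for sample, row in self.counts.iterrows():
                vals = "\t".join(str(int(v)) for v in row.to_numpy())
                fh.write(f"genus\t{sample}\t{n}\t{vals}\n")
        with open(metadata_path, "w") as fh:
            fh.write("sample\tgroup\treplicate\tday\n")
            for sample, row in self.metadata.iterrows():
                fh.write(
                    f"{sample}\t{row['group']}\t{int(row['replicate'])}\t"
                    f"{row['day']:g}\n"
                )

    @classmethod
    def read(cls, shared_path, metadata_path) -> "AbundanceTable":
        """Read a shared-style TSV plus metadata TSV (see :meth:`write`)."""
        with open(shared_path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            if header[:3] != ["label", "Group", "numOtus"]:
                raise SharedFileParseError(
                    f"{shared_path}: line 1: expected columns "
                    "label/Group/numOtus, got " + "/".join(header[:3])
                )
            taxa = header[3:]
            rows: dict[str, list[int]] = {}
            for lineno, line in enumerate(fh, start=2):
                if not line.strip():
                    continue
                parts = line.rstrip("\n").split("\t")
                if len(parts) != 3 + len(taxa):
                    raise SharedFileParseError(
                        f"{shared_path}: line {lineno}: expected "
                        f"{3 + len(taxa)} fields, got {len(parts)}"
                    )
                try:
                    rows[parts[1]] = [int(v) for v in parts[3:]]
                except ValueError as exc:
                    raise SharedFileParseError(
                        f"{shared_path}: line {lineno}: non-integer count ({exc})"
                    ) from None
        counts = pd.DataFrame.from_dict(rows, orient="index", columns=taxa)

        meta = pd.read_csv(metadata_path, sep="\t", dtype={"sample": str})
        if "sample" not in meta.columns:
            raise SharedFileParseError(
                f"{metadata_path}: missing required 'sample' column"
            )
        meta = meta.set_index("sample")
        missing = [s for s in counts.index if s not in meta.index]
        if missing:
            raise ValueError(f"metadata missing sample(s): {missing}")
        return cls(counts, meta)


def read_abundance_table(shared_path, metadata_path) -> AbundanceTable:
    """Module-level alias for :meth:`AbundanceTable.read`."""
    return AbundanceTable.read(shared_path, metadata_path)


def to_relative(table: AbundanceTable | pd.DataFrame) -> pd.DataFrame:
    """Per-sample relative abundances; every row sums to 1.

    Raises ``ValueError`` naming the first sample with a zero total.
    """
    counts = table.counts if isinstance(table, AbundanceTable) else table
    totals = counts.sum(axis=1)
    zero = totals.index[totals == 0].tolist()
    if zero:
        raise ValueError(f"sample(s) with zero total counts: {zero}")
    return counts.div(totals, axis=0)


@dataclass
class MembershipClass:
    """Abundance/coreness classification of one taxon (within one scope)."""

    taxon: str
    abundance_class: str
    coreness: str
    mean_relative_abundance: float
    prevalence: float
    group: str | None = None


def _classify_scope(
    rel: pd.DataFrame, high_cutoff: float, rare_cutoff: float, group: str | None
) -> list[MembershipClass]:
    means = rel.mean(axis=0)
    prevalence = (rel > 0).mean(axis=0)
    out = []
    for taxon in rel.columns:
        m = float(means[taxon])
        # boundary values (exactly 0.1% or 1%) fall in the closed "low" range
        if m > high_cutoff:
            klass = "high"
        elif m < rare_cutoff:
            klass = "rare"
        else:
            klass = "low"
        core = "core" if prevalence[taxon] == 1.0 else "non_core"
        out.append(
            MembershipClass(
                taxon=taxon,
                abundance_class=klass,
                coreness=core,
                mean_relative_abundance=m,
                prevalence=float(prevalence[taxon]),
                group=group,
            )
        )
    return out


def classify_membership(
    table: AbundanceTable,
    high_cutoff: float = 0.01,
    rare_cutoff: float = 0.001,
    scope: str = "per_group",
) -> list[MembershipClass]:
    """Classify taxa as high/low/rare abundance and core/non-core.

    ``high`` iff mean per-sample relative abundance strictly exceeds
    ``high_cutoff``; ``rare`` iff strictly below ``rare_cutoff``; ``low``
    otherwise (closed interval).  ``core`` iff the taxon is present in
    every sample of the evaluated scope.
    """
    if not 0 < rare_cutoff < high_cutoff < 1:
        raise ValueError("cutoffs must satisfy 0 < rare_cutoff < high_cutoff < 1")
    if len(table.samples) == 0:
        raise ValueError("empty abundance table")
    if scope == "all_samples":
        return _classify_scope(to_relative(table), high_cutoff, rare_cutoff, None)
    if scope == "per_group":
        out: list[MembershipClass] = []
        for g in table.groups:
            out.extend(
                _classify_scope(
                    to_relative(table.subset(g)), high_cutoff, rare_cutoff, g
                )
            )
        return out
    raise ValueError(f"unknown scope {scope!r}; use 'per_group' or 'all_samples'")


def membership_frame(records: Iterable[MembershipClass]) -> pd.DataFrame:
    """Tabulate :class:`MembershipClass` records for CSV export."""
    return pd.DataFrame(
        [
            {
                "taxon": r.taxon,
                "group": r.group if r.group is not None else "all",
                "abundance_class": r.abundance_class,
                "coreness": r.coreness,
                "mean_relative_abundance": r.mean_relative_abundance,
                "prevalence": r.prevalence,
            }
            for r in records
        ]
    )


def _check_integer_counts(counts) -> np.ndarray:
    arr = np.asarray(counts)
    if arr.ndim != 1:
        raise ValueError("expected a 1-D vector of counts for one sample")
    if not np.issubdtype(arr.dtype, np.integer):
        if not np.allclose(arr, np.round(arr)):
            raise ValueError("diversity estimators need integer counts")
        arr = np.round(arr).astype(np.int64)
    if (arr < 0).any():
        raise ValueError("counts must be non-negative")
    if arr.sum() == 0:
        raise ValueError("total count must be positive")
    return arr.astype(np.int64)


def np_shannon(counts) -> float:
    """Coverage-adjusted (Chao-Shen) nonparametric Shannon index.

    Sample coverage ``C = 1 - F1/n`` shrinks observed proportions, and each
    term is inflated by the inverse probability that the taxon appears in a
    sample of size ``n``.
    """
    arr = _check_integer_counts(counts)
    n = int(arr.sum())
    p = arr[arr > 0] / n
    f1 = int((arr == 1).sum())
    coverage = 1.0 - f1 / n
    if coverage <= 0.0:
        # degenerate all-singleton sample; fall back to minimal coverage
        coverage = 1.0 / n
    pa = coverage * p
    return float(-np.sum(pa * np.log(pa) / (1.0 - (1.0 - pa) ** n)))


def inv_simpson(counts) -> float:
    """Inverse Simpson concentration, ``1 / sum(p_i^2)``."""
    arr = _check_integer_counts(counts)
    p = arr[arr > 0] / arr.sum()
    return float(1.0 / np.sum(p**2))


def chao1(counts) -> float:
    """Chao1 richness: ``S_obs + F1^2 / (2 F2)``, or
    ``S_obs + F1 (F1 - 1) / 2`` when there are no doubletons."""
    arr = _check_integer_counts(counts)
    s_obs = int((arr > 0).sum())
    f1 = int((arr == 1).sum())
    f2 = int((arr == 2).sum())
    if f2 == 0:
        return float(s_obs + f1 * (f1 - 1) / 2.0)
    return float(s_obs + f1 * f1 / (2.0 * f2))


def alpha_diversity(counts) -> dict[str, float]:
    """All three alpha-diversity estimators for one sample's counts."""
    return {
        "np_shannon": np_shannon(counts),
        "inv_simpson": inv_simpson(counts),
        "chao1": chao1(counts),
    }


def diversity_frame(table: AbundanceTable) -> pd.DataFrame:
    """Per-sample alpha-diversity table with the sample metadata attached."""
    rows = []
    for sample in table.samples:
        rec = alpha_diversity(table.counts.loc[sample].to_numpy())
        rec["sample"] = sample
        rows.append(rec)
    frame = pd.DataFrame(rows).set_index("sample")
    return frame.join(table.metadata)


def _t_statistic(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = len(a), len(b)
    diff = a.mean() - b.mean()
    var = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    denom = np.sqrt(var * (1.0 / na + 1.0 / nb))
    if denom == 0.0:
        return float(np.inf) if diff != 0 else 0.0
    return float(diff / denom)


def permutation_t_test(
    values_a: Sequence[float],
    values_b: Sequence[float],
    n_perm: int = 9999,
    seed: int | np.random.Generator | None = None,
) -> float:
    """Two-sample permutation t-test p-value.

    ``p = (1 + #{permuted |t| >= observed |t|}) / (1 + n_perm)`` with the
    pooled-variance t statistic.  Constant pooled data make t undefined;
    that case returns 1.0 with a warning.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least two values")
    if n_perm < 99:
        raise ValueError("n_perm must be at least 99")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        warnings.warn("constant pooled data: t undefined, returning p = 1")
        return 1.0
    t_obs = abs(_t_statistic(a, b))
    rng = np.random.default_rng(seed)
    perms = rng.permuted(np.tile(pooled, (n_perm, 1)), axis=1)
    pa, pb = perms[:, : len(a)], perms[:, len(a):]
    na, nb = len(a), len(b)
    diff = pa.mean(axis=1) - pb.mean(axis=1)
    var = ((na - 1) * pa.var(axis=1, ddof=1) + (nb - 1) * pb.var(axis=1, ddof=1)) / (
        na + nb - 2
    )
    denom = np.sqrt(var * (1.0 / na + 1.0 / nb))
    with np.errstate(divide="ignore", invalid="ignore"):
        t_perm = np.abs(np.where(denom > 0, diff / denom, np.where(diff != 0, np.inf, 0.0)))
    count = int(np.sum(t_perm >= t_obs - 1e-12))
    return (1 + count) / (1 + n_perm)
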