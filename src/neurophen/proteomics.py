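"""Differential protein abundance and enrichment.

Per-protein differential abundance between two groups of log2 intensities is
assessed with a two-sided Welch's t-test (unequal variances, Welch-
Satterthwaite degrees of freedom) followed by Benjamini-Hochberg FDR control
at 5%. Significantly changed proteins feed two enrichment stages:

* hypergeometric over-representation of gene sets (GMT format) among the
  up- or down-regulated proteins, and
* a transparent upstream-regulator score: for each candidate regulator with
  a signed target list, a one-sided Fisher exact test of target overlap with
  the differential proteins (p < 0.05, linear fold change >= 1.5), plus an
  activation z-score
  ``z = (n_sign_consistent - n_sign_inconsistent) / sqrt(n_signed_overlap)``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger("neurophen.proteomics")


@dataclass
class AbundanceTable:
    """Proteins x samples log2 intensities with per-sample group labels.

    ``data`` is indexed by protein id with sample ids as columns; ``groups``
    maps sample id -> group label. Missing values are NaN; a protein is
    tested only when both compared groups have at least
    ``min_valid_per_group`` finite values.
    """

    data: pd.DataFrame
    groups: pd.Series
    min_valid_per_group: int = 3

    def __post_init__(self) -> None:
        self.groups = pd.Series(self.groups)
        missing = [s for s in self.data.columns if s not in self.groups.index]
        if missing:
            raise ValueError(f"samples without group labels: {missing}")
        counts = self.groups.loc[list(self.data.columns)].value_counts()
        small = counts[counts < 2]
        if len(small):
            raise ValueError(f"groups with < 2 samples: {dict(small)}")

    def group_columns(self, group: str) -> list[str]:
        cols = [s for s in self.data.columns if self.groups[s] == group]
        if not cols:
            raise ValueError(f"group {group!r} has no samples")
        return cols


def _welch_arrays(a: np.ndarray, b: np.ndarray):
    """Vectorised NaN-aware Welch t over rows of a (proteins x samples_A) and b."""
    import warnings

    na = np.sum(np.isfinite(a), axis=1).astype(float)
    nb = np.sum(np.isfinite(b), axis=1).astype(float)
    # rows failing the min-valid filter legitimately produce all-NaN slices
    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        ma = np.nanmean(a, axis=1)
        mb = np.nanmean(b, axis=1)
        va = np.nanvar(a, axis=1, ddof=1)
        vb = np.nanvar(b, axis=1, ddof=1)
    return na, nb, ma, mb, va, vb


def welch_de(
    table: AbundanceTable,
    group_a: str,
    group_b: str,
    alpha: float = 0.05,
    min_valid_per_group: int | None = None,
) -> pd.DataFrame:
    """Two-sided Welch differential abundance of group_b vs group_a with BH FDR.

    Returns one row per tested protein: ``log2fc`` (mean B - mean A),
    ``t_stat``, Satterthwaite ``df``, two-sided ``p``, BH ``q``,
    ``significant`` (q < alpha) and ``direction``. Proteins with fewer than
    ``min_valid_per_group`` finite values in either group are excluded and
    logged. A protein with zero variance in both groups gets t=0/p=1 when the
    means agree; with unequal means the p-value is set to the smallest
    positive normal float and the row is flagged ``degenerate``.
    """
    if min_valid_per_group is None:
        min_valid_per_group = table.min_valid_per_group
    a = table.data[table.group_columns(group_a)].to_numpy(dtype=float)
    b = table.data[table.group_columns(group_b)].to_numpy(dtype=float)
    na, nb, ma, mb, va, vb = _welch_arrays(a, b)
    tested = (na >= min_valid_per_group) & (nb >= min_valid_per_group)
    n_dropped = int((~tested).sum())
    if n_dropped:
        logger.warning(
            "%d protein(s) excluded: fewer than %d valid values in a group",
            n_dropped, min_valid_per_group,
        )

    na, nb = na[tested], nb[tested]
    ma, mb, va, vb = ma[tested], mb[tested], va[tested], vb[tested]
    ids = table.data.index[tested]

    se2 = va / na + vb / nb
    degenerate = se2 == 0
    log2fc = mb - ma
    t_stat = np.zeros_like(se2)
    df = np.full_like(se2, np.nan)
    p = np.ones_like(se2)

    ok = ~degenerate
    t_stat[ok] = log2fc[ok] / np.sqrt(se2[ok])
    df[ok] = se2[ok] ** 2 / (
        (va[ok] / na[ok]) ** 2 / (na[ok] - 1) + (vb[ok] / nb[ok]) ** 2 / (nb[ok] - 1)
    )
    p[ok] = 2.0 * stats.t.sf(np.abs(t_stat[ok]), df[ok])
    p[ok] = np.minimum(p[ok], 1.0)

    # zero variance in both groups: equal means -> t=0, p=1; unequal means ->
    # infinitely strong evidence at this resolution, flagged
    deg_unequal = degenerate & (log2fc != 0)
    if np.any(deg_unequal):
        p[deg_unequal] = np.finfo(float).tiny
        t_stat[deg_unequal] = np.sign(log2fc[deg_unequal]) * np.inf
        df[deg_unequal] = na[deg_unequal] + nb[deg_unequal] - 2
        logger.warning("%d protein(s) with zero variance and unequal means", int(deg_unequal.sum()))
    deg_equal = degenerate & (log2fc == 0)
    df[deg_equal] = na[deg_equal] + nb[deg_equal] - 2

    reject, q, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    out = pd.DataFrame(
        {
            "protein_id": ids,
            "mean_a": ma,
            "mean_b": mb,
            "log2fc": log2fc,
            "t_stat": t_stat,
            "df": df,
            "p": p,
            "q": q,
            "significant": reject,
            "direction": np.where(log2fc < 0, "down", "up"),
            "degenerate": degenerate,
        }
    ).set_index("protein_id")
    return out


@dataclass
class GeneSetCollection:
    """Named gene sets over a universe of identifiers (case-folded matching)."""

    sets: dict[str, frozenset[str]]
    universe: frozenset[str]

    def __post_init__(self) -> None:
        uni = frozenset(str(u).casefold() for u in self.universe)
        cleaned: dict[str, frozenset[str]] = {}
        for name, members in self.sets.items():
            mem = frozenset(str(m).casefold() for m in members) & uni
            if not mem:
                logger.warning("gene set %r empty after mapping to universe; dropped", name)
                continue
            cleaned[name] = mem
        self.sets = cleaned
        self.universe = uni

    @classmethod
    def from_gmt(cls, path, universe) -> "GeneSetCollection":
        sets: dict[str, list[str]] = {}
        with open(path) as fh:
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                if len(parts) < 3 or not parts[0]:
                    continue
                sets[parts[0]] = [m for m in parts[2:] if m]
        return cls(sets={k: frozenset(v) for k, v in sets.items()}, universe=frozenset(universe))


def enrich_sets(
    query_ids,
    collection: GeneSetCollection,
    min_overlap: int = 1,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Hypergeometric over-representation of each set in a query list.

    For a universe of size N, a set of size K and a query of size n with
    overlap k, the p-value is the upper tail P(X >= k) of
    Hypergeometric(N, K, n). Sets overlapping fewer than ``min_overlap``
    query members are omitted. Rows are BH-adjusted and sorted by p, ties by
    descending overlap then set name.
    """
    query = {str(q).casefold() for q in query_ids}
    if not query:
        raise ValueError("empty query: no significant proteins to enrich")
    unmapped = query - collection.universe
    if unmapped:
        logger.warning("%d query id(s) not in universe, dropped: %s",
                       len(unmapped), sorted(unmapped)[:10])
        query -= unmapped
    if not query:
        raise ValueError("no query ids map into the universe")
    N = len(collection.universe)
    n = len(query)
    rows = []
    for name, members in collection.sets.items():
        k = len(query & members)
        if k < min_overlap:
            continue
        K = len(members)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append({"set": name, "set_size": K, "overlap": k, "query_size": n, "p": min(p, 1.0)})
    out = pd.DataFrame(rows, columns=["set", "set_size", "overlap", "query_size", "p"])
    if len(out):
        _, q, _, _ = multipletests(out["p"].to_numpy(), alpha=alpha, method="fdr_bh")
        out["q"] = q
        out = out.sort_values(
            ["p", "overlap", "set"], ascending=[True, False, True]
        ).reset_index(drop=True)
    else:
        out["q"] = pd.Series(dtype=float)
    return out


@dataclass
class RegulatorNetwork:
    """Candidate upstream regulators with signed target lists.

    ``targets[regulator]`` is a list of (target id, expected sign) where the
    sign is +1 (regulator activation raises the target), -1 (lowers it) or 0
    (direction unknown).
    """

    targets: dict[str, list[tuple[str, int]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        cleaned = {}
        for reg, pairs in self.targets.items():
            pp = [(str(t).casefold(), int(s)) for t, s in pairs]
            if any(s not in (-1, 0, 1) for _, s in pp):
                raise ValueError(f"regulator {reg}: signs must be in {{-1, 0, +1}}")
            cleaned[reg] = pp
        self.targets = cleaned
        if not self.targets:
            raise ValueError("regulator network is empty")

    @classmethod
    def from_gmt(cls, path) -> "RegulatorNetwork":
        """Read a regulator GMT; member ids may end in '+'/'-' for the
        expected sign (no suffix means unknown direction)."""
        targets: dict[str, list[tuple[str, int]]] = {}
        with open(path) as fh:
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                if len(parts) < 3 or not parts[0]:
                    continue
                pairs = []
                for member in parts[2:]:
                    if not member:
                        continue
                    if member.endswith("+"):
                        pairs.append((member[:-1], 1))
                    elif member.endswith(("-", "−")):
                        pairs.append((member[:-1], -1))
                    else:
                        pairs.append((member, 0))
                targets[parts[0]] = pairs
        return cls(targets=targets)


def regulator_enrichment(
    de_table: pd.DataFrame,
    network: RegulatorNetwork,
    p_cut: float = 0.05,
    fc_cut: float = 1.5,
) -> pd.DataFrame:
    """Score candidate regulators against a differential-abundance result.

    The input set is every tested protein with p < ``p_cut`` and linear fold
    change of at least ``fc_cut`` in either direction (|log2fc| >= log2
    fc_cut). Per regulator: a one-sided Fisher exact p for target overlap
    with the input set, and the activation z-score over sign-annotated
    overlapping targets. A regulator with no overlapping targets is reported
    with p=1 and undefined (NaN) z. Rows sorted by overlap p.
    """
    universe = {str(i).casefold() for i in de_table.index}
    lfc = pd.Series(de_table["log2fc"].to_numpy(), index=[str(i).casefold() for i in de_table.index])
    sel = (de_table["p"].to_numpy() < p_cut) & (
        np.abs(de_table["log2fc"].to_numpy()) >= math.log2(fc_cut)
    )
    input_set = {str(i).casefold() for i in de_table.index[sel]}
    N = len(universe)
    n = len(input_set)
    rows = []
    for reg, pairs in network.targets.items():
        targ = {t for t, _ in pairs if t in universe}
        K = len(targ)
        k = len(targ & input_set)
        if k == 0:
            rows.append({"regulator": reg, "n_targets": K, "overlap": 0,
                         "p": 1.0, "z": float("nan"), "n_signed_overlap": 0})
            continue
        tbl = [[k, K - k], [n - k, N - K - (n - k)]]
        _, p = stats.fisher_exact(tbl, alternative="greater")
        n_cons = n_incons = 0
        for t, s in pairs:
            if s == 0 or t not in input_set:
                continue
            if s * np.sign(lfc[t]) > 0:
                n_cons += 1
            elif s * np.sign(lfc[t]) < 0:
                n_incons += 1
        n_signed = n_cons + n_incons
        z = (n_cons - n_incons) / math.sqrt(n_signed) if n_signed else float("nan")
        rows.append({"regulator": reg, "n_targets": K, "overlap": k,
                     "p": float(p), "z": z, "n_signed_overlap": n_signed})
    out = pd.DataFrame(rows).sort_values(["p", "regulator"]).reset_index(drop=True)
    return out
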