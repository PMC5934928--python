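"""Rank-invariant agreement measures for paired ordered categorical data.

Implements Svensson's approach for two ratings of the same subjects on an
ordinal scale (test-retest or before-after designs):

* **PA** — percentage agreement, the proportion of identical paired ratings
  (optionally within ``k`` scale steps).
* **RP** — relative position, ``P(Y > X) - P(Y < X)`` for independent draws
  ``X`` from the occasion-1 marginal and ``Y`` from the occasion-2 marginal;
  a systematic group-level shift, positive when the second occasion sits
  higher (better) on the scale.
* **RC** — relative concentration, a signed contrast of how central each
  occasion's ratings are relative to the other occasion's distribution;
  positive when the second occasion is more concentrated toward the middle
  of the scale.
* **RV** — relative rank variance, the count-weighted mean squared
  difference between each cell's augmented mean ranks for the two
  occasions; zero exactly for rank-transformable patterns (all observed
  change explainable by a common monotone shift) and larger when
  individuals depart from the common pattern.

All four measures depend on the data only through the square contingency
table of paired categories, and are invariant under strictly monotone
relabelling of the categories.  Standard errors are leave-one-pair-out
jackknife estimates with normal-approximation confidence intervals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np
from scipy.stats import norm, rankdata

__all__ = [
    "PairedOrdinalTable",
    "MarginalPair",
    "AugmentedRanks",
    "SvenssonResult",
    "AnalysisConfig",
    "build_paired_table",
    "marginal_distributions",
    "percentage_agreement",
    "relative_position",
    "relative_concentration",
    "augmented_mean_ranks",
    "relative_rank_variance",
    "jackknife_se",
    "confidence_interval",
    "roc_points",
    "svensson_analysis",
    "read_paired_csv",
    "result_to_dict",
]


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class PairedOrdinalTable:
    """Square count matrix of paired ordinal ratings.

    Rows index the occasion-1 (baseline) category, columns the occasion-2
    (retest / follow-up) category.  Categories are listed in increasing
    order and higher category means better health; reverse-scored items
    must be recoded before a table is built.
    """

    counts: np.ndarray
    categories: tuple

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 2 or counts.shape[0] != counts.shape[1]:
            raise ValueError("counts must be a square matrix")
        if np.any(counts < 0):
            raise ValueError("counts must be non-negative")
        if not np.all(np.equal(np.mod(counts, 1), 0)):
            raise ValueError("counts must be integers")
        counts = counts.astype(np.int64)
        cats = tuple(self.categories)
        if len(cats) != counts.shape[0]:
            raise ValueError(
                f"{len(cats)} categories for a {counts.shape[0]}x{counts.shape[1]} table"
            )
        if len(cats) < 2:
            raise ValueError("need at least two categories")
        if len(set(cats)) != len(cats):
            raise ValueError("category labels must be unique")
        try:
            if any(cats[i] >= cats[i + 1] for i in range(len(cats) - 1)):
                raise ValueError("category labels must be strictly increasing")
        except TypeError:
            pass  # labels not mutually comparable; uniqueness already checked
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "categories", cats)

    @property
    def n(self) -> int:
        """Total number of pairs."""
        return int(self.counts.sum())

    @property
    def n_categories(self) -> int:
        return len(self.categories)

    def transposed(self) -> "PairedOrdinalTable":
        """Swap the two occasions (RP and RC change sign; PA and RV do not)."""
        return PairedOrdinalTable(self.counts.T.copy(), self.categories)

    def relabelled(self, categories: Sequence) -> "PairedOrdinalTable":
        """Same counts under a strictly monotone relabelling of categories."""
        return PairedOrdinalTable(self.counts.copy(), tuple(categories))

    def _require_pairs(self, minimum: int = 1) -> None:
        if self.n < minimum:
            raise ValueError(f"operation requires at least {minimum} pair(s); table has {self.n}")


@dataclass(frozen=True)
class MarginalPair:
    """Marginal category distributions of the two occasions.

    ``F1``/``F2`` are cumulative distributions of length ``C + 1`` with
    ``F[0] = 0`` and ``F[C] = 1`` so that ``F[c]`` is the probability of a
    rating at or below category ``c`` (1-based).
    """

    p1: np.ndarray
    p2: np.ndarray
    F1: np.ndarray
    F2: np.ndarray


@dataclass(frozen=True)
class AugmentedRanks:
    """Cell-wise mean augmented ranks with respect to each occasion.

    ``rbar1[i, j]`` is the mean rank of the subjects in cell ``(i, j)`` when
    all subjects are ordered primarily by their occasion-1 category with
    ties broken by the occasion-2 category (mid-ranks within a cell);
    ``rbar2`` orders primarily by occasion 2.  Entries of empty cells are
    NaN.
    """

    rbar1: np.ndarray
    rbar2: np.ndarray


@dataclass(frozen=True)
class SvenssonResult:
    """PA, RP, RC and RV with jackknife SEs and normal CIs for one variable."""

    pa: float
    rp: float
    rc: float
    rv: float
    se_rp: float
    se_rc: float
    se_rv: float
    ci_rp: tuple[float, float]
    ci_rc: tuple[float, float]
    ci_rv: tuple[float, float]
    level: float
    significant_rp: bool
    significant_rc: bool
    significant_rv: bool
    n: int


@dataclass(frozen=True)
class AnalysisConfig:
    """Tunable constants of a Svensson analysis.

    ``rc_normalizer`` scales the raw concentration contrast so that RC
    reaches +/-1 in the maximally concentrated configuration (all
    second-occasion mass strictly between a half/half split of the
    first-occasion mass).  ``rv_warning_threshold`` flags heterogeneous
    individual change; ``min_n_warning`` flags samples below the size the
    method is considered robust for.
    """

    confidence_level: float = 0.95
    z_quantile: float | None = None  # derived from confidence_level when None
    rc_normalizer: float = 4.0
    pa_within_steps: int = 0
    rv_warning_threshold: float = 0.20
    min_n_warning: int = 12

    def __post_init__(self) -> None:
        if not 0.0 < self.confidence_level < 1.0:
            raise ValueError("confidence_level must be in (0, 1)")
        if self.rc_normalizer <= 0:
            raise ValueError("rc_normalizer must be positive")
        if self.pa_within_steps < 0 or int(self.pa_within_steps) != self.pa_within_steps:
            raise ValueError("pa_within_steps must be a non-negative integer")

    @property
    def z(self) -> float:
        if self.z_quantile is not None:
            return self.z_quantile
        return float(norm.ppf(0.5 + self.confidence_level / 2.0))


# ---------------------------------------------------------------------------
# construction


def build_paired_table(
    pairs: Iterable[tuple], categories: Sequence
) -> PairedOrdinalTable:
    """Tally (occasion-1, occasion-2) category pairs into a square table."""
    pairs = list(pairs)
    if not pairs:
        raise ValueError("no complete pairs")
    cats = list(categories)
    index = {c: k for k, c in enumerate(cats)}
    counts = np.zeros((len(cats), len(cats)), dtype=np.int64)
    for a, b in pairs:
        if a not in index:
            raise ValueError(f"occasion-1 value {a!r} is not among the categories")
        if b not in index:
            raise ValueError(f"occasion-2 value {b!r} is not among the categories")
        counts[index[a], index[b]] += 1
    return PairedOrdinalTable(counts, tuple(cats))


# ---------------------------------------------------------------------------
# internal kernels on raw count matrices (shared with the jackknife)


def _marginals(counts: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    n = counts.sum()
    p1 = counts.sum(axis=1) / n
    p2 = counts.sum(axis=0) / n
    F1 = np.concatenate(([0.0], np.cumsum(p1)))
    F2 = np.concatenate(([0.0], np.cumsum(p2)))
    F1[-1] = 1.0
    F2[-1] = 1.0
    return p1, p2, F1, F2


def _pa(counts: np.ndarray, within_steps: int = 0) -> float:
    n = counts.sum()
    C = counts.shape[0]
    i, j = np.indices(counts.shape)
    return float(counts[np.abs(i - j) <= within_steps].sum() / n)


def _rp(counts: np.ndarray) -> float:
    _, p2, F1, _ = _marginals(counts)
    C = counts.shape[0]
    j = np.arange(1, C + 1)
    return float(np.sum(p2 * F1[j - 1]) - np.sum(p2 * (1.0 - F1[j])))


def _rc(counts: np.ndarray, kappa: float = 4.0) -> float:
    p1, p2, F1, F2 = _marginals(counts)
    C = counts.shape[0]
    j = np.arange(1, C + 1)
    c21 = np.sum(p2 * F1[j - 1] * (1.0 - F1[j]))
    c12 = np.sum(p1 * F2[j - 1] * (1.0 - F2[j]))
    return float(kappa * (c21 - c12))


def _aug_ranks(counts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    row = counts.sum(axis=1)
    col = counts.sum(axis=0)
    rows_before = np.concatenate(([0], np.cumsum(row)[:-1]))[:, None]
    cols_before = np.concatenate(([0], np.cumsum(col)[:-1]))[None, :]
    in_row_before = np.cumsum(counts, axis=1) - counts
    in_col_before = np.cumsum(counts, axis=0) - counts
    mid = (counts + 1) / 2.0
    rbar1 = rows_before + in_row_before + mid
    rbar2 = cols_before + in_col_before + mid
    return rbar1, rbar2


def _rv(counts: np.ndarray) -> float:
    n = counts.sum()
    rbar1, rbar2 = _aug_ranks(counts)
    d2 = np.where(counts > 0, (rbar1 - rbar2) ** 2, 0.0)
    return float(6.0 / n**3 * np.sum(counts * d2))


_STATISTICS: dict[str, Callable[[np.ndarray], float]] = {
    "PA": _pa,
    "RP": _rp,
    "RC": _rc,
    "RV": _rv,
}


# ---------------------------------------------------------------------------
# public operations


def marginal_distributions(table: PairedOrdinalTable) -> MarginalPair:
    """Row/column relative frequencies and their cumulative distributions."""
    table._require_pairs()
    p1, p2, F1, F2 = _marginals(table.counts)
    return MarginalPair(p1=p1, p2=p2, F1=F1, F2=F2)


def percentage_agreement(table: PairedOrdinalTable, within_steps: int = 0) -> float:
    """Proportion of pairs rated identically (or within ``within_steps``).

    With ``within_steps=0`` this is the diagonal proportion — the fraction
    of subjects giving the same answer at both occasions.
    """
    table._require_pairs()
    if within_steps < 0 or int(within_steps) != within_steps:
        raise ValueError("within_steps must be a non-negative integer")
    if within_steps >= table.n_categories:
        warnings.warn(
            f"within_steps={within_steps} spans the whole {table.n_categories}-category "
            "scale; agreement is trivially 1",
            stacklevel=2,
        )
    return _pa(table.counts, int(within_steps))


def relative_position(table: PairedOrdinalTable) -> float:
    """Systematic shift: P(occasion-2 higher) - P(occasion-2 lower).

    Computed from the two marginal distributions only; positive values mean
    the group moved toward higher (better) categories at the second
    occasion.
    """
    table._require_pairs()
    return _rp(table.counts)


def relative_concentration(table: PairedOrdinalTable, kappa: float = 4.0) -> float:
    """Signed shift in concentration toward the centre of the scale.

    The contrast compares the probability that an occasion-2 draw lies
    strictly between two independent occasion-1 draws with the symmetric
    probability, scaled by ``kappa`` (default 4, attaining +/-1 for the
    maximally concentrated configurations).  Positive values mean the
    second occasion's answers sit more centrally.
    """
    table._require_pairs()
    if kappa <= 0:
        raise ValueError("kappa must be positive")
    return _rc(table.counts, kappa)


def augmented_mean_ranks(table: PairedOrdinalTable) -> AugmentedRanks:
    """Mean augmented (tie-adjusted) ranks of each cell for both occasions."""
    table._require_pairs()
    rbar1, rbar2 = _aug_ranks(table.counts)
    empty = table.counts == 0
    rbar1 = np.where(empty, np.nan, rbar1)
    rbar2 = np.where(empty, np.nan, rbar2)
    return AugmentedRanks(rbar1=rbar1, rbar2=rbar2)


def relative_rank_variance(
    table: PairedOrdinalTable, warn_threshold: float | None = 0.20
) -> float:
    """Individual dispersion from the group's common pattern of change.

    ``RV = (6 / n^3) * sum_ij counts_ij * (rbar1_ij - rbar2_ij)^2`` — zero
    exactly when every non-empty cell has equal mean ranks for the two
    occasions (a rank-transformable pattern), growing as individuals cross
    each other in rank between occasions.  Values above ``warn_threshold``
    (0.20 by convention) flag heterogeneous individual change and emit a
    warning; so do values above 1, which are possible only for extreme
    reversal patterns.
    """
    table._require_pairs()
    rv = _rv(table.counts)
    if warn_threshold is not None and rv > warn_threshold:
        warnings.warn(
            f"RV = {rv:.3f} exceeds {warn_threshold:g}: indication of individual "
            "departures from a common pattern of change",
            stacklevel=2,
        )
    if rv > 1.0:
        warnings.warn(
            f"RV = {rv:.3f} exceeds 1: extreme reversal pattern", stacklevel=2
        )
    return rv


def jackknife_se(
    table: PairedOrdinalTable, statistic: str, **kwargs
) -> float:
    """Leave-one-pair-out jackknife standard error of PA, RP, RC or RV.

    For each observed pair the statistic is recomputed on the table with
    that pair removed; the SE is ``sqrt((n-1)/n * sum_i (theta_(-i) -
    mean)^2)`` over all ``n`` leave-one-out values (grouped by cell, since
    pairs in the same cell give identical leave-one-out tables).
    """
    if statistic not in _STATISTICS:
        raise ValueError(f"unknown statistic {statistic!r}; choose from {sorted(_STATISTICS)}")
    n = table.n
    if n < 2:
        raise ValueError("SE undefined for fewer than 2 pairs")
    fn = _STATISTICS[statistic]
    counts = table.counts
    thetas = []
    weights = []
    for i, j in zip(*np.nonzero(counts)):
        loo = counts.copy()
        loo[i, j] -= 1
        thetas.append(fn(loo, **kwargs) if kwargs else fn(loo))
        weights.append(counts[i, j])
    thetas = np.asarray(thetas, dtype=float)
    weights = np.asarray(weights, dtype=float)
    mean = np.average(thetas, weights=weights)
    var = (n - 1) / n * np.sum(weights * (thetas - mean) ** 2)
    return float(np.sqrt(max(var, 0.0)))


def confidence_interval(
    estimate: float, se: float, level: float = 0.95
) -> tuple[float, float]:
    """Normal-approximation interval ``estimate +/- z(level) * se``."""
    if not 0.0 < level < 1.0:
        raise ValueError("confidence level must be in (0, 1)")
    if se < 0:
        raise ValueError("standard error must be non-negative")
    z = float(norm.ppf(0.5 + level / 2.0))
    return (estimate - z * se, estimate + z * se)


def _significant(ci: tuple[float, float]) -> bool:
    """Zero outside the interval <=> significant change."""
    low, high = ci
    return bool(low > 0.0 or high < 0.0)


def roc_points(table: PairedOrdinalTable) -> np.ndarray:
    """Cumulative-marginal ROC curve: points ``(F1(c), F2(c))``, c = 0..C.

    Identical marginals put every point on the identity diagonal; a
    systematic shift bows the curve away from it.
    """
    table._require_pairs()
    _, _, F1, F2 = _marginals(table.counts)
    return np.column_stack([F1, F2])


def svensson_analysis(
    table: PairedOrdinalTable, config: AnalysisConfig | None = None
) -> SvenssonResult:
    """Full analysis of one paired ordinal variable.

    Composes PA, RP, RC and RV with jackknife SEs, normal CIs at the
    configured level, and significance flags (zero outside the CI).
    """
    if config is None:
        config = AnalysisConfig()
    if table.n < 2:
        raise ValueError("analysis requires at least 2 pairs")
    if table.n < config.min_n_warning:
        warnings.warn(
            f"only {table.n} pairs; the method is considered robust down to "
            f"roughly {config.min_n_warning} subjects",
            stacklevel=2,
        )
    pa = percentage_agreement(table, config.pa_within_steps)
    rp = relative_position(table)
    rc = relative_concentration(table, config.rc_normalizer)
    rv = relative_rank_variance(table, config.rv_warning_threshold)
    se_rp = jackknife_se(table, "RP")
    se_rc = jackknife_se(table, "RC", kappa=config.rc_normalizer)
    se_rv = jackknife_se(table, "RV")
    z = config.z
    ci_rp = (rp - z * se_rp, rp + z * se_rp)
    ci_rc = (rc - z * se_rc, rc + z * se_rc)
    ci_rv = (rv - z * se_rv, rv + z * se_rv)
    return SvenssonResult(
        pa=pa,
        rp=rp,
        rc=rc,
        rv=rv,
        se_rp=se_rp,
        se_rc=se_rc,
        se_rv=se_rv,
        ci_rp=ci_rp,
        ci_rc=ci_rc,
        ci_rv=ci_rv,
        level=config.confidence_level,
        significant_rp=_significant(ci_rp),
        significant_rc=_significant(ci_rc),
        significant_rv=_significant(ci_rv),
        n=table.n,
    )


def read_paired_csv(path, categories: Sequence | None = None) -> PairedOrdinalTable:
    """Build a table from a two-column CSV of (occasion-1, occasion-2) ratings.

    Rows with a missing value are dropped (complete-case).  When
    ``categories`` is omitted the pooled sorted unique values are used.
    """
    import pandas as pd

    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValueError("paired CSV needs two columns (occasion1, occasion2)")
    df = df.iloc[:, :2].dropna()
    pairs = list(df.itertuples(index=False, name=None))
    if categories is None:
        categories = sorted({v for pair in pairs for v in pair})
    return build_paired_table(pairs, categories)


def result_to_dict(result: SvenssonResult) -> dict:
    """Flatten a result for JSON/CSV serialization."""
    return {
        "n": result.n,
        "PA": result.pa,
        "RP": result.rp,
        "RP_SE": result.se_rp,
        "RP_CI_low": result.ci_rp[0],
        "RP_CI_high": result.ci_rp[1],
        "RP_significant": result.significant_rp,
        "RC": result.rc,
        "RC_SE": result.se_rc,
        "RC_CI_low": result.ci_rc[0],
        "RC_CI_high": result.ci_rc[1],
        "RC_significant": result.significant_rc,
        "RV": result.rv,
        "RV_SE": result.se_rv,
        "RV_CI_low": result.ci_rv[0],
        "RV_CI_high": result.ci_rv[1],
        "RV_significant": result.significant_rv,
        "level": result.level,
    }


# ---------------------------------------------------------------------------
# independent-check helpers used by the test-suite oracles


def expanded_rank_vectors(table: PairedOrdinalTable) -> tuple[np.ndarray, np.ndarray]:
    """Per-subject augmented ranks via explicit expansion to individuals.

    Expands the table to one row per subject and ranks with mid-ranks over
    the lexicographic keys (occasion-1, occasion-2) and (occasion-2,
    occasion-1).  Used as an independent cross-check of
    :func:`augmented_mean_ranks`; not on the analysis path.
    """
    C = table.n_categories
    i, j = np.nonzero(table.counts)
    reps = table.counts[i, j]
    a = np.repeat(i, reps)
    b = np.repeat(j, reps)
    r1 = rankdata(a * (C + 1) + b, method="average")
    r2 = rankdata(b * (C + 1) + a, method="average")
    return r1, r2
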