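"""End-to-end study pipeline for a two-occasion RAND-36 validation design.

Reproduces the analysis products of a paired-ordinal validation study from
a wide cohort CSV: eligibility filtering on the test-retest (or follow-up)
window, subscale scoring, the Health-change cross-tabulation with its
same/improved/worsened triangle summary, per-subscale Svensson tables with
jackknife SEs and CIs, per-subscale ordinal alpha, and cumulative-marginal
ROC point exports.

Two modes differ only in their default eligibility window and hypothesis
label: ``reliability`` (retest within 7-17 days, expecting no change) and
``responsiveness`` (follow-up within 50-70 days, expecting improvement).
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
import platform
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .polychoric import ordinal_alpha
from .scoring import (
    SUBSCALES,
    Rand36Record,
    health_change_category,
    records_from_frame,
    score_all,
)
from .svensson import (
    AnalysisConfig,
    PairedOrdinalTable,
    SvenssonResult,
    build_paired_table,
    roc_points,
    svensson_analysis,
)

__all__ = [
    "StudyConfig",
    "DEFAULT_WINDOWS",
    "pair_scored_records",
    "filter_by_window",
    "health_change_crosstab",
    "scores_to_paired_table",
    "svensson_table",
    "run_study",
]

logger = logging.getLogger("rand36val")

DEFAULT_WINDOWS = {"reliability": (7, 17), "responsiveness": (50, 70)}


@dataclass(frozen=True)
class StudyConfig:
    """Configuration of one full study run."""

    mode: str
    input_csv: str | Path
    out_dir: str | Path
    window_days: tuple[int, int] | None = None
    aggregator: str = "mean"
    missing_policy: str = "complete_only"
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    alpha_occasions: tuple[str, ...] = ("baseline",)
    occasions: tuple[str, str] = ("baseline", "followup")
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.mode not in DEFAULT_WINDOWS:
            raise ValueError(f"mode must be one of {sorted(DEFAULT_WINDOWS)}")
        if self.window_days is not None and self.window_days[0] > self.window_days[1]:
            raise ValueError("window must satisfy min <= max")

    @property
    def window(self) -> tuple[int, int]:
        return self.window_days or DEFAULT_WINDOWS[self.mode]


def round_percent(x: float) -> int:
    """Nearest-integer percent, rounding halves away from zero."""
    return int(math.floor(abs(x) + 0.5)) * (1 if x >= 0 else -1)


# ---------------------------------------------------------------------------
# pairing, scoring and eligibility


def score_records(
    records: list[Rand36Record],
    aggregator: str = "mean",
    missing_policy: str = "complete_only",
) -> pd.DataFrame:
    """One row per record: keys, eight subscale scores and health_change."""
    rows = []
    for rec in records:
        scored = score_all(rec, aggregator, missing_policy)
        row = {
            "patient_id": rec.patient_id,
            "group": rec.group,
            "occasion": rec.occasion,
            "date": rec.date,
        }
        row.update({name: scored.scores[name] for name in SUBSCALES})
        row["health_change"] = scored.health_change
        rows.append(row)
    return pd.DataFrame(rows)


def pair_scored_records(
    scored: pd.DataFrame, occasions: tuple[str, str] = ("baseline", "followup")
) -> pd.DataFrame:
    """Merge the two occasions into one row per patient (suffix _1 / _2).

    Patients lacking either occasion are dropped with a warning; duplicate
    patient-occasion rows are an error.
    """
    first, second = occasions
    missing = set(scored["occasion"]) - set(occasions)
    if missing:
        raise ValueError(f"unexpected occasion labels: {sorted(missing)}")
    if scored.duplicated(["patient_id", "occasion"]).any():
        raise ValueError("duplicate patient-occasion rows")
    wide1 = scored[scored["occasion"] == first].set_index("patient_id")
    wide2 = scored[scored["occasion"] == second].set_index("patient_id")
    unpaired = set(wide1.index) ^ set(wide2.index)
    if unpaired:
        warnings.warn(
            f"excluding {len(unpaired)} unpaired patient(s)", stacklevel=2
        )
    paired = wide1.join(wide2, how="inner", lsuffix="_1", rsuffix="_2")
    return paired.reset_index()


def filter_by_window(
    paired: pd.DataFrame, window: tuple[int, int]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Keep pairs whose occasion day difference lies within the window.

    Returns (eligible pairs, exclusion log).  Bounds are inclusive; a
    negative day difference means the occasions are mislabelled and raises.
    """
    lo, hi = window
    days = paired.apply(
        lambda row: (row["date_2"] - row["date_1"]).days, axis=1
    ).astype(int) if len(paired) else pd.Series([], dtype=int)
    if (days < 0).any():
        bad = paired.loc[days < 0, "patient_id"].tolist()
        raise ValueError(f"negative day difference (occasions mislabelled?): {bad}")
    ok = (days >= lo) & (days <= hi)
    exclusions = pd.DataFrame(
        {
            "patient_id": paired.loc[~ok, "patient_id"],
            "days": days[~ok],
            "reason": f"outside {lo}-{hi} day window",
        }
    )
    for _, row in exclusions.iterrows():
        logger.info(
            "excluded %s: %d days outside window", row["patient_id"], row["days"]
        )
    return paired[ok].reset_index(drop=True), exclusions.reset_index(drop=True)


# ---------------------------------------------------------------------------
# analysis tables


def health_change_crosstab(
    paired: pd.DataFrame,
) -> tuple[PairedOrdinalTable, dict]:
    """Health-change cross-table (higher = better) plus triangle summary.

    Only complete pairs (item answered at both occasions) contribute.  The
    summary gives counts and whole-number percents of patients answering
    the same (diagonal), better at the second occasion (improved) and worse
    (worsened).
    """
    ok = paired["health_change_1"].notna() & paired["health_change_2"].notna()
    pairs = list(
        zip(
            paired.loc[ok, "health_change_1"].astype(int),
            paired.loc[ok, "health_change_2"].astype(int),
        )
    )
    if not pairs:
        raise ValueError("no complete health-change pairs")
    table = build_paired_table(pairs, categories=(1, 2, 3, 4, 5))
    n = table.n
    same = int(np.trace(table.counts))
    improved = int(np.triu(table.counts, k=1).sum())  # second occasion higher
    worsened = int(np.tril(table.counts, k=-1).sum())
    summary = {
        "n": n,
        "same": same,
        "improved": improved,
        "worsened": worsened,
        "same_percent": round_percent(100.0 * same / n),
        "improved_percent": round_percent(100.0 * improved / n),
        "worsened_percent": round_percent(100.0 * worsened / n),
    }
    return table, summary


def scores_to_paired_table(pairs) -> PairedOrdinalTable:
    """Paired table over the pooled sorted unique score values.

    Rank-invariance of the Svensson measures makes the fine score grid
    harmless: only the ordering of the observed values matters.
    """
    pairs = [(a, b) for a, b in pairs]
    if not pairs:
        raise ValueError("no complete pairs")
    categories = sorted({v for pair in pairs for v in pair})
    if len(categories) < 2:
        # a degenerate single-valued variable still needs a 2-category frame
        categories = categories + [categories[0] + 1]
    return build_paired_table(pairs, categories)


def svensson_table(
    paired: pd.DataFrame, config: AnalysisConfig | None = None
) -> tuple[pd.DataFrame, dict[str, PairedOrdinalTable]]:
    """Per-subscale Svensson analysis of paired subscale scores.

    Returns the results table (one row per subscale, layout mirroring a
    test-retest/responsiveness report) and the underlying paired tables for
    ROC export.
    """
    rows = []
    tables: dict[str, PairedOrdinalTable] = {}
    for name in SUBSCALES:
        sub = paired[[f"{name}_1", f"{name}_2"]].dropna()
        if len(sub) < 2:
            logger.warning("subscale %s: fewer than 2 complete pairs; skipped", name)
            continue
        table = scores_to_paired_table(
            zip(sub[f"{name}_1"], sub[f"{name}_2"])
        )
        res = svensson_analysis(table, config)
        tables[name] = table
        rows.append(_result_row(name, res))
    return pd.DataFrame(rows), tables


def _result_row(name: str, res: SvenssonResult) -> dict:
    from .svensson import result_to_dict

    row = {"subscale": name, **result_to_dict(res)}
    row["PA_percent"] = round_percent(100.0 * res.pa)
    return row


def subscale_means(
    scored: pd.DataFrame, level: float = 0.95
) -> pd.DataFrame:
    """Mean subscale score with a normal CI, per occasion."""
    from scipy.stats import norm

    z = float(norm.ppf(0.5 + level / 2.0))
    rows = []
    for occasion, chunk in scored.groupby("occasion", sort=False):
        for name in SUBSCALES:
            vals = chunk[name].dropna().to_numpy(dtype=float)
            if len(vals) == 0:
                continue
            m = vals.mean()
            half = z * vals.std(ddof=1) / np.sqrt(len(vals)) if len(vals) > 1 else 0.0
            rows.append(
                {
                    "occasion": occasion,
                    "subscale": name,
                    "n": len(vals),
                    "mean": m,
                    "ci_low": m - half,
                    "ci_high": m + half,
                }
            )
    return pd.DataFrame(rows)


def alpha_table(
    records: list[Rand36Record], occasions: tuple[str, ...] = ("baseline",)
) -> pd.DataFrame:
    """Per-subscale ordinal alpha from item-level responses.

    Uses the requested occasions' records (baseline only by default;
    pass both occasions to pool).  Complete-case per subscale.  Estimation
    failures are recorded as NaN with the error message.
    """
    from .scoring import recode_item

    use = [r for r in records if r.occasion in occasions]
    rows = []
    for name, items in SUBSCALES.items():
        # recoded (higher-is-better) values: reverse-scored raw items would
        # otherwise flip the sign of their inter-item correlations
        data = pd.DataFrame(
            {
                f"q{item}": [
                    None if r.response(item) is None else recode_item(item, r.response(item))
                    for r in use
                ]
                for item in items
            },
            dtype="float",
        )
        try:
            res = ordinal_alpha(data)
            rows.append(
                {
                    "subscale": name,
                    "k": res.k,
                    "n_complete": res.n_complete,
                    "alpha": res.alpha,
                    "mean_interitem_rho": res.mean_offdiag,
                    "note": "",
                }
            )
        except Exception as exc:  # noqa: BLE001 - failures reported in the table
            logger.warning("alpha failed for %s: %s", name, exc)
            rows.append(
                {
                    "subscale": name,
                    "k": len(items),
                    "n_complete": int(data.dropna().shape[0]),
                    "alpha": float("nan"),
                    "mean_interitem_rho": float("nan"),
                    "note": str(exc),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# full run


def _config_digest(config: StudyConfig) -> str:
    payload = json.dumps(asdict(config), default=str, sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_study(config: StudyConfig) -> dict:
    """Run the whole analysis and write its report bundle to ``out_dir``.

    Products: completeness table, per-occasion subscale means with CIs,
    ordinal-alpha table, Health-change cross-tab + Svensson result,
    per-subscale Svensson table, ROC point CSVs, exclusion log and a run
    manifest (seed, config hash, package versions).  Returns the bundle as
    a dict of in-memory objects and written paths.
    """
    from .scoring import completeness_summary

    out = Path(config.out_dir)
    logging.basicConfig(level=config.log_level)

    df = pd.read_csv(config.input_csv, dtype={"patient_id": str})
    if df.empty:
        raise ValueError(f"input file {config.input_csv} contains no records")
    records = records_from_frame(df)

    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setLevel(config.log_level)
    logger.addHandler(handler)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # summaries below report the same facts
            completeness = completeness_summary(records)
            scored = score_records(records, config.aggregator, config.missing_policy)
            means = subscale_means(scored, config.analysis.confidence_level)
            alphas = alpha_table(records, config.alpha_occasions)
            paired = pair_scored_records(scored, config.occasions)
            eligible, exclusions = filter_by_window(paired, config.window)
            if eligible.empty:
                raise ValueError("no eligible pairs after window filtering")
            hc_table, hc_summary = health_change_crosstab(eligible)
            hc_result = svensson_analysis(hc_table, config.analysis)
            sv_table, tables = svensson_table(eligible, config.analysis)

        completeness.to_csv(out / "completeness.csv", index=False)
        means.to_csv(out / "subscale_means.csv", index=False)
        alphas.to_csv(out / "alpha.csv", index=False)
        exclusions.to_csv(out / "exclusions.csv", index=False)
        sv_table.to_csv(out / "svensson_subscales.csv", index=False)
        pd.DataFrame(
            hc_table.counts,
            index=[f"baseline_{c}" for c in hc_table.categories],
            columns=[f"followup_{c}" for c in hc_table.categories],
        ).to_csv(out / "health_change_crosstab.csv")
        with open(out / "health_change_svensson.json", "w") as fh:
            json.dump(
                {"summary": hc_summary, "svensson": _result_row("Health change", hc_result)},
                fh,
                indent=2,
            )
        roc_dir = out / "roc"
        roc_dir.mkdir(exist_ok=True)
        roc_paths = {}
        all_tables = {"Health change": hc_table, **tables}
        for name, table in all_tables.items():
            pts = roc_points(table)
            slug = name.lower().replace(" ", "_").replace("/", "_")
            path = roc_dir / f"{slug}.csv"
            pd.DataFrame(
                {
                    "category": ["origin", *table.categories],
                    "cum1": pts[:, 0],
                    "cum2": pts[:, 1],
                }
            ).to_csv(path, index=False)
            roc_paths[name] = path

        manifest = {
            "mode": config.mode,
            "window_days": list(config.window),
            "aggregator": config.aggregator,
            "missing_policy": config.missing_policy,
            "seed": config.seed,
            "config_hash": _config_digest(config),
            "n_input_pairs": int(len(paired)),
            "n_eligible": int(len(eligible)),
            "n_excluded": int(len(exclusions)),
            "versions": {
                "rand36val": __version__,
                "python": platform.python_version(),
                "numpy": np.__version__,
                "pandas": pd.__version__,
            },
        }
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)
    finally:
        logger.removeHandler(handler)
        handler.close()

    return {
        "completeness": completeness,
        "subscale_means": means,
        "alpha": alphas,
        "paired": paired,
        "eligible": eligible,
        "exclusions": exclusions,
        "health_change_table": hc_table,
        "health_change_summary": hc_summary,
        "health_change_result": hc_result,
        "svensson_table": sv_table,
        "tables": all_tables,
        "roc_paths": roc_paths,
        "manifest": manifest,
        "out_dir": out,
    }
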