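"""Synthetic two-occasion RAND-36 cohorts from a latent-trait model.

The generator emulates the two designs a paired-ordinal validation study
needs: a *reliability* cohort that is clinically stable between test and
retest (no latent shift) and a *responsiveness* cohort that improves
between baseline and follow-up (positive latent shift at the second
occasion).

Model, per subscale (plus the stand-alone Health-change item):

* subject trait ``theta ~ N(0, 1)``;
* occasion factor ``f_t = sqrt(r) * theta + sqrt(1 - r) * eps_t + delta * 1(t=2)``
  so the two occasions' factors correlate ``r`` and occasion 2 is shifted by
  ``delta`` latent standard deviations;
* item latent ``z_it = lambda * f_t + sqrt(1 - lambda^2) * e_it``;
* the observed category is ``z_it`` cut at the item's thresholds, then
  mapped onto the item's native raw scale (reversing where the RAND raw
  scale runs best-to-worst).

Item-level missingness is MCAR at a configurable rate; completion dates are
a fixed baseline date plus a uniform integer day offset for the second
occasion, with an optional out-of-window contaminated tail to exercise
eligibility filtering.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import date, timedelta
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .scoring import (
    HEALTH_CHANGE_ITEM,
    ITEM_CHOICES,
    ITEM_REVERSED,
    RECODE_TABLE,
    SUBSCALES,
)

__all__ = [
    "LatentCohortConfig",
    "generate_paired_item",
    "generate_rand36_cohort",
    "reliability_scenario",
    "responsiveness_scenario",
    "config_from_file",
]


@dataclass(frozen=True)
class LatentCohortConfig:
    """All parameters of the synthetic two-occasion cohort generator.

    ``retest_r`` is the test-retest correlation of each subscale factor;
    ``shift`` the latent improvement at the second occasion (0 for a stable
    reliability design); ``loading`` the common item loading on its
    subscale factor.  ``date_offset_days`` bounds the uniform integer day
    offset of the second occasion; ``n_out_of_window`` extra subjects get
    offsets from ``out_of_window_offset_days`` instead, to exercise the
    eligibility filter.  ``thresholds`` optionally overrides the
    equiprobable per-item cut points (on the higher-is-better latent
    scale).  The seed is mandatory: a config fully determines its cohort.
    """

    n_subjects: int
    seed: int
    group: str = "reliability"
    loading: float = 0.8
    retest_r: float = 0.85
    shift: float = 0.0
    thresholds: Mapping[int, tuple] | None = None
    missing_rate: float = 0.0075
    date_offset_days: tuple[int, int] = (7, 17)
    n_out_of_window: int = 0
    out_of_window_offset_days: tuple[int, int] = (18, 60)
    baseline_date: date = date(2017, 3, 1)
    occasions: tuple[str, str] = ("baseline", "followup")

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be positive")
        if not 0.0 <= self.loading <= 1.0:
            raise ValueError("loading must be in [0, 1]")
        if not 0.0 <= self.retest_r <= 1.0:
            raise ValueError("retest_r must be in [0, 1]")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")
        for lo, hi in (self.date_offset_days, self.out_of_window_offset_days):
            if lo > hi:
                raise ValueError("day-offset bounds must satisfy min <= max")
        if self.thresholds is not None:
            for item, tau in self.thresholds.items():
                _check_thresholds(item, np.asarray(tau, dtype=float))


def _check_thresholds(item: int, tau: np.ndarray) -> None:
    if item not in ITEM_CHOICES:
        raise ValueError(f"unknown item number {item}")
    if len(tau) != ITEM_CHOICES[item] - 1:
        raise ValueError(
            f"item {item} has {ITEM_CHOICES[item]} choices and needs "
            f"{ITEM_CHOICES[item] - 1} thresholds, got {len(tau)}"
        )
    if np.any(np.diff(tau) <= 0):
        raise ValueError(f"item {item}: thresholds must be strictly increasing")


def _equiprobable_thresholds(n_categories: int) -> np.ndarray:
    from scipy.stats import norm

    return norm.ppf(np.arange(1, n_categories) / n_categories)


def generate_paired_item(
    n: int,
    thresholds,
    r: float,
    delta: float,
    seed: int | np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Paired categories (1-based) for one item under the latent model.

    ``z_t = sqrt(r) * theta + sqrt(1 - r) * eps_t + delta * 1(t=2)``, cut at
    ``thresholds``.  Deterministic given the seed.
    """
    tau = np.asarray(thresholds, dtype=float)
    if tau.ndim != 1 or (len(tau) > 1 and np.any(np.diff(tau) <= 0)):
        raise ValueError("thresholds must be a strictly increasing vector")
    if not 0.0 <= r <= 1.0:
        raise ValueError("r must be in [0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    theta = rng.standard_normal(n)
    z1 = np.sqrt(r) * theta + np.sqrt(1.0 - r) * rng.standard_normal(n)
    z2 = np.sqrt(r) * theta + np.sqrt(1.0 - r) * rng.standard_normal(n) + delta
    return np.searchsorted(tau, z1) + 1, np.searchsorted(tau, z2) + 1


def _goodness_to_raw(item: int, goodness: np.ndarray) -> np.ndarray:
    """Map a higher-is-better category to the item's native raw coding."""
    if ITEM_REVERSED[item]:
        return ITEM_CHOICES[item] + 1 - goodness
    return goodness


def generate_rand36_cohort(config: LatentCohortConfig) -> pd.DataFrame:
    """Wide two-occasion cohort table: one row per patient per occasion.

    Columns: patient_id, group, occasion, date, q1..q36 (raw responses on
    each item's native scale, blank = missing).  Byte-identical output for
    identical config (including seed).
    """
    rng = np.random.default_rng(config.seed)
    n_total = config.n_subjects + config.n_out_of_window
    r, lam, delta = config.retest_r, config.loading, config.shift
    item_groups = dict(SUBSCALES)
    item_groups["Health change"] = (HEALTH_CHANGE_ITEM,)

    # goodness-scale categories per item and occasion
    goodness: dict[tuple[int, int], np.ndarray] = {}
    for name in sorted(item_groups):
        items = item_groups[name]
        # a single-item group IS its construct: no loading dilution
        lam_g = 1.0 if len(items) == 1 else lam
        theta = rng.standard_normal(n_total)
        for t in (0, 1):
            eps = rng.standard_normal(n_total)
            f = np.sqrt(r) * theta + np.sqrt(1.0 - r) * eps + delta * t
            for item in items:
                e = rng.standard_normal(n_total)
                z = lam_g * f + np.sqrt(1.0 - lam_g**2) * e
                tau = (
                    np.asarray(config.thresholds[item], dtype=float)
                    if config.thresholds and item in config.thresholds
                    else _equiprobable_thresholds(ITEM_CHOICES[item])
                )
                goodness[(item, t)] = np.searchsorted(tau, z) + 1

    # MCAR missingness per item-occasion cell
    missing = {
        key: rng.random(n_total) < config.missing_rate for key in sorted(goodness)
    }

    # follow-up day offsets: in-window for the main cohort, contaminated tail
    lo, hi = config.date_offset_days
    offsets = rng.integers(lo, hi + 1, size=n_total)
    if config.n_out_of_window:
        olo, ohi = config.out_of_window_offset_days
        offsets[config.n_subjects:] = rng.integers(
            olo, ohi + 1, size=config.n_out_of_window
        )

    width = len(str(n_total))
    rows = []
    for s in range(n_total):
        pid = f"P{s + 1:0{width}d}"
        for t, occasion in enumerate(config.occasions):
            when = config.baseline_date + timedelta(days=int(offsets[s]) * t)
            row: dict[str, object] = {
                "patient_id": pid,
                "group": config.group,
                "occasion": occasion,
                "date": when.isoformat(),
            }
            for item in sorted(ITEM_CHOICES):
                if missing[(item, t)][s]:
                    row[f"q{item}"] = np.nan
                else:
                    row[f"q{item}"] = int(
                        _goodness_to_raw(item, goodness[(item, t)][s])
                    )
            rows.append(row)
    return pd.DataFrame(rows)


def reliability_scenario(seed: int = 0, **overrides) -> LatentCohortConfig:
    """Stable test-retest design: 84 subjects, retest 7-17 days, no shift."""
    cfg = LatentCohortConfig(
        n_subjects=84,
        seed=seed,
        group="reliability",
        retest_r=0.85,
        shift=0.0,
        date_offset_days=(7, 17),
    )
    return replace(cfg, **overrides) if overrides else cfg


def responsiveness_scenario(seed: int = 0, **overrides) -> LatentCohortConfig:
    """Improving design: 97 in-window subjects (follow-up 50-70 days) with a
    positive latent shift, plus 15 late responders outside the window."""
    cfg = LatentCohortConfig(
        n_subjects=97,
        seed=seed,
        group="responsiveness",
        retest_r=0.70,
        shift=0.6,
        date_offset_days=(50, 70),
        n_out_of_window=15,
        out_of_window_offset_days=(71, 120),
    )
    return replace(cfg, **overrides) if overrides else cfg


def config_from_file(path) -> LatentCohortConfig:
    """Load a scenario config from YAML (or JSON, a YAML subset)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValueError("scenario file must contain a mapping")
    if "baseline_date" in raw:
        raw["baseline_date"] = date.fromisoformat(str(raw["baseline_date"]))
    for key in ("date_offset_days", "out_of_window_offset_days", "occasions"):
        if key in raw:
            raw[key] = tuple(raw[key])
    if "thresholds" in raw and raw["thresholds"] is not None:
        raw["thresholds"] = {
            int(k): tuple(v) for k, v in raw["thresholds"].items()
        }
    return LatentCohortConfig(**raw)
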