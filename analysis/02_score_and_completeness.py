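"""Score both cohorts and tabulate item completeness.

Recode the 36 raw items to 0-100, aggregate the eight subscales under the
complete-case rule, and report how many patients answered every member item
of each subscale at both occasions (the denominator the paired analyses
will use).

Reads results/cohort_*.csv; writes results/scores_*.csv and
results/completeness_*.csv.
"""

import warnings
from pathlib import Path

from rand36val.pipeline import score_records
from rand36val.scoring import completeness_summary, read_cohort_csv

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    for name in ("reliability", "responsiveness"):
        records = read_cohort_csv(RESULTS / f"cohort_{name}.csv")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            completeness = completeness_summary(records)
        scored = score_records(records)
        scored.to_csv(RESULTS / f"scores_{name}.csv", index=False)
        completeness.to_csv(RESULTS / f"completeness_{name}.csv", index=False)
        worst = completeness.loc[completeness["percent_complete"].idxmin()]
        print(f"{name}: scored {len(scored)} records")
        print(
            f"  completeness ranges {completeness['percent_complete'].min():.0f}%"
            f"-{completeness['percent_complete'].max():.0f}% by subscale "
            f"(lowest: {worst['subscale']})"
        )


if __name__ == "__main__":
    main()
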