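"""Test-retest reliability analysis of the stable cohort.

Runs the full pipeline on the reliability cohort: eligibility filter
(retest within 7-17 days), Health-change cross-tabulation, per-subscale
Svensson tables with jackknife SEs and 95% CIs, ordinal alpha, and ROC
point exports.  In a stable cohort the relative position (RP) of every
subscale should be non-significant — zero inside the CI.

Reads results/cohort_reliability.csv; writes results/reliability/.
"""

from pathlib import Path

from rand36val.pipeline import StudyConfig, run_study

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    bundle = run_study(
        StudyConfig(
            mode="reliability",
            input_csv=RESULTS / "cohort_reliability.csv",
            out_dir=RESULTS / "reliability",
            seed=20170301,
        )
    )
    s = bundle["health_change_summary"]
    print(
        f"eligible pairs: {bundle['manifest']['n_eligible']} "
        f"({bundle['manifest']['n_excluded']} excluded by the 7-17 day window)"
    )
    print(
        f"health change: same {s['same_percent']}%, improved {s['improved_percent']}%, "
        f"worsened {s['worsened_percent']}% (n={s['n']})"
    )
    sv = bundle["svensson_table"]
    stable = (~sv["RP_significant"]).sum()
    print(f"subscales with RP CI covering zero: {stable}/{len(sv)} (stability)")
    print(
        sv[["subscale", "n", "PA_percent", "RP", "RP_CI_low", "RP_CI_high", "RV"]]
        .round(3)
        .to_string(index=False)
    )


if __name__ == "__main__":
    main()
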