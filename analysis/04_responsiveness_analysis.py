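"""Responsiveness analysis of the improving cohort.

Runs the full pipeline on the responsiveness cohort: eligibility filter
(follow-up within 50-70 days, dropping the late responders), Health-change
cross-tabulation, per-subscale Svensson tables, ordinal alpha and ROC
exports.  With a genuine improvement the subscale RPs should be
significantly positive, and the relative rank variance (RV) flags how
heterogeneous the individual responses are around that group change.

Reads results/cohort_responsiveness.csv; writes results/responsiveness/.
"""

from pathlib import Path

from rand36val.pipeline import StudyConfig, run_study

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    bundle = run_study(
        StudyConfig(
            mode="responsiveness",
            input_csv=RESULTS / "cohort_responsiveness.csv",
            out_dir=RESULTS / "responsiveness",
            seed=20170301,
        )
    )
    s = bundle["health_change_summary"]
    print(
        f"eligible pairs: {bundle['manifest']['n_eligible']} "
        f"({bundle['manifest']['n_excluded']} late responders excluded)"
    )
    print(
        f"health change: same {s['same_percent']}%, improved {s['improved_percent']}%, "
        f"worsened {s['worsened_percent']}% (n={s['n']})"
    )
    sv = bundle["svensson_table"]
    improved = (sv["RP_significant"] & (sv["RP"] > 0)).sum()
    hetero = (sv["RV"] > 0.2).sum()
    print(f"subscales with significantly positive RP: {improved}/{len(sv)}")
    print(f"subscales with sizable individual variation (RV > 0.2): {hetero}/{len(sv)}")
    print(
        sv[["subscale", "n", "PA_percent", "RP", "RP_CI_low", "RP_CI_high", "RV"]]
        .round(3)
        .to_string(index=False)
    )


if __name__ == "__main__":
    main()
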