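"""Group-level evaluation: chance bounds and Wilcoxon tests.

Part 1 recomputes every published group statistic from the bundled
per-subject accuracy table (means/SDs, the 70% adjusted-Wald chance
limit, and the four signed-rank tests) and prints a match/mismatch
verdict per value.  Part 2 applies the same evaluation layer to the
simulated cohort decoded by 02_decode_sessions.py, when present.
"""

import json
from pathlib import Path

from nirstate import chance_upper_bound, group_summary, wilcoxon_one_sample
from nirstate.stats import format_report, reproduce_results

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    print("=== published accuracy table (bundled fixture) ===")
    report = reproduce_results()
    print(format_report(report))

    results = ROOT / "results"
    results.mkdir(exist_ok=True)
    (results / "reproduction_report.json").write_text(
        json.dumps(report, indent=2) + "\n"
    )

    cohort = results / "cohort_accuracies.tsv"
    if cohort.exists():
        print("\n=== simulated cohort ===")
        rows = [ln.split("\t") for ln in cohort.read_text().splitlines()[1:]]
        calib = [float(r[1]) for r in rows]
        online = [float(r[2]) for r in rows]
        bound = chance_upper_bound(21, 2, 0.05)
        gc, go = group_summary(calib), group_summary(online)
        print(f"chance upper bound (21 trials): {bound.upper_bound:.2f}%")
        print(f"calibration: M={gc.mean:.2f} SD={gc.sd:.2f}")
        print(f"online:      M={go.mean:.2f} SD={go.sd:.2f}")
        for name, vals in (("calibration", calib), ("online", online)):
            for mu in (50.0, bound.upper_bound):
                r = wilcoxon_one_sample(vals, mu)
                print(
                    f"wilcoxon {name} vs {mu:.1f}: T+={r.t_plus:.0f} "
                    f"p={r.p_value:.4f} r_rb={r.r_rb:.2f}"
                )
    else:
        print("\n(no simulated cohort found; run scripts 01 and 02 for part 2)")


if __name__ == "__main__":
    main()
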