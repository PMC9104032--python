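"""Decode every cohort session: 5-fold CV on calibration, replay online.

Reads the recordings written by 01_simulate_cohort.py, runs the full
pipeline (MBLL -> filter -> epoch -> Gaussian-bell GLM -> linear SVM)
and writes a per-subject accuracy table to results/cohort_accuracies.tsv
in the same layout as the bundled study table.
"""

import sys
from pathlib import Path

from nirstate import PipelineConfig, default_montage, process_recording, run_session
from nirstate.io import read_recording

ROOT = Path(__file__).resolve().parents[1]
SUBJECTS = list("ABCDEFGHIJKL")


def main(seed: int = 1) -> None:
    indir = ROOT / "scratch" / "cohort"
    if not indir.exists():
        sys.exit("run analysis/01_simulate_cohort.py first")
    montage = default_montage()
    rows = []
    for i, subject in enumerate(SUBJECTS):
        cfg = PipelineConfig(seed=seed + i)
        calib_rec = read_recording(indir / f"{subject}_calibration.tsv", montage=montage)
        calib_res, manifest, _cv, calib_fm = run_session(
            cfg, calib_rec, subject_id=subject
        )
        online_rec = read_recording(indir / f"{subject}_online.tsv", montage=montage)
        online_res, _m, _cv2, _fm = run_session(
            cfg, online_rec, session="online",
            calibration_features=calib_fm, subject_id=subject,
        )
        rows.append((subject, calib_res.accuracy, online_res.accuracy))
        print(
            f"subject {subject}: calibration {calib_res.accuracy:5.1f}%  "
            f"online {online_res.accuracy:5.1f}%  "
            f"({manifest.n_epochs} epochs)"
        )
    results = ROOT / "results"
    results.mkdir(exist_ok=True)
    out = results / "cohort_accuracies.tsv"
    with open(out, "w", newline="\n") as fh:
        fh.write("subject\tcalibration\tonline\n")
        for subject, c, o in rows:
            fh.write(f"{subject}\t{c:.2f}\t{o:.2f}\n")
    print(f"\nwrote {out}")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 1)
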