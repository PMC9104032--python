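"""Simulate a 12-subject cohort: one calibration and one online session each.

Subjects differ in hemodynamic response amplitude (drawn around 1 µM);
online sessions carry a reduced amplitude (0.6x) to emulate the drop in
task engagement once stimulus control moves from button presses to the
classifier's feedback signal.  Recordings land under scratch/cohort/ as
TSV; the manifest of simulation parameters goes to results/.
"""

import json
import sys
from pathlib import Path

import numpy as np

from nirstate import SimConfig, simulate_session
from nirstate.io import write_recording

ROOT = Path(__file__).resolve().parents[1]
SUBJECTS = list("ABCDEFGHIJKL")
ONLINE_AMPLITUDE_FACTOR = 0.6


def main(seed: int = 1) -> None:
    outdir = ROOT / "scratch" / "cohort"
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    params = {}
    for i, subject in enumerate(SUBJECTS):
        amplitude = float(rng.uniform(0.6, 1.4))
        for session, amp in (
            ("calibration", amplitude),
            ("online", ONLINE_AMPLITUDE_FACTOR * amplitude),
        ):
            cfg = SimConfig(
                seed=int(rng.integers(0, 2**31 - 1)),
                activation_amplitude_hbo=amp,
            )
            rec, _truth = simulate_session(cfg)
            write_recording(rec, outdir / f"{subject}_{session}.tsv")
        params[subject] = {"amplitude_uM": round(amplitude, 3)}
        print(f"subject {subject}: amplitude {amplitude:.2f} uM, two sessions written")
    results = ROOT / "results"
    results.mkdir(exist_ok=True)
    (results / "cohort_params.json").write_text(json.dumps(
        {"seed": seed, "online_amplitude_factor": ONLINE_AMPLITUDE_FACTOR,
         "subjects": params}, indent=2) + "\n")
    print(f"\n{2 * len(SUBJECTS)} recordings under {outdir}")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 1)
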