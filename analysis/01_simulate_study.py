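#!/usr/bin/env python
"""Simulate the oddball study and persist the epochs plus ground truth.

Writes one fixture file per subject x session under scratch/ (binary,
regenerable) and the ground-truth amplitude/kappa table under results/.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
import common  # noqa: E402

from toneosc import synth  # noqa: E402
from toneosc.epochs import write_epochs  # noqa: E402


def main():
    common.ensure_dirs()
    design = common.study_design()
    truth = synth.ground_truth_table(design)
    truth_path = common.RESULTS / "ground_truth.tsv"
    truth.to_csv(truth_path, sep="\t", index=False, float_format="%.4f")

    epoch_dir = common.SCRATCH / "epochs"
    epoch_dir.mkdir(parents=True, exist_ok=True)
    sessions, _ = synth.generate_study(design)
    n = 0
    for (group, subject, session), es in sessions:
        write_epochs(es, epoch_dir / f"{subject}_{session}.npz", "fixture")
        n += 1
    print(f"simulated {n} subject-sessions "
          f"({sum(design.groups.values())} subjects x {len(design.sessions)} sessions), "
          f"{es.n_trials} trials each at {es.fs:g} Hz")
    print(f"ground truth ({len(truth)} cells) -> {truth_path}")


if __name__ == "__main__":
    main()
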