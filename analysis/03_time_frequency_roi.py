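#!/usr/bin/env python
"""Wavelet power and phase locking -> band/window ROI table.

Each surviving subject-session is convolved with the Morlet family
(8-50 Hz, m = 9), power is baseline-corrected against -280..-100 ms, PLS
is computed against Cz (alpha) / FCz (gamma), and both are averaged inside
the alpha (8-13 Hz, 100-500 ms) and gamma (28-50 Hz, 200-400 ms) windows
over the midline/lateral region scheme.  The full long-format table lands
in scratch/ (regenerable); a condition-mean summary goes to results/.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
import common  # noqa: E402

from toneosc import pipeline  # noqa: E402
from toneosc.epochs import read_epochs  # noqa: E402
from toneosc.roi import build_roi_table, write_roi_table  # noqa: E402
from toneosc.wavelets import build_wavelet_family  # noqa: E402


def main():
    common.ensure_dirs()
    cfg = common.study_config()
    fam = build_wavelet_family(cfg.f_min, cfg.f_max, cfg.f_step, cfg.m, cfg.design.fs)
    per_subject, excluded = {}, set()
    for p in sorted((common.SCRATCH / "epochs").glob("*.npz")):
        es = read_epochs(p, "fixture")
        subject = es.trial_labels.subject.iloc[0]
        rec = pipeline.process_subject_session(es, cfg, fam)
        if rec is None:
            excluded.add(subject)  # screening drops the whole subject
            continue
        per_subject.setdefault(subject, []).extend(rec)
    records = [r for s, recs in per_subject.items() if s not in excluded for r in recs]
    table = build_roi_table(records, cfg.montage)
    roi_path = common.SCRATCH / "roi_table.tsv"
    write_roi_table(table, roi_path, pipeline.config_hash(cfg))

    summary = (
        table.groupby(["measure", "band", "scheme", "group", "session", "condition"])
        ["value"].mean().reset_index()
    )
    out = common.RESULTS / "roi_condition_means.tsv"
    summary.to_csv(out, sep="\t", index=False, float_format="%.4f")
    print(f"ROI table: {len(table)} rows -> {roi_path}")
    if excluded:
        print(f"subjects excluded by screening: {sorted(excluded)}")
    g = summary[(summary.measure == "power") & (summary.band == "gamma")
                & (summary.scheme == "midline")]
    print("midline gamma power, group x session means:")
    print(g.pivot_table(index="group", columns="session", values="value").round(1).to_string())
    print(f"condition means -> {out}")


if __name__ == "__main__":
    main()
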