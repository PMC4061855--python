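#!/usr/bin/env python
"""Type-I error and power of the stats layer on simulated studies (small run).

Two design variants, each simulated end to end (generate -> wavelet ->
ROI -> ANOVA): a null with identical cells everywhere, and a training
effect doubling the English group's post-session gamma amplitude.  The
session x group interaction on midline gamma power should reject at the
nominal 5% under the null and with high probability under the effect.
This driver uses 25 replicates per variant for speed; the test suite runs
the full 200/100-replicate version.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
import common  # noqa: E402

from toneosc import pipeline, synth  # noqa: E402
from toneosc.roi import GAMMA_BAND  # noqa: E402
from toneosc.stats import rm_anova, type1_power_suite  # noqa: E402

MID = ("Fz", "FCz", "Cz", "CPz", "Pz")


def design(seed, null):
    kw = dict(master_seed=seed, groups={"English": 5, "Chinese": 5},
              n_standards=24, n_deviants=24, gamma_only=True, n_blocks=1,
              restrict_channels=MID + ("M2",))
    if null:
        kw["null_effects"] = True
    else:
        kw["english_post_gamma_factor"] = 2.0
    return synth.scaled_design(**kw)


def analysis(d):
    cfg = pipeline.PipelineConfig(design=d, f_min=28, f_max=50, f_step=2.0,
                                  bands=(GAMMA_BAND,), channels=MID, min_trials=0,
                                  single_precision=True)
    table = pipeline.roi_table_for_design(cfg)
    sub = table[(table.measure == "power") & (table.scheme == "midline")]
    return rm_anova(sub, within=["session"], between="group")


def main():
    common.ensure_dirs()
    out = type1_power_suite(
        {"null": lambda s: design(s, True), "training_2x": lambda s: design(s, False)},
        analysis, ["session", "session:group"], n_sims=25, seed=common.MASTER_SEED,
    )
    path = common.RESULTS / "power_suite.tsv"
    out.to_csv(path, sep="\t", index=False, float_format="%.4f")
    print(out.round(3).to_string(index=False))
    print(f"-> {path}")


if __name__ == "__main__":
    main()
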