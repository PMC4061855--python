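#!/usr/bin/env python
"""Mixed repeated-measures ANOVAs and follow-ups on the ROI table.

Runs the four headline analyses (midline/lateral gamma and alpha power,
lateral alpha/gamma PLS) with group as the between factor and session,
tone, condition, anteriority (and hemisphere, laterally) within; then
Bonferroni group post-hocs on pre-training gamma power and the Spearman
correlation between left-fronto-central gamma and left-centro-parietal
alpha power.  Note the generator couples each subject's alpha and gamma
amplitudes through one positive scale factor, so unlike real learners it
does not produce a negative alpha-gamma correlation.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
import common  # noqa: E402

from toneosc import pipeline  # noqa: E402
from toneosc.roi import read_roi_table  # noqa: E402
from toneosc.stats import bonferroni_pairwise, rm_anova, spearman  # noqa: E402


def main():
    common.ensure_dirs()
    cfg = common.study_config()
    table = read_roi_table(common.SCRATCH / "roi_table.tsv")

    for plan in cfg.stats_plan:
        sub = table[(table.measure == plan["measure"]) & (table.band == plan["band"])
                    & (table.scheme == plan["scheme"])]
        anova = rm_anova(sub, within=list(plan["within"]), between=plan["between"])
        out = common.RESULTS / f"anova_{plan['name']}.tsv"
        anova.to_csv(out, sep="\t", index=False, float_format="%.5g")
        top = anova.sort_values("p_gg").head(3)
        print(f"\n{plan['name']}: top effects")
        print(top[["effect", "F", "df1_gg", "df2_gg", "p_gg"]].round(4).to_string(index=False))

    pre_gamma = table[(table.measure == "power") & (table.band == "gamma")
                      & (table.scheme == "lateral") & (table.session == "pre")]
    posthoc = bonferroni_pairwise(pre_gamma, factor="group")
    posthoc.to_csv(common.RESULTS / "posthoc_group_gamma_pre.tsv", sep="\t",
                   index=False, float_format="%.5g")
    print("\npre-training lateral gamma power, pairwise groups (Bonferroni):")
    print(posthoc.round(4).to_string(index=False))

    # alpha-gamma coupling across subjects (left fronto-central gamma vs
    # left centro-parietal alpha, collapsed over everything else)
    g = table[(table.measure == "power") & (table.band == "gamma")
              & (table.location == "fronto-central/L")
              & table.group.isin(["English", "Chinese"])]
    a = table[(table.measure == "power") & (table.band == "alpha")
              & (table.location == "centro-parietal/L")
              & table.group.isin(["English", "Chinese"])]
    gm = g.groupby("subject").value.mean()
    am = a.groupby("subject").value.mean()
    res = spearman(gm.values, am[gm.index].values)
    print(f"\nalpha-gamma Spearman rho = {res.rho:+.2f} (n = {res.n}, "
          f"p = {res.p:.3f}, {res.method}) — the generator's shared subject "
          "scale factor induces positive coupling; a negative correlation is "
          "a feature of real learners it does not emulate")
    pd.DataFrame([res.__dict__]).to_csv(common.RESULTS / "alpha_gamma_correlation.tsv",
                                        sep="\t", index=False)


if __name__ == "__main__":
    main()
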