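"""Mixed-design repeated-measures ANOVA with Greenhouse-Geisser correction,
Bonferroni pairwise follow-ups, and Spearman rank correlation.

The ANOVA is the classical univariate decomposition for designs with any
number of fully-crossed within-subject factors and one between-subjects
factor.  For each within effect W the subject x cell matrix is projected
onto an orthonormal contrast basis (Kronecker products of Helmert
contrasts for factors in W and normalized averaging vectors for the rest).
Each effect and its interaction with the group factor are tested against
the effect's own subject-level error term; sphericity of that term is
summarized by the Greenhouse-Geisser estimate

    eps = (tr S)^2 / (k * tr(S^2))

over the pooled within-group covariance S of the contrast variables
(equivalently, the mean-square of S's eigenvalues relative to their mean),
bounded in [1/k, 1].  The correction multiplies both degrees of freedom by
eps and is applied only when an effect has more than one numerator df
(two-level factors are spherical by construction, eps = 1).  With
unbalanced groups, within-effect sums of squares use the unweighted-means
(Type III) form, which coincides with the classical formula for balanced
designs.
"""

from __future__ import annotations

import itertools
import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps


# ---------------------------------------------------------------------------
# contrast machinery

def _helmert(levels: int) -> np.ndarray:
    """Orthonormal (levels x levels-1) contrast matrix orthogonal to 1."""
    c = np.zeros((levels, levels - 1))
    for j in range(1, levels):
        c[:j, j - 1] = 1.0
        c[j, j - 1] = -j
        c[:, j - 1] /= np.sqrt(j * (j + 1))
    return c


def gg_epsilon(cov: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon of a contrast-space covariance matrix."""
    cov = np.asarray(cov, float)
    k = cov.shape[0]
    if k == 1:
        return 1.0
    tr = np.trace(cov)
    tr2 = np.trace(cov @ cov)
    if tr2 <= 0:
        return 1.0
    return float(np.clip(tr ** 2 / (k * tr2), 1.0 / k, 1.0))


# ---------------------------------------------------------------------------
# core decomposition on a subjects x cells matrix

def _mixed_anova_matrix(Y, group_codes, within_levels, within_names, between_name="group"):
    """Univariate mixed RM-ANOVA on Y (subjects x cells).

    Cells are ordered row-major over ``within_names`` (first factor
    slowest).  ``group_codes`` are integer group indices per subject (all
    zeros for a purely within design).
    """
    Y = np.asarray(Y, float)
    n_subj = Y.shape[0]
    groups = np.asarray(group_codes)
    glevels = np.unique(groups)
    g = len(glevels)
    nj = np.array([(groups == lv).sum() for lv in glevels])
    if np.any(nj < 2):
        raise ValueError("need at least 2 subjects per group")
    if Y.shape[1] != int(np.prod(within_levels)):
        raise ValueError("cell count does not match within-factor levels")

    results = []

    def _one_way(z):
        """Group means, pooled residual SS and covariance for columns z."""
        means = np.vstack([z[groups == lv].mean(axis=0) for lv in glevels])
        resid = z - means[np.searchsorted(glevels, groups)]
        return means, resid

    # between-subjects effect on the subject averages
    u = np.ones(Y.shape[1]) / np.sqrt(Y.shape[1])
    v = Y @ u
    vm, vresid = _one_way(v[:, None])
    sse_b = float((vresid ** 2).sum())
    if g > 1:
        grand_w = float(nj @ vm[:, 0]) / n_subj
        ss_b = float(nj @ (vm[:, 0] - grand_w) ** 2)
        df1, df2 = g - 1, n_subj - g
        F = (ss_b / df1) / (sse_b / df2)
        results.append(dict(effect=between_name, df1=df1, df2=df2,
                            ss_effect=ss_b, ss_error=sse_b, F=F, eps=1.0,
                            df1_gg=float(df1), df2_gg=float(df2),
                            p_uncorrected=float(sps.f.sf(F, df1, df2)),
                            p_gg=float(sps.f.sf(F, df1, df2))))

    # within effects and their group interactions
    bases = []
    for L in within_levels:
        bases.append({False: np.ones((L, 1)) / np.sqrt(L), True: _helmert(L)})
    for r in range(1, len(within_names) + 1):
        for W in itertools.combinations(range(len(within_names)), r):
            K = np.ones((1, 1))
            for i in range(len(within_names)):
                K = np.kron(K, bases[i][i in W])
            Z = Y @ K
            kW = Z.shape[1]
            means, resid = _one_way(Z)
            sse = float((resid ** 2).sum())
            df_err = kW * (n_subj - g)
            S = resid.T @ resid / (n_subj - g)
            eps = gg_epsilon(S) if kW > 1 else 1.0
            name = "*".join(within_names[i] for i in W)

            # main within effect (unweighted group means under imbalance)
            h = float((1.0 / nj).sum())
            col_means = means.sum(axis=0)          # sum over groups of group means
            ss_w = float((col_means ** 2).sum() / h)
            F = (ss_w / kW) / (sse / df_err)
            results.append(dict(effect=name, df1=kW, df2=df_err,
                                ss_effect=ss_w, ss_error=sse, F=F, eps=eps,
                                df1_gg=eps * kW, df2_gg=eps * df_err,
                                p_uncorrected=float(sps.f.sf(F, kW, df_err)),
                                p_gg=float(sps.f.sf(F, eps * kW, eps * df_err))))

            if g > 1:
                grand_w = (nj[:, None] * means).sum(axis=0) / n_subj
                ss_wg = float((nj[:, None] * (means - grand_w) ** 2).sum())
                df1 = kW * (g - 1)
                Fg = (ss_wg / df1) / (sse / df_err)
                results.append(dict(effect=f"{name}:{between_name}", df1=df1,
                                    df2=df_err, ss_effect=ss_wg, ss_error=sse,
                                    F=Fg, eps=eps, df1_gg=eps * df1,
                                    df2_gg=eps * df_err,
                                    p_uncorrected=float(sps.f.sf(Fg, df1, df_err)),
                                    p_gg=float(sps.f.sf(Fg, eps * df1, eps * df_err))))
    return pd.DataFrame(results)


# ---------------------------------------------------------------------------
# public interfaces on the long-format ROI table

def pivot_within(table: pd.DataFrame, dv: str, within, subject: str = "subject"):
    """Subjects x cells matrix (cells averaged over unlisted factors),
    plus the cell ordering and level lists.  Raises on missing cells."""
    within = list(within)
    levels = [list(pd.unique(table[f])) for f in within]
    pv = table.pivot_table(index=subject, columns=within, values=dv, aggfunc="mean")
    full = list(itertools.product(*levels)) if len(within) > 1 else [
        (lv,) for lv in levels[0]
    ]
    cols = [c if isinstance(c, tuple) else (c,) for c in pv.columns]
    missing = [c for c in full if c not in cols]
    if missing or pv.isna().any().any():
        raise ValueError(f"unbalanced design; missing cells: {missing or 'NaN cells'}")
    order = [c if len(within) > 1 else c[0] for c in full]
    pv = pv[order]
    return pv, [len(lv) for lv in levels], within


def rm_anova(table: pd.DataFrame, dv: str = "value", within=("session",),
             between: str | None = "group", subject: str = "subject") -> pd.DataFrame:
    """Mixed-design repeated-measures ANOVA on a long-format table.

    Values are averaged over any factors not listed; every subject must
    have every within cell.  Returns one row per effect with uncorrected
    and GG-corrected p-values.
    """
    pv, levels, within = pivot_within(table, dv, within, subject)
    if between is not None:
        gmap = table.groupby(subject)[between].agg(pd.unique)
        if gmap.map(len).max() > 1:
            raise ValueError(f"subject assigned to multiple {between} levels")
        glabels = gmap.map(lambda a: a[0]).reindex(pv.index)
        codes = pd.factorize(glabels)[0]
        between_name = between
    else:
        codes = np.zeros(len(pv), dtype=int)
        between_name = "group"
    return _mixed_anova_matrix(pv.to_numpy(), codes, levels, within, between_name)


def follow_up_anovas(table: pd.DataFrame, by: str, **kwargs) -> dict:
    """Separate ANOVAs per level of ``by`` (no alpha adjustment)."""
    out = {}
    for lv in pd.unique(table[by]):
        sub = table[table[by] == lv]
        kw = dict(kwargs)
        if kw.get("between") == by:
            kw["between"] = None
        out[lv] = rm_anova(sub, **kw)
    return out


def bonferroni_pairwise(table: pd.DataFrame, dv: str = "value",
                        factor: str = "group", subject: str = "subject") -> pd.DataFrame:
    """All pairwise comparisons of ``factor`` levels, p multiplied by the
    number of pairs (capped at 1).  Paired t-tests when both levels share
    the same subjects (within factor), pooled independent t otherwise."""
    levels = list(pd.unique(table[factor]))
    if len(levels) < 2:
        raise ValueError("need at least two levels")
    per = table.groupby([factor, subject], sort=False)[dv].mean()
    pairs = list(itertools.combinations(levels, 2))
    rows = []
    for a, b in pairs:
        xa, xb = per[a], per[b]
        shared = xa.index.intersection(xb.index)
        if len(shared) == len(xa) == len(xb):
            t, p = sps.ttest_rel(xa[shared], xb[shared])
            kind = "paired"
        else:
            t, p = sps.ttest_ind(xa, xb)
            kind = "independent"
        rows.append(dict(level_a=a, level_b=b, test=kind, t=float(t),
                         p_raw=float(p), p_bonferroni=min(1.0, float(p) * len(pairs))))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Spearman correlation

@dataclass(frozen=True)
class CorrelationResult:
    rho: float
    n: int
    p: float
    method: str
    degenerate: bool = False


def spearman(x, y) -> CorrelationResult:
    """Spearman rank correlation with average ranks for ties.

    Two-sided p from the t approximation for n >= 10 and from the exact
    permutation distribution of the ranks below that.  Constant input has
    no defined rank correlation and returns a flagged degenerate result.
    """
    x, y = np.asarray(x, float), np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be paired 1-d arrays")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 pairs")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return CorrelationResult(np.nan, n, np.nan, "degenerate", True)
    if n >= 10:
        rho, p = sps.spearmanr(x, y)
        return CorrelationResult(float(rho), n, float(p), "t-approximation")
    rx, ry = sps.rankdata(x), sps.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    perms = np.array(list(itertools.permutations(range(n))))
    rxc = rx - rx.mean()
    ryc = ry - ry.mean()
    num = (ryc[perms] * rxc).sum(axis=1)
    denom = np.sqrt((rxc ** 2).sum() * (ryc ** 2).sum())
    rho_perm = num / denom
    p = float((np.abs(rho_perm) >= abs(rho) - 1e-12).mean())
    return CorrelationResult(rho, n, p, "exact-permutation")


# ---------------------------------------------------------------------------
# simulation harness

def type1_power_suite(designs: dict, analysis, effects, n_sims: int = 200,
                      seed: int = 0, alpha: float = 0.05) -> pd.DataFrame:
    """Rejection rates of chosen effects over simulated studies.

    ``designs`` maps a variant name to a StudyDesign factory taking a
    per-simulation seed; ``analysis`` maps a StudyDesign to an ANOVA table
    (e.g. the pipeline's scaled gamma-power path).  Reports per effect the
    fraction of simulations with GG-corrected p < alpha plus a 95%
    Clopper-Pearson interval.  Fully deterministic under ``seed``.
    """
    if n_sims < 1:
        raise ValueError("n_sims must be positive")
    rows = []
    for name, factory in designs.items():
        hits = {e: 0 for e in effects}
        for i in range(n_sims):
            name_key = zlib.crc32(str(name).encode()) % (2 ** 31)
            sim_seed = int(np.random.SeedSequence([seed, name_key, i])
                           .generate_state(1)[0] % (2 ** 31))
            anova = analysis(factory(sim_seed))
            for e in effects:
                row = anova[anova["effect"] == e]
                if len(row) and float(row["p_gg"].iloc[0]) < alpha:
                    hits[e] += 1
        for e in effects:
            k = hits[e]
            lo = sps.beta.ppf(0.025, k, n_sims - k + 1) if k > 0 else 0.0
            hi = sps.beta.ppf(0.975, k + 1, n_sims - k) if k < n_sims else 1.0
            rows.append(dict(design=name, effect=e, n_sims=n_sims, rejections=k,
                             rate=k / n_sims, ci_low=float(lo), ci_high=float(hi)))
    return pd.DataFrame(rows)
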