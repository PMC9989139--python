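"""Inferential layer: paired tests, two-way within-subject ANOVA, correlations.

The ANOVA is the fully within-subject two-factor design (condition x time):
each factor's F uses its own subject-by-factor interaction as the error
term.  Mauchly's sphericity test is run on the time factor (collapsed over
condition) and a Greenhouse-Geisser correction is applied to the time and
interaction terms when sphericity is rejected at P < 0.05.  Pearson
correlations carry Bonferroni-adjusted p-values (multiplied by the family
size, capped at 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats as sps


@dataclass
class PairedTTestResult:
    t: float
    p: float
    significant: bool
    degenerate: bool = False
    n: int = 0


@dataclass
class AnovaResult:
    """Per-factor F table plus sphericity diagnostics for the time factor."""

    table: pd.DataFrame  # factor, F, df_num, df_den, p, p_corrected
    sphericity_W: float
    sphericity_p: float
    gg_epsilon: float


def paired_ttest(a, b, alpha: float = 0.01) -> PairedTTestResult:
    """Two-sided paired t-test of a vs b (positive t means a > b).

    A zero-variance difference is reported as a degenerate result rather
    than an exception: t = 0, p = 1 when the difference is identically zero,
    t = +-inf, p = 0 when it is a non-zero constant.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("a and b must be equal-length 1-D paired samples")
    n = a.size
    if n < 3:
        raise ValueError("need at least 3 pairs")
    d = a - b
    sd = d.std(ddof=1)
    if sd == 0:
        if d.mean() == 0:
            return PairedTTestResult(0.0, 1.0, False, degenerate=True, n=n)
        t = np.inf * np.sign(d.mean())
        return PairedTTestResult(float(t), 0.0, True, degenerate=True, n=n)
    t = d.mean() / (sd / np.sqrt(n))
    p = 2 * sps.t.sf(abs(t), n - 1)
    return PairedTTestResult(float(t), float(p), bool(p < alpha), n=n)


def _check_balanced(df: pd.DataFrame, subject: str, factors: tuple[str, str]) -> None:
    counts = df.groupby([subject, *factors], observed=True).size()
    subjects = df[subject].unique()
    a_levels = df[factors[0]].unique()
    b_levels = df[factors[1]].unique()
    missing = [
        (s, a, b)
        for s in subjects
        for a in a_levels
        for b in b_levels
        if (s, a, b) not in counts.index
    ]
    if missing:
        raise ValueError(f"unbalanced design; missing cells: {missing[:10]}")


def rm_anova_2way(
    df: pd.DataFrame,
    dv: str = "value",
    subject: str = "subject",
    within: tuple[str, str] = ("condition", "time"),
) -> AnovaResult:
    """Two-way fully within-subject ANOVA by sums-of-squares decomposition.

    Cells with replicates (e.g. one value per density) are averaged per
    subject x condition x time before decomposition.  F for each factor is
    MS_factor / MS_(factor x subject).
    """
    fa, fb = within
    _check_balanced(df, subject, within)
    cell = df.groupby([subject, fa, fb], observed=True)[dv].mean().reset_index()
    a_levels = sorted(cell[fa].unique())
    b_levels = sorted(cell[fb].unique())
    Y = cell.pivot_table(index=subject, columns=[fa, fb], values=dv)
    Y = Y.reindex(columns=pd.MultiIndex.from_product([a_levels, b_levels]))
    n = Y.shape[0]
    a, b = len(a_levels), len(b_levels)
    cube = Y.to_numpy().reshape(n, a, b)  # subject x A x B

    grand = cube.mean()
    m_a = cube.mean(axis=(0, 2))
    m_b = cube.mean(axis=(0, 1))
    m_s = cube.mean(axis=(1, 2))
    m_ab = cube.mean(axis=0)
    m_as = cube.mean(axis=2)
    m_bs = cube.mean(axis=1)

    ss_a = n * b * np.sum((m_a - grand) ** 2)
    ss_b = n * a * np.sum((m_b - grand) ** 2)
    ss_ab = n * np.sum((m_ab - m_a[:, None] - m_b[None, :] + grand) ** 2)
    ss_as = b * np.sum((m_as - m_a[None, :] - m_s[:, None] + grand) ** 2)
    ss_bs = a * np.sum((m_bs - m_b[None, :] - m_s[:, None] + grand) ** 2)
    resid = (
        cube
        - m_ab[None]
        - m_as[:, :, None]
        - m_bs[:, None, :]
        + m_a[None, :, None]
        + m_b[None, None, :]
        + m_s[:, None, None]
        - grand
    )
    ss_abs = np.sum(resid**2)

    rows = []
    for name, ss_eff, df_eff, ss_err, df_err in [
        (fa, ss_a, a - 1, ss_as, (a - 1) * (n - 1)),
        (fb, ss_b, b - 1, ss_bs, (b - 1) * (n - 1)),
        (f"{fa} * {fb}", ss_ab, (a - 1) * (b - 1), ss_abs, (a - 1) * (b - 1) * (n - 1)),
    ]:
        F = (ss_eff / df_eff) / (ss_err / df_err)
        p = sps.f.sf(F, df_eff, df_err)
        rows.append(
            {"factor": name, "F": float(F), "df_num": df_eff, "df_den": df_err,
             "p": float(p)}
        )
    table = pd.DataFrame(rows)

    # Mauchly's test and GG epsilon on the time factor, collapsed over A
    time_table = cell.groupby([subject, fb], observed=True)[dv].mean().reset_index()
    if b > 2:
        spher = pg.sphericity(time_table, dv=dv, within=fb, subject=subject)
        W, p_sph = float(spher.W), float(spher.pval)
        eps = float(pg.epsilon(time_table, dv=dv, within=fb, subject=subject,
                               correction="gg"))
    else:
        W, p_sph, eps = 1.0, 1.0, 1.0
    table["p_corrected"] = table["p"]
    if p_sph < 0.05:
        for idx, row in table.iterrows():
            if fb in row["factor"]:
                table.loc[idx, "p_corrected"] = float(
                    sps.f.sf(row["F"], row["df_num"] * eps, row["df_den"] * eps)
                )
    return AnovaResult(table=table, sphericity_W=W, sphericity_p=p_sph, gg_epsilon=eps)


def shapiro_normality(values) -> tuple[float, float]:
    """Shapiro-Wilk statistic and p-value (reported, never gating)."""
    w, p = sps.shapiro(np.asarray(values, dtype=float))
    return float(w), float(p)


CONTRAST_SCHEMES = ("consecutive", "vs_baseline")


def posthoc_contrasts(
    df: pd.DataFrame,
    scheme: str = "consecutive",
    dv: str = "value",
    subject: str = "subject",
    time: str = "window",
    baseline: str = "baseline",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Paired t contrasts over the window sequence, Bonferroni-corrected.

    'consecutive' tests each adjacent window pair (baseline vs T1, T1 vs T2,
    ...); 'vs_baseline' tests every post-stimulus window against baseline.
    """
    if scheme not in CONTRAST_SCHEMES:
        raise ValueError(f"unknown contrast scheme {scheme!r}; use {CONTRAST_SCHEMES}")
    wide = df.groupby([subject, time], observed=True)[dv].mean().unstack(time)
    windows = [w for w in df[time].unique()]
    ordered = [baseline] + sorted(
        [w for w in windows if w != baseline],
        key=lambda w: str(w),
    )
    if scheme == "consecutive":
        pairs = list(zip(ordered, ordered[1:]))
    else:
        pairs = [(baseline, w) for w in ordered[1:]]
    rows = []
    for w1, w2 in pairs:
        res = paired_ttest(wide[w2].to_numpy(), wide[w1].to_numpy(), alpha)
        rows.append(
            {"contrast": f"{w1} vs {w2}", "t": res.t, "p": res.p,
             "p_bonf": min(res.p * len(pairs), 1.0) if np.isfinite(res.p) else res.p}
        )
    out = pd.DataFrame(rows)
    out["significant"] = out["p_bonf"] < alpha
    return out


def correlate_bonferroni(
    pairs: list[tuple[str, np.ndarray, np.ndarray]],
    family_size: int | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Pearson r with Bonferroni-adjusted p for a family of variable pairs.

    ``pairs`` holds (name, x, y) triples; the family size defaults to the
    number of pairs.  Zero variance in either member yields a degenerate row
    (r and p NaN) rather than an exception.
    """
    m = family_size or len(pairs)
    rows = []
    for name, x, y in pairs:
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if x.size != y.size or x.size < 4:
            raise ValueError(f"pair {name!r}: need >= 4 paired observations")
        if x.std() == 0 or y.std() == 0:
            rows.append({"pair": name, "r": np.nan, "p_raw": np.nan,
                         "p_adj": np.nan, "degenerate": True})
            continue
        r, p = sps.pearsonr(x, y)
        rows.append(
            {"pair": name, "r": float(r), "p_raw": float(p),
             "p_adj": float(min(p * m, 1.0)), "degenerate": False}
        )
    out = pd.DataFrame(rows)
    out["significant"] = out["p_adj"] < alpha
    return out
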