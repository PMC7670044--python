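"""Behavioral statistics for the recognition-memory task.

Covers hit/correct-rejection rate tables, equal-variance Gaussian
signal-detection measures (sensitivity d' and criterion c), paired t tests
with Cohen's dz, the two-one-sided-tests (TOST) equivalence procedure on a
paired standardized effect, and the 3 (Item: 1x, 3x, new) x 2 (Run:
incentivize-old, incentivize-new) repeated-measures ANOVA with partial
eta squared.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .design import ITEM_TYPES, RUN_TYPES


class MissingCellError(ValueError):
    """A subject x condition cell has no trials / is absent."""


class DegenerateInputError(ValueError):
    """Input carries no variance where variance is required."""


# ---------------------------------------------------------------------------
# Rates
# ---------------------------------------------------------------------------

def score_responses(responses: pd.DataFrame) -> pd.DataFrame:
    """Per subject x run_type x item_type accuracy and correct-trial RT.

    ``rate`` is the proportion of correct responses in the cell (a hit rate
    for old items, a correct-rejection rate for new items);
    ``mean_rt_correct_ms`` averages RTs over correct trials only.
    """
    if responses.empty:
        raise MissingCellError("empty response table")
    g = responses.groupby(["subject", "run_type", "item_type"], sort=True)
    out = g.agg(
        n_trials=("correct", "size"),
        n_correct=("correct", "sum"),
    ).reset_index()
    out["rate"] = out["n_correct"] / out["n_trials"]
    rt = (
        responses[responses["correct"]]
        .groupby(["subject", "run_type", "item_type"])["rt_ms"]
        .mean()
        .rename("mean_rt_correct_ms")
        .reset_index()
    )
    out = out.merge(rt, on=["subject", "run_type", "item_type"], how="left")
    if (out["n_trials"] == 0).any():
        raise MissingCellError("cell with zero trials")
    return out


def collapse_hit_rate(rate_1x: float, rate_3x: float,
                      n_1x: int, n_3x: int) -> float:
    """Trial-weighted pooled hit rate over once- and thrice-studied items.

    With equal trial counts (the default design) this is the plain mean.
    """
    return (rate_1x * n_1x + rate_3x * n_3x) / (n_1x + n_3x)


# ---------------------------------------------------------------------------
# Signal detection
# ---------------------------------------------------------------------------

def sdt_measures(H: float, F: float, n_old: int, n_new: int,
                 criterion_sign: str = "standard") -> tuple[float, float]:
    """Sensitivity d' and criterion c from hit and false-alarm rates.

    Rates of exactly 0 or 1 are replaced by ``1/(2N)`` / ``1 - 1/(2N)``
    before the inverse-normal transform (N = trial count on that rate).
    d' = z(H) - z(F). The criterion defaults to the standard location
    measure c = -0.5 [z(H) + z(F)], negative when the observer is liberal;
    ``criterion_sign="literal"`` returns +0.5 [z(H) + z(F)] instead.
    """
    if not (0.0 <= H <= 1.0 and 0.0 <= F <= 1.0):
        raise ValueError("rates must lie in [0, 1]")
    if n_old <= 0 or n_new <= 0:
        raise ValueError("trial counts must be positive")
    H = min(max(H, 1.0 / (2 * n_old)), 1.0 - 1.0 / (2 * n_old))
    F = min(max(F, 1.0 / (2 * n_new)), 1.0 - 1.0 / (2 * n_new))
    zH, zF = stats.norm.ppf(H), stats.norm.ppf(F)
    d_prime = zH - zF
    c = 0.5 * (zH + zF)
    if criterion_sign == "standard":
        c = -c
    elif criterion_sign != "literal":
        raise ValueError(f"unknown criterion_sign {criterion_sign!r}")
    return float(d_prime), float(c)


def sdt_summary(rates: pd.DataFrame,
                criterion_sign: str = "standard") -> pd.DataFrame:
    """Per subject x run_type SDT summary from a rate table.

    Hit rates for 1x and 3x items are pooled (trial-weighted) into a single
    H; F is 1 minus the correct-rejection rate. Group-level d'/c are meant
    to be taken as means of these per-subject values.
    """
    rows = []
    for (subj, run_type), grp in rates.groupby(["subject", "run_type"]):
        cells = grp.set_index("item_type")
        for it in ITEM_TYPES:
            if it not in cells.index:
                raise MissingCellError(f"missing {it} for subject {subj}")
        n1, n3 = int(cells.loc["1x", "n_trials"]), int(cells.loc["3x", "n_trials"])
        H = collapse_hit_rate(cells.loc["1x", "rate"], cells.loc["3x", "rate"],
                              n1, n3)
        F = 1.0 - cells.loc["new", "rate"]
        n_new = int(cells.loc["new", "n_trials"])
        d, c = sdt_measures(H, F, n1 + n3, n_new, criterion_sign)
        rows.append((subj, run_type, H, F, d, c))
    return pd.DataFrame(rows, columns=[
        "subject", "run_type", "H", "F", "d_prime", "c",
    ])


# ---------------------------------------------------------------------------
# Paired comparisons and equivalence
# ---------------------------------------------------------------------------

def paired_t(a, b) -> tuple[float, int, float, float]:
    """Paired t test with Cohen's dz.

    Returns ``(t, df, p, dz)`` where dz = mean(diff) / sd(diff) and the
    identity dz = t / sqrt(n) holds exactly.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("need two equal-length samples of size >= 2")
    diff = a - b
    sd = diff.std(ddof=1)
    if sd == 0.0:
        raise DegenerateInputError("zero variance of paired differences")
    n = diff.size
    dz = diff.mean() / sd
    t = dz * np.sqrt(n)
    p = 2.0 * stats.t.sf(abs(t), n - 1)
    return float(t), n - 1, float(p), float(dz)


@dataclass(frozen=True)
class TostResult:
    """Two-one-sided-tests equivalence result on a paired effect size."""

    dz: float
    n: int
    bound: float
    t_lower: float
    t_upper: float
    df: int
    p_lower: float
    p_upper: float
    alpha: float

    @property
    def p_binding(self) -> float:
        return max(self.p_lower, self.p_upper)

    @property
    def t_binding(self) -> float:
        """|t| of the one-sided test with the larger p (the binding test)."""
        return abs(self.t_lower if self.p_lower >= self.p_upper
                   else self.t_upper)

    @property
    def equivalent(self) -> bool:
        return self.p_binding < self.alpha


def tost_paired(dz: float, n: int, bound: float,
                alpha: float = 0.05) -> TostResult:
    """TOST equivalence test from a paired standardized effect size.

    Tests H0: |effect| >= bound against equivalence within (-bound, bound)
    using t_lower = (dz + bound) sqrt(n) (one-sided upper p) and
    t_upper = (dz - bound) sqrt(n) (one-sided lower p), each on n - 1
    degrees of freedom. Equivalence is declared when both one-sided tests
    reject at ``alpha``.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    if bound <= 0:
        raise ValueError("bound must be > 0")
    rt_n = np.sqrt(n)
    t_lower = (dz + bound) * rt_n
    t_upper = (dz - bound) * rt_n
    df = n - 1
    p_lower = float(stats.t.sf(t_lower, df))   # H0: dz <= -bound
    p_upper = float(stats.t.cdf(t_upper, df))  # H0: dz >= +bound
    return TostResult(dz=dz, n=n, bound=bound, t_lower=float(t_lower),
                      t_upper=float(t_upper), df=df, p_lower=p_lower,
                      p_upper=p_upper, alpha=alpha)


# ---------------------------------------------------------------------------
# Repeated-measures ANOVA
# ---------------------------------------------------------------------------

def rm_anova_2way(table: pd.DataFrame,
                  dv: str = "value",
                  subject: str = "subject",
                  factor_a: str = "item_type",
                  factor_b: str = "run_type") -> pd.DataFrame:
    """Two-way fully within-subject ANOVA with partial eta squared.

    Expects a complete balanced long table with one observation per
    subject x A x B cell. Returns one row per effect (A, B, A x B) with the
    F ratio against its own subject-interaction error term, degrees of
    freedom, p value, partial eta squared, and the sums of squares of the
    effect and its error (no sphericity correction).
    """
    df = table[[subject, factor_a, factor_b, dv]].copy()
    a_levels = sorted(df[factor_a].unique())
    b_levels = sorted(df[factor_b].unique())
    subjects = sorted(df[subject].unique())
    n, a, b = len(subjects), len(a_levels), len(b_levels)
    if len(df) != n * a * b or df.duplicated([subject, factor_a, factor_b]).any():
        raise MissingCellError("table must be complete and balanced")

    y = (
        df.set_index([subject, factor_a, factor_b])[dv]
        .unstack([factor_a, factor_b])
        .loc[subjects]
        .to_numpy(dtype=float)
        .reshape(n, a, b)
    )
    grand = y.mean()
    m_a = y.mean(axis=(0, 2))       # A marginal means
    m_b = y.mean(axis=(0, 1))       # B marginal means
    m_s = y.mean(axis=(1, 2))       # subject means
    m_ab = y.mean(axis=0)           # A x B cell means
    m_sa = y.mean(axis=2)           # subject x A means
    m_sb = y.mean(axis=1)           # subject x B means

    ss_a = n * b * np.sum((m_a - grand) ** 2)
    ss_b = n * a * np.sum((m_b - grand) ** 2)
    ss_s = a * b * np.sum((m_s - grand) ** 2)
    ss_ab = n * np.sum((m_ab - m_a[:, None] - m_b[None, :] + grand) ** 2)
    ss_sa = b * np.sum((m_sa - m_s[:, None] - m_a[None, :] + grand) ** 2)
    ss_sb = a * np.sum((m_sb - m_s[:, None] - m_b[None, :] + grand) ** 2)
    ss_total = np.sum((y - grand) ** 2)
    ss_sab = ss_total - (ss_a + ss_b + ss_ab + ss_s + ss_sa + ss_sb)

    effects = [
        (factor_a, ss_a, a - 1, ss_sa, (a - 1) * (n - 1)),
        (factor_b, ss_b, b - 1, ss_sb, (b - 1) * (n - 1)),
        (f"{factor_a} x {factor_b}", ss_ab, (a - 1) * (b - 1),
         ss_sab, (a - 1) * (b - 1) * (n - 1)),
    ]
    rows = []
    for name, ss_eff, df1, ss_err, df2 in effects:
        ms_eff = ss_eff / df1
        ms_err = ss_err / df2
        F = np.inf if ms_err == 0 and ms_eff > 0 else (
            0.0 if ms_err == 0 else ms_eff / ms_err)
        p = 0.0 if np.isinf(F) else float(stats.f.sf(F, df1, df2))
        pes = ss_eff / (ss_eff + ss_err) if (ss_eff + ss_err) > 0 else 0.0
        rows.append((name, ss_eff, df1, ss_err, df2, float(F), p, float(pes)))
    out = pd.DataFrame(rows, columns=[
        "effect", "ss_effect", "df_num", "ss_error", "df_den",
        "F", "p", "partial_eta_sq",
    ])
    out.attrs["ss_total"] = float(ss_total)
    out.attrs["ss_subject"] = float(ss_s)
    return out


def accuracy_anova_table(rates: pd.DataFrame) -> pd.DataFrame:
    """Long table of per-cell accuracy ready for :func:`rm_anova_2way`."""
    df = rates[["subject", "run_type", "item_type", "rate"]].copy()
    return df.rename(columns={"rate": "value"})


def rt_anova_table(rates: pd.DataFrame) -> pd.DataFrame:
    """Long table of per-cell correct-response RTs for the ANOVA."""
    df = rates[["subject", "run_type", "item_type",
                "mean_rt_correct_ms"]].copy()
    return df.rename(columns={"mean_rt_correct_ms": "value"})
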