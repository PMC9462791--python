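"""Dose-response and activity statistics for engineered Na,K-ATPases.

Raw plate absorbances are calibrated against the fully inhibited background
well, converted to percent non-inhibited activity (dose wells) and to
baseline ATP-hydrolysis activity in nmol Pi / mg protein / min (control
wells, via a phosphate standard curve). CTS resistance is summarized as
log10 IC50 from a four-parameter logistic with the top asymptote fixed at
100 and the bottom at 0, leaving only the midpoint and (positive) slope
free.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import least_squares

from .io_core import AssayRecord


@dataclass
class StandardCurve:
    """Linear phosphate standard: absorbance = intercept + slope * mM Pi."""

    slope: float  # absorbance units per mM Pi
    intercept: float = 0.0

    @classmethod
    def fit(cls, conc_mM, absorbance) -> "StandardCurve":
        conc_mM = np.asarray(conc_mM, float)
        absorbance = np.asarray(absorbance, float)
        if conc_mM.size < 3:
            raise ValueError("standard curve needs at least 3 points")
        slope, intercept = np.polyfit(conc_mM, absorbance, 1)
        return cls(slope=float(slope), intercept=float(intercept))

    def to_mM(self, absorbance) -> float:
        return (absorbance - self.intercept) / self.slope


@dataclass
class ActivityMeasure:
    construct: str
    replicate: int
    activity: float  # nmol Pi / mg protein / min
    below_detection: bool = False


@dataclass
class IC50Fit:
    construct: str
    replicate: int
    log10_ic50: float
    slope: float
    rss: float
    censored: bool = False


def percent_activity(record: AssayRecord) -> pd.DataFrame:
    """Percent non-inhibited activity per ouabain concentration:
    100 x (well - background) / (control - background)."""
    span = record.control_absorbance - record.background_absorbance
    if span <= 0:
        raise ValueError(
            f"control <= background for {record.construct} rep "
            f"{record.replicate}: no measurable activity")
    rows = [(conc, np.log10(conc),
             100.0 * (ab - record.background_absorbance) / span)
            for conc, ab in record.dose_absorbance.items()]
    return pd.DataFrame(rows, columns=["conc_M", "log10_conc", "percent"])


def baseline_activity(record: AssayRecord, curve: StandardCurve,
                      volume_uL: float = 1.0) -> ActivityMeasure:
    """Baseline activity from the no-ouabain control well.

    The background-corrected control absorbance is converted to mM Pi via
    the standard curve; 1 mM Pi corresponds to 1 nmol/µL, so nmol released
    = mM x assay volume (µL). The default volume of 1 µL gives the
    volume-free convention activity = mM Pi / (mg x min).
    """
    corrected = record.control_absorbance - record.background_absorbance
    pi_mM = curve.to_mM(corrected + curve.intercept)
    nmol = pi_mM * volume_uL
    act = nmol / (record.protein_mass_mg * record.incubation_min)
    return ActivityMeasure(construct=record.construct,
                           replicate=record.replicate,
                           activity=float(act),
                           below_detection=act <= 0)


def normalize_assay(record: AssayRecord, curve: StandardCurve,
                    volume_uL: float = 1.0):
    """Percent-activity table plus the baseline ActivityMeasure for one
    biological replicate."""
    return percent_activity(record), baseline_activity(record, curve,
                                                       volume_uL=volume_uL)


def logistic4p(log10_conc, log10_ic50, slope):
    """Fixed-asymptote logistic: 100 / (1 + 10^(slope (x - m)))."""
    return 100.0 / (1.0 + 10.0 ** (slope * (log10_conc - log10_ic50)))


def fit_ic50(percent, log10_conc, construct: str = "", replicate: int = 0,
             slope_starts=(0.5, 1.0, 2.0)) -> IC50Fit:
    """Least-squares fit of the fixed-asymptote logistic.

    The slope is constrained positive (inhibition); fits whose midpoint
    lands at or above the highest tested concentration are censored: the
    IC50 is not measurable within the tested range.
    """
    y = np.asarray(percent, float)
    x = np.asarray(log10_conc, float)
    if x.size < 4:
        raise ValueError("need at least 4 concentrations")
    x_max = x.max()

    def resid(theta):
        return logistic4p(x, theta[0], theta[1]) - y

    best = None
    for s0 in slope_starts:
        res = least_squares(resid, x0=[np.median(x), s0],
                            bounds=([-15.0, 1e-3], [6.0, 50.0]),
                            xtol=1e-10, ftol=1e-10, gtol=1e-10)
        if best is None or res.cost < best.cost:
            best = res
    m, s = best.x
    rss = float(2 * best.cost)
    censored = m >= x_max
    return IC50Fit(construct=construct, replicate=replicate,
                   log10_ic50=float(m), slope=float(s), rss=rss,
                   censored=censored)


def ic50_summary(fits) -> pd.DataFrame:
    """Mean and SE of log10 IC50 over biological replicates per construct;
    constructs with any censored replicate are reported censored ('X')."""
    rows = []
    df = pd.DataFrame([f.__dict__ for f in fits])
    for construct, grp in df.groupby("construct"):
        cens = bool(grp.censored.any())
        vals = grp.log10_ic50
        rows.append((construct, np.nan if cens else vals.mean(),
                     np.nan if cens else vals.sem(), len(grp), cens))
    return pd.DataFrame(rows, columns=["construct", "log10_ic50_mean",
                                       "log10_ic50_se", "n", "censored"])


def paired_t_bonferroni(wild_type, mutant, n_tests: int = 15):
    """Two-sided paired t-test with a Bonferroni multiplier.

    Returns (t, raw p, Bonferroni-adjusted p, flag). Zero-variance
    differences are guarded: identical vectors give p = 1; identical
    nonzero shifts give p -> 0 with a flag.
    """
    w = np.asarray(wild_type, float)
    m = np.asarray(mutant, float)
    if w.shape != m.shape or w.size < 2:
        raise ValueError("need >= 2 paired replicates")
    d = m - w
    if np.allclose(d.std(ddof=1), 0.0):
        if np.allclose(d, 0.0):
            return 0.0, 1.0, 1.0, "zero-diff"
        return np.inf, 0.0, 0.0, "zero-variance"
    t, p = stats.ttest_rel(m, w)
    return float(t), float(p), float(min(1.0, p * n_tests)), "ok"


def epistasis_anova(df: pd.DataFrame, response: str = "value") -> float:
    """Background-dependence (epistasis) test: p-value of the background x
    substitution interaction in a two-factor linear model.

    ``df`` needs columns background, has_state (whether the construct
    carries the focal derived state; reverse substitutions are aligned to
    the forward direction by this coding) and the response column.
    """
    import statsmodels.formula.api as smf
    from statsmodels.stats.anova import anova_lm
    data = df.rename(columns={response: "_y"})
    counts = data.groupby(["background", "has_state"]).size().unstack()
    if counts.isna().any().any():
        raise ValueError("empty design cell: every background needs both "
                         "with- and without-state measurements")
    fit = smf.ols("_y ~ C(background) * C(has_state)", data=data).fit()
    table = anova_lm(fit, typ=2)
    inter = [i for i in table.index if ":" in i][0]
    return float(table.loc[inter, "PR(>F)"])


def direction_binomial(n_decrease: int, n_increase: int) -> float:
    """Exact two-sided binomial test at p = 0.5: twice the smaller tail,
    capped at 1."""
    n = n_decrease + n_increase
    if n < 1:
        raise ValueError("need at least one observation")
    k = max(n_decrease, n_increase)
    tail = stats.binom.sf(k - 1, n, 0.5)
    return float(min(1.0, 2.0 * tail))


def pvalue_uniformity(p_values, n_bins: int = 5):
    """Chi-squared goodness-of-fit of p-values against uniform on [0, 1]
    with equal-width bins; df = n_bins - 1."""
    p = np.asarray(p_values, float)
    if p.size < 5:
        raise ValueError("need at least 5 p-values")
    counts, _ = np.histogram(p, bins=n_bins, range=(0.0, 1.0))
    stat, pval = stats.chisquare(counts)
    return float(stat), float(pval)


def derived_state_resistance_correlation(n_derived, log10_ic50,
                                         n_perm: int | None = None,
                                         seed: int | None = None):
    """Spearman correlation between the number of derived states at the
    two key sites (0/1/2) and log10 IC50 across wild-type enzymes, with an
    optional permutation p-value for small panels."""
    x = np.asarray(n_derived, float)
    y = np.asarray(log10_ic50, float)
    if x.size < 4:
        raise ValueError("need at least 4 enzymes")
    if np.std(x) == 0 or np.std(y) == 0:
        return float("nan"), float("nan")
    rho, p = stats.spearmanr(x, y)
    if n_perm:
        rng = np.random.default_rng(seed)
        null = np.array([stats.spearmanr(x, rng.permutation(y)).statistic
                         for _ in range(n_perm)])
        p = (1 + np.sum(np.abs(null) >= abs(rho))) / (1 + n_perm)
    return float(rho), float(p)
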