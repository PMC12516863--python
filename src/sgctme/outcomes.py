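"""Per-patient aggregation, group comparison, and survival analysis.

Cell-type (or cellular-neighborhood) frequencies are computed per ROI,
aggregated as per-patient medians, compared across groups with
Mann-Whitney-U / Kruskal-Wallis tests under Benjamini-Hochberg correction,
correlated with ECM module eigengenes (Spearman), and dichotomized at the
median (positive-vs-zero when the median is 0) for Kaplan-Meier, log-rank
(two- or one-sided), and Cox proportional-hazards analyses with
complete-separation detection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from scipy import stats
from statsmodels.stats.multitest import multipletests

FIVE_YEARS_MONTHS = 60.0


def roi_fractions(cells: pd.DataFrame, label_col: str = "label_final",
                  vocabulary=None) -> pd.DataFrame:
    """Per-ROI cell-type fraction vectors (rows sum to 1)."""
    counts = (cells.groupby(["patient_id", "roi_id"])[label_col]
              .value_counts().unstack(fill_value=0))
    if vocabulary is not None:
        counts = counts.reindex(columns=list(vocabulary), fill_value=0)
    frac = counts.div(counts.sum(axis=1), axis=0)
    assert np.allclose(frac.sum(axis=1), 1.0)
    return frac


def per_patient_frequencies(cells: pd.DataFrame,
                            label_col: str = "label_final",
                            vocabulary=None,
                            primaries_only: bool = False,
                            primary_flag_col: str = "is_primary",
                            ) -> pd.DataFrame:
    """Median across each patient's ROIs of the per-ROI fractions."""
    if primaries_only:
        if primary_flag_col not in cells.columns:
            raise KeyError(f"missing column {primary_flag_col}")
        cells = cells[cells[primary_flag_col].astype(bool)]
        if cells.empty:
            raise ValueError("no primary ROIs present")
    frac = roi_fractions(cells, label_col, vocabulary)
    return frac.groupby(level="patient_id").median()


def compare_groups(frequencies: pd.DataFrame, groups: pd.Series,
                   mode: str = "auto") -> pd.DataFrame:
    """Per-cell-type group comparison with BH adjustment across types.

    Mann-Whitney U for two groups, Kruskal-Wallis for more; groups with
    fewer than 2 observations skip the test for that type with a warning.
    """
    groups = groups.loc[frequencies.index]
    names = [g for g in pd.unique(groups) if pd.notna(g)]
    if len(names) < 2:
        raise ValueError("need at least 2 groups")
    if mode == "auto":
        mode = "two-group" if len(names) == 2 else "multi-group"
    rows = []
    for ct in frequencies.columns:
        samples = [frequencies.loc[groups == g, ct].dropna() for g in names]
        if any(len(s) < 2 for s in samples):
            warnings.warn(f"group with < 2 observations; skipping {ct}",
                          stacklevel=2)
            continue
        if all(s.nunique() == 1 for s in samples) and \
                len(set(s.iloc[0] for s in samples)) == 1:
            stat, p = 0.0, 1.0
        elif mode == "two-group":
            stat, p = stats.mannwhitneyu(samples[0], samples[1],
                                         alternative="two-sided")
        else:
            stat, p = stats.kruskal(*samples)
        rows.append({"cell_type": ct, "statistic": float(stat),
                     "p": float(p)})
    if not rows:
        return pd.DataFrame(columns=["statistic", "p", "p_adj"],
                            index=pd.Index([], name="cell_type"))
    out = pd.DataFrame(rows).set_index("cell_type")
    out["p_adj"] = multipletests(out["p"], method="fdr_bh")[1]
    return out


def spearman_vs_eigengenes(frequencies: pd.DataFrame,
                           eigengenes: pd.DataFrame) -> pd.DataFrame:
    """Spearman rho of each cell type against each ECM module eigengene.

    BH correction spans the whole matrix (one family per correlation
    table).  Requires >= 3 overlapping samples.
    """
    common = frequencies.index.intersection(eigengenes.index)
    if len(common) < 3:
        raise ValueError("fewer than 3 overlapping samples")
    f, e = frequencies.loc[common], eigengenes.loc[common]
    rows = []
    for ct in f.columns:
        for mod in e.columns:
            rho, p = stats.spearmanr(f[ct], e[mod])
            rows.append({"cell_type": ct, "module": mod,
                         "rho": float(rho), "p": float(p)})
    out = pd.DataFrame(rows)
    out["p_adj"] = multipletests(out["p"], method="fdr_bh")[1]
    return out


def dichotomize_median(values: pd.Series) -> pd.Series:
    """Median split; when the median is 0, positive-vs-zero instead.

    Values above the cut are "high", ties go to "low".
    """
    if len(values) < 2:
        raise ValueError("need at least 2 patients")
    if values.nunique() == 1:
        raise ValueError("constant values cannot be dichotomized")
    med = values.median()
    cut = 0.0 if med == 0 else med
    return pd.Series(np.where(values > cut, "high", "low"),
                     index=values.index, name="group")


# ---------------------------------------------------------------------------
# survival


def km_estimate(times, events, eval_times=(FIVE_YEARS_MONTHS,)):
    """Product-limit survival estimate plus rates at requested times.

    Returns (step-function table with columns time / survival, dict of
    survival at each eval time).  Survival at 60 months is the five-year
    rate.
    """
    kmf = KaplanMeierFitter()
    kmf.fit(np.asarray(times, dtype=float), np.asarray(events, dtype=bool))
    table = kmf.survival_function_.reset_index()
    table.columns = ["time", "survival"]
    at = {float(t): float(kmf.predict(float(t))) for t in eval_times}
    return table, at


def logrank(times_a, events_a, times_b, events_b,
            sidedness: str = "two") -> tuple[float, float]:
    """Log-rank test between two groups.

    Returns (chi-square statistic, p).  One-sided tests the alternative
    that group A has the higher hazard (worse survival); its p comes from
    the signed normal deviate z = (O_A - E_A) / sqrt(V).
    """
    ta = np.asarray(times_a, dtype=float)
    tb = np.asarray(times_b, dtype=float)
    ea = np.asarray(events_a, dtype=bool)
    eb = np.asarray(events_b, dtype=bool)
    if ea.sum() + eb.sum() == 0:
        raise ValueError("log-rank requires at least one event")

    t = np.concatenate([ta, tb])
    e = np.concatenate([ea, eb])
    g = np.concatenate([np.ones(len(ta), bool), np.zeros(len(tb), bool)])
    o_minus_e, var = 0.0, 0.0
    for tj in np.unique(t[e]):
        at_risk = t >= tj
        n = at_risk.sum()
        n_a = (at_risk & g).sum()
        d = (e & (t == tj)).sum()
        d_a = (e & (t == tj) & g).sum()
        o_minus_e += d_a - d * n_a / n
        if n > 1:
            var += d * (n_a / n) * (1 - n_a / n) * (n - d) / (n - 1)
    if var == 0:
        return 0.0, 1.0
    z = o_minus_e / np.sqrt(var)
    chi2 = z * z
    if sidedness == "two":
        return float(chi2), float(stats.chi2.sf(chi2, df=1))
    if sidedness == "one":
        return float(chi2), float(stats.norm.sf(z))
    raise ValueError("sidedness must be 'two' or 'one'")


@dataclass
class CoxResult:
    table: pd.DataFrame            # per covariate: hr, ci_low, ci_high, p
    excluded: dict                 # covariate -> reason
    n_events: int


def _separated(cov: pd.Series, events: np.ndarray) -> bool:
    """Binary covariate level holding all or none of the events."""
    vals = pd.unique(cov)
    if len(vals) != 2:
        return False
    for v in vals:
        level_events = events[cov == v].sum()
        if level_events == events.sum() or level_events == 0:
            return True
    return False


def cox_fit(covariates: pd.DataFrame, times, events,
            mode: str = "multivariate") -> CoxResult:
    """Cox proportional-hazards fit with complete-separation detection.

    Binary covariates whose levels contain all or none of the events (or
    that leave the partial likelihood unbounded) are flagged and excluded
    from the fit, mirroring how N stage had to be dropped in practice.
    ``mode='univariate'`` fits each covariate alone.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if events.sum() == 0:
        raise ValueError("Cox regression requires at least one event")

    excluded = {}
    usable = []
    for c in covariates.columns:
        col = covariates[c]
        if col.nunique() <= 1:
            excluded[c] = "constant covariate"
        elif _separated(col, events):
            excluded[c] = "complete separation"
        else:
            usable.append(c)

    def fit_one(cols):
        df = covariates[cols].astype(float).copy()
        df["T"] = times
        df["E"] = events.astype(int)
        cph = CoxPHFitter()
        cph.fit(df, duration_col="T", event_col="E")
        s = cph.summary
        return pd.DataFrame({
            "hr": np.exp(s["coef"]),
            "ci_low": np.exp(s["coef lower 95%"]),
            "ci_high": np.exp(s["coef upper 95%"]),
            "p": s["p"],
        })

    tables = []
    targets = [[c] for c in usable] if mode == "univariate" else \
        ([usable] if usable else [])
    for cols in targets:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                tables.append(fit_one(cols))
        except (ConvergenceError, ValueError) as err:
            for c in cols:
                excluded[c] = f"did not converge ({err.__class__.__name__})"
    table = (pd.concat(tables) if tables else
             pd.DataFrame(columns=["hr", "ci_low", "ci_high", "p"]))
    return CoxResult(table=table, excluded=excluded,
                     n_events=int(events.sum()))
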