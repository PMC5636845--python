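"""Repeated-measures evaluation of the brain-age estimate.

Serial recordings within an infant are not independent, so the agreement
between EMA and post-menstrual age is summarised with a linear mixed
model — fixed slope of EMA over PMA, random intercept per infant — and
the adjusted correlation is the Pearson correlation between PMA and the
random-intercept-corrected EMA.  Error metrics, serial-growth
classification and paired montage comparisons (Wilcoxon signed-rank on
per-recording squared errors) complete the report.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sstats

__all__ = [
    "EvaluationReport",
    "fit_lmm",
    "error_metrics",
    "growth_analysis",
    "evaluate_ema_table",
    "compare_montages",
]


@dataclass
class EvaluationReport:
    """Headline agreement metrics for an EMA table."""

    mse_days2: float
    adjusted_r: float
    sd_days: float
    se_percent: float
    bias_days: float
    pct_within_1wk: float
    pct_within_2wk: float
    n_recordings: int
    n_infants: int
    lmm_slope: float = float("nan")
    lmm_slope_ci: tuple[float, float] = (float("nan"), float("nan"))
    growth: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        out = {k: v for k, v in self.__dict__.items() if k != "growth"}
        out["lmm_slope_ci"] = list(self.lmm_slope_ci)
        out["growth"] = dict(self.growth)
        return out


def fit_lmm(
    ema_days: np.ndarray,
    pma_days: np.ndarray,
    infant_ids: np.ndarray,
) -> dict:
    """Random-intercept mixed model EMA ~ PMA, REML.

    Fits ``EMA_ij = b0 + b1 * PMA_ij + u_i + e_ij`` with a random
    intercept per infant and returns the fixed slope with its 95% CI and
    the adjusted correlation: Pearson r between PMA and ``EMA - u_i``
    (the per-infant offsets absorbed before correlating).  A singular fit
    (zero intercept variance) falls back to ordinary least squares with a
    warning.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    df = pd.DataFrame(
        {"ema": np.asarray(ema_days, dtype=float),
         "pma": np.asarray(pma_days, dtype=float),
         "infant": np.asarray(infant_ids)}
    )
    if df["infant"].nunique() < 2 or len(df) < 3:
        raise ValueError("mixed model needs >= 2 infants and >= 3 recordings")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = smf.mixedlm("ema ~ pma", df, groups=df["infant"])
            fit = model.fit(reml=True)
        singular = not np.isfinite(fit.cov_re.iloc[0, 0]) or fit.cov_re.iloc[0, 0] <= 0
    except Exception:
        singular = True
        fit = None
    if singular or fit is None:
        warnings.warn(
            "singular mixed-model fit: falling back to ordinary regression",
            stacklevel=2,
        )
        ols = sm.OLS(df["ema"], sm.add_constant(df["pma"])).fit()
        r = float(np.corrcoef(df["pma"], df["ema"])[0, 1])
        ci = ols.conf_int().loc["pma"]
        return {
            "adjusted_r": r,
            "slope": float(ols.params["pma"]),
            "slope_ci": (float(ci[0]), float(ci[1])),
            "intercept_sd": 0.0,
            "residual_sd": float(np.sqrt(ols.mse_resid)),
            "random_intercepts": {g: 0.0 for g in df["infant"].unique()},
        }
    re = {g: float(v.iloc[0]) for g, v in fit.random_effects.items()}
    corrected = df["ema"] - df["infant"].map(re)
    r = float(np.corrcoef(df["pma"], corrected)[0, 1])
    ci = fit.conf_int().loc["pma"]
    return {
        "adjusted_r": r,
        "slope": float(fit.params["pma"]),
        "slope_ci": (float(ci[0]), float(ci[1])),
        "intercept_sd": float(np.sqrt(fit.cov_re.iloc[0, 0])),
        "residual_sd": float(np.sqrt(fit.scale)),
        "random_intercepts": re,
    }


def error_metrics(ema_days: np.ndarray, pma_days: np.ndarray) -> dict:
    """Per-recording error summary between EMA and PMA.

    ``mse`` in days², ``bias`` (mean error) and ``sd`` (error standard
    deviation) in days, ``se_percent`` the mean absolute error as a
    percentage of mean PMA, and the share of recordings within one and
    two weeks of the true age.
    """
    ema = np.asarray(ema_days, dtype=float)
    pma = np.asarray(pma_days, dtype=float)
    if ema.shape != pma.shape:
        raise ValueError("ema and pma must have the same length")
    e = ema - pma
    return {
        "mse": float(np.mean(e**2)),
        "bias": float(np.mean(e)),
        "sd": float(np.std(e, ddof=1)) if e.size > 1 else 0.0,
        "se_percent": float(100.0 * np.mean(np.abs(e)) / np.mean(pma)),
        "pct_within_1wk": float(100.0 * np.mean(np.abs(e) <= 7.0)),
        "pct_within_2wk": float(100.0 * np.mean(np.abs(e) <= 14.0)),
    }


def growth_analysis(ema_table: pd.DataFrame, outlier_days: float = 14.0) -> dict:
    """Serial-growth classification of per-infant EMA trajectories.

    For every infant with >= 2 recordings (ordered by PMA): does the EMA
    increase between first and last recording, and per consecutive pair?
    A decreasing pair is attributed to an outlier recording when either
    endpoint deviates from its PMA by more than ``outlier_days``.
    """
    df = ema_table.sort_values(["infant_id", "pma_days"])
    n_inc_first_last = 0
    n_serial = 0
    inc_pairs = 0
    dec_pairs = 0
    dec_with_outlier = 0
    outliers = []
    single = 0
    for infant, g in df.groupby("infant_id"):
        if len(g) < 2:
            single += 1
            continue
        n_serial += 1
        ema = g["ema_days"].to_numpy()
        pma = g["pma_days"].to_numpy()
        if ema[-1] > ema[0]:
            n_inc_first_last += 1
        dev = np.abs(ema - pma) > outlier_days
        for rid, d in zip(g["recording_id"], dev):
            if d:
                outliers.append(rid)
        for k in range(len(ema) - 1):
            if ema[k + 1] > ema[k]:
                inc_pairs += 1
            else:
                dec_pairs += 1
                if dev[k] or dev[k + 1]:
                    dec_with_outlier += 1
    return {
        "n_infants_serial": n_serial,
        "n_single_recording": single,
        "n_increasing_first_last": n_inc_first_last,
        "pct_increasing_first_last": (
            100.0 * n_inc_first_last / n_serial if n_serial else float("nan")
        ),
        "n_pairs": inc_pairs + dec_pairs,
        "n_increasing_pairs": inc_pairs,
        "n_deviant_pairs": dec_pairs,
        "n_deviant_pairs_outlier_attributed": dec_with_outlier,
        "outlier_recordings": sorted(set(outliers)),
    }


def evaluate_ema_table(ema_table: pd.DataFrame) -> EvaluationReport:
    """Full repeated-measures evaluation of an EMA table."""
    ema = ema_table["ema_days"].to_numpy(dtype=float)
    pma = ema_table["pma_days"].to_numpy(dtype=float)
    lmm = fit_lmm(ema, pma, ema_table["infant_id"].to_numpy())
    err = error_metrics(ema, pma)
    return EvaluationReport(
        mse_days2=err["mse"],
        adjusted_r=lmm["adjusted_r"],
        sd_days=err["sd"],
        se_percent=err["se_percent"],
        bias_days=err["bias"],
        pct_within_1wk=err["pct_within_1wk"],
        pct_within_2wk=err["pct_within_2wk"],
        n_recordings=len(ema_table),
        n_infants=ema_table["infant_id"].nunique(),
        lmm_slope=lmm["slope"],
        lmm_slope_ci=lmm["slope_ci"],
        growth=growth_analysis(ema_table),
    )


def paired_signed_rank(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test for paired samples.

    Zero differences are dropped (Wilcoxon convention); all-zero
    differences return statistic 0 with p = 1 (the variants are
    identical).
    """
    d = np.asarray(x, dtype=float) - np.asarray(y, dtype=float)
    if np.all(d == 0):
        return 0.0, 1.0
    res = sstats.wilcoxon(d, zero_method="wilcox", alternative="two-sided")
    return float(res.statistic), float(res.pvalue)


def compare_montages(
    ema_tables: dict[str, pd.DataFrame],
    reference: str,
) -> pd.DataFrame:
    """Per-montage evaluation with a paired test against the reference.

    ``ema_tables`` maps montage names to LOIO EMA tables over the same
    recordings.  Each variant is evaluated and its per-recording squared
    errors compared with the reference montage by a two-sided Wilcoxon
    signed-rank test; recordings missing from a variant are dropped from
    the pairing with a warning.
    """
    if reference not in ema_tables:
        raise KeyError(f"reference montage {reference!r} missing")
    ref = ema_tables[reference].set_index("recording_id")
    ref_se = (ref["ema_days"] - ref["pma_days"]) ** 2
    rows = []
    for name, table in ema_tables.items():
        t = table.set_index("recording_id")
        common = ref_se.index.intersection(t.index)
        if len(common) < len(ref_se) or len(common) < len(t):
            warnings.warn(
                f"montage {name!r}: unpaired recordings dropped from the test",
                stacklevel=2,
            )
        se = (t.loc[common, "ema_days"] - t.loc[common, "pma_days"]) ** 2
        if name == reference:
            stat, p = 0.0, 1.0
        else:
            stat, p = paired_signed_rank(se.to_numpy(), ref_se.loc[common].to_numpy())
        report = evaluate_ema_table(table)
        rows.append(
            {
                "montage": name,
                "n_recordings": report.n_recordings,
                "mse_days2": report.mse_days2,
                "adjusted_r": report.adjusted_r,
                "signed_rank_stat": stat,
                "p_value": p,
            }
        )
    return pd.DataFrame(rows)
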