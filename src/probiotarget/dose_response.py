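"""Growth-inhibition analytics: percent inhibition, MIC calling, IC50 fits.

A microplate table holds OD600 readings per (drug, concentration, replicate)
with a role column (treated / growth_control / blank).  Percent inhibition
is (1 - OD_treated / OD_control) x 100 relative to the drug-free growth
control; the MIC is the lowest tested concentration reaching >= 90% mean
inhibition; IC50 comes from a four-parameter log-logistic (LL4) least-
squares fit; per-concentration treated-vs-control comparisons use Welch
t-tests with Benjamini–Hochberg correction across concentrations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.stats.multitest import multipletests

PLATE_COLUMNS = ("drug", "concentration_ug_ml", "replicate", "od600", "role")


def validate_plate(plate: pd.DataFrame) -> pd.DataFrame:
    missing = set(PLATE_COLUMNS) - set(plate.columns)
    if missing:
        raise ValueError(f"plate table missing columns: {sorted(missing)}")
    if not np.isfinite(plate["concentration_ug_ml"]).all():
        raise ValueError("concentrations must be finite")
    if (plate["concentration_ug_ml"] < 0).any():
        raise ValueError("concentrations must be >= 0")
    for drug, sub in plate.groupby("drug"):
        if not (sub["role"] == "growth_control").any():
            raise ValueError(f"drug {drug!r} has no growth_control wells")
    return plate


def percent_inhibition(od_treated, od_control) -> float | np.ndarray:
    """Inhibition (%) = (1 - OD_treated / OD_control) x 100.

    May be negative (growth stimulation); never clamped.
    """
    od_control = np.asarray(od_control, dtype=float)
    if np.any(od_control <= 0):
        raise ValueError("od_control must be > 0")
    value = (1.0 - np.asarray(od_treated, dtype=float) / od_control) * 100.0
    return value.item() if value.ndim == 0 else value


def inhibition_table(plate: pd.DataFrame, drug: str) -> pd.DataFrame:
    """Per-well percent inhibition against the mean drug-free control OD."""
    validate_plate(plate)
    sub = plate[plate["drug"] == drug]
    control = sub.loc[sub["role"] == "growth_control", "od600"].mean()
    treated = sub[sub["role"] == "treated"].copy()
    treated["inhibition_pct"] = percent_inhibition(treated["od600"], control)
    return treated


def call_mic(inhibition_by_concentration: pd.Series, threshold: float = 90.0) -> float | None:
    """Lowest tested concentration with mean inhibition >= threshold.

    ``inhibition_by_concentration`` maps concentration -> mean inhibition %.
    Returns None when no concentration reaches the threshold ("not reached").
    """
    if len(inhibition_by_concentration) < 2:
        raise ValueError("need inhibition at >= 2 concentrations")
    series = inhibition_by_concentration.sort_index()
    hits = series[series >= threshold]
    return None if hits.empty else float(hits.index[0])


def ll4(x, b, c, d, e):
    """Four-parameter log-logistic: c + (d - c) / (1 + exp(b (ln x - ln e))).

    At x = 0 the curve takes its limiting asymptote (d for b > 0, c for
    b < 0); at x = e the response is midway between c and d.
    """
    x = np.asarray(x, dtype=float)
    with np.errstate(divide="ignore", over="ignore"):
        u = np.exp(b * (np.log(np.where(x > 0, x, np.nan)) - np.log(e)))
        core = c + (d - c) / (1.0 + u)
    limit = d if b > 0 else c  # x -> 0+ limit
    return np.where(x > 0, core, limit)


@dataclass
class DoseResponseFit:
    """LL4 fit result.  ``e`` is the inflection = IC50 (half-maximal dose).

    The model is fitted with the inflection on the log scale (the
    parameterization recommended for dose-scale inference, since the
    sampling distribution of a concentration parameter is right-skewed);
    ``log_ic50``/``log_ic50_se`` are the fitted parameter and its standard
    error, ``ic50_se`` the natural-scale delta-method transform.
    """

    b: float
    c: float
    d: float
    e: float
    ic50: float
    ic50_se: float
    log_ic50: float
    log_ic50_se: float
    converged: bool
    response: str  # "inhibition" or "od"
    message: str = ""

    def predict(self, x):
        return ll4(x, self.b, self.c, self.d, self.e)


def fit_ic50(
    plate: pd.DataFrame,
    drug: str,
    response: str = "inhibition",
    use_replicates: bool = True,
) -> DoseResponseFit:
    """Fit an LL4 curve and report the IC50 with its standard error.

    Default response is replicate-level percent inhibition (growth controls
    enter at concentration 0); ``response="od"`` fits raw OD600 instead.
    All four parameters are free.  Non-convergence returns a flagged fit
    rather than raising.
    """
    validate_plate(plate)
    sub = plate[plate["drug"] == drug]
    if response == "od":
        x = sub["concentration_ug_ml"].to_numpy(float)
        y = sub["od600"].to_numpy(float)
    elif response == "inhibition":
        control = sub.loc[sub["role"] == "growth_control", "od600"].mean()
        treated = sub[sub["role"] == "treated"]
        x = np.concatenate(
            [
                treated["concentration_ug_ml"].to_numpy(float),
                np.zeros((sub["role"] == "growth_control").sum()),
            ]
        )
        y = np.concatenate(
            [
                percent_inhibition(treated["od600"].to_numpy(float), control),
                percent_inhibition(
                    sub.loc[sub["role"] == "growth_control", "od600"].to_numpy(float), control
                ),
            ]
        )
    else:
        raise ValueError("response must be 'inhibition' or 'od'")

    if not use_replicates:
        means = pd.DataFrame({"x": x, "y": y}).groupby("x")["y"].mean()
        x, y = means.index.to_numpy(float), means.to_numpy(float)

    if len(np.unique(x)) < 4 or 0.0 not in x:
        raise ValueError("need >= 4 distinct concentrations including 0")

    pos = x[x > 0]
    le0 = float(np.mean(np.log(pos)))
    if response == "od":
        p0 = (1.0, float(y.min()), float(y.max()), le0)  # decreasing, b > 0
    else:
        p0 = (-1.0, float(y.min()), float(y.max()), le0)  # increasing, b < 0

    def model(x_, b_, c_, d_, le_):
        return ll4(x_, b_, c_, d_, np.exp(le_))

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, pcov = optimize.curve_fit(
                model, x, y, p0=p0, maxfev=20000, xtol=1e-13, ftol=1e-13
            )
        b, c, d, le = (float(v) for v in popt)
        e = float(np.exp(le))
        se_le = float(np.sqrt(pcov[3, 3])) if np.all(np.isfinite(pcov)) else float("nan")
        se = e * se_le  # delta method back to the concentration scale
        converged = e > 0 and np.isfinite(e) and np.isfinite(se)
        # the fitted curve must describe an actual inhibitory effect:
        # inhibition rising (OD falling) from the zero-dose limit
        y_zero = d if b > 0 else c
        y_inf = c if b > 0 else d
        effect_ok = (y_inf > y_zero) if response == "inhibition" else (y_inf < y_zero)
        converged = converged and effect_ok
        msg = "" if converged else "IC50 not estimable from the fitted curve"
        return DoseResponseFit(b, c, d, e, e, se, le, se_le, converged, response, msg)
    except (RuntimeError, ValueError) as err:
        nan = float("nan")
        return DoseResponseFit(
            nan, nan, nan, nan, nan, nan, nan, nan, False, response, str(err)
        )


def treated_vs_control_tests(plate: pd.DataFrame, drug: str) -> pd.DataFrame:
    """Welch t-test of treated OD vs control OD per concentration, with
    Benjamini–Hochberg adjustment across the drug's concentrations."""
    validate_plate(plate)
    sub = plate[plate["drug"] == drug]
    control = sub.loc[sub["role"] == "growth_control", "od600"].to_numpy(float)
    rows = []
    for conc, grp in sub[sub["role"] == "treated"].groupby("concentration_ug_ml"):
        vals = grp["od600"].to_numpy(float)
        if len(vals) < 2 or len(control) < 2:
            warnings.warn(f"<2 replicates at {conc} ug/mL: p-value missing")
            rows.append({"concentration_ug_ml": conc, "p": np.nan})
            continue
        if np.ptp(vals) == 0 and np.ptp(control) == 0 and vals[0] == control[0]:
            p = 1.0  # identical groups: t = 0 by convention
        else:
            p = float(stats.ttest_ind(vals, control, equal_var=False).pvalue)
        rows.append({"concentration_ug_ml": conc, "p": p})
    out = pd.DataFrame(rows).sort_values("concentration_ug_ml").reset_index(drop=True)
    mask = out["p"].notna()
    out["p_adj"] = np.nan
    if mask.any():
        out.loc[mask, "p_adj"] = multipletests(out.loc[mask, "p"], method="fdr_bh")[1]
    return out
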