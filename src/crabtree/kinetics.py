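"""Quantitative physiology of aerobic batch fermentations.

Operations over fermenter time courses (biomass, glucose, ethanol, acetate,
CFU counts) and off-gas profiles (inlet/outlet O2 and CO2 mole fractions):

* maximum specific growth rate mu_max from a sliding log-linear fit,
* product and biomass yields on glucose (g/g) over the consumption phase,
* specific rates q_s = mu/Y_xs and q_p = q_s * Y_ps (g per g biomass per h),
* oxygen transfer rate (OTR) and CO2 evolution rate (CER) in mM/L/h from
  the gas balance, optionally inert-gas corrected,
* respiratory quotient RQ = integrated CER / integrated OTR,
* diauxic switch time from glucose exhaustion to the onset of ethanol
  consumption,
* phase-truncated Pearson correlations (glucose vs ethanol/acetate during
  production; ethanol vs bacterial death until ethanol decline).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

#: molar volume of an ideal gas at 25 degC, 1 atm (L/mol)
MOLAR_VOLUME_25C = 24.45

#: residual glucose below this (g/L) counts as exhaustion
GLUCOSE_EXHAUSTION_THRESHOLD = 0.1


@dataclass
class GrowthFit:
    mu_max: float          # 1/h
    window: tuple[int, int]  # [start, stop) sample indices of the fitted window
    r_squared: float
    degraded: bool = False   # no window met the R^2 floor; best window returned


def _window_fit(t: np.ndarray, ln_x: np.ndarray) -> tuple[float, float]:
    """OLS slope and R^2 for one window; R^2 = 1 on a zero-variance response."""
    slope, intercept = np.polyfit(t, ln_x, 1)
    resid = ln_x - (slope * t + intercept)
    ss_res = float(resid @ resid)
    ss_tot = float(((ln_x - ln_x.mean()) ** 2).sum())
    if ss_tot <= 1e-30:
        return slope, 1.0
    return slope, 1.0 - ss_res / ss_tot


def specific_growth_rate(tc: pd.DataFrame, *, biomass_col: str = "biomass_dw",
                         min_points: int = 4,
                         r2_floor: float = 0.98) -> GrowthFit:
    """Maximum specific growth rate from sliding log-linear regressions.

    ln(biomass) is regressed on time over every contiguous window of at
    least ``min_points`` samples; the maximum slope among windows with
    R^2 >= ``r2_floor`` is returned.  If no window clears the floor the
    best-R^2 window is returned with ``degraded=True``.
    """
    df = tc[["time", biomass_col]].dropna()
    mask = df[biomass_col] > 0
    t = df.loc[mask, "time"].to_numpy(float)
    x = df.loc[mask, biomass_col].to_numpy(float)
    if len(t) < min_points:
        raise ValueError(f"need >= {min_points} positive biomass points, have {len(t)}")
    ln_x = np.log(x)
    best_ok: GrowthFit | None = None
    best_any: GrowthFit | None = None
    n = len(t)
    for start in range(n - min_points + 1):
        for stop in range(start + min_points, n + 1):
            slope, r2 = _window_fit(t[start:stop], ln_x[start:stop])
            fit = GrowthFit(float(slope), (start, stop), float(r2))
            if r2 >= r2_floor and (best_ok is None or slope > best_ok.mu_max):
                best_ok = fit
            if best_any is None or r2 > best_any.r_squared:
                best_any = fit
    if best_ok is not None:
        return best_ok
    assert best_any is not None
    return GrowthFit(best_any.mu_max, best_any.window, best_any.r_squared,
                     degraded=True)


def _exhaustion_index(glucose: np.ndarray,
                      threshold: float = GLUCOSE_EXHAUSTION_THRESHOLD) -> int | None:
    below = np.flatnonzero(glucose < threshold)
    return int(below[0]) if below.size else None


def product_yield(tc: pd.DataFrame, product: str, substrate: str = "glucose",
                  *, exhaustion_threshold: float = GLUCOSE_EXHAUSTION_THRESHOLD
                  ) -> float:
    """Yield Y_ps (g product per g substrate) over the consumption phase.

    Y = (peak product - initial product) / (initial substrate - substrate at
    the product peak), with the peak sought between t = 0 and substrate
    exhaustion (or the end of the series if the substrate never runs out).
    ``product`` may also be a biomass column to obtain Y_xs.
    """
    df = tc[["time", substrate, product]].dropna()
    s = df[substrate].to_numpy(float)
    p = df[product].to_numpy(float)
    if len(s) < 2:
        raise ValueError("need at least 2 samples")
    end = _exhaustion_index(s, exhaustion_threshold)
    end = len(s) - 1 if end is None else end
    peak = int(np.argmax(p[: end + 1]))
    if p[peak] <= p[0]:          # product never rises: yield is zero
        peak = end
        if s[0] - s[peak] <= 0:
            raise ValueError(f"no {substrate} consumed; yield undefined")
        return 0.0
    d_s = s[0] - s[peak]
    if d_s <= 0:
        raise ValueError(f"no {substrate} consumed by the {product} peak; "
                         "yield undefined")
    return float((p[peak] - p[0]) / d_s)


def specific_rates(mu_max: float, y_xs: float, y_ps: float = 0.0
                   ) -> tuple[float, float]:
    """Specific substrate uptake and product formation rates.

    q_s = mu_max / Y_xs and q_p = q_s * Y_ps, both in g per g biomass per
    hour — the standard Pirt relations for balanced exponential growth.
    """
    if y_xs <= 0:
        raise ValueError("Y_xs must be positive")
    q_s = mu_max / y_xs
    return q_s, q_s * y_ps


def otr_cer(gp: pd.DataFrame, *, inert_correction: bool = True,
            molar_volume: float = MOLAR_VOLUME_25C) -> pd.DataFrame:
    """Oxygen transfer and CO2 evolution rates (mM/L/h) from the gas balance.

    CER = F/(V*Vm) * (y_co2_out - y_co2_in) * 1000.  OTR uses the inert-gas
    balance by default: the outlet molar flow differs from the inlet
    whenever OTR != CER, and the ratio of inert fractions
    (1 - y_o2_in - y_co2_in)/(1 - y_o2_out - y_co2_out) corrects for it:
    OTR = F/(V*Vm) * (y_o2_in - y_o2_out * inert_ratio) * 1000.  With
    ``inert_correction=False`` the simple difference (y_o2_in - y_o2_out)
    is used for OTR.
    """
    flow = gp["gas_flow"].to_numpy(float)
    vol = gp["volume"].to_numpy(float)
    if np.any(flow <= 0) or np.any(vol <= 0):
        raise ValueError("gas_flow and volume must be positive")
    y_o2_in = gp["y_o2_in"].to_numpy(float)
    y_o2_out = gp["y_o2_out"].to_numpy(float)
    y_co2_in = gp["y_co2_in"].to_numpy(float)
    y_co2_out = gp["y_co2_out"].to_numpy(float)
    base = flow / (vol * molar_volume) * 1000.0   # mmol total gas / L / h
    cer = base * (y_co2_out - y_co2_in)
    if inert_correction:
        inert_out = 1.0 - y_o2_out - y_co2_out
        if np.any(inert_out <= 0):
            raise ValueError("inert-gas fraction at the outlet must be positive")
        inert_ratio = (1.0 - y_o2_in - y_co2_in) / inert_out
        otr = base * (y_o2_in - y_o2_out * inert_ratio)
    else:
        otr = base * (y_o2_in - y_o2_out)
    return pd.DataFrame({"time": gp["time"], "OTR": otr, "CER": cer})


def respiratory_quotient(rates: pd.DataFrame,
                         window: tuple[float, float] | None = None) -> float:
    """RQ = time-integrated CER / time-integrated OTR over a time window.

    ``rates`` is the output of :func:`otr_cer`.  ``window`` is (t_start,
    t_stop) in hours; default is the whole profile.  Samples with OTR <= 0
    are trimmed with a warning (RQ is undefined without O2 consumption).
    RQ = 1 marks fully respiratory metabolism; Crabtree-positive yeasts in
    glucose excess reach 2 or more.
    """
    t = rates["time"].to_numpy(float)
    otr = rates["OTR"].to_numpy(float)
    cer = rates["CER"].to_numpy(float)
    if window is not None:
        mask = (t >= window[0]) & (t <= window[1])
        t, otr, cer = t[mask], otr[mask], cer[mask]
    pos = otr > 0
    if not pos.all():
        warnings.warn(f"trimmed {int((~pos).sum())} samples with OTR <= 0 "
                      "from the RQ window", stacklevel=2)
        t, otr, cer = t[pos], otr[pos], cer[pos]
    if len(t) < 2:
        raise ValueError("RQ window has fewer than 2 usable samples")
    o2 = float(np.trapezoid(otr, t))
    co2 = float(np.trapezoid(cer, t))
    if o2 <= 0:
        raise ValueError("integrated OTR is not positive; RQ undefined")
    return co2 / o2


def _sustained_decrease_start(series: np.ndarray, start: int = 0) -> int | None:
    """Index where a run of >= 2 strictly decreasing steps begins, or None."""
    for i in range(start, len(series) - 2):
        if series[i + 1] < series[i] and series[i + 2] < series[i + 1]:
            return i
    return None


def switch_time(tc: pd.DataFrame, gas_rates: pd.DataFrame | None = None, *,
                exhaustion_threshold: float = GLUCOSE_EXHAUSTION_THRESHOLD,
                use_gas: bool = False) -> float:
    """Diauxic switch time (h): glucose exhaustion to ethanol-consumption onset.

    Exhaustion is the first sample with glucose below the threshold
    (default 0.1 g/L).  Onset is the start of a sustained ethanol decrease
    (two consecutive strictly decreasing steps, robust to single-point
    noise).  With ``use_gas=True`` and an :func:`otr_cer` table, onset is
    instead the first sustained CER recovery after its post-exhaustion drop.
    """
    glucose = tc["glucose"].to_numpy(float)
    t = tc["time"].to_numpy(float)
    exhaust = _exhaustion_index(glucose, exhaustion_threshold)
    if exhaust is None:
        raise ValueError("glucose never drops below the exhaustion threshold")
    t_exhaust = t[exhaust]
    if use_gas:
        if gas_rates is None:
            raise ValueError("use_gas=True requires an OTR/CER table")
        gt = gas_rates["time"].to_numpy(float)
        cer = gas_rates["CER"].to_numpy(float)
        # CER collapses at glucose exhaustion; onset is its first sustained
        # recovery (two consecutive strictly increasing steps) afterwards
        after = int(np.searchsorted(gt, t_exhaust))
        rise = _sustained_decrease_start(-cer, start=after)
        if rise is None:
            raise ValueError("no CER recovery after the post-exhaustion drop")
        return float(gt[rise] - t_exhaust)
    ethanol = tc["ethanol"].to_numpy(float)
    onset = _sustained_decrease_start(ethanol, start=exhaust)
    if onset is None:
        raise ValueError("no sustained ethanol decrease after glucose "
                         "exhaustion; onset absent")
    return float(t[onset] - t_exhaust)


def bacterial_death(log_cfu: np.ndarray | pd.Series) -> np.ndarray:
    """Cumulative death signal: running-peak log10 CFU minus current log10 CFU."""
    arr = np.asarray(log_cfu, dtype=float)
    return np.maximum.accumulate(arr) - arr


@dataclass
class PhaseCorrelation:
    r_squared: float
    p_value: float
    sign: int            # sign of Pearson r; 0 when undefined
    n_points: int
    t_stop: float        # end of the truncated window (h)
    defined: bool = True


def phase_correlation(tc: pd.DataFrame, var_a: str, var_b: str,
                      rule: str = "until_decrease_of_b") -> PhaseCorrelation:
    """Pearson correlation of two time-course variables over a phase window.

    The window runs from t = 0 until a rule-determined stop:

    * ``"until_decrease_of_b"`` — until ``var_b`` begins a sustained
      decrease (used for glucose vs ethanol/acetate during production);
    * ``"until_ethanol_decline"`` — until the ethanol column begins a
      sustained decrease (used for ethanol vs bacterial death).

    ``var_b`` (or ``var_a``) named ``"bacterial_death"`` is computed from
    the ``bacteria_cfu`` column as the cumulative peak-to-date log10 CFU
    decline.  Reported as R^2 with the sign of r carried separately.
    """
    df = tc.copy()
    for v in (var_a, var_b):
        if v == "bacterial_death":
            df["bacterial_death"] = bacterial_death(df["bacteria_cfu"])
    t = df["time"].to_numpy(float)
    if rule == "until_decrease_of_b":
        marker = df[var_b].to_numpy(float)
    elif rule == "until_ethanol_decline":
        marker = df["ethanol"].to_numpy(float)
    else:
        raise ValueError(f"unknown truncation rule {rule!r}")
    stop = _sustained_decrease_start(marker)
    stop = len(t) if stop is None else stop + 1   # include the last pre-decline point
    a = df[var_a].to_numpy(float)[:stop]
    b = df[var_b].to_numpy(float)[:stop]
    keep = np.isfinite(a) & np.isfinite(b)
    a, b = a[keep], b[keep]
    if len(a) < 3:
        raise ValueError(f"fewer than 3 points in the truncated window "
                         f"(rule {rule!r})")
    if np.all(a == a[0]) or np.all(b == b[0]):
        return PhaseCorrelation(float("nan"), float("nan"), 0, len(a),
                                float(t[min(stop, len(t)) - 1]), defined=False)
    r, p = stats.pearsonr(a, b)
    return PhaseCorrelation(float(r * r), float(p), int(np.sign(r)), len(a),
                            float(t[min(stop, len(t)) - 1]))


def fold_change_vs_reference(value: float, reference: float) -> float:
    """Ratio of a quantity (e.g. an ethanol yield) to a reference strain's."""
    if reference <= 0:
        raise ValueError("reference must be positive")
    return value / reference


def kinetics_summary(tc: pd.DataFrame, gp: pd.DataFrame | None = None,
                     products: tuple[str, ...] = ("ethanol", "acetate",
                                                  "glycerol", "pyruvate"),
                     ) -> pd.DataFrame:
    """One-row-per-metric summary of a fermentation run (TSV-friendly)."""
    rows: list[tuple[str, float, str]] = []
    fit = specific_growth_rate(tc)
    rows.append(("mu_max", fit.mu_max, "1/h"))
    rows.append(("mu_max_r_squared", fit.r_squared, ""))
    y_xs = product_yield(tc, "biomass_dw")
    rows.append(("Y_xs", y_xs, "g/g"))
    for prod in products:
        if prod in tc.columns and tc[prod].notna().any():
            y = product_yield(tc, prod)
            rows.append((f"Y_{prod}", y, "g/g"))
            q_s, q_p = specific_rates(fit.mu_max, y_xs, y)
            rows.append((f"q_{prod}", q_p, "g/g/h"))
    rows.append(("q_glucose", specific_rates(fit.mu_max, y_xs)[0], "g/g/h"))
    try:
        rows.append(("switch_time", switch_time(tc), "h"))
    except ValueError:
        pass
    if gp is not None:
        rates = otr_cer(gp)
        t_ex = None
        ex = _exhaustion_index(tc["glucose"].to_numpy(float))
        if ex is not None:
            t_ex = float(tc["time"].iloc[ex])
        window = (0.0, t_ex) if t_ex else None
        rows.append(("RQ", respiratory_quotient(rates, window), ""))
        rows.append(("OTR_max", float(rates["OTR"].max()), "mM/L/h"))
        rows.append(("CER_max", float(rates["CER"].max()), "mM/L/h"))
    return pd.DataFrame(rows, columns=["metric", "value", "unit"])
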