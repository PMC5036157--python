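"""Growth, enzyme activity, secretion and expression analyses.

Growth trajectories are fit to a logistic model N(t) = K / (1 + ((K -
N0)/N0) exp(-r t)) by multi-start nonlinear least squares; trajectories
that peak and then decline (cell clumping or death) fall back to an
exponential fit restricted to the ascending window. Lag time uses the
classic tangent construction on log-density: the tangent at the point of
maximum log-slope is intersected with the initial observed log-density,
and the crossing time (floored at zero) is the lag. Genotype-phenotype
association uses Fisher's exact test; bulk enzyme activity is the slope
of the most linear window of the A235 curve normalised by culture
density; qPCR expression uses efficiency-corrected ratios against
reference genes with a label-permutation p-value.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats


@dataclass
class GrowthCurve:
    strain: str
    substrate: str
    fraction: str
    replicate: int
    time: np.ndarray  # hours, strictly increasing
    od: np.ndarray  # OD600 readings

    def __post_init__(self):
        self.time = np.asarray(self.time, float)
        self.od = np.asarray(self.od, float)
        if len(self.time) < 6:
            raise ValueError("need at least 6 time points")
        if not (np.diff(self.time) > 0).all():
            raise ValueError("times must be strictly increasing")
        if (self.od < 0).any():
            raise ValueError("negative OD readings")


@dataclass
class GrowthFit:
    r: float  # exponential-phase rate, 1/h
    K: float
    n0: float
    lag: float  # hours; NaN when no growth
    model: str  # logistic | exponential | none
    rmse: float
    converged: bool


def _logistic(t, r, K, n0):
    return K / (1.0 + ((K - n0) / n0) * np.exp(-r * t))


def _peak_decline(od: np.ndarray) -> int | None:
    """Index of the peak if the curve then declines >=10% with >=2 points."""
    i = int(np.argmax(od))
    if i <= 1 or i >= len(od) - 2:
        return None
    tail = od[i + 1:]
    if tail.min() <= od[i] * 0.9:
        return i
    return None


def fit_growth(
    curve: GrowthCurve,
    no_growth_rate: float = 1e-3,
    n_starts: int = 5,
) -> GrowthFit:
    """Fit one replicate's trajectory; never raises on non-convergence."""
    t, y = curve.time, curve.od
    peak = _peak_decline(y)
    if peak is not None:
        return _fit_exponential(t, y, peak)

    span = y.max() - y.min()
    if span <= max(1e-12, 0.02 * y.max()):
        return GrowthFit(0.0, float(y.mean()), float(y.mean()),
                         float("nan"), "none", float(np.std(y)), True)

    k0 = y.max()
    n00 = max(y[0], 1e-6)
    # crude rate guesses from the log-slope plus geometric alternatives
    with np.errstate(divide="ignore"):
        ly = np.log(np.clip(y, 1e-12, None))
    slopes = np.diff(ly) / np.diff(t)
    r_guess = max(float(np.nanmax(slopes)), 1e-3)
    starts = [(r_guess, k0, n00)]
    for f in (0.3, 3.0, 10.0, 0.1):
        starts.append((r_guess * f, k0, n00))
    best = None
    for r0, K0, N0 in starts[:n_starts]:
        try:
            popt, _ = optimize.curve_fit(
                _logistic, t, y, p0=[r0, K0, N0],
                bounds=([1e-6, 1e-9, 1e-12], [20.0, 100.0, 10.0]),
                maxfev=20000,
            )
        except (RuntimeError, ValueError):
            continue
        resid = y - _logistic(t, *popt)
        sse = float(resid @ resid)
        if best is None or sse < best[0]:
            best = (sse, popt)
    if best is None:
        return GrowthFit(float("nan"), float("nan"), float("nan"),
                         float("nan"), "logistic", float("nan"), False)
    sse, (r, K, n0) = best
    rmse = float(np.sqrt(sse / len(y)))
    if r <= no_growth_rate or (K - n0) < 1e-6:
        return GrowthFit(float(r), float(K), float(n0), float("nan"),
                         "none", rmse, True)
    lag = _tangent_lag(t, y, lambda tt: _logistic(tt, r, K, n0))
    return GrowthFit(float(r), float(K), float(n0), lag, "logistic", rmse, True)


def _fit_exponential(t, y, peak: int) -> GrowthFit:
    """Exponential fit restricted to the ascending window before the peak."""
    tw, yw = t[: peak + 1], y[: peak + 1]
    pos = yw > 0
    tw, yw = tw[pos], yw[pos]
    if len(tw) < 3:
        return GrowthFit(float("nan"), float("nan"), float("nan"),
                         float("nan"), "exponential", float("nan"), False)
    # drop the flat (lag) part: keep from the last reading within 20% of the
    # minimum onwards, so the regression sees the exponential phase
    thresh = yw.min() * 1.2
    start = int(np.where(yw <= thresh)[0][-1]) if (yw <= thresh).any() else 0
    tf, yf = tw[start:], yw[start:]
    if len(tf) < 3:
        tf, yf = tw, yw
    slope, intercept = np.polyfit(tf, np.log(yf), 1)
    if slope <= 0:
        return GrowthFit(0.0, float(y.max()), float(yw[0]), float("nan"),
                         "none", float("nan"), True)
    n0_obs = max(y[0], 1e-12)
    lag = max((np.log(n0_obs) - intercept) / slope, 0.0)
    resid = np.log(yf) - (slope * tf + intercept)
    return GrowthFit(float(slope), float(y.max()), float(np.exp(intercept)),
                     float(lag), "exponential", float(np.sqrt(resid @ resid / len(yf))),
                     True)


def _tangent_lag(t, y, model) -> float:
    """Tangent-intercept lag on the fitted log-density curve."""
    grid = np.linspace(t[0], t[-1], 512)
    ln = np.log(np.clip(model(grid), 1e-300, None))
    dln = np.gradient(ln, grid)
    i = int(np.argmax(dln))
    slope = dln[i]
    if slope <= 0:
        return float("nan")
    baseline = np.log(max(y[0], 1e-12))
    lag = grid[i] + (baseline - ln[i]) / slope
    return float(max(lag, 0.0))


def fit_growth_table(df: pd.DataFrame, **kwargs) -> pd.DataFrame:
    """Fit every (strain, substrate, fraction, replicate) series; then
    average parameters over replicates (technical-replicate convention)."""
    fits = []
    for (strain, substrate, fraction, rep), sub in df.groupby(
        ["strain", "substrate", "fraction", "replicate"], sort=True
    ):
        sub = sub.sort_values("time_h")
        curve = GrowthCurve(strain, substrate, fraction, rep,
                            sub["time_h"].to_numpy(), sub["od600"].to_numpy())
        f = fit_growth(curve, **kwargs)
        fits.append(
            dict(strain=strain, substrate=substrate, fraction=fraction,
                 replicate=rep, r=f.r, K=f.K, n0=f.n0, lag=f.lag,
                 model=f.model, rmse=f.rmse, converged=f.converged)
        )
    per_rep = pd.DataFrame(fits)
    mean = (
        per_rep.groupby(["strain", "substrate", "fraction"], sort=True)
        .agg(r=("r", "mean"), K=("K", "mean"), n0=("n0", "mean"),
             lag=("lag", "mean"), n_replicates=("replicate", "count"))
        .reset_index()
    )
    return per_rep, mean


def classify_growth(
    fits: pd.DataFrame,
    r_min: float = 0.05,
    delta_od_min: float = 0.05,
) -> pd.DataFrame:
    """Growth call per strain x substrate: r >= r_min AND (K - N0) >= delta."""
    out = fits.copy()
    out["grows"] = (out["r"].fillna(0.0) >= r_min) & (
        (out["K"] - out["n0"]).fillna(0.0) >= delta_od_min
    )
    return out


def genotype_phenotype_test(
    table: pd.DataFrame, genotype_col: str, phenotype_col: str
) -> tuple[float, float, np.ndarray]:
    """Two-sided Fisher exact association between genotype and phenotype.

    Returns (odds ratio, p, 2x2 table). The odds ratio is the sample OR
    with a Haldane 0.5 correction when any cell is zero.
    """
    g = table[genotype_col].astype(bool)
    ph = table[phenotype_col].astype(bool)
    if g.all() or (~g).all():
        raise ValueError(f"degenerate margin: all strains share {genotype_col}")
    a = int((g & ph).sum())
    b = int((g & ~ph).sum())
    c = int((~g & ph).sum())
    d = int((~g & ~ph).sum())
    tab = np.array([[a, b], [c, d]])
    _, p = stats.fisher_exact(tab, alternative="two-sided")
    if min(a, b, c, d) == 0:
        orr = (a + 0.5) * (d + 0.5) / ((b + 0.5) * (c + 0.5))
    else:
        orr = a * d / (b * c)
    return float(orr), float(p), tab


def fisher_pit(table: np.ndarray, u: float) -> float:
    """Randomized probability-integral transform of the two-sided Fisher p.

    Conditional on the margins, ``P(point(X) < point(a)) + u * P(point(X)
    = point(a))`` is exactly uniform under independence (``u`` ~
    Uniform(0,1)); the plain two-sided p is discrete and conservative, so
    its raw distribution is not uniform even when the computation is
    correct. Used to verify calibration.
    """
    (a, b), (c, d) = np.asarray(table, dtype=int)
    n = a + b + c + d
    r1, c1 = a + b, a + c
    lo, hi = max(0, c1 - (n - r1)), min(r1, c1)
    support = np.arange(lo, hi + 1)
    probs = stats.hypergeom.pmf(support, n, r1, c1)
    obs = probs[support == a][0]
    tol = obs * 1e-10
    p_lt = probs[probs < obs - tol].sum()
    p_eq = probs[np.abs(probs - obs) <= tol].sum()
    return float(p_lt + u * p_eq)


def build_pheno_geno_table(
    copy_numbers: pd.DataFrame, growth_calls: pd.DataFrame,
    aly_families=("PL6", "PL7"), oal_families=("PL15", "PL17"),
) -> pd.DataFrame:
    """Strain table of pathway genotype flags joined with growth booleans."""
    aly = [f for f in aly_families if f in copy_numbers.columns]
    oal = [f for f in oal_families if f in copy_numbers.columns]
    geno = pd.DataFrame(
        dict(
            has_aly=copy_numbers[aly].sum(axis=1) > 0 if aly else False,
            has_oal=copy_numbers[oal].sum(axis=1) > 0 if oal else False,
        ),
        index=copy_numbers.index,
    ).rename_axis("strain")
    wide = growth_calls.pivot_table(
        index="strain", columns="substrate", values="grows", aggfunc="any"
    )
    wide.columns = [f"grows_{c}" for c in wide.columns]
    return geno.join(wide, how="inner").reset_index()


# ---------------------------------------------------------------------------
# enzyme activity


def activity_slope(
    times_min: np.ndarray,
    a235: np.ndarray,
    od600: float,
    min_window: int = 5,
    r2_min: float = 0.99,
) -> tuple[float, bool]:
    """Slope of the most linear A235 window, normalised by OD600.

    The linear part is the longest contiguous window (>= min_window
    points) whose least-squares fit reaches R^2 >= r2_min; among
    equal-length windows the steepest wins, then the earliest. Only
    windows with positive slope qualify: product absorbance cannot
    genuinely decline, so flat or falling stretches (saturation, substrate
    exhaustion) are not the activity phase. If no window qualifies the
    global fit is used and flagged low-quality. Invariant to a constant
    baseline shift. Returns (normalised slope, quality flag).
    """
    t = np.asarray(times_min, float)
    y = np.asarray(a235, float)
    if len(t) < min_window:
        raise ValueError(f"need at least {min_window} points")
    if od600 <= 0:
        raise ValueError("od600 must be positive")
    if float(((y - y.mean()) ** 2).sum()) == 0.0:
        return 0.0, True  # constant series: no activity
    best = None  # (length, |slope|, -start, slope)
    n = len(t)
    for length in range(n, min_window - 1, -1):
        for start in range(0, n - length + 1):
            tw, yw = t[start:start + length], y[start:start + length]
            slope, intercept = np.polyfit(tw, yw, 1)
            pred = slope * tw + intercept
            ss_res = float(((yw - pred) ** 2).sum())
            ss_tot = float(((yw - yw.mean()) ** 2).sum())
            flat_tol = (1e-9 * max(float(np.abs(yw).max()), 1e-300)) ** 2 * len(yw)
            if ss_tot <= flat_tol or slope <= 0:
                continue  # plateau/decline is not the activity phase
            r2 = 1.0 - ss_res / ss_tot
            if r2 >= r2_min:
                cand = (length, abs(slope), -start, slope)
                if best is None or cand[:3] > best[:3]:
                    best = cand
        if best is not None:
            break  # longest qualifying length found
    if best is not None:
        return float(best[3] / od600), True
    slope, _ = np.polyfit(t, y, 1)
    return float(slope / od600), False


def halo_ratio(
    colony_area: float,
    halo_area: float,
    broadcaster_min: float = 1.1,
    super_broadcaster_min: float = 5.0,
) -> tuple[float, str]:
    """Halo/colony area ratio and broadcast class."""
    if colony_area <= 0:
        raise ValueError("colony area must be positive")
    if halo_area < 0:
        raise ValueError("areas must be non-negative")
    ratio = halo_area / colony_area
    if ratio < 1.0:  # measurement artifact: halo cannot be smaller
        ratio = 1.0
    if ratio >= super_broadcaster_min:
        cls = "super-broadcaster"
    elif ratio >= broadcaster_min:
        cls = "broadcaster"
    else:
        cls = "non-broadcaster"
    return float(ratio), cls


# ---------------------------------------------------------------------------
# RT-qPCR expression ratios


def expression_ratio(
    ct: pd.DataFrame,
    efficiencies: dict[str, float],
    reference_genes: tuple[str, ...] = ("rpoD", "gyrB"),
    control: str = "control",
    treated: str = "treated",
    permutations: int = 2000,
    seed: int = 0,
) -> pd.DataFrame:
    """Efficiency-corrected expression ratios with permutation p-values.

    ``ct`` columns: gene, condition, replicate, ct. Ratio per target gene:
    E_t^{dCt_t} / geomean_ref(E_ref^{dCt_ref}) with dCt = mean
    Ct(control) - mean Ct(treated). The p-value randomly reallocates
    replicate samples between the two conditions and counts permutations
    whose |log ratio| strictly exceeds the observed one (ties — including
    the identity and mirror relabellings — are not exceedances; with few
    replicates they would otherwise floor the p-value).
    """
    required = {"gene", "condition", "replicate", "ct"}
    if not required.issubset(ct.columns):
        raise ValueError(f"Ct table needs columns {sorted(required)}")
    for ref in reference_genes:
        if ref not in set(ct["gene"]):
            raise ValueError(f"missing reference gene {ref!r}")
    for g, e in efficiencies.items():
        if not 1.0 <= e <= 2.0:
            raise ValueError(f"amplification efficiency out of [1,2] for {g!r}")
    wide = ct.pivot_table(index=["condition", "replicate"], columns="gene",
                          values="ct")
    ctrl = wide.loc[control]
    trt = wide.loc[treated]
    genes = [g for g in wide.columns if g not in reference_genes]
    rng = np.random.default_rng(seed)

    order = list(wide.columns)
    M = np.vstack([ctrl.to_numpy(), trt.to_numpy()])  # samples x genes
    if np.isnan(M).any():
        raise ValueError("incomplete Ct table")
    n_ctrl, n_total = len(ctrl), len(ctrl) + len(trt)
    log_e = np.array([np.log(efficiencies[g]) for g in order])
    ref_idx = [order.index(r) for r in reference_genes]

    def log_ratios(ctrl_mask: np.ndarray) -> np.ndarray:
        """Per-gene log expression ratio for one condition assignment."""
        dct = M[ctrl_mask].mean(axis=0) - M[~ctrl_mask].mean(axis=0)
        terms = log_e * dct
        return terms - terms[ref_idx].mean()

    base = np.zeros(n_total, dtype=bool)
    base[:n_ctrl] = True
    obs = log_ratios(base)
    exceed = np.zeros(len(order), dtype=int)
    for _ in range(permutations):
        mask = np.zeros(n_total, dtype=bool)
        mask[rng.choice(n_total, n_ctrl, replace=False)] = True
        exceed += np.abs(log_ratios(mask)) > np.abs(obs) + 1e-12
    rows = []
    for g in genes:
        i = order.index(g)
        rows.append(
            dict(gene=g, ratio=float(np.exp(obs[i])),
                 log2_ratio=float(obs[i] / np.log(2)),
                 p_permutation=exceed[i] / permutations)
        )
    return pd.DataFrame(rows, columns=["gene", "ratio", "log2_ratio", "p_permutation"])
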