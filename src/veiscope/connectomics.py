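"""Statistics for pairwise functional-connectomics tables.

The unit of analysis is a neuron pair: a presynaptic neuron whose axon
co-travels with a (potential) postsynaptic partner's dendrite. Connected
pairs carry at least one synapse; axonal-dendritic proximity (ADP) pairs
co-travel without a synapse and control for anatomical opportunity. Because
presynaptic neurons differ in both their functional properties and their
overall synapse budget, pairwise metrics are re-centered per presynaptic
neuron (plus a regional baseline) and synapse counts are adjusted by each
presynaptic neuron's expected conversion rate before any aggregation.

Required table columns: ``presyn_id``, ``postsyn_id``, ``connected``,
``n_syn``, ``co_travel_mm``, plus metric columns such as ``mei_similarity``,
``vei_similarity``, ``diversity_pre``, ``diversity_post``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit


def _check_table(table: pd.DataFrame, columns=()):
    required = {"presyn_id", "connected", "n_syn", "co_travel_mm"} | set(columns)
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"pair table is missing columns: {sorted(missing)}")
    if (table["co_travel_mm"] <= 0).any():
        raise ValueError("co_travel_mm must be positive for every pair")


def adjust_pairwise_metric(table: pd.DataFrame, metric_name: str) -> pd.DataFrame:
    """Per-presynaptic re-centering of a pairwise metric.

    value -> value - mean over that presynaptic neuron's pairs (connected and
    ADP alike) + the global mean over all pairs. The within-presyn ordering is
    preserved (it is a shift) and the grand mean is unchanged.
    """
    _check_table(table, [metric_name])
    out = table.copy()
    presyn_mean = out.groupby("presyn_id")[metric_name].transform("mean")
    global_mean = out[metric_name].mean()
    out[metric_name + "_adj"] = out[metric_name] - presyn_mean + global_mean
    return out


def adjust_synapse_counts(table: pd.DataFrame) -> pd.DataFrame:
    """Adjust observed synapse counts by the presynaptic conversion rate.

    Each presynaptic neuron's conversion rate is its total synapse count over
    its total co-travel distance (across connected and ADP pairs); the
    expected count of a pair is rate x co-travel. adjusted = observed -
    expected + regional_rate x co-travel, which conserves the total count.
    """
    _check_table(table)
    if not table["connected"].any():
        raise ValueError("no connected pairs present")
    out = table.copy()
    grp = out.groupby("presyn_id")
    rate = grp["n_syn"].transform("sum") / grp["co_travel_mm"].transform("sum")
    regional_rate = out["n_syn"].sum() / out["co_travel_mm"].sum()
    out["n_syn_adj"] = (out["n_syn"] - rate * out["co_travel_mm"]
                        + regional_rate * out["co_travel_mm"])
    return out


@dataclass
class ConversionRateCurve:
    bin_edges: np.ndarray
    bin_centers: np.ndarray
    rates: np.ndarray
    rate_sd: np.ndarray
    n_connected: np.ndarray
    kept: np.ndarray                 # boolean per original bin


def conversion_rate_by_bin(table: pd.DataFrame, metric_name: str,
                           bin_edges=None, n_bins: int = 8,
                           min_connected: int = 10, min_fraction: float = 0.025,
                           n_boot: int = 1000, seed: int = 0) -> ConversionRateCurve:
    """Synapse conversion rate (synapses per mm co-travel) binned by a
    pairwise metric, with bootstrap standard deviations.

    Default bin edges are equal-count octiles of the metric among connected
    pairs. A bin is kept only if it holds strictly more than ``min_connected``
    connected pairs and at least ``min_fraction`` of all connected pairs. The
    s.d. is estimated by resampling pairs with replacement and re-binning.
    """
    _check_table(table, [metric_name])
    values = table[metric_name].to_numpy()
    connected = table["connected"].to_numpy(dtype=bool)
    n_syn = table["n_syn"].to_numpy(dtype=float)
    co = table["co_travel_mm"].to_numpy(dtype=float)
    if bin_edges is None:
        qs = np.linspace(0, 1, n_bins + 1)
        bin_edges = np.quantile(values[connected], qs)
        bin_edges[0], bin_edges[-1] = values.min(), values.max()
    bin_edges = np.asarray(bin_edges, dtype=float)
    idx = np.clip(np.searchsorted(bin_edges, values, side="right") - 1,
                  0, len(bin_edges) - 2)

    def binned_rates(sel):
        num = np.bincount(idx[sel], weights=n_syn[sel], minlength=len(bin_edges) - 1)
        den = np.bincount(idx[sel], weights=co[sel], minlength=len(bin_edges) - 1)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(den > 0, num / den, np.nan)

    n_conn_bin = np.bincount(idx[connected], minlength=len(bin_edges) - 1)
    total_conn = connected.sum()
    kept = (n_conn_bin > min_connected) & (n_conn_bin >= min_fraction * total_conn)
    if not kept.any():
        raise ValueError("no bin survives the connected-pair thresholds")
    rates = binned_rates(np.ones_like(connected))

    rng = np.random.default_rng(seed)
    n = len(values)
    boot = np.full((n_boot, len(bin_edges) - 1), np.nan)
    for b in range(n_boot):
        take = rng.integers(0, n, n)
        num = np.bincount(idx[take], weights=n_syn[take], minlength=len(bin_edges) - 1)
        den = np.bincount(idx[take], weights=co[take], minlength=len(bin_edges) - 1)
        with np.errstate(invalid="ignore", divide="ignore"):
            boot[b] = np.where(den > 0, num / den, np.nan)
    sd = np.nanstd(boot, axis=0)
    centers = 0.5 * (bin_edges[:-1] + bin_edges[1:])
    return ConversionRateCurve(
        bin_edges=bin_edges, bin_centers=centers[kept], rates=rates[kept],
        rate_sd=sd[kept], n_connected=n_conn_bin[kept], kept=kept)


def fit_exponential_decay(x, y):
    """Least-squares fit of y = a * exp(-b * x) + c.

    Returns (amplitude, rate, offset, r_squared) with R^2 = 1 - SS_res/SS_tot
    about the mean of y. A negative fitted rate (monotone-increasing data) is
    returned as-is for the caller to flag; constant data yield a ~ 0 and
    R^2 = 0 under the total-variance convention.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 4:
        raise ValueError("need at least 4 points")
    span = y.max() - y.min()
    if span == 0:
        return 0.0, 0.0, float(y.mean()), 0.0
    x_scale = np.ptp(x) if np.ptp(x) > 0 else 1.0
    model = lambda t, a, b, c: a * np.exp(-b * t) + c

    # try decaying and growing initializations; keep the better fit
    starts = [(span, 1.0 / x_scale, y.min()),
              (-span, 1.0 / x_scale, y.max()),
              (span, -1.0 / x_scale, y.min() - span)]
    best, best_sse = None, np.inf
    last_err = None
    for p0 in starts:
        try:
            popt, _ = curve_fit(model, x, y, p0=p0, maxfev=20000)
        except RuntimeError as err:
            last_err = err
            continue
        sse = float(np.sum((y - model(x, *popt)) ** 2))
        if sse < best_sse:
            best, best_sse = popt, sse
    if best is None:
        residual = y - y.mean()
        raise RuntimeError(
            f"exponential fit did not converge (residual s.d. "
            f"{residual.std():.3g})") from last_err
    a, b, c = best
    fit = a * np.exp(-b * x) + c
    ss_res = float(np.sum((y - fit) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    return float(a), float(b), float(c), float(r2)


def bootstrap_mean_difference(group_a, group_b, weights_a=None, weights_b=None,
                              n_resamples: int = 10000, seed: int = 0):
    """Weighted bootstrap of the difference between two group means.

    Each group is resampled with replacement with the given sampling weights
    (e.g. adjusted synapse counts for connected pairs, co-travel distances for
    ADP controls). Returns (observed weighted mean difference, two-sided p),
    with p floored at 1/n_resamples (a value at the floor should be reported
    as a bound, "< 1/n").
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be nonempty")

    def norm_weights(w, n):
        if w is None:
            return np.full(n, 1.0 / n)
        w = np.asarray(w, dtype=float)
        total = w.sum()
        if total <= 0:
            raise ValueError("zero total weight")
        return w / total

    wa = norm_weights(weights_a, len(a))
    wb = norm_weights(weights_b, len(b))
    rng = np.random.default_rng(seed)
    idx_a = rng.choice(len(a), size=(n_resamples, len(a)), p=wa)
    idx_b = rng.choice(len(b), size=(n_resamples, len(b)), p=wb)
    diffs = a[idx_a].mean(axis=1) - b[idx_b].mean(axis=1)
    observed = float(a @ wa - b @ wb)
    p_low = np.mean(diffs <= 0)
    p_high = np.mean(diffs >= 0)
    p = min(1.0, 2.0 * min(p_low, p_high))
    p = max(p, 1.0 / n_resamples)
    return observed, float(p)


def poisson_rate_trend(table: pd.DataFrame, metric_name: str):
    """Test whether the synapse conversion rate increases with a pairwise
    metric, by Poisson regression with presynaptic fixed effects.

    Models the synapse count of every pair (connected and ADP alike) as
    Poisson with log-mean = offset(log co-travel) + presyn intercepts +
    slope * metric, the fixed-effect analogue of a random-intercept model
    (appropriate at the tens-of-presynaptic-neurons scale). Returns
    (slope, two-sided p) for the metric coefficient.
    """
    import statsmodels.api as sm

    _check_table(table, [metric_name])
    presyn = pd.get_dummies(table["presyn_id"], prefix="pre", drop_first=True)
    X = pd.concat([pd.Series(1.0, index=table.index, name="intercept"),
                   table[metric_name].astype(float), presyn.astype(float)],
                  axis=1)
    model = sm.GLM(table["n_syn"].astype(float), X,
                   family=sm.families.Poisson(),
                   offset=np.log(table["co_travel_mm"].astype(float)))
    # quasi-Poisson scale: pair counts are zero-inflated relative to Poisson,
    # and unscaled standard errors would be anti-conservative
    fit = model.fit(scale="X2")
    return float(fit.params[metric_name]), float(fit.pvalues[metric_name])


def load_pair_table(path) -> pd.DataFrame:
    table = pd.read_csv(path)
    _check_table(table)
    bad = table.loc[table["connected"].astype(bool) != (table["n_syn"] >= 1)]
    if len(bad):
        raise ValueError("connected flag must match n_syn >= 1")
    return table
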