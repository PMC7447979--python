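"""Crossover outcome vs repair-template RPA: distance bins, bootstrap CIs,
absolute crossover rates, lifespan least squares, and the crossover feature
regression with stepwise-AIC selection.

The lifespan model: the repair-template RPA signal per DSB in a set of
hotspots is proportional to the average time an inter-homolog intermediate
exists there.  If a fraction ``c`` of DSBs resolves as crossovers (lifespan
``L_co``) and the rest of the inter-homolog intermediates as non-crossovers
(lifespan ``L_nco``), with a fraction ``s`` of DSBs repaired off the sister
(contributing no template RPA), then per DSB

    R = c * L_co + ((1 - s) - c) * L_nco

Groups of hotspots with different crossover rates (e.g. centromere-proximal
vs telomere-proximal bins) give a linear system solved for
``(L_co, L_nco)`` by least squares; only the ratio is identified (the
signal scale is arbitrary).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "LifespanEstimate",
    "equal_signal_bins",
    "bin_fractions",
    "rescale_crossover_rate",
    "estimate_lifespans",
    "crossover_feature_model",
    "select_features",
    "standardize_predictors",
]

DEFAULT_CO_SHARE = 0.10


@dataclass
class LifespanEstimate:
    L_co: float
    L_nco: float
    co_share: float = DEFAULT_CO_SHARE
    sister_fraction: float = 0.0

    @property
    def ratio(self) -> float:
        return self.L_co / self.L_nco


def equal_signal_bins(weights, order_key, n_bins: int = 4) -> np.ndarray:
    """Assign hotspots to ``n_bins`` equal-weight bins along ``order_key``.

    Hotspots are sorted by ``order_key`` (distance to the centromere) and
    split at cumulative-weight quantiles of the DSB-proxy ``weights``; each
    bin's total weight is within one hotspot's weight of ``total/n_bins``.
    Returns per-hotspot bin ids 0..n_bins-1 in the original order.
    """
    weights = np.asarray(weights, dtype=float)
    order_key = np.asarray(order_key, dtype=float)
    if np.any(weights < 0):
        raise ValueError("weights must be nonnegative")
    total = weights.sum()
    if total <= 0:
        raise ValueError("total weight must be positive")
    if np.any(weights > total / n_bins):
        warnings.warn("a single hotspot holds more than a bin's share of the "
                      "total weight; bins will be unbalanced", stacklevel=2)
    order = np.argsort(order_key, kind="stable")
    cum_mid = np.cumsum(weights[order]) - weights[order] / 2.0
    bins_sorted = np.minimum((cum_mid / (total / n_bins)).astype(int), n_bins - 1)
    bins = np.empty(len(weights), dtype=int)
    bins[order] = bins_sorted
    return bins


def bin_fractions(bin_ids, events, n_bins: int = 4, iterations: int = 100_000,
                  seed=None, chunk: int = 2000):
    """Per-bin event fractions with bootstrap 95% CIs.

    ``events`` holds per-hotspot event counts (crossovers, or a signal such
    as repair-template RPA).  The CI resamples *hotspots* with replacement
    from the full set and recomputes the fractions; the hotspot is the
    sampling unit.
    """
    bin_ids = np.asarray(bin_ids)
    events = np.asarray(events, dtype=float)
    total = events.sum()
    if total <= 0:
        raise ValueError("no events")
    onehot = np.zeros((len(events), n_bins))
    onehot[np.arange(len(events)), bin_ids] = events
    fractions = onehot.sum(axis=0) / total
    rng = np.random.default_rng(seed)
    n = len(events)
    boots = np.empty((iterations, n_bins))
    done = 0
    while done < iterations:
        b = min(chunk, iterations - done)
        counts = rng.multinomial(n, np.full(n, 1.0 / n), size=b).astype(float)
        sums = counts @ onehot
        tot = sums.sum(axis=1, keepdims=True)
        tot[tot == 0] = np.nan
        boots[done : done + b] = sums / tot
        done += b
    ci = np.nanpercentile(boots, [2.5, 97.5], axis=0).T
    return fractions, ci


def rescale_crossover_rate(co_counts, dsb_proxy, mean_rate: float = DEFAULT_CO_SHARE):
    """Absolute per-bin crossover probability per DSB.

    Raw per-bin CO/DSB-proxy ratios are multiplied by one constant so that
    the proxy-weighted mean rate equals ``mean_rate`` (the assumed average
    crossover resolution rate, 10%); between-bin ratios are preserved
    exactly.
    """
    co_counts = np.asarray(co_counts, dtype=float)
    dsb_proxy = np.asarray(dsb_proxy, dtype=float)
    if np.any(dsb_proxy <= 0):
        raise ValueError("dsb proxy totals must be positive")
    if co_counts.sum() <= 0:
        raise ValueError("zero crossovers overall")
    raw = co_counts / dsb_proxy
    scale = mean_rate * dsb_proxy.sum() / co_counts.sum()
    return raw * scale


def estimate_lifespans(co_rate, template_rpa, co_share: float = DEFAULT_CO_SHARE,
                       sister_fraction: float = 0.0) -> LifespanEstimate:
    """Least-squares (L_co, L_nco) from per-bin crossover rates and template RPA.

    ``co_rate`` is the absolute crossover probability per DSB in each bin
    (mean across bins typically calibrated to ``co_share`` times the
    inter-homolog share); ``template_rpa`` is repair-template RPA per DSB.
    Sister repair (fraction ``sister_fraction`` of DSBs) contributes no
    template RPA.
    """
    c = np.asarray(co_rate, dtype=float)
    r = np.asarray(template_rpa, dtype=float)
    if len(c) < 2 or np.ptp(c) < 1e-12:
        raise ValueError("crossover rates identical across bins: singular system")
    if np.any(c > 1 - sister_fraction + 1e-12):
        raise ValueError("crossover rate exceeds the inter-homolog share")
    design = np.column_stack([c, (1.0 - sister_fraction) - c])
    (l_co, l_nco), _, _, _ = np.linalg.lstsq(design, r, rcond=None)
    return LifespanEstimate(float(l_co), float(l_nco), co_share, sister_fraction)


def standardize_predictors(X) -> np.ndarray:
    """Center to mean 0 and scale to variance 1, column-wise."""
    X = np.asarray(X, dtype=float)
    sd = X.std(axis=0, ddof=0)
    if np.any(sd == 0):
        raise ValueError("constant predictor cannot be standardized")
    return (X - X.mean(axis=0)) / sd


def crossover_feature_model(X, y, names=None):
    """OLS of per-hotspot crossover counts on standardized recombination measures.

    ``X`` holds the eight measures (H3K4me3, RPA, DMC1, RAD51 on the
    DSB-initiating and repair-template homologs), already standardized to
    mean 0 / variance 1 (validated).  Perfectly collinear columns are
    dropped with a warning.  Returns a fitted statsmodels OLS results
    object with predictor names attached.
    """
    import statsmodels.api as sm

    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if names is None:
        names = [f"x{i}" for i in range(X.shape[1])]
    names = list(names)
    if not (np.allclose(X.mean(axis=0), 0, atol=1e-6)
            and np.allclose(X.std(axis=0, ddof=0), 1, atol=1e-6)):
        raise ValueError("predictors must be standardized to mean 0, variance 1")
    keep = []
    for j in range(X.shape[1]):
        cols = keep + [j]
        if np.linalg.matrix_rank(X[:, cols]) == len(cols):
            keep.append(j)
        else:
            warnings.warn(f"dropping perfectly collinear predictor {names[j]!r}",
                          stacklevel=2)
    Xk = sm.add_constant(X[:, keep])
    res = sm.OLS(y, Xk).fit()
    res.predictor_names = [names[j] for j in keep]
    return res


def select_features(X, y, names=None, direction: str = "both"):
    """Stepwise AIC-minimizing subset search, bidirectional from the full model.

    At each step the single add or drop that lowers AIC most is taken;
    the search stops when no move improves AIC.  Returns
    ``(selected_names, results)``.
    """
    import statsmodels.api as sm

    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if names is None:
        names = [f"x{i}" for i in range(X.shape[1])]
    names = list(names)

    def fit(cols):
        Xc = sm.add_constant(X[:, cols]) if cols else sm.add_constant(
            np.empty((len(y), 0)))
        return sm.OLS(y, Xc).fit()

    current = list(range(X.shape[1]))
    best = fit(current)
    improved = True
    while improved:
        improved = False
        moves = []
        if direction in ("both", "backward"):
            for j in current:
                cols = [c for c in current if c != j]
                moves.append((fit(cols).aic, cols))
        if direction in ("both", "forward"):
            for j in range(X.shape[1]):
                if j not in current:
                    cols = sorted(current + [j])
                    moves.append((fit(cols).aic, cols))
        if moves:
            aic, cols = min(moves, key=lambda t: t[0])
            if aic < best.aic - 1e-9:
                current = cols
                best = fit(current)
                improved = True
    best.predictor_names = [names[j] for j in current]
    return [names[j] for j in current], best
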