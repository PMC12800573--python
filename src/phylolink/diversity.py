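"""Incidence-based rarefaction and extrapolation of trait richness.

Sample-based (incidence) rarefaction over strains: the expected number of
traits (e.g. gene cluster families) seen in a random subset of t of the T
strains, computed from the hypergeometric expectation

    S(t) = S_obs − Σ_i C(T − Y_i, t) / C(T, t),

where Y_i is the number of strains carrying trait i.  Extrapolation beyond
T uses the Chao2 incidence estimator built from the uniques Q1 (traits in
exactly one strain) and duplicates Q2 (exactly two):

    Chao2 = S_obs + ((T − 1)/T) · Q1² / (2 Q2)          (Q2 > 0)
    Chao2 = S_obs + ((T − 1)/T) · Q1 (Q1 − 1) / 2       (Q2 = 0, bias-corrected)

    S(T + m) = S_obs + Q0 · [1 − (1 − Q1 / (Q1 + T·Q0))^m],   Q0 = Chao2 − S_obs.

Only richness (Hill order q = 0) is computed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .io import PhylolinkError, TraitMatrix

__all__ = ["IncidenceCurve", "incidence_rarefaction", "chao2"]


@dataclass
class IncidenceCurve:
    """Rarefaction/extrapolation curve of trait richness over strains."""

    sizes: np.ndarray  # strain counts
    estimates: np.ndarray  # expected richness at each size
    segment: list[str]  # "rarefied" | "extrapolated"
    s_obs: int
    chao2: float
    q1: int
    q2: int
    n_strains: int
    lower: np.ndarray | None = None  # bootstrap CI, present only if requested
    upper: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        cols = {"size": self.sizes, "q0_estimate": self.estimates,
                "segment": self.segment}
        if self.lower is not None:
            cols["lower"] = self.lower
            cols["upper"] = self.upper
        return pd.DataFrame(cols)

    def plot(self, ax=None, label: str | None = None, color=None):
        """Plot the curve: solid rarefied part, dashed extrapolation,
        shaded confidence band if present.  Requires matplotlib."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        seg = np.array(self.segment)
        rare = seg == "rarefied"
        (line,) = ax.plot(self.sizes[rare], self.estimates[rare], "-",
                          color=color, label=label)
        color = line.get_color()
        if (~rare).any():
            join = np.r_[np.flatnonzero(rare)[-1:], np.flatnonzero(~rare)]
            ax.plot(self.sizes[join], self.estimates[join], "--", color=color)
        if self.lower is not None:
            ax.fill_between(self.sizes, self.lower, self.upper,
                            color=color, alpha=0.2, linewidth=0)
        ax.set_xlabel("number of strains")
        ax.set_ylabel("trait richness (q = 0)")
        return ax


def chao2(s_obs: int, t: int, q1: int, q2: int) -> float:
    """Chao2 asymptotic richness from uniques/duplicates incidence counts."""
    if t < 1:
        raise PhylolinkError("need at least one sampling unit")
    k = (t - 1) / t
    if q2 > 0:
        return s_obs + k * q1 * q1 / (2.0 * q2)
    return s_obs + k * q1 * (q1 - 1) / 2.0


def _log_comb(n: np.ndarray, k: float) -> np.ndarray:
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def incidence_rarefaction(
    matrix: TraitMatrix,
    extrapolate_to: int | None = None,
    sizes: np.ndarray | None = None,
    n_bootstrap: int = 0,
    ci: float = 0.95,
    seed: int = 0,
) -> IncidenceCurve:
    """Rarefy (and optionally extrapolate) trait richness over strains.

    ``extrapolate_to`` must be >= the number of strains; sizes beyond it use
    the Chao2-based estimator and are labelled "extrapolated".  Traits with
    zero incidences contribute nothing (they are invisible to incidence
    data).  ``n_bootstrap > 0`` adds percentile confidence bands from
    resampling strains with replacement (off by default).
    """
    data = matrix.data.to_numpy()
    if data.size == 0:
        raise PhylolinkError("empty trait matrix")
    T = data.shape[0]
    y = data.sum(axis=0)
    y = y[y > 0]
    s_obs = int(y.size)
    if s_obs == 0:
        raise PhylolinkError("matrix has no incidences")
    q1 = int((y == 1).sum())
    q2 = int((y == 2).sum())
    s_inf = chao2(s_obs, T, q1, q2)
    q0 = s_inf - s_obs
    if extrapolate_to is None:
        extrapolate_to = T
    if extrapolate_to < T:
        raise PhylolinkError("extrapolate_to must be >= number of strains")
    if sizes is None:
        sizes = np.arange(1, extrapolate_to + 1)
    sizes = np.asarray(sizes, dtype=np.int64)
    est = np.empty(sizes.shape, dtype=float)
    segment = []
    for i, t in enumerate(sizes):
        if t <= T:
            # hypergeometric expectation; C(T - y_i, t) = 0 when T - y_i < t
            keep = (T - y) >= t
            terms = np.zeros(y.shape)
            if keep.any():
                terms[keep] = np.exp(
                    _log_comb((T - y[keep]).astype(float), float(t))
                    - (gammaln(T + 1) - gammaln(t + 1) - gammaln(T - t + 1))
                )
            est[i] = s_obs - terms.sum()
            segment.append("rarefied")
        else:
            m = t - T
            if q0 <= 0 or q1 == 0:
                est[i] = float(s_obs)
            else:
                est[i] = s_obs + q0 * (1.0 - (1.0 - q1 / (q1 + T * q0)) ** m)
            segment.append("extrapolated")
    lower = upper = None
    if n_bootstrap > 0:
        rng = np.random.default_rng(seed)
        reps = np.empty((n_bootstrap, sizes.size))
        for b in range(n_bootstrap):
            rows = rng.integers(0, T, size=T)
            boot = TraitMatrix(
                matrix.data.iloc[rows].set_axis(
                    [f"b{i}" for i in range(T)], axis=0
                ),
                matrix.kind,
            )
            try:
                reps[b] = incidence_rarefaction(
                    boot, extrapolate_to=extrapolate_to, sizes=sizes
                ).estimates
            except PhylolinkError:
                reps[b] = np.nan
        # resampling duplicates strains and so underestimates richness;
        # use the bootstrap for spread only, centering the band on the
        # analytic estimate (centered percentile band)
        q = (1 - ci) / 2
        delta = reps - np.nanmean(reps, axis=0, keepdims=True)
        lower = est + np.nanquantile(delta, q, axis=0)
        upper = est + np.nanquantile(delta, 1 - q, axis=0)
    return IncidenceCurve(
        sizes=sizes, estimates=est, segment=segment, s_obs=s_obs,
        chao2=float(s_inf), q1=q1, q2=q2, n_strains=T,
        lower=lower, upper=upper,
    )
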