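"""Limit-of-detection estimation from mixture ensembles.

Two estimators are provided, mirroring the two ways a dilution limit is read
off in analytical verification of a binary classifier:

* the **90%-concordance rule**: simulate mixtures over a grid of diluent
  fractions, compute at each fraction the share of simulated mixtures whose
  call agrees with the parent's reference label, and report the most diluted
  fraction at which that concordance is still >= 0.90. Monte-Carlo noise can
  make the raw concordance curve non-monotone, so a decreasing isotonic
  regression is applied before thresholding. Confidence intervals come from a
  within-grid-point bootstrap of the simulated calls.

* **spline boundary crossing**: for measured (fraction, score) series, fit a
  cubic smoothing spline (smoothing chosen by generalized cross-validation)
  and locate by root finding the smallest fraction at which the fitted curve
  crosses the decision boundary away from the parent's side.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline, make_smoothing_spline
from scipy.optimize import brentq
from sklearn.isotonic import IsotonicRegression

from .classifier import ClassifierModel, score_counts

__all__ = [
    "ConcordanceCurve",
    "LODEstimate",
    "concordance_curve",
    "curve_from_calls",
    "estimate_lod",
    "lod_bootstrap_ci",
    "spline_crossing",
]

_EPS = 1e-9


@dataclass
class ConcordanceCurve:
    """Concordance frequency with the parent's call over a fraction grid."""

    fractions: np.ndarray
    concordance: np.ndarray
    n_simulations: np.ndarray
    reference_call: str
    concordant_counts: np.ndarray = field(default=None)  # per-point successes

    def __post_init__(self) -> None:
        f = np.asarray(self.fractions, dtype=float)
        c = np.asarray(self.concordance, dtype=float)
        n = np.asarray(self.n_simulations, dtype=int)
        if f.ndim != 1 or len(f) < 2:
            raise ValueError("need at least 2 grid points")
        if np.any(np.diff(f) <= 0):
            raise ValueError("fraction grid must be strictly increasing")
        if np.any((c < 0) | (c > 1)):
            raise ValueError("concordance values must lie in [0, 1]")
        if np.any(n < 1):
            raise ValueError("every grid point needs a nonempty ensemble")
        self.fractions, self.concordance, self.n_simulations = f, c, n
        if self.concordant_counts is None:
            self.concordant_counts = np.round(c * n).astype(int)
        else:
            self.concordant_counts = np.asarray(self.concordant_counts, dtype=int)


@dataclass
class LODEstimate:
    """A limit of detection: the most diluted fraction still called correctly."""

    point: float
    lower: float | None = None
    upper: float | None = None
    threshold: float = 0.90
    method: str = "concordance"
    n_bootstrap: int = 0
    detected: bool = True

    def __post_init__(self) -> None:
        if self.method == "concordance" and not 0.5 < self.threshold < 1.0:
            raise ValueError("concordance threshold must lie in (0.5, 1)")
        if self.lower is not None and self.upper is not None and self.detected:
            if not self.lower - _EPS <= self.point <= self.upper + _EPS:
                raise ValueError("CI must bracket the point estimate")

    def to_dict(self) -> dict:
        return {
            "point": self.point, "lower": self.lower, "upper": self.upper,
            "threshold": self.threshold, "method": self.method,
            "n_bootstrap": self.n_bootstrap, "detected": self.detected,
        }


def concordance_curve(
    ensembles: dict[float, pd.DataFrame],
    model: ClassifierModel,
    reference_call: str,
) -> ConcordanceCurve:
    """Score every simulated mixture and tally agreement with the parent call."""
    if len(ensembles) < 2:
        raise ValueError("need ensembles at >= 2 grid points")
    fractions = np.array(sorted(ensembles), dtype=float)
    conc, n, succ = [], [], []
    for f in fractions:
        ens = ensembles[float(f)]
        if ens.shape[1] == 0:
            raise ValueError(f"empty ensemble at fraction {f}")
        calls = score_counts(model, ens)["call"].to_numpy()
        k = int((calls == reference_call).sum())
        succ.append(k)
        n.append(ens.shape[1])
        conc.append(k / ens.shape[1])
    return ConcordanceCurve(
        fractions=fractions,
        concordance=np.array(conc),
        n_simulations=np.array(n),
        reference_call=reference_call,
        concordant_counts=np.array(succ),
    )


def curve_from_calls(
    fractions, concordant: np.ndarray, reference_call: str = "UIP"
) -> ConcordanceCurve:
    """Build a curve from a (grid points x simulations) boolean call matrix."""
    concordant = np.asarray(concordant, dtype=bool)
    n = np.full(concordant.shape[0], concordant.shape[1])
    k = concordant.sum(axis=1)
    return ConcordanceCurve(
        fractions=np.asarray(fractions, dtype=float),
        concordance=k / n,
        n_simulations=n,
        reference_call=reference_call,
        concordant_counts=k,
    )


def _threshold_scan(fractions, smoothed, threshold) -> tuple[float, bool]:
    ok = smoothed >= threshold - _EPS
    if not ok.any():
        return 0.0, False
    return float(fractions[ok].max()), True


def estimate_lod(curve: ConcordanceCurve, threshold: float = 0.90) -> LODEstimate:
    """Most diluted fraction with (isotonically smoothed) concordance >= threshold.

    The raw curve is projected onto the decreasing monotone cone (weighted by
    per-point simulation counts) before the threshold scan; on deterministic
    decreasing curves this is the identity and the estimator reduces to a grid
    scan. If no point qualifies the LOD is 0 with ``detected=False``.
    """
    iso = IsotonicRegression(increasing=False, y_min=0.0, y_max=1.0)
    smoothed = iso.fit_transform(
        curve.fractions, curve.concordance, sample_weight=curve.n_simulations
    )
    point, detected = _threshold_scan(curve.fractions, smoothed, threshold)
    return LODEstimate(point=point, threshold=threshold, detected=detected)


def lod_bootstrap_ci(
    curve: ConcordanceCurve,
    threshold: float = 0.90,
    n_bootstrap: int = 500,
    seed: int = 0,
) -> LODEstimate:
    """Percentile bootstrap CI for the 90%-rule LOD.

    The bootstrap unit is the individual simulated mixture: calls are
    resampled with replacement within each grid point. Because each call is
    binary, resampling n_i calls with replacement is exactly a
    Binomial(n_i, c_i) draw on the concordant count, which is what is
    implemented (vectorized over bootstrap replicates).
    """
    if n_bootstrap < 100:
        raise ValueError("n_bootstrap must be >= 100")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 606]))
    n = curve.n_simulations
    k = curve.concordant_counts
    phat = k / n
    boots = rng.binomial(n[None, :], phat[None, :], size=(n_bootstrap, len(n))) / n
    iso = IsotonicRegression(increasing=False, y_min=0.0, y_max=1.0)
    points = np.empty(n_bootstrap)
    for b in range(n_bootstrap):
        smoothed = iso.fit_transform(curve.fractions, boots[b], sample_weight=n)
        points[b], _ = _threshold_scan(curve.fractions, smoothed, threshold)
    base = estimate_lod(curve, threshold)
    lower, upper = np.percentile(points, [2.5, 97.5])
    # The percentile band can exclude the plug-in point on very coarse grids;
    # widen to bracket it so the estimate remains internally consistent.
    lower = min(float(lower), base.point)
    upper = max(float(upper), base.point)
    return LODEstimate(
        point=base.point, lower=lower, upper=upper, threshold=threshold,
        method="concordance", n_bootstrap=n_bootstrap, detected=base.detected,
    )


def spline_crossing(
    fractions,
    scores,
    boundary: float = 0.0,
    parent_side: float | None = None,
) -> LODEstimate:
    """LOD as the first boundary crossing of a smoothed score-vs-fraction curve.

    Replicate scores at the same fraction are averaged (and weight the fit).
    The smoothing parameter is chosen by generalized cross-validation; with
    fewer than 5 distinct fractions a natural cubic interpolant is used
    instead. ``parent_side`` is the sign of (parent score - boundary); when
    omitted it is taken from the fitted value at the smallest fraction. If the
    fitted curve never leaves the parent's side the result is flagged
    ``detected=False``.
    """
    f = np.asarray(fractions, dtype=float)
    s = np.asarray(scores, dtype=float)
    if f.shape != s.shape or f.ndim != 1:
        raise ValueError("fractions and scores must be equal-length vectors")
    grouped = pd.DataFrame({"f": f, "s": s}).groupby("f")["s"].agg(["mean", "size"])
    fu = grouped.index.to_numpy()
    su = grouped["mean"].to_numpy()
    wu = grouped["size"].to_numpy(dtype=float)
    if len(fu) < 4:
        raise ValueError("need scores at >= 4 distinct fractions")
    if len(fu) >= 5:
        spline = make_smoothing_spline(fu, su, w=wu)
    else:
        spline = CubicSpline(fu, su)
    side = float(np.sign(spline(fu[0]) - boundary)) if parent_side is None else float(np.sign(parent_side))
    if side == 0.0:
        side = -1.0  # boundary ties call non-UIP: treat the parent as negative

    grid = np.linspace(fu[0], fu[-1], 2001)
    vals = side * (np.asarray(spline(grid)) - boundary)
    crossing = None
    for i in range(len(grid) - 1):
        if vals[i] > 0 >= vals[i + 1]:
            if vals[i + 1] == 0.0:
                crossing = grid[i + 1]
            else:
                crossing = brentq(lambda x: side * (float(spline(x)) - boundary),
                                  grid[i], grid[i + 1])
            break
    if crossing is None:
        return LODEstimate(point=float("nan"), threshold=0.90,
                           method="spline", detected=False)
    return LODEstimate(point=float(crossing), threshold=0.90, method="spline")
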