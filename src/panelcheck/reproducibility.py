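"""Score variance components, noise tolerance, inter-laboratory concordance.

The reproducibility battery treats classifier scores from a nested study
design (samples x labs x runs x replicates) and decomposes their variability:

* **within-run SD** — pooled SD of residuals about each (sample, run)
  replicate-group mean: the noise floor of the assay inside one processing run;
* **run-to-run SD** — pooled SD of replicate scores about per-sample means:
  the nested total technical SD a repeat measurement of the same sample sees
  (it includes the within-run component);
* **inter-laboratory pooled SD** — the same per-sample pooling applied to
  measurements of shared samples in different labs;
* **inter-class SD** — the SD of per-sample mean scores across labeled
  samples of both classes: biological spread, the comparator that technical
  SDs must sit well below.

Confidence intervals use a residual bootstrap (residuals of the centering
model resampled with replacement, scores rebuilt, component re-estimated).
Noise tolerance injects Gaussian score noise into cross-validated scores and
reports the largest noise SD before cross-validated sensitivity or
specificity drops more than a margin below baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .classifier import NON_UIP, UIP, cross_validated_scores
from .errors import EstimationError

__all__ = [
    "VarianceComponents",
    "NoiseToleranceResult",
    "InterlabResult",
    "simulate_replicate_scores",
    "simulate_interlab_scores",
    "estimate_variance_components",
    "sd_bootstrap_ci",
    "injected_performance",
    "noise_tolerance",
    "interlab_concordance",
    "storage_anova",
]


@dataclass
class VarianceComponents:
    within_run_sd: float | None = None
    run_to_run_sd: float | None = None
    interlab_pooled_sd: float | None = None
    interclass_sd: float | None = None
    ci: dict = field(default_factory=dict)  # component -> (lower, upper)
    n: dict = field(default_factory=dict)  # component -> observations used

    def __post_init__(self) -> None:
        for name in ("within_run_sd", "run_to_run_sd", "interlab_pooled_sd", "interclass_sd"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be >= 0")

    def to_dict(self) -> dict:
        return {
            "within_run_sd": self.within_run_sd,
            "run_to_run_sd": self.run_to_run_sd,
            "interlab_pooled_sd": self.interlab_pooled_sd,
            "interclass_sd": self.interclass_sd,
            "ci": {k: list(v) for k, v in self.ci.items()},
            "n": self.n,
        }


@dataclass
class NoiseToleranceResult:
    sd_grid: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    baseline_sensitivity: float
    baseline_specificity: float
    margin: float
    max_tolerable_sd: float

    def to_dict(self) -> dict:
        return {
            "sd_grid": self.sd_grid.tolist(),
            "sensitivity": self.sensitivity.tolist(),
            "specificity": self.specificity.tolist(),
            "baseline_sensitivity": self.baseline_sensitivity,
            "baseline_specificity": self.baseline_specificity,
            "margin": self.margin,
            "max_tolerable_sd": self.max_tolerable_sd,
        }


@dataclass
class InterlabResult:
    concordance_pct: float
    r_squared: float
    pooled_sd: float
    n_samples: int
    flags: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "concordance_pct": self.concordance_pct,
            "r_squared": self.r_squared,
            "pooled_sd": self.pooled_sd,
            "n_samples": self.n_samples,
            "flags": self.flags,
        }


# ---------------------------------------------------------------------------
# score-scale study simulators


def simulate_replicate_scores(
    n_samples: int = 9,
    n_runs: int = 3,
    n_replicates: int = 3,
    run_variance: float = 0.0076,
    residual_variance: float = 0.0324,
    sample_means=None,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a nested reproducibility study on the score scale.

    Each score is ``sample mean + run effect + residual`` with run effects
    drawn per (sample, run) with the given variance and iid residuals within
    the run. Defaults are the reference design: 9 pooled samples processed in
    triplicate across 3 runs, run variance 0.0076 and residual variance
    0.0324 (so the nested replicate variance is 0.04).
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 909]))
    if sample_means is None:
        sample_means = np.linspace(-3.0, 3.0, n_samples)
    sample_means = np.asarray(sample_means, dtype=float)
    rows = []
    for i in range(n_samples):
        for r in range(n_runs):
            run_eff = rng.normal(0.0, np.sqrt(run_variance))
            for k in range(n_replicates):
                rows.append({
                    "sample_id": f"S{i + 1}",
                    "run_id": f"R{r + 1}",
                    "replicate": k + 1,
                    "score": sample_means[i] + run_eff
                    + rng.normal(0.0, np.sqrt(residual_variance)),
                })
    return pd.DataFrame(rows)


def simulate_interlab_scores(
    n_samples: int = 20,
    measurement_sd: float = 0.15,
    score_range: tuple[float, float] = (-3.5, 3.5),
    boundary_margin: float = 0.75,
    boundary: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a two-laboratory comparison of shared samples.

    True sample scores are spread uniformly over the display range excluding
    a ``boundary_margin`` band around the decision boundary (so calls are
    stable at >= margin/sd noise SDs from the boundary); each lab measures
    every sample once with independent Normal noise.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 919]))
    lo, hi = score_range
    per_side = n_samples // 2
    below = np.linspace(lo, boundary - boundary_margin, per_side)
    above = np.linspace(boundary + boundary_margin, hi, n_samples - per_side)
    truth = np.concatenate([below, above])
    rows = []
    for i, mu in enumerate(truth):
        for lab in ("L1", "L2"):
            rows.append({
                "sample_id": f"S{i + 1}",
                "lab_id": lab,
                "score": mu + rng.normal(0.0, measurement_sd),
                "true_score": mu,
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# estimators


def _pooled_sd_about_group_means(scores: pd.Series, groups: pd.Series) -> tuple[float, int, int]:
    """Pooled SD of deviations about group means, divisor N - k."""
    resid = scores - scores.groupby(groups).transform("mean")
    n = len(scores)
    k = groups.nunique()
    dof = n - k
    if dof < 1:
        raise EstimationError("no replication left after removing group means")
    return float(np.sqrt((resid ** 2).sum() / dof)), n, dof


def estimate_variance_components(scores: pd.DataFrame, score_col: str = "score") -> VarianceComponents:
    """Estimate nested technical and biological score SDs from a scores table.

    Expects columns ``sample_id`` and ``score``; ``run_id``, ``lab_id`` and
    ``class_label`` unlock the corresponding components:

    * within_run_sd: pooled residual SD about (sample_id, lab_id, run_id)
      replicate-group means — requires >= 2 replicates in some group;
    * run_to_run_sd: pooled SD about per-sample means (nested total);
    * interlab_pooled_sd: pooled SD about per-sample means, computed when two
      or more labs share samples;
    * interclass_sd: SD of per-sample mean scores across samples labeled UIP
      or non-UIP (both classes required).
    """
    if "sample_id" not in scores.columns or score_col not in scores.columns:
        raise ValueError("scores table needs 'sample_id' and score columns")
    df = scores.copy()
    s = df[score_col].astype(float)
    out = VarianceComponents()

    counts = df.groupby("sample_id").size()
    if (counts < 2).all():
        raise EstimationError("run_to_run_sd: no sample has >= 2 measurements")
    out.run_to_run_sd, n_rr, _ = _pooled_sd_about_group_means(s, df["sample_id"])
    out.n["run_to_run_sd"] = n_rr

    if "run_id" in df.columns:
        cell = df["sample_id"].astype(str)
        if "lab_id" in df.columns:
            cell = cell + "/" + df["lab_id"].astype(str)
        cell = cell + "/" + df["run_id"].astype(str)
        if df.groupby(cell).size().max() >= 2:
            out.within_run_sd, n_wr, _ = _pooled_sd_about_group_means(s, cell)
            out.n["within_run_sd"] = n_wr

    if "lab_id" in df.columns and df["lab_id"].nunique() >= 2:
        per_lab = df.groupby(["sample_id", "lab_id"])[score_col].mean().reset_index()
        shared = per_lab.groupby("sample_id")["lab_id"].nunique()
        keep = per_lab["sample_id"].isin(shared[shared >= 2].index)
        if keep.sum() >= 4:
            out.interlab_pooled_sd, n_il, _ = _pooled_sd_about_group_means(
                per_lab.loc[keep, score_col], per_lab.loc[keep, "sample_id"]
            )
            out.n["interlab_pooled_sd"] = int(n_il)

    if "class_label" in df.columns:
        labeled = df[df["class_label"].isin([UIP, NON_UIP])]
        means = labeled.groupby("sample_id")[score_col].mean()
        if len(means) >= 2 and labeled.groupby("sample_id")["class_label"].first().nunique() == 2:
            out.interclass_sd = float(means.std(ddof=1))
            out.n["interclass_sd"] = int(len(means))

    return out


_COMPONENTS = ("within_run_sd", "run_to_run_sd", "interlab_pooled_sd")


def sd_bootstrap_ci(
    scores: pd.DataFrame,
    component: str,
    n_bootstrap: int = 1000,
    seed: int = 0,
    score_col: str = "score",
) -> tuple[float, float]:
    """Residual-bootstrap 95% CI for one technical variance component.

    Residuals of the component's centering model (replicate-group means for
    within_run_sd, per-sample means otherwise) are resampled with
    replacement, scores are rebuilt as fitted + resampled residual, and the
    component is re-estimated; the percentile 2.5/97.5 band is returned.
    """
    if component not in _COMPONENTS:
        raise ValueError(f"component must be one of {_COMPONENTS}")
    if n_bootstrap < 100:
        raise ValueError("n_bootstrap must be >= 100")
    df = scores.copy().reset_index(drop=True)
    if component == "within_run_sd":
        groups = df["sample_id"].astype(str)
        if "lab_id" in df.columns:
            groups = groups + "/" + df["lab_id"].astype(str)
        groups = groups + "/" + df["run_id"].astype(str)
    elif component == "interlab_pooled_sd":
        # the estimator first averages replicates within (sample, lab)
        df = (df.groupby(["sample_id", "lab_id"], as_index=False)[score_col].mean())
        groups = df["sample_id"]
    else:
        groups = df["sample_id"]
    s = df[score_col].astype(float)
    fitted = s.groupby(groups).transform("mean").to_numpy()
    resid = (s.to_numpy() - fitted)
    n = len(resid)
    codes, _ = pd.factorize(groups)
    k = codes.max() + 1
    if n - k < 1:
        raise EstimationError(f"{component}: no replication to bootstrap")
    # residuals about group means understate the error variance by (N-k)/N;
    # inflate before resampling so the bootstrap is centered on the estimate
    resid = resid * np.sqrt(n / (n - k))
    rng = np.random.default_rng(np.random.SeedSequence([seed, 929]))
    onehot = np.zeros((n, k))
    onehot[np.arange(n), codes] = 1.0
    counts = onehot.sum(axis=0)
    draws = fitted[None, :] + rng.choice(resid, size=(n_bootstrap, n), replace=True)
    means = (draws @ onehot) / counts  # (B, k) group means
    dev = draws - means[:, codes]
    estimates = np.sqrt((dev ** 2).sum(axis=1) / (n - k))
    lo, hi = np.percentile(estimates, [2.5, 97.5])
    return float(lo), float(hi)


def injected_performance(
    base_scores: np.ndarray,
    labels,
    sd_grid,
    n_repeats: int = 50,
    seed: int = 0,
    boundary: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Sensitivity/specificity after adding Gaussian noise to fixed scores.

    For each SD on the grid, ``n_repeats`` independent noise vectors are added
    to ``base_scores`` before calling at ``boundary``; at SD 0 the noise-free
    calls are used. Returns (sensitivity, specificity) arrays over the grid.
    """
    y = np.asarray(labels)
    base_scores = np.asarray(base_scores, dtype=float)
    sd_grid = np.asarray(sd_grid, dtype=float)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 939]))
    sens = np.empty(len(sd_grid))
    spec = np.empty(len(sd_grid))
    is_uip = y == UIP
    for i, sd in enumerate(sd_grid):
        if sd == 0.0:
            noisy = base_scores[None, :]
        else:
            noisy = base_scores[None, :] + rng.normal(0.0, sd, size=(n_repeats, len(y)))
        call_uip = noisy > boundary
        sens[i] = call_uip[:, is_uip].mean()
        spec[i] = (~call_uip)[:, ~is_uip].mean()
    return sens, spec


def noise_tolerance(
    transformed: pd.DataFrame,
    labels,
    sd_grid=None,
    margin: float = 0.05,
    folds: int = 5,
    n_repeats: int = 50,
    seed: int = 0,
    penalty: float = 1.0,
) -> NoiseToleranceResult:
    """How much extra score noise the classifier tolerates before quality drops.

    Cross-validated scores are computed once; at each grid SD, Gaussian noise
    is added before calling and cross-validated sensitivity/specificity are
    averaged over ``n_repeats`` noise draws. The maximum tolerable SD is the
    largest grid value up to which both stay within ``margin`` (a proportion,
    default 5 percentage points) of the noise-free baseline; the first grid
    value that breaches the margin caps the tolerance.
    """
    if sd_grid is None:
        sd_grid = np.round(np.arange(0.0, 1.0001, 0.05), 4)
    sd_grid = np.asarray(sorted(float(v) for v in sd_grid))
    if sd_grid[0] != 0.0:
        raise ValueError("the SD grid must include 0 (the baseline)")
    if margin <= 0:
        raise ValueError("margin must be positive")
    base_scores = cross_validated_scores(
        transformed, labels, folds=folds, seed=seed, penalty=penalty
    ).to_numpy()
    sens, spec = injected_performance(base_scores, labels, sd_grid,
                                      n_repeats=n_repeats, seed=seed)
    base_sens, base_spec = sens[0], spec[0]
    ok = (sens >= base_sens - margin) & (spec >= base_spec - margin)
    breach = np.argmin(ok) if not ok.all() else len(ok)
    max_sd = float(sd_grid[breach - 1]) if breach > 0 else 0.0
    return NoiseToleranceResult(
        sd_grid=sd_grid, sensitivity=sens, specificity=spec,
        baseline_sensitivity=float(base_sens), baseline_specificity=float(base_spec),
        margin=margin, max_tolerable_sd=max_sd,
    )


def interlab_concordance(
    scores: pd.DataFrame, boundary: float = 0.0, score_col: str = "score"
) -> InterlabResult:
    """Agreement between two laboratories measuring the same samples.

    Concordance is the percentage of shared samples receiving the same
    binary call in both labs; R^2 is the squared Pearson correlation of the
    two labs' score vectors; the pooled SD is taken about per-sample means.
    A high R^2 with poor concordance (e.g. anti-correlated scores) is
    flagged as inconsistent rather than reported silently.
    """
    labs = sorted(scores["lab_id"].unique())
    if len(labs) != 2:
        raise ValueError("interlab concordance needs exactly 2 labs")
    wide = scores.pivot_table(index="sample_id", columns="lab_id", values=score_col,
                              aggfunc="mean").dropna()
    if len(wide) < 2:
        raise ValueError("need >= 2 samples shared by both labs")
    a = wide[labs[0]].to_numpy()
    b = wide[labs[1]].to_numpy()
    conc = float(np.mean((a > boundary) == (b > boundary)) * 100.0)
    r = np.corrcoef(a, b)[0, 1]
    r2 = float(r ** 2) if np.isfinite(r) else 0.0
    long = scores[scores["sample_id"].isin(wide.index)]
    pooled, _, _ = _pooled_sd_about_group_means(
        long[score_col].astype(float), long["sample_id"]
    )
    flags = []
    if r2 > 0.5 and r < 0 or (r2 > 0.9 and conc < 50.0):
        flags.append("high correlation but poor call agreement: sign inconsistency")
    return InterlabResult(
        concordance_pct=conc, r_squared=r2, pooled_sd=pooled,
        n_samples=int(len(wide)), flags=flags,
    )


def storage_anova(dv200: pd.DataFrame, value_col: str = "dv200", bin_col: str = "storage_bin"):
    """One-way ANOVA of RNA quality (DV200) across storage-time bins.

    Returns ``(F, p)``. Requires >= 2 bins with >= 2 values each.
    """
    groups = [g[value_col].to_numpy(dtype=float) for _, g in dv200.groupby(bin_col)]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise EstimationError("storage ANOVA needs >= 2 bins with >= 2 values each")
    if np.ptp(np.concatenate(groups)) == 0:
        return 0.0, 1.0
    f, p = stats.f_oneway(*groups)
    if np.isnan(f):  # zero within-group variance everywhere, equal means
        return 0.0, 1.0
    return float(f), float(p)
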