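"""Synthetic panel RNA-seq data with the structure of an analytical-verification study.

The real assay this toolkit emulates sequences a fixed panel of 190 genes from
transbronchial-biopsy (TBB) RNA and feeds the counts to a locked classifier that
calls UIP (usual interstitial pneumonia) versus non-UIP. Neither the gene list
nor clinical count data are public, so every analysis here runs on synthetic
data with the same statistical anatomy:

* a gene panel with one designated blood-marker gene (the "HBB" role) and
  per-gene exonic lengths (used to allocate genomic-DNA reads);
* per-tissue expression profiles on the simplex — UIP / non-UIP TBB pools,
  surgical-lung-biopsy (SLB) profiles, whole blood dominated by the marker
  gene, adjacent-normal lung, and a genomic-DNA background whose abundance is
  proportional to exonic length;
* negative-binomial counts: the library total is gamma-overdispersed
  (per-gene marginal variance mu + alpha*mu^2) and the composition is
  multinomial, so gene proportions are stable across technical replicates —
  the regime of a capture assay run on pooled RNA;
* study layouts (subjects x runs x labs x replicates) with run/lab/replicate
  effects injected on the classifier-score scale via a count-level tilt along
  the classifier weight vector.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GenePanel",
    "ExpressionProfile",
    "SampleAnnotation",
    "GeneratorConfig",
    "StudyLayout",
    "PROFILE_ROLES",
    "make_panel",
    "make_profiles",
    "simulate_counts",
    "simulate_study",
]

#: Tissue/contaminant roles for which :func:`make_profiles` emits a profile.
PROFILE_ROLES = (
    "uip_tbb",
    "nonuip_tbb",
    "uip_slb",
    "nonuip_slb",
    "blood",
    "adjacent_normal",
    "gdna",
)

_CLASS_OF_ROLE = {
    "uip_tbb": "UIP",
    "uip_slb": "UIP",
    "nonuip_tbb": "non-UIP",
    "nonuip_slb": "non-UIP",
    "blood": "none",
    "adjacent_normal": "none",
    "gdna": "none",
}


@dataclass(frozen=True)
class GenePanel:
    """A fixed gene panel: unique gene ids, exonic lengths, one blood marker."""

    gene_ids: tuple[str, ...]
    exonic_length: np.ndarray  # bases, > 0
    marker_gene: str

    def __post_init__(self) -> None:
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("gene_ids must be unique")
        if len(self.gene_ids) != len(self.exonic_length):
            raise ValueError("exonic_length must match gene_ids in length")
        if np.any(np.asarray(self.exonic_length) <= 0):
            raise ValueError("exonic lengths must be positive")
        if self.marker_gene not in self.gene_ids:
            raise ValueError(f"marker gene {self.marker_gene!r} not in panel")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def marker_index(self) -> int:
        return self.gene_ids.index(self.marker_gene)


@dataclass(frozen=True)
class ExpressionProfile:
    """Per-gene relative abundances (on the simplex) plus an NB dispersion."""

    name: str
    abundance: np.ndarray
    dispersion: float

    def __post_init__(self) -> None:
        a = np.asarray(self.abundance, dtype=float)
        if np.any(a < 0):
            raise ValueError("abundances must be nonnegative")
        if abs(a.sum() - 1.0) > 1e-9:
            raise ValueError(f"abundances must sum to 1 (got {a.sum():.12f})")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        object.__setattr__(self, "abundance", a)


@dataclass
class SampleAnnotation:
    """One row of the sample sheet for a simulated library."""

    sample_id: str
    subject_id: str = ""
    class_label: str = "none"  # UIP | non-UIP | none
    tissue_role: str = "nonuip_tbb"
    run_id: str = "R1"
    lab_id: str = "L1"
    replicate_index: int = 1
    input_mass_ng: float = 15.0
    storage_days_cold: float = 0.0
    dv200: float = 85.0

    def __post_init__(self) -> None:
        if self.class_label not in ("UIP", "non-UIP", "none"):
            raise ValueError(f"bad class label {self.class_label!r}")
        if self.input_mass_ng <= 0:
            raise ValueError("input_mass_ng must be positive")
        if not 0.0 <= self.dv200 <= 100.0:
            raise ValueError("dv200 must be a percentage in [0, 100]")
        expected = _CLASS_OF_ROLE.get(self.tissue_role)
        # an unlabeled sample of any tissue is fine; only contradictions fail
        if (self.class_label != "none" and expected is not None
                and expected != "none" and self.class_label != expected):
            raise ValueError(
                f"class_label {self.class_label!r} inconsistent with "
                f"tissue_role {self.tissue_role!r}"
            )


@dataclass
class GeneratorConfig:
    """All knobs of the synthetic study generator.

    Defaults are the study conditions of the verification battery: a 190-gene
    panel, 15 ng nominal RNA input, a handful of strongly discriminating genes
    (the locked classifier was built for clean class separation), run / lab /
    replicate score effects on the order of the reported technical SDs, a pure
    blood marker fraction of 0.3075 (the value implied by linear mixing from a
    0.3% TBB baseline reaching 7% marker share at 22% blood), and a 2% SD on
    realized mixing fractions.
    """

    n_genes: int = 190
    n_discriminating: int = 20
    log2_fold_change: float = 1.5
    depth: float = 1e6  # expected total reads per library at nominal input
    dispersion: float = 0.05  # NB alpha of the library total
    run_effect_sd: float = 0.087  # score units; 0.087^2 ~ 0.0076
    lab_effect_sd: float = 0.11
    replicate_sd: float = 0.18
    mix_jitter_sd: float = 0.02  # sigma_f on realized mixing fractions
    blood_marker_fraction: float = 0.3075
    tbb_marker_fraction: float = 0.003
    mass_reference_ng: float = 15.0
    depth_jitter_sd: float = 0.05  # lognormal sd of effective depth at nominal mass
    mass_depth_exponent: float = 1.0  # effective depth ~ (mass/reference)^exponent
    mass_jitter_exponent: float = 0.5  # jitter sd ~ (reference/mass)^exponent
    abundance_log_sd: float = 1.5  # spread of baseline abundances across genes
    profile_jitter_sd: float = 0.2  # ln-scale tissue-to-tissue jitter
    n_train_per_class: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("run_effect_sd", "lab_effect_sd", "replicate_sd",
                     "mix_jitter_sd", "depth_jitter_sd", "dispersion"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("blood_marker_fraction", "tbb_marker_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.n_genes < 2:
            raise ValueError("panel needs at least 2 genes")
        if self.n_discriminating > self.n_genes - 1:
            raise ValueError("more discriminating genes than non-marker panel genes")
        if self.depth <= 0 or self.mass_reference_ng <= 0:
            raise ValueError("depth and mass_reference_ng must be positive")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        return cls(**d)


@dataclass
class StudyLayout:
    """Crossing of subjects x labs x runs x replicates for a study design.

    ``subjects`` maps subject ids to tissue roles (profile names); every
    subject is measured in every (lab, run, replicate) cell.
    """

    subjects: dict[str, str] = field(default_factory=dict)
    n_runs: int = 3
    n_labs: int = 1
    n_replicates: int = 3
    input_mass_ng: float = 15.0

    def __post_init__(self) -> None:
        if not self.subjects or self.n_runs < 1 or self.n_labs < 1 or self.n_replicates < 1:
            raise ValueError("study layout must be nonempty")

    @property
    def n_samples(self) -> int:
        return len(self.subjects) * self.n_runs * self.n_labs * self.n_replicates


def make_panel(n_genes: int = 190, seed: int = 0) -> GenePanel:
    """Build a synthetic gene panel with one designated blood-marker gene.

    Gene ids are synthetic (``PNL0001`` ...); one gene, chosen at random, takes
    the marker id ``HBB``. Exonic lengths are lognormal around ~1.5 kb
    (clipped below at 200 b), the scale of targeted capture panels.
    """
    if n_genes < 2:
        raise ValueError("n_genes must be >= 2")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 101]))
    ids = [f"PNL{i + 1:04d}" for i in range(n_genes)]
    marker_pos = int(rng.integers(n_genes))
    ids[marker_pos] = "HBB"
    lengths = np.maximum(200, np.round(rng.lognormal(np.log(1500.0), 0.5, n_genes)))
    return GenePanel(gene_ids=tuple(ids), exonic_length=lengths, marker_gene="HBB")


def _pin_marker(abundance: np.ndarray, marker_index: int, fraction: float) -> np.ndarray:
    """Rescale non-marker mass so the marker gene holds exactly ``fraction``."""
    a = abundance.copy()
    a[marker_index] = 0.0
    a *= (1.0 - fraction) / a.sum()
    a[marker_index] = fraction
    return a


def make_profiles(panel: GenePanel, config: GeneratorConfig) -> dict[str, ExpressionProfile]:
    """Generate one expression profile per tissue/contaminant role.

    The UIP and non-UIP TBB profiles share a common lung baseline and differ on
    exactly ``config.n_discriminating`` genes by ``config.log2_fold_change``
    (half up, half down in UIP). SLB and adjacent-normal profiles are jittered
    copies of the corresponding TBB baseline; blood holds the marker gene at
    the configured pure-blood fraction with an otherwise lung-like (non-UIP)
    background; the genomic-DNA profile allocates reads proportional to exonic
    length.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 202]))
    n = panel.n_genes
    mi = panel.marker_index

    base = rng.lognormal(0.0, config.abundance_log_sd, n)
    base = _pin_marker(base / base.sum(), mi, config.tbb_marker_fraction)

    candidates = np.setdiff1d(np.arange(n), [mi])
    disc = rng.choice(candidates, size=config.n_discriminating, replace=False)
    tilt = np.ones(n)
    half = config.n_discriminating // 2
    tilt[disc[:half]] = 2.0 ** config.log2_fold_change
    tilt[disc[half:]] = 2.0 ** -config.log2_fold_change

    uip = base * tilt
    uip /= uip.sum()

    def jitter(a: np.ndarray) -> np.ndarray:
        j = a * rng.lognormal(0.0, config.profile_jitter_sd, n)
        return j / j.sum()

    nonuip_slb = jitter(base)
    uip_slb = jitter(uip)
    adjacent = jitter(base)
    blood = _pin_marker(jitter(base), mi, config.blood_marker_fraction)
    gdna = panel.exonic_length / panel.exonic_length.sum()

    alpha = config.dispersion
    return {
        "uip_tbb": ExpressionProfile("uip_tbb", uip, alpha),
        "nonuip_tbb": ExpressionProfile("nonuip_tbb", base, alpha),
        "uip_slb": ExpressionProfile("uip_slb", uip_slb, alpha),
        "nonuip_slb": ExpressionProfile("nonuip_slb", nonuip_slb, alpha),
        "blood": ExpressionProfile("blood", blood, alpha),
        "adjacent_normal": ExpressionProfile("adjacent_normal", adjacent, alpha),
        "gdna": ExpressionProfile("gdna", gdna, alpha),
    }


def simulate_counts(
    profile: ExpressionProfile,
    annotation: SampleAnnotation,
    config: GeneratorConfig,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Draw one library of per-gene counts for ``profile``.

    The library total is negative-binomial: a gamma factor with dispersion
    ``profile.dispersion`` multiplies the expected depth, which itself scales
    with input mass (``(mass/reference)**mass_depth_exponent``) and carries a
    lognormal jitter whose SD grows at low mass
    (``depth_jitter_sd * (reference/mass)**mass_jitter_exponent``). Gene counts
    are then multinomial in the profile's abundances, so each gene's marginal
    variance is ``mu + alpha*mu**2`` while the composition stays stable.
    """
    if config.depth <= 0:
        raise ValueError("depth must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    mass_ratio = annotation.input_mass_ng / config.mass_reference_ng
    eff_depth = config.depth * mass_ratio ** config.mass_depth_exponent
    jit_sd = config.depth_jitter_sd * (1.0 / mass_ratio) ** config.mass_jitter_exponent
    if jit_sd > 0:
        eff_depth *= np.exp(rng.normal(0.0, jit_sd))
    alpha = profile.dispersion
    if alpha > 0:
        eff_depth *= rng.gamma(1.0 / alpha, alpha)
    total = rng.poisson(eff_depth)
    return rng.multinomial(total, profile.abundance)


def simulate_study(
    panel: GenePanel,
    profiles: dict[str, ExpressionProfile],
    layout: StudyLayout,
    config: GeneratorConfig,
    seed: int = 0,
    model=None,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Simulate counts for every (subject, lab, run, replicate) cell of a layout.

    Run, lab and replicate effects are drawn on the classifier-score scale
    (SDs from ``config``) and realized in the counts by tilting each library
    along the classifier weight vector on the variance-stabilized scale (see
    :func:`panelcheck.classifier.tilt_counts`); a fitted ``model`` is therefore
    required whenever any effect SD is positive. Returns the count matrix
    (genes x samples), the sample annotation table, and a truth record holding
    every injected effect.
    """
    any_noise = config.run_effect_sd > 0 or config.lab_effect_sd > 0 or config.replicate_sd > 0
    if any_noise and model is None:
        raise ValueError(
            "score-scale run/lab/replicate effects require a classifier model "
            "to realize the count-level tilt; pass model= or zero the effect SDs"
        )
    from .classifier import tilt_counts  # deferred: classifier depends on preprocess only

    ss = np.random.SeedSequence([seed, 303])
    rng = np.random.default_rng(ss)

    lab_ids = [f"L{i + 1}" for i in range(layout.n_labs)]
    run_ids = [f"R{i + 1}" for i in range(layout.n_runs)]
    lab_eff = {lab: float(rng.normal(0.0, config.lab_effect_sd)) for lab in lab_ids}
    # Run effects are nested within (subject, lab, run) replicate groups: each
    # processing run perturbs each sample's score independently.
    truth: dict = {
        "lab_effects": lab_eff,
        "run_effects": {},
        "replicate_effects": {},
    }

    columns: dict[str, np.ndarray] = {}
    rows = []
    for subject, role in layout.subjects.items():
        profile = profiles[role]
        for lab in lab_ids:
            for run in run_ids:
                run_key = f"{subject}/{lab}/{run}"
                run_eff = float(rng.normal(0.0, config.run_effect_sd))
                truth["run_effects"][run_key] = run_eff
                for rep in range(1, layout.n_replicates + 1):
                    sid = f"{subject}_{lab}_{run}_rep{rep}"
                    ann = SampleAnnotation(
                        sample_id=sid,
                        subject_id=subject,
                        class_label=_CLASS_OF_ROLE.get(role, "none"),
                        tissue_role=role,
                        run_id=run,
                        lab_id=lab,
                        replicate_index=rep,
                        input_mass_ng=layout.input_mass_ng,
                    )
                    counts = simulate_counts(profile, ann, config, rng)
                    resid = float(rng.normal(0.0, config.replicate_sd))
                    truth["replicate_effects"][sid] = resid
                    delta = lab_eff[lab] + run_eff + resid
                    if delta != 0.0 and model is not None:
                        counts = tilt_counts(model, counts, delta)
                    columns[sid] = counts
                    rows.append(dataclasses.asdict(ann))

    counts_df = pd.DataFrame(columns, index=list(panel.gene_ids))
    counts_df.index.name = "gene_id"
    annotations = pd.DataFrame(rows)
    return counts_df, annotations, truth
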