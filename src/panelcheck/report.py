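"""End-to-end orchestration of the verification battery into one report.

``run_validation_suite`` executes, from a single (config, seed) pair, the
whole study battery a locked expression classifier is put through before
clinical use: simulate a training cohort, train the surrogate classifier,
check its cross-validated quality, estimate limits of detection for three
diluents (UIP surgical tissue into a non-UIP parent, blood and
adjacent-normal tissue into a UIP parent), run the genomic-DNA and input-mass
interference studies, and estimate reproducibility (variance components with
bootstrap CIs, inter-laboratory concordance, score-noise tolerance, and the
DV200 storage-stability ANOVA). The report is reproducible bit-for-bit from
(config, seed): a single top-level seed fans out to per-stage child seeds via
``numpy.random.SeedSequence([seed, stage_index])``.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import interference, reproducibility
from .classifier import evaluate_cv, score_counts, train_pipeline
from .lod import concordance_curve, lod_bootstrap_ci
from .mixtures import grid_ensembles
from .preprocess import estimate_size_factors, vst_transform
from .syndata import (
    GeneratorConfig, SampleAnnotation, StudyLayout,
    make_panel, make_profiles, simulate_counts, simulate_study,
)

__all__ = ["ValidationReport", "ReportSpec", "run_validation_suite"]


@dataclass
class ReportSpec:
    """Numeric specifications the report's pass/fail flags are checked against."""

    min_cv_sensitivity: float = 0.80
    min_cv_specificity: float = 0.80
    max_technical_sd: float = 0.48  # 7% of a ~7-unit score range
    min_interlab_concordance_pct: float = 100.0
    alpha: float = 0.05


@dataclass
class ValidationReport:
    seed: int
    config_digest: str
    classifier: dict
    lod_studies: list = field(default_factory=list)
    interference_studies: list = field(default_factory=list)
    reproducibility: dict = field(default_factory=dict)
    flags: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=1, sort_keys=True)

    def to_markdown(self) -> str:
        lines = [
            "# Panel classifier verification report",
            "",
            f"- seed: {self.seed}",
            f"- config digest: `{self.config_digest}`",
            "",
            "## Classifier quality (cross validation)",
            f"- sensitivity: {self.classifier['cv_sensitivity']:.3f}",
            f"- specificity: {self.classifier['cv_specificity']:.3f}",
            "",
            "## Limits of detection (90% concordance rule)",
        ]
        for s in self.lod_studies:
            if s.get("skipped"):
                lines.append(f"- {s['name']}: skipped ({s['reason']})")
                continue
            lod = s["lod"]
            ci = (f" [CI {lod['lower'] * 100:.0f}-{lod['upper'] * 100:.0f}%]"
                  if lod["lower"] is not None else "")
            lines.append(
                f"- {s['name']}: tolerates up to {lod['point'] * 100:.0f}% diluent{ci}"
            )
        lines += ["", "## Interference studies"]
        for s in self.interference_studies:
            if s.get("skipped"):
                lines.append(f"- {s['contaminant']}: skipped ({s['reason']})")
                continue
            lines.append(
                f"- {s['contaminant']}: effect p-value {s['p_value']:.3f} "
                f"({'significant' if s['significant'] else 'not significant'})"
            )
        rep = self.reproducibility
        if rep:
            vc = rep["variance_components"]
            lines += [
                "",
                "## Score variability",
                "",
                "| component | SD | 95% CI | n |",
                "|---|---|---|---|",
            ]
            for comp in ("within_run_sd", "run_to_run_sd", "interlab_pooled_sd",
                         "interclass_sd"):
                v = vc.get(comp)
                if v is None:
                    continue
                ci = vc["ci"].get(comp)
                ci_txt = f"{ci[0]:.2f}-{ci[1]:.2f}" if ci else "-"
                lines.append(
                    f"| {comp.replace('_', ' ')} | {v:.2f} | {ci_txt} | "
                    f"{vc['n'].get(comp, '-')} |"
                )
            lines += [
                "",
                f"- inter-lab concordance: {rep['interlab']['concordance_pct']:.0f}% "
                f"(R^2 = {rep['interlab']['r_squared']:.2f})",
                f"- max tolerable injected score SD: "
                f"{rep['noise_tolerance']['max_tolerable_sd']:.2f} units",
                f"- storage-stability ANOVA p-value: {rep['storage']['p_value']:.2f}",
            ]
        lines += ["", "## Flags", ""]
        for k, v in sorted(self.flags.items()):
            lines.append(f"- {k}: {'PASS' if v else 'FAIL'}")
        return "\n".join(lines) + "\n"


def _digest(config: GeneratorConfig) -> str:
    return hashlib.sha256(
        json.dumps(config.to_dict(), sort_keys=True).encode()
    ).hexdigest()[:16]


def run_validation_suite(
    config: GeneratorConfig | None = None,
    seed: int = 0,
    out_dir=None,
    spec: ReportSpec | None = None,
    n_simulations: int = 200,
    n_bootstrap: int = 200,
    depth: int = 100_000,
) -> ValidationReport:
    """Run the full battery and return (optionally write) the report.

    ``n_simulations`` / ``n_bootstrap`` / ``depth`` size the Monte-Carlo
    stages; the defaults keep the full suite to a couple of minutes on one
    core while leaving every estimate comfortably inside its Monte-Carlo
    tolerance.
    """
    config = config or GeneratorConfig()
    spec = spec or ReportSpec()
    flags: dict[str, bool] = {}

    def stage_seed(i: int) -> int:
        return int(np.random.SeedSequence([seed, i]).generate_state(1)[0] % (2 ** 31))

    # -- stage 0: panel, profiles, training cohort ----------------------
    panel = make_panel(config.n_genes, seed=config.seed)
    profiles = make_profiles(panel, config)
    rng = np.random.default_rng(stage_seed(0))
    cols, labels = {}, []
    for cls, role in (("UIP", "uip_tbb"), ("non-UIP", "nonuip_tbb")):
        for i in range(config.n_train_per_class):
            sid = f"train_{role}_{i + 1}"
            ann = SampleAnnotation(sample_id=sid, class_label=cls, tissue_role=role)
            cols[sid] = simulate_counts(profiles[role], ann, config, rng)
            labels.append(cls)
    train_counts = pd.DataFrame(cols, index=list(panel.gene_ids))
    labels = np.asarray(labels)

    model = train_pipeline(train_counts, labels, seed=stage_seed(1))
    sf = estimate_size_factors(train_counts)
    transformed = vst_transform(train_counts, sf, model.dispersion)
    sens, spec_cv = evaluate_cv(transformed, labels, folds=5, seed=stage_seed(1))
    classifier_info = {
        "cv_sensitivity": sens, "cv_specificity": spec_cv,
        "dispersion": model.dispersion, "n_train": int(len(labels)),
    }
    classifier_ok = sens >= spec.min_cv_sensitivity and spec_cv >= spec.min_cv_specificity
    flags["classifier_quality"] = classifier_ok

    report = ValidationReport(
        seed=seed, config_digest=_digest(config), classifier=classifier_info,
    )

    # -- stage 1: limits of detection ------------------------------------
    lod_plan = [
        ("uip_into_nonuip", "nonuip_tbb", "uip_slb"),
        ("blood_into_uip", "uip_tbb", "blood"),
        ("adjacent_normal_into_uip", "uip_tbb", "adjacent_normal"),
    ]
    fractions = np.round(np.arange(0.0, 1.0001, 0.05), 4)
    for i, (name, parent_role, diluent_role) in enumerate(lod_plan):
        if not classifier_ok:
            report.lod_studies.append({
                "name": name, "skipped": True,
                "reason": "classifier quality below specification",
            })
            continue
        srng = np.random.default_rng(stage_seed(10 + i))
        lib = {}
        for role in (parent_role, diluent_role):
            ann = SampleAnnotation(
                sample_id=role, tissue_role=role,
                class_label={"uip_tbb": "UIP", "uip_slb": "UIP",
                             "nonuip_tbb": "non-UIP", "nonuip_slb": "non-UIP"
                             }.get(role, "none"),
            )
            lib[role] = simulate_counts(profiles[role], ann, config, srng)
        lib_df = pd.DataFrame(lib, index=list(panel.gene_ids))
        reference = score_counts(model, lib_df[[parent_role]])["call"].iloc[0]
        ens = grid_ensembles(
            lib_df, [parent_role], [diluent_role], fractions,
            n_simulations=n_simulations, sigma_f=config.mix_jitter_sd,
            depth=depth, seed=stage_seed(10 + i),
        )
        curve = concordance_curve({f: ens[f][0] for f in ens}, model, reference)
        lod = lod_bootstrap_ci(curve, threshold=0.90, n_bootstrap=n_bootstrap,
                               seed=stage_seed(10 + i))
        report.lod_studies.append({
            "name": name, "parent": parent_role, "diluent": diluent_role,
            "reference_call": reference, "lod": lod.to_dict(),
            "concordance": curve.concordance.tolist(),
            "fractions": curve.fractions.tolist(),
        })

    # -- stage 2: interference -------------------------------------------
    if classifier_ok:
        irng = np.random.default_rng(stage_seed(20))
        gdna_samples = {}
        for role in ("uip_tbb", "nonuip_tbb", "nonuip_slb"):
            ann = SampleAnnotation(
                sample_id=f"gdna_{role}", tissue_role=role,
                class_label="UIP" if role.startswith("uip") else "non-UIP",
            )
            gdna_samples[role] = simulate_counts(profiles[role], ann, config, irng)
        gdna = interference.gdna_spike_test(
            gdna_samples, profiles["gdna"], model, fraction=0.30,
            n_replicates=3, depth=depth, replicate_sd=config.replicate_sd,
            seed=stage_seed(21),
        )
        mass = interference.input_mass_test(
            {r: profiles[r] for r in ("uip_tbb", "nonuip_tbb", "nonuip_slb")},
            model, config, seed=stage_seed(22),
        )
        report.interference_studies = [gdna.to_dict(), mass.to_dict()]
        flags["gdna_no_effect"] = not gdna.significant
        flags["input_mass_no_effect"] = not mass.significant
        # third interference axis, blood, is covered by the blood LOD study:
        # its marker-proportion trace is recorded there
        blood = next(s for s in report.lod_studies if s["name"] == "blood_into_uip")
        flags["blood_lod_positive"] = bool(
            blood["lod"]["detected"] and blood["lod"]["point"] > 0
        )
    else:
        report.interference_studies = [
            {"contaminant": c, "skipped": True,
             "reason": "classifier quality below specification"}
            for c in ("gdna", "input_mass")
        ]

    # -- stage 3: reproducibility ----------------------------------------
    layout = StudyLayout(
        subjects={f"P{i + 1}": ("uip_tbb" if i % 2 == 0 else "nonuip_tbb")
                  for i in range(9)},
        n_runs=3, n_replicates=3,
    )
    _, annotations, _ = counts_ann_truth = simulate_study(
        panel, profiles, layout, config, seed=stage_seed(30), model=model,
    )
    study_counts = counts_ann_truth[0]
    scored = score_counts(model, study_counts)
    scores = annotations.merge(
        scored.reset_index(), on="sample_id", validate="one_to_one"
    )
    # the repeated-measures unit is the subject's pooled library, not the
    # individual replicate library id
    scores = scores.drop(columns=["sample_id"]).rename(columns={"subject_id": "sample_id"})
    vc = reproducibility.estimate_variance_components(scores)
    for comp in ("within_run_sd", "run_to_run_sd"):
        vc.ci[comp] = reproducibility.sd_bootstrap_ci(
            scores, comp, n_bootstrap=max(200, n_bootstrap), seed=stage_seed(31)
        )
    flags["technical_sd_within_tolerance"] = (
        vc.run_to_run_sd is not None and vc.run_to_run_sd <= spec.max_technical_sd
    )

    interlab_scores = reproducibility.simulate_interlab_scores(seed=stage_seed(32))
    il = reproducibility.interlab_concordance(interlab_scores)
    flags["interlab_concordant"] = il.concordance_pct >= spec.min_interlab_concordance_pct

    tol = reproducibility.noise_tolerance(
        transformed, labels, folds=5, n_repeats=50, seed=stage_seed(33)
    )

    srng = np.random.default_rng(stage_seed(34))
    bins = np.repeat(["0-3d", "4-7d", "8-14d"], 30)
    dv200 = pd.DataFrame({
        "storage_bin": bins,
        "dv200": np.clip(srng.normal(80.0, 8.0, len(bins)), 0, 100),
    })
    f_stat, p_val = reproducibility.storage_anova(dv200)
    flags["storage_stable"] = p_val >= spec.alpha

    report.reproducibility = {
        "variance_components": vc.to_dict(),
        "interlab": il.to_dict(),
        "noise_tolerance": tol.to_dict(),
        "storage": {"F": f_stat, "p_value": p_val, "n_per_bin": 30},
    }
    report.flags = flags

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(report.to_json() + "\n")
        (out / "report.md").write_text(report.to_markdown())
    return report
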