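"""End-to-end orchestration of the analysis stages with a run config.

The stage order mirrors the study design: preprocessing, per-subject
change maps, clinical paired test, permutation t-map, severity
regressions, group-level spatial-similarity tests against the template
network, per-patient alignment and outcome regressions, the local
VTA-overlap analysis, the sign-split connectivity GLM with cluster
correction, and the OrT/CVA cross-validation. Every stochastic stage
receives an explicit seed derived from the run seed, and the JSON
summary records every seed, setting, and deviation tag, so identical
configs yield byte-identical summaries.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import alignment as alignment_mod
from . import clinical as clinical_mod
from . import connglm as connglm_mod
from . import ortcva as ortcva_mod
from . import spatialnull, voxelwise
from .errors import ConfigError, EmptyROIError
from .simulate import Cohort, read_cohort
from .volumes import BrainMap, read_volume, resample, write_mask, write_volume

SCHEMA_VERSION = "1"

STAGES = (
    "clinical",
    "stim_effect",
    "severity_regression",
    "similarity",
    "alignment",
    "local_roi",
    "connglm",
    "ortcva",
)

DEVIATION_TAGS = (
    "mirroring=rigid_reflection (substitutes nonlinear warp)",
    "cluster_correction=huh_jhun_permutation (substitutes RFT)",
    "ortcva=simplified_closed_form_variant",
)


@dataclass
class RunConfig:
    """Everything a reproducible run needs; round-trips through YAML."""

    cohort_dir: str = ""
    template_path: str = ""          # left-lateralized template network
    out_dir: str = "tremornet_out"
    seed: int = 0
    stages: dict = field(default_factory=lambda: {s: True for s in STAGES})
    n_perm: int = 10_000
    n_surr: int = 10_000
    alpha: float = 0.05
    cluster_forming_p: float = 0.001
    cluster_n_perm: int = 500
    metric: str = "spearman"
    mirror_strategy: str = "mirror_template_bilateral"
    min_vta_overlap: int = 3
    n_components: int = 5
    n_boot: int = 100
    local_readout: str = "delta"     # or "on" (Stim-On uptake)
    # maps entering MSR similarity are block-resampled to this voxel size
    # (the dense Moran eigenbasis is cubic in voxel count); None = no resample
    similarity_resample_mm: float | None = 8.0

    def stage_seed(self, stage: str) -> int:
        """Named per-stage substream of the run seed (kept below 2**31)."""
        return int(
            np.random.SeedSequence(
                entropy=self.seed, spawn_key=(STAGES.index(stage),)
            ).generate_state(1)[0] % (2**31)
        )

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def validate(self) -> None:
        if not any(self.stages.get(s, False) for s in STAGES):
            raise ConfigError("all stage toggles are off; nothing to run")
        bad = set(self.stages) - set(STAGES)
        if bad:
            raise ConfigError(f"unknown stages: {sorted(bad)}")


def _sim_result_dict(res: spatialnull.SimilarityResult) -> dict:
    return json.loads(res.to_json())


class _MsrRunner:
    """Runs paired-direction MSR tests with resampling and basis reuse.

    The Moran eigenbasis depends only on the support voxels, so it is
    computed once per distinct support and shared across comparisons.
    """

    def __init__(self, config: RunConfig):
        self.config = config
        self._cache: dict[bytes, spatialnull.MoranBasis] = {}

    def _coarsen(self, bmap: BrainMap) -> BrainMap:
        target = self.config.similarity_resample_mm
        if target is None or all(v >= target for v in bmap.grid.voxel_size_mm):
            return bmap
        return resample(bmap, target)

    def _basis_for(self, ma: BrainMap, mb: BrainMap, support: str) -> spatialnull.MoranBasis:
        sup = spatialnull.extract_support(ma, mb, support)
        key = sup.tobytes()
        if key not in self._cache:
            weights = spatialnull.build_weights(ma.grid, sup)
            self._cache[key] = spatialnull.moran_eigenbasis(weights)
        return self._cache[key]

    def pair(
        self, ma: BrainMap, mb: BrainMap, seed: int, support: str = "intersection_mask"
    ) -> dict:
        ma, mb = self._coarsen(ma), self._coarsen(mb)
        basis = self._basis_for(ma, mb, support)
        ra = spatialnull.similarity_test(
            ma, mb, n_surr=self.config.n_surr, seed=seed,
            permuted_side="a", support=support, basis=basis,
        )
        rb = spatialnull.similarity_test(
            ma, mb, n_surr=self.config.n_surr, seed=seed + 1,
            permuted_side="b", support=support, basis=basis,
        )
        return {"permute_a": _sim_result_dict(ra), "permute_b": _sim_result_dict(rb)}


def run(
    config: RunConfig,
    cohort: Cohort | None = None,
    template_left: BrainMap | None = None,
) -> dict:
    """Execute the configured stages and write the report bundle.

    ``cohort``/``template_left`` may be passed in-memory (tests, library
    use); otherwise they are read from the configured paths.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if cohort is None:
        cohort = read_cohort(config.cohort_dir)
    if template_left is None and config.template_path:
        mask = cohort.analysis_mask
        template_left = read_volume(config.template_path, mask=mask)
    summary: dict = {
        "schema_version": SCHEMA_VERSION,
        "seed": config.seed,
        "config": dataclasses.asdict(config),
        "deviation_tags": list(DEVIATION_TAGS),
        "n_patients": cohort.n,
        "stages": {},
    }

    on_maps = [p.on_map for p in cohort.patients]
    off_maps = [p.off_map for p in cohort.patients]
    deltas = voxelwise.diff_maps(on_maps, off_maps)
    trs_off = np.array([p.trs_off for p in cohort.patients])
    trs_on = np.array([p.trs_on for p in cohort.patients])
    amplitude = np.array([p.amplitude for p in cohort.patients])
    improvement = clinical_mod.cohort_improvement(trs_off, trs_on)
    params = pd.DataFrame(
        {
            "amplitude": amplitude,
            "pulse_width": [p.pulse_width for p in cohort.patients],
            "frequency": [p.frequency for p in cohort.patients],
        }
    )

    tmap = None
    if config.stages.get("clinical", False):
        ptt = clinical_mod.paired_ttest(trs_off, trs_on)
        summary["stages"]["clinical"] = {
            "paired_ttest": dataclasses.asdict(ptt),
            "improvement_mean_of_patients": improvement["mean_of_patient_percentages"],
            "improvement_group_mean_ratio": improvement["group_mean_ratio"],
            "improvement_range": list(improvement["range"]),
        }

    if config.stages.get("stim_effect", False):
        seed = config.stage_seed("stim_effect")
        sm = voxelwise.one_sample_perm_t(deltas, n_perm=config.n_perm, seed=seed)
        tmap = sm.stat
        write_volume(sm.stat, out / "stim_effect_t.nii.gz")
        write_volume(sm.p_fwe, out / "stim_effect_pfwe.nii.gz")
        sm.suprathreshold_table(config.alpha).to_csv(
            out / "stim_effect_suprathreshold.tsv", sep="\t", index=False
        )
        summary["stages"]["stim_effect"] = {
            "seed": seed,
            "n_permutations": sm.n_permutations,
            "exact": sm.exact,
            "n_significant": int(np.sum((sm.p_fwe.data <= config.alpha) & sm.p_fwe.mask)),
        }

    severity_maps = {}
    if config.stages.get("severity_regression", False):
        seed = config.stage_seed("severity_regression")
        reg_off = voxelwise.voxelwise_regression(
            off_maps, trs_off, n_perm=config.n_perm, seed=seed
        )
        reg_on = voxelwise.voxelwise_regression(
            on_maps, trs_on, n_perm=config.n_perm, seed=seed + 1
        )
        reg_imp = voxelwise.voxelwise_regression(
            deltas, improvement["per_patient"], n_perm=config.n_perm, seed=seed + 2
        )
        severity_maps = {
            "off_severity": reg_off.stat,
            "on_residual": reg_on.stat,
            "delta_improvement": reg_imp.stat,
        }
        for name, m in severity_maps.items():
            write_volume(m, out / f"regression_{name}_t.nii.gz")
        summary["stages"]["severity_regression"] = {
            "seed": seed,
            "n_permutations": config.n_perm,
            "maps": sorted(severity_maps),
        }

    template_bilateral = None
    if template_left is not None:
        template_bilateral, _ = alignment_mod.prepare_template(
            template_left, "mirror_template_bilateral"
        )

    if config.stages.get("similarity", False):
        if template_bilateral is None or tmap is None:
            raise ConfigError(
                "similarity stage needs the stim_effect stage and a template"
            )
        seed = config.stage_seed("similarity")
        pairs = {"stim_effect_vs_template": (tmap, template_bilateral)}
        if "off_severity" in severity_maps:
            pairs["off_severity_vs_template"] = (
                severity_maps["off_severity"], template_bilateral
            )
            pairs["stim_effect_vs_off_severity"] = (
                tmap, severity_maps["off_severity"]
            )
        msr = _MsrRunner(config)
        sim_results = {
            name: msr.pair(ma, mb, seed + 2 * i)
            for i, (name, (ma, mb)) in enumerate(sorted(pairs.items()))
        }
        (out / "similarity.json").write_text(json.dumps(sim_results, indent=2, sort_keys=True))
        summary["stages"]["similarity"] = {"seed": seed, "comparisons": sim_results}

    scores_z = None
    if config.stages.get("alignment", False):
        if template_left is None:
            raise ConfigError("alignment stage needs a template")
        results = {}
        ids = [p.id for p in cohort.patients]
        for strategy in ("mirror_template_bilateral", "average_pet_to_left"):
            template, transform = alignment_mod.prepare_template(template_left, strategy)
            ds = [alignment_mod.apply_pet_transform(d, transform) for d in deltas]
            for metric in ("spearman", "product_sum"):
                scores = alignment_mod.cohort_alignment(ds, template, metric, ids=ids)
                scores.table().to_csv(
                    out / f"alignment_{strategy}_{metric}.tsv", sep="\t", index=False
                )
                with_amp = clinical_mod.outcome_regression(
                    improvement["per_patient"], scores.z,
                    covariates=pd.DataFrame({"amplitude": amplitude}),
                )
                results[f"{strategy}/{metric}"] = {
                    "r_squared": with_amp.r_squared,
                    "model_p": with_amp.f_pvalue,
                    "alignment_coef": with_amp.coef["alignment_z"],
                    "alignment_p": with_amp.pvalues["alignment_z"],
                    "covariate_free_r_squared": with_amp.covariate_free.r_squared,
                    "covariate_free_model_p": with_amp.covariate_free.f_pvalue,
                }
                if (
                    strategy == config.mirror_strategy
                    and metric == config.metric
                ):
                    scores_z = scores.z
        screen = clinical_mod.screen_confounds(
            scores_z if scores_z is not None else scores.z, params, alpha=config.alpha
        )
        screen.to_csv(out / "alignment_confound_screen.tsv", sep="\t", index=False)
        summary["stages"]["alignment"] = {
            "outcome_models": results,
            "primary": f"{config.mirror_strategy}/{config.metric}",
        }

    sig_params = ["amplitude"]
    if config.stages.get("local_roi", False):
        try:
            roi = clinical_mod.vta_overlap_roi(cohort, config.min_vta_overlap)
        except EmptyROIError as exc:
            summary["stages"]["local_roi"] = {"error": str(exc)}
        else:
            write_mask(roi.mask, cohort.template_grid, out / "vta_overlap_roi.nii.gz")
            readout = roi.mean_delta if config.local_readout == "delta" else roi.mean_on
            sd = readout.std(ddof=1)
            z_read = (readout - readout.mean()) / sd
            screen = clinical_mod.screen_confounds(z_read, params, alpha=config.alpha)
            screen.to_csv(out / "local_confound_screen.tsv", sep="\t", index=False)
            sig = screen.loc[screen["significant_independent"], "parameter"].tolist()
            sig_params = sig if sig else ["amplitude"]
            amp_model = clinical_mod.outcome_regression(
                z_read, (amplitude - amplitude.mean()) / amplitude.std(ddof=1)
            )
            out_model = clinical_mod.outcome_regression(
                improvement["per_patient"], z_read,
                covariates=pd.DataFrame({"amplitude": amplitude}),
            )
            summary["stages"]["local_roi"] = {
                "n_roi_voxels": roi.n_voxels,
                "readout": config.local_readout,
                "uptake_vs_amplitude_r_squared": amp_model.r_squared,
                "uptake_vs_amplitude_p": amp_model.f_pvalue,
                "improvement_vs_uptake_r_squared": out_model.covariate_free.r_squared
                if out_model.covariate_free else out_model.r_squared,
                "improvement_vs_uptake_with_amplitude_r_squared": out_model.r_squared,
                "screened_significant_parameters": sig,
            }

    glm_results = None
    if config.stages.get("connglm", False):
        seed = config.stage_seed("connglm")
        conn_maps = [p.conn_map for p in cohort.patients]
        glm_results = connglm_mod.connectivity_glm(deltas, conn_maps, amplitude)
        stage = {"seed": seed, "predictors": {}, "screened_covariates": sig_params}
        for pred in ("pos_conn", "neg_conn"):
            write_volume(glm_results.t_map(pred), out / f"connglm_{pred}_t.nii.gz")
            cres = glm_results.cluster_correct(
                pred,
                cluster_forming_p=config.cluster_forming_p,
                n_perm=config.cluster_n_perm,
                seed=seed + (0 if pred == "pos_conn" else 1),
            )
            cres.table().to_csv(out / f"connglm_{pred}_clusters.tsv", sep="\t", index=False)
            stage["predictors"][pred] = {
                "n_clusters": len(cres.clusters),
                "n_significant": len(cres.significant(config.alpha)),
                "min_p": min((c.p for c in cres.clusters), default=None),
                "deviation_tags": list(cres.deviation_tags),
            }
        summary["stages"]["connglm"] = stage

    if config.stages.get("ortcva", False):
        seed = config.stage_seed("ortcva")
        pattern = ortcva_mod.ortcva_fit(
            on_maps, off_maps,
            n_components=config.n_components, n_boot=config.n_boot, seed=seed,
        )
        write_volume(pattern.pattern, out / "ortcva_pattern.nii.gz")
        if pattern.bootstrap_z is not None:
            write_volume(pattern.bootstrap_z, out / "ortcva_bootstrap_z.nii.gz")
        pattern.expression.to_csv(out / "ortcva_expression.tsv", sep="\t", index=False)
        stage = {
            "seed": seed,
            "ordinal_violations": pattern.ordinal_violations,
            "n_components": pattern.n_components,
            "ridge_applied": pattern.ridge_applied,
        }
        if tmap is not None:
            pair = _MsrRunner(config).pair(pattern.pattern, tmap, seed + 100)
            stage["similarity_to_tmap"] = {
                "permute_pattern": pair["permute_a"],
                "permute_tmap": pair["permute_b"],
            }
        summary["stages"]["ortcva"] = stage

    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    return summary
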