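"""Named, seeded, config-driven experiments on a synthetic cohort.

Each experiment tag reproduces one of the study designs on synthetic data:
per-measure subspace analyses of SC, cFC, mFC, CT3 and raw BOLD (d1_*), the
no-GSR control (d2), the three label-permutation controls (d5), pooled
model-generated FC (d6), pooled empirical-plus-simulated FC (d7), the
intrahemispheric-only variant (d8), residual FC (d9), the average-subject
homotopic manipulation (d10), and windowed dynamic FC (d11).

"Empirical" data here means BOLD generated from each subject's *intact* SC
by a reference model held out of the simulated-model list, while "simulated"
FC is generated from the *degraded* SC (interhemispheric links deleted, as
diffusion tractography would miss them).  This planted asymmetry is what
lets the pooled and residual analyses exhibit the homotopic-error structure
the designs probe for.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from functools import cached_property
from pathlib import Path

import numpy as np

from .atlas import generate_atlas
from .cohort import CohortSpec, SCMatrix, degrade_sc, generate_ground_truth_sc, generate_subject_sc
from .fc import (
    BOLDRun,
    ct3,
    dynamic_fc,
    global_signal_regression,
    mi_fc,
    pearson_fc,
    unvectorize,
    vectorize_upper,
)
from .inversion import SCEstimate, estimate_sc_pipeline
from .io import write_report
from .models import (
    HEMODYNAMIC_SETTLE,
    ModelConfig,
    balloon_windkessel,
    config_for_samples,
    simulate_dynamics,
    simulate_fc,
)
from .subspace import (
    DataMatrix,
    bold_to_datamatrix,
    bootstrap_svd,
    permute_dataset,
    pool_datasets,
    residual_fc,
    svd_variance,
)

logger = logging.getLogger(__name__)

EXPERIMENT_TAGS = (
    "d1_sc",
    "d1_cfc",
    "d1_mfc",
    "d1_ct3",
    "d1_bold",
    "d2_nogsr",
    "d5_permutations",
    "d6_simulated",
    "d7_pooled",
    "d8_intrahemispheric",
    "d9_residual",
    "d10_average_subject",
    "d11_dynamic",
)

#: default couplings per model (kept below the linear stability bound where
#: one applies; chosen once for the desk-scale cohort and documented)
DEFAULT_COUPLINGS = {
    "sar": 0.4,
    "rate": 0.7,
    "kuramoto": 0.2,
    "wilson_cowan": 3.0,
    "fitzhugh_nagumo": 0.1,
}


@dataclass
class ExperimentConfig:
    """Desk-scale study configuration; all seeds flow from ``seed``."""

    n_regions: int = 40
    n_subjects: int = 5
    n_samples: int = 200
    tr: float = 3.29
    models: tuple[str, ...] = ("sar", "kuramoto", "rate")
    empirical_model: str = "wilson_cowan"
    couplings: dict = field(default_factory=lambda: dict(DEFAULT_COUPLINGS))
    window_sizes: tuple[int, ...] = (8, 10, 20, 25, 40, 50, 100)
    bootstrap_b: int = 200
    alpha: float = 0.05
    seed: int = 0
    mi_k: int = 4
    gain_sd: float = 0.2
    noise_sd: float = 5e-4
    interhemispheric_miss_rate: float = 0.8
    homotopic_weight: float = 0.02
    homotopic_value: float = 0.5
    density_intra: float = 0.35
    density_inter: float = 0.02
    inversion_floor: float = 1e-6
    inversion_ref: float = 1e-4
    inversion_ref_out: float = 1e-3

    def __post_init__(self):
        for w in self.window_sizes:
            if self.n_samples % w != 0:
                raise ValueError(f"window size {w} does not divide run length {self.n_samples}")
        merged = dict(DEFAULT_COUPLINGS)
        merged.update(self.couplings)
        self.couplings = merged

    @classmethod
    def from_dict(cls, data: dict) -> "ExperimentConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "models" in data:
            data = {**data, "models": tuple(data["models"])}
        if "window_sizes" in data:
            data = {**data, "window_sizes": tuple(data["window_sizes"])}
        return cls(**data)


class SyntheticStudy:
    """Lazily generated cohort and all derived data for one configuration."""

    def __init__(self, config: ExperimentConfig):
        self.config = config
        self.subjects = [f"s{j:02d}" for j in range(config.n_subjects)]

    # ---- cohort ---------------------------------------------------------

    @cached_property
    def atlas(self):
        return generate_atlas(self.config.n_regions)

    @cached_property
    def ground_truth_sc(self) -> SCMatrix:
        c = self.config
        return generate_ground_truth_sc(
            self.atlas,
            density_intra=c.density_intra,
            density_inter=c.density_inter,
            homotopic_weight=c.homotopic_weight,
            seed=c.seed,
        )

    @cached_property
    def cohort_spec(self) -> CohortSpec:
        c = self.config
        return CohortSpec(
            n_subjects=c.n_subjects,
            gain_sd=c.gain_sd,
            noise_sd=c.noise_sd,
            interhemispheric_miss_rate=c.interhemispheric_miss_rate,
            seed=c.seed,
        )

    @cached_property
    def intact_scs(self) -> dict[str, SCMatrix]:
        return {
            s: generate_subject_sc(self.ground_truth_sc, self.cohort_spec, j)
            for j, s in enumerate(self.subjects)
        }

    @cached_property
    def observed_scs(self) -> dict[str, SCMatrix]:
        """Per-subject SC as a tractography pipeline would see it."""
        c = self.config
        return {
            s: degrade_sc(self.intact_scs[s], c.interhemispheric_miss_rate, seed=c.seed + j)
            for j, s in enumerate(self.subjects)
        }

    # ---- signals and FC -------------------------------------------------

    def _model_config(self, model: str, subject_index: int) -> ModelConfig:
        c = self.config
        return config_for_samples(
            model,
            c.n_samples,
            tr=c.tr,
            seed=c.seed * 1000 + subject_index,
            global_coupling=c.couplings[model],
        )

    @cached_property
    def empirical_bold(self) -> dict[str, BOLDRun]:
        """BOLD from the intact SC under the held-out reference model (no GSR)."""
        c = self.config
        runs = {}
        for j, s in enumerate(self.subjects):
            cfg = self._model_config(c.empirical_model, j)
            neural = simulate_dynamics(self.intact_scs[s], cfg)
            bold = balloon_windkessel(neural, tr=c.tr)
            n_drop = int(np.ceil(HEMODYNAMIC_SETTLE / c.tr))
            vals = bold.values[:, n_drop : n_drop + c.n_samples]
            runs[s] = BOLDRun(values=vals, tr=c.tr, gsr_applied=False)
        return runs

    @cached_property
    def empirical_bold_gsr(self) -> dict[str, BOLDRun]:
        return {s: global_signal_regression(r) for s, r in self.empirical_bold.items()}

    @cached_property
    def empirical_cfc(self) -> dict[str, np.ndarray]:
        return {
            s: vectorize_upper(pearson_fc(r), self.atlas).values
            for s, r in self.empirical_bold_gsr.items()
        }

    @cached_property
    def empirical_cfc_matrices(self) -> dict[str, np.ndarray]:
        return {
            s: unvectorize(v, vectorize_upper(np.zeros((self.config.n_regions,) * 2)).index,
                           self.config.n_regions)
            for s, v in self.empirical_cfc.items()
        }

    @cached_property
    def simulated_cfc(self) -> dict[str, dict[str, np.ndarray]]:
        """Per model, per subject: FC simulated from the degraded (observed) SC."""
        c = self.config
        out: dict[str, dict[str, np.ndarray]] = {}
        for model in c.models:
            per_subject = {}
            for j, s in enumerate(self.subjects):
                cfg = self._model_config(model, j)
                vec = simulate_fc(model, self.observed_scs[s], cfg, tr=c.tr,
                                  n_samples=c.n_samples)
                per_subject[s] = vec.values
            out[model] = per_subject
            logger.info("simulated FC for model %s", model)
        return out

    # ---- data matrices --------------------------------------------------

    def sc_datamatrix(self, which: str = "observed") -> DataMatrix:
        scs = self.observed_scs if which == "observed" else self.intact_scs
        return DataMatrix(
            X=np.column_stack(
                [vectorize_upper(scs[s].weights, self.atlas).values for s in self.subjects]
            ),
            subject_ids=list(self.subjects),
            source_tags=["sc"] * len(self.subjects),
        )

    def fc_datamatrix(self, vectors: dict[str, np.ndarray], tag: str) -> DataMatrix:
        return DataMatrix(
            X=np.column_stack([vectors[s] for s in self.subjects]),
            subject_ids=list(self.subjects),
            source_tags=[tag] * len(self.subjects),
        )

    def pooled_datamatrix(self, subset: str = "all") -> DataMatrix:
        dm = pool_datasets(
            [("empirical", self.empirical_cfc)]
            + [(m, d) for m, d in self.simulated_cfc.items()]
        )
        if subset == "intrahemispheric":
            codes = self.atlas.hemisphere_codes()
            idx = vectorize_upper(np.zeros((self.config.n_regions,) * 2)).index
            keep = codes[idx[:, 0]] == codes[idx[:, 1]]
            dm = DataMatrix(
                X=dm.X[keep],
                subject_ids=dm.subject_ids,
                source_tags=dm.source_tags,
            )
        return dm

    # ---- inversion ------------------------------------------------------

    def invert_sc(self) -> SCEstimate:
        c = self.config
        return estimate_sc_pipeline(
            self.empirical_cfc,
            self.simulated_cfc,
            self.observed_scs,
            floor=c.inversion_floor,
            ref=c.inversion_ref,
            ref_out=c.inversion_ref_out,
            B=c.bootstrap_b,
            alpha=c.alpha,
            seed=c.seed,
        )


def _svd_report(study: SyntheticStudy, dm: DataMatrix, extra: dict | None = None) -> dict:
    c = study.config
    res = bootstrap_svd(dm, B=c.bootstrap_b, alpha=c.alpha, seed=c.seed)
    report = {
        "n_features": dm.n_features,
        "n_columns": dm.n_observations,
        **res.summary(),
    }
    if extra:
        report.update(extra)
    return report


def run_experiment(name: str, config: ExperimentConfig, out_dir=None,
                   study: SyntheticStudy | None = None) -> dict:
    """Run one named experiment; returns (and optionally writes) its report."""
    if name not in EXPERIMENT_TAGS:
        raise ValueError(f"unknown experiment tag {name!r}; choose from {EXPERIMENT_TAGS}")
    study = study or SyntheticStudy(config)
    c = config
    report: dict = {"experiment": name, "seed": c.seed}

    if name == "d1_sc":
        dm = study.sc_datamatrix("observed")
        res = bootstrap_svd(dm, B=c.bootstrap_b, alpha=c.alpha, seed=c.seed)
        gt = vectorize_upper(study.ground_truth_sc.weights, study.atlas).values
        report.update(res.summary())
        report["n_features"] = dm.n_features
        report["corr_dim1_with_ground_truth_sc"] = float(
            np.corrcoef(res.left_vectors[:, 0], gt)[0, 1]
        )
    elif name == "d1_cfc":
        report.update(_svd_report(study, study.fc_datamatrix(study.empirical_cfc, "empirical")))
    elif name == "d1_mfc":
        vectors = {
            s: mi_fc(r, k=c.mi_k).values for s, r in study.empirical_bold_gsr.items()
        }
        report.update(_svd_report(study, study.fc_datamatrix(vectors, "empirical_mfc")))
    elif name == "d1_ct3":
        vectors = {
            s: ct3(r, k=c.mi_k).values for s, r in study.empirical_bold_gsr.items()
        }
        report.update(_svd_report(study, study.fc_datamatrix(vectors, "empirical_ct3")))
    elif name == "d1_bold":
        dm = bold_to_datamatrix(study.empirical_bold_gsr)
        report.update(_svd_report(study, dm))
    elif name == "d2_nogsr":
        vectors = {
            s: vectorize_upper(pearson_fc(r), study.atlas).values
            for s, r in study.empirical_bold.items()
        }
        report.update(_svd_report(study, study.fc_datamatrix(vectors, "empirical_nogsr")))
    elif name == "d5_permutations":
        matrices = [study.empirical_cfc_matrices[s] for s in study.subjects]
        modes = {}
        for mode in ("links", "regions", "within_hemisphere"):
            dm = permute_dataset(matrices, study.atlas, mode, seed=c.seed,
                                 subject_ids=study.subjects)
            modes[mode] = _svd_report(study, dm)
        report["modes"] = modes
    elif name == "d6_simulated":
        dm = pool_datasets([(m, d) for m, d in study.simulated_cfc.items()])
        report.update(_svd_report(study, dm))
    elif name == "d7_pooled":
        dm = study.pooled_datamatrix()
        res = bootstrap_svd(dm, B=c.bootstrap_b, alpha=c.alpha, seed=c.seed)
        gt = vectorize_upper(study.ground_truth_sc.weights, study.atlas).values
        report.update(res.summary())
        report["n_features"] = dm.n_features
        report["n_columns"] = dm.n_observations
        report["corr_dim1_with_ground_truth_sc"] = float(
            np.corrcoef(res.left_vectors[:, 0], gt)[0, 1]
        )
    elif name == "d8_intrahemispheric":
        dm = study.pooled_datamatrix(subset="intrahemispheric")
        report.update(_svd_report(study, dm))
    elif name == "d9_residual":
        dm = residual_fc(study.empirical_cfc, study.simulated_cfc)
        report.update(_svd_report(study, dm, extra={"n_columns": dm.n_observations}))
    elif name == "d10_average_subject":
        report.update(_run_average_subject(study))
    elif name == "d11_dynamic":
        windows = {}
        for w in c.window_sizes:
            vectors = {
                s: dynamic_fc(r, w).values for s, r in study.empirical_bold_gsr.items()
            }
            dm = study.fc_datamatrix(vectors, f"dynfc_w{w}")
            res = bootstrap_svd(dm, B=c.bootstrap_b, alpha=c.alpha, seed=c.seed)
            windows[str(w)] = {
                "n_windows": c.n_samples // w,
                "window_duration_s": w * c.tr,
                **res.summary(),
            }
        report["windows"] = windows

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_report(report, out_dir / f"{name}.json")
    return report


def _run_average_subject(study: SyntheticStudy) -> dict:
    """Average-subject manipulation: set homotopic links to a fixed value.

    The average observed SC is fed to every model as-is and with homotopic
    entries forced to ``homotopic_value``; standard (non-bootstrap) SVD of
    the resulting average-FC + simulated-FC matrix shows how restoring
    homotopic links shifts variance onto the first dimension.
    """
    c = study.config
    avg_w = np.mean([study.observed_scs[s].weights for s in study.subjects], axis=0)
    avg_sc = SCMatrix(weights=avg_w, atlas=study.atlas)
    manip_w = avg_w.copy()
    for i, j in study.atlas.homotopic_pairs():
        manip_w[i, j] = manip_w[j, i] = c.homotopic_value
    manip_sc = SCMatrix(weights=manip_w, atlas=study.atlas)
    avg_fc = np.mean([study.empirical_cfc[s] for s in study.subjects], axis=0)

    out = {}
    for label, sc in (("original", avg_sc), ("homotopic_set", manip_sc)):
        cols = [avg_fc]
        tags = ["empirical_avg"]
        for model in c.models:
            cfg = study._model_config(model, 0)
            cols.append(simulate_fc(model, sc, cfg, tr=c.tr, n_samples=c.n_samples).values)
            tags.append(model)
        _, fracs, _, _ = svd_variance(np.column_stack(cols))
        out[label] = {"variance_fraction": [float(f) for f in fracs[:3]]}
    out["homotopic_value"] = c.homotopic_value
    out["first_fraction_gain"] = (
        out["homotopic_set"]["variance_fraction"][0]
        - out["original"]["variance_fraction"][0]
    )
    return out


def run_all(config: ExperimentConfig, out_dir=None) -> dict[str, dict]:
    """Run every experiment tag on a shared synthetic study."""
    study = SyntheticStudy(config)
    return {
        tag: run_experiment(tag, config, out_dir=out_dir, study=study)
        for tag in EXPERIMENT_TAGS
    }
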