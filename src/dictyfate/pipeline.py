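"""Config-driven end-to-end runs with manifests.

A run config is a flat, JSON-compatible mapping (mirroring the CLI flags)
naming the stages to execute, the thresholds and model kinds to apply and
an explicit seed for every stochastic stage.  Outputs are TSV/JSON files
under the configured output directory plus a ``manifest.json`` recording
inputs, parameters, seeds and SHA-256 checksums — identical configs give
byte-identical numeric outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import fitting, io, synthetic, variability
from .classification import classify_remi_mutants
from .fate_model import CCIFEnsemble, DecayParams, FateModelParams
from .perturbation import PerturbationScenario, predict_propensity_curve

__all__ = ["RunConfig", "run_pipeline", "KNOWN_STAGES"]

log = logging.getLogger("dictyfate")

KNOWN_STAGES = ("simulate_timecourse", "simulate_matrix", "fit", "compare",
                "variability", "classify", "perturb")


@dataclass(frozen=True)
class RunConfig:
    """Flat run configuration; round-trips losslessly through JSON."""

    stages: tuple = KNOWN_STAGES
    out_dir: str = "dictyfate_run"
    seed: int = 0
    # model / simulation
    C0_star: float = 0.57
    beta: float = 0.41
    timepoints: tuple = (0.0, 1.0, 2.0, 3.0, 4.0, 5.0)
    cells_per_timepoint: int = 200
    n_sets: int = 4
    model_kinds: tuple = ("linear", "exponential")
    # synthetic matrix
    n_cells: int = 500
    n_stable: int = 400
    n_cycle: int = 50
    n_stochastic: int = 50
    # thresholds
    fdr: float = 0.05
    auroc_threshold: float = 0.65
    min_count: int = 5
    z_enrich: float = 1.5
    z_deplete: float = -1.0
    # optional inputs (synthetic when absent)
    timecourse_path: str | None = None
    matrix_path: str | None = None
    remi_path: str | None = None
    # perturbation
    scenario: str = "burst_up"
    delta_p: float = 0.05
    arrest_t: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "stages", tuple(self.stages))
        object.__setattr__(self, "timepoints", tuple(self.timepoints))
        object.__setattr__(self, "model_kinds", tuple(self.model_kinds))
        unknown = set(self.stages) - set(KNOWN_STAGES)
        if unknown:
            raise ValueError(f"unknown pipeline stage(s): {sorted(unknown)}")

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        return cls(**json.loads(Path(path).read_text()))

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format="%.10g")


def _default_params(cfg: RunConfig) -> FateModelParams:
    return FateModelParams.from_rescaled(cfg.C0_star, cfg.beta)


def _ensemble_params(cfg: RunConfig) -> FateModelParams:
    # ensemble chosen so the rescaled model (C0_star, beta) is reproduced:
    # mu and sigma from the ensemble, R placed so (C0-R)/sigma = C0_star
    ens = CCIFEnsemble(G=100, p_bar=0.5, x_bar=1.0, s2=0.25)
    sigma = float(np.sqrt(ens.sigma2))
    decay = DecayParams(kind="linear", A0=0.0, beta=cfg.beta * sigma)
    return FateModelParams(decay=decay, ccif=ens,
                           R=ens.mu - cfg.C0_star * sigma)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the requested stages in dependency order; return the manifest."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, str] = {}
    manifest: dict = {"config": asdict(config), "seeds": {}, "outputs": {},
                      "thresholds": {"fdr": config.fdr,
                                     "auroc_threshold": config.auroc_threshold,
                                     "min_count": config.min_count,
                                     "z_enrich": config.z_enrich,
                                     "z_deplete": config.z_deplete}}
    stages = [s for s in KNOWN_STAGES if s in config.stages]  # dependency order
    tc = None
    matrix = None

    for stage in stages:
        log.info("stage %s", stage)
        if stage == "simulate_timecourse":
            seed = config.seed
            manifest["seeds"][stage] = seed
            tc = synthetic.simulate_propensity_timecourse(
                _default_params(config), config.timepoints,
                config.cells_per_timepoint, seed=seed, n_sets=config.n_sets)
            path = out_dir / "timecourse.tsv"
            _write_tsv(tc.data, path)
            outputs[stage] = str(path)

        elif stage == "simulate_matrix":
            seed = config.seed + 1
            manifest["seeds"][stage] = seed
            spec = [
                synthetic.GeneClassSpec("stable", config.n_stable, mean=20.0),
                synthetic.GeneClassSpec("cycle_MS", config.n_cycle // 2, mean=10.0),
                synthetic.GeneClassSpec("cycle_G2", config.n_cycle -
                                        config.n_cycle // 2, mean=10.0),
                synthetic.GeneClassSpec("stochastic", config.n_stochastic,
                                        p=0.1, b=50.0),
            ]
            matrix = synthetic.simulate_expression_matrix(
                config.n_cells, spec, seed=seed)
            path = out_dir / "counts.tsv"
            io.write_dense_tsv(matrix.counts, path)
            truth = out_dir / "gene_truth.tsv"
            _write_tsv(matrix.gene_truth, truth, index=True)
            outputs[stage] = str(path)
            outputs[stage + ".truth"] = str(truth)

        elif stage in ("fit", "compare"):
            data = _load_timecourse(config, tc, stage)
            norm = fitting.normalize_propensity_sets(data)
            if stage == "fit":
                fit = fitting.fit_model(norm, "linear")
                path = out_dir / "fit.json"
                path.write_text(json.dumps(fit.to_dict(), indent=2) + "\n")
            else:
                cmp_ = fitting.compare_models(norm, config.model_kinds)
                path = out_dir / "model_comparison.tsv"
                _write_tsv(cmp_.to_frame(), path)
            outputs[stage] = str(path)

        elif stage == "variability":
            counts = _load_matrix(config, matrix, stage)
            res = variability.call_variable_genes(
                counts, fdr_threshold=config.fdr, min_count=config.min_count)
            norm, _ = variability.normalize_counts(counts)
            if matrix is not None:
                groups = matrix.cell_truth["phase"]
            else:
                groups = pd.qcut(norm.sum(axis=0), 2, labels=["lo", "hi"])
            aur = variability.auroc_association(
                norm, groups, threshold=config.auroc_threshold)
            classes = variability.partition_variable_genes(
                res, aur["cycle_associated"])
            res_out = res.assign(max_auroc=aur["max_auroc"],
                                 **{"class": classes})
            path = out_dir / "variability.tsv"
            _write_tsv(res_out, path, index=True)
            outputs[stage] = str(path)

        elif stage == "classify":
            if config.remi_path:
                records = pd.read_csv(config.remi_path, sep="\t")
            else:
                records = _demo_remi_table(config.seed + 2)
                manifest["seeds"][stage] = config.seed + 2
            classified = classify_remi_mutants(
                records, z_enrich=config.z_enrich, z_deplete=config.z_deplete)
            path = out_dir / "remi_classes.tsv"
            _write_tsv(classified, path)
            outputs[stage] = str(path)

        elif stage == "perturb":
            params = _ensemble_params(config)
            scenario = PerturbationScenario(kind=config.scenario,
                                            delta_p=config.delta_p,
                                            arrest_t=config.arrest_t)
            grid = np.linspace(0.0, max(config.timepoints), 51)
            curve = predict_propensity_curve(params, scenario, grid)
            path = out_dir / "perturbation_curve.tsv"
            _write_tsv(curve, path)
            outputs[stage] = str(path)

    for name, path in outputs.items():
        manifest["outputs"][name] = {"path": path, "sha256": _sha256(Path(path))}
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest


def _load_timecourse(config: RunConfig, tc, stage: str):
    if tc is not None:
        return tc
    if config.timecourse_path:
        return fitting.read_timecourse(config.timecourse_path)
    raise FileNotFoundError(
        f"stage {stage!r}: no time course available — run simulate_timecourse "
        "or set timecourse_path")


def _load_matrix(config: RunConfig, matrix, stage: str) -> pd.DataFrame:
    if matrix is not None:
        return matrix.counts
    if config.matrix_path:
        return io.read_dense_tsv(config.matrix_path)
    raise FileNotFoundError(
        f"stage {stage!r}: no count matrix available — run simulate_matrix "
        "or set matrix_path")


def _demo_remi_table(seed: int) -> pd.DataFrame:
    """Small synthetic REMI Z-score table for demo runs (no real screen data)."""
    rng = np.random.default_rng(seed)
    n = 100
    return pd.DataFrame({
        "mutant_id": [f"m{i:03d}" for i in range(n)],
        "gene_id": [f"gene{i:03d}" for i in range(n)],
        "z_dif_r2": rng.normal(1.0, 1.0, n).round(3),
        "z_dif_r6": rng.normal(1.0, 1.0, n).round(3),
        "z_camp": rng.normal(0.0, 1.0, n).round(3),
        "growth_flag": rng.random(n) < 0.1,
    })
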