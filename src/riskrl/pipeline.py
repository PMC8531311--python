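"""End-to-end orchestration: simulate -> fit -> compare -> recover -> analyze.

A run is fully described by a :class:`RunConfig` (serializable to YAML) plus
its master seed; every stage draws its randomness from named substreams of
that seed, and each output file is checksummed into a manifest, so re-running
the same config reproduces identical delimited outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import io as rio
from .analysis import learning_rate_contrast, summarize_behavior
from .fitting import em_fit
from .models import get_model
from .recovery import run_model_recovery, run_parameter_recovery
from .simulate import TraitSpec, default_population, sample_population, sample_traits

log = logging.getLogger("riskrl")


@dataclass
class RunConfig:
    """Everything needed to reproduce a pipeline run."""

    seed: int = 0
    models: list[str] = field(default_factory=lambda: ["standard", "hybrid"])
    simulate_model: str = "hybrid"
    n_subjects: int = 8
    beta_shift: float = 1.0
    mc_samples: int = 300
    em_max_iter: int = 200
    em_tol: float = 1e-2
    em_restarts: int = 5
    recovery_datasets: int = 5
    out_dir: str = "runs/run0"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        unknown = set(payload) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**payload)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _stream(seed: int, *key: int) -> int:
    return int(
        np.random.SeedSequence(seed, spawn_key=tuple(key)).generate_state(1)[0]
        % (2**31)
    )


def run_pipeline(config: RunConfig) -> Path:
    """Execute all stages, writing artifacts and a checksummed manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": asdict(config), "stages": {}}
    manifest_path = out / "manifest.json"

    def record(stage: str, *paths: Path) -> None:
        manifest["stages"].setdefault(stage, {"files": {}, "seed": None})
        for p in paths:
            manifest["stages"][stage]["files"][str(p.relative_to(out))] = _checksum(p)
        manifest_path.write_text(json.dumps(manifest, indent=2))

    try:
        # --- simulate -------------------------------------------------
        model = get_model(config.simulate_model)
        pop = default_population(model, config.n_subjects, config.beta_shift)
        sim_seed = _stream(config.seed, 0)
        manifest["stages"]["simulate"] = {"files": {}, "seed": sim_seed}
        pairs = sample_population(pop, sim_seed)
        cohort = [d for _, d in pairs]
        choices_path = rio.write_choices(cohort, out / "choices.csv")
        truth = model.to_natural(np.array([p.raw_array for p, _ in pairs]))
        trait_spec = TraitSpec(n_subjects=config.n_subjects)
        traits, _ = sample_traits(trait_spec, None, _stream(config.seed, 0, 1))
        traits_path = rio.write_traits(traits, out / "traits.csv")
        record("simulate", choices_path, traits_path)
        log.info("simulated %d subjects", config.n_subjects)

        # --- fit + compare --------------------------------------------
        results = []
        for j, name in enumerate(config.models):
            result = em_fit(
                cohort,
                get_model(name),
                max_iter=config.em_max_iter,
                tol=config.em_tol,
                seed=_stream(config.seed, 1, j),
                n_restarts=config.em_restarts,
                mc_samples=config.mc_samples,
            )
            results.append(result)
            rio.write_fit_result(result, out / "fits")
            log.info("fitted %s: iBIC=%.2f", name, result.ibic)
        fit_files = sorted((out / "fits").glob("*"))
        record("fit", *fit_files)
        cmp_path = rio.write_comparison(results, out / "comparison.csv")
        record("compare", cmp_path)

        # --- recover (scaled down) ------------------------------------
        rec_dir = out / "recovery"
        rec_dir.mkdir(exist_ok=True)
        em_kwargs = {
            "max_iter": min(config.em_max_iter, 20),
            "n_restarts": min(config.em_restarts, 2),
        }
        confusion = run_model_recovery(
            config.models,
            n_datasets=config.recovery_datasets,
            seed=_stream(config.seed, 2),
            mc_samples=config.mc_samples,
            em_kwargs=em_kwargs,
        )
        confusion.counts.to_csv(rec_dir / "confusion_counts.csv")
        confusion.mean_ibic.to_csv(rec_dir / "confusion_mean_ibic.csv")
        report = run_parameter_recovery(
            config.simulate_model,
            n_datasets=max(config.n_subjects, 4),
            seed=_stream(config.seed, 3),
            mc_samples=config.mc_samples,
            em_kwargs=em_kwargs,
        )
        report.correlations.rename("r").to_csv(rec_dir / "parameter_recovery.csv")
        record("recover", *sorted(rec_dir.glob("*")))

        # --- analyze --------------------------------------------------
        ana_dir = out / "analysis"
        ana_dir.mkdir(exist_ok=True)
        summary = summarize_behavior(cohort)
        summary.advantageous.to_csv(ana_dir / "advantageous.csv", index=False)
        summary.risk.to_csv(ana_dir / "risk.csv", index=False)
        summary.reflection.rename("reflection").to_csv(ana_dir / "reflection.csv")
        record("analyze", *sorted(ana_dir.glob("*")))
        manifest["status"] = "complete"
        manifest_path.write_text(json.dumps(manifest, indent=2))
    except Exception as exc:
        manifest["status"] = "failed"
        manifest["error"] = f"{type(exc).__name__}: {exc}"
        manifest_path.write_text(json.dumps(manifest, indent=2))
        raise
    return out
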