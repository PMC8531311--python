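"""Delimited-text I/O for choice data, trait tables, and fit reports.

Choice data: one row per trial with header
``subject,domain,trial,opt_left,opt_right,chosen,outcome``; domain is
``gain``/``loss`` and outcome the coded integer.  Rows whose ``chosen`` or
``outcome`` field is empty (missed responses) are dropped on read.  Trait
tables carry ``subject,pp,sp,ta``.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .fitting import FitResult
from .task import SubjectDataset, cohort_from_frame, cohort_to_frame

CHOICE_COLUMNS = ("subject", "domain", "trial", "opt_left", "opt_right",
                  "chosen", "outcome")
TRAIT_COLUMNS = ("subject", "pp", "sp", "ta")


def _sep(path: Path) -> str:
    return "\t" if path.suffix in (".tsv", ".tab") else ","


def write_choices(cohort: Iterable[SubjectDataset], path: str | Path) -> Path:
    path = Path(path)
    cohort_to_frame(cohort).to_csv(path, sep=_sep(path), index=False)
    return path


def read_choices(path: str | Path) -> list[SubjectDataset]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"choice data file not found: {path}")
    frame = pd.read_csv(path, sep=_sep(path))
    missing = set(CHOICE_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    # missed responses: no recorded choice or outcome
    frame = frame.dropna(subset=["chosen", "outcome"])
    return cohort_from_frame(frame)


def write_traits(traits: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    traits.to_csv(path, sep=_sep(path), index=False)
    return path


def read_traits(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"trait table not found: {path}")
    frame = pd.read_csv(path, sep=_sep(path))
    missing = set(TRAIT_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return frame


def write_fit_result(result: FitResult, out_dir: str | Path) -> Path:
    """Write a fit report: subject MAP table (CSV) + JSON summary."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.map_table().to_csv(out / f"{result.model_name}_map.csv", index=False)
    summary = {
        "model": result.model_name,
        "lml": result.lml,
        "ibic": result.ibic,
        "n_obs": result.n_obs,
        "converged": result.converged,
        "em_trace": list(result.em_trace),
        "prior_mean": result.prior.mean.tolist(),
        "prior_variance": result.prior.variance.tolist(),
        "slots": list(result.prior.model.slot_names),
    }
    with open(out / f"{result.model_name}_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    return out


def write_comparison(results: Sequence[FitResult], path: str | Path) -> Path:
    """Ranked model-comparison table (ascending iBIC)."""
    path = Path(path)
    rows = [
        {
            "model": r.model_name,
            "n_params": r.prior.model.n_params,
            "ibic": r.ibic,
            "neg_lml": -r.lml,
            "converged": r.converged,
        }
        for r in results
    ]
    frame = pd.DataFrame(rows).sort_values("ibic").reset_index(drop=True)
    frame.to_csv(path, sep=_sep(path), index=False)
    return path
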