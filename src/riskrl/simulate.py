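"""Generative simulation: RL agents, population samples, and trait scores.

Agents play the same 420-trial task the participants did, choosing between
the two presented options by softmax over current values and learning from
the sampled outcome with the model's update rule.  Population sampling draws
each subject's raw-scale parameters from independent Gaussians; when
emulating the recovery protocol the sampled inverse temperature is shifted
by +1 on the natural scale to keep choices from being too random to fit.

Trait-score generation is a synthetic stand-in for questionnaire data
(primary/secondary psychopathy, trait anxiety): traits are Gaussian, and a
requested set of standardized trait (or trait-interaction) effects can be
imprinted onto RL parameters so the moderated-regression machinery is
testable against known ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .models import ModelSpec, ParameterVector
from .task import (
    BLOCK_ORDERS,
    DOMAINS,
    GAIN,
    LOSS,
    ChoiceRecord,
    Option,
    SubjectDataset,
    TrialSchedule,
    build_schedule,
    draw_outcome,
)

TRAITS = ("pp", "sp", "ta")  # primary/secondary psychopathy, trait anxiety


def _child_seed(seed_seq: np.random.SeedSequence) -> int:
    """A 31-bit integer seed derived from a SeedSequence."""
    return int(seed_seq.generate_state(1, dtype=np.uint32)[0] % (2**31))


def simulate_subject(
    params: ParameterVector,
    model: ModelSpec,
    schedules: tuple[TrialSchedule, TrialSchedule],
    block_order: str = "gain-first",
    seed: int = 0,
    subject_id: str = "sim",
) -> SubjectDataset:
    """Simulate one agent through both blocks of the task.

    Choices are sampled from the softmax over the presented pair's current
    values; the chosen option's value is updated with the drawn outcome's
    subjective utility.  Values start at zero and reset between blocks.
    """
    if block_order not in BLOCK_ORDERS:
        raise ValueError(f"unknown block order: {block_order!r}")
    by_domain = {s.domain: s for s in schedules}
    if set(by_domain) != set(DOMAINS):
        raise ValueError("schedules must cover both domains exactly once")
    p8 = model.kernel_params(params.natural)
    alphas = p8[:4]
    if np.any((alphas <= 0.0) | (alphas >= 1.0)):
        raise ValueError("learning rates must lie in (0, 1)")

    rng = np.random.default_rng(seed)
    order = (GAIN, LOSS) if block_order == "gain-first" else (LOSS, GAIN)
    records: list[ChoiceRecord] = []
    for dom in order:
        d = 0 if dom == GAIN else 1
        beta = p8[4 + d]
        q = dict.fromkeys(("Z1", "Z2", "T10", "W20", "R"), 0.0)
        options = {oid: Option.make(oid, dom) for oid in q}
        for t, (left, right) in enumerate(by_domain[dom].trials):
            dq = beta * (q[left] - q[right])
            p_left = 1.0 / (1.0 + np.exp(-dq)) if dq > -700 else 0.0
            chosen = left if rng.random() < p_left else right
            outcome = draw_outcome(options[chosen], rng)
            if outcome == 2:
                u = 2.0 * p8[6]
            elif outcome == -2:
                u = -2.0 * p8[7]
            else:
                u = float(outcome)
            pe = u - q[chosen]
            if pe > 0.0:
                q[chosen] += p8[0 + d] * pe
            elif pe < 0.0:
                q[chosen] += p8[2 + d] * pe
            records.append(
                ChoiceRecord(t + 1, dom, (left, right), chosen, outcome)
            )
    return SubjectDataset(subject_id, records, block_order)


@dataclass
class PopulationSpec:
    """Gaussian population over a model's raw-scale parameters.

    ``beta_shift`` is added to the natural-scale inverse temperature after
    transformation (1.0 when emulating the recovery protocol, else 0).
    """

    model: ModelSpec
    raw_means: np.ndarray
    raw_sds: np.ndarray
    n_subjects: int
    beta_shift: float = 0.0

    def __post_init__(self) -> None:
        self.raw_means = np.asarray(self.raw_means, dtype=float)
        self.raw_sds = np.asarray(self.raw_sds, dtype=float)
        k = self.model.n_params
        if self.raw_means.shape != (k,) or self.raw_sds.shape != (k,):
            raise ValueError(f"means/sds must have shape ({k},)")
        if np.any(self.raw_sds < 0):
            raise ValueError("raw_sds must be non-negative")
        if self.beta_shift < 0:
            raise ValueError("beta_shift must be non-negative")


def default_population(
    model: ModelSpec, n_subjects: int, beta_shift: float = 1.0
) -> PopulationSpec:
    """Dispersed recovery population: learning rates spread over roughly
    0.1-0.9, inverse temperature around 2-4 after the +1 shift, utility
    weight around 1, raw SDs 1.0."""
    means = []
    for slot in model.slots:
        if slot.kind == "alpha":
            means.append(-0.5)
        elif slot.kind == "beta":
            means.append(0.7)
        else:
            means.append(0.0)
    return PopulationSpec(
        model, np.array(means), np.ones(model.n_params), n_subjects, beta_shift
    )


def sample_parameters(
    spec: PopulationSpec, rng: np.random.Generator
) -> ParameterVector:
    """Draw one subject's parameters; returns the (possibly shifted) truth."""
    raw = rng.normal(spec.raw_means, spec.raw_sds)
    natural = spec.model.to_natural(raw)
    if spec.beta_shift:
        for j, slot in enumerate(spec.model.slots):
            if slot.kind == "beta":
                natural[j] += spec.beta_shift
    return ParameterVector.from_natural(spec.model, natural)


def sample_population(
    spec: PopulationSpec, seed: int
) -> list[tuple[ParameterVector, SubjectDataset]]:
    """Draw a cohort of parameter vectors and simulate each subject.

    Block order alternates gain-first / loss-first across subjects.  All
    randomness (parameter draws, schedules, choices, outcomes) derives from
    ``seed`` through named substreams, so identical seeds reproduce the
    cohort bit-for-bit.
    """
    root = np.random.SeedSequence(seed)
    param_rng = np.random.default_rng(root.spawn(1)[0])
    cohort: list[tuple[ParameterVector, SubjectDataset]] = []
    for i in range(spec.n_subjects):
        subj_seq = np.random.SeedSequence(seed, spawn_key=(1, i))
        sched_g, sched_l, sim = subj_seq.spawn(3)
        params = sample_parameters(spec, param_rng)
        schedules = (
            build_schedule(GAIN, _child_seed(sched_g)),
            build_schedule(LOSS, _child_seed(sched_l)),
        )
        order = BLOCK_ORDERS[i % 2]
        data = simulate_subject(
            params,
            spec.model,
            schedules,
            order,
            seed=_child_seed(sim),
            subject_id=f"sim{i:03d}",
        )
        cohort.append((params, data))
    return cohort


@dataclass
class TraitSpec:
    """Synthetic questionnaire-score generator.

    ``target_effects`` is a list of (trait term, parameter slot, standardized
    slope) triples; a trait term is either a single trait name ('pp', 'sp',
    'ta') or an interaction 'pp:ta'.  Targeted parameter slots are
    regenerated as linear functions of the standardized traits plus Gaussian
    noise scaled so the requested slopes are population standardized
    coefficients.
    """

    n_subjects: int
    means: dict[str, float] = field(
        default_factory=lambda: {"pp": 34.4, "sp": 21.0, "ta": 49.1}
    )
    sds: dict[str, float] = field(
        default_factory=lambda: {"pp": 5.4, "sp": 3.7, "ta": 11.1}
    )
    target_effects: list[tuple[str, str, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if any(self.sds[t] <= 0 for t in TRAITS):
            raise ValueError("trait sds must be positive")
        for term, _, slope in self.target_effects:
            if not np.isfinite(slope):
                raise ValueError("slopes must be finite")
            for part in term.split(":"):
                if part not in TRAITS:
                    raise ValueError(f"unknown trait {part!r} in {term!r}")


def sample_traits(
    trait_spec: TraitSpec,
    true_params: Sequence[ParameterVector] | None,
    seed: int,
) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """Generate trait scores and optionally imprint effects on parameters.

    Returns (trait table, modified natural-scale parameter table).  The
    second element is ``None`` when no parameters were supplied.  With empty
    ``target_effects`` the traits are independent of every parameter.
    """
    n = trait_spec.n_subjects
    if true_params is not None and len(true_params) != n:
        raise ValueError("true_params length must match n_subjects")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    z = {t: rng.standard_normal(n) for t in TRAITS}
    traits = pd.DataFrame(
        {t: trait_spec.means[t] + trait_spec.sds[t] * z[t] for t in TRAITS}
    )
    traits.insert(0, "subject", [f"sim{i:03d}" for i in range(n)])

    if true_params is None:
        return traits, None

    model = true_params[0].model
    table = pd.DataFrame(
        [p.as_dict("natural") for p in true_params],
        index=traits["subject"],
    )
    by_slot: dict[str, list[tuple[str, float]]] = {}
    for term, slot, slope in trait_spec.target_effects:
        by_slot.setdefault(slot, []).append((term, slope))
    for slot, effects in by_slot.items():
        col = table[slot].to_numpy()
        mu, sd = col.mean(), col.std()
        sd = sd if sd > 0 else 1.0
        total = sum(s**2 for _, s in effects)
        noise_sd = np.sqrt(max(1.0 - total, 0.05))
        y = rng.standard_normal(n) * noise_sd
        for term, slope in effects:
            parts = term.split(":")
            x = np.ones(n)
            for p in parts:
                x = x * z[p]
            y = y + slope * x
        # map the standardized construct back onto the slot's original scale
        table[slot] = mu + sd * y
        if model.slots[model.slot_index(slot)].kind == "alpha":
            table[slot] = table[slot].clip(0.01, 0.99)
    return traits, table.reset_index()
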