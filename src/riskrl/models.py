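"""Reinforcement-learning model family for the gain/loss task.

All models are Rescorla–Wagner delta-rule learners with softmax choice.  The
family is generated by three optional elaborations of the standard two-
parameter model:

* separate learning rates for positive and negative prediction errors
  (``alpha_p`` / ``alpha_n``);
* a multiplicative subjective-utility weight ``kappa`` on the large (±20)
  outcome, so the coded reward 2 enters the update as ``2*kappa_g`` and -2 as
  ``-2*kappa_l``;
* splitting any of the three parameter kinds by domain (gain vs loss).

Eight variants are registered (see :data:`MODELS`), with free-parameter
counts 2, 3, 3, 4, 5, 6, 5 and 8.  Subject-level parameters live on an
unbounded "raw" scale used by the hierarchical fitter; learning rates map to
(0, 1) through a sigmoid and inverse temperature / utility weights map to
(0, inf) through an exponential.  A diagnostic variant with an identity
transform on the inverse temperature (admitting negative values) is also
registered for checking that fitted choice behavior is value-guided.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.special import expit, logit

from . import _kernels
from .task import GAIN, LOSS, SubjectDataset

SIGMOID = "sigmoid"
EXP = "exp"
IDENTITY = "identity"

_FORWARD = {SIGMOID: expit, EXP: np.exp, IDENTITY: np.asarray}
_INVERSE = {SIGMOID: logit, EXP: np.log, IDENTITY: np.asarray}


@dataclass(frozen=True)
class Slot:
    """One free parameter: its kind, scale transform, and routing.

    ``pe_sign`` restricts a learning rate to positive ('P') or negative ('N')
    prediction errors; ``domain`` restricts any slot to one domain.  ``None``
    means the slot applies to both cases.
    """

    name: str
    kind: str  # 'alpha' | 'beta' | 'kappa'
    transform: str = SIGMOID
    pe_sign: str | None = None
    domain: str | None = None


@dataclass(frozen=True)
class ModelSpec:
    """Declarative description of one model variant.

    ``fixed`` pins kernel quantities for reduced/diagnostic models, e.g.
    ``{"beta": 0.0}`` yields a pure random-choice likelihood regardless of
    the remaining parameters (useful as a closed-form test case).
    """

    name: str
    slots: tuple[Slot, ...]
    fixed: tuple[tuple[str, float], ...] = ()

    @property
    def n_params(self) -> int:
        return len(self.slots)

    @property
    def slot_names(self) -> tuple[str, ...]:
        return tuple(s.name for s in self.slots)

    def slot_index(self, name: str) -> int:
        return self.slot_names.index(name)

    def to_natural(self, raw: np.ndarray) -> np.ndarray:
        raw = np.asarray(raw, dtype=float)
        out = np.empty_like(raw)
        # optimizer line searches may probe absurd raw values; exp overflow
        # to inf is handled downstream (infinite temperature -> -inf loglik)
        with np.errstate(over="ignore"):
            for j, slot in enumerate(self.slots):
                out[..., j] = _FORWARD[slot.transform](raw[..., j])
        return out

    def to_raw(self, natural: np.ndarray) -> np.ndarray:
        natural = np.asarray(natural, dtype=float)
        out = np.empty_like(natural)
        for j, slot in enumerate(self.slots):
            out[..., j] = _INVERSE[slot.transform](natural[..., j])
        return out

    def _select(self, kind: str, sign: str | None, domain: str) -> int | None:
        """Index of the unique slot serving (kind, PE sign, domain)."""
        matches = [
            j
            for j, s in enumerate(self.slots)
            if s.kind == kind
            and s.pe_sign in (None, sign)
            and s.domain in (None, domain)
        ]
        if not matches:
            return None
        if len(matches) > 1:  # pragma: no cover - registry is validated
            raise ValueError(
                f"{self.name}: ambiguous {kind} slot for sign={sign}, "
                f"domain={domain}"
            )
        return matches[0]

    def kernel_map(self) -> list[tuple[int, float]]:
        """Mapping from natural-scale slots to the 8-entry kernel layout.

        Layout: [a_p(gain), a_p(loss), a_n(gain), a_n(loss), beta(gain),
        beta(loss), kappa_gain, kappa_loss].  Each entry is (slot index,
        default) with index -1 meaning "use the default constant".
        """
        fixed = dict(self.fixed)
        entries: list[tuple[int, float]] = []
        for kind, sign, default_key, default in (
            ("alpha", "P", "alpha", np.nan),
            ("alpha", "N", "alpha", np.nan),
            ("beta", None, "beta", np.nan),
            ("kappa", None, "kappa", 1.0),
        ):
            for domain in (GAIN, LOSS):
                if default_key in fixed:
                    entries.append((-1, float(fixed[default_key])))
                    continue
                j = self._select(kind, sign, domain)
                if j is None:
                    if np.isnan(default):
                        raise ValueError(
                            f"{self.name}: no slot or fixed value for {kind}"
                        )
                    entries.append((-1, default))
                else:
                    entries.append((j, 0.0))
        # reorder: the loop above yields pairs (gain, loss) already in the
        # kernel's [0..7] order: ap_g, ap_l, an_g, an_l, b_g, b_l, k_g, k_l
        return entries

    def kernel_params(self, natural: np.ndarray) -> np.ndarray:
        """Expand natural-scale parameters into the kernel's 8-vector(s).

        Accepts a (k,) vector or an (S, k) matrix; returns (8,) or (S, 8).
        """
        natural = np.asarray(natural, dtype=float)
        single = natural.ndim == 1
        nat = np.atleast_2d(natural)
        out = np.empty((nat.shape[0], 8))
        for col, (j, const) in enumerate(self.kernel_map()):
            out[:, col] = const if j < 0 else nat[:, j]
        return out[0] if single else out


@dataclass(frozen=True)
class ParameterVector:
    """A subject's parameters on the raw (unbounded) scale, with transforms."""

    model: ModelSpec
    raw: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.raw) != self.model.n_params:
            raise ValueError(
                f"expected {self.model.n_params} raw values for "
                f"{self.model.name}, got {len(self.raw)}"
            )

    @property
    def raw_array(self) -> np.ndarray:
        return np.asarray(self.raw, dtype=float)

    @property
    def natural(self) -> np.ndarray:
        return self.model.to_natural(self.raw_array)

    def as_dict(self, scale: str = "natural") -> dict[str, float]:
        values = self.natural if scale == "natural" else self.raw_array
        return dict(zip(self.model.slot_names, map(float, values)))

    def __getitem__(self, name: str) -> float:
        return float(self.natural[self.model.slot_index(name)])

    @classmethod
    def from_natural(
        cls, model: ModelSpec, natural: Sequence[float] | Mapping[str, float]
    ) -> "ParameterVector":
        if isinstance(natural, Mapping):
            natural = [natural[n] for n in model.slot_names]
        raw = model.to_raw(np.asarray(natural, dtype=float))
        return cls(model, tuple(map(float, raw)))


def _a(name: str, sign: str | None = None, domain: str | None = None) -> Slot:
    return Slot(name, "alpha", SIGMOID, sign, domain)


def _b(name: str, domain: str | None = None, transform: str = EXP) -> Slot:
    return Slot(name, "beta", transform, None, domain)


def _k(name: str, domain: str | None = None) -> Slot:
    return Slot(name, "kappa", EXP, None, domain)


#: The eight registered model variants, in increasing elaboration.
MODELS: dict[str, ModelSpec] = {
    "standard": ModelSpec("standard", (_a("alpha"), _b("beta"))),
    "dual_alpha": ModelSpec(
        "dual_alpha", (_a("alpha_p", "P"), _a("alpha_n", "N"), _b("beta"))
    ),
    "utility": ModelSpec("utility", (_a("alpha"), _b("beta"), _k("kappa"))),
    "hybrid": ModelSpec(
        "hybrid",
        (_a("alpha_p", "P"), _a("alpha_n", "N"), _b("beta"), _k("kappa")),
    ),
    "hybrid_beta_split": ModelSpec(
        "hybrid_beta_split",
        (
            _a("alpha_p", "P"),
            _a("alpha_n", "N"),
            _b("beta_g", GAIN),
            _b("beta_l", LOSS),
            _k("kappa"),
        ),
    ),
    "hybrid_alpha_split": ModelSpec(
        "hybrid_alpha_split",
        (
            _a("alpha_gp", "P", GAIN),
            _a("alpha_gn", "N", GAIN),
            _a("alpha_lp", "P", LOSS),
            _a("alpha_ln", "N", LOSS),
            _b("beta"),
            _k("kappa"),
        ),
    ),
    "hybrid_kappa_split": ModelSpec(
        "hybrid_kappa_split",
        (
            _a("alpha_p", "P"),
            _a("alpha_n", "N"),
            _b("beta"),
            _k("kappa_g", GAIN),
            _k("kappa_l", LOSS),
        ),
    ),
    "hybrid_full": ModelSpec(
        "hybrid_full",
        (
            _a("alpha_gp", "P", GAIN),
            _a("alpha_gn", "N", GAIN),
            _a("alpha_lp", "P", LOSS),
            _a("alpha_ln", "N", LOSS),
            _b("beta_g", GAIN),
            _b("beta_l", LOSS),
            _k("kappa_g", GAIN),
            _k("kappa_l", LOSS),
        ),
    ),
}

#: Diagnostic variant: inverse temperature on an identity scale, so negative
#: values are admissible (used to check that choices are value-guided).
MODELS["hybrid_beta_identity"] = ModelSpec(
    "hybrid_beta_identity",
    (
        _a("alpha_p", "P"),
        _a("alpha_n", "N"),
        _b("beta", transform=IDENTITY),
        _k("kappa"),
    ),
)


def get_model(name: str) -> ModelSpec:
    try:
        return MODELS[name]
    except KeyError:
        raise KeyError(
            f"unknown model {name!r}; registered: {sorted(MODELS)}"
        ) from None


def list_models() -> dict[str, tuple[str, ...]]:
    """Machine-readable registry listing: model name -> parameter slots."""
    return {name: spec.slot_names for name, spec in MODELS.items()}


def utility(
    outcome_coded: int, model: ModelSpec, params: ParameterVector
) -> float:
    """Subjective value of a coded outcome.

    0 and ±1 pass through unchanged; +2 is weighted by the gain-domain
    utility parameter and -2 by the loss-domain one (1 when the model has no
    utility parameter).
    """
    if outcome_coded not in (-2, -1, 0, 1, 2):
        raise ValueError(f"outcome {outcome_coded} outside coded range")
    p8 = model.kernel_params(params.natural)
    if outcome_coded == 2:
        return float(2.0 * p8[6])
    if outcome_coded == -2:
        return float(-2.0 * p8[7])
    return float(outcome_coded)


def update_value(
    q: float,
    subjective_outcome: float,
    model: ModelSpec,
    params: ParameterVector,
    domain: str,
) -> tuple[float, float]:
    """One delta-rule update of the chosen option's value.

    The learning rate is selected by the sign of the prediction error and,
    in domain-split models, by the trial's domain.  A zero prediction error
    leaves the value unchanged (no rate needs selecting).
    """
    pe = subjective_outcome - q
    p8 = model.kernel_params(params.natural)
    d = 0 if domain == GAIN else 1
    if pe > 0:
        alpha = p8[0 + d]
    elif pe < 0:
        alpha = p8[2 + d]
    else:
        return q, 0.0
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"learning rate {alpha} outside (0, 1)")
    return q + alpha * pe, pe


def choice_probability(q_chosen: float, q_other: float, beta: float) -> float:
    """Softmax probability of the chosen option among the presented pair."""
    return float(expit(beta * (q_chosen - q_other)))


def sequence_log_likelihood(
    data: SubjectDataset, model: ModelSpec, params: ParameterVector
) -> float:
    """Log likelihood of a subject's choice sequence under the model.

    Replays trials in presentation order, accumulating the log softmax
    probability of each observed choice and updating only the chosen
    option's value with the observed outcome's subjective utility.  Values
    reset to zero at block boundaries.
    """
    chosen, other, outcome, domain, block_start = data.arrays()
    p8 = model.kernel_params(params.natural)
    return float(
        _kernels.loglik_one(chosen, other, outcome, domain, block_start, p8)
    )


def sequence_log_likelihood_batch(
    data: SubjectDataset, model: ModelSpec, natural_matrix: np.ndarray
) -> np.ndarray:
    """Log likelihood of one dataset under many parameter vectors (S, k)."""
    chosen, other, outcome, domain, block_start = data.arrays()
    p8 = np.ascontiguousarray(model.kernel_params(natural_matrix))
    return _kernels.loglik_batch(chosen, other, outcome, domain, block_start, p8)
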