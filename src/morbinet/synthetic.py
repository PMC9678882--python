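"""Synthetic cohorts with planted comorbidity structure.

The generator is a pairwise binary Markov random field (an Ising-type model
in 0/1 coding),

    P(x) propto exp( sum_i alpha_i x_i + sum_{i<j} theta_ij x_i x_j ),

which is exactly the k=2 mixed-graphical-model class for all-binary nodes:
the planted coupling matrix ``theta`` is the recovery target for the
nodewise LASSO estimator. Intercepts ``alpha`` control marginal
prevalences; covariate effects shift block intercepts per respondent (age
and social-class gradients), so pattern profiling has a recoverable signal
while the conditional-dependence structure itself stays covariate-free.

Sampling is by single-site systematic-scan Gibbs sweeps; each respondent is
an independent chain (rows are exchangeable), burned in and thinned, which
for small p is verified against exact enumeration of the 2^p states.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from morbinet.schema import Cohort, VariableSchema, canonical_schema, generic_schema


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


@dataclass
class CovariateEffects:
    """Per-block additive intercept shifts as functions of covariates.

    ``age_slope[b]`` is the log-odds shift of block *b* members per decade
    of age above 60; ``class_slope[b]`` the shift per social-class step
    above the midpoint (SC3.5). Positive age slopes make a block's diseases
    more prevalent among the old; positive class slopes among lower classes.
    """

    age_slope: np.ndarray
    class_slope: np.ndarray

    def shifts(self, blocks: np.ndarray, age: np.ndarray, social_class: np.ndarray) -> np.ndarray:
        """(n, p) intercept shift matrix."""
        a = np.asarray(self.age_slope)[blocks]  # (p,)
        c = np.asarray(self.class_slope)[blocks]
        age_term = ((np.asarray(age, dtype=float) - 60.0) / 10.0)[:, None] * a[None, :]
        class_term = (np.asarray(social_class, dtype=float) - 3.5)[:, None] * c[None, :]
        return age_term + class_term


@dataclass
class PlantedModel:
    """A planted pairwise binary MRF with block (community) structure."""

    theta: np.ndarray
    alpha: np.ndarray
    blocks: np.ndarray
    covariate_effects: Optional[CovariateEffects] = None
    schema: VariableSchema = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.theta = np.asarray(self.theta, dtype=float)
        self.alpha = np.asarray(self.alpha, dtype=float)
        self.blocks = np.asarray(self.blocks, dtype=int)
        p = self.theta.shape[0]
        if self.theta.shape != (p, p) or not np.allclose(self.theta, self.theta.T):
            raise ValueError("theta must be a symmetric square matrix")
        if np.any(np.diag(self.theta) != 0):
            raise ValueError("theta must have zero diagonal")
        if self.alpha.shape != (p,):
            raise ValueError("alpha must have length p")
        if self.blocks.shape != (p,):
            raise ValueError("blocks must have length p")
        if self.schema is None:
            self.schema = generic_schema(p)

    @property
    def p(self) -> int:
        return self.theta.shape[0]

    @property
    def node_names(self) -> list[str]:
        names = self.schema.condition_names
        pair = self.schema.shared_slot_pair()
        if pair is None:
            return names
        male, female = pair
        out = []
        for v in self.schema:
            if v.role != "condition":
                continue
            if v.name == male.name:
                out.append("prostate_menopausal")
            elif v.name == female.name:
                continue
            else:
                out.append(v.name)
        return out

    def to_json(self, path) -> Path:
        """Sidecar recording the planted truth for test harnesses."""
        payload = {
            "p": self.p,
            "theta": self.theta.tolist(),
            "alpha": self.alpha.tolist(),
            "blocks": self.blocks.tolist(),
            "node_names": self.node_names,
        }
        if self.covariate_effects is not None:
            payload["covariate_effects"] = {
                "age_slope": np.asarray(self.covariate_effects.age_slope).tolist(),
                "class_slope": np.asarray(self.covariate_effects.class_slope).tolist(),
            }
        path = Path(path)
        path.write_text(json.dumps(payload, indent=1))
        return path


@dataclass
class SimulationConfig:
    """Gibbs sampling settings; defaults mix well at desk scale (p <= 40)."""

    n: int
    burnin: int = 200
    thin: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.burnin < 0:
            raise ValueError("burnin must be >= 0")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.n < 1:
            raise ValueError("n must be >= 1")


def _ring_edges(members: np.ndarray) -> list[tuple[int, int]]:
    k = len(members)
    if k < 2:
        return []
    if k == 2:
        return [(members[0], members[1])]
    return [(members[i], members[(i + 1) % k]) for i in range(k)]


def block_model(
    n_blocks: int = 4,
    block_size: int = 6,
    theta_in: float = 0.9,
    theta_out: float = 0.0,
    topology: str = "ring",
    alpha: float | np.ndarray = -1.5,
    covariate_effects: Optional[CovariateEffects] = None,
) -> PlantedModel:
    """Planted block model: sparse within-block couplings, none between.

    ``topology="ring"`` places each block's couplings on a cycle (so the
    estimator's behaviour on non-clique neighbourhoods is exercised);
    ``"clique"`` couples all within-block pairs. ``theta_out`` optionally
    adds a weak coupling between consecutive blocks' first members.
    """
    p = n_blocks * block_size
    blocks = np.repeat(np.arange(n_blocks), block_size)
    theta = np.zeros((p, p))
    for b in range(n_blocks):
        members = np.flatnonzero(blocks == b)
        if topology == "ring":
            edges = _ring_edges(members)
        elif topology == "clique":
            edges = list(itertools.combinations(members, 2))
        else:
            raise ValueError(f"unknown topology {topology!r}")
        for i, j in edges:
            theta[i, j] = theta[j, i] = theta_in
    if theta_out != 0.0:
        for b in range(n_blocks - 1):
            i = b * block_size
            j = (b + 1) * block_size
            theta[i, j] = theta[j, i] = theta_out
    alpha_vec = np.full(p, float(alpha)) if np.isscalar(alpha) else np.asarray(alpha, float)
    return PlantedModel(theta, alpha_vec, blocks, covariate_effects)


# Target marginal prevalences for the survey-like generator, chosen to span
# the realistic 2%-40% range of diagnosed chronic conditions, highest for
# hypertension/arthrosis/back pain/cholesterol.
_SURVEY_PREVALENCE = {
    "hypertension": 0.40,
    "infarction": 0.04,
    "coronary_disease": 0.05,
    "other_heart": 0.10,
    "varicose_veins": 0.18,
    "arthrosis": 0.36,
    "lumbar_pain": 0.32,
    "cervical_pain": 0.28,
    "allergy": 0.16,
    "asthma": 0.08,
    "respiratory_disease": 0.08,
    "diabetes": 0.15,
    "stomach_ulcer": 0.06,
    "urinary_incontinence": 0.10,
    "cholesterol": 0.33,
    "cataracts": 0.17,
    "skin_condition": 0.08,
    "constipation": 0.09,
    "hepatic_dysfunction": 0.02,
    "depression": 0.15,
    "anxiety": 0.14,
    "other_mental": 0.03,
    "stroke": 0.03,
    "migraine": 0.14,
    "haemorrhoids": 0.11,
    "cancer": 0.05,
    "osteoporosis": 0.11,
    "thyroid_disease": 0.09,
    "kidney_disease": 0.06,
    "prostate_menopausal": 0.12,
    "accidents": 0.07,
    "obesity": 0.20,
}

# Disease communities planted by the survey-like generator (block id per
# node), mirroring the systems clinically expected to co-occur.
_SURVEY_BLOCKS = {
    0: [  # cardiovascular-metabolic
        "hypertension", "infarction", "coronary_disease", "other_heart",
        "diabetes", "cholesterol", "stroke", "obesity",
    ],
    1: [  # musculoskeletal and pain
        "varicose_veins", "arthrosis", "lumbar_pain", "cervical_pain",
        "migraine", "osteoporosis",
    ],
    2: ["allergy", "asthma", "respiratory_disease", "skin_condition"],
    3: [  # digestive
        "stomach_ulcer", "constipation", "hepatic_dysfunction",
        "haemorrhoids", "thyroid_disease",
    ],
    4: [  # excretory and sensory
        "urinary_incontinence", "prostate_menopausal", "kidney_disease",
        "cataracts",
    ],
    5: ["depression", "anxiety", "other_mental"],
    6: ["cancer", "accidents"],
}

# Age gradient per decade and social-class gradient per step, by block:
# cardiovascular/musculoskeletal/excretory rise with age, allergies fall;
# pain and complex patterns skew toward lower classes.
_SURVEY_AGE_SLOPE = np.array([0.45, 0.40, -0.35, 0.10, 0.40, 0.05, 0.15])
_SURVEY_CLASS_SLOPE = np.array([0.05, 0.12, -0.10, 0.08, 0.10, 0.12, 0.05])


def survey_model(
    theta_in: float = 0.8,
    topology: str = "ring",
    covariate_gradients: bool = True,
) -> PlantedModel:
    """A 32-condition survey-like planted model with 7 disease communities.

    Node names and the sex-specific slot-30 pair follow the canonical
    survey schema; marginal prevalences target the 2%-40% range via a
    mean-field intercept correction.
    """
    schema = canonical_schema(include_bmi=False)
    # node order = analysis-matrix order (slot order, pair merged at 30)
    names = []
    for v in sorted(
        (v for v in schema if v.role == "condition"),
        key=lambda v: (v.slot, v.name),
    ):
        nm = "prostate_menopausal" if v.slot == 30 else v.name
        if nm not in names:
            names.append(nm)
    p = len(names)
    idx = {nm: i for i, nm in enumerate(names)}
    blocks = np.zeros(p, dtype=int)
    for b, members in _SURVEY_BLOCKS.items():
        for nm in members:
            blocks[idx[nm]] = b
    theta = np.zeros((p, p))
    for b, members in _SURVEY_BLOCKS.items():
        mem = np.array([idx[nm] for nm in members])
        if topology == "ring":
            edges = _ring_edges(mem)
        else:
            edges = list(itertools.combinations(mem, 2))
        for i, j in edges:
            theta[i, j] = theta[j, i] = theta_in
    prev = np.array([_SURVEY_PREVALENCE[nm] for nm in names])
    # mean-field correction keeps marginals near the target despite couplings
    alpha = np.log(prev / (1 - prev)) - 0.5 * theta @ prev
    effects = (
        CovariateEffects(_SURVEY_AGE_SLOPE, _SURVEY_CLASS_SLOPE)
        if covariate_gradients
        else None
    )
    return PlantedModel(theta, alpha, blocks, effects, schema=schema)


def planted_edge_set(model: PlantedModel, tol: float = 1e-8) -> set[tuple[int, int]]:
    """Index pairs (i < j) with |theta_ij| > tol: the recovery target."""
    p = model.p
    return {
        (i, j)
        for i in range(p)
        for j in range(i + 1, p)
        if abs(model.theta[i, j]) > tol
    }


def _draw_covariates(n: int, rng: np.random.Generator) -> pd.DataFrame:
    """Survey-like covariate marginals: age ~ N(60.8, 17) clipped to
    [16, 95], sex 40.7% male, social class SC1..SC6 with a bottom-heavy
    distribution."""
    age = np.clip(np.round(rng.normal(60.8, 17.0, size=n)), 16, 95).astype(int)
    sex = np.where(rng.random(n) < 0.407, "male", "female")
    sc = rng.choice(
        np.arange(1, 7), size=n, p=[0.08, 0.12, 0.20, 0.20, 0.20, 0.20]
    )
    return pd.DataFrame({"sex": sex, "age": age, "social_class": sc})


def sample_cohort(model: PlantedModel, config: SimulationConfig) -> Cohort:
    """Gibbs-sample ``config.n`` respondents from the planted model.

    Each row is an independent single-site systematic-scan chain: random
    initialization from the independent-Bernoulli approximation, ``burnin``
    sweeps, then ``thin`` further sweeps before the state is retained.
    Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    n, p = config.n, model.p
    cov = _draw_covariates(n, rng)
    row_alpha = np.broadcast_to(model.alpha, (n, p)).copy()
    if model.covariate_effects is not None:
        row_alpha += model.covariate_effects.shifts(
            model.blocks, cov["age"].to_numpy(), cov["social_class"].to_numpy()
        )
    x = (rng.random((n, p)) < _sigmoid(row_alpha)).astype(np.int8)
    theta = model.theta
    for _ in range(config.burnin + config.thin):
        for i in range(p):
            eta = row_alpha[:, i] + x @ theta[:, i]
            x[:, i] = rng.random(n) < _sigmoid(eta)

    names = model.node_names
    frame = pd.DataFrame(x, columns=names)
    pair = model.schema.shared_slot_pair()
    if pair is not None:
        male, female = pair
        merged = frame.pop("prostate_menopausal")
        is_male = cov["sex"] == "male"
        frame[male.name] = np.where(is_male, merged, np.nan)
        frame[female.name] = np.where(is_male, np.nan, merged)
    if set(model.schema.covariate_names) & {"sex", "age", "social_class"}:
        for c in ("sex", "age", "social_class"):
            if c in model.schema.covariate_names:
                frame[c] = cov[c].to_numpy()
    frame = frame[[v.name for v in model.schema]]
    return Cohort(frame, model.schema)


def exact_state_distribution(
    model: PlantedModel, row_alpha: Optional[np.ndarray] = None
) -> tuple[np.ndarray, np.ndarray]:
    """Enumerate the 2^p Boltzmann distribution (p <= 16).

    Returns (states, probabilities) with states in binary-counting order,
    first variable as the most significant bit.
    """
    p = model.p
    if p > 16:
        raise ValueError("exact enumeration limited to p <= 16")
    alpha = model.alpha if row_alpha is None else np.asarray(row_alpha, float)
    states = np.array(list(itertools.product((0, 1), repeat=p)), dtype=float)
    energy = states @ alpha + 0.5 * np.einsum("si,ij,sj->s", states, model.theta, states)
    w = np.exp(energy - energy.max())
    return states.astype(int), w / w.sum()
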