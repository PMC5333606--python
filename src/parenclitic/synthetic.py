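"""Synthetic cohort generator.

Emulates the statistical structure that the deviation-network analysis
assumes about a clinical biomarker table: a reference ("control", surviving)
population in which selected feature pairs follow linear relations with
Gaussian noise, and a case (non-surviving) population that deviates from a
subset of those relations.

Controls satisfy, for every relation (k -> l),

    f_l = intercept + slope * f_k + N(0, noise_sd^2).

Cases are generated by the same process and then perturbed on the configured
``perturbed_pairs``. The default deviation mode adds ``delta * noise_sd`` to
the response feature with a per-subject random sign, so that the expected
absolute residual Z-score on a perturbed pair is ~ ``delta`` (folded normal)
while the response's marginal mean is unchanged — the deviation lives in the
pairwise relation, not in any single feature, and is therefore invisible to a
linear classifier on raw features. Optional marginal effects (mean shifts on
single features, mimicking a strong prognostic biomarker such as LDH) and
class-dependent binary rates (mimicking yes/no history flags such as TURP)
add the kinds of single-feature signal real cohorts carry.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import DEFAULT_LABEL, Cohort

__all__ = [
    "Relation",
    "SyntheticConfig",
    "generate_cohort",
    "ground_truth",
    "random_relations",
    "default_benchmark_config",
]


@dataclass(frozen=True)
class Relation:
    """A linear control-population relation ``response = intercept + slope*predictor + noise``."""

    predictor: str
    response: str
    intercept: float = 0.0
    slope: float = 1.0
    noise_sd: float = 1.0


class ConfigurationError(ValueError):
    """Raised for an internally inconsistent SyntheticConfig."""


@dataclass(frozen=True)
class SyntheticConfig:
    """Full description of a synthetic cohort.

    Attributes
    ----------
    n_controls, n_cases:
        Class sizes (label 0 survivors / label 1 deaths).
    n_numeric, n_binary:
        Feature counts; numeric features are named ``num_01..``, binary
        ``bin_01..``. Binary features take values in {0, 1}.
    relation_pairs:
        Linear relations satisfied by controls. Each response feature may
        appear at most once as a response (so generation is well defined).
    perturbed_pairs:
        (predictor, response) pairs — a subset of ``relation_pairs`` — on
        which cases deviate.
    effect_size_delta:
        Deviation magnitude in units of the relation's ``noise_sd``.
    deviation_mode:
        "shift" (additive shift of the response, validated default),
        "slope" (case slope multiplied by ``1 + delta``) or
        "variance" (case noise sd multiplied by ``1 + delta``).
    shift_sign:
        For mode "shift": "random" (per subject-pair, mean-zero), "positive"
        or "negative".
    marginal_effect_features:
        ``(feature, mean_shift)`` pairs applied to cases only.
    binary_rate_control, binary_rate_case:
        Bernoulli rates for binary features; per-feature overrides via
        ``binary_rates`` mapping name -> (control_rate, case_rate).
    seed:
        Seed for all randomness; identical config => byte-identical cohort.
    """

    n_controls: int
    n_cases: int
    n_numeric: int = 80
    n_binary: int = 12
    relation_pairs: tuple[Relation, ...] = ()
    perturbed_pairs: tuple[tuple[str, str], ...] = ()
    effect_size_delta: float = 0.0
    deviation_mode: str = "shift"
    shift_sign: str = "random"
    marginal_effect_features: tuple[tuple[str, float], ...] = ()
    binary_rate_control: float = 0.3
    binary_rate_case: float = 0.3
    binary_rates: tuple[tuple[str, tuple[float, float]], ...] = ()
    seed: int = 0

    @property
    def numeric_names(self) -> list[str]:
        return [f"num_{i + 1:02d}" for i in range(self.n_numeric)]

    @property
    def binary_names(self) -> list[str]:
        return [f"bin_{i + 1:02d}" for i in range(self.n_binary)]

    @property
    def feature_names(self) -> list[str]:
        return self.numeric_names + self.binary_names

    def validate(self) -> None:
        if self.n_controls < 0 or self.n_cases < 0:
            raise ConfigurationError("class sizes must be non-negative")
        if self.deviation_mode not in ("shift", "slope", "variance"):
            raise ConfigurationError(
                f"unknown deviation_mode {self.deviation_mode!r}")
        if self.shift_sign not in ("random", "positive", "negative"):
            raise ConfigurationError(f"unknown shift_sign {self.shift_sign!r}")
        names = set(self.feature_names)
        responses = [r.response for r in self.relation_pairs]
        if len(responses) != len(set(responses)):
            raise ConfigurationError(
                "each feature may appear at most once as a relation response")
        for rel in self.relation_pairs:
            if rel.noise_sd <= 0:
                raise ConfigurationError(
                    f"noise_sd must be positive (relation {rel.predictor}->{rel.response})")
            if rel.predictor not in names or rel.response not in names:
                raise ConfigurationError(
                    f"relation references unknown feature: {rel!r}")
            if rel.predictor == rel.response:
                raise ConfigurationError("relation predictor == response")
        relation_keys = {(r.predictor, r.response) for r in self.relation_pairs}
        for pair in self.perturbed_pairs:
            if tuple(pair) not in relation_keys:
                raise ConfigurationError(
                    f"perturbed pair {pair!r} is not a relation pair")
        for feat, _ in self.marginal_effect_features:
            if feat not in names:
                raise ConfigurationError(f"unknown marginal feature {feat!r}")
        for feat, _ in self.binary_rates:
            if feat not in set(self.binary_names):
                raise ConfigurationError(f"unknown binary feature {feat!r}")


def ground_truth(config: SyntheticConfig) -> set[tuple[str, str]]:
    """The set of feature pairs on which cases truly deviate."""
    return {tuple(p) for p in config.perturbed_pairs}


def _generate_class(config: SyntheticConfig, n: int, is_case: bool,
                    rng: np.random.Generator) -> pd.DataFrame:
    numeric = config.numeric_names
    relations = {r.response: r for r in config.relation_pairs}
    cols: dict[str, np.ndarray] = {}
    # Numeric features in name order; a response's predictor always has a
    # lower index (enforced by random_relations; user configs may order
    # freely, so resolve dependencies by iterating until settled).
    pending = list(numeric)
    guard = 0
    while pending:
        progressed = False
        for name in list(pending):
            rel = relations.get(name)
            if rel is None:
                cols[name] = rng.standard_normal(n)
                pending.remove(name)
                progressed = True
            elif rel.predictor in cols:
                noise_sd = rel.noise_sd
                slope = rel.slope
                if is_case and config.deviation_mode == "slope" and \
                        (rel.predictor, rel.response) in set(map(tuple, config.perturbed_pairs)):
                    slope = slope * (1.0 + config.effect_size_delta)
                if is_case and config.deviation_mode == "variance" and \
                        (rel.predictor, rel.response) in set(map(tuple, config.perturbed_pairs)):
                    noise_sd = noise_sd * (1.0 + config.effect_size_delta)
                cols[name] = (rel.intercept + slope * cols[rel.predictor]
                              + rng.normal(0.0, noise_sd, size=n))
                pending.remove(name)
                progressed = True
        guard += 1
        if not progressed or guard > len(numeric) + 1:
            raise ConfigurationError("cyclic relation structure")
    if is_case and config.deviation_mode == "shift":
        delta = config.effect_size_delta
        for predictor, response in config.perturbed_pairs:
            sd = relations[response].noise_sd
            if config.shift_sign == "random":
                sign = rng.choice([-1.0, 1.0], size=n)
            elif config.shift_sign == "positive":
                sign = 1.0
            else:
                sign = -1.0
            cols[response] = cols[response] + sign * delta * sd
    if is_case:
        for feat, shift in config.marginal_effect_features:
            cols[feat] = cols[feat] + shift
    rate_overrides = dict(config.binary_rates)
    base = config.binary_rate_case if is_case else config.binary_rate_control
    for name in config.binary_names:
        if name in rate_overrides:
            rate = rate_overrides[name][1 if is_case else 0]
        else:
            rate = base
        cols[name] = (rng.random(n) < rate).astype(float)
    frame = pd.DataFrame({k: cols[k] for k in config.feature_names})
    frame.insert(0, DEFAULT_LABEL, int(is_case))
    return frame


def generate_cohort(config: SyntheticConfig) -> Cohort:
    """Generate a labelled cohort; identical config (incl. seed) is byte-identical."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    controls = _generate_class(config, config.n_controls, False, rng)
    cases = _generate_class(config, config.n_cases, True, rng)
    frame = pd.concat([controls, cases], ignore_index=True)
    frame.index = pd.Index(
        [f"S{i + 1:05d}" for i in range(len(frame))], name="subject_id")
    return Cohort(frame, DEFAULT_LABEL)


def random_relations(config_or_n, n_relations: int, seed: int, *,
                     slope_range: tuple[float, float] = (0.5, 0.9),
                     intercept_range: tuple[float, float] = (-1.0, 1.0),
                     noise_sd: float | None = None,
                     max_degree: int = 3) -> tuple[Relation, ...]:
    """Draw a sparse random relation topology over the numeric features.

    Each response feature appears exactly once as a response, every feature
    takes part in at most ``max_degree`` relations, and the predictor always
    has a lower index than its response. Slope magnitudes are drawn from
    ``slope_range`` with random sign. By default the noise level is
    variance-stationary, ``noise_sd = sqrt(1 - slope^2)``, so every feature
    has unit variance regardless of its depth in the dependency graph (as in
    a stationary autoregressive process); pass an explicit ``noise_sd`` to
    override.
    """
    if isinstance(config_or_n, SyntheticConfig):
        names = config_or_n.numeric_names
    else:
        names = [f"num_{i + 1:02d}" for i in range(int(config_or_n))]
    rng = np.random.default_rng(seed)
    degree = {name: 0 for name in names}
    used_response: set[str] = set()
    relations: list[Relation] = []
    attempts = 0
    while len(relations) < n_relations and attempts < 200 * n_relations:
        attempts += 1
        j = int(rng.integers(1, len(names)))
        i = int(rng.integers(0, j))
        pred, resp = names[i], names[j]
        if resp in used_response or degree[pred] >= max_degree or \
                degree[resp] >= max_degree:
            continue
        slope = float(rng.uniform(*slope_range)) * float(rng.choice([-1.0, 1.0]))
        intercept = float(rng.uniform(*intercept_range))
        sd = noise_sd if noise_sd is not None else float(np.sqrt(1.0 - slope ** 2))
        relations.append(Relation(pred, resp, intercept, slope, sd))
        used_response.add(resp)
        degree[pred] += 1
        degree[resp] += 1
    if len(relations) < n_relations:
        raise ConfigurationError(
            f"could not place {n_relations} relations among {len(names)} features")
    return tuple(sorted(relations, key=lambda r: (r.response, r.predictor)))


def default_benchmark_config(seed: int = 0, n_controls: int = 1000,
                             n_cases: int = 1000,
                             effect_size_delta: float = 2.0,
                             perturbed_fraction: float = 0.10,
                             marginal_shift: float = 1.2) -> SyntheticConfig:
    """The default benchmark cohort: 92 features, balanced classes.

    70 variance-stationary linear relations among the 80 numeric features
    (every feature has unit variance); ``perturbed_fraction``
    of them deviate in cases with effect size ``effect_size_delta``; one
    relation-free numeric feature carries an LDH-like marginal mean shift.
    """
    n_numeric, n_binary, n_rel = 80, 12, 70
    relations = random_relations(n_numeric, n_rel, seed=seed)
    n_pert = int(round(perturbed_fraction * n_rel))
    # Plant deviations on the relations whose response covers the most
    # fitted pairs (single-direction regression: a feature is the response
    # for every lower-index partner), so the planted signal is visible to
    # the network stage by design rather than by topology luck.
    coverage = sorted(relations,
                      key=lambda r: r.response, reverse=True)[:n_pert]
    perturbed = tuple(sorted((r.predictor, r.response) for r in coverage))
    in_relation = {r.predictor for r in relations} | {r.response for r in relations}
    free = [f"num_{i + 1:02d}" for i in range(n_numeric)
            if f"num_{i + 1:02d}" not in in_relation]
    marginal = ((free[0] if free else "num_01", marginal_shift),) \
        if marginal_shift else ()
    return SyntheticConfig(
        n_controls=n_controls, n_cases=n_cases,
        n_numeric=n_numeric, n_binary=n_binary,
        relation_pairs=relations, perturbed_pairs=perturbed,
        effect_size_delta=effect_size_delta,
        marginal_effect_features=marginal,
        seed=seed,
    )
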