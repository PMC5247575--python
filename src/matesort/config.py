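"""Configuration objects for simulation and pipeline runs.

``SimConfig`` encodes the study design being emulated: ten isogenic female
lines assayed in all 45 pairwise two-female trials (10-20 replicates per
pair), a latent line quality expressed redundantly through a visual and a
chemical cue channel, female receptivity and offspring production loading
on the same quality, repellent cuticular hydrocarbons loading negatively
on it, zero-inflated offspring counts (~10% structural zeros), and a
200-minute right-censoring window for courtship-to-mating times.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

__all__ = ["SimConfig", "RunConfig", "CONDITIONS", "ValidationError"]

#: Chooser sensory conditions: which cue channels the male can access.
CONDITIONS = ("intact", "no_visual", "no_chemical", "neither")


class ValidationError(ValueError):
    """Raised when a configuration violates its invariants."""


@dataclass
class SimConfig:
    """Parameters of the synthetic study.

    Defaults mirror the emulated design: 10 lines, 14 replicate trials per
    pair (the first wild-type assay's replication), 10% zero-inflated
    offspring vials, 200-minute censoring.
    """

    n_lines: int = 10
    n_reps_per_pair: int = 14
    latent_quality_sd: float = 1.0
    #: (visual, chemical) channel weights; must be nonnegative and sum to 1.
    channel_weights: tuple[float, float] = (0.5, 0.5)
    #: sd of line-level cue noise around quality, per channel.
    channel_noise_sd: float = 0.3
    #: sd of per-trial perception noise added to the combined signal.
    perception_noise_sd: float = 0.5
    #: logistic slope on the perceived-attractiveness difference.
    choice_steepness: float = 3.0
    #: probability a trial yields any mating when both channels are blocked.
    detection_floor: float = 0.02
    #: probability a trial yields a mating with full sensory access.
    base_mating_rate: float = 0.7
    #: correlation loading of receptivity (as a deficit score) on quality.
    receptivity_loading: float = 0.8
    #: additive weight of the female receptivity term in the chooser model.
    receptivity_weight: float = 0.5
    #: (positive) magnitude of the negative loading of repellent CHCs on quality.
    chc_loading: float = 0.8
    #: loading of log offspring mean on quality.
    productivity_loading: float = 0.6
    #: optional line index whose productivity is decoupled from attractiveness.
    outlier_line: int | None = None
    #: probability a mated female yields zero offspring beyond NB zeros.
    zero_inflation: float = 0.10
    #: negative-binomial size (dispersion) parameter.
    nb_dispersion: float = 2.0
    #: coefficient of variation of individual courtship-to-mating times.
    receptivity_cv: float = 0.35
    #: right-censoring window for courtship-to-mating observations (minutes).
    censor_minutes: float = 200.0
    #: fraction of proximity trials with total dwell below the 50 s filter.
    short_trial_fraction: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        self.channel_weights = tuple(float(w) for w in self.channel_weights)
        self.validate()

    def validate(self) -> None:
        if self.n_lines < 3:
            raise ValidationError(f"n_lines must be >= 3, got {self.n_lines}")
        if self.n_reps_per_pair < 1:
            raise ValidationError("n_reps_per_pair must be >= 1")
        wv, wc = self.channel_weights
        if wv < 0 or wc < 0 or abs(wv + wc - 1.0) > 1e-9:
            raise ValidationError(
                f"channel_weights must be nonnegative and sum to 1, got {self.channel_weights}"
            )
        for name in ("detection_floor", "base_mating_rate", "zero_inflation",
                     "short_trial_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1], got {v}")
        for name in ("receptivity_loading", "chc_loading", "productivity_loading"):
            v = getattr(self, name)
            if not -1.0 <= v <= 1.0:
                raise ValidationError(f"{name} must be in [-1, 1], got {v}")
        if self.nb_dispersion <= 0:
            raise ValidationError("nb_dispersion must be > 0")
        if self.latent_quality_sd < 0 or self.perception_noise_sd < 0:
            raise ValidationError("sd parameters must be nonnegative")
        if self.censor_minutes <= 0:
            raise ValidationError("censor_minutes must be > 0")
        if self.outlier_line is not None and not 0 <= self.outlier_line < self.n_lines:
            raise ValidationError(
                f"outlier_line {self.outlier_line} outside 0..{self.n_lines - 1}"
            )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["channel_weights"] = list(self.channel_weights)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        return cls(**d)


@dataclass
class RunConfig:
    """End-to-end pipeline configuration.

    Permutation counts default to the analysis convention: 100,000
    direction randomizations for transitivity, 10,000 label permutations
    for trait correlations.
    """

    sim: SimConfig = field(default_factory=SimConfig)
    n_perm_transitivity: int = 100_000
    n_perm_correlation: int = 10_000
    alpha: float = 0.05
    seed: int = 0
    outdir: str = "matesort_out"
    #: per-line sample sizes for the trait assays
    n_receptivity_per_line: int = 20
    n_offspring_per_line: int = 14
    n_proximity_pairs: int = 5
    n_proximity_trials: int = 30

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_perm_transitivity < 100 or self.n_perm_correlation < 100:
            raise ValidationError("permutation counts must be >= 100")
        if not 0 < self.alpha < 1:
            raise ValidationError("alpha must be in (0, 1)")
        self.sim.validate()

    def to_dict(self) -> dict:
        d = asdict(self)
        d["sim"] = self.sim.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "sim" in d and isinstance(d["sim"], dict):
            d["sim"] = SimConfig.from_dict(d["sim"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
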