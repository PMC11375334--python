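"""Pipeline configuration: one validated object, YAML round-trip.

Defaults mirror the study conditions of the subtyping analysis: consensus
clustering with maxK=9, 50 resampling repetitions, 80% sample subsampling,
all features, Euclidean k-means; the standard (0.1, 0.9) ambiguity window
for the proportion of ambiguous clustering; the (3.9, 7.0, 9.5) disease-ratio
breakpoints of the published cluster->subtype merge; an 80/20 stratified
split for the classifiers.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import yaml

PAPER_BREAKPOINTS = (3.9, 7.0, 9.5)
#: Published letter permutation for the breakpoint bands, top ratio band
#: first (the published naming does not follow ratio order).
PAPER_BAND_LABELS = ("B", "C", "A", "D")


@dataclass
class PipelineConfig:
    # consensus clustering
    max_k: int = 9
    reps: int = 50
    p_item: float = 0.8
    p_feature: float = 1.0
    distance: str = "euclidean"
    algorithm: str = "kmeans"
    n_restarts: int = 10
    # PAC ambiguity window
    pac_x1: float = 0.1
    pac_x2: float = 0.9
    # cluster -> subtype merge
    breakpoints: tuple[float, ...] | None = PAPER_BREAKPOINTS
    band_labels: tuple[str, ...] | None = PAPER_BAND_LABELS
    target_groups: int | None = None
    # differential screen
    alpha: float = 0.05
    lda_cutoff: float = 2.0
    fdr_method: str = "BH"
    # classifiers
    train_frac: float = 0.8
    min_test_total: int = 60
    # randomness
    seed: int = 0

    def __post_init__(self) -> None:
        if self.max_k < 2:
            raise ValueError(f"max_k must be >= 2, got {self.max_k}")
        if not 0 < self.p_item <= 1:
            raise ValueError(f"p_item must be in (0, 1], got {self.p_item}")
        if not 0 < self.p_feature <= 1:
            raise ValueError(f"p_feature must be in (0, 1], got {self.p_feature}")
        if not 0 < self.pac_x1 < self.pac_x2 < 1:
            raise ValueError(
                f"PAC window must satisfy 0 < x1 < x2 < 1, got ({self.pac_x1}, {self.pac_x2})"
            )
        if not 0 < self.train_frac < 1:
            raise ValueError(f"train_frac must be in (0, 1), got {self.train_frac}")
        if self.reps < 1:
            raise ValueError("reps must be >= 1")
        if self.breakpoints is not None:
            bp = tuple(float(b) for b in self.breakpoints)
            if any(b2 <= b1 for b1, b2 in zip(bp, bp[1:])):
                raise ValueError(f"breakpoints must be strictly increasing: {bp}")
            self.breakpoints = bp
        if self.band_labels is not None:
            self.band_labels = tuple(self.band_labels)

    def to_dict(self) -> dict:
        return asdict(self)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("breakpoints", "band_labels"):
            if raw.get(key) is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)
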