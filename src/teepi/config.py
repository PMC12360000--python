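"""Scalar parameters shared across the pipeline.

All coordinates in the package are 0-based half-open (BED convention).
Distances are in base pairs unless a name says otherwise.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import yaml


@dataclass
class Config:
    """Tunable parameters of the TE epigenetic-effect pipeline.

    Attributes
    ----------
    flank_bp
        Length of the upstream/downstream flanking sequence extracted around
        each TE for breakpoint projection.
    breakpoint_tolerance_bp
        Maximum absolute gap/overlap allowed between the projected upstream
        and downstream flanks for a breakpoint to be accepted.
    window_bp
        Width of each non-overlapping analysis window next to a TE.
    n_windows_per_side
        Number of windows per side (20 x 1 kb = +/- 20 kb by default).
    bin_bp
        Signal track resolution; must divide ``window_bp``.
    alpha
        Per-window significance level for the rank-sum tests.
    z_threshold
        |z| cutoff for calling a TE-gene expression link significant.
    n_permutations
        Null-model sample size for the permutation tests.
    loess_span
        Fraction of offsets used by the local regression smoother of
        metaprofiles.
    min_copies_family
        Family-level tests require at least this many genomic copies.
    min_effect_copies_family
        ... and at least this many copies with an epigenetic effect.
    min_bins_per_window
        Minimum non-missing 10-bp bins (out of window_bp/bin_bp per genome)
        for a window to enter a rank-sum test.
    max_missing_fraction
        Windows with a larger fraction of missing bins are excluded.
    rng_seed
        Seed for every stochastic stage (permutations, synthetic cohorts).
    """

    flank_bp: int = 500
    breakpoint_tolerance_bp: int = 50
    window_bp: int = 1000
    n_windows_per_side: int = 20
    bin_bp: int = 10
    alpha: float = 0.05
    z_threshold: float = 1.96
    n_permutations: int = 1000
    loess_span: float = 0.10
    min_copies_family: int = 20
    min_effect_copies_family: int = 8
    min_bins_per_window: int = 50
    max_missing_fraction: float = 0.5
    min_mapq: int = 30
    min_flank_coverage: float = 0.8
    expressed_min_cpm: float = 1.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for name in (
            "flank_bp",
            "breakpoint_tolerance_bp",
            "window_bp",
            "n_windows_per_side",
            "bin_bp",
            "n_permutations",
            "min_copies_family",
            "min_effect_copies_family",
            "min_bins_per_window",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must lie in (0, 1), got {self.alpha}")
        if not 0.0 < self.loess_span <= 1.0:
            raise ValueError(f"loess_span must lie in (0, 1], got {self.loess_span}")
        if self.window_bp % self.bin_bp != 0:
            raise ValueError("bin_bp must divide window_bp")
        if not 0.0 <= self.max_missing_fraction <= 1.0:
            raise ValueError("max_missing_fraction must lie in [0, 1]")
        if self.z_threshold <= 0:
            raise ValueError("z_threshold must be positive")

    @property
    def bins_per_window(self) -> int:
        return self.window_bp // self.bin_bp

    @property
    def span_bp(self) -> int:
        """Total flank length analysed on each side of a TE."""
        return self.n_windows_per_side * self.window_bp

    @classmethod
    def from_yaml(cls, path: str | Path) -> "Config":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**payload)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)
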