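"""Analysis configuration: every screening/filter threshold in one place.

The defaults are the thresholds of the published analysis protocol this
package implements (co-expression |r| > 0.4 at p < 0.001, DE at FDR < 0.05
and |log2FC| > 1.5, pair 1-frequency in (0.20, 0.80), univariate Cox
p < 0.01, 1/2/3-year ROC horizons).
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import yaml

DAYS_PER_YEAR = 365.25


@dataclasses.dataclass
class AnalysisConfig:
    """Thresholds, cross-validation settings and seed for the pipeline.

    Parameters
    ----------
    corr_r : minimum absolute Pearson correlation between a lncRNA and an
        immune gene for the lncRNA to count as immune-related.
    corr_p : maximum correlation p-value for the same screen.
    de_fdr : Benjamini-Hochberg FDR ceiling for differential expression.
    de_log2fc : minimum |log2 fold change| (tumor minus normal, log2 scale).
    pair_low, pair_high : open interval for the valid-pair 1-frequency.
    uni_cox_p : Wald p ceiling for the univariate Cox pair screen.
    cv_folds, cv_repeats : cross-validation layout for the LASSO-Cox
        penalty search (repeats > 1 averages fold deviances over repeated
        random fold assignments).
    n_lambdas : length of the penalty grid.
    horizons_years : ROC evaluation horizons, converted to days with
        365.25 days/year.
    log2_transform : whether correlation/DE work on log2(x+1) values
        (pairing always uses the raw scale; it is rank-invariant).
    corr_tumor_only : compute the co-expression screen on tumor samples
        only (default) or on all samples.
    """

    corr_r: float = 0.4
    corr_p: float = 0.001
    de_fdr: float = 0.05
    de_log2fc: float = 1.5
    pair_low: float = 0.20
    pair_high: float = 0.80
    uni_cox_p: float = 0.01
    cv_folds: int = 10
    cv_repeats: int = 1
    n_lambdas: int = 100
    seed: int = 0
    horizons_years: tuple[float, ...] = (1.0, 2.0, 3.0)
    log2_transform: bool = True
    corr_tumor_only: bool = True
    min_followup_days: float = 30.0

    def __post_init__(self) -> None:
        if not (0.0 < self.pair_low < self.pair_high < 1.0):
            raise ValueError(
                f"pair frequency bounds must satisfy 0 < low < high < 1, "
                f"got ({self.pair_low}, {self.pair_high})"
            )
        for name in ("corr_p", "de_fdr", "uni_cox_p"):
            v = getattr(self, name)
            if not (0.0 <= v < 1.0) and name != "de_fdr":
                raise ValueError(f"{name} must lie in [0, 1), got {v}")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")

    @property
    def horizons_days(self) -> tuple[float, ...]:
        return tuple(DAYS_PER_YEAR * y for y in self.horizons_years)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "horizons_years" in raw:
            raw["horizons_years"] = tuple(raw["horizons_years"])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["horizons_years"] = list(d["horizons_years"])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)
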