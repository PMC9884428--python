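"""Percentage positivity and the weighted H-score.

Percentages are kept as fractions in [0, 1], so the H-score
``1*%weak + 2*%medium + 3*%strong`` lives on a 0-3 scale.  The
conventional pathology 0-300 H-score is this value times 100.
"""

from __future__ import annotations

from dataclasses import dataclass

from .classify import PixelCounts


class EmptyROIError(ValueError):
    """Raised when a sample's ROI contains no pixels, so no score is defined."""

    def __init__(self, sample_id: str | None = None):
        self.sample_id = sample_id
        who = f" for sample {sample_id!r}" if sample_id else ""
        super().__init__(f"empty ROI (n_total = 0){who}: positivity is undefined")


@dataclass(frozen=True)
class PositivityFractions:
    """Per-bin positivity fractions of one sample's ROI."""

    frac_weak: float
    frac_medium: float
    frac_strong: float

    def __post_init__(self) -> None:
        for name in ("frac_weak", "frac_medium", "frac_strong"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} = {v} outside [0, 1]")
        if self.frac_positive > 1.0 + 1e-12:
            raise ValueError("positivity fractions sum above 1")

    @property
    def frac_positive(self) -> float:
        """Percentage of total positivity, N_positive / N_total."""
        return self.frac_weak + self.frac_medium + self.frac_strong


@dataclass(frozen=True)
class HScoreResult:
    sample_id: str
    fractions: PositivityFractions
    h_score: float


def compute_fractions(
    counts: PixelCounts, sample_id: str | None = None
) -> PositivityFractions:
    """Divide the weak/medium/strong pixel counts by the ROI pixel total.

    Raises
    ------
    EmptyROIError
        If ``counts.n_total`` is zero.
    """
    if counts.n_total == 0:
        raise EmptyROIError(sample_id)
    n = counts.n_total
    return PositivityFractions(
        frac_weak=counts.n_weak / n,
        frac_medium=counts.n_medium / n,
        frac_strong=counts.n_strong / n,
    )


def compute_hscore(
    fractions: PositivityFractions, sample_id: str = ""
) -> HScoreResult:
    """Weighted H-score = 1*frac_weak + 2*frac_medium + 3*frac_strong, in [0, 3]."""
    h = fractions.frac_weak + 2.0 * fractions.frac_medium + 3.0 * fractions.frac_strong
    return HScoreResult(sample_id=sample_id, fractions=fractions, h_score=h)


def hscore_from_counts(counts: PixelCounts, sample_id: str = "") -> HScoreResult:
    """Convenience path from raw pixel counts straight to the H-score."""
    return compute_hscore(compute_fractions(counts, sample_id or None), sample_id)
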