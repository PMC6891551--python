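"""Left-right Symmetry Index features and GHQ-12 questionnaire scoring.

The Symmetry Index (SI) quantifies the inter-limb difference of a gait
parameter as a percentage of the inter-limb mean:

    SI = |R − L| / ((R + L) / 2) × 100  (%)

0 % is perfect symmetry and 200 % the degenerate one-sided limit.  The SI
is applied to both the mean and the stride-to-stride SD of each gait
parameter, giving eight asymmetry features per subject (4 parameters ×
{mean, SD}).

GHQ-12 totals use the bimodal (0-0-1-1) scoring convention: each item's
4-point response collapses to 1 point on the "agree" side (codes 2–3)
and 0 on the "disagree" side (codes 0–1), yielding a 0–12 total where
higher means worse general mental health.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import ResponseCodingError, SideMissingError, SIUndefinedError
from .io import GHQResponse
from .parameters import PARAMETERS, SubjectGaitSummary

__all__ = ["SIFeatures", "GHQScore", "symmetry_index", "si_features", "score_ghq12"]


@dataclass(frozen=True)
class SIFeatures:
    """Eight SI values (%): per parameter, SI of the side means and side SDs."""

    si_mean: dict[str, float]
    si_sd: dict[str, float]

    def as_dict(self) -> dict[str, float]:
        out = {}
        for p in PARAMETERS:
            out[f"{p}_si_mean"] = self.si_mean[p]
            out[f"{p}_si_sd"] = self.si_sd[p]
        return out


@dataclass(frozen=True)
class GHQScore:
    subject_id: str
    total: int


def symmetry_index(r_value: float, l_value: float) -> float:
    """Symmetry Index of a nonnegative right/left quantity pair, in percent.

    Raises
    ------
    SIUndefinedError
        If ``r_value + l_value == 0`` (inter-limb mean vanishes).
    """
    if r_value < 0 or l_value < 0:
        raise ValueError("symmetry_index expects nonnegative inputs")
    denom = 0.5 * (r_value + l_value)
    if denom == 0:
        raise SIUndefinedError("SI undefined: both sides are zero")
    return abs(r_value - l_value) / denom * 100.0


def si_features(summary: SubjectGaitSummary) -> SIFeatures:
    """SI of side means and side SDs for all four gait parameters.

    Raises
    ------
    SideMissingError
        If either side lacks records for any parameter.
    """
    si_mean: dict[str, float] = {}
    si_sd: dict[str, float] = {}
    for p in PARAMETERS:
        for side in "LR":
            if summary.n_steps[side] == 0 or p not in summary.side_mean[side]:
                raise SideMissingError(f"no {side}-side records for {p}")
        si_mean[p] = symmetry_index(summary.side_mean["R"][p], summary.side_mean["L"][p])
        si_sd[p] = symmetry_index(summary.side_sd["R"][p], summary.side_sd["L"][p])
    return SIFeatures(si_mean=si_mean, si_sd=si_sd)


def score_ghq12(response: GHQResponse) -> GHQScore:
    """Bimodal (0-0-1-1) GHQ-12 total: one point per agree-side item.

    Raises
    ------
    ResponseCodingError
        If the response has != 12 items or any code outside {0,1,2,3}.
    """
    items = response.items
    if len(items) != 12:
        raise ResponseCodingError(f"expected 12 items, got {len(items)}")
    for i, v in enumerate(items):
        if v not in (0, 1, 2, 3):
            raise ResponseCodingError(f"item {i + 1} code {v!r} outside 0-3")
    return GHQScore(subject_id=response.subject_id,
                    total=sum(1 for v in items if v >= 2))
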