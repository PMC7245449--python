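"""WHO 2025 nutrition-target assessment from posterior prevalence draws.

Three targets are assessed per district against a 2012 baseline wave:

* stunting — the interim share of the 40% total relative reduction required
  by the assessment year (the analysis uses a 17% interim reduction for
  2012->2017; linear and geometric pro-rating rules are available as
  alternatives);
* wasting — prevalence below 5% at the assessment wave;
* obesity — no increase relative to baseline (ties count as met).

"Met" is judged on the posterior median, with the exceedance probability of
the same event reported alongside; an exceedance probability strictly above
0.8 is deemed significant (Richardson criterion).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import SIGNIFICANCE_LEVEL, is_significant

__all__ = [
    "required_interim_fraction",
    "assess_stunting_target",
    "assess_wasting_target",
    "assess_obesity_target",
    "summarize_targets",
    "TargetAssessment",
    "assess_all_districts",
    "WASTING_THRESHOLD",
    "STUNTING_TOTAL_REDUCTION",
]

WASTING_THRESHOLD = 0.05
STUNTING_TOTAL_REDUCTION = 0.40
#: Interim relative reduction used for the 2012->2017 stunting assessment.
PAPER_INTERIM_FRACTION = 0.17


def required_interim_fraction(
    total_reduction: float = STUNTING_TOTAL_REDUCTION,
    baseline_year: int = 2012,
    target_year: int = 2025,
    interim_year: int = 2017,
    rule: str = "paper_constant",
) -> float:
    """Relative reduction required by the interim year to stay on track for
    the total reduction by the target year.

    Rules: ``paper_constant`` returns the published 17% constant;
    ``linear`` pro-rates the total linearly in time; ``geometric`` assumes a
    constant annual rate of decline.
    """
    if not baseline_year < interim_year <= target_year:
        raise ValueError("need baseline_year < interim_year <= target_year")
    if rule == "paper_constant":
        return PAPER_INTERIM_FRACTION
    frac_time = (interim_year - baseline_year) / (target_year - baseline_year)
    if rule == "linear":
        return total_reduction * frac_time
    if rule == "geometric":
        return 1.0 - (1.0 - total_reduction) ** frac_time
    raise ValueError(f"unknown rule {rule!r}")


def _cell_draws(pi_draws: np.ndarray, district: int, wave: int) -> np.ndarray:
    return pi_draws[:, district - 1, wave - 1]


def assess_stunting_target(
    pi_draws: np.ndarray,
    district: int,
    baseline_wave: int,
    interim_wave: int,
    fraction: float = PAPER_INTERIM_FRACTION,
) -> tuple[bool, float]:
    """Has the district achieved the interim relative reduction in stunting?

    met is judged on the posterior medians of the two waves; the exceedance
    probability is P[(pi_base - pi_interim)/pi_base >= fraction] over draws.
    Draws with pi_base = 0 have an undefined relative reduction and are
    excluded from the probability.
    """
    base = _cell_draws(pi_draws, district, baseline_wave)
    interim = _cell_draws(pi_draws, district, interim_wave)
    ok = base > 0
    if not ok.any():
        raise ValueError(f"all baseline draws are zero for district {district}")
    reduction = (base[ok] - interim[ok]) / base[ok]
    prob = float(np.mean(reduction >= fraction))
    med_base = float(np.median(base))
    med_interim = float(np.median(interim))
    met = med_base > 0 and (med_base - med_interim) / med_base >= fraction
    return bool(met), prob


def assess_wasting_target(
    pi_draws: np.ndarray,
    district: int,
    wave: int,
    threshold: float = WASTING_THRESHOLD,
) -> tuple[bool, float]:
    """Is wasting prevalence below the 5% threshold at the given wave?"""
    cell = _cell_draws(pi_draws, district, wave)
    met = bool(np.median(cell) < threshold)
    prob = float(np.mean(cell < threshold))
    return met, prob


def assess_obesity_target(
    pi_draws: np.ndarray, district: int, baseline_wave: int, interim_wave: int
) -> tuple[bool, float]:
    """Has the district avoided an increase in obesity?  "No increase"
    includes equality, so ties count as meeting the target."""
    base = _cell_draws(pi_draws, district, baseline_wave)
    interim = _cell_draws(pi_draws, district, interim_wave)
    met = bool(np.median(interim) <= np.median(base))
    prob = float(np.mean(interim <= base))
    return met, prob


def summarize_targets(flags) -> tuple[int, int]:
    """National roll-up: (number of districts meeting the target, percentage
    rounded to the nearest integer)."""
    flags = np.asarray(flags, dtype=bool)
    count = int(flags.sum())
    # round-half-up, matching the published counting arithmetic
    percent = int(np.floor(100.0 * count / len(flags) + 0.5))
    return count, percent


@dataclass(frozen=True)
class TargetAssessment:
    outcome: str
    per_district: pd.DataFrame  # district_id, met, exceedance_prob, significant
    count_met: int
    percent_met: int

    @property
    def count_significant(self) -> int:
        return int(self.per_district["significant"].sum())


def assess_all_districts(
    results,
    outcome: str,
    baseline_wave: int = 3,
    interim_wave: int = 5,
    fraction: float = PAPER_INTERIM_FRACTION,
    wasting_threshold: float = WASTING_THRESHOLD,
) -> TargetAssessment:
    """Apply the outcome's target rule to every district and roll up.

    ``results`` is a fitted :class:`~malnutmap.model.SpaceTimeCARResults` or
    a raw (draws, I, J) array of posterior prevalence draws.
    """
    draws = results if isinstance(results, np.ndarray) else results.pi_draws
    I = draws.shape[1]
    rows = []
    for d in range(1, I + 1):
        if outcome == "stunting":
            met, prob = assess_stunting_target(
                draws, d, baseline_wave, interim_wave, fraction
            )
        elif outcome in ("thinness_wasting", "wasting"):
            met, prob = assess_wasting_target(draws, d, interim_wave, wasting_threshold)
        elif outcome == "obesity":
            met, prob = assess_obesity_target(draws, d, baseline_wave, interim_wave)
        else:
            raise ValueError(f"unknown outcome {outcome!r}")
        rows.append(
            {
                "district_id": d,
                "met": met,
                "exceedance_prob": prob,
                "significant": is_significant(prob),
            }
        )
    per_district = pd.DataFrame(rows)
    count, percent = summarize_targets(per_district["met"])
    return TargetAssessment(
        outcome=outcome,
        per_district=per_district,
        count_met=count,
        percent_met=percent,
    )
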