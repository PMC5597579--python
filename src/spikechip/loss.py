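"""Minichromosome loss-rate estimation from colony retention counts.

The per-division loss rate inverts a geometric retention model: if a
fraction ``I`` of cells carry the minichromosome initially and ``F``
after ``N`` non-selective divisions, the per-division loss rate is

    rate (%) = 100 * (1 - (F / I)**(1/N))

Replicate colonies are summarized as the mean rate ± sample s.d.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import LossAssayObservation


@dataclass(frozen=True)
class ColonyRate:
    """Per-colony loss-rate estimate with an optional anomaly flag:
    ``complete_loss`` (F = 0, rate pinned at 100%) or ``gain`` (F > I,
    formally negative rate from scoring noise)."""

    colony_id: str
    rate_pct: float
    flag: str | None = None


@dataclass
class LossRateResult:
    per_colony: list[ColonyRate]
    mean_rate: float
    sd_rate: float  # NaN below two colonies
    n_colonies: int

    @property
    def rates(self) -> list[float]:
        return [c.rate_pct for c in self.per_colony]


def loss_rate(obs: LossAssayObservation) -> ColonyRate:
    """Per-division loss rate (%) of one colony.

    ``F = 0`` makes the formula undefined; the rate is reported as 100%
    with a ``complete_loss`` flag.  ``F > I`` (apparent gain from
    scoring noise) yields a negative rate with a ``gain`` flag.
    """
    if obs.final_pct == 0:
        return ColonyRate(obs.colony_id, 100.0, flag="complete_loss")
    rate = 100.0 * (
        1.0 - (obs.final_pct / obs.initial_pct) ** (1.0 / obs.n_divisions)
    )
    flag = "gain" if obs.final_pct > obs.initial_pct else None
    return ColonyRate(obs.colony_id, rate, flag=flag)


def aggregate_loss(
    observations: list[LossAssayObservation],
) -> LossRateResult:
    """Mean loss rate ± sample s.d. over independent colonies."""
    if not observations:
        raise ValueError("no observations")
    per_colony = [loss_rate(o) for o in observations]
    rates = np.array([c.rate_pct for c in per_colony])
    sd = float(np.std(rates, ddof=1)) if rates.size >= 2 else float("nan")
    return LossRateResult(
        per_colony=per_colony,
        mean_rate=float(rates.mean()),
        sd_rate=sd,
        n_colonies=rates.size,
    )
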