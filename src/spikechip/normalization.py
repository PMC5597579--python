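"""Spike-in (ChIP-Rx) calibration statistics and SES background scaling.

Two calibration modes operate on genome-split read totals:

* ``E^IP`` — the spike-in normalized IP/input ratio,
  ``(IP_exp/input_exp) / (IP_spike/input_spike)``; constant across
  samples for the spike-in control by design, so it calibrates the
  experimental signal.
* ``N`` — the multiplier rescaling a raw read-count ratio so it equals
  ``E^IP`` (IP vs input within a sample) or the ``E^IP`` ratio between
  conditions (mutant IP vs wild-type IP).

For targets assayed without a spike-in, signal extraction scaling (SES)
estimates a background scale from the maximal gap between the cumulative
IP and input signal curves over bins sorted by increasing IP signal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import BinnedTrack, SpikeInCounts


class UndefinedStatisticError(ZeroDivisionError):
    """A required read total is zero; the calibration is undefined."""


class DegenerateEnrichmentError(ValueError):
    """SES background contains no reads in IP or input."""


@dataclass(frozen=True)
class NormalizationResult:
    """A calibration constant: ``e_ip`` (the target ratio) and
    ``n_factor`` (the multiplier achieving it), with the mode recorded."""

    e_ip: float
    n_factor: float
    mode: str  # "ip_vs_input" | "mutant_vs_wt" | "ses"

    def __post_init__(self) -> None:
        if self.e_ip <= 0 or self.n_factor <= 0:
            raise ValueError("e_ip and n_factor must be positive")
        if self.mode not in {"ip_vs_input", "mutant_vs_wt", "ses"}:
            raise ValueError(f"unknown mode {self.mode!r}")


def compute_eip(c: SpikeInCounts) -> float:
    """Spike-in normalized IP/input ratio.

    ``E^IP = (ip_exp / input_exp) / (ip_spike / input_spike)``.
    Invariant under uniform depth rescaling of the IP library and of the
    input library; scales linearly with experimental-genome IP recovery.
    """
    if c.input_exp == 0 or c.ip_spike == 0 or c.input_spike == 0:
        raise UndefinedStatisticError(
            "E^IP undefined: input_exp, ip_spike and input_spike must be > 0 "
            f"(got {c})"
        )
    return (c.ip_exp / c.input_exp) / (c.ip_spike / c.input_spike)


def n_factor_ip_vs_input(c: SpikeInCounts) -> NormalizationResult:
    """Scaling factor N with ``N * ip_exp / input_exp = E^IP``."""
    e_ip = compute_eip(c)
    if c.ip_exp == 0:
        raise UndefinedStatisticError("N undefined when ip_exp = 0")
    n = e_ip * c.input_exp / c.ip_exp
    return NormalizationResult(e_ip=e_ip, n_factor=n, mode="ip_vs_input")


def n_factor_mut_vs_wt(
    c_mut: SpikeInCounts, c_wt: SpikeInCounts
) -> NormalizationResult:
    """Scaling factor N with ``N * ip_mut / ip_wt = E^IP_mut / E^IP_wt``.

    The resulting ``e_ip`` field holds the spike-calibrated mutant/wt
    fold change of the IP.
    """
    e_mut = compute_eip(c_mut)
    e_wt = compute_eip(c_wt)
    if c_mut.ip_exp == 0:
        raise UndefinedStatisticError("N undefined when mutant ip_exp = 0")
    if c_wt.ip_exp == 0:
        raise UndefinedStatisticError("N undefined when wild-type ip_exp = 0")
    ratio = e_mut / e_wt
    n = ratio * c_wt.ip_exp / c_mut.ip_exp
    return NormalizationResult(e_ip=ratio, n_factor=n, mode="mutant_vs_wt")


def ses_scale(ip: BinnedTrack, input_: BinnedTrack) -> float:
    """Signal-extraction-scaling factor for an IP/input pair.

    Bins are sorted ascending by IP signal; the cut index ``k*``
    maximizes (cumulative input fraction − cumulative IP fraction), with
    ties broken at the smallest index (the most conservative
    background).  Bins up to ``k*`` form the background, and the scale
    is ``(background IP / total IP) / (background input / total input)``
    — applied multiplicatively to the *input* track before ratio
    formation so that the background ratio becomes one.
    """
    if ip.bin_width != input_.bin_width or ip.layout is not input_.layout:
        if ip.layout.chromosomes != input_.layout.chromosomes:
            raise ValueError("tracks are on different layouts")
        if ip.bin_width != input_.bin_width:
            raise ValueError("tracks have different bin widths")
    ip_v = ip.concat()
    in_v = input_.concat()
    total_ip, total_in = ip_v.sum(), in_v.sum()
    if total_ip <= 0 or total_in <= 0:
        raise DegenerateEnrichmentError("both tracks need positive totals")
    order = np.argsort(ip_v, kind="stable")
    cum_ip = np.cumsum(ip_v[order]) / total_ip
    cum_in = np.cumsum(in_v[order]) / total_in
    gap = cum_in - cum_ip
    k_star = int(np.argmax(gap))  # first maximum
    bg_ip = float(np.sum(ip_v[order][: k_star + 1]))
    bg_in = float(np.sum(in_v[order][: k_star + 1]))
    if bg_ip <= 0 or bg_in <= 0:
        raise DegenerateEnrichmentError(
            "SES background has zero IP or input signal at the cut point"
        )
    return (bg_ip / total_ip) / (bg_in / total_in)
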