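"""Transition-state-theory (Eyring) barrier ↔ rate conversion.

k = (kB·T/h) · exp(−ΔG‡ / (kB_molar·T)), transmission coefficient fixed at 1.

The canonical worked example: an enzymatic turnover of 20 min⁻¹ at ~70 °C
(343.15 K) corresponds to an activation free energy of ≈ 20.9 kcal/mol.
Rates carry explicit unit tags ("1/s" or "1/min"); silent unit guessing is
deliberately impossible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .constants import KB_KCAL, KB_OVER_H

__all__ = ["RateResult", "rate_to_barrier", "barrier_to_rate", "RATE_UNITS"]

RATE_UNITS = {"1/s": 1.0, "s^-1": 1.0, "1/min": 1.0 / 60.0, "min^-1": 1.0 / 60.0}


@dataclass(frozen=True)
class RateResult:
    rate_per_s: float
    barrier_kcal_mol: float
    temperature_K: float
    transmission_coefficient: float = 1.0


def _to_per_second(k: float, unit: str) -> float:
    if unit not in RATE_UNITS:
        raise ValueError(f"unknown rate unit {unit!r}; use one of {sorted(RATE_UNITS)}")
    return k * RATE_UNITS[unit]


def rate_to_barrier(k: float, temperature: float, unit: str = "1/s") -> RateResult:
    """Activation free energy ΔG‡ (kcal/mol) implied by a first-order rate.

    ΔG‡ = kB_molar·T·ln((kB·T/h)/k); requires k > 0 and T > 0.
    """
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    k_s = _to_per_second(k, unit)
    if k_s <= 0:
        raise ValueError("rate constant must be positive")
    prefactor = KB_OVER_H * temperature
    barrier = KB_KCAL * temperature * math.log(prefactor / k_s)
    return RateResult(rate_per_s=k_s, barrier_kcal_mol=barrier, temperature_K=temperature)


def barrier_to_rate(barrier: float, temperature: float) -> RateResult:
    """First-order rate (s⁻¹) for an activation free energy ΔG‡ (kcal/mol)."""
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    k_s = KB_OVER_H * temperature * math.exp(-barrier / (KB_KCAL * temperature))
    return RateResult(rate_per_s=k_s, barrier_kcal_mol=float(barrier),
                      temperature_K=temperature)
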