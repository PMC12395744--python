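"""Bayesian combination of clinical absolute risk with a mean-1 PRS.

The clinical 5-year risk is treated as a prior probability; the centered
PRS (population mean ~1) acts as a likelihood-ratio multiplier on the
prior odds:

    posterior odds = prior odds * PRS**alpha,   alpha = 1 by default

A PRS of exactly 1 leaves the risk unchanged.  The optional attenuation
exponent ``alpha`` allows calibrations that shrink the PRS effect (for
example in women with strong family history); it is never applied by
default, matching a combined model with no PRS-by-family-history
interaction.
"""

from __future__ import annotations

__all__ = ["to_odds", "to_probability", "combine_bcsc_prs"]


def to_odds(p: float) -> float:
    """Convert a probability strictly inside (0, 1) to odds p/(1-p)."""
    if not 0.0 < p < 1.0:
        raise ValueError(f"probability {p} must lie strictly in (0, 1)")
    return p / (1.0 - p)


def to_probability(odds: float) -> float:
    """Inverse of :func:`to_odds`."""
    if not odds > 0:
        raise ValueError(f"odds {odds} must be > 0")
    return odds / (1.0 + odds)


def combine_bcsc_prs(bcsc_5yr: float, prs: float, attenuation: float = 1.0) -> float:
    """Posterior 5-year risk from prior risk and PRS.

    Parameters
    ----------
    bcsc_5yr:
        Clinical (prior) 5-year absolute risk, strictly in (0, 1).
    prs:
        Centered polygenic risk score, > 0.
    attenuation:
        Exponent alpha on the PRS in odds space; 1 (default) is the plain
        prior-odds multiplication.
    """
    if not prs > 0:
        raise ValueError(f"prs {prs} must be > 0")
    return to_probability(to_odds(bcsc_5yr) * prs**attenuation)
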