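"""Conversion of mutation-scaled divergence times to calendar years.

A divergence time reported on the substitutions-per-site scale
(t_scaled = t_generations × mu) is converted to years by dividing by the
per-site per-year mutation rate and multiplying by the generation time:

    years = t_scaled / mu × gen_time_years

With a one-year generation time this is the familiar t/mu rule.
"""

from __future__ import annotations

__all__ = ["convert_divergence_time"]


def convert_divergence_time(
    t_scaled: float, mu: float, gen_time_years: float = 1.0
) -> float:
    """Convert a substitutions-per-site divergence time to years.

    Parameters
    ----------
    t_scaled
        Divergence time on the mutation scale (substitutions per site).
    mu
        Mutation rate per site per year.
    gen_time_years
        Generation time in years (default 1, appropriate for small
        short-lived passerines).
    """
    if mu <= 0:
        raise ValueError("mutation rate mu must be > 0")
    if gen_time_years <= 0:
        raise ValueError("generation time must be > 0")
    return t_scaled / mu * gen_time_years
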