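"""Unit conversions. Global totals are reported in Pg C; per-area fluxes in
g C m^-2 d^-1. The g -> Pg conversion lives here and nowhere else."""

G_PER_PG = 1.0e15

#: Earth radius used for pixel areas, m.
EARTH_RADIUS_M = 6.371e6

#: Days per model year (365-day calendar, no leap days).
DAYS_PER_YEAR = 365


def grams_to_petagrams(g):
    """Convert grams (C or N) to petagrams."""
    return g / G_PER_PG
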