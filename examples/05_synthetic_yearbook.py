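"""Generate a synthetic yearbook-style series and validate against it.

Yearbook quantities grow roughly geometrically with small multiplicative
deviations.  The generator reproduces that structure, which makes the
validation arithmetic testable end to end: we generate a noisy series, treat
the noiseless compound-growth path as the "simulation", and compute the
same percent-error statistics used for real historical series.
"""

from ltcisim import (
    HistoricalPair,
    generate_yearbook_series,
    mean_absolute_error,
    mean_error,
)

years = range(2012, 2019)
noisy = generate_yearbook_series(x0=182.15, g=0.06, sigma=0.02, years=years, seed=42)
clean = generate_yearbook_series(x0=182.15, g=0.06, sigma=0.0, years=years, seed=42)

pairs = [
    HistoricalPair(year=y, actual=a, simulated=s, series="synthetic_insured")
    for y, a, s in zip(noisy.years, noisy.values, clean.values)
]

print(f"{'year':>6} {'actual (noisy)':>15} {'simulated (clean)':>18} {'error %':>9}")
for p in pairs:
    print(f"{p.year:>6} {p.actual:>15.2f} {p.simulated:>18.2f} {p.error:>9.3f}")

print(f"\nsigned mean error:   {mean_error(pairs):+.2f}%")
print(f"absolute mean error: {mean_absolute_error(pairs):.2f}%")
print(
    "\nwith sigma = 0.02 the absolute errors sit in the 1-2% band seen in "
    "real yearbook validation tables; the signed mean is near zero because "
    "the noise is centred on the growth path."
)
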