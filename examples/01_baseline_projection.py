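"""Project the LTCI fund balance under current policy settings.

Loads the packaged base-year parameters, calibrates the expenditure
escalation rate, and prints the 2019-2030 revenue/expenditure/balance
trajectory in millions of yuan.  The balance turns negative in 2030: the
fund runs its first annual deficit in the final simulated year.
"""

from ltcisim import (
    calibrate_escalation,
    deficit_year,
    simulate,
    table_fixtures,
    to_millions,
)

params, _ = table_fixtures()
params = params.replace(esc=calibrate_escalation(params))
print(f"calibrated escalation rate: {params.esc:.4f}/yr\n")

trajectory = simulate(params)
print(f"{'year':>6} {'revenue':>10} {'expenditure':>12} {'balance':>10}   (million yuan)")
for rec in trajectory:
    print(
        f"{rec.year:>6} {to_millions(rec.rev_total):>10.1f} "
        f"{to_millions(rec.expenditure):>12.1f} "
        f"{to_millions(rec.balance_annual):>10.1f}"
    )

print(f"\nfirst annual-deficit year: {deficit_year(trajectory, 'annual')}")
print(
    "revenue grows "
    f"{trajectory.record(2030).rev_total / trajectory.record(2019).rev_total:.1f}x, "
    "expenditure "
    f"{trajectory.record(2030).expenditure / trajectory.record(2019).expenditure:.1f}x "
    "over the horizon — expenditure outpaces revenue, so the fund tips into deficit."
)
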