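"""Choosing a common censoring day for batches that end at different times.

Uses the published batch summaries of the two brown-layer lines: a late
common day loses whole batches, an early day censors more of the survivors.
"""
from layersel import censorcv, datasets

for line, days in (("BD", [351.0, 372.0, 413.0]), ("B1", [372.0, 395.0, 414.0])):
    get = datasets.bd_batches if line == "BD" else datasets.b1_batches
    print(f"line {line}:")
    for day in days:
        out = censorcv.censoring_tradeoff(get(day), day)
        print(f"  day {day:5.0f}: {out.pct_censored:5.1f}% censored, "
              f"{out.pct_data_lost:5.1f}% of data lost "
              f"(n={out.n_total}, retained={out.n_retained})")
# The adopted compromises are 372 d for BD (40% censored, 32% lost) and
# 395 d for B1 (54% censored, 20% lost).
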