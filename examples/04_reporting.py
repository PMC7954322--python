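"""Reporting arithmetic on published life-expectancy point estimates.

Uses the bundled TLE/HLE point estimates at age 60 from the EPS, CRELES
and SHARE multistate analyses to reproduce the derived summaries such
analyses quote: healthy-years shares, gender gaps, and between-country
contrasts, plus a grouped table.
"""

from hale.reference import PUBLISHED_LE_AT_60, published_estimate
from hale.report import (build_le_table, format_le_table, group_difference,
                         percent_healthy)

print("healthy-years share at 60, men (100*HLE/TLE):")
for country in ("chile", "costa_rica", "spain"):
    vals = PUBLISHED_LE_AT_60[country]["men"]
    share = percent_healthy(vals["tle"], vals["hle"])
    print(f"  {country:11s} {share:.1f}%")

print("\ngender gaps in TLE at 60 (women - men, years):")
for country in ("chile", "costa_rica", "spain"):
    gap = group_difference(published_estimate(country, "women"),
                           published_estimate(country, "men"), "tle")
    print(f"  {country:11s} {gap:.1f}")

gap = group_difference(published_estimate("costa_rica", "men"),
                       published_estimate("spain", "men"), "tle")
print(f"\nCosta Rican men live {gap:.1f} years longer than Spanish men, "
      "yet spend a smaller share of those years healthy.")

table = build_le_table({
    country: {sex: published_estimate(country, sex)
              for sex in ("men", "women")}
    for country in ("chile", "costa_rica", "spain")})
print("\n" + format_le_table(table))
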