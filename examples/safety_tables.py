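"""Safety tabulation on a deterministic fixture roster.

Builds a 17-patient roster across three dose levels with known category
counts (15 any-TRAE, 4 grade >= 3, 3 serious, 3 DLT patients at the top
level) and re-tabulates it: each printed cell is "n (percentage)" with a
patient counted once per category at worst grade.
"""

import datetime as dt

from boindosim import exposure_duration_weeks, safety_summary
from boindosim.synthdata import build_fixture_roster

patients, attrs = build_fixture_roster([
    {"dl_index": 0, "n": 3, "cycle1_gbq": 1.85, "any_trae": 3, "male": 2},
    {"dl_index": 1, "n": 9, "cycle1_gbq": 9.25, "any_trae": 8, "serious_trae": 1,
     "male": 5},
    {"dl_index": 2, "n": 5, "cycle1_gbq": 11.1, "dlt": 3, "dlt_grades": [4, 3, 3],
     "grade3plus_trae": 4, "any_trae": 4, "serious_trae": 2, "male": 5},
])

table = safety_summary(
    patients, dl_labels={0: "1.85+5.55 GBq", 1: "9.25 GBq", 2: "11.1 GBq"}
)
print(table.to_string())

d0 = dt.date(2021, 3, 30)
print(f"\nsingle-cycle exposure: {exposure_duration_weeks(d0, d0):.2f} wk")
print(f"three 6-weekly cycles: "
      f"{exposure_duration_weeks(d0, d0 + dt.timedelta(days=84)):.2f} wk")
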