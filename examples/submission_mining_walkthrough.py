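"""Mine submission dates and principal investigators from flatfiles.

Generates a small GenBank-style flatfile with controlled authors and
submission dates, parses it back, and prints the monthly submission
series and the last-author ranking.
"""

import datetime as dt
import tempfile
from pathlib import Path

import xenqc as xq

text, _ = xq.make_flatfiles(
    n=40,
    authors=["Richardson,P.", "Zorn,A.M.", "Jones,K.", "Papalopulu,N."],
    date_range=(dt.date(2002, 1, 1), dt.date(2004, 12, 31)),
    seed=8,
    libraries=["XGC-tadpole", "NICHD-egg"],
)
with tempfile.TemporaryDirectory() as d:
    path = Path(d) / "records.gb"
    path.write_text(text)
    records = xq.parse_flatfile(path)

series, undated = xq.monthly_counts(records)
print("submissions per month (individual dates):")
for month, count in series:
    print(f"  {month}  {'#' * count} {count}")

lib_series, _ = xq.monthly_counts(records, group_by_library=True)
print("\npooled at each library's earliest submission month:")
for month, count in lib_series:
    print(f"  {month}  {count}")

ranking, unattributed = xq.rank_last_authors(records, top_n=5)
print("\nmost prolific submitters (last author of first listed publication):")
for count, author in ranking:
    print(f"  {count:3d}  {author}")
print(
    f"\n{len(records)} records, {undated} undated, {unattributed} without an "
    "extractable author; large-scale projects surface at the top of the "
    "ranking, individual labs below."
)
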