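"""Synthetic cohort generation and the long-format dataset schema.

Builds a 121-ROI cohort with tissue compositions drawn at the packaged
frequency table, assembles the long table (one row per ROI x wavelength) and
prints its summary: row counts, flag percentages and the most common tissue
compositions.
"""
import json

from hybridqc.schema import summarize
from hybridqc.synthetic import generate_cohort

res = generate_cohort(121, seed=7)
table = res["table"]
s = summarize(table)
print(f"rows: {s['n_rows']} (= 2 x {s['n_rois']} ROIs)")
print(f"columns: {', '.join(table.df.columns)}")
print(f"surgery {s['surgery']['pct']}%, skull {s['skull']['pct']}%, "
      f"hematoma {s['hematoma']['pct']}%")
top = sorted(s["composition_counts"].items(), key=lambda kv: -kv[1])[:5]
print("most common compositions:", json.dumps(dict(top)))
print("age mean {:.0f} (SD {:.0f}) years".format(s["age"]["mean"], s["age"]["sd"]))
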