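"""The nine bedside case presets and their expected verdicts.

Generates every preset (healthy H0 plus eight pathology-mimicking cases),
runs the evaluation pipeline, and tabulates observed vs. expected verdicts.
Every row should agree: the presets are the classifier's test surface.
"""
import logging

logging.disable(logging.WARNING)

from hybridqc.io import evaluate_case
from hybridqc.synthetic import CASE_IDS, generate_case

print(f"{'case':7s} {'TRS':22s} {'DCS':22s} description")
for cid in CASE_IDS:
    bundle = generate_case(cid, seed=1)
    preset = bundle["ground_truth"]
    report = evaluate_case(bundle)
    exp = preset.expected_verdicts
    trs = f"{report['trs']['label']} (exp {exp['trs']})"
    dcs = f"{report['dcs']['label']} (exp {exp['dcs']})"
    print(f"{cid:7s} {trs:22s} {dcs:22s} {preset.description.split(';')[0]}")
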