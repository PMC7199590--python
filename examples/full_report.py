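"""Run the whole pipeline — simulate, fit, compare, classify, test — in one call.

Produces the four-table report bundle (baseline characteristics, odds
ratios, added-value comparisons for three outcomes, trajectory-mortality
table) plus a provenance block; writes report.json / report.txt and the
generated CSVs when an output directory is given.
"""

from rdwprog import run_pipeline
from rdwprog.pipeline_report import render_text_report

bundle = run_pipeline(
    {"generator": {"n": 318, "seed": 1}},
    out_dir="scratch/example_report",
    quiet=True,
)
print(render_text_report(bundle))
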