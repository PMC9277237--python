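"""Run the whole pipeline into an output directory.

Writes the simulated tables, the index table, diel and cover summaries,
analysis_report.json, a plain-text results paragraph, three SVG figures
and a manifest with checksums. Equivalent CLI:

    cloverwatch run --out out/demo --seed 42
"""

from cloverwatch import run_pipeline
from cloverwatch.pipeline import format_report_text

report = run_pipeline("out/demo", seed=42)
print(format_report_text(report))
print("\noutputs:", ", ".join(sorted(report["manifest"]["outputs"])))
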