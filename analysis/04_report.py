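"""Tie the stages into one reproducible end-to-end run with a report.

Executes simulate -> clean -> workload -> precision -> adequacy -> report via
the pipeline orchestrator (fresh synthetic data, per-stage seeds derived from
one master seed), then prints where the report landed and the headline
numbers it contains.

Run:  python analysis/04_report.py [seed]
"""

import json
import pathlib
import sys

sys.path.insert(0, str(pathlib.Path(__file__).resolve().parents[1] / "src"))

from wardstaff.pipeline import RunConfig, run_pipeline

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 0
OUT = pathlib.Path(__file__).resolve().parents[1] / "results" / "run"


def main() -> None:
    run_dir = run_pipeline(RunConfig(outdir=str(OUT), seed=SEED))
    manifest = json.loads((run_dir / "manifest.json").read_text())
    print(json.dumps(manifest["stages"], indent=1))
    print(f"\nreport: {run_dir / 'report.md'}")


if __name__ == "__main__":
    main()
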