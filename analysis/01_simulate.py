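"""Generate the synthetic hospital fleet the rest of the analysis runs on.

Four hospitals, 20 medical/surgical units each, one year of unit-days: acuity
censuses whose establishment series carry realistic day-to-day variation,
deployed staffing around the tool-implied requirement, and next-morning
staffing-adequacy reports from the planted three-level outcome models.
Writes census.csv, staffing.csv, responses.csv, profiles.csv and the
truth.json sidecar under results/synthetic/.

Run:  python analysis/01_simulate.py [seed]
"""

import pathlib
import sys

sys.path.insert(0, str(pathlib.Path(__file__).resolve().parents[1] / "src"))

from wardstaff.simulate import generate_dataset, write_dataset

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 0
OUT = pathlib.Path(__file__).resolve().parents[1] / "results" / "synthetic"


def main() -> None:
    dataset = generate_dataset(seed=SEED)
    write_dataset(dataset, OUT)
    profiles = dataset["profiles"]
    responses = dataset["responses"]
    print(f"fleet: {profiles['hospital'].nunique()} hospitals, "
          f"{len(profiles)} units, {profiles['beds'].sum()} beds")
    print(f"unit-days with responses: {len(responses)}")
    rates = responses[["enough_staff", "care_left_undone", "breaks_missed"]].mean()
    print("marginal response rates:", rates.round(3).to_dict())
    print(f"tables written to {OUT}")


if __name__ == "__main__":
    main()
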