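#!/usr/bin/env python
"""Build the bedside decision table at the common cutoff (-7.2): for each
nadir balloon temperature (-30..-53 deg C) and unsuccessful-application
count (0..3), the minimal TTI that makes a vein test-positive, or an
always/never-test verdict. Writes results/decision_table.csv (long form)
and results/decision_table.txt (aligned grid)."""

from pathlib import Path

from cryoerc.erc_model import decision_table

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    ROOT.mkdir(exist_ok=True)
    table = decision_table()
    table.to_long_frame().to_csv(ROOT / "decision_table.csv", index=False)
    text = table.to_frame().to_string()
    (ROOT / "decision_table.txt").write_text(text + "\n")
    print(text)
    n_never = sum(c.kind.value == "never_test" for c in table.cells.values())
    n_always = sum(c.kind.value == "always_test" for c in table.cells.values())
    print(f"\n{n_always} always-test cells, {n_never} no-test cells, "
          f"{96 - n_always - n_never} TTI-threshold cells")


if __name__ == "__main__":
    main()
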