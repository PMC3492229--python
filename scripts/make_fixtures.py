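"""Regenerate the shipped synthetic fixture files under src/biopsymdp/data/.

The tables are synthetic stand-ins shaped like US life tables (other-cause
mortality) and SEER-style post-diagnosis survival (expected remaining life
by age for invasive disease and DCIS); the kernel is the versioned
ground-truth annual risk-score kernel.  Deterministic: rerunning reproduces
the same files.
"""

from pathlib import Path

import pandas as pd

from biopsymdp.model_core import Horizon
from biopsymdp.rewards import write_age_table
from biopsymdp.synthetic_data import default_true_kernel, make_fixture_tables
from biopsymdp.transitions import write_kernel

DATA = Path(__file__).resolve().parents[1] / "src" / "biopsymdp" / "data"


def main() -> None:
    DATA.mkdir(parents=True, exist_ok=True)
    horizon = Horizon()
    mortality, lump, terminal = make_fixture_tables(horizon)
    write_age_table(mortality.other_cause, DATA / "other_cause_mortality.csv")
    write_age_table(mortality.treated_bc, DATA / "treated_bc_mortality.csv")
    write_age_table(lump.invasive_expected_life, DATA / "invasive_expected_life.csv")
    write_age_table(lump.dcis_expected_life, DATA / "dcis_expected_life.csv")
    pd.DataFrame({"age": [horizon.terminal_age], "value": [terminal]}).to_csv(
        DATA / "terminal_reward.csv", index=False, float_format="%.12g"
    )
    write_kernel(default_true_kernel(), DATA / "base_kernel.csv")
    print(f"fixtures written to {DATA}")


if __name__ == "__main__":
    main()
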