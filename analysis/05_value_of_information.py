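"""Value-of-information analysis from the PSA sample.

Computes EVPI and regression-based EVPPI for the main parameter groups at
£20,000/QALY: which uncertainties would be most valuable to resolve before
adopting the triage test?
"""

from pathlib import Path

import pandas as pd

from cystotriage.cli import _DEFAULT_SUBSETS
from cystotriage.parameters import build_base_case
from cystotriage.sensitivity import run_psa
from cystotriage.voi import voi_table

OUT = Path(__file__).resolve().parents[1] / "results"
SEED = 1
N = 5000
WTP = 20000.0


def main() -> None:
    OUT.mkdir(exist_ok=True)
    params = build_base_case()
    sample = run_psa(params, n=N, seed=SEED, price_range=(50.0, 620.0))
    result = voi_table(sample, _DEFAULT_SUBSETS, WTP)

    rows = [{"subset": "ALL (EVPI)", "value_per_patient": result.evpi}]
    rows += [{"subset": k, "value_per_patient": v}
             for k, v in sorted(result.evppi.items(), key=lambda kv: -kv[1])]
    table = pd.DataFrame(rows)
    table.to_csv(OUT / "voi.csv", index=False)
    print(f"EVPI per patient at £{WTP:.0f}/QALY: £{result.evpi:.2f}")
    print(table.round(2).to_string(index=False))


if __name__ == "__main__":
    main()
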