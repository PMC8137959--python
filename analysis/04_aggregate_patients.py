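"""Collapse per-nucleus features to per-patient mean/std vectors.

Reads cell_shapes.csv from 03, writes patient_features.csv to scratch
and reports how strongly the per-patient mean elongation separates
patients who died from those censored (a first look at the signal the
survival model will formalize).
"""

from pathlib import Path

import pandas as pd

from nucmorph import io as nio
from nucmorph.aggregate import aggregate_patients, clean_clinical

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch" / "cohort"
RESULTS = ROOT / "results"


def main() -> None:
    cs = nio.read_cell_shapes(SCRATCH / "cell_shapes.csv")
    pf = aggregate_patients(cs)
    nio.write_table(pf, SCRATCH / "patient_features.csv")

    clinical = clean_clinical(pd.read_csv(SCRATCH / "clinical_data_cleaned.csv"))
    merged = clinical.merge(pf, on="patient_id")
    by_event = merged.groupby("FUS")[["elongation_mean", "esf_mean", "csf_mean"]].mean()
    RESULTS.mkdir(exist_ok=True)
    by_event.to_csv(RESULTS / "patient_features_by_outcome.csv")
    print(f"{len(pf)} patients aggregated ({pf.shape[1] - 1} feature columns)")
    print(by_event.round(4).to_string())
    d = by_event.loc[1, "elongation_mean"] - by_event.loc[0, "elongation_mean"]
    print(f"\nfinding: deceased patients' nuclei are more elongated on average "
          f"(mean elongation difference {d:+.3f}), consistent with the "
          "shape -> hazard coupling built into the generator.")


if __name__ == "__main__":
    main()
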