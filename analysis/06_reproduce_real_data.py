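"""Optional: rerun the validation on a real DLBCL-Morph download.

Point --data-root at a directory containing Cells/ and
clinical_data_cleaned.csv (the public dataset's layout); the pipeline
then recomputes per-nucleus features, patient aggregation, and the
optimism-corrected C-indices for the three feature sets with the full
1000 bootstrap replicates.  This script is not part of the synthetic
analysis and requires the external download.
"""

import argparse
from pathlib import Path

from nucmorph.pipeline import PipelineConfig, run_pipeline


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--data-root", type=Path, required=True)
    ap.add_argument("--out-dir", type=Path, default=Path("scratch/real_data_out"))
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--n-bootstrap", type=int, default=1000)
    args = ap.parse_args()

    cfg = PipelineConfig(
        out_dir=str(args.out_dir),
        cells_dir=str(args.data_root / "Cells"),
        clinical_csv=str(args.data_root / "clinical_data_cleaned.csv"),
        n_bootstrap=args.n_bootstrap,
        seed=args.seed,
    )
    report = run_pipeline(cfg)
    for fs, r in report.items():
        print(
            f"{fs}: corrected C = {r['corrected_c']:.3f} "
            f"({r['ci_low']:.3f}, {r['ci_high']:.3f})"
        )


if __name__ == "__main__":
    main()
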