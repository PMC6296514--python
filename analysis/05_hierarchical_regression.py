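#!/usr/bin/env python
"""Predict decoding skill from connectivity metrics, per scheme.

Two-step hierarchical OLS (nuisance: age, accuracy, latency; then the
nine metric x modality predictors), nested F test for the connectivity
increment, and the LMG relative-importance decomposition with bootstrap
contrasts.  Writes coefficient, share, and contrast tables per scheme to
results/regression/ and prints the model summaries.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from readnet import fit_hierarchical, importance_contrasts
from readnet.inference import build_design
from readnet.simulate import read_subjects

ROOT = Path(__file__).resolve().parent.parent


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--metrics", type=Path, default=ROOT / "results" / "metrics_aggregated.csv")
    ap.add_argument("--subjects", type=Path,
                    default=ROOT / "results" / "cohort" / "subjects.csv")
    ap.add_argument("--out", type=Path, default=ROOT / "results" / "regression")
    ap.add_argument("--bootstrap", type=int, default=1000)
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()

    table = pd.read_csv(args.metrics)
    subjects = read_subjects(args.subjects)
    args.out.mkdir(parents=True, exist_ok=True)

    for scheme in ("significance", "mcc"):
        fit = fit_hierarchical(subjects, table, scheme)
        X, y, added = build_design(subjects, table, scheme)
        imp = importance_contrasts(
            X, y, contrast_cols=added, n_boot=args.bootstrap, seed=args.seed
        )
        fit.coef_table.to_csv(args.out / f"coefficients_{scheme}.csv")
        imp.shares.to_csv(args.out / f"importance_shares_{scheme}.csv")
        imp.contrasts.to_csv(args.out / f"importance_contrasts_{scheme}.csv", index=False)
        (args.out / f"summary_{scheme}.json").write_text(
            json.dumps(fit.summary_dict(), indent=2, sort_keys=True)
        )
        d = fit.summary_dict()
        print(
            f"[{scheme}] step 1 (nuisance): F({d['step1']['df'][0]},{d['step1']['df'][1]})"
            f"={d['step1']['f']:.2f}, p={d['step1']['p']:.2f}, adjR2={d['step1']['adj_r2']:.3f}"
        )
        print(
            f"[{scheme}] step 2 (+9 metrics): F({d['step2']['df'][0]},{d['step2']['df'][1]})"
            f"={d['step2']['f']:.2f}, p={d['step2']['p']:.3f}, adjR2={d['step2']['adj_r2']:.3f}"
        )
        print(
            f"[{scheme}] increment: F({d['delta']['df'][0]},{d['delta']['df'][1]})"
            f"={d['delta']['f']:.2f}, p={d['delta']['p']:.3f}; "
            f"{int(imp.contrasts['significant'].sum())} significant importance contrast(s)"
        )


if __name__ == "__main__":
    main()
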