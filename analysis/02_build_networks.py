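#!/usr/bin/env python
"""Binarize every run's correlation matrix under both thresholding schemes.

Reads the time series written by 01_simulate_cohort.py, computes zero-lag
Pearson correlation matrices, and writes 0/1 adjacencies for the
significance scheme (p < .05, two-sided, uncorrected) and the minimum
connected component to results/networks/.  Prints the edge-count contrast
between the two schemes — the significance networks are dense, the MCC
networks sparse by construction.
"""

import argparse
from pathlib import Path

import numpy as np

from readnet import correlation_matrix, mcc_threshold, significance_threshold
from readnet.connectivity import load_cohort_timeseries, write_adjacency

ROOT = Path(__file__).resolve().parent.parent


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--cohort", type=Path, default=ROOT / "results" / "cohort")
    ap.add_argument("--out", type=Path, default=ROOT / "results" / "networks")
    ap.add_argument("--alpha", type=float, default=0.05)
    args = ap.parse_args()

    runs = load_cohort_timeseries(args.cohort / "timeseries")
    args.out.mkdir(parents=True, exist_ok=True)
    counts = {"significance": [], "mcc": []}
    for run in runs:
        corr = correlation_matrix(run)
        for scheme, net in (
            ("significance", significance_threshold(corr, alpha=args.alpha)),
            ("mcc", mcc_threshold(corr)),
        ):
            name = f"{run.subject_id}_{run.modality}_run{run.run_index}_{scheme}.tsv"
            write_adjacency(args.out / name, net)
            counts[scheme].append(net.n_edges)
    n_pairs = runs[0].n_nodes * (runs[0].n_nodes - 1) // 2
    for scheme, c in counts.items():
        print(
            f"{scheme}: mean {np.mean(c):.0f} edges of {n_pairs} possible "
            f"(density {np.mean(c) / n_pairs:.2f})"
        )


if __name__ == "__main__":
    main()
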