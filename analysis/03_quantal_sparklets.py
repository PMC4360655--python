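#!/usr/bin/env python
"""Quantal sparklet analysis on a synthetic TIRF movie.

Simulates a 100-Hz calibrated Ca2+ sparklet movie with two planted sites
(38 nM quantal amplitude), detects sites, fits the all-points-histogram
quantal mixture per site and reports nPs against the planted truth.
"""

import argparse
from pathlib import Path

import pandas as pd

from cavcoupling.idealize import fit_quantal_mixture
from cavcoupling.imaging import detect_sparklet_sites
from cavcoupling.io import write_stack, write_table
from cavcoupling.synthetic import GatingParams, simulate_sparklet_movie


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    centers = [(14.0, 14.0), (30.0, 27.0)]
    sites_spec = [
        (c, GatingParams(n_channels=2, p_co=0.02, p_oc=0.05, kappa=0.3,
                         amplitude=38.0, noise_sd=0.0, fs=100.0, duration=5.0,
                         seed=args.seed * 10 + i))
        for i, c in enumerate(centers)
    ]
    movie, truths = simulate_sparklet_movie(
        sites_spec, noise_sd=38.0 / 5.0, seed=args.seed
    )
    write_stack(args.out / "sparklet_movie.tif", movie)

    sites = detect_sparklet_sites(movie)
    rows = []
    for i, s in enumerate(sites):
        # quantal spacing from the peak pixel: the site's 3x3-average trace
        # carries a PSF-attenuated quantum, the peak pixel the full 38 nM
        peak_trace = movie.frames[:, s.center[0], s.center[1]]
        fit = fit_quantal_mixture(peak_trace, max_levels=5)
        rows.append({
            "site": i, "row": s.center[0], "col": s.center[1],
            "nPs": s.nps.value, "n_quantal_levels": s.n_quantal_levels,
            "q_hat_nM": fit.q,
        })
    df = pd.DataFrame(rows)
    write_table(args.out / "sparklet_sites.csv", df)
    print(f"planted {len(truths)} sites, detected {len(sites)}")
    print(df)
    for i, tr in enumerate(truths):
        print(f"truth site {i}: nPs = {tr.mean():.4f}")


if __name__ == "__main__":
    main()
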