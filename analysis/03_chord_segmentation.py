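"""Chord-segment the phantom myocardium and extract sector profiles.

Divides each slice into 20 wedges × 5 radial sections about the cardiac
centroid and tabulates mean signal per sector on the longest-TSL (48 ms)
weighted image, where scar/myocardium contrast is highest.  The normalized
mid-myocardial (sections 2–4) profile shows the infarct arc as the bright
wedges.  Writes the sector tables under results/chords/.
"""

from pathlib import Path

import numpy as np

from t1rho_infarct import PhantomConfig, add_noise, build_chord_grid, \
    generate_phantom, sector_signal, simulate_tsl_series

OUT = Path(__file__).resolve().parents[1] / "results" / "chords"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = PhantomConfig(n_slices=10, seed=3)
    truth = generate_phantom(cfg)
    series = add_noise(simulate_tsl_series(truth, cfg), cfg.noise_sigma,
                       cfg.seed)
    grid = build_chord_grid(truth.contours, truth.myocardial_mask)
    sectors = sector_signal(grid, series.data[..., -1])
    sectors.table.to_csv(OUT / "sector_table.csv", index=False)
    sectors.midwall.to_csv(OUT / "midwall_profile.csv", index=False)

    profile = (sectors.midwall.groupby("wedge")["normalized"].mean())
    bright = profile[profile > 0.8].index.tolist()
    arc = (cfg.arc_start_deg % 360,
           (cfg.arc_start_deg + cfg.infarct_angular_extent) % 360)
    print(f"{len(sectors.table)} sectors over {cfg.n_slices} slices "
          f"({grid.n_fallback} depth-clamped pixels)")
    print("normalized mid-wall profile by wedge (48 ms TSL):")
    with np.printoptions(precision=2):
        print(" ", np.array(profile))
    print(f"wedges above 0.8 of max: {bright} "
          f"(true infarct arc {arc[0]:.0f}-{arc[1]:.0f} deg)")
    print(f"wrote tables to {OUT}")


if __name__ == "__main__":
    main()
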